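"""miRNA-target network: filter interactions, count bipartite degrees.

Uses the bundled synthetic interaction fixture (invented edges over real
lung-cancer gene symbols) to show the filtering rules: keep only
experimentally observed or high-confidence predicted edges of signature
miRNAs that are disease-associated, then list hub miRNAs (>10 targets)
and hub genes (regulated by >5 signature miRNAs).
"""

from ebcpanel.network import degree_summary, filter_edges, load_example_interactions

interactions = load_example_interactions()
signature = sorted(interactions["mirna"].unique())
print(f"interaction table: {len(interactions)} edges, "
      f"{interactions['mirna'].nunique()} miRNAs, {interactions['gene'].nunique()} genes")

edges = filter_edges(interactions, signature)
print(f"after evidence/disease filtering: {len(edges)} edges")

summary = degree_summary(edges, mirna_threshold=10, gene_threshold=5)
print(f"miRNAs with more than 10 retained targets: {summary.hub_mirnas}")
print(f"genes regulated by more than 5 signature miRNAs: {summary.hub_genes}")
print("top target counts per miRNA:")
print(summary.mirna_degree.sort_values(ascending=False).head(5).to_string())
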