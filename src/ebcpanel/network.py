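"""miRNA-target interaction filtering and bipartite degree summaries.

Works on a user-supplied interaction table (miRNA, gene, evidence level,
disease-association flag).  Edges are kept when the miRNA belongs to the
signature of interest, the evidence is experimentally observed or
high-confidence predicted, and the target has a disease association.
Degree summaries count, per miRNA, how many retained targets it hits and,
per gene, how many signature miRNAs regulate it; the highlight lists use
strict thresholds (more than ``mirna_threshold`` targets / more than
``gene_threshold`` regulators).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "EVIDENCE_LEVELS",
    "EVIDENCE_KEPT",
    "read_interaction_table",
    "load_example_interactions",
    "filter_edges",
    "degree_summary",
    "NetworkSummary",
]

EVIDENCE_LEVELS = (
    "experimentally_observed",
    "high_confidence_predicted",
    "low_confidence_predicted",
)
EVIDENCE_KEPT = EVIDENCE_LEVELS[:2]
_EVIDENCE_RANK = {e: i for i, e in enumerate(EVIDENCE_LEVELS)}

_COLUMNS = ["mirna", "gene", "evidence", "lung_cancer_associated"]


def read_interaction_table(path) -> pd.DataFrame:
    """Read a miRNA->gene interaction TSV and validate its vocabulary."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    return validate_interactions(df)


def validate_interactions(df: pd.DataFrame) -> pd.DataFrame:
    bad = ~df["evidence"].isin(EVIDENCE_LEVELS)
    if bad.any():
        i = int(df.index[bad][0])
        raise ValueError(
            f"unknown evidence label {df.loc[i, 'evidence']!r} in row {i}"
        )
    out = df.copy()
    col = out["lung_cancer_associated"]
    if col.dtype != bool:
        mapping = {"true": True, "false": False, "1": True, "0": False,
                   "yes": True, "no": False}
        parsed = col.astype(str).str.strip().str.lower().map(mapping)
        if parsed.isna().any():
            i = int(col.index[parsed.isna()][0])
            raise ValueError(
                f"unparseable lung_cancer_associated value {col.loc[i]!r} in row {i}"
            )
        out["lung_cancer_associated"] = parsed.astype(bool)
    return out


def load_example_interactions() -> pd.DataFrame:
    """Bundled synthetic interaction fixture (invented edges over real
    lung-cancer gene symbols); illustrative only, not curated biology."""
    with resources.files("ebcpanel.data").joinpath(
        "synthetic_lung_cancer_targets.tsv"
    ).open() as fh:
        return validate_interactions(pd.read_csv(fh, sep="\t"))


def filter_edges(table: pd.DataFrame, mirnas_of_interest) -> pd.DataFrame:
    """Keep high-evidence, disease-associated edges of the signature miRNAs.

    Duplicate (miRNA, gene) pairs collapse to a single edge carrying the
    strongest evidence.  Filtering is idempotent.
    """
    df = validate_interactions(table)
    keep = set(mirnas_of_interest)
    df = df[
        df["mirna"].isin(keep)
        & df["evidence"].isin(EVIDENCE_KEPT)
        & df["lung_cancer_associated"]
    ].copy()
    df["_rank"] = df["evidence"].map(_EVIDENCE_RANK)
    df = (
        df.sort_values(["mirna", "gene", "_rank"], kind="stable")
        .drop_duplicates(subset=["mirna", "gene"], keep="first")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return df


@dataclass
class NetworkSummary:
    mirna_degree: pd.Series  # targets per signature miRNA
    gene_degree: pd.Series  # regulators per gene
    hub_mirnas: list[str]  # degree > mirna_threshold
    hub_genes: list[str]  # degree > gene_threshold
    n_edges: int

    def to_dict(self) -> dict:
        return {
            "n_edges": self.n_edges,
            "mirna_degree": {k: int(v) for k, v in self.mirna_degree.items()},
            "gene_degree": {k: int(v) for k, v in self.gene_degree.items()},
            "hub_mirnas": self.hub_mirnas,
            "hub_genes": self.hub_genes,
        }


def degree_summary(
    filtered: pd.DataFrame,
    mirna_threshold: int = 10,
    gene_threshold: int = 5,
) -> NetworkSummary:
    """Bipartite degrees of the retained edge set.

    Highlight lists use strict inequality: miRNAs with more than
    ``mirna_threshold`` targets and genes regulated by more than
    ``gene_threshold`` signature miRNAs.  Degree totals on both sides
    equal the number of edges.
    """
    md = filtered["mirna"].value_counts().sort_index() if len(filtered) else pd.Series(dtype=int)
    gd = filtered["gene"].value_counts().sort_index() if len(filtered) else pd.Series(dtype=int)
    return NetworkSummary(
        mirna_degree=md,
        gene_degree=gd,
        hub_mirnas=sorted(md.index[md > mirna_threshold]),
        hub_genes=sorted(gd.index[gd > gene_threshold]),
        n_edges=int(len(filtered)),
    )
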