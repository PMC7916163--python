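"""End-to-end orchestration: simulate -> preprocess -> DE -> panel -> network.

A :class:`RunConfig` (YAML-loadable) describes either a simulation or
paths to existing probe-level data, the contrasts to analyse, the
thresholds, and the master seed.  :func:`run_all` executes every stage
for every contrast, writes each intermediate artifact before the next
stage reads it, and emits a reproducibility manifest with input hashes,
seeds and per-stage row counts plus a summary table (per contrast:
selected trio, AUC, specificity, sensitivity).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import filter_top_abundance
from .network import degree_summary, filter_edges, load_example_interactions, read_interaction_table
from .preprocess import ExpressionMatrix, run_preprocessing
from .selection import RFConfig, run_panel_discovery
from .simulate import (
    EffectSpec,
    NoiseModel,
    PlatformSpec,
    make_study_design,
    read_probe_table,
    simulate_dataset,
    write_probe_table,
    write_truth,
)

__all__ = ["RunConfig", "ConfigError", "DataError", "run_all"]

log = logging.getLogger(__name__)

DEFAULT_CONTRASTS = ("cancer", "histology", "stage", "invasion", "outcome_500d")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    # simulation parameters (used when probe_table_path is None)
    probe_table_path: Path | None = None
    metadata_path: Path | None = None
    n_probesets: int = 2000
    n_human_mirnas: int = 500
    probes_per_set: int = 4
    n_healthy: int = 21
    n_cancer: int = 21
    planted_per_contrast: int = 3
    planted_log2_shift: float = 1.5
    # analysis thresholds
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    p_threshold: float = 0.05
    filter_fraction: float = 0.05
    target_k: int = 3
    n_trees: int = 500
    interactions_path: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(doc) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        if "out_dir" not in doc:
            raise ConfigError("config must set out_dir")
        for key in ("out_dir", "probe_table_path", "metadata_path", "interactions_path"):
            if doc.get(key) is not None:
                doc[key] = Path(doc[key])
        if "contrasts" in doc:
            doc["contrasts"] = tuple(doc["contrasts"])
        return cls(**doc)

    def validate(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ConfigError("p_threshold must be in (0,1)")
        if not (0 < self.filter_fraction < 1):
            raise ConfigError("filter_fraction must be in (0,1)")
        if self.target_k < 1:
            raise ConfigError("target_k must be >= 1")
        bad = [c for c in self.contrasts if c not in DEFAULT_CONTRASTS]
        if bad:
            raise ConfigError(f"unknown contrast column(s): {bad}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _plant_effects(config: RunConfig, platform: PlatformSpec, noise: NoiseModel) -> list[EffectSpec]:
    """Plant `planted_per_contrast` effects per contrast on distinct
    high-abundance human miRNAs, so the planted features survive the
    top-abundance filter and each contrast has its own signature."""
    from .simulate import high_abundance_human_indices

    total = config.planted_per_contrast * len(config.contrasts)
    top = high_abundance_human_indices(platform, noise, config.seed, total)
    effects = []
    it = iter(top)
    for contrast in config.contrasts:
        for _ in range(config.planted_per_contrast):
            effects.append(
                EffectSpec(
                    mirna_index=int(next(it)),
                    log2_shift=config.planted_log2_shift,
                    group_factor=contrast,
                )
            )
    return effects


def run_all(config: RunConfig) -> Path:
    """Execute the whole pipeline; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "stages": {},
        "input_hashes": {},
    }

    # ---- stage: obtain probe-level data -------------------------------
    if config.probe_table_path is not None:
        if config.metadata_path is None:
            raise ConfigError("metadata_path required with probe_table_path")
        table = read_probe_table(config.probe_table_path)
        metadata = pd.read_csv(config.metadata_path)
        manifest["input_hashes"]["probe_table"] = _sha256(Path(config.probe_table_path))
        manifest["input_hashes"]["metadata"] = _sha256(Path(config.metadata_path))
    else:
        platform = PlatformSpec(
            n_probesets=config.n_probesets,
            n_human_mirnas=config.n_human_mirnas,
            probes_per_set=config.probes_per_set,
        )
        metadata = make_study_design(config.n_healthy, config.n_cancer, seed=config.seed)
        noise = NoiseModel()
        effects = _plant_effects(config, platform, noise)
        table, truth = simulate_dataset(
            platform, metadata, effects, noise, seed=config.seed
        )
        write_probe_table(table, out / "probe_table.tsv")
        metadata.to_csv(out / "metadata.csv", index=False)
        write_truth(truth, out / "truth.yaml")
    missing = [c for c in config.contrasts if c not in metadata.columns]
    if missing:
        raise ConfigError(f"metadata lacks contrast column(s): {missing}")
    manifest["stages"]["simulate_or_load"] = {
        "n_probes": len(table.probes),
        "n_samples": len(table.sample_ids),
    }
    log.info("probe data ready: %d probes x %d samples", len(table.probes),
             len(table.sample_ids))

    # ---- stage: preprocessing -----------------------------------------
    expr, qc = run_preprocessing(table)
    expr.to_tsv(out / "expression.tsv")
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc.to_dict(), fh, indent=1)
    manifest["stages"]["preprocess"] = {"n_probesets": len(expr.values)}

    # ---- stage: abundance filter --------------------------------------
    expr = ExpressionMatrix.from_tsv(out / "expression.tsv")
    filt = filter_top_abundance(expr, fraction=config.filter_fraction)
    filtered = filt.subset(expr)
    filtered.to_csv(out / "filtered_expression.tsv", sep="\t", index_label="mirna_id")
    manifest["stages"]["filter"] = {"n_retained": len(filt.retained)}

    # ---- stage: per-contrast panel discovery --------------------------
    summary_rows = []
    all_selected: set[str] = set()
    for ci, contrast in enumerate(config.contrasts):
        rf = RFConfig(n_trees=config.n_trees, seed=config.seed + 10007 * (ci + 1))
        try:
            report = run_panel_discovery(
                filtered,
                metadata,
                contrast,
                rf,
                alpha=config.p_threshold,
                target_k=config.target_k,
            )
        except ValueError as exc:
            raise DataError(f"contrast {contrast!r}: {exc}") from exc
        cdir = out / f"contrast_{contrast}"
        cdir.mkdir(exist_ok=True)
        report.de.table.to_csv(cdir / "de_table.tsv", sep="\t", index_label="mirna_id")
        with open(cdir / "selection_trace.json", "w") as fh:
            json.dump(report.trace.to_dict(), fh, indent=1)
        report.subset_eval.to_frame().to_csv(cdir / "subset_eval.csv", index=False)
        with open(cdir / "panel_model.json", "w") as fh:
            json.dump(
                {
                    "coef": {k: float(v) for k, v in report.panel.coef.items()},
                    "separation": report.panel.separation,
                    "converged": report.panel.converged,
                    "positive_class": report.panel.positive_class,
                },
                fh,
                indent=1,
            )
        for f, roc in report.roc_individual.items():
            roc.to_frame().to_csv(cdir / f"roc_{f}.csv", index=False)
        report.roc_panel.to_frame().to_csv(cdir / "roc_panel.csv", index=False)
        report.roc_panel_loocv.to_frame().to_csv(cdir / "roc_panel_loocv.csv", index=False)
        with open(cdir / "report.json", "w") as fh:
            json.dump(report.summary(), fh, indent=1)
        summary_rows.append(
            {
                "contrast": contrast,
                "case": report.case,
                "control": report.control,
                "panel": "+".join(report.trace.selected),
                "n_regulated": len(report.regulated),
                "auc": round(report.roc_panel.auc, 3),
                "specificity": round(report.roc_panel.youden_specificity, 3),
                "sensitivity": round(report.roc_panel.youden_sensitivity, 3),
            }
        )
        all_selected.update(report.trace.selected)
        manifest["stages"][f"contrast_{contrast}"] = {
            "n_regulated": len(report.regulated),
            "panel": report.trace.selected,
        }
        log.info("contrast %s done: panel=%s auc=%.3f", contrast,
                 report.trace.selected, report.roc_panel.auc)

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "panel_summary.csv", index=False)

    # ---- stage: target network ----------------------------------------
    if config.interactions_path is not None:
        inter = read_interaction_table(config.interactions_path)
        manifest["input_hashes"]["interactions"] = _sha256(Path(config.interactions_path))
    else:
        inter = load_example_interactions()
    edges = filter_edges(inter, all_selected)
    net = degree_summary(edges)
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    with open(out / "network_summary.json", "w") as fh:
        json.dump(net.to_dict(), fh, indent=1)
    manifest["stages"]["network"] = {"n_edges": net.n_edges}

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
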