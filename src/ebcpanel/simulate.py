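"""Synthetic probe-level miRNA array data with known ground truth.

The generator emulates an Affymetrix-like miRNA platform: a few tens of
thousands of probe sets (a subset of which interrogate human mature
miRNAs), several replicate probes per set, and raw fluorescence that is
an additive mixture of a normal optical background and an exponentially
distributed true-signal component.  That normal + exponential mixture is
exactly the convolution model the downstream background-correction step
assumes, so parameter recovery is a meaningful end-to-end check.

Every dataset carries a :class:`SyntheticTruth` sidecar recording the
per-group true mean log2 level of every human miRNA and the planted
differential effects, so downstream inference can be scored against
ground truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PlatformSpec",
    "EffectSpec",
    "NoiseModel",
    "SyntheticTruth",
    "ProbeTable",
    "make_study_design",
    "simulate_dataset",
    "write_probe_table",
    "read_probe_table",
    "write_truth",
    "read_truth",
    "POSITIVE_LEVELS",
]

#: For each metadata column of the study design, the level that carries a
#: planted effect when an EffectSpec does not name one explicitly.  The
#: convention matches the contrasts' case groups (patients, SCC, advanced
#: stage, invasive, deceased).
POSITIVE_LEVELS = {
    "cancer": "cancer",
    "histology": "SCC",
    "stage": "IV",
    "invasion": "yes",
    "outcome_500d": "deceased",
}


@dataclass(frozen=True)
class PlatformSpec:
    """Array geometry: probe sets, human-miRNA subset, replicate probes.

    Defaults mirror a genome-wide miRNA chip with 30,424 probe sets of
    which 2,578 interrogate human mature miRNAs.
    """

    n_probesets: int = 30424
    n_human_mirnas: int = 2578
    probes_per_set: int = 4

    def __post_init__(self) -> None:
        if self.n_probesets < 1 or self.n_human_mirnas < 1 or self.probes_per_set < 1:
            raise ValueError("all platform counts must be >= 1")
        if self.n_human_mirnas > self.n_probesets:
            raise ValueError(
                f"n_human_mirnas ({self.n_human_mirnas}) exceeds "
                f"n_probesets ({self.n_probesets})"
            )


@dataclass(frozen=True)
class EffectSpec:
    """A planted differential effect on one human miRNA.

    ``log2_shift`` is added to the true log2 level of samples whose
    metadata column ``group_factor`` equals ``group_level`` (defaulting
    to the case level of that factor, see :data:`POSITIVE_LEVELS`).
    """

    mirna_index: int
    log2_shift: float
    group_factor: str = "cancer"
    group_level: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_shift):
            raise ValueError("log2_shift must be finite")

    def resolved_level(self) -> str:
        if self.group_level is not None:
            return self.group_level
        try:
            return POSITIVE_LEVELS[self.group_factor]
        except KeyError:
            raise ValueError(
                f"no default case level for factor {self.group_factor!r}; "
                "pass group_level explicitly"
            ) from None


@dataclass(frozen=True)
class NoiseModel:
    """Noise structure of the simulated fluorescence.

    observed = N(bg_mean, bg_sd^2) + A * 2**(shift + affinity + eps)

    where A ~ Exponential(rate=signal_rate) is the probe set's base
    abundance (drawn once per set, giving the heavy-tailed log-scale
    abundance heterogeneity real arrays show), ``affinity`` is a fixed
    per-probe offset ~ N(0, probe_affinity_sd^2) (drawn once, so median
    polish has a probe structure to remove), and eps ~ N(0, probe_sd^2)
    is per-observation log-scale noise.
    """

    bg_mean: float = 100.0
    bg_sd: float = 20.0
    signal_rate: float = 1.0 / 200.0
    probe_sd: float = 0.25
    probe_affinity_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.bg_sd <= 0:
            raise ValueError("bg_sd must be > 0")
        if self.signal_rate <= 0:
            raise ValueError("signal_rate must be > 0")
        if self.probe_sd < 0 or self.probe_affinity_sd < 0:
            raise ValueError("probe noise sds must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset (regenerable from the seed)."""

    seed: int
    mirna_ids: list[str]
    group_factor_levels: dict[str, list[str]]
    #: per-miRNA true mean log2 level for each (factor, level) cell actually
    #: used by a planted effect, plus the shared baseline.
    baseline_log2: dict[str, float] = field(default_factory=dict)
    effects: list[EffectSpec] = field(default_factory=list)

    def true_log2_mean(self, mirna_id: str, factor: str, level: str) -> float:
        """True mean log2 signal of one miRNA in one group."""
        mu = self.baseline_log2[mirna_id]
        idx = self.mirna_ids.index(mirna_id)
        for e in self.effects:
            if (
                e.mirna_index == idx
                and e.group_factor == factor
                and e.resolved_level() == level
            ):
                mu += e.log2_shift
        return mu


@dataclass
class ProbeTable:
    """Probe-level raw intensities plus annotation.

    ``probes`` has columns probe_id, probeset_id, species; ``intensities``
    is a probes x samples array aligned with ``probes`` rows and
    ``sample_ids``.
    """

    probes: pd.DataFrame
    intensities: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.probes["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.intensities.shape != (len(self.probes), len(self.sample_ids)):
            raise ValueError("intensity matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = self.probes.copy()
        for j, s in enumerate(self.sample_ids):
            df[s] = self.intensities[:, j]
        return df

    def equals(self, other: "ProbeTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.probes.equals(other.probes)
            and np.array_equal(self.intensities, other.intensities)
        )


def make_study_design(
    n_healthy: int = 21,
    n_cancer: int = 21,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample metadata shaped like a case/control lung-cancer cohort.

    Columns: sample_id, cancer (healthy/cancer), histology (AD/SCC, NA
    for controls), stage (I-III/IV, NA for controls), invasion (yes/no),
    outcome_500d (alive/deceased/missing).  Clinical attributes are
    assigned to patients in roughly the cohort proportions reported for
    the study this emulates (11 AD / 10 SCC, 10 stage I-III / 11 stage
    IV, ~half invasive, 10 deceased / 8 alive / 3 missing at 500 days),
    shuffled deterministically by ``seed`` so attributes are not
    confounded with sample order.
    """
    if n_healthy < 2 or n_cancer < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_healthy):
        rows.append(
            {
                "sample_id": f"HD{i + 1:02d}",
                "cancer": "healthy",
                "histology": "NA",
                "stage": "NA",
                "invasion": "NA",
                "outcome_500d": "NA",
            }
        )

    def split(n: int, k: int, a: str, b: str) -> list[str]:
        lab = [a] * k + [b] * (n - k)
        rng.shuffle(lab)
        return lab

    histology = split(n_cancer, round(n_cancer * 11 / 21), "AD", "SCC")
    stage = split(n_cancer, round(n_cancer * 10 / 21), "I-III", "IV")
    invasion = split(n_cancer, round(n_cancer * 10 / 21), "no", "yes")
    outcome = (
        ["deceased"] * round(n_cancer * 10 / 21)
        + ["alive"] * round(n_cancer * 8 / 21)
    )
    outcome += ["NA"] * (n_cancer - len(outcome))
    rng.shuffle(outcome)
    for i in range(n_cancer):
        rows.append(
            {
                "sample_id": f"LC{i + 1:02d}",
                "cancer": "cancer",
                "histology": histology[i],
                "stage": stage[i],
                "invasion": invasion[i],
                "outcome_500d": outcome[i],
            }
        )
    return pd.DataFrame(rows)


def _validate(platform: PlatformSpec, groups: pd.DataFrame, effects: list[EffectSpec]) -> None:
    if "sample_id" not in groups.columns:
        raise ValueError("metadata must have a sample_id column")
    if len(groups) < 4:
        raise ValueError("need at least 2 samples per group (>= 4 total)")
    for e in effects:
        if not (0 <= e.mirna_index < platform.n_human_mirnas):
            raise ValueError(
                f"effect mirna_index {e.mirna_index} outside the human range "
                f"[0, {platform.n_human_mirnas})"
            )
        if e.group_factor not in groups.columns:
            raise ValueError(f"effect factor {e.group_factor!r} not in metadata")
        level = e.resolved_level()
        if level not in set(groups[e.group_factor]):
            raise ValueError(
                f"level {level!r} absent from metadata column {e.group_factor!r}"
            )


def simulate_dataset(
    platform: PlatformSpec,
    groups: pd.DataFrame,
    effects: list[EffectSpec] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[ProbeTable, SyntheticTruth]:
    """Generate a probe-level dataset with planted differential miRNAs.

    Identical ``seed`` and parameters give bit-identical output.  Human
    probe sets are named ``hsa-miR-NNNN`` and flagged species="human";
    the remainder get species="other" and exist only to exercise the
    trimming step of the differential-expression stage.
    """
    effects = list(effects or [])
    noise = noise or NoiseModel()
    _validate(platform, groups, effects)

    rng = np.random.default_rng(seed)
    G, P = platform.n_probesets, platform.probes_per_set
    n_h = platform.n_human_mirnas
    samples = list(groups["sample_id"])
    S = len(samples)

    probeset_ids = [f"hsa-miR-{i + 1:04d}" for i in range(n_h)] + [
        f"other-{i + 1:05d}" for i in range(G - n_h)
    ]
    species = ["human"] * n_h + ["other"] * (G - n_h)

    # base abundance per probe set: exponential, hence ~5% of sets are
    # high-abundance under the default rate
    base = rng.exponential(scale=1.0 / noise.signal_rate, size=G)
    base = np.maximum(base, 1e-6)
    base_log2 = np.log2(base)

    # planted shifts: G x S matrix of log2 offsets
    shift = np.zeros((G, S))
    for e in effects:
        mask = (groups[e.group_factor] == e.resolved_level()).to_numpy()
        shift[e.mirna_index, mask] += e.log2_shift

    affinity = rng.normal(0.0, noise.probe_affinity_sd, size=(G, P))
    eps = rng.normal(0.0, noise.probe_sd, size=(G, P, S))
    log2_signal = base_log2[:, None, None] + shift[:, None, :] + affinity[:, :, None] + eps
    background = rng.normal(noise.bg_mean, noise.bg_sd, size=(G, P, S))
    intens = background + np.exp2(log2_signal)

    probes = pd.DataFrame(
        {
            "probe_id": [f"{ps}_p{p + 1}" for ps in probeset_ids for p in range(P)],
            "probeset_id": np.repeat(probeset_ids, P),
            "species": np.repeat(species, P),
        }
    )
    table = ProbeTable(
        probes=probes,
        intensities=intens.reshape(G * P, S),
        sample_ids=samples,
    )
    truth = SyntheticTruth(
        seed=seed,
        mirna_ids=probeset_ids[:n_h],
        group_factor_levels={
            c: sorted(set(groups[c])) for c in groups.columns if c != "sample_id"
        },
        baseline_log2={probeset_ids[i]: float(base_log2[i]) for i in range(n_h)},
        effects=effects,
    )
    return table, truth


def high_abundance_human_indices(
    platform: PlatformSpec, noise: NoiseModel, seed: int, k: int
) -> np.ndarray:
    """Indices of the k most abundant human miRNAs a dataset will have.

    Reproduces the base-abundance draw :func:`simulate_dataset` makes for
    the same (platform, noise, seed), so planted effects can target
    features that survive the downstream top-abundance filter.
    """
    rng = np.random.default_rng(seed)
    base = rng.exponential(scale=1.0 / noise.signal_rate, size=platform.n_probesets)
    order = np.argsort(base[: platform.n_human_mirnas])[::-1]
    return order[:k]


# ---------------------------------------------------------------------------
# I/O

def write_probe_table(table: ProbeTable, path) -> None:
    """Write a probe table as TSV (probe_id, probeset_id, species, samples...)."""
    if not table.sample_ids:
        raise ValueError("probe table has no samples")
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_probe_table(path) -> ProbeTable:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["probe_id", "probeset_id", "species"]
    sample_ids = [c for c in df.columns if c not in meta_cols]
    return ProbeTable(
        probes=df[meta_cols].copy(),
        intensities=df[sample_ids].to_numpy(dtype=float),
        sample_ids=sample_ids,
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    doc = {
        "seed": truth.seed,
        "mirna_ids": truth.mirna_ids,
        "group_factor_levels": truth.group_factor_levels,
        "baseline_log2": truth.baseline_log2,
        "effects": [
            {
                "mirna_index": e.mirna_index,
                "log2_shift": e.log2_shift,
                "group_factor": e.group_factor,
                "group_level": e.group_level,
            }
            for e in truth.effects
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SyntheticTruth(
        seed=doc["seed"],
        mirna_ids=doc["mirna_ids"],
        group_factor_levels=doc["group_factor_levels"],
        baseline_log2=doc["baseline_log2"],
        effects=[EffectSpec(**e) for e in doc["effects"]],
    )
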