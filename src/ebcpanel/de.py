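"""Differential expression of summarized miRNA profiles.

The workflow mirrors a standard two-group microarray analysis: restrict
to human miRNA probe sets, keep the most abundant 5% by median across
all arrays, fit a per-feature two-group least-squares model, and shrink
the residual variances by empirical Bayes before forming moderated
t-statistics.  The shrinkage treats the observed per-feature variances
s_g^2 as draws from a scaled-F around a prior variance s0^2 with d0
prior degrees of freedom; (d0, s0^2) are estimated by matching moments
of log s_g^2 through the digamma/trigamma identities, and the moderated
variance is the precision-weighted blend

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g).

Also provided: per-feature z-scaling, PCA scores of the scaled matrix,
and a deterministic average-linkage ordering for heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

__all__ = [
    "FilterResult",
    "DEResult",
    "ScaledMatrix",
    "PCAResult",
    "filter_top_abundance",
    "moderated_t_test",
    "estimate_prior_variance",
    "trigamma_inverse",
    "scale_features",
    "pca_scores",
    "hierarchical_order",
]


@dataclass
class FilterResult:
    retained: list[str]
    medians: pd.Series  # per human miRNA, median across all samples
    cutoff: float

    def subset(self, expr: ExpressionMatrix) -> pd.DataFrame:
        return expr.values.loc[self.retained]


def filter_top_abundance(
    expr: ExpressionMatrix, fraction: float = 0.05
) -> FilterResult:
    """Keep the top ``fraction`` of human miRNAs by median abundance.

    Non-human probe sets are trimmed first.  Exactly
    floor(fraction * n_human) features are retained; ties at the cutoff
    are broken by lexicographic miRNA id so the retained set is
    deterministic.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    human = expr.human_subset()
    if human.empty:
        raise ValueError("no human miRNA rows to filter")
    medians = human.median(axis=1)
    k = int(np.floor(fraction * len(human)))
    # sort by (-median, id): highest abundance first, ties lexicographic
    ordered = medians.sort_index().sort_values(ascending=False, kind="stable")
    retained = list(ordered.index[:k])
    cutoff = float(ordered.iloc[k - 1]) if k > 0 else float("inf")
    return FilterResult(retained=retained, medians=medians, cutoff=cutoff)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from observed variances.

    Under the model s_g^2 ~ s0^2 * F(df, d0), the log variances satisfy
        E[log s^2] = log s0^2 + digamma(df/2) - log(df/2)
                     - digamma(d0/2) + log(d0/2)
        Var[log s^2] = trigamma(df/2) + trigamma(d0/2),
    so d0 comes from inverting the trigamma and s0^2 from the mean.
    Returns (inf, exp(mean)) when the empirical variance of log s^2 is
    no larger than the sampling term (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.exp(np.mean(np.log(np.maximum(s2, 1e-300)))))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * trigamma_inverse(evar)
    s0_2 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


@dataclass
class DEResult:
    table: pd.DataFrame  # index mirna; logFC, FC, t, p, q, s2, s2_post, direction
    d0: float
    s0_2: float
    group_order: tuple[str, str]  # (case, control): logFC = case - control

    def significant(self, alpha: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["p"] < alpha])


def moderated_t_test(
    expr: pd.DataFrame,
    groups: pd.Series,
    case: str | None = None,
    prior_df: float | None = None,
) -> DEResult:
    """Per-feature two-group moderated t-test.

    ``expr`` is features x samples; ``groups`` maps sample id to one of
    two levels.  ``case`` names the level whose mean enters with a plus
    sign (positive logFC = up in case); defaults to the lexicographically
    larger level so cancer-vs-healthy codes cancer as case.  ``prior_df``
    overrides the estimated d0 (0 gives the ordinary pooled t; inf gives
    complete shrinkage to s0^2).
    """
    groups = groups.reindex(expr.columns)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    if case is None:
        case = levels[1]
    control = levels[0] if case == levels[1] else levels[1]
    m1 = (groups == case).to_numpy()
    m0 = (groups == control).to_numpy()
    n1, n0 = int(m1.sum()), int(m0.sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs >= 2 samples")

    X = expr.to_numpy(dtype=float)
    mean1 = X[:, m1].mean(axis=1)
    mean0 = X[:, m0].mean(axis=1)
    logfc = mean1 - mean0
    df_resid = n1 + n0 - 2
    ss = ((X[:, m1] - mean1[:, None]) ** 2).sum(axis=1) + (
        (X[:, m0] - mean0[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_2 = estimate_prior_variance(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_prior_variance(s2, df_resid)
        if d0 == 0:
            s0_2 = float(np.exp(np.mean(np.log(np.maximum(s2, 1e-300)))))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    # an all-constant feature in both groups still gets a positive
    # moderated variance from the prior unless d0 = 0
    s2_post = np.maximum(s2_post, 1e-300)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    t = logfc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "FC": np.exp2(logfc),
            "t": t,
            "p": p,
            "q": q,  # BH adjunct; the significance call uses raw p < 0.05
            "s2": s2,
            "s2_post": s2_post,
            "direction": np.where(logfc >= 0, "up", "down"),
        },
        index=expr.index,
    )
    return DEResult(table=table, d0=d0, s0_2=s0_2, group_order=(case, control))


# ---------------------------------------------------------------------------
# scaling, PCA, clustering order

@dataclass
class ScaledMatrix:
    values: pd.DataFrame  # features x samples, each row mean 0 sd 1
    means: pd.Series
    sds: pd.Series


def scale_features(expr: pd.DataFrame, ddof: int = 1) -> ScaledMatrix:
    """Per-feature z-scores: subtract the row mean, divide by the row sd."""
    means = expr.mean(axis=1)
    sds = expr.std(axis=1, ddof=ddof)
    bad = sds[sds <= 0]
    if len(bad):
        raise ValueError(f"zero-variance feature(s): {list(bad.index)}")
    z = expr.sub(means, axis=0).div(sds, axis=0)
    return ScaledMatrix(values=z, means=means, sds=sds)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray


def pca_scores(scaled: ScaledMatrix) -> PCAResult:
    """PCA of the scaled matrix via SVD of the samples x features array.

    Rows were already centered/scaled per feature, so no further
    centering is applied.  Sign convention: each component is flipped so
    its largest-magnitude loading is positive.
    """
    M = scaled.values.to_numpy(dtype=float).T  # samples x features
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 features")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    if not np.any(S > 0):
        raise ValueError("matrix has rank 0")
    for k in range(len(S)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S
    evr = S**2 / np.sum(S**2)
    comps = [f"PC{k + 1}" for k in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=scaled.values.columns, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=scaled.values.index, columns=comps),
        explained_variance_ratio=evr,
    )


def hierarchical_order(scaled: ScaledMatrix) -> tuple[list[str], list[str]]:
    """Row and column leaf orders from average-linkage Euclidean clustering."""

    def order(mat: np.ndarray, labels) -> list[str]:
        if len(labels) < 2:
            return list(labels)
        Z = hierarchy.linkage(pdist(mat, metric="euclidean"), method="average")
        return [labels[i] for i in hierarchy.leaves_list(Z)]

    vals = scaled.values.to_numpy(dtype=float)
    rows = order(vals, list(scaled.values.index))
    cols = order(vals.T, list(scaled.values.columns))
    return rows, cols
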