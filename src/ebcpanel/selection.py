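"""Random-forest biomarker panel selection and evaluation.

The selection procedure is recursive feature elimination driven by
out-of-bag (OOB) permutation importance: at each iteration the number of
candidate features per split (mtry) is tuned by stratified k-fold
cross-validated accuracy, a forest is grown on all samples, each
feature's importance is measured as the mean over trees of the drop in
OOB accuracy when that feature's values are permuted among the tree's
OOB samples, and the least important feature is removed — until three
features remain.  The trio is then evaluated by leave-one-out
cross-validation over all seven non-empty subsets, a binomial GLM
(logit link) panel model is fitted on the trio, and ROC curves with AUC,
sensitivity and specificity at the Youden-optimal threshold are computed
for each individual feature and for the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils import check_random_state

from .de import DEResult, moderated_t_test, pca_scores, scale_features

__all__ = [
    "RFConfig",
    "SelectionTrace",
    "SubsetEvaluation",
    "PanelModel",
    "RocCurve",
    "default_mtry_grid",
    "tune_mtry",
    "oob_permutation_importance",
    "rfe_select",
    "loocv_accuracy",
    "loocv_subset_eval",
    "fit_panel_glm",
    "roc_analysis",
    "run_panel_discovery",
    "PanelReport",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFConfig:
    """Forest and tuning settings for the selection procedure."""

    n_trees: int = 500
    mtry_grid: tuple[int, ...] | None = None  # None -> {1, sqrt(p), p/3, p}
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def default_mtry_grid(p: int) -> tuple[int, ...]:
    cand = {1, int(np.sqrt(p)), p // 3, p}
    return tuple(sorted(c for c in cand if 1 <= c <= p))


def _forest(n_trees: int, mtry: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def tune_mtry(X: np.ndarray, y: np.ndarray, config: RFConfig) -> int:
    """Pick mtry by stratified k-fold CV accuracy; ties -> smallest mtry."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to tune mtry")
    p = X.shape[1]
    grid = config.mtry_grid or default_mtry_grid(p)
    grid = tuple(sorted({min(m, p) for m in grid if m >= 1}))
    if len(grid) == 1:
        return grid[0]
    min_class = min(np.sum(y == c) for c in classes)
    folds = max(2, min(config.cv_folds, int(min_class)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    splits = list(skf.split(X, y))
    best_mtry, best_acc = grid[0], -1.0
    for mtry in grid:
        correct = 0
        for k, (tr, te) in enumerate(splits):
            clf = _forest(config.n_trees, mtry, seed=config.seed + 1000 + k)
            clf.fit(X[tr], y[tr])
            correct += int(np.sum(clf.predict(X[te]) == y[te]))
        acc = correct / len(y)
        if acc > best_acc:  # strict: ties keep the smaller mtry
            best_mtry, best_acc = mtry, acc
    return best_mtry


# ---------------------------------------------------------------------------
# OOB permutation importance

def _bootstrap_indices(tree_random_state, n_samples: int) -> np.ndarray:
    """The bootstrap sample indices a sklearn forest drew for one tree.

    Reproduces the forest's own unweighted draw (a RandomState seeded
    with the tree's random_state drawing n uniform integers with
    replacement), which is what sklearn's private helper does.
    """
    rs = check_random_state(tree_random_state)
    return rs.randint(0, n_samples, n_samples)


def oob_permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Mean decrease in OOB accuracy when each feature is permuted.

    For every tree: find its out-of-bag samples, measure accuracy on
    them, then re-measure with one feature's values permuted among those
    OOB samples; the feature's importance is the mean accuracy drop over
    trees.  Trees with no OOB samples are skipped (logged).  Constant
    features give exactly zero (permutation cannot change them).
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    counts = np.zeros(p)
    is_constant = np.array([np.all(X[:, j] == X[0, j]) for j in range(p)])
    varying = np.flatnonzero(~is_constant)
    # class index of each sample in the forest's label order
    ycode = np.searchsorted(forest.classes_, y)
    for tree in forest.estimators_:
        mask = np.ones(n, dtype=bool)
        mask[_bootstrap_indices(tree.random_state, n)] = False
        oob = np.flatnonzero(mask)
        if oob.size == 0:
            log.debug("tree has no OOB samples; skipped")
            continue
        Xo, yo = X[oob], ycode[oob]
        perm = rng.permutation(oob.size)
        # one low-level predict for the intact block plus every permuted
        # feature block (avoids per-call validation overhead)
        blocks = [Xo]
        for j in varying:
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            blocks.append(Xp)
        votes = tree.tree_.predict(np.ascontiguousarray(np.concatenate(blocks)))
        votes = votes.reshape(votes.shape[0], -1)  # (rows, n_classes)
        pred = np.argmax(votes, axis=1).reshape(len(blocks), oob.size)
        acc = np.mean(pred == yo[None, :], axis=1)
        base = acc[0]
        drops[varying] += base - acc[1:]
        counts += 1  # constant features count too: their drop is exactly 0
    if np.any(counts == 0):
        raise RuntimeError("no tree had OOB samples")
    return drops / counts


# ---------------------------------------------------------------------------
# recursive feature elimination

@dataclass
class SelectionIteration:
    features: list[str]
    mtry: int
    importance: pd.Series
    eliminated: str


@dataclass
class SelectionTrace:
    iterations: list[SelectionIteration]
    selected: list[str]

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "iterations": [
                {
                    "features": it.features,
                    "mtry": it.mtry,
                    "importance": {k: float(v) for k, v in it.importance.items()},
                    "eliminated": it.eliminated,
                }
                for it in self.iterations
            ],
        }


def rfe_select(
    X: pd.DataFrame,
    y: np.ndarray,
    config: RFConfig,
    target_k: int = 3,
) -> SelectionTrace:
    """Eliminate the least-important feature per iteration down to target_k.

    ``X`` is samples x features (columns are miRNA ids).  Importance
    ties at the minimum are broken by dropping the lexicographically
    last feature id.  Deterministic given ``config.seed``.
    """
    feats = list(X.columns)
    if len(feats) < target_k:
        raise ValueError(f"need >= {target_k} features, got {len(feats)}")
    y = np.asarray(y)
    iterations: list[SelectionIteration] = []
    step = 0
    while len(feats) > target_k:
        sub = X[feats].to_numpy(dtype=float)
        it_cfg = RFConfig(
            n_trees=config.n_trees,
            mtry_grid=config.mtry_grid,
            cv_folds=config.cv_folds,
            seed=config.seed + 7919 * step,  # per-iteration stream
        )
        mtry = tune_mtry(sub, y, it_cfg)
        clf = _forest(config.n_trees, mtry, seed=it_cfg.seed + 1)
        clf.fit(sub, y)
        imp = pd.Series(
            oob_permutation_importance(clf, sub, y, seed=it_cfg.seed + 2),
            index=feats,
        )
        lo = imp.min()
        ties = sorted(imp.index[imp == lo])
        drop = ties[-1]
        iterations.append(
            SelectionIteration(features=list(feats), mtry=mtry, importance=imp, eliminated=drop)
        )
        feats = [f for f in feats if f != drop]
        step += 1
    return SelectionTrace(iterations=iterations, selected=feats)


# ---------------------------------------------------------------------------
# LOOCV subset evaluation

@dataclass
class SubsetEvaluation:
    results: dict[tuple[str, ...], dict]  # subset -> {accuracy, probabilities}
    best_subset: tuple[str, ...]

    @property
    def accuracies(self) -> dict[tuple[str, ...], float]:
        return {k: v["accuracy"] for k, v in self.results.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "+".join(k), "size": len(k), "accuracy": v["accuracy"]}
            for k, v in self.results.items()
        ]
        return pd.DataFrame(rows)


def loocv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    config: RFConfig,
    mtry: int | None = None,
    pos_label: str | None = None,
) -> tuple[float, np.ndarray]:
    """Leave-one-out CV with a random forest; returns accuracy and the
    per-sample held-out probability of the positive class (default: the
    lexicographically larger level)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    classes = np.unique(y)
    positive = classes[-1] if pos_label is None else pos_label
    probs = np.empty(n)
    correct = 0
    m = mtry if mtry is not None else max(1, int(np.sqrt(X.shape[1])))
    for i in range(n):
        tr = np.arange(n) != i
        clf = _forest(config.n_trees, min(m, X.shape[1]), seed=config.seed + i)
        clf.fit(X[tr], y[tr])
        pr = clf.predict_proba(X[i : i + 1])[0]
        pos = np.where(clf.classes_ == positive)[0]
        probs[i] = pr[pos[0]] if len(pos) else 0.0
        pred = clf.classes_[np.argmax(pr)]
        correct += int(pred == y[i])
    return correct / n, probs


def loocv_subset_eval(
    X: pd.DataFrame,
    y: np.ndarray,
    trio: list[str],
    config: RFConfig,
    pos_label: str | None = None,
) -> SubsetEvaluation:
    """Evaluate all 7 non-empty subsets of a 3-feature panel by LOOCV.

    The best subset maximizes accuracy; ties prefer larger subsets, then
    lexicographic order, so the result is deterministic.
    """
    if len(trio) != 3:
        raise ValueError("trio must have exactly 3 features")
    y = np.asarray(y)
    if len(y) < 4:
        raise ValueError("need >= 4 samples for LOOCV")
    results: dict[tuple[str, ...], dict] = {}
    for size in (1, 2, 3):
        for subset in combinations(sorted(trio), size):
            acc, probs = loocv_accuracy(
                X[list(subset)].to_numpy(dtype=float), y, config, pos_label=pos_label
            )
            results[subset] = {"accuracy": acc, "probabilities": probs}
    best = max(
        results, key=lambda k: (results[k]["accuracy"], len(k), tuple(reversed(k)))
    )
    return SubsetEvaluation(results=results, best_subset=best)


# ---------------------------------------------------------------------------
# binomial GLM panel model

#: |coefficient| beyond which a logit fit is treated as quasi-separated
SEPARATION_GUARD = 15.0


@dataclass
class PanelModel:
    features: list[str]
    coef: pd.Series  # intercept + one per feature
    fitted_probabilities: np.ndarray
    converged: bool
    separation: bool
    positive_class: str


def fit_panel_glm(
    X: pd.DataFrame,
    y: np.ndarray,
    ridge: float = 1e-4,
    pos_label: str | None = None,
) -> PanelModel:
    """Binomial GLM (logit link) on the selected features.

    Fitted by IRLS; if the solution diverges (quasi-separation: any
    |coefficient| beyond the guard, or non-convergence), the model is
    refitted with a small L2 penalty and flagged.  The positive class
    defaults to the lexicographically larger level of ``y``.
    """
    Xv = X.to_numpy(dtype=float)
    if not np.isfinite(Xv).all():
        raise ValueError("non-finite feature values")
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    positive = classes[-1] if pos_label is None else pos_label
    yb = (y == positive).astype(float)
    design = sm.add_constant(Xv, has_constant="add")

    separation = False
    converged = True
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected and handled below; the warning is noise
            warnings.simplefilter("ignore")
            fit = sm.GLM(yb, design, family=sm.families.Binomial()).fit(maxiter=100)
        beta = np.asarray(fit.params)
        converged = bool(fit.converged)
    except Exception:  # perfect separation can abort IRLS outright
        beta = np.full(design.shape[1], np.nan)
        converged = False
    if (not converged) or (not np.isfinite(beta).all()) or np.any(
        np.abs(beta) > SEPARATION_GUARD
    ):
        separation = True
        beta = _ridge_logit(design, yb, lam=ridge)
    eta = design @ beta
    probs = 1.0 / (1.0 + np.exp(-eta))
    names = ["intercept"] + list(X.columns)
    return PanelModel(
        features=list(X.columns),
        coef=pd.Series(beta, index=names),
        fitted_probabilities=probs,
        converged=converged,
        separation=separation,
        positive_class=str(positive),
    )


def _ridge_logit(design: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """IRLS for logistic regression with L2 penalty lam (not on intercept)."""
    n, p = design.shape
    beta = np.zeros(p)
    pen = np.full(p, lam)
    pen[0] = 0.0
    for _ in range(200):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / W
        A = design.T @ (design * W[:, None]) + np.diag(pen)
        b = design.T @ (W * z)
        new = np.linalg.solve(A, b)
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


# ---------------------------------------------------------------------------
# ROC analysis

@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    flipped: bool  # scores were negated so that AUC >= 0.5
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def roc_analysis(
    scores: np.ndarray, labels: np.ndarray, pos_label: str | None = None
) -> RocCurve:
    """ROC curve over thresholds at the unique score values.

    A sample is called positive when score >= threshold; positives
    default to the lexicographically larger label.  If the raw AUC is below 0.5 the
    score is negated (flag ``flipped``) so the reported curve reads in
    the conventional orientation.  The trapezoidal AUC equals the
    tie-corrected rank statistic (concordant + ties/2) / (n1*n0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need both classes present")
    pos = labels == (classes[-1] if pos_label is None else pos_label)
    n1, n0 = int(pos.sum()), int((~pos).sum())

    def curve(s: np.ndarray):
        thr = np.concatenate(([np.inf], np.unique(s)[::-1]))
        sens = np.array([np.mean(s[pos] >= t) for t in thr])
        spec = np.array([np.mean(s[~pos] < t) for t in thr])
        auc = _auc_trapezoid(1.0 - spec, sens)
        return thr, sens, spec, auc

    thr, sens, spec, auc = curve(scores)
    flipped = False
    if auc < 0.5:
        flipped = True
        thr, sens, spec, auc = curve(-scores)
    j = sens + spec - 1.0
    best = int(np.argmax(j))
    return RocCurve(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        flipped=flipped,
        youden_threshold=float(thr[best]),
        youden_sensitivity=float(sens[best]),
        youden_specificity=float(spec[best]),
    )


# ---------------------------------------------------------------------------
# end-to-end per-contrast discovery

@dataclass
class PanelReport:
    contrast: str
    case: str
    control: str
    de: DEResult
    regulated: list[str]
    trace: SelectionTrace
    subset_eval: SubsetEvaluation
    panel: PanelModel
    roc_individual: dict[str, RocCurve]
    roc_panel: RocCurve
    roc_panel_loocv: RocCurve
    pca_explained: np.ndarray | None = None

    def summary(self) -> dict:
        return {
            "contrast": self.contrast,
            "case": self.case,
            "control": self.control,
            "n_regulated": len(self.regulated),
            "panel": self.trace.selected,
            "panel_auc": round(self.roc_panel.auc, 4),
            "panel_specificity": round(self.roc_panel.youden_specificity, 4),
            "panel_sensitivity": round(self.roc_panel.youden_sensitivity, 4),
            "individual_auc": {
                f: round(r.auc, 4) for f, r in self.roc_individual.items()
            },
            "loocv_accuracy": {
                "+".join(k): round(v, 4)
                for k, v in self.subset_eval.accuracies.items()
            },
            "separation_flag": self.panel.separation,
        }


def run_panel_discovery(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: str,
    config: RFConfig,
    case: str | None = None,
    alpha: float = 0.05,
    target_k: int = 3,
    prior_df: float | None = None,
) -> PanelReport:
    """Full per-contrast analysis on an abundance-filtered matrix.

    ``expr`` is features x samples (already trimmed/filtered);
    ``metadata`` must contain sample_id and the ``contrast`` column with
    exactly two informative levels ("NA" rows are dropped).  Stages:
    moderated t (p < alpha defines the regulated set) -> RFE to
    ``target_k`` features -> LOOCV over all subsets -> binomial GLM panel
    -> ROC per individual miRNA (raw expression as score) and for the
    panel (fitted probabilities; an LOOCV-probability ROC is attached as
    a secondary output).
    """
    meta = metadata.set_index("sample_id")
    groups = meta[contrast].reindex(expr.columns)
    keep = groups.notna() & (groups != "NA")
    groups = groups[keep]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"contrast {contrast!r} must have 2 levels, got {levels}")
    for lv in levels:
        if (groups == lv).sum() < 4:
            raise ValueError(f"contrast level {lv!r} has < 4 samples")
    sub = expr[groups.index]

    if case is None:
        # the study's case level for known contrasts (cancer, SCC, stage IV,
        # invasive, deceased); otherwise the lexicographically larger level
        from .simulate import POSITIVE_LEVELS

        default = POSITIVE_LEVELS.get(contrast)
        case = default if default in levels else levels[1]

    de = moderated_t_test(sub, groups, case=case, prior_df=prior_df)
    regulated = de.significant(alpha)
    if len(regulated) < target_k + 1:
        # too few significant features to run elimination: fall back to the
        # smallest workable set of top-ranked features by p-value
        regulated = list(de.table.sort_values("p").index[: target_k + 1])
        log.warning(
            "contrast %s: fewer than %d features at p<%g; using top %d by p",
            contrast, target_k + 1, alpha, len(regulated),
        )

    y = groups.to_numpy()
    Xreg = sub.loc[regulated].T  # samples x features
    trace = rfe_select(Xreg, y, config, target_k=target_k)
    trio = trace.selected
    subset_eval = loocv_subset_eval(Xreg, y, trio, config, pos_label=case)
    panel = fit_panel_glm(Xreg[trio], y, pos_label=case)

    roc_individual = {
        f: roc_analysis(sub.loc[f, groups.index].to_numpy(), y, pos_label=case)
        for f in trio
    }
    roc_panel = roc_analysis(panel.fitted_probabilities, y, pos_label=case)
    full = tuple(sorted(trio))
    roc_panel_loocv = roc_analysis(
        subset_eval.results[full]["probabilities"], y, pos_label=case
    )

    pca_expl = None
    if len(regulated) >= 2:
        pca_expl = pca_scores(scale_features(sub.loc[regulated])).explained_variance_ratio

    return PanelReport(
        contrast=contrast,
        case=de.group_order[0],
        control=de.group_order[1],
        de=de,
        regulated=regulated,
        trace=trace,
        subset_eval=subset_eval,
        panel=panel,
        roc_individual=roc_individual,
        roc_panel=roc_panel,
        roc_panel_loocv=roc_panel_loocv,
        pca_explained=pca_expl,
    )
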