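"""PLS-DA disease classification from structural connectivity.

Protocol: for each binary contrast the cohort is split (stratified) into
~80% training and ~20% test; feature selection — either the "key"
connections found by rerunning the distance-based scan plus δ top-5 on
the training subjects only, or the full set of n(n-1)/2 edge weights —
is followed by a partial-least-squares classifier whose component count
is tuned by cross-validated AUC inside the training set.  Test subjects
never influence selection or tuning.  The whole procedure is repeated
over independent splits and the key-vs-full performance difference is
assessed by a paired t-test across repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.iolib.table import SimpleTable

from .cohort import Cohort
from .mdmr import ConnectomeMDMR
from .network import upper_triangle_pairs
from .posthoc import delta_effect_size, top_k_connections

__all__ = ["split_cohort", "FeatureSet", "select_features", "PLSDAModel",
           "train_plsda", "evaluate", "rank_auc", "compare_models",
           "run_classification", "ClassificationReport"]

DEFAULT_CLASSIFICATION_COMPARISONS = {
    "CNvsCMCI": ("CN", "cMCI"),
    "CNvsAD": ("CN", "AD"),
}


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def split_cohort(labels, test_fraction: float = 0.2, seed=None):
    """Stratified train/test split of one binary comparison's subjects.

    Test size is ``round(test_fraction * n)``, allocated across classes
    by largest remainder so class proportions are preserved.  Returns
    (train_indices, test_indices); reproducible given ``seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if np.any(counts < 5):
        small = classes[counts < 5][0]
        raise ValueError(f"class {small!r} has fewer than 5 members; "
                         "stratified folds impossible")
    n_test = int(round(test_fraction * n))
    exact = counts * n_test / n
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = n_test - base.sum()
    for i in np.argsort(-remainder)[:short]:
        base[i] += 1
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls, k in zip(classes, base):
        members = np.flatnonzero(labels == cls)
        test_idx.extend(rng.choice(members, size=k, replace=False))
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return train_idx, test_idx


@dataclass
class FeatureSet:
    """Edges used as classifier features, with their selection provenance."""

    mode: str                      # "key" or "full"
    edges: list = field(default_factory=list)   # (i, j) pairs, i < j
    provenance: pd.DataFrame | None = None      # key mode: seed/partner/delta
    flags: tuple = ()

    @property
    def n_features(self) -> int:
        return len(self.edges)


def select_features(cohort: Cohort, mode: str = "key",
                    covariates=("age", "sex", "apoe4"),
                    seed_p_threshold: float = 0.001, k: int = 5,
                    permutations: int = 199, n_randomizations: int = 100,
                    fallback_n_seeds: int = 3, seed=None) -> FeatureSet:
    """Choose classifier features from a *training* cohort.

    ``full`` mode returns every upper-triangle node pair.  ``key`` mode
    reruns the region scan on the training subjects, keeps regions with
    permutation p below ``seed_p_threshold`` (falling back to the
    ``fallback_n_seeds`` smallest-p regions when none pass, flagged),
    computes δ per seed and returns the deduplicated union of each
    seed's top-``k`` connections.
    """
    if mode == "full":
        return FeatureSet(mode="full",
                          edges=upper_triangle_pairs(cohort.n_nodes))
    if mode != "key":
        raise ValueError("mode must be 'key' or 'full'")
    ss = _seedseq(seed)
    s_scan, s_delta = ss.spawn(2)
    scan = ConnectomeMDMR(cohort, covariates=covariates).fit(
        permutations=permutations, seed=np.random.default_rng(s_scan))
    seeds = scan.seed_regions(p_threshold=seed_p_threshold)
    flags = ()
    if not seeds:
        seeds = scan.table.sort_values(
            ["p_perm", "pseudo_F"], ascending=[True, False],
            kind="mergesort").head(fallback_n_seeds)["region"].tolist()
        flags = ("seed_fallback",)
        warnings.warn("no region passed the seed threshold; falling back "
                      f"to the {fallback_n_seeds} smallest-p regions",
                      stacklevel=2)
    effects = []
    for child, region in zip(s_delta.spawn(len(seeds)), seeds):
        effects.append(delta_effect_size(
            cohort, region, covariates=covariates,
            n_randomizations=n_randomizations,
            seed=np.random.default_rng(child)))
    effects = pd.concat(effects, ignore_index=True)
    top = top_k_connections(effects, k=k)
    edges, seen = [], set()
    for row in top.itertuples():
        e = (min(row.seed, row.partner), max(row.seed, row.partner))
        if e not in seen:
            seen.add(e)
            edges.append(e)
    return FeatureSet(mode="key", edges=edges, provenance=top, flags=flags)


def rank_auc(scores, y) -> float:
    """AUC by the rank (Mann-Whitney) formula with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined for a single-class sample")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


class PLSDAModel:
    """Fitted PLS discriminant analysis: PLS regression on a 0/1 class
    indicator, classifying by thresholding the predicted indicator."""

    def __init__(self, pls: PLSRegression, n_components: int,
                 threshold: float = 0.5, cv_auc: float | None = None):
        self.pls = pls
        self.n_components = n_components
        self.threshold = threshold
        self.cv_auc = cv_auc

    def decision_scores(self, X) -> np.ndarray:
        return np.asarray(self.pls.predict(np.asarray(X, dtype=float))).ravel()

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold).astype(int)


def _fit_pls(X, y, n_components) -> PLSRegression:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=n_components, scale=True)
        pls.fit(X, y.astype(float))
    return pls


def train_plsda(X, y, folds: int = 5, component_grid=None,
                seed=None) -> PLSDAModel:
    """Tune the PLS component count by cross-validated AUC and refit.

    The grid defaults to 1..10 and is truncated to the rank the training
    data permits (with a warning).  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if np.any(counts < folds):
        raise ValueError(f"need at least {folds} subjects per class")
    # components beyond the rank of the (centered) smallest training
    # fold make the NIPALS deflation degenerate
    fold_n = X.shape[0] - X.shape[0] // folds
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    max_comp = max(1, min(X.shape[1], fold_n - 1, rank - 1))
    if component_grid is None:
        component_grid = range(1, 11)
    grid = [c for c in component_grid if c <= max_comp]
    if not grid:
        grid = [1]
    if len(grid) < len(list(component_grid)):
        warnings.warn(f"component grid truncated to <= {max_comp}",
                      stacklevel=2)
    rng_seed = int(_seedseq(seed).generate_state(1)[0] % 2**31)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    best = (None, -np.inf)
    for c in grid:
        aucs = []
        for tr, te in cv.split(X, y):
            pls = _fit_pls(X[tr], y[tr], c)
            scores = np.asarray(pls.predict(X[te])).ravel()
            if len(np.unique(y[te])) < 2:
                continue
            aucs.append(rank_auc(scores, y[te]))
        mean_auc = float(np.mean(aucs)) if aucs else 0.5
        if mean_auc > best[1] + 1e-12:
            best = (c, mean_auc)
    n_comp, cv_auc = best
    return PLSDAModel(_fit_pls(X, y, n_comp), n_comp, cv_auc=cv_auc)


def evaluate(model: PLSDAModel, X_test, y_test) -> dict:
    """Test-set sensitivity, specificity, ROC points and AUC.

    Sensitivity is computed on the positive (patient) class; AUC uses
    the rank formula on the continuous decision scores.
    """
    y = np.asarray(y_test, dtype=int)
    scores = model.decision_scores(X_test)
    pred = (scores >= model.threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    out = {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }
    if len(np.unique(y)) < 2:
        warnings.warn("single-class test set; AUC undefined", stacklevel=2)
        out["auc"] = np.nan
        out["roc"] = None
        return out
    out["auc"] = rank_auc(scores, y)
    thresholds = np.concatenate(([np.inf], np.sort(np.unique(scores))[::-1]))
    tpr = [np.mean(scores[y == 1] >= t) for t in thresholds]
    fpr = [np.mean(scores[y == 0] >= t) for t in thresholds]
    out["roc"] = pd.DataFrame({"fpr": fpr, "tpr": tpr,
                               "threshold": thresholds})
    return out


def compare_models(metrics_a, metrics_b) -> float:
    """Paired two-sided t-test p on per-resample metric differences."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired resamples of equal length")
    d = a - b
    if np.allclose(d, 0.0):
        return 1.0
    if np.isclose(np.std(d, ddof=1), 0.0):
        return 0.0  # constant nonzero difference: degenerate t
    return float(scipy.stats.ttest_rel(a, b).pvalue)


@dataclass
class ClassificationReport:
    """Per-repeat metrics for key and full feature modes, per comparison."""

    table: pd.DataFrame
    comparisons: dict
    repeats: int

    def aggregate(self) -> pd.DataFrame:
        return (self.table.groupby(["comparison", "mode"])
                [["sensitivity", "specificity", "auc"]].mean().reset_index())

    def compare(self) -> pd.DataFrame:
        """Key-vs-full paired comparison per metric and comparison."""
        rows = []
        for name in self.table["comparison"].unique():
            sub = self.table[self.table["comparison"] == name]
            key = sub[sub["mode"] == "key"].sort_values("repeat")
            full = sub[sub["mode"] == "full"].sort_values("repeat")
            if len(key) == 0 or len(full) == 0:
                continue
            for metric in ("sensitivity", "specificity", "auc"):
                rows.append((name, metric,
                             compare_models(key[metric].to_numpy(),
                                            full[metric].to_numpy())))
        return pd.DataFrame(rows, columns=["comparison", "metric", "p_value"])

    def summary(self) -> SimpleTable:
        agg = self.aggregate()
        rows = [[r.comparison, r.mode, f"{r.sensitivity:.3f}",
                 f"{r.specificity:.3f}", f"{r.auc:.3f}"]
                for r in agg.itertuples()]
        return SimpleTable(
            rows,
            headers=["comparison", "features", "sens", "spec", "AUC"],
            title=f"PLS-DA over {self.repeats} repeats (mean of repeats)")


def run_classification(cohort: Cohort, comparisons: dict | None = None,
                       modes=("key", "full"), repeats: int = 5,
                       folds: int = 5, test_fraction: float = 0.2,
                       covariates=("age", "sex", "apoe4"),
                       seed_p_threshold: float = 0.001, k: int = 5,
                       selection_permutations: int = 199,
                       n_randomizations: int = 100,
                       component_grid=None,
                       seed=None) -> ClassificationReport:
    """The full repeated-split classification protocol.

    For each comparison and repeat: stratified split, train-side feature
    selection per mode, component tuning by ``folds``-fold CV, and
    held-out evaluation.  The patient (non-CN) group is the positive
    class.  Deterministic given ``seed``.
    """
    if comparisons is None:
        present = set(cohort.labels)
        comparisons = {n: g for n, g
                       in DEFAULT_CLASSIFICATION_COMPARISONS.items()
                       if set(g) <= present}
    rows = []
    master = np.random.SeedSequence(seed)
    comp_seeds = master.spawn(len(comparisons))
    for comp_ss, (name, groups) in zip(comp_seeds, comparisons.items()):
        sub = cohort.subset(groups=groups)
        positive = next(g for g in groups if g != "CN") \
            if "CN" in groups else groups[-1]
        y_all = (sub.labels == positive).astype(int)
        for repeat, rep_ss in enumerate(comp_ss.spawn(repeats), start=1):
            s_split, s_select, s_train = rep_ss.spawn(3)
            train_idx, test_idx = split_cohort(
                sub.labels, test_fraction,
                seed=np.random.default_rng(s_split))
            train = sub.subset(indices=train_idx)
            for mode in modes:
                fs = select_features(
                    train, mode=mode, covariates=covariates,
                    seed_p_threshold=seed_p_threshold, k=k,
                    permutations=selection_permutations,
                    n_randomizations=n_randomizations,
                    seed=s_select)
                X = sub.feature_matrix(fs.edges)
                model = train_plsda(X[train_idx], y_all[train_idx],
                                    folds=folds,
                                    component_grid=component_grid,
                                    seed=s_train)
                metrics = evaluate(model, X[test_idx], y_all[test_idx])
                rows.append((name, mode, repeat, metrics["sensitivity"],
                             metrics["specificity"], metrics["auc"],
                             model.n_components, fs.n_features,
                             ";".join(fs.flags)))
    table = pd.DataFrame(rows, columns=[
        "comparison", "mode", "repeat", "sensitivity", "specificity",
        "auc", "n_components", "n_features", "flags"])
    return ClassificationReport(table=table, comparisons=comparisons,
                                repeats=repeats)
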