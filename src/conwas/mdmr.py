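"""Multivariate distance matrix regression (MDMR) on connectivity vectors.

For every brain region the connectivity vectors of all subjects are
compared through the correlation distance

    d_uv = sqrt(2 (1 - r_uv)),

with r_uv the Pearson correlation between the vectors of subjects u and
v.  A distance-based sum-of-squares decomposition yields the pseudo-F
statistic

    F = (n - 1) * SSA / SSW,      SSA = SST - SSW,

whose significance is assessed by permutation (no distributional
assumption), with nuisance covariates handled through hat-matrix
projections of the Gower-centered inner-product matrix and Freedman-Lane
residual permutation.  Benjamini-Hochberg FDR corrects across regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort

__all__ = [
    "correlation_distance", "RegionDistanceMatrix", "region_distance_matrix",
    "pseudo_f_groups", "gower_center", "pseudo_f_adjusted",
    "permutation_test", "fdr_correct", "MDMR", "MDMRResults",
    "ConnectomeMDMR", "MDMRScanResults", "run_mdmr", "DEFAULT_COMPARISONS",
]

#: The comparisons of the default pipeline: three case-control contrasts
#: and one three-group disease-progression contrast.
DEFAULT_COMPARISONS = {
    "CNvsSMCI": ("CN", "sMCI"),
    "CNvsCMCI": ("CN", "cMCI"),
    "CNvsAD": ("CN", "AD"),
    "CN-CMCI-AD": ("CN", "cMCI", "AD"),
}

_EPS = 1e-12


# ---------------------------------------------------------------------------
# distances

def _pearson_rows(X: np.ndarray):
    """Pairwise Pearson correlations between rows; zero-variance rows get
    r = 0 against everything (returned as the degenerate set)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    degenerate = np.flatnonzero(norms <= _EPS * max(1.0, float(np.abs(X).max(initial=0.0))))
    safe = norms.copy()
    safe[safe == 0] = 1.0
    R = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    np.clip(R, -1.0, 1.0, out=R)
    if degenerate.size:
        R[degenerate, :] = 0.0
        R[:, degenerate] = 0.0
    np.fill_diagonal(R, 1.0)
    return R, degenerate


def correlation_distance(vec_u, vec_v) -> float:
    """Correlation distance sqrt(2 (1 - r)) between two vectors.

    Bounded in [0, 2].  If either vector has zero variance the Pearson
    correlation is undefined; r is then taken as 0 (distance sqrt(2))
    and a warning is emitted.
    """
    u = np.asarray(vec_u, dtype=float)
    v = np.asarray(vec_v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if u.size < 3:
        raise ValueError("need vectors of length >= 3")
    su, sv = np.std(u), np.std(v)
    if su <= _EPS or sv <= _EPS:
        warnings.warn("zero-variance connectivity vector; r taken as 0",
                      stacklevel=2)
        r = 0.0
    else:
        r = float(np.corrcoef(u, v)[0, 1])
    r = min(1.0, max(-1.0, r))
    return float(np.sqrt(2.0 * (1.0 - r)))


@dataclass
class RegionDistanceMatrix:
    """Subject-space correlation distances for one seed region."""

    seed_region: int
    distances: np.ndarray
    degenerate_subjects: tuple = ()

    @property
    def n_subjects(self) -> int:
        return self.distances.shape[0]


def region_distance_matrix(cohort, seed_region: int) -> RegionDistanceMatrix:
    """All pairwise correlation distances between subjects' connectivity
    vectors for one region.

    ``cohort`` may be a :class:`~conwas.cohort.Cohort` or an
    (n_subjects, n_features) array of precomputed vectors.
    """
    X = cohort.vectors(seed_region) if isinstance(cohort, Cohort) \
        else np.asarray(cohort, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    R, degenerate = _pearson_rows(X)
    D = np.sqrt(np.maximum(2.0 * (1.0 - R), 0.0))
    np.fill_diagonal(D, 0.0)
    if degenerate.size:
        warnings.warn(
            f"region {seed_region}: {degenerate.size} zero-variance "
            "connectivity vector(s); r taken as 0 for those subjects",
            stacklevel=2)
    return RegionDistanceMatrix(seed_region, D, tuple(degenerate.tolist()))


# ---------------------------------------------------------------------------
# sums of squares and pseudo-F

@dataclass
class PseudoF:
    statistic: float
    sst: float
    ssw: float
    ssa: float
    flags: tuple = ()


def _as_distances(D) -> np.ndarray:
    if isinstance(D, RegionDistanceMatrix):
        return D.distances
    return np.asarray(D, dtype=float)


def pseudo_f_groups(D, labels) -> PseudoF:
    """Label-based pseudo-F with its sum-of-squares decomposition.

    SST = (1/n) sum_{u<v} d_uv^2 ; SSW sums, per group g, the squared
    within-group distances scaled by 1/n_g (the two-group form extended
    additively to k groups); F = (n-1) (SST - SSW) / SSW.  Every group
    needs at least 2 members.  If SSW is zero the statistic is +inf.
    """
    Dm = _as_distances(D)
    labels = np.asarray(labels)
    n = Dm.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must align with the distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        small = groups[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    D2 = Dm ** 2
    sst = float(D2.sum() / (2.0 * n))
    ssw = 0.0
    for g, ng in zip(groups, counts):
        idx = np.flatnonzero(labels == g)
        ssw += float(D2[np.ix_(idx, idx)].sum() / (2.0 * ng))
    ssa = sst - ssw
    flags = ()
    if ssw <= _EPS * max(1.0, sst):
        if ssa <= _EPS:
            return PseudoF(0.0 if sst == 0 else np.inf, sst, ssw, ssa,
                           ("zero_ssw",))
        return PseudoF(np.inf, sst, ssw, ssa, ("zero_ssw",))
    return PseudoF((n - 1) * ssa / ssw, sst, ssw, ssa, flags)


def gower_center(D) -> np.ndarray:
    """Gower-centered inner-product matrix G = C A C, A = -D^2 / 2.

    Rows and columns of G sum to zero; traces of projected G recover the
    distance-based sums of squares.
    """
    Dm = _as_distances(D)
    n = Dm.shape[0]
    A = -0.5 * Dm ** 2
    C = np.eye(n) - np.ones((n, n)) / n
    return C @ A @ C


def _design_matrices(labels, covariates, covariate_names=None):
    """Reduced (intercept + covariates) and full (+ group dummies) designs.

    Constant covariate columns are dropped with a warning; a rank-
    deficient full design raises, naming the offending columns.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    names_cov = ["intercept"]
    X_cov = [np.ones(n)]
    if covariates is not None:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise ValueError("covariates must align with subjects")
        if covariate_names is None:
            covariate_names = [f"x{i}" for i in range(Z.shape[1])]
        for i in range(Z.shape[1]):
            col = Z[:, i]
            if np.ptp(col) <= _EPS:
                warnings.warn(f"constant covariate {covariate_names[i]!r} "
                              "dropped", stacklevel=3)
                continue
            X_cov.append(col)
            names_cov.append(str(covariate_names[i]))
    X_cov = np.column_stack(X_cov)
    groups = np.unique(labels)
    dummies = [(labels == g).astype(float) for g in groups[1:]]
    X_full = np.column_stack([X_cov] + dummies)
    names_full = names_cov + [f"group[{g}]" for g in groups[1:]]
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        # locate collinear columns via pivoted QR
        from scipy.linalg import qr
        _, R, piv = qr(X_full, mode="economic", pivoting=True)
        bad = sorted(piv[rank:].tolist())
        raise ValueError("rank-deficient design; collinear columns: "
                         + ", ".join(names_full[i] for i in bad))
    return X_cov, X_full, names_full


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def pseudo_f_adjusted(D, labels, covariates=None,
                      covariate_names=None) -> float:
    """Covariate-adjusted pseudo-F via the semi-partial trace statistic.

    F = (n-1) tr((H_full - H_cov) G) / tr((I - H_full) G), with H_cov the
    hat matrix of intercept + covariates and H_full additionally spanning
    the group indicators.  With no covariates this equals the plain
    label-based statistic exactly.
    """
    Dm = _as_distances(D)
    labels = np.asarray(labels)
    n = Dm.shape[0]
    G = gower_center(Dm)
    Hd, R_full, R_cov = _projectors(labels, covariates, covariate_names)
    return _trace_f(G, Hd, R_full, R_cov, n)


def _projectors(labels, covariates=None, covariate_names=None):
    X_cov, X_full, _ = _design_matrices(labels, covariates, covariate_names)
    n = X_cov.shape[0]
    H_cov = _hat(X_cov)
    H_full = _hat(X_full)
    Hd = H_full - H_cov            # projector onto the group effect space
    R_full = np.eye(n) - H_full    # residual projector
    R_cov = np.eye(n) - H_cov
    return Hd, R_full, R_cov


def _trace_f(G, Hd, R_full, R_cov, n) -> float:
    num = float(np.sum(Hd * G))      # tr(Hd G), symmetric matrices
    den = float(np.sum(R_full * G))  # tr(R_full G)
    if den <= _EPS * max(1.0, abs(num)):
        return np.inf if num > _EPS else 0.0
    return (n - 1) * num / den


def permutation_test(D, labels, covariates=None, permutations: int = 5000,
                     seed=None, scheme: str = "freedman_lane",
                     covariate_names=None, return_null: bool = False):
    """Permutation p-value for the (adjusted) pseudo-F.

    p = (1 + #{F_perm >= F_obs}) / (B + 1), ties counted as extreme.
    ``permutations`` may be an integer B (random permutations drawn from
    ``seed``) or an explicit (B, n) array of permutation index rows, e.g.
    a full enumeration for exact small-n inference.  With covariates the
    default scheme permutes the reduced-model residual structure of the
    Gower matrix (Freedman-Lane); ``scheme="raw"`` permutes subject
    indices of G directly.
    """
    if scheme not in ("freedman_lane", "raw"):
        raise ValueError("scheme must be 'freedman_lane' or 'raw'")
    Dm = _as_distances(D)
    labels = np.asarray(labels)
    n = Dm.shape[0]
    G = gower_center(Dm)
    Hd, R_full, R_cov = _projectors(labels, covariates, covariate_names)
    F_obs = _trace_f(G, Hd, R_full, R_cov, n)

    Gr = R_cov @ G @ R_cov if scheme == "freedman_lane" else G
    if np.isscalar(permutations):
        B = int(permutations)
        if B < 99:
            raise ValueError("need at least 99 permutations")
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((B, n)), axis=1)
    else:
        perms = np.asarray(permutations, dtype=int)
        B = perms.shape[0]
    F_null = _null_f(Gr, Hd, R_full, n, perms)
    tol = 1e-9 * max(1.0, abs(F_obs)) if np.isfinite(F_obs) else 0.0
    count = int(np.sum(F_null >= F_obs - tol))
    p = (1.0 + count) / (B + 1.0)
    if return_null:
        return p, F_obs, F_null
    return p


def _null_f(Gr, Hd, R_full, n, perms, chunk: int = 256) -> np.ndarray:
    """Trace pseudo-F over permuted Gower matrices, chunked fancy indexing."""
    B = perms.shape[0]
    out = np.empty(B)
    for start in range(0, B, chunk):
        P = perms[start:start + chunk]
        Gp = Gr[P[:, :, None], P[:, None, :]]
        num = np.einsum("ij,bij->b", Hd, Gp)
        den = np.einsum("ij,bij->b", R_full, Gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (n - 1) * num / den
        small = np.abs(den) <= _EPS
        f[small] = np.where(np.abs(num[small]) <= _EPS, 0.0, np.inf)
        out[start:start + chunk] = f
    return out


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# model / results objects

class MDMR:
    """Distance matrix regression model for one region.

    Parameters
    ----------
    distances : RegionDistanceMatrix or (n, n) array
        Subject-space distance matrix.
    groups : array_like of str
        Group label per subject.
    covariates : array_like, optional
        Nuisance design columns (no intercept; it is added internally).
    """

    def __init__(self, distances, groups, covariates=None,
                 covariate_names=None, permutation_scheme="freedman_lane"):
        self.distances = _as_distances(distances)
        self.groups = np.asarray(groups)
        self.covariates = covariates
        self.covariate_names = covariate_names
        self.permutation_scheme = permutation_scheme
        if self.distances.shape[0] != self.groups.shape[0]:
            raise ValueError("groups must align with the distance matrix")

    @classmethod
    def from_vectors(cls, X, groups, **kwargs) -> "MDMR":
        """Build the model from per-subject multivariate profiles."""
        D = region_distance_matrix(np.asarray(X, dtype=float), 0)
        return cls(D.distances, groups, **kwargs)

    def fit(self, permutations: int = 5000, seed=None) -> "MDMRResults":
        decomp = pseudo_f_groups(self.distances, self.groups)
        F_adj = pseudo_f_adjusted(self.distances, self.groups,
                                  self.covariates, self.covariate_names)
        p, F_obs, F_null = permutation_test(
            self.distances, self.groups, self.covariates,
            permutations=permutations, seed=seed,
            scheme=self.permutation_scheme,
            covariate_names=self.covariate_names, return_null=True)
        return MDMRResults(model=self, pseudo_f=F_obs, p_value=p,
                           sst=decomp.sst, ssw=decomp.ssw, ssa=decomp.ssa,
                           unadjusted_f=decomp.statistic,
                           n_permutations=(permutations if np.isscalar(permutations)
                                           else len(permutations)),
                           flags=decomp.flags)


@dataclass
class MDMRResults:
    """Fitted MDMR for one region: statistic, decomposition, p-value."""

    model: MDMR
    pseudo_f: float
    p_value: float
    sst: float
    ssw: float
    ssa: float
    unadjusted_f: float
    n_permutations: int
    flags: tuple = ()

    @property
    def pseudo_r2(self) -> float:
        """Share of distance variation explained by group: SSA / SST."""
        return self.ssa / self.sst if self.sst > 0 else 0.0

    def summary(self) -> SimpleTable:
        rows = [
            ["n subjects", f"{self.model.distances.shape[0]}"],
            ["pseudo-F (adjusted)", f"{self.pseudo_f:.4f}"],
            ["pseudo-F (unadjusted)", f"{self.unadjusted_f:.4f}"],
            ["permutation p", f"{self.p_value:.4g}"],
            ["SST", f"{self.sst:.4f}"],
            ["SSW", f"{self.ssw:.4f}"],
            ["SSA", f"{self.ssa:.4f}"],
            ["pseudo-R2", f"{self.pseudo_r2:.4f}"],
            ["permutations", f"{self.n_permutations}"],
        ]
        return SimpleTable(rows, headers=["", "MDMR"],
                           title="Multivariate distance matrix regression")


class ConnectomeMDMR:
    """Region-by-region MDMR scan of a cohort (the connectome-wide test).

    Parameters
    ----------
    cohort : Cohort
        Thresholded cohort to scan.
    comparison : sequence of str, optional
        Groups to contrast (default: all groups present).
    covariates : sequence of str
        Cohort-table columns used as nuisance covariates.
    """

    def __init__(self, cohort: Cohort, comparison=None,
                 covariates=("age", "sex", "apoe4"),
                 permutation_scheme="freedman_lane"):
        if comparison is not None:
            missing = set(comparison) - set(cohort.labels)
            if missing:
                raise ValueError(f"groups absent from cohort: {sorted(missing)}")
            cohort = cohort.subset(groups=comparison)
        self.cohort = cohort
        self.covariate_names = tuple(covariates or ())
        self.permutation_scheme = permutation_scheme

    def fit(self, permutations: int = 5000, seed=None) -> "MDMRScanResults":
        cohort = self.cohort
        labels = cohort.labels
        covs = (cohort.covariate_matrix(self.covariate_names)
                if self.covariate_names else None)
        rng = np.random.default_rng(seed)
        n = cohort.n_subjects
        Hd, R_full, R_cov = _projectors(labels, covs, self.covariate_names)
        rows = []
        B = int(permutations)
        for region in range(cohort.n_nodes):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rdm = region_distance_matrix(cohort, region)
            G = gower_center(rdm.distances)
            F_obs = _trace_f(G, Hd, R_full, R_cov, n)
            Gr = (R_cov @ G @ R_cov if self.permutation_scheme == "freedman_lane"
                  else G)
            perms = np.argsort(rng.random((B, n)), axis=1)
            F_null = _null_f(Gr, Hd, R_full, n, perms)
            tol = 1e-9 * max(1.0, abs(F_obs)) if np.isfinite(F_obs) else 0.0
            p = (1.0 + np.sum(F_null >= F_obs - tol)) / (B + 1.0)
            decomp = pseudo_f_groups(rdm.distances, labels)
            flags = list(decomp.flags)
            if rdm.degenerate_subjects:
                flags.append("zero_variance_vectors")
            rows.append((region, cohort.node_labels[region], F_obs, p,
                         decomp.sst, decomp.ssw, decomp.ssa,
                         ";".join(flags)))
        table = pd.DataFrame(rows, columns=[
            "region", "region_label", "pseudo_F", "p_perm",
            "SST", "SSW", "SSA", "flags"])
        table["q_fdr"] = fdr_correct(table["p_perm"].to_numpy())
        table = table[["region", "region_label", "pseudo_F", "p_perm",
                       "q_fdr", "SST", "SSW", "SSA", "flags"]]
        return MDMRScanResults(table=table, covariates=self.covariate_names,
                               n_permutations=B,
                               scheme=self.permutation_scheme)


@dataclass
class MDMRScanResults:
    """Per-region pseudo-F, permutation p and FDR q for one comparison."""

    table: pd.DataFrame
    covariates: tuple
    n_permutations: int
    scheme: str

    def significant(self, alpha: float = 0.05, on: str = "q_fdr"):
        return self.table[self.table[on] < alpha]

    def seed_regions(self, p_threshold: float = 0.001) -> list[int]:
        """Regions passing the seed-selection threshold on permutation p."""
        return self.table.loc[self.table["p_perm"] < p_threshold,
                              "region"].tolist()

    def summary(self) -> SimpleTable:
        top = self.table.sort_values(["p_perm", "pseudo_F"],
                                     ascending=[True, False],
                                     kind="mergesort").head(10)
        rows = [[r.region_label, f"{r.pseudo_F:.3f}", f"{r.p_perm:.4g}",
                 f"{r.q_fdr:.4g}"] for r in top.itertuples()]
        return SimpleTable(
            rows, headers=["region", "pseudo-F", "p", "q(FDR)"],
            title=(f"MDMR scan ({len(self.table)} regions, "
                   f"B={self.n_permutations}, "
                   f"covariates={list(self.covariates)})"))


def run_mdmr(cohort: Cohort, comparisons: dict | None = None,
             covariates=("age", "sex", "apoe4"), permutations: int = 5000,
             seed=None, permutation_scheme="freedman_lane"
             ) -> dict[str, MDMRScanResults]:
    """Run the full MDMR scan for each requested group comparison.

    ``comparisons`` maps a name to a tuple of group labels; the default
    runs the three case-control contrasts and the three-group contrast.
    Deterministic given ``seed`` (one sub-stream per comparison).
    """
    if comparisons is None:
        present = set(cohort.labels)
        comparisons = {name: gs for name, gs in DEFAULT_COMPARISONS.items()
                       if set(gs) <= present}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(comparisons))
    out = {}
    for child, (name, groups) in zip(children, comparisons.items()):
        model = ConnectomeMDMR(cohort, comparison=groups,
                               covariates=covariates,
                               permutation_scheme=permutation_scheme)
        out[name] = model.fit(permutations=permutations,
                              seed=np.random.default_rng(child))
    return out
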