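"""Post-hoc attribution and amplitude comparison for significant regions.

Two complementary follow-ups to a region-level multivariate association:

* the δ effect size attributes the association to individual connections
  by measuring how much the pseudo-R² (SSA/SST of the region's distance
  matrix) drops when one connectivity column is randomized across
  subjects — a pattern-level, randomization-based attribution;
* nodal overall strength (sum of absolute incident edge weights)
  compared between groups by a covariate-adjusted general linear model
  and pairwise permutation tests — an amplitude-level comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .cohort import Cohort
from .mdmr import _EPS, _projectors
from .network import nodal_strength  # noqa: F401  (re-exported surface)

__all__ = ["delta_effect_size", "top_k_connections", "nodal_strength",
           "strength_table", "strength_group_glm",
           "pairwise_strength_permutation"]


def _centering(n: int) -> np.ndarray:
    return np.eye(n) - np.ones((n, n)) / n


def _corr_from_stats(S, a, q, m):
    """Pearson correlation matrix from inner products S, row sums a and
    row sums of squares q over m coordinates."""
    cov = S - np.outer(a, a) / m
    var = np.maximum(q - a ** 2 / m, 0.0)
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = cov / denom
    R[~np.isfinite(R)] = 0.0
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return R


def _pseudo_r2_from_corr(R, M1, M2) -> float:
    """Semi-partial pseudo-R² from a correlation matrix.

    Uses A = R - 1 (elementwise) as the Gower kernel of the correlation
    distance, so tr(P G) = sum(C P C * R) - const for projectors P; the
    constant cancels because C P C annihilates the all-ones matrix.
    """
    num = float(np.sum(M1 * R))
    den = float(np.sum(M2 * R))
    if abs(den) <= _EPS:
        return 0.0
    return num / den


def delta_effect_size(cohort: Cohort, seed_region: int, covariates=None,
                      n_randomizations: int = 100, seed=None) -> pd.DataFrame:
    """δ effect size of each connection of a seed region.

    For each partner column j of the seed's connectivity vectors,
    δ_j = pseudoR²(observed) - mean_b pseudoR²(column j permuted across
    subjects), over ``n_randomizations`` independent permutations.
    Larger δ means the connection contributes more to the group
    association.  Constant columns get δ = 0 and a flag.

    Returns a DataFrame with columns seed, partner, partner_label,
    delta, rank, flags (rank 1 = largest δ, ties broken by node order).
    """
    if n_randomizations < 50:
        raise ValueError("need at least 50 randomizations")
    labels = cohort.labels
    covs = None
    cov_names = None
    if covariates:
        cov_names = tuple(covariates)
        covs = cohort.covariate_matrix(cov_names)
    X = np.asarray(cohort.vectors(seed_region), dtype=float)
    n, m = X.shape
    C = _centering(n)
    Hd, R_full, R_cov = _projectors(labels, covs, cov_names)
    M1 = C @ Hd @ C
    M2 = C @ R_cov @ C

    S = X @ X.T
    a = X.sum(axis=1)
    q = (X ** 2).sum(axis=1)
    r2_obs = _pseudo_r2_from_corr(_corr_from_stats(S, a, q, m), M1, M2)

    rng = np.random.default_rng(seed)
    partners = [p for p in range(cohort.n_nodes) if p != seed_region]
    deltas = np.zeros(m)
    flags = [""] * m
    for j in range(m):
        c = X[:, j]
        if np.ptp(c) <= _EPS:
            flags[j] = "constant_column"
            continue
        acc = 0.0
        for _ in range(n_randomizations):
            cp = c[rng.permutation(n)]
            Sp = S - np.outer(c, c) + np.outer(cp, cp)
            ap = a - c + cp
            qp = q - c ** 2 + cp ** 2
            acc += _pseudo_r2_from_corr(_corr_from_stats(Sp, ap, qp, m),
                                        M1, M2)
        deltas[j] = r2_obs - acc / n_randomizations

    order = np.lexsort((np.arange(m), -deltas))
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    return pd.DataFrame({
        "seed": seed_region,
        "partner": partners,
        "partner_label": [cohort.node_labels[p] for p in partners],
        "delta": deltas,
        "rank": rank,
        "flags": flags,
    })


def top_k_connections(effects: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The k largest-δ partners per seed (ties broken by node order).

    If a seed has fewer than k finite entries all are returned with a
    ``too_few`` flag; tied δ at the boundary is flagged ``tie``.
    """
    out = []
    for seed, grp in effects.groupby("seed", sort=True):
        grp = grp[np.isfinite(grp["delta"])]
        grp = grp.sort_values(["delta", "partner"],
                              ascending=[False, True], kind="mergesort")
        top = grp.head(k).copy()
        top["rank"] = np.arange(1, len(top) + 1)
        if len(grp) < k:
            top["flags"] = (top["flags"].astype(str) + ";too_few").str.strip(";")
            warnings.warn(f"seed {seed}: only {len(grp)} finite effects",
                          stacklevel=2)
        elif len(grp) > k and np.isclose(grp["delta"].iloc[k - 1],
                                         grp["delta"].iloc[k]):
            top["flags"] = (top["flags"].astype(str) + ";tie").str.strip(";")
        out.append(top)
    return pd.concat(out, ignore_index=True)


def strength_table(cohort: Cohort) -> pd.DataFrame:
    """Nodal overall strength of every subject at every node."""
    return cohort.strengths()


def _strength_design(strengths: pd.DataFrame, cohort: Cohort, node: int,
                     covariates=("age", "sex", "apoe4")):
    sub = strengths[strengths["node"] == node].set_index("subject_id")
    y = sub.loc[cohort.table["subject_id"], "strength"].to_numpy(dtype=float)
    covs = cohort.covariate_matrix(covariates) if covariates else \
        np.empty((cohort.n_subjects, 0))
    if covs.size:
        keep = np.ptp(covs, axis=0) > _EPS
        if not keep.all():
            dropped = [c for c, k in zip(covariates, keep) if not k]
            warnings.warn(f"constant covariate(s) {dropped} dropped",
                          stacklevel=3)
            covs = covs[:, keep]
    return y, covs


def strength_group_glm(strengths: pd.DataFrame, cohort: Cohort, node: int,
                       covariates=("age", "sex", "apoe4")) -> float:
    """Partial-F p-value for the group effect on one node's strength.

    OLS of strength on group indicators plus covariates, compared against
    the covariates-only model.  Identical strengths (zero group sum of
    squares) give p = 1.
    """
    y, covs = _strength_design(strengths, cohort, node, covariates)
    labels = cohort.labels
    groups = np.unique(labels)
    dummies = np.column_stack([(labels == g).astype(float)
                               for g in groups[1:]])
    n = len(y)
    X_red = sm.add_constant(covs) if covs.size else np.ones((n, 1))
    X_full = np.column_stack([X_red, dummies])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design for strength GLM")
    fit_red = sm.OLS(y, X_red).fit()
    fit_full = sm.OLS(y, X_full).fit()
    ss_diff = fit_red.ssr - fit_full.ssr
    df_diff = X_full.shape[1] - X_red.shape[1]
    df_resid = n - X_full.shape[1]
    scale = max(np.mean(np.abs(y)) ** 2, 1.0)
    if ss_diff <= 1e-12 * scale:
        return 1.0
    if fit_full.ssr <= 1e-12 * scale:
        return 0.0
    F = (ss_diff / df_diff) / (fit_full.ssr / df_resid)
    return float(scipy.stats.f.sf(F, df_diff, df_resid))


def pairwise_strength_permutation(strengths: pd.DataFrame, cohort: Cohort,
                                  node: int, group_pair,
                                  covariates=("age", "sex", "apoe4"),
                                  permutations: int = 5000,
                                  seed=None) -> float:
    """Two-sided permutation p for the adjusted strength difference
    between two groups at one node.

    Strengths are residualized on intercept + covariates; the statistic
    is |mean residual difference| between the two groups, with group
    labels permuted.  Add-one convention: p >= 1/(B+1).
    """
    g1, g2 = group_pair
    for g in (g1, g2):
        if g not in set(cohort.labels):
            raise ValueError(f"group {g!r} absent from cohort")
    pair = cohort.subset(groups=[g1, g2])
    y, covs = _strength_design(strengths, pair, node, covariates)
    X = sm.add_constant(covs) if covs.size else np.ones((len(y), 1))
    resid = sm.OLS(y, X).fit().resid
    is_g1 = pair.labels == g1
    n1 = int(is_g1.sum())
    obs = abs(resid[is_g1].mean() - resid[~is_g1].mean())
    rng = np.random.default_rng(seed)
    B = int(permutations)
    count = 0
    for _ in range(B):
        perm = rng.permutation(len(resid))
        rp = resid[perm]
        stat = abs(rp[:n1].mean() - rp[n1:].mean())
        if stat >= obs - 1e-12 * max(1.0, obs):
            count += 1
    return (1.0 + count) / (B + 1.0)
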