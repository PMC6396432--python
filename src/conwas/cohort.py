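"""Cohorts: subject tables aligned with per-subject connectomes."""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .aal import default_labels
from .network import Connectome, apply_density_threshold

__all__ = ["GROUPS", "Cohort", "apply_exclusion_counts"]

#: Diagnostic groups, in disease-stage order: cognitively normal, stable
#: MCI, MCI converting to dementia, Alzheimer's disease.
GROUPS = ("CN", "sMCI", "cMCI", "AD")

REQUIRED_COLUMNS = ("subject_id", "group", "age", "sex", "apoe4")


class Cohort:
    """Subject records plus their connectivity matrices.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per subject with columns subject_id, group, age, sex,
        apoe4.  Groups must come from :data:`GROUPS`; covariates must be
        complete (the default pipeline has no missing-data handling).
    matrices : (n_subjects, n_nodes, n_nodes) ndarray
        Subject weight matrices in table row order.
    """

    def __init__(self, table: pd.DataFrame, matrices: np.ndarray,
                 node_labels: Sequence[str] | None = None,
                 ground_truth: dict | None = None, validate: bool = True):
        self.table = table.reset_index(drop=True)
        self.matrices = np.asarray(matrices, dtype=float)
        if node_labels is None:
            node_labels = default_labels(self.matrices.shape[-1])
        self.node_labels = tuple(node_labels)
        #: For synthetic cohorts: which (seed, partner) edges were planted.
        self.ground_truth = ground_truth
        if validate:
            self._validate()

    def _validate(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.table.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        if self.table["subject_id"].duplicated().any():
            dup = self.table.loc[self.table["subject_id"].duplicated(),
                                 "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(
                f"unknown group labels {sorted(bad)}; allowed: {list(GROUPS)}")
        if self.table[["age", "apoe4"]].isna().any().any():
            raise ValueError("covariates must be complete (no missing values)")
        if not np.all(np.isfinite(self.table["age"].to_numpy(dtype=float))):
            raise ValueError("non-finite age values")
        if self.matrices.ndim != 3 or len(self.table) != self.matrices.shape[0]:
            raise ValueError("matrices must align with the subject table")
        if self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be square")
        if len(self.node_labels) != self.matrices.shape[1]:
            raise ValueError("node labels must match matrix size")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """Group label per subject."""
        return self.table["group"].to_numpy()

    def connectome(self, index: int) -> Connectome:
        return Connectome(self.matrices[index], self.node_labels,
                          validate=False)

    def subset(self, groups: Sequence[str] | None = None,
               indices=None) -> "Cohort":
        """Restrict to named groups and/or explicit subject positions."""
        mask = np.ones(self.n_subjects, dtype=bool)
        if groups is not None:
            mask &= np.isin(self.labels, list(groups))
        idx = np.flatnonzero(mask)
        if indices is not None:
            idx = idx[np.isin(idx, np.asarray(indices))] if groups is not None \
                else np.asarray(indices, dtype=int)
        return Cohort(self.table.iloc[idx], self.matrices[idx],
                      self.node_labels, ground_truth=self.ground_truth,
                      validate=False)

    def thresholded(self, density: float = 0.05) -> "Cohort":
        """Apply the per-subject density threshold to every matrix."""
        out = np.empty_like(self.matrices)
        for s in range(self.n_subjects):
            out[s] = apply_density_threshold(
                self.connectome(s), density).weights
        return Cohort(self.table, out, self.node_labels,
                      ground_truth=self.ground_truth, validate=False)

    def vectors(self, seed_region: int) -> np.ndarray:
        """All subjects' connectivity vectors for one region.

        Returns an (n_subjects, n_nodes-1) array: each row is a subject's
        connections from the seed to the remaining nodes.
        """
        if not 0 <= seed_region < self.n_nodes:
            raise IndexError(f"seed region {seed_region} out of range")
        rows = self.matrices[:, seed_region, :]
        return np.delete(rows, seed_region, axis=1)

    def feature_matrix(self, edges: Sequence[tuple[int, int]]) -> np.ndarray:
        """Edge weights for the given (i, j) pairs, one row per subject."""
        i = np.array([e[0] for e in edges], dtype=int)
        j = np.array([e[1] for e in edges], dtype=int)
        return self.matrices[:, i, j]

    def strengths(self) -> pd.DataFrame:
        """Long table of nodal strengths: subject_id, node, strength."""
        S = np.abs(self.matrices).sum(axis=2)
        recs = []
        for s in range(self.n_subjects):
            sid = self.table.at[s, "subject_id"]
            for node in range(self.n_nodes):
                recs.append((sid, node, self.node_labels[node], S[s, node]))
        return pd.DataFrame(recs, columns=["subject_id", "node",
                                           "node_label", "strength"])

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Numeric covariate columns (sex encoded female=1, male=0)."""
        cols = []
        for name in names:
            if name == "sex":
                col = (self.table["sex"].astype(str).str.upper()
                       .isin(["F", "FEMALE", "1"])).astype(float)
            else:
                col = self.table[name].astype(float)
            cols.append(col.to_numpy())
        return np.column_stack(cols) if cols else np.empty((self.n_subjects, 0))

    def __repr__(self) -> str:  # pragma: no cover
        counts = self.table["group"].value_counts().to_dict()
        return f"Cohort(n_subjects={self.n_subjects}, groups={counts})"


def apply_exclusion_counts(initial: int, exclusions: Sequence[int]) -> int:
    """Sample size remaining after successive exclusion steps.

    Used for the screening arithmetic of an observational cohort: an
    initial search count minus each exclusion criterion's count.
    """
    if initial <= 0:
        raise ValueError("initial sample size must be positive")
    remaining = initial
    for step, count in enumerate(exclusions):
        if count < 0:
            raise ValueError("exclusion counts must be nonnegative")
        remaining -= count
        if remaining < 0:
            raise ValueError(f"exclusion step {step} exceeds remaining sample")
    return remaining
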