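"""Reading and writing connectomes, cohort tables and result files.

Dialects: comma-separated with header for matrices and cohort tables,
tab-separated for edge lists and result tables, UTF-8, '.' decimal.
"""

from __future__ import annotations

from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .aal import default_labels
from .cohort import GROUPS, Cohort, apply_exclusion_counts  # noqa: F401
from .network import Connectome

__all__ = ["read_connectome", "write_connectome", "read_cohort_table",
           "load_cohort", "write_cohort", "apply_exclusion_counts"]

_SYMMETRY_TOL = 1e-9


def read_connectome(path, node_labels: Sequence[str] | None = None
                    ) -> Connectome:
    """Read a connectome from a CSV matrix or a long-format TSV edge list.

    CSV matrices carry node labels as header and index; edge lists have
    columns node_i, node_j, weight (labels or integer indices).  An
    asymmetric matrix is symmetrized by averaging only when the
    discrepancy is within 1e-9; larger mismatches are an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        return _read_edge_list(path, node_labels)
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels disagree")
    labels = [str(c) for c in df.columns]
    if node_labels is not None and list(node_labels) != labels:
        raise ValueError(f"{path}: node labels do not match the expected "
                         "vocabulary")
    W = df.to_numpy(dtype=float)
    neg = np.argwhere(W < 0)
    if len(neg):
        i, j = neg[0]
        raise ValueError(f"{path}: negative weight at ({labels[i]}, "
                         f"{labels[j]})")
    asym = np.abs(W - W.T).max()
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance "
                         f"(max |w_ij - w_ji| = {asym:.3g})")
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return Connectome(W, labels)


def _read_edge_list(path, node_labels):
    df = pd.read_csv(path, sep="\t")
    for col in ("node_i", "node_j", "weight"):
        if col not in df.columns:
            raise ValueError(f"{path}: edge list missing column {col!r}")
    if node_labels is None:
        if df["node_i"].dtype.kind in "iu":
            n = int(max(df["node_i"].max(), df["node_j"].max())) + 1
            node_labels = default_labels(n)
        else:
            node_labels = sorted(set(df["node_i"]) | set(df["node_j"]))
    index = {lab: k for k, lab in enumerate(node_labels)}
    n = len(node_labels)
    W = np.full((n, n), np.nan)
    for row in df.itertuples(index=False):
        i = int(row.node_i) if isinstance(row.node_i, (int, np.integer)) \
            else index[row.node_i]
        j = int(row.node_j) if isinstance(row.node_j, (int, np.integer)) \
            else index[row.node_j]
        if not np.isnan(W[j, i]) and abs(W[j, i] - row.weight) > _SYMMETRY_TOL:
            raise ValueError(
                f"{path}: inconsistent duplicate edge ({row.node_i}, "
                f"{row.node_j}): {W[j, i]!r} vs {row.weight!r}")
        W[i, j] = W[j, i] = row.weight
    W = np.nan_to_num(W, nan=0.0)
    np.fill_diagonal(W, 0.0)
    if np.any(W < 0):
        raise ValueError(f"{path}: negative edge weight")
    return Connectome(W, node_labels)


def write_connectome(connectome: Connectome, path) -> None:
    connectome.to_frame().to_csv(path)


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort table CSV.

    Requires columns subject_id, group, age, sex, apoe4; group labels
    must come from the fixed diagnostic set.
    """
    df = pd.read_csv(path)
    for col in ("subject_id", "group", "age", "sex", "apoe4"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"{path}: duplicate subject_id {dup!r}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}; "
                         f"allowed: {list(GROUPS)}")
    return df


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort as one CSV matrix per subject plus cohort.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(out / "cohort.csv", index=False)
    for s in range(cohort.n_subjects):
        sid = cohort.table.at[s, "subject_id"]
        write_connectome(cohort.connectome(s), out / f"{sid}.csv")


def load_cohort(matrices_dir, cohort_csv=None) -> Cohort:
    """Load a cohort written by :func:`write_cohort`."""
    matrices_dir = Path(matrices_dir)
    if cohort_csv is None:
        cohort_csv = matrices_dir / "cohort.csv"
    table = read_cohort_table(cohort_csv)
    mats, labels = [], None
    for sid in table["subject_id"]:
        conn = read_connectome(matrices_dir / f"{sid}.csv", labels)
        labels = list(conn.node_labels)
        mats.append(conn.weights)
    return Cohort(table, np.array(mats), labels)
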