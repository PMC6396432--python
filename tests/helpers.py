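"""Shared oracles and cohort builders for the test suite."""

import numpy as np

from conwas import SyntheticSpec


def brute_force_ss(D, labels):
    """Independent sum-of-squares oracle: explicit pair loops."""
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    sst = sum(D[u, v] ** 2 for u in range(n) for v in range(u + 1, n)) / n
    ssw = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ssw += sum(D[u, v] ** 2 for u in idx for v in idx if u < v) / len(idx)
    return sst, ssw, sst - ssw


def random_distance_matrix(rng, n):
    """Correlation-distance matrix of random profiles (Euclidean-embeddable)."""
    from conwas import region_distance_matrix
    X = rng.standard_normal((n, 8))
    return region_distance_matrix(X, 0).distances


def two_group_spec(effect_size, n_per_group=15, n_nodes=20, seeds=(0, 5, 9),
                   **kwargs):
    """Small two-group study condition for unit-level tests."""
    kwargs.setdefault("base_density", 0.35)
    return SyntheticSpec(
        n_nodes=n_nodes,
        group_sizes={"CN": n_per_group, "AD": n_per_group},
        planted_seeds=seeds,
        effect_size=effect_size,
        **kwargs,
    )


RECOVERY_SEEDS = (10, 40, 70)


def recovery_spec(effect_size=2.0, n_per_group=40, **kwargs):
    """The calibrated planted-effect study condition: full 90-node atlas,
    three hub seed regions, moderately heavy-tailed weights."""
    kwargs.setdefault("base_density", 0.10)
    kwargs.setdefault("edge_weight_sigma", 0.6)
    return SyntheticSpec(
        n_nodes=90,
        group_sizes={"CN": n_per_group, "AD": n_per_group},
        planted_seeds=RECOVERY_SEEDS,
        effect_size=effect_size,
        **kwargs,
    )
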