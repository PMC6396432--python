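"""Synthetic cohorts of group-structured structural connectomes.

The generator emulates the kind of data a diffusion-tractography study
produces after network construction: per-subject symmetric nonnegative
weight matrices with heavy-tailed (log-normal) edge weights, a sparse
population template, and demographic covariates.  Disease effects are
planted as *pattern* changes at chosen seed regions — coordinated
up/down shifts over a subset of the seed's strong hub-to-hub edges,
plus rerouting of another subset to previously absent partners — with
magnitude growing across disease stages.  This is what a distance-based
multivariate test detects, as distinct from a pure amplitude
(nodal-strength) change, and the signal concentrates at the seed: each
individual partner sees only one modest, noise-scale change.

All randomness flows from one master seed; regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aal import DEFAULT_SEED_LABELS, default_labels
from .cohort import GROUPS, Cohort

__all__ = ["SyntheticSpec", "generate_cohort", "generate_streamline_summary",
           "template_connectome"]

_TABLE1_SIZES = {"CN": 46, "sMCI": 48, "cMCI": 27, "AD": 40}
_AGE_MEAN = {"CN": 74.5, "sMCI": 74.5, "cMCI": 76.5, "AD": 74.6}
_AGE_SD = {"CN": 5.9, "sMCI": 8.4, "cMCI": 7.3, "AD": 7.7}
_FEMALE_PROP = {"CN": 24 / 46, "sMCI": 18 / 48, "cMCI": 11 / 27, "AD": 17 / 40}
_APOE4_PROB = {"CN": 0.0, "sMCI": 0.167, "cMCI": 0.222, "AD": 0.15}
#: Stage progression of the planted effect: no alteration in CN, almost
#: none in stable MCI, growing through converting MCI into dementia.
_STAGE_MULT = {"CN": 0.0, "sMCI": 0.0, "cMCI": 1.0, "AD": 2.0}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic connectome cohort.

    Defaults mirror a matched four-group observational cohort
    (46/48/27/40 subjects; ages ~74-77 y; APOE-4 carrier rates 0-22%).
    ``effect_size`` is the base perturbation scale e; each group's
    effective magnitude is ``effect_size * stage_multipliers[group]``.
    ``amplified_fraction`` of a seed's edges shift up and an equal
    fraction shifts down (a pattern change that leaves total amplitude
    roughly constant); ``rerouted_fraction`` lose weight to previously
    absent partners.
    """

    n_nodes: int = 90
    group_sizes: dict = field(default_factory=lambda: dict(_TABLE1_SIZES))
    planted_seeds: tuple = None  # type: ignore[assignment]
    effect_size: float = 1.0
    stage_multipliers: dict = field(default_factory=lambda: dict(_STAGE_MULT))
    progressive: bool = True
    base_density: float = 0.10
    edge_weight_mu: float = 0.0
    edge_weight_sigma: float = 1.0
    subject_sigma: float = 0.4
    amplified_fraction: float = 0.30
    rerouted_fraction: float = 0.15
    age_mean: dict = field(default_factory=lambda: dict(_AGE_MEAN))
    age_sd: dict = field(default_factory=lambda: dict(_AGE_SD))
    female_prop: dict = field(default_factory=lambda: dict(_FEMALE_PROP))
    apoe4_prob: dict = field(default_factory=lambda: dict(_APOE4_PROB))
    confounded: bool = False
    confound_age_shift: float = 4.0
    effect_driver: str = "group"  # "group" or "age"
    rng_seed: int = 0

    def __post_init__(self):
        if self.planted_seeds is None:
            if self.n_nodes == 90:
                labels = default_labels(90)
                self.planted_seeds = tuple(labels.index(x)
                                           for x in DEFAULT_SEED_LABELS)
            else:
                self.planted_seeds = ()
        self.planted_seeds = tuple(int(s) for s in self.planted_seeds)

    def validate(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        for g, size in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; allowed {list(GROUPS)}")
            if size < 2:
                raise ValueError(
                    f"group {g} has {size} subjects; at least 2 required "
                    "(within-group sums of squares need a within-group pair)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if any(m < 0 for m in self.stage_multipliers.values()):
            raise ValueError("stage multipliers must be nonnegative")
        if self.stage_multipliers.get("CN", 0.0) != 0.0:
            raise ValueError("the CN stage multiplier is 0 by definition")
        if self.progressive:
            stages = [self.stage_multipliers.get(g, 0.0)
                      for g in ("CN", "cMCI", "AD")]
            if not all(a <= b for a, b in zip(stages, stages[1:])):
                raise ValueError("progressive mode requires nondecreasing "
                                 "effect across CN -> cMCI -> AD")
        if not 0 < self.base_density <= 1:
            raise ValueError("base_density must be in (0, 1]")
        if not (0 <= self.amplified_fraction <= 1
                and 0 <= self.rerouted_fraction <= 1
                and self.amplified_fraction + self.rerouted_fraction <= 1):
            raise ValueError("edge fractions must be in [0, 1] and sum <= 1")
        for s in self.planted_seeds:
            if not 0 <= s < self.n_nodes:
                raise ValueError(f"planted seed {s} out of range")
        if self.effect_driver not in ("group", "age"):
            raise ValueError("effect_driver must be 'group' or 'age'")
        if self.edge_weight_sigma <= 0 or self.subject_sigma < 0:
            raise ValueError("weight scales must be positive")


def _streams(spec: SyntheticSpec, seed=None):
    master = spec.rng_seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(5)
    return [np.random.default_rng(c) for c in children]


#: Planted seed regions are treated as network hubs: their template rows
#: are this much denser than the background, mirroring the hub-like
#: character of the subcortical/limbic regions such analyses implicate.
_SEED_DEGREE_BOOST = 2.0


def _template(spec: SyntheticSpec, rng) -> np.ndarray:
    """Population template: log-normal weights on a random sparse support."""
    n = spec.n_nodes
    iu = np.triu_indices(n, k=1)
    p_edge = np.full(len(iu[0]), spec.base_density)
    if spec.planted_seeds:
        seed_mask = (np.isin(iu[0], spec.planted_seeds)
                     | np.isin(iu[1], spec.planted_seeds))
        p_edge[seed_mask] = np.minimum(
            1.0, _SEED_DEGREE_BOOST * spec.base_density)
    present = rng.random(len(iu[0])) < p_edge
    vals = np.where(
        present,
        np.exp(spec.edge_weight_mu
               + spec.edge_weight_sigma * rng.standard_normal(len(iu[0]))),
        0.0)
    W = np.zeros((n, n))
    W[iu] = vals
    return W + W.T


#: Each rerouted edge's moved weight is split evenly over this many
#: previously absent partners, so the pattern change concentrates at the
#: seed region rather than at any single receiving node.
_TARGETS_PER_REROUTE = 3
#: Log-scale shift per unit effect applied to each patterned edge.  Kept
#: of the same order as the subject noise so that no single partner
#: region inherits a dominant univariate signal; the seed's many
#: coordinated shifts are what the multivariate test detects.
_PATTERN_LOG_SCALE = 0.15
#: Guard against division by zero for isolated candidate partners.
_EPS_STRENGTH = 1e-12


def _perturbation_plans(spec: SyntheticSpec, template: np.ndarray, rng):
    """Per-seed planted pattern: coordinated up/down shifts over the
    seed's edges plus rerouting of a subset to absent partners.

    One plan per seed, shared by all affected groups, so stages alter
    the same pattern with growing magnitude.  ``amplified_fraction`` of
    the seed's edges shift up, an equal fraction shifts down (pattern,
    not amplitude), and ``rerouted_fraction`` lose weight to previously
    absent partners.
    """
    degree = (template > 0).sum(axis=0)
    strength = template.sum(axis=0)
    # weight of the last edge surviving a 5% density cut on the template:
    # patterned edges should sit above it so the shift is visible after
    # per-subject thresholding
    n = template.shape[0]
    iu_vals = template[np.triu_indices(n, k=1)]
    m_keep = max(1, int(0.05 * len(iu_vals)))
    cut = np.partition(iu_vals, len(iu_vals) - m_keep)[len(iu_vals) - m_keep]
    plans = {}
    used: set[int] = set(spec.planted_seeds)
    for s in spec.planted_seeds:
        row = template[s].copy()
        row[s] = 0.0
        partners = np.flatnonzero(row > 0)
        absent = np.setdiff1d(np.flatnonzero(row == 0), [s])
        n_amp = int(round(spec.amplified_fraction * len(partners)))
        n_re = int(round(spec.rerouted_fraction * len(partners)))
        # altered connections concentrate on strong hub-to-hub edges:
        # strong, so the shift survives density thresholding; hub
        # partners (for whom this edge is a small share of their total
        # strength), so no partner's profile is dominated by its one
        # shifted edge
        by_weight = partners[np.argsort(-row[partners], kind="stable")]
        n_strong = max(2 * n_amp + n_re, int(np.sum(row[partners] > cut)))
        strong = by_weight[:n_strong]
        share = row[strong] / np.maximum(strength[strong], _EPS_STRENGTH)
        ranked = strong[np.argsort(share, kind="stable")]
        # keep per-seed pools disjoint so no partner accumulates shifted
        # edges from several seeds
        fresh = ranked[~np.isin(ranked, list(used))]
        pool = fresh[:2 * n_amp + n_re]
        if len(pool) < 2 * n_amp + n_re:
            extra = ranked[np.isin(ranked, list(used))]
            pool = np.concatenate(
                [pool, extra[:2 * n_amp + n_re - len(pool)]])
        used.update(int(x) for x in pool)
        perm = rng.permutation(pool)
        amplified = np.sort(perm[:n_amp])
        suppressed = np.sort(perm[n_amp:2 * n_amp])
        rerouted = np.sort(perm[2 * n_amp:2 * n_amp + n_re])
        n_tgt = min(_TARGETS_PER_REROUTE * len(rerouted), len(absent))
        if n_tgt:
            candidates = absent[~np.isin(absent, list(used))]
            if len(candidates) < n_tgt:
                candidates = absent
            by_str = candidates[np.argsort(-strength[candidates],
                                           kind="stable")]
            targets = np.sort(by_str[:n_tgt])
            used.update(int(x) for x in targets)
        else:
            targets = absent[:0]
        if len(targets) == 0:
            rerouted = rerouted[:0]
        plans[s] = {"amplified": amplified, "suppressed": suppressed,
                    "rerouted": rerouted, "targets": targets}
    return plans


def _apply_effect(W: np.ndarray, plans: dict, eff: float) -> None:
    if eff == 0.0:
        return
    shift = np.exp(_PATTERN_LOG_SCALE * eff)
    rho = 1.0 - 1.0 / shift  # fraction of weight moved to new partners
    for s, plan in plans.items():
        up, down = plan["amplified"], plan["suppressed"]
        re, tgt = plan["rerouted"], plan["targets"]
        W[s, up] *= shift
        W[up, s] = W[s, up]
        W[s, down] /= shift
        W[down, s] = W[s, down]
        if len(re) == 0 or len(tgt) == 0:
            continue
        moved = rho * W[s, re]
        W[s, re] -= moved
        W[re, s] = W[s, re]
        W[s, tgt] += moved.sum() / len(tgt)
        W[tgt, s] = W[s, tgt]


def generate_cohort(spec: SyntheticSpec, seed: int | None = None) -> Cohort:
    """Draw a full synthetic cohort from a :class:`SyntheticSpec`.

    Returns a :class:`~conwas.cohort.Cohort` whose matrices are symmetric,
    nonnegative and zero-diagonal, with ``ground_truth`` recording the
    planted edges.  ``seed`` overrides ``spec.rng_seed``.
    """
    spec.validate()
    rng_tpl, rng_plan, rng_subj, rng_cov, _ = _streams(spec, seed)
    template = _template(spec, rng_tpl)
    plans = _perturbation_plans(spec, template, rng_plan)
    n = spec.n_nodes
    iu = np.triu_indices(n, k=1)
    tpl_vals = template[iu]

    rows, mats = [], []
    k = 0
    for g in GROUPS:
        if g not in spec.group_sizes:
            continue
        mult = spec.stage_multipliers.get(g, 0.0)
        for _ in range(spec.group_sizes[g]):
            age = rng_cov.normal(
                spec.age_mean[g] + (spec.confound_age_shift * mult
                                    if spec.confounded else 0.0),
                spec.age_sd[g])
            sex = "F" if rng_cov.random() < spec.female_prop[g] else "M"
            apoe4 = int(rng_cov.random() < spec.apoe4_prob[g])

            vals = tpl_vals * np.exp(
                spec.subject_sigma * rng_subj.standard_normal(len(tpl_vals)))
            W = np.zeros((n, n))
            W[iu] = vals
            W += W.T
            if spec.effect_driver == "age":
                eff = spec.effect_size * float(np.clip((age - 60.0) / 20.0,
                                                       0.0, 2.0))
            else:
                eff = spec.effect_size * mult
            _apply_effect(W, plans, eff)

            rows.append((f"S{k:04d}", g, age, sex, apoe4))
            mats.append(W)
            k += 1

    table = pd.DataFrame(rows, columns=["subject_id", "group", "age",
                                        "sex", "apoe4"])
    planted_edges = set()
    signal_partners = {}
    for s, plan in plans.items():
        for arr in plan.values():
            planted_edges.update((min(s, int(p)), max(s, int(p)))
                                 for p in arr)
        signal_partners[s] = sorted(
            set(plan["amplified"]) | set(plan["suppressed"])
            | set(plan["rerouted"]))
    truth = {"seeds": plans, "planted_edges": planted_edges,
             "signal_partners": signal_partners, "template": template}
    return Cohort(table, np.array(mats), default_labels(n),
                  ground_truth=truth)


def template_connectome(spec: SyntheticSpec, seed: int | None = None):
    """The population template weight matrix a spec implies."""
    from .network import Connectome
    spec.validate()
    rng_tpl = _streams(spec, seed)[0]
    return Connectome(_template(spec, rng_tpl), default_labels(spec.n_nodes))


def generate_streamline_summary(spec: SyntheticSpec, seed: int | None = None):
    """Tractography-style summary consistent with the spec's template.

    Returns ``(summary, surfaces)``: a per-pair table with columns
    node_i, node_j, count, mean_length (harmonic mean, arbitrary length
    units) and an array of per-node surface areas.  Feeding the summary
    to :func:`conwas.network.weights_from_summary` reproduces the
    template weight matrix.
    """
    spec.validate()
    streams = _streams(spec, seed)
    rng_tpl, rng_sum = streams[0], streams[4]
    template = _template(spec, rng_tpl)
    n = spec.n_nodes
    surfaces = np.exp(3.0 + 0.3 * rng_sum.standard_normal(n))
    iu = np.triu_indices(n, k=1)
    recs = []
    for i, j in zip(*iu):
        w = template[i, j]
        if w == 0:
            recs.append((i, j, 0, 1.0))
            continue
        count = int(rng_sum.integers(20, 200))
        # harmonic mean length that makes the connection-density formula
        # return exactly the template weight
        mean_length = 2.0 * count / ((surfaces[i] + surfaces[j]) * w)
        recs.append((i, j, count, mean_length))
    summary = pd.DataFrame(recs, columns=["node_i", "node_j", "count",
                                          "mean_length"])
    return summary, surfaces
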