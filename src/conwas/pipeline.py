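"""End-to-end driver: simulate -> build -> mdmr -> posthoc -> classify."""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import run_classification
from .cohort import Cohort
from .io import load_cohort, write_cohort
from .mdmr import DEFAULT_COMPARISONS, run_mdmr
from .posthoc import (delta_effect_size, pairwise_strength_permutation,
                      strength_group_glm, strength_table, top_k_connections)
from .synthetic import SyntheticSpec, generate_cohort

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

ALL_STAGES = ("simulate", "build", "mdmr", "posthoc", "classify")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    out_dir: str = "conwas_run"
    matrices_dir: str | None = None       # load instead of simulate
    cohort_csv: str | None = None
    stages: tuple = ALL_STAGES
    density: float = 0.05
    permutations: int = 5000
    n_randomizations: int = 100           # delta randomizations
    seed_p_threshold: float = 0.001       # seed-region selection (3-group)
    k_top: int = 5
    covariates: tuple = ("age", "sex", "apoe4")
    comparisons: dict | None = None
    classification_repeats: int = 5
    classification_folds: int = 5
    master_seed: int = 0
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides

    def validate(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if not 0 < self.seed_p_threshold < 1:
            raise ValueError("seed_p_threshold must be in (0, 1)")
        for name, value in (("permutations", self.permutations),
                            ("n_randomizations", self.n_randomizations),
                            ("k_top", self.k_top),
                            ("classification_repeats",
                             self.classification_repeats),
                            ("classification_folds",
                             self.classification_folds)):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        if isinstance(cfg.covariates, list):
            cfg.covariates = tuple(cfg.covariates)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["covariates"] = list(self.covariates)
        return d


@dataclass
class RunManifest:
    """Record sufficient for exact replay: config, seeds, warnings."""

    config: dict
    version: str
    stage_seeds: dict
    warnings: list
    timestamps: dict

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _stage_seed(master: int, stage: str) -> int:
    idx = ALL_STAGES.index(stage)
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0]
               % 2**31)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the requested stages in order, writing all outputs.

    Result tables are byte-identical across reruns with the same config
    (the manifest's wall-clock stamps are the only varying output).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {s: _stage_seed(config.master_seed, s)
                   for s in config.stages}
    caught: list[str] = []
    stamps = {}
    cohort: Cohort | None = None

    def _run_stage(name, fn):
        stamps[name + "_start"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                result = fn()
            caught.extend(f"{name}: {w.message}" for w in wlist)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                from exc
        stamps[name + "_end"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        return result

    if "simulate" in config.stages:
        def _simulate():
            spec = SyntheticSpec(**config.synthetic)
            c = generate_cohort(spec, seed=stage_seeds["simulate"])
            write_cohort(c, out / "cohort")
            return c
        cohort = _run_stage("simulate", _simulate)
    elif config.matrices_dir is not None:
        cohort = load_cohort(config.matrices_dir, config.cohort_csv)

    if cohort is None:
        raise RuntimeError("no cohort: request the simulate stage or give "
                           "matrices_dir")

    if "build" in config.stages:
        cohort = _run_stage("build",
                            lambda: cohort.thresholded(config.density))

    scans = None
    if "mdmr" in config.stages:
        def _mdmr():
            res = run_mdmr(cohort, comparisons=config.comparisons,
                           covariates=config.covariates,
                           permutations=config.permutations,
                           seed=stage_seeds["mdmr"])
            for name, scan in res.items():
                scan.table.to_csv(out / f"mdmr_{name}.tsv", sep="\t",
                                  index=False)
            return res
        scans = _run_stage("mdmr", _mdmr)

    if "posthoc" in config.stages and scans is not None:
        def _posthoc():
            three = next((n for n, g in (config.comparisons
                                         or DEFAULT_COMPARISONS).items()
                          if len(g) == 3 and n in scans), None)
            source = scans[three] if three else next(iter(scans.values()))
            seeds = source.seed_regions(config.seed_p_threshold)
            if not seeds:
                warnings.warn("no seed region passed the threshold; using "
                              "the 3 smallest-p regions")
                seeds = source.table.nsmallest(3, "p_perm")["region"].tolist()
            groups = ((config.comparisons or DEFAULT_COMPARISONS)[three]
                      if three else tuple(np.unique(cohort.labels)))
            sub = cohort.subset(groups=groups)
            rng_children = np.random.SeedSequence(
                stage_seeds["posthoc"]).spawn(len(seeds) + 1)
            effects = pd.concat(
                [delta_effect_size(sub, s, covariates=config.covariates,
                                   n_randomizations=config.n_randomizations,
                                   seed=np.random.default_rng(child))
                 for child, s in zip(rng_children, seeds)],
                ignore_index=True)
            top = top_k_connections(effects, k=config.k_top)
            effects.to_csv(out / "delta_effects.tsv", sep="\t", index=False)
            top.to_csv(out / "top_connections.tsv", sep="\t", index=False)

            strengths = strength_table(sub)
            strengths.to_csv(out / "nodal_strengths.tsv", sep="\t",
                             index=False)
            rng_pair = np.random.default_rng(rng_children[-1])
            pairs = [(a, b) for i, a in enumerate(groups)
                     for b in groups[i + 1:]]
            rows = []
            for s in seeds:
                glm_p = strength_group_glm(strengths, sub, s,
                                           config.covariates)
                row = {"region": s, "region_label": cohort.node_labels[s],
                       "glm_p": glm_p}
                for a, b in pairs:
                    row[f"perm_p_{a}_vs_{b}"] = pairwise_strength_permutation(
                        strengths, sub, s, (a, b), config.covariates,
                        permutations=min(config.permutations, 1999),
                        seed=rng_pair)
                rows.append(row)
            pd.DataFrame(rows).to_csv(out / "strength_comparison.tsv",
                                      sep="\t", index=False)
            # radar-chart-ready per-group mean connectivity along top axes
            radar = []
            for r in top.itertuples():
                w = sub.matrices[:, r.seed, r.partner]
                for g in groups:
                    radar.append((cohort.node_labels[r.seed],
                                  cohort.node_labels[r.partner], g,
                                  float(w[sub.labels == g].mean())))
            pd.DataFrame(radar, columns=["seed", "partner", "group",
                                         "mean_weight"]).to_csv(
                out / "radar_axes.csv", index=False)
            return seeds
        _run_stage("posthoc", _posthoc)

    if "classify" in config.stages:
        def _classify():
            report = run_classification(
                cohort, repeats=config.classification_repeats,
                folds=config.classification_folds,
                covariates=config.covariates,
                seed_p_threshold=config.seed_p_threshold,
                k=config.k_top,
                n_randomizations=config.n_randomizations,
                seed=stage_seeds["classify"])
            report.table.to_csv(out / "classification.tsv", sep="\t",
                                index=False)
            report.aggregate().to_csv(out / "classification_mean.tsv",
                                      sep="\t", index=False)
            report.compare().to_csv(out / "classification_comparison.tsv",
                                    sep="\t", index=False)
            return report
        _run_stage("classify", _classify)

    manifest = RunManifest(config=config.to_dict(), version=__version__,
                           stage_seeds=stage_seeds, warnings=caught,
                           timestamps=stamps)
    manifest.write(out / "manifest.json")
    return manifest
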