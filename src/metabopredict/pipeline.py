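"""End-to-end pipeline: simulate -> preprocess -> features -> stratify ->
fit/validate -> associate, as one reproducible run.

A :class:`RunConfig` mirrors each stage's parameters, round-trips through
YAML, and is hashed into every output.  One master seed feeds the run;
per-stage seeds are derived by stable hashing (CRC32 of the stage name
mixed into a ``SeedSequence``), so toggling one stage never perturbs
another stage's randomness.  All tabular intermediates are plain delimited
text.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import association, preprocess, srv
from .library import default_library, dump_library
from .simulate import CohortConfig, simulate_cohort, write_cohort
from .stratify import groups_to_targets, stratify as stratify_table
from .spectra import SpectralDataset
from .srv import FeatureTable
from .validation import validate_model

__all__ = ["RunConfig", "run_pipeline", "extract_features", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "run_out"
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "preprocess": True, "features": True,
        "stratify": True, "fit": True, "associate": True, "screen": True,
    })
    simulate: dict = field(default_factory=dict)   # CohortConfig overrides
    preprocess: dict = field(default_factory=lambda: {
        "max_shift": 20, "min_segment": 32, "corr_gain_threshold": 0.0,
        "exclude": [[4.5, 5.0], [5.4, 6.2]],       # water / urea windows
    })
    features: dict = field(default_factory=lambda: {
        "corr_threshold": 0.9, "min_size": 3, "mode": "mean", "log": True,
    })
    stratify: dict = field(default_factory=lambda: {
        "glycemia_col": "CG", "bw_col": "BW", "k_sd": 2.0, "lng_quantile": 0.1,
    })
    fit: dict = field(default_factory=lambda: {
        "contrasts": ["extreme", "lean_vs_ob", "ng_vs_igt", "lng_vs_ligt"],
        "k": 7, "n_orth": 1, "scaling": "uv", "n_iter": 999,
    })
    associate: dict = field(default_factory=lambda: {
        "alpha": 0.05, "n_iter": 999,
    })
    screen: dict = field(default_factory=lambda: {
        "timepoints": [0], "k": 7, "n_orth": 1, "n_iter": 199, "alpha": 0.05,
    })

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for key, value in payload.items():
            default = getattr(base, key)
            if isinstance(default, dict) and isinstance(value, dict):
                merged = dict(default)
                merged.update(value)
                setattr(base, key, merged)
            else:
                setattr(base, key, value)
        return base

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([int(self.seed), zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % 2**31)


def extract_features(
    ds: SpectralDataset,
    library,
    corr_threshold: float = 0.9,
    min_size: int = 3,
    mode: str = "mean",
    log: bool = True,
) -> FeatureTable:
    """PQN (full resolution) -> SRV clustering -> annotation -> cluster
    intensities -> log.

    PQN runs on the full-resolution spectra, where the median quotient is
    taken over thousands of columns dominated by baseline and unloaded
    resonances and therefore tracks instrumental dilution; a median
    quotient over the handful of cluster features would instead absorb any
    biology shared by many metabolites and bias every feature.
    """
    normed, dil = preprocess.pqn_normalize(ds)
    clusters = srv.srv_cluster(normed, corr_threshold=corr_threshold, min_size=min_size)
    clusters = srv.annotate_clusters(clusters, library)
    ft = srv.cluster_intensities(normed, clusters, mode=mode)
    meta = dict(ft.meta)
    meta["pqn_dilution"] = {s: float(d) for s, d in dil.items()}
    ft = FeatureTable(ft.values, ft.clusters, ft.sample_ids, meta)
    if log:
        ft = srv.log_transform(ft)
    return ft


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the enabled stages in order; returns the run report dict.

    Identical config + seed gives an identical report.  Stage failures
    propagate with the stage name prefixed.
    """
    cfg = config or RunConfig()
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "timings": {},
    }
    cfg.to_yaml(os.path.join(cfg.outdir, "run_config.yaml"))

    cohort = None
    datasets: dict = {}
    features: dict = {}
    pheno = None
    strat_result = None

    def _stage(name):
        enabled = cfg.stages.get(name, False)
        if enabled:
            report["timings"][name] = time.perf_counter()
        return enabled

    def _done(name):
        report["timings"][name] = round(time.perf_counter() - report["timings"][name], 3)

    try:
        if _stage("simulate"):
            sim_cfg = CohortConfig(**{"seed": cfg.stage_seed("simulate"), **cfg.simulate})
            cohort = simulate_cohort(sim_cfg)
            write_cohort(cohort, os.path.join(cfg.outdir, "cohort"))
            dump_library(cohort.library, os.path.join(cfg.outdir, "cohort", "library.yaml"))
            datasets = dict(cohort.spectra)
            pheno = cohort.phenotypes
            _done("simulate")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    library = cohort.library if cohort is not None else default_library()

    try:
        if _stage("preprocess") and datasets:
            pp = cfg.preprocess
            regions = [tuple(r) for r in pp.get("exclude", [])]
            for tp in list(datasets):
                res = preprocess.rspa_align(
                    datasets[tp],
                    max_shift=pp.get("max_shift", 20),
                    min_segment=pp.get("min_segment", 32),
                    corr_gain_threshold=pp.get("corr_gain_threshold", 0.0),
                )
                ds = preprocess.exclude_regions(res.aligned, regions)
                datasets[tp] = ds
                ds.write(os.path.join(cfg.outdir, f"preprocessed_day{tp}.tsv"))
            _done("preprocess")
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        if _stage("features") and datasets:
            fc = cfg.features
            for tp, ds in datasets.items():
                ft = extract_features(
                    ds, library,
                    corr_threshold=fc.get("corr_threshold", 0.9),
                    min_size=fc.get("min_size", 3),
                    mode=fc.get("mode", "mean"),
                    log=fc.get("log", True),
                )
                features[tp] = ft
                ft.write(os.path.join(cfg.outdir, f"features_day{tp}.tsv"))
            report["features"] = {
                str(tp): len(ft.clusters) for tp, ft in features.items()
            }
            _done("features")
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc

    try:
        if _stage("stratify") and pheno is not None:
            sc = cfg.stratify
            strat_result = stratify_table(
                pheno, sc.get("glycemia_col", "CG"), sc.get("bw_col", "BW"),
                k_sd=sc.get("k_sd", 2.0), lng_quantile=sc.get("lng_quantile", 0.5),
            )
            labelled = pheno.copy()
            labelled["group"] = strat_result.labels
            labelled.to_csv(os.path.join(cfg.outdir, "phenotypes_labelled.tsv"),
                            sep="\t", index_label="animal")
            report["stratification"] = {
                "counts": strat_result.counts(),
                "thresholds": strat_result.thresholds,
                "rule": strat_result.rule,
            }
            _done("stratify")
    except Exception as exc:
        raise RuntimeError(f"stage 'stratify' failed: {exc}") from exc

    try:
        if _stage("fit") and strat_result is not None and 0 in features:
            fc = cfg.fit
            day0 = features[0]
            contrasts_out = {}
            for contrast in fc.get("contrasts", []):
                try:
                    ids, ybin, comp = groups_to_targets(strat_result, contrast)
                except ValueError as exc:
                    contrasts_out[contrast] = {"error": str(exc)}
                    continue
                sub = day0.subset_samples([i for i in ids if i in day0.sample_ids])
                yv = ybin.loc[sub.sample_ids].to_numpy(dtype=float)
                n1 = int(yv.sum())
                # 7-fold when both classes support stratification, else LOO
                k = fc.get("k", 7)
                if min(n1, len(yv) - n1) < k:
                    k = len(yv)
                rep = validate_model(
                    sub.values, yv, mode="da",
                    k=k,
                    n_orth=fc.get("n_orth", 1), scaling=fc.get("scaling", "uv"),
                    n_iter=fc.get("n_iter", 999),
                    seed=cfg.stage_seed(f"fit:{contrast}"),
                )
                entry = rep.to_dict()
                entry.update(comp)
                contrasts_out[contrast] = entry
            report["contrasts"] = contrasts_out
            _done("fit")
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc

    try:
        if _stage("associate") and 0 in features and pheno is not None:
            ac = cfg.associate
            numeric = pheno.select_dtypes("number")
            amat = association.build_association_matrix(
                features[0], numeric,
                alpha=ac.get("alpha", 0.05), n_iter=ac.get("n_iter", 999),
                seed=cfg.stage_seed("associate"),
            )
            amat.write(os.path.join(cfg.outdir, "associations"))
            report["association"] = {
                "n_cells": int(amat.rho.size),
                "n_significant": amat.n_significant(),
                "alpha": amat.alpha,
                "n_iter": amat.n_iter,
            }
            _done("associate")
    except Exception as exc:
        raise RuntimeError(f"stage 'associate' failed: {exc}") from exc

    try:
        if _stage("screen") and features and pheno is not None:
            sc = cfg.screen
            subset = {tp: features[tp] for tp in sc.get("timepoints", [0])
                      if tp in features}
            table = association.phenotype_prediction_screen(
                subset, pheno.select_dtypes("number"),
                k=sc.get("k", 7), n_orth=sc.get("n_orth", 1),
                n_iter=sc.get("n_iter", 199), alpha=sc.get("alpha", 0.05),
                seed=cfg.stage_seed("screen"),
            )
            table.to_csv(os.path.join(cfg.outdir, "phenotype_screen.tsv"),
                         sep="\t", index=False)
            report["screen"] = {
                "n_models": int(len(table)),
                "n_significant": int(table["significant"].sum()),
                "alpha": sc.get("alpha", 0.05),
            }
            _done("screen")
    except Exception as exc:
        raise RuntimeError(f"stage 'screen' failed: {exc}") from exc

    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
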