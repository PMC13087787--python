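"""End-to-end orchestration from a resolved configuration.

Stages run in a fixed order — load/simulate and standardize, paired trait
tests, functional space + per-site indices, hypervolume overlap table,
counterfactual decomposition + variation partitioning, spatial GLS — and
every stage writes its interface file into the output directory, plus a
``run_manifest.json`` with the resolved configuration, stage seeds and
wall times.  One global seed deterministically derives per-stage seeds
through ``numpy.random.SeedSequence(global_seed).spawn``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import PREDICTOR_NAMES, TRAIT_NAMES, SiteTable, SurveyPair
from .decomposition import build_components, build_shared_space, variation_partition
from .fspace import axis_trait_correlation, site_indices
from .hypervolume import survey_overlap_table
from .io import read_survey, write_survey
from .simulate import SyntheticScenario, generate_scenario
from .spatialgls import select_and_average, vif_filter
from .traitstats import cwm_table, paired_cwm_tests

log = logging.getLogger(__name__)

#: every tunable must be present in a resolved config (no hidden defaults)
REQUIRED_KEYS = (
    "seed", "outdir", "pool_periods", "k_use", "hv_quantile",
    "hv_samples_per_point", "hv_resample_samples_per_point", "n_perm",
    "n_boot", "alpha", "vif_threshold", "delta_aic", "importance_cutoff",
    "moran_alpha", "drop_unknown_species",
)


def default_config(seed: int = 0, outdir: str = "fdshift_out") -> dict[str, Any]:
    """A fully-resolved default configuration (edit and pass to run_pipeline)."""
    return {
        "seed": seed,
        "outdir": outdir,
        "input": None,  # path map for read_survey, or None to simulate
        "simulate": {},  # SyntheticScenario overrides when input is None
        "pool_periods": True,
        "k_use": 4,
        "hv_quantile": 0.95,
        "hv_samples_per_point": 500,
        "hv_resample_samples_per_point": 100,
        "n_perm": 999,
        "n_boot": 999,
        "alpha": 0.05,
        "vif_threshold": 5.0,
        "delta_aic": 2.0,
        "importance_cutoff": 0.5,
        "moran_alpha": 0.05,
        "drop_unknown_species": False,
    }


class ConfigError(ValueError):
    pass


def resolve_config(cfg: Mapping[str, Any]) -> dict[str, Any]:
    missing = [k for k in REQUIRED_KEYS if k not in cfg]
    if missing:
        raise ConfigError(f"configuration missing required key(s): {missing}")
    out = dict(cfg)
    out.setdefault("input", None)
    out.setdefault("simulate", {})
    return out


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        return resolve_config(yaml.safe_load(fh))


def _stage_seeds(seed: int, names: tuple[str, ...]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)}


STAGES = ("simulate", "overlap", "gls")


def run_pipeline(cfg: Mapping[str, Any]) -> dict[str, Any]:
    """Execute all stages; returns a report bundle of in-memory results."""
    cfg = resolve_config(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]), STAGES)
    manifest: dict[str, Any] = {
        "config": {k: v for k, v in cfg.items() if k != "simulate"}
        | {"simulate": {k: np.asarray(v).tolist() if isinstance(v, np.ndarray) else v
                        for k, v in cfg["simulate"].items()}},
        "stage_seeds": seeds,
        "version": __version__,
        "wall_times_s": {},
    }
    log.info("resolved config: %s", json.dumps(manifest["config"], default=str))
    report: dict[str, Any] = {}

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                manifest["wall_times_s"][name] = round(time.perf_counter() - self.t0, 3)
        return _T()

    # ---- stage: load or simulate -------------------------------------
    with timed("load"):
        if cfg["input"] is not None:
            pair, sites = read_survey(cfg["input"],
                                      drop_unknown_species=cfg["drop_unknown_species"])
            truth = None
        else:
            scenario = SyntheticScenario(**{"rng_seed": seeds["simulate"],
                                            **cfg["simulate"]})
            pair, sites, truth = generate_scenario(scenario)
            write_survey(pair, sites, outdir / "input")
            with open(outdir / "input" / "ground_truth.json", "w") as fh:
                json.dump(truth.to_jsonable(), fh, indent=1)
    report["pair"], report["sites"], report["truth"] = pair, sites, truth

    # ---- stage: space, indices, CWMs, paired tests -------------------
    with timed("space_indices"):
        fs, st = build_shared_space(pair, k_use=cfg["k_use"],
                                    pool_periods=cfg["pool_periods"])
        report["space"] = fs
        axes = pd.DataFrame(
            fs.coordinates,
            index=pd.MultiIndex.from_tuples(fs.species, names=["period", "species_id"]),
            columns=[f"axis{i+1}" for i in range(fs.coordinates.shape[1])],
        )
        axes.to_csv(outdir / "axes.csv", float_format="%.10g")
        report["axis_trait"] = axis_trait_correlation(fs, st)
        report["axis_trait"].to_csv(outdir / "axis_trait_correlations.csv", index=False)

        indices = {}
        cwms = {}
        for period in ("P1990", "P2020"):
            comm = pair.community(period)
            idx = site_indices(fs, comm, period_key=lambda s, p=period: (p, s),
                               k_use=cfg["k_use"])
            z = st.rows_for(period)
            cw = cwm_table(comm, z)
            cwms[period] = cw
            out = idx.join(cw.rename(columns=lambda c: f"CWM_{c.replace('/', '_')}"))
            out.to_csv(outdir / f"fd_indices_{period[1:]}.csv", float_format="%.10g")
            indices[period] = out
        report["indices"] = indices
        report["cwm"] = cwms
        tests = paired_cwm_tests(cwms["P1990"], cwms["P2020"], alpha=cfg["alpha"])
        tests.to_csv(outdir / "trait_tests.csv", index=False, float_format="%.10g")
        report["trait_tests"] = tests

    # ---- stage: hypervolume overlaps ---------------------------------
    with timed("overlap"):
        overlaps = survey_overlap_table(
            st, n_perm=cfg["n_perm"], n_boot=cfg["n_boot"],
            seed=seeds["overlap"],
            samples_per_point=cfg["hv_samples_per_point"],
            quantile=cfg["hv_quantile"],
            resample_samples_per_point=cfg["hv_resample_samples_per_point"],
            include_total=True,
        )
        overlaps.to_csv(outdir / "overlaps.csv", index=False, float_format="%.10g")
        report["overlaps"] = overlaps

    # ---- stage: decomposition ----------------------------------------
    with timed("decomposition"):
        cv = build_components(pair, k_use=cfg["k_use"], fs=fs)
        cv.table.to_csv(outdir / "decomposition.csv", float_format="%.10g")
        vp = variation_partition(cv)
        with open(outdir / "decomposition_summary.json", "w") as fh:
            json.dump(vp.summary(), fh, indent=1, default=float)
        report["components"], report["partition"] = cv, vp

    # ---- stage: spatial GLS ------------------------------------------
    with timed("gls"):
        X = sites.predictors(scaled=True)
        retained, vift = vif_filter(X, threshold=cfg["vif_threshold"])
        Xr = X[retained]
        coords = sites.coords
        responses: dict[str, np.ndarray] = {}
        for trait in TRAIT_NAMES:
            delta = (cwms["P2020"][trait] - cwms["P1990"][trait]).to_numpy()
            responses[f"dCWM_{trait.replace('/', '_')}"] = delta
        for name in ("SR", "FRic", "FEve", "FDiv"):
            delta = (indices["P2020"][name] - indices["P1990"][name]).to_numpy()
            responses[f"d{name}"] = delta
        rows = []
        gls_models = {}
        for rname, yv in responses.items():
            if np.any(~np.isfinite(yv)) or np.std(yv) == 0.0:
                log.warning("GLS: skipping %s (undefined or constant)", rname)
                continue
            summ = select_and_average(
                yv, Xr, coords, response=rname,
                moran_alpha=cfg["moran_alpha"], delta_aic=cfg["delta_aic"],
                importance_cutoff=cfg["importance_cutoff"],
            )
            gls_models[rname] = summ
            best = summ.best
            for pred in ["Intercept", *best.predictors]:
                rows.append({
                    "response": rname, "predictor": pred,
                    "coef": best.coefficients[pred], "se": best.se[pred],
                    "p": best.p_values[pred], "structure": best.structure,
                    "AIC": best.aic, "BIC": best.bic, "logLik": best.loglik,
                    "importance": summ.importance.get(pred, np.nan),
                    "retained": pred in summ.retained,
                    "moran_I": summ.moran[0], "moran_p": summ.moran[2],
                })
        gls_df = pd.DataFrame(rows)
        gls_df.to_csv(outdir / "gls_results.csv", index=False, float_format="%.10g")
        report["gls"], report["gls_table"] = gls_models, gls_df
        vift.to_csv(outdir / "vif.csv", float_format="%.10g")

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    report["manifest"] = manifest
    return report
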