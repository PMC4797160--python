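"""End-to-end analysis pipeline: ice -> histories -> CJS -> selection -> GOF.

Ties the stages together for file-based runs: read (or simulate) the fish
registry, tracking records, reach table and winter weather; compute the ice
covariate; classify fates and build pooled encounter histories; fit the
candidate CJS models; estimate overdispersion on the covariate-free global
model; rank by QAICc; and test the maturity/fate association.  Every run
writes a manifest with the seed and a config hash so reruns are
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .assoc import mantel_haenszel, maturity_fate_table, risk_ratio
from .cjs import fit as fit_cjs
from .cjs import real_estimates
from .design import CJSData
from .histories import (
    TRACKING_ACCURACY_M,
    build_history,
    classify_fate,
    default_reach_table,
    fish_covariates,
    pool_occasions,
    truncate_mortality,
)
from .icegrowth import IcePhysics, grow_series
from .selection import ModelResult, adjust_for_overdispersion, median_chat, rank_models
from .synthetic import SimulationConfig, simulate_dataset, weekly_ice_covariate

logger = logging.getLogger("wintercmr")

__all__ = ["PipelineConfig", "PipelineError", "prepare_cjs_data", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # either file inputs ...
    registry_path: str | None = None
    tracking_path: str | None = None
    reach_path: str | None = None
    weather_path: str | None = None
    # ... or a synthetic run
    simulate: bool = False

    n_occasions: int = 26
    accuracy_m: float = TRACKING_ACCURACY_M
    pooling_width: int = 2
    cessation_weeks: int | None = None  # mortality-truncation rule; off unless set
    ice_physics: dict = field(default_factory=dict)
    models: list = field(
        default_factory=lambda: [
            "{phi(1)p(g)}",
            "{phi(cond)p(g x ice)}",
            "{phi(cond)p(g x ice + complex)}",
        ]
    )
    global_model: str = "{phi(g)p(g x t)}"
    chat_levels: tuple = (1.0, 1.25, 1.5, 1.75, 2.0)
    chat_n_rep: int = 30
    run_chat: bool = True
    run_assoc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accuracy_m <= 0:
            raise ValueError("tracking accuracy must be positive")
        if self.pooling_width < 1:
            raise ValueError("pooling width must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        blob = yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def prepare_cjs_data(
    registry,
    tracking,
    reach,
    ice_weekly: np.ndarray,
    n_occasions: int = 26,
    accuracy: float = TRACKING_ACCURACY_M,
    pooling_width: int = 2,
    cessation_weeks: int | None = None,
) -> tuple[CJSData, pd.DataFrame]:
    """Fate-classify, truncate, pool, and assemble the CJS input.

    Returns the pooled :class:`CJSData` over residents plus a per-fish frame
    with fates and covariates (all fish, for reporting).  The pooled ice
    covariate is the mean weekly thickness over each pooled window.
    """
    by_fish: dict[str, list] = {f.fish_id: [] for f in registry}
    for rec in tracking:
        if rec.fish_id not in by_fish:
            raise ValueError(f"tracking record for unknown fish {rec.fish_id}")
        by_fish[rec.fish_id].append(rec)

    rows, hist_mat, groups, ids = [], [], [], []
    for fish in registry:
        recs = by_fish[fish.fish_id]
        fish.fate = classify_fate(fish, recs, accuracy)
        covs = fish_covariates(fish, recs, reach)
        rows.append({"fish_id": fish.fish_id, "group": fish.group, "fate": fish.fate, **covs})
        if fish.fate != "resident":
            continue
        hist = build_history(fish.fish_id, recs, n_occasions)
        if cessation_weeks is not None:
            det = [r.occasion for r in recs if r.detected]
            dead = (
                bool(det)
                and max(det) <= n_occasions - cessation_weeks
                and not fish.spring_recaptured
            )
            hist = truncate_mortality(hist, recs, dead, accuracy)
        hist = pool_occasions(hist, pooling_width)
        hist_mat.append(hist.bits)
        groups.append(fish.group)
        ids.append(fish.fish_id)

    per_fish = pd.DataFrame(rows)
    if not hist_mat:
        raise ValueError("no resident fish; nothing to model")
    ice_pooled = np.asarray(ice_weekly)[: n_occasions].reshape(-1, pooling_width).mean(axis=1)
    resident_covs = per_fish.set_index("fish_id").loc[ids, ["cond", "depth", "distance", "complex", "tag_burden"]]
    data = CJSData(
        histories=np.array(hist_mat),
        groups=np.array(groups),
        covariates=resident_covs.reset_index(drop=True),
        time_covariates={"ice": ice_pooled},
        fish_ids=np.array(ids),
    )
    return data, per_fish


def _stage(name):
    logger.info("stage %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write a report bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.hash(), "seed": config.seed}
    timers = {}

    # --- inputs -----------------------------------------------------------
    t0 = _stage("inputs")
    try:
        if config.simulate:
            ds = simulate_dataset(SimulationConfig(seed=config.seed, n_occasions=config.n_occasions))
            registry, tracking, reach, winter = ds.registry, ds.tracking, ds.reach, ds.winter
        else:
            registry = wio.read_registry(config.registry_path)
            tracking = wio.read_tracking(config.tracking_path)
            reach = wio.read_reach(config.reach_path) if config.reach_path else default_reach_table()
            winter = wio.read_weather(config.weather_path)
        if not tracking:
            raise ValueError("tracking input is empty")
    except Exception as e:
        raise PipelineError("inputs", str(e)) from e
    timers["inputs"] = time.time() - t0

    # --- ice --------------------------------------------------------------
    t0 = _stage("ice")
    try:
        physics = IcePhysics(**config.ice_physics)
        ice = grow_series(winter, physics)
        ice_weekly = weekly_ice_covariate(ice, config.n_occasions)
        wio.write_ice_series(ice, outdir / "ice_series.csv")
    except Exception as e:
        raise PipelineError("ice", str(e)) from e
    timers["ice"] = time.time() - t0

    # --- histories --------------------------------------------------------
    t0 = _stage("histories")
    try:
        data, per_fish = prepare_cjs_data(
            registry,
            tracking,
            reach,
            ice_weekly,
            n_occasions=config.n_occasions,
            accuracy=config.accuracy_m,
            pooling_width=config.pooling_width,
            cessation_weeks=config.cessation_weeks,
        )
        per_fish.to_csv(outdir / "fish_fates.csv", index=False)
        from .histories import EncounterHistory

        hists = [
            EncounterHistory(fish_id=fid, bits=row, pooled=True)
            for fid, row in zip(data.fish_ids, data.histories)
        ]
        wio.write_inp(outdir / "histories.inp", hists, list(data.groups),
                      data.covariates, group_levels=data.group_levels)
        counts = per_fish.groupby(["group", "fate"]).size().unstack(fill_value=0)
        report["fate_counts"] = json.loads(counts.to_json())
        report["n_resident"] = int(data.n)
        report["n_tagged"] = len(registry)
    except Exception as e:
        raise PipelineError("histories", str(e)) from e
    timers["histories"] = time.time() - t0

    # --- goodness of fit (median c-hat on the covariate-free global model) -
    c_hat = 1.0
    if config.run_chat:
        t0 = _stage("gof")
        try:
            est = median_chat(
                config.global_model,
                data,
                levels=config.chat_levels,
                n_rep=config.chat_n_rep,
                seed=config.seed,
            )
            c_hat = max(1.0, est.c_hat)
            report["c_hat"] = {"estimate": est.c_hat, "se": est.se, "boundary": est.boundary}
        except Exception as e:
            raise PipelineError("gof", str(e)) from e
        timers["gof"] = time.time() - t0

    # --- model fitting and QAICc ranking ----------------------------------
    t0 = _stage("fit")
    try:
        results, fits = [], {}
        for m in config.models:
            fitted = adjust_for_overdispersion(fit_cjs(m, data, seed=config.seed), c_hat)
            fits[m] = fitted
            results.append(ModelResult.from_fit(fitted, c_hat=c_hat, name=m))
        table = rank_models(results)
        table.to_csv(outdir / "model_table.csv", index=False)
        report["model_table"] = json.loads(table.to_json(orient="records"))
        top_name = table.iloc[0]["model"]
        top = fits[top_name]
        est = real_estimates(top)
        est.to_csv(outdir / "real_estimates.csv", index=False)
        report["top_model"] = {
            "name": top_name,
            "log_likelihood": top.log_likelihood,
            "n_estimable": top.n_estimable,
            "terminal_confounded": top.terminal_confounded,
            "beta": dict(zip(top.dm.labels, top.beta.tolist())),
            "se": dict(zip(top.dm.labels, top.se.tolist())),
        }
    except Exception as e:
        raise PipelineError("fit", str(e)) from e
    timers["fit"] = time.time() - t0

    # --- association ------------------------------------------------------
    if config.run_assoc:
        t0 = _stage("assoc")
        try:
            adults = [f for f in registry if f.maturity in ("spawning", "spent")]
            if adults:
                tbl = maturity_fate_table(adults)
                stat, pval = mantel_haenszel(tbl)
                report["maturity_association"] = {
                    "table": [tbl.a, tbl.b, tbl.c, tbl.d],
                    "chi_square": stat,
                    "p_value": pval,
                    "risk_ratio": risk_ratio(tbl) if tbl.c > 0 else None,
                }
        except Exception as e:
            raise PipelineError("assoc", str(e)) from e
        timers["assoc"] = time.time() - t0

    report["timers_s"] = {k: round(v, 3) for k, v in timers.items()}
    manifest = {
        "config_hash": report["config_hash"],
        "seed": config.seed,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
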