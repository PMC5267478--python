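"""Config-driven orchestration of the full analysis pipeline.

Stages run in order synth -> fit -> ppd -> cba -> classify -> bifurcate ->
scenarios; each stage persists its outputs (CSV/JSON only) into the artifact
directory and is skipped on re-run if its outputs already exist, so the
pipeline is resumable.  A manifest records the configuration, seeds and
content hashes of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import bayes, cba, classify, scenarios, synth
from .bayes import Dataset, PosteriorSample, mcmc_sample, posterior_predict
from .model import Condition, ParamVec

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "load_config"]

log = logging.getLogger("mapkqb.pipeline")

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["synth", "fit", "ppd", "cba", "classify", "bifurcate",
               "scenarios"],
    "model": {
        "fp": True,
        "fn": False,
        "sigma_log": 0.2,
        "times": [0.0, 2.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0],
        "n_replicates": 4,
    },
    "prior": {
        "rate_bounds": [1e-4, 1e4],
        "g_bounds": [1.0, 8.0],
        "K_bounds": [0.5, 100.0],
    },
    "sampler": {
        "n_steps": 20000,
        "burn_in": 0.5,
        "n_retain": 500,
        "grc_model": "gauss",
    },
    "scenarios": {
        "ku_grid": [0.0, 0.25, 0.5, 1.0, 2.0, 4.0],
        "t_off_list": [None, 3.0, 12.0],
        "t_report": [17.0],
        "ppd_times": [2.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0],
    },
}


def load_config(path) -> dict:
    """Read a YAML config and merge it over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _merge(base: dict, upd: dict) -> dict:
    out = dict(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> dict:
    """Schema and invariant checks; returns the merged config."""
    cfg = _merge(DEFAULT_CONFIG, config)
    known = set(DEFAULT_CONFIG)
    extra = set(cfg) - known
    if extra:
        raise ValueError(f"unknown config keys: {sorted(extra)}")
    m = cfg["model"]
    if m["fp"] and m["fn"]:
        raise ValueError("model.fp and model.fn must not both be true")
    if m["sigma_log"] <= 0.0:
        raise ValueError("model.sigma_log must be > 0")
    if cfg["sampler"]["n_steps"] < 10:
        raise ValueError("sampler.n_steps must be >= 10")
    bad = [s for s in cfg["stages"] if s not in DEFAULT_CONFIG["stages"]]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    prior = bayes.PriorSpec(
        rate_bounds=tuple(cfg["prior"]["rate_bounds"]),
        g_bounds=tuple(cfg["prior"]["g_bounds"]),
        K_bounds=tuple(cfg["prior"]["K_bounds"]))

    def _require(stage: str, path: Path, loader):
        """Load a persisted upstream artifact or fail naming the stage."""
        if not path.exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {path}; run its upstream stage first")
        return loader(path.parent)

    ds_dir = out / "dataset"
    fit_dir = out / "fit"
    dataset = sample = None

    if "synth" in cfg["stages"]:
        if not (ds_dir / "timecourse.csv").exists():
            log.info("stage synth: generating calibration dataset")
            design = synth.default_design(
                seed=seed,
                times=tuple(cfg["model"]["times"]),
                sigma_log=float(cfg["model"]["sigma_log"]),
                n_replicates=int(cfg["model"]["n_replicates"]))
            generate = synth.generate_dataset(design)
            generate.save(ds_dir)
        dataset = Dataset.load(ds_dir)

    if "fit" in cfg["stages"]:
        if not (fit_dir / "posterior.csv").exists():
            if dataset is None:
                dataset = _require("fit", ds_dir / "timecourse.csv",
                                   Dataset.load)
            log.info("stage fit: MCMC with %d steps", cfg["sampler"]["n_steps"])
            sample = mcmc_sample(
                dataset, n_steps=int(cfg["sampler"]["n_steps"]),
                seed=seed, prior=prior,
                burn_in=float(cfg["sampler"]["burn_in"]),
                n_retain=int(cfg["sampler"]["n_retain"]),
                grc_model=cfg["sampler"]["grc_model"])
            sample.save(fit_dir)
        sample = PosteriorSample.load(fit_dir)

    if "ppd" in cfg["stages"]:
        if sample is None:
            sample = _require("ppd", fit_dir / "posterior.csv",
                              PosteriorSample.load)
        log.info("stage ppd")
        times = np.asarray(cfg["scenarios"]["ppd_times"], dtype=float)
        for gf in ("EGF", "NGF"):
            band, n_failed = posterior_predict(
                sample, Condition.for_growth_factor(gf), times,
                sigma_log=float(cfg["model"]["sigma_log"]), seed=seed)
            band.to_csv(out / f"ppd_{gf.lower()}_ppERK.csv", index=False)
            if n_failed:
                log.warning("ppd %s: %d draws failed", gf, n_failed)

    if "cba" in cfg["stages"]:
        if sample is None:
            sample = _require("cba", fit_dir / "posterior.csv",
                              PosteriorSample.load)
        log.info("stage cba: rest-state classification per draw")
        rows = []
        for i, theta in enumerate(sample.iter_params()):
            sset = cba.find_steady_states(theta, 0.0, Condition.ngf_control())
            x4s = sset.stable_x4()
            rows.append((i, 0.0, len(sset.states), sset.n_stable,
                         sset.classification,
                         x4s[-1] if sset.classification == "bistable" else ""))
        import pandas as pd
        pd.DataFrame(rows, columns=["draw_id", "u", "n_steady", "n_stable",
                                    "class", "zbar3_raw"]).to_csv(
            out / "cba_classification.csv", index=False)
        zbar, n_bi, n_excl = cba.second_state_distribution(sample)
        _write_json(out / "cba_summary.json",
                    {"n_draws": len(sample), "n_bistable": n_bi,
                     "n_excluded": n_excl,
                     "zbar3": [float(v) for v in zbar]})

    if "classify" in cfg["stages"]:
        if sample is None:
            sample = _require("classify", fit_dir / "posterior.csv",
                              PosteriorSample.load)
        log.info("stage classify: trajectory classification per draw")
        fractions, per_draw = classify.population_classify(sample)
        per_draw.to_csv(out / "trajectory_classification.csv", index=False)
        filt = classify.min_switch_filter(per_draw)
        filt.to_csv(out / "min_switch_filter.csv", index=False)
        _write_json(out / "class_fractions.json", fractions)

    if "bifurcate" in cfg["stages"]:
        log.info("stage bifurcate: input sweeps for the frozen fixtures")
        u_grid = np.concatenate([[0.0], np.geomspace(1e-4, 1.0, 40)])
        for name in ("theta_B", "theta_Q"):
            theta = synth.load_fixture(name)
            diagram = classify.bifurcation_sweep(theta, Condition.ngf_control(),
                                                 u_grid)
            diagram.to_frame().to_csv(out / f"bifurcation_{name}.csv",
                                      index=False)
            _write_json(out / f"bifurcation_{name}.json",
                        {"u_snb": list(diagram.u_snb)})

    if "scenarios" in cfg["stages"]:
        if sample is None:
            sample = _require("scenarios", fit_dir / "posterior.csv",
                              PosteriorSample.load)
        log.info("stage scenarios")
        sc = cfg["scenarios"]
        for gf in ("EGF", "NGF"):
            _, summary = scenarios.dose_response(sample, gf, sc["ku_grid"])
            summary.to_csv(out / f"dose_response_{gf.lower()}.csv", index=False)
        times = np.asarray(cfg["scenarios"]["ppd_times"], dtype=float)
        mek = scenarios.mek_inhibition(sample, times, seed=seed)
        mek["control"].to_csv(out / "mek_control_pRaf.csv", index=False)
        mek["mek_inhibited"].to_csv(out / "mek_inhibited_pRaf.csv", index=False)
        fb = scenarios.feedback_removal(sample, times, seed=seed)
        fb["feedback_removed"].to_csv(out / "feedback_removed_ppERK.csv",
                                      index=False)
        term = scenarios.signal_termination(sample, "NGF", sc["t_off_list"],
                                            sc["t_report"], seed=seed)
        med = {k: float(v["mean"].iloc[-1]) for k, v in term.items()
               if k != "n_failed"}
        _write_json(out / "signal_termination.json", med)

    manifest = {
        "config": cfg,
        "artifacts": {p.name: _sha256(p) for p in sorted(out.iterdir())
                      if p.is_file() and p.name != "manifest.json"},
    }
    _write_json(out / "manifest.json", manifest)
    return out
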