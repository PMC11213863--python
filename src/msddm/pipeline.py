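"""End-to-end orchestration: simulate -> preprocess -> fit -> diagnose ->
predictive check -> multisensory metrics.

A :class:`RunConfig` captures every knob of every stage plus the root seed;
the resolved copy (all defaults materialised) is written into the run
directory together with each stage's artifacts, a MANIFEST recording
completion state and checksums, and a structured log.  Stages fail
atomically: a failed stage leaves earlier artifacts and an honest MANIFEST
behind, and a re-run with the same directory resumes after the last
completed stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import DesignSpec, AgeGenerativeModel, simulate_dataset
from .preprocess import preprocess
from .model import build_model, variant_by_id, DEFAULT_AGE_THRESHOLD
from .sampler import sample_posterior, SamplerSettings, Posterior
from .diagnostics import (convergence_report, dic, select_model,
                          posterior_predictive_check)
from .metrics import estimates_from_posterior, benefit_report

logger = logging.getLogger("msddm")

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "preprocess", "fit", "diagnose", "ppc", "metrics")


@dataclass
class RunConfig:
    stages: tuple = ALL_STAGES
    seed: int = 0
    out_dir: str = "msddm_run"
    n_participants: int = 8
    design: dict = field(default_factory=dict)       # DesignSpec overrides
    generator: dict = field(default_factory=dict)    # AgeGenerativeModel overrides
    trials_csv: str | None = None                    # load instead of simulate
    accuracy_threshold: float = 0.5
    accuracy_per_condition: bool = False
    mad_multiplier: float = 2.5
    mad_per_condition: bool = False
    variants: tuple = (8,)
    n_chains: int = 5
    n_iter: int = 11_000
    burn_in: int = 1_000
    thin: int = 2
    age_threshold: float = DEFAULT_AGE_THRESHOLD
    rhat_threshold: float = 1.02
    ppc_draws: int = 200
    point_estimate: str = "mean"

    def resolved(self) -> dict:
        d = asdict(self)
        # the output directory is environment, not analysis configuration;
        # keeping it out makes runs byte-comparable across directories
        d.pop("out_dir")
        d["stages"] = list(self.stages)
        d["variants"] = list(self.variants)
        d["design"] = {**asdict(DesignSpec()), **self.design}
        gen_defaults = asdict(AgeGenerativeModel())
        for key in ("delta_intercepts", "delta_slopes", "theta_intercepts",
                    "theta_slopes", "tau_intercepts", "tau_slopes"):
            gen_defaults[key] = {f"{c}/{h}": v for (c, h), v in
                                 gen_defaults[key].items()}
        d["generator"] = {**gen_defaults, **self.generator}
        d["version"] = __version__
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known - {"version"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.pop("version", None)
        for key in ("stages", "variants"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def design_spec(self) -> DesignSpec:
        base = asdict(DesignSpec())
        base.update(self.design)
        base.pop("conditions", None), base.pop("coherences", None)
        base.pop("categories", None)
        return DesignSpec(**{k: v for k, v in base.items()
                             if k in DesignSpec.__dataclass_fields__})

    def generative_model(self) -> AgeGenerativeModel:
        kwargs = {}
        for key, val in self.generator.items():
            if key.endswith(("_intercepts", "_slopes")) and isinstance(val, dict):
                kwargs[key] = {tuple(k.split("/")): v for k, v in val.items()}
            elif key in AgeGenerativeModel.__dataclass_fields__:
                kwargs[key] = tuple(val) if key == "age_range" else val
        return AgeGenerativeModel(**kwargs)

    def sampler_settings(self) -> SamplerSettings:
        return SamplerSettings(n_chains=self.n_chains, n_iter=self.n_iter,
                               burn_in=self.burn_in, thin=self.thin)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}, "files": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_done(self, stage: str) -> bool:
        return self.data["stages"].get(stage) == "completed"

    def mark(self, stage: str, state: str) -> None:
        self.data["stages"][stage] = state
        self.flush()

    def record(self, path: Path) -> None:
        self.data["files"][path.name] = _sha256(path)
        self.flush()

    def flush(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Raises on the first failing stage after persisting partial outputs and
    marking the failure in the MANIFEST.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    manifest = _Manifest(out / "MANIFEST.json")
    (out / "config.yaml").write_text(yaml.safe_dump(config.resolved(),
                                                    sort_keys=True))
    manifest.record(out / "config.yaml")

    def run_stage(name, fn):
        if name not in config.stages:
            return
        if manifest.stage_done(name):
            logger.info("stage %s already completed; skipping", name)
            return
        manifest.mark(name, "running")
        t0 = time.time()
        try:
            fn()
        except Exception:
            manifest.mark(name, "failed")
            raise
        manifest.mark(name, "completed")
        logger.info("stage %s completed in %.1fs", name, time.time() - t0)

    state: dict = {}

    def _load_trials() -> pd.DataFrame:
        if "trials" not in state:
            src = out / "trials.csv" if (out / "trials.csv").exists() \
                else Path(config.trials_csv)
            state["trials"] = pd.read_csv(src)
        return state["trials"]

    def stage_simulate():
        if config.trials_csv:
            trials = pd.read_csv(config.trials_csv)
            truth = None
        else:
            trials, truth = simulate_dataset(
                config.design_spec(), config.generative_model(),
                config.n_participants, config.seed)
        trials.to_csv(out / "trials.csv", index=False)
        manifest.record(out / "trials.csv")
        if truth is not None:
            truth.to_csv(out / "ground_truth.csv", index=False)
            manifest.record(out / "ground_truth.csv")
        state["trials"] = trials

    def stage_preprocess():
        trials = _load_trials()
        clean, report = preprocess(
            trials, accuracy_threshold=config.accuracy_threshold,
            accuracy_per_condition=config.accuracy_per_condition,
            mad_multiplier=config.mad_multiplier,
            mad_per_condition=config.mad_per_condition)
        clean.to_csv(out / "trials_clean.csv", index=False)
        (out / "exclusion_report.json").write_text(
            json.dumps(report.to_dict(), indent=1))
        manifest.record(out / "trials_clean.csv")
        manifest.record(out / "exclusion_report.json")
        state["clean"] = clean

    def _load_clean() -> pd.DataFrame:
        if "clean" not in state:
            state["clean"] = pd.read_csv(out / "trials_clean.csv")
        return state["clean"]

    def stage_fit():
        clean = _load_clean()
        state["posteriors"] = {}
        state["models"] = {}
        for vid in config.variants:
            model = build_model(variant_by_id(vid), clean,
                                age_threshold=config.age_threshold)
            post = sample_posterior(model, config.sampler_settings(),
                                    seed=config.seed + vid)
            post.save(out / f"posterior_v{vid}.csv",
                      out / f"posterior_v{vid}.meta.json")
            manifest.record(out / f"posterior_v{vid}.csv")
            manifest.record(out / f"posterior_v{vid}.meta.json")
            state["posteriors"][vid] = post
            state["models"][vid] = model

    def _load_fit(vid: int):
        if "posteriors" not in state or vid not in state["posteriors"]:
            post = Posterior.load(out / f"posterior_v{vid}.csv",
                                  out / f"posterior_v{vid}.meta.json")
            model = build_model(variant_by_id(vid), _load_clean(),
                                age_threshold=config.age_threshold)
            state.setdefault("posteriors", {})[vid] = post
            state.setdefault("models", {})[vid] = model
        return state["posteriors"][vid], state["models"][vid]

    def stage_diagnose():
        results = {}
        dics = {}
        for vid in config.variants:
            post, model = _load_fit(vid)
            cr = convergence_report(post, threshold=config.rhat_threshold)
            dr = dic(post, model)
            dics[f"variant_{vid}"] = dr.dic
            results[f"variant_{vid}"] = {
                "max_rhat": cr.max_rhat, "rhat_passed": cr.passed,
                **dr.to_dict()}
        if len(dics) >= 2:
            results["selection"] = select_model(dics)
        (out / "diagnostics.json").write_text(json.dumps(results, indent=1))
        manifest.record(out / "diagnostics.json")
        state["dics"] = dics

    def stage_ppc():
        vid = config.variants[0] if len(config.variants) == 1 else \
            int(min(state.get("dics", {f"variant_{config.variants[0]}": 0}),
                    key=state.get("dics", {f"variant_{config.variants[0]}": 0}).get
                    ).split("_")[1])
        post, model = _load_fit(vid)
        report = posterior_predictive_check(
            post, model, _load_clean(), n_draws=config.ppc_draws,
            seed=config.seed)
        report["variant"] = vid
        (out / "ppc.json").write_text(json.dumps(report, indent=1))
        manifest.record(out / "ppc.json")

    def stage_metrics():
        vid = config.variants[0]
        post, model = _load_fit(vid)
        estimates = estimates_from_posterior(post, model,
                                             point=config.point_estimate)
        rep = benefit_report(estimates)
        rep["per_participant"].to_csv(out / "benefits.csv", index=False)
        (out / "benefit_correlations.json").write_text(
            json.dumps(rep["age_correlations"], indent=1))
        manifest.record(out / "benefits.csv")
        manifest.record(out / "benefit_correlations.json")

    run_stage("simulate", stage_simulate)
    run_stage("preprocess", stage_preprocess)
    run_stage("fit", stage_fit)
    run_stage("diagnose", stage_diagnose)
    run_stage("ppc", stage_ppc)
    run_stage("metrics", stage_metrics)
    return out
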