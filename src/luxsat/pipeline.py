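"""End-to-end pipeline: simulate -> fit surrogate -> sweep saturation points
-> fit control surface -> validate.

Every inter-stage artifact is plain CSV/JSON, written into the run's output
directory:

    samples.csv     simulated gas-exchange table
    model.json      fitted surrogate (normalization + parameters)
    sweep.csv       optimized saturation point per (T, CO2) pair
    surface.json    fitted polynomial control surface
    validation.json predicted-vs-analytic validation line
    manifest.json   config hash, artifact paths, per-stage metrics

A single global seed deterministically derives a per-stage seed
(stage-name keyed), so re-running the whole pipeline — or resuming after
deleting a downstream artifact — reproduces artifacts byte-for-byte.
Existing artifacts are treated as intact stage outputs and are loaded
instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import control_model, optimizer, surrogate, synthetic_data
from .optimizer import AcoConfig, GaConfig, arith_grid
from .surrogate import SvmConfig
from .synthetic_data import DesignGrid, TruthParams

__all__ = [
    "RunConfig",
    "RunManifest",
    "stage_seed",
    "run_pipeline",
    "compare_surrogates",
    "compare_optimizers",
    "default_config",
]

logger = logging.getLogger(__name__)

#: CV grids used when the pipeline tunes the SVR (log2-spaced, fixed a priori).
TUNE_C_GRID = tuple(2.0**k for k in (-1, 1, 3, 5, 7, 9))
TUNE_G_GRID = tuple(2.0**k for k in (-3, -1.5, 0, 1.5, 3))


@dataclass(frozen=True)
class SweepSpec:
    temp_start: float = 12.0
    temp_stop: float = 36.0
    temp_step: float = 3.0
    co2_start: float = 300.0
    co2_stop: float = 2000.0
    co2_step: float = 200.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            object.__setattr__(self, f.name, float(getattr(self, f.name)))

    def temp_grid(self) -> np.ndarray:
        return arith_grid(self.temp_start, self.temp_stop, self.temp_step)

    def co2_grid(self) -> np.ndarray:
        return arith_grid(self.co2_start, self.co2_stop, self.co2_step)


@dataclass(frozen=True)
class ValidationSpec:
    """Off-grid (T, CO2) set scored against analytic saturation points."""

    temp_levels: tuple = (12.0, 15.0, 20.0, 25.0, 30.0)
    co2_levels: tuple = (300.0, 600.0, 800.0, 1000.0, 1200.0, 1500.0)

    def __post_init__(self):
        object.__setattr__(self, "temp_levels", tuple(float(v) for v in self.temp_levels))
        object.__setattr__(self, "co2_levels", tuple(float(v) for v in self.co2_levels))


@dataclass(frozen=True)
class RunConfig:
    truth: TruthParams = TruthParams()
    grid: DesignGrid = field(default_factory=synthetic_data.default_design_grid)
    surrogate_kind: str = "svm"          # svm | rbf | bp
    svm: SvmConfig = SvmConfig()
    tune: bool = True                    # CV-tune (c, g) instead of using svm.c/svm.g
    train_frac: float = 0.85
    optimizer_algo: str = "aco"          # aco | ga
    aco: AcoConfig = AcoConfig()
    ga: GaConfig = GaConfig()
    sweep: SweepSpec = SweepSpec()
    co2_scale: float = control_model.DEFAULT_CO2_SCALE
    validation: ValidationSpec = ValidationSpec()
    seed: int = 0
    outdir: str = "luxsat_run"


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    artifacts: dict
    metrics: dict
    version: str
    seed: int


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def config_from_dict(doc: dict) -> RunConfig:
    def sub(cls, key, **extra):
        d = dict(doc.get(key) or {})
        d.update(extra)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown {key} config keys: {sorted(unknown)}")
        for name in ("domain", "eta", "temp_levels", "co2_levels", "ppfd_levels"):
            if name in d and isinstance(d[name], list):
                d[name] = tuple(d[name])
        return cls(**d)

    top = {f.name: doc[f.name] for f in dataclasses.fields(RunConfig)
           if f.name in doc and f.name not in
           ("truth", "grid", "svm", "aco", "ga", "sweep", "validation")}
    return RunConfig(
        truth=sub(TruthParams, "truth"),
        grid=sub(DesignGrid, "grid") if "grid" in doc else synthetic_data.default_design_grid(),
        svm=sub(SvmConfig, "svm"),
        aco=sub(AcoConfig, "aco"),
        ga=sub(GaConfig, "ga"),
        sweep=sub(SweepSpec, "sweep"),
        validation=sub(ValidationSpec, "validation"),
        **top,
    )


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed keyed by stage name, below 2**31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def default_config(seed: int = 0, outdir: str = "luxsat_run") -> RunConfig:
    return RunConfig(seed=int(seed), outdir=str(outdir))


# ---------------------------------------------------------------------------
# stages

def _fit_surrogate(config: RunConfig, train: pd.DataFrame):
    kind = config.surrogate_kind
    if kind == "svm":
        svm_cfg = config.svm
        if config.tune:
            tuned = surrogate.tune_svm(
                train, TUNE_C_GRID, TUNE_G_GRID, k_folds=5,
                seed=stage_seed(config.seed, "tune"),
            )
            svm_cfg = replace(tuned, epsilon=config.svm.epsilon)
            logger.info("CV-tuned SVR hyperparameters: c=%.4g g=%.4g", svm_cfg.c, svm_cfg.g)
        return surrogate.fit_svm(train, svm_cfg)
    if kind == "rbf":
        return surrogate.fit_rbf_net(train)
    if kind == "bp":
        return surrogate.fit_bp_net(train, seed=stage_seed(config.seed, "bp"))
    raise ValueError(f"unknown surrogate kind {kind!r}")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute (or resume) all five stages; returns the run manifest.

    Any stage error aborts with the stage name; the partial manifest written
    so far stays on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / name for name in
             ("samples.csv", "model.json", "sweep.csv", "surface.json", "validation.json")}
    metrics: dict = {}

    def stage(name, artifact, compute, write, read):
        path = paths[artifact]
        try:
            if path.exists():
                logger.info("stage %-10s resuming from %s", name, path)
            else:
                write(compute(), path)
                logger.info("stage %-10s wrote %s", name, path)
            # downstream stages always consume the serialized artifact, so a
            # resumed run sees bit-identical inputs to a fresh one
            return read(path)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    samples = stage(
        "generate", "samples.csv",
        lambda: synthetic_data.simulate_dataset(
            config.grid, config.truth, stage_seed(config.seed, "generate")),
        synthetic_data.write_samples_csv,
        synthetic_data.read_samples_csv,
    )
    metrics["generate"] = {"n_samples": len(samples)}

    train, test = surrogate.split_train_test(
        samples, config.train_frac, stage_seed(config.seed, "split"))

    def fit_and_eval():
        model = _fit_surrogate(config, train)
        return model

    model = stage("surrogate", "model.json", fit_and_eval,
                  surrogate.save_model, surrogate.load_model)
    report = surrogate.evaluate(model, test)
    metrics["surrogate"] = {"kind": model.kind, **dataclasses.asdict(report)}

    opt_cfg = config.ga if config.optimizer_algo == "ga" else config.aco
    opt_cfg = replace(opt_cfg, seed=stage_seed(config.seed, "sweep"))

    def compute_sweep():
        return optimizer.sweep_saturation_points(
            model, config.sweep.temp_grid(), config.sweep.co2_grid(), opt_cfg)

    sweep = stage(
        "sweep", "sweep.csv", compute_sweep,
        lambda df, path: df.to_csv(path, index=False, float_format="%.6f"),
        pd.read_csv,
    )
    metrics["sweep"] = {"n_points": len(sweep), "algo": config.optimizer_algo}

    surface = stage(
        "surface", "surface.json",
        lambda: control_model.fit_control_surface(sweep, config.co2_scale),
        control_model.save_surface,
        control_model.load_surface,
    )
    metrics["surface"] = {"r2": surface.r2, "rmse": surface.rmse}

    def compute_validation():
        temps, co2s = np.meshgrid(
            config.validation.temp_levels, config.validation.co2_levels, indexing="ij")
        ref = pd.DataFrame({
            "temp_c": temps.ravel(),
            "co2_umol_mol": co2s.ravel(),
            "ppfd_sat": synthetic_data.analytic_saturation_point(
                config.truth, temps.ravel(), co2s.ravel()),
        })
        rep = control_model.validate_model(surface, ref)
        return {"slope": rep.slope, "intercept": rep.intercept, "r2": rep.r2, "n": rep.n}

    validation = stage(
        "validate", "validation.json", compute_validation,
        lambda doc, path: path.write_text(json.dumps(doc, indent=1)),
        lambda path: json.loads(path.read_text()),
    )
    metrics["validate"] = validation

    from . import __version__
    manifest = RunManifest(
        config_hash=config_hash(config),
        artifacts={k: str(v) for k, v in paths.items()},
        metrics=_to_plain(metrics),
        version=__version__,
        seed=config.seed,
    )
    (outdir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# comparison tables

def compare_surrogates(config: RunConfig) -> pd.DataFrame:
    """Fit SVM, RBF and BP on the same seeded split; one metrics row each."""
    samples = synthetic_data.simulate_dataset(
        config.grid, config.truth, stage_seed(config.seed, "generate"))
    train, test = surrogate.split_train_test(
        samples, config.train_frac, stage_seed(config.seed, "split"))
    rows = {}
    for kind in ("svm", "rbf", "bp"):
        model = _fit_surrogate(replace(config, surrogate_kind=kind), train)
        rep = surrogate.evaluate(model, test)
        rows[kind] = {"MAE": rep.mae, "MRE": rep.mre, "RMSE": rep.rmse, "R2": rep.r2}
    return pd.DataFrame.from_dict(rows, orient="index")[["MAE", "MRE", "RMSE", "R2"]]


def compare_optimizers(config: RunConfig) -> pd.DataFrame:
    """Score ACO and GA saturation points against the analytic reference.

    Both algorithms run on identical objectives: the noiseless synthetic
    truth curves over the sweep grid.  Reports MAE, MRE (%) and RMSE of
    ppfd_sat versus the closed-form saturation points.
    """
    truth_fn = lambda x, t, c: synthetic_data.true_photosynthesis(x, t, c, config.truth)
    temp_grid, co2_grid = config.sweep.temp_grid(), config.sweep.co2_grid()
    seed = stage_seed(config.seed, "compare_optimizers")
    rows = {}
    for algo in ("aco", "ga"):
        cfg = replace(config.ga if algo == "ga" else config.aco, seed=seed)
        sweep = optimizer.sweep_saturation_points(truth_fn, temp_grid, co2_grid, cfg)
        ref = synthetic_data.analytic_saturation_point(
            config.truth, sweep["temp_c"].to_numpy(), sweep["co2_umol_mol"].to_numpy())
        err = sweep["ppfd_sat"].to_numpy() - ref
        rows[algo] = {
            "MAE": float(np.mean(np.abs(err))),
            "MRE": float(100.0 * np.mean(np.abs(err) / ref)),
            "RMSE": float(np.sqrt(np.mean(err**2))),
        }
    return pd.DataFrame.from_dict(rows, orient="index")[["MAE", "MRE", "RMSE"]]
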