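"""End-to-end orchestration: simulate → preprocess → train → translate →
evaluate, as plain functions the CLI and scripts wrap thinly.

Every stage takes explicit seeds; a single run seed pins simulation, model
initialization, training batch order/noise and sampling, so a rerun with the
same config reproduces every artifact byte-for-byte (timestamps aside).
Stage failures are re-raised annotated with the failing stage name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import preprocessing as prep
from .backbone import BackboneConfig
from .diffusion import ancestral_sample, build_schedule
from .evaluation import MetricsReport, evaluate_windows
from .lbm import LatticeConfig
from .synthetic import SimConfig, generate_dataset, save_dataset
from .training import LossWeights, TrainConfig, TranslationModel, train

__all__ = ["RunConfig", "StageError", "simulate", "preprocess", "fit", "translate",
           "evaluate_pair", "e2e_smoke"]


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Nested configuration of a full run; YAML-friendly flat dataclasses."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_records: int = 20
    af_fraction: float = 0.0
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    diffusion_T: int = 50
    # None: derive from diffusion_T so total corruption matches a T=1000
    # reference chain (see hemodiff.diffusion.default_beta_range)
    beta_start: float | None = None
    beta_end: float | None = None
    weights: LossWeights = field(default_factory=LossWeights)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for key, sub_cls in (("sim", SimConfig), ("lattice", LatticeConfig),
                             ("backbone", BackboneConfig), ("weights", LossWeights),
                             ("train", TrainConfig)):
            if key in raw:
                sub = raw.pop(key)
                if key == "lattice" and "velocities" in sub:
                    sub["velocities"] = tuple(sub["velocities"])
                kw[key] = sub_cls(**sub)
        kw.update(raw)
        return cls(**kw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, exc) from exc

        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped

    return deco


@_stage("simulate")
def simulate(cfg: RunConfig, out_path: str | Path | None = None):
    """Generate the paired dataset; optionally persist container + manifest."""
    if cfg.n_records < 1:
        raise ValueError("n_records must be >= 1")
    records = generate_dataset(cfg.n_records, cfg.sim, seed=cfg.seed,
                               af_fraction=cfg.af_fraction)
    if out_path is not None:
        save_dataset(records, out_path)
    return records


@_stage("preprocess")
def preprocess(records, out_path: str | Path | None = None, **kwargs):
    windows = prep.windows_from_records(records, **kwargs)
    if out_path is not None:
        prep.save_windows(windows, out_path)
    return windows


@_stage("train")
def fit(windows, cfg: RunConfig, checkpoint_dir: str | Path | None = None,
        log_stream=None):
    """Train a fresh model on the given windows; returns (model, schedule, history)."""
    model = TranslationModel(cfg.lattice, cfg.backbone, seed=cfg.seed)
    from .diffusion import default_beta_range

    lo, hi = default_beta_range(cfg.diffusion_T)
    schedule = build_schedule(
        cfg.diffusion_T,
        lo if cfg.beta_start is None else cfg.beta_start,
        hi if cfg.beta_end is None else cfg.beta_end,
    )

    def log_fn(rec):
        if log_stream is not None:
            print(json.dumps({k: round(v, 6) if isinstance(v, float) else v
                              for k, v in rec.items()}), file=log_stream)

    history = train(windows, model, schedule, cfg.weights, cfg.train,
                    log_fn=log_fn if log_stream is not None else None,
                    checkpoint_dir=checkpoint_dir)
    return model, schedule, history


@_stage("translate")
def translate(model: TranslationModel, schedule, windows, seed: int,
              clip_x0: bool = True) -> np.ndarray:
    """PPG→ECG: encode each window's PPG and run ancestral sampling.

    Output rows align 1:1 with the input windows.
    """
    from . import autodiff as ad
    from .autodiff import Tensor

    ppg = np.stack([w.ppg for w in windows])
    if ppg.shape[1] != model.backbone_cfg.length:
        raise ValueError(
            f"window length {ppg.shape[1]} does not match checkpoint length "
            f"{model.backbone_cfg.length}"
        )
    with ad.no_grad():
        h_phys = model.encoder(Tensor(ppg)).data
    return ancestral_sample(model.unet, h_phys, schedule, seed=seed, clip_x0=clip_x0)


@_stage("evaluate")
def evaluate_pair(true_windows, generated: np.ndarray, fs: float) -> MetricsReport:
    true_ecg = np.stack([w.ecg for w in true_windows])
    return evaluate_windows(true_ecg, generated, fs)


def e2e_smoke(cfg: RunConfig | None = None, n_eval: int = 8,
              log_stream=None) -> MetricsReport:
    """Tiny end-to-end pipeline on one CPU: simulate, train, translate, score.

    The last ``n_eval`` windows are held out of training and used for the
    metric report.
    """
    if cfg is None:
        cfg = RunConfig(
            sim=SimConfig(duration_s=30.0, noise_sd=0.01),
            n_records=6,
            backbone=BackboneConfig(base_width=8, attention_dim=8, temb_dim=16,
                                    groups=4, n_timesteps=50),
            diffusion_T=10,
            train=TrainConfig(steps=30, batch_size=8),
        )
    records = simulate(cfg)
    windows = preprocess(records)
    if len(windows) <= n_eval:
        raise StageError("preprocess", ValueError("not enough windows for a held-out split"))
    train_wins, eval_wins = windows[:-n_eval], windows[-n_eval:]
    model, schedule, _ = fit(train_wins, cfg, log_stream=log_stream)
    generated = translate(model, schedule, eval_wins, seed=cfg.seed + 1)
    return evaluate_pair(eval_wins, generated, eval_wins[0].fs)
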