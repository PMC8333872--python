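"""Orchestration: simulate -> preprocess -> train -> evaluate, reproducibly.

A single :class:`PipelineConfig` holds every block of settings; one master
seed deterministically derives per-stage seeds (simulation, balancing,
split, training) so any stage can be re-run in isolation. Each stage reads
its inputs from and writes its artifacts to a run directory, stamps them
with the config hash, and logs its in/out bookkeeping (frames simulated,
frames removed by the likelihood filter, per-tile balancing quota, split
sizes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gazenet, preprocess, synthetic
from .dlc_io import read_dlc_csv, write_dlc_csv
from .evaluation import ErrorReport, build_error_report
from .geometry import ScreenGeometry

__all__ = [
    "PipelineConfig",
    "derive_seed",
    "run_simulate",
    "run_preprocess",
    "run_train",
    "run_evaluate",
    "run_all",
]

logger = logging.getLogger(__name__)

_STAGE_STREAMS = {"simulate": 1, "balance": 2, "split": 3, "train": 4}

LANDMARKS_FILE = "landmarks.csv"
TARGETS_FILE = "targets.csv"
DATASET_FILE = "dataset.csv"
PREPROCESS_REPORT_FILE = "preprocess_report.json"
MODEL_FILE = "model.npz"
TRACE_FILE = "trace.csv"
REPORT_FILE = "error_report.json"
PER_SAMPLE_FILE = "per_sample_errors.csv"
CONFIG_FILE = "config.yaml"


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    stream = _STAGE_STREAMS[stage]
    state = np.random.SeedSequence([int(master_seed), stream]).generate_state(1)[0]
    return int(state % (2**31))


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, serializable to/from YAML."""

    # geometry
    screen_width_mm: float = 595.0
    screen_height_mm: float = 335.0
    screen_width_px: int = 2560
    screen_height_px: int = 1440
    viewing_distance_mm: float = 500.0
    # simulation
    n_lines: int = 5
    base_speed_px_s: float = 300.0
    slow_factor: float = 0.4
    fast_factor: float = 1.6
    margin_px: float = 50.0
    fps: float = 30.0
    noise_sd_px: float = 1.0
    blink_probability: float = 0.027
    pose_yaws_deg: tuple[float, ...] = (-20.0, 0.0, 20.0)
    # preprocessing
    likelihood_threshold: float = 0.7
    balance_edge_px: float = 530.0
    norm_constant: float = 600.0
    split_fractions: tuple[float, float, float] = (0.50, 0.25, 0.25)
    # training
    learning_rate0: float = 0.03
    momentum: float = 0.6
    halve_every_epochs: int = 2000
    batch_size: int = 4
    max_epochs: int = 15000
    validate_every_epochs: int = 10
    target_scale: float = 600.0
    # evaluation
    region_edge_px: float = 160.0
    histogram_bins: int = 30
    kde_grid: int = 400
    kde_levels: int = 12
    regression_mode: str = "region"
    # bookkeeping
    seed: int = 0

    # ---- derived objects -------------------------------------------------
    def geometry(self) -> ScreenGeometry:
        return ScreenGeometry(
            width_mm=self.screen_width_mm,
            height_mm=self.screen_height_mm,
            width_px=self.screen_width_px,
            height_px=self.screen_height_px,
            viewing_distance_mm=self.viewing_distance_mm,
        )

    def simulation_config(self) -> synthetic.SimulationConfig:
        return synthetic.SimulationConfig(
            noise_sd_px=self.noise_sd_px,
            blink_probability=self.blink_probability,
            fps=self.fps,
            seed=derive_seed(self.seed, "simulate"),
            poses=tuple(synthetic.HeadPose(yaw_deg=y) for y in self.pose_yaws_deg),
        )

    def train_config(self, epochs: int | None = None) -> gazenet.TrainConfig:
        return gazenet.TrainConfig(
            learning_rate0=self.learning_rate0,
            momentum=self.momentum,
            halve_every_epochs=self.halve_every_epochs,
            batch_size=self.batch_size,
            max_epochs=epochs if epochs is not None else self.max_epochs,
            validate_every_epochs=self.validate_every_epochs,
            seed=derive_seed(self.seed, "train"),
            target_scale=self.target_scale,
        )

    # ---- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["pose_yaws_deg"] = list(out["pose_yaws_deg"])
        out["split_fractions"] = list(out["split_fractions"])
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("pose_yaws_deg", "split_fractions"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run the '{stage}' stage first"
        )
    return path


def _stamp(outdir: Path, name: str, payload: dict) -> None:
    (outdir / name).write_text(json.dumps(payload, indent=2))


def run_simulate(cfg: PipelineConfig, outdir: str | Path) -> tuple[Path, Path]:
    """Generate a landmark session + ground-truth trace into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom = cfg.geometry()
    path = synthetic.generate_calibration_path(
        geom,
        n_lines=cfg.n_lines,
        fps=cfg.fps,
        slow_factor=cfg.slow_factor,
        fast_factor=cfg.fast_factor,
        base_speed_px_s=cfg.base_speed_px_s,
        margin_px=cfg.margin_px,
    )
    sim_cfg = cfg.simulation_config()
    landmarks, targets = synthetic.simulate_session(
        path, synthetic.FaceModel(), synthetic.CameraModel(), geom, sim_cfg
    )
    write_dlc_csv(landmarks, outdir / LANDMARKS_FILE)
    targets.to_csv(outdir / TARGETS_FILE)
    cfg.to_yaml(outdir / CONFIG_FILE)
    logger.info(
        "simulate: %d path frames x %d poses -> %d frames", len(path), len(sim_cfg.poses), len(landmarks)
    )
    _stamp(
        outdir,
        "simulate_meta.json",
        {
            "config_hash": cfg.config_hash(),
            "seed": sim_cfg.seed,
            "n_path_frames": int(len(path)),
            "n_poses": len(sim_cfg.poses),
            "n_frames": int(len(landmarks)),
        },
    )
    return outdir / LANDMARKS_FILE, outdir / TARGETS_FILE


def run_preprocess(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Filter, featurize, balance and split the simulated session."""
    outdir = Path(outdir)
    landmarks = read_dlc_csv(_require(outdir / LANDMARKS_FILE, "simulate"))
    targets = pd.read_csv(_require(outdir / TARGETS_FILE, "simulate"), index_col="frame")
    geom = cfg.geometry()

    kept, filter_report = preprocess.filter_low_likelihood(
        landmarks, threshold=cfg.likelihood_threshold
    )
    features = preprocess.assemble_features(kept, norm_constant=cfg.norm_constant)
    samples = preprocess.make_samples(features, targets)
    balanced, balance_report = preprocess.balance_spatial(
        samples, geom, edge_px=cfg.balance_edge_px, seed=derive_seed(cfg.seed, "balance")
    )
    dataset = preprocess.split(
        balanced, fractions=cfg.split_fractions, seed=derive_seed(cfg.seed, "split")
    )
    labeled = []
    for name, part in (
        ("train", dataset.train),
        ("validation", dataset.validation),
        ("test", dataset.test),
    ):
        part = part.copy()
        part["split"] = name
        labeled.append(part)
    out = pd.concat(labeled).sort_index()
    out.to_csv(outdir / DATASET_FILE, index_label="frame")
    logger.info(
        "preprocess: %d frames -> filter removed %d -> balanced %d -> split %s",
        filter_report["n_input"],
        filter_report["n_removed"],
        balance_report["n_after"],
        dataset.sizes,
    )
    _stamp(
        outdir,
        PREPROCESS_REPORT_FILE,
        {
            "config_hash": cfg.config_hash(),
            "filter": filter_report,
            "balance": balance_report,
            "split_sizes": {
                "train": len(dataset.train),
                "validation": len(dataset.validation),
                "test": len(dataset.test),
            },
            "split_seed": dataset.seed,
        },
    )
    return outdir / DATASET_FILE


def _load_dataset(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(_require(outdir / DATASET_FILE, "preprocess"), index_col="frame")


def _split_arrays(dataset: pd.DataFrame, part: str) -> tuple[np.ndarray, np.ndarray]:
    rows = dataset[dataset["split"] == part]
    x = rows[list(preprocess.FEATURE_COLUMNS)].to_numpy(dtype=float)
    t = rows[["target_x_px", "target_y_px"]].to_numpy(dtype=float)
    return x, t


def run_train(
    cfg: PipelineConfig, outdir: str | Path, epochs: int | None = None
) -> tuple[gazenet.NetworkParams, gazenet.TrainingTrace]:
    """Train the regressor on the preprocessed dataset artifact."""
    outdir = Path(outdir)
    dataset = _load_dataset(outdir)
    x_tr, t_tr = _split_arrays(dataset, "train")
    x_va, t_va = _split_arrays(dataset, "validation")
    train_cfg = cfg.train_config(epochs)
    params, trace = gazenet.train(x_tr, t_tr, x_va, t_va, train_cfg)
    gazenet.save_params(params, train_cfg, outdir / MODEL_FILE)
    trace.records.to_csv(outdir / TRACE_FILE, index=False)
    logger.info(
        "train: %d epochs, best validation loss %.3g at epoch %d",
        train_cfg.max_epochs,
        trace.best_val_loss,
        trace.best_epoch,
    )
    _stamp(
        outdir,
        "train_meta.json",
        {
            "config_hash": cfg.config_hash(),
            "seed": train_cfg.seed,
            "max_epochs": train_cfg.max_epochs,
            "best_epoch": trace.best_epoch,
            "best_val_loss": trace.best_val_loss,
        },
    )
    return params, trace


def run_evaluate(cfg: PipelineConfig, outdir: str | Path) -> ErrorReport:
    """Evaluate the trained model on the held-out test split."""
    outdir = Path(outdir)
    dataset = _load_dataset(outdir)
    params, train_cfg = gazenet.load_params(_require(outdir / MODEL_FILE, "train"))
    x_te, t_te = _split_arrays(dataset, "test")
    estimates = gazenet.predict(params, x_te, train_cfg)
    report = build_error_report(
        t_te,
        estimates,
        cfg.geometry(),
        n_bins=cfg.histogram_bins,
        region_edge_px=cfg.region_edge_px,
        kde_grid=cfg.kde_grid,
        kde_levels=cfg.kde_levels,
        regression_mode=cfg.regression_mode,
        meta={"config_hash": cfg.config_hash(), "seed": cfg.seed},
    )
    report.to_json(outdir / REPORT_FILE)
    report.per_sample.to_csv(outdir / PER_SAMPLE_FILE, index=False)
    logger.info(
        "evaluate: n=%d, median error %.3f dva, mean error %.1f px",
        len(report.per_sample),
        report.median_dva,
        report.mean_error_px,
    )
    return report


def run_all(cfg: PipelineConfig, outdir: str | Path, epochs: int | None = None) -> ErrorReport:
    """Run every stage in order and return the final error report."""
    run_simulate(cfg, outdir)
    run_preprocess(cfg, outdir)
    run_train(cfg, outdir, epochs=epochs)
    return run_evaluate(cfg, outdir)
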