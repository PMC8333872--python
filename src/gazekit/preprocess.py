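"""Turn raw landmark tables plus target traces into training-ready data.

The chain is: likelihood filter (drop any frame where any landmark falls
below 0.7) -> pupil-center derivation (mean of the four pupil-rim corners
per eye) -> 14-element feature assembly (x, y of seven landmarks, divided
by a homogeneous normalization constant of 600, the larger webcam-frame
dimension) -> spatial balancing on a 530 px tile grid (subsample every
occupied tile down to the occupied-tile minimum) -> random 50/25/25
train/validation/test split. Filtering runs before balancing so corrupted
frames cannot consume a tile's quota.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry, tile_screen

__all__ = [
    "FEATURE_LANDMARKS",
    "FEATURE_COLUMNS",
    "pupil_center",
    "filter_low_likelihood",
    "assemble_features",
    "make_samples",
    "balance_spatial",
    "split",
    "SplitDataset",
]

logger = logging.getLogger(__name__)

# Fixed order of the seven landmarks in the 14-element feature vector.
FEATURE_LANDMARKS: tuple[str, ...] = (
    "left_lateral_corner",
    "left_pupil",
    "left_medial_corner",
    "right_medial_corner",
    "right_pupil",
    "right_lateral_corner",
    "lip_philtrum",
)
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{name}_{axis}" for name in FEATURE_LANDMARKS for axis in ("x", "y")
)
TARGET_COLUMNS: tuple[str, ...] = ("target_x_px", "target_y_px")


def pupil_center(four_corner_points) -> np.ndarray:
    """Pupil center as the componentwise mean of its four rim corners."""
    pts = np.asarray(four_corner_points, dtype=float)
    if pts.shape != (4, 2):
        raise ValueError(f"expected exactly 4 (x, y) points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("pupil corner points must be finite")
    return pts.mean(axis=0)


def filter_low_likelihood(
    observations: pd.DataFrame, threshold: float = 0.7
) -> tuple[pd.DataFrame, dict]:
    """Drop every frame where ANY landmark likelihood is strictly below threshold.

    Returns the kept frames and a removal report
    ``{n_input, n_removed, fraction_removed, threshold}``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    likelihood = observations.xs("likelihood", axis=1, level="coords")
    drop = (likelihood < threshold).any(axis=1)
    kept = observations.loc[~drop]
    n = len(observations)
    report = {
        "n_input": int(n),
        "n_removed": int(drop.sum()),
        "fraction_removed": float(drop.sum() / n) if n else 0.0,
        "threshold": float(threshold),
    }
    return kept, report


def assemble_features(observations: pd.DataFrame, norm_constant: float = 600.0) -> pd.DataFrame:
    """Build the 14-element feature table from a raw landmark table.

    Derives the two pupil centers by averaging the four rim corners of each
    eye, orders the seven landmarks as in :data:`FEATURE_LANDMARKS`, and
    divides every coordinate by ``norm_constant`` (homogeneous scaling:
    relative point positions are preserved).
    """
    if norm_constant <= 0:
        raise ValueError("norm_constant must be positive")
    present = set(observations.columns.get_level_values("bodyparts"))
    coords: dict[str, pd.Series] = {}
    for side in ("left", "right"):
        corners = [f"{side}_pupil_corner_{k}" for k in (1, 2, 3, 4)]
        missing = [c for c in corners if c not in present]
        if missing:
            raise KeyError(f"missing landmark(s) {missing} required for {side} pupil center")
        for axis in ("x", "y"):
            coords[f"{side}_pupil_{axis}"] = sum(
                observations[(c, axis)] for c in corners
            ) / 4.0
    for name in FEATURE_LANDMARKS:
        if name.endswith("_pupil"):
            continue
        if name not in present:
            raise KeyError(f"missing landmark {name!r}")
        for axis in ("x", "y"):
            coords[f"{name}_{axis}"] = observations[(name, axis)]
    features = pd.DataFrame({col: coords[col] for col in FEATURE_COLUMNS})
    return features / norm_constant


def make_samples(features: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Row-align features with ground-truth targets by frame index.

    ``targets`` must cover every feature frame; a length/index mismatch
    beyond the frames removed by filtering is an error, never silently
    truncated.
    """
    missing = features.index.difference(targets.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} feature frames have no ground-truth target "
            f"(first: {missing[:5].tolist()})"
        )
    aligned = targets.loc[features.index, list(TARGET_COLUMNS)]
    return pd.concat([features, aligned], axis=1)


def balance_spatial(
    samples: pd.DataFrame,
    geom: ScreenGeometry,
    edge_px: float = 530.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Equalize per-tile sample counts over a square screen tiling.

    The screen is tiled with ``edge_px`` squares; the smallest count over
    *occupied* tiles becomes the per-tile quota and that many samples are
    drawn uniformly without replacement from every occupied tile. Empty
    tiles contribute nothing (a warning is logged when any exist). The
    output is sorted by frame index, which makes the operation idempotent
    for a fixed seed.
    """
    if len(samples) == 0:
        raise ValueError("no samples to balance")
    grid = tile_screen(geom, edge_px)
    tile_ids = grid.flat_index_of(
        samples["target_x_px"].to_numpy(), samples["target_y_px"].to_numpy()
    )
    counts = pd.Series(tile_ids).value_counts().sort_index()
    n_empty = grid.n_tiles - len(counts)
    if n_empty:
        logger.warning("%d of %d tiles contain no samples", n_empty, grid.n_tiles)
    quota = int(counts.min())
    rng = np.random.default_rng(seed)
    keep_positions: list[np.ndarray] = []
    for tid in counts.index:
        positions = np.flatnonzero(tile_ids == tid)
        keep_positions.append(rng.choice(positions, size=quota, replace=False))
    keep = np.sort(np.concatenate(keep_positions))
    balanced = samples.iloc[keep]
    report = {
        "edge_px": float(edge_px),
        "n_tiles": int(grid.n_tiles),
        "n_occupied_tiles": int(len(counts)),
        "per_tile_counts_before": {int(k): int(v) for k, v in counts.items()},
        "quota_per_tile": quota,
        "n_before": int(len(samples)),
        "n_after": int(len(balanced)),
        "seed": int(seed),
    }
    return balanced, report


@dataclass(frozen=True)
class SplitDataset:
    """Disjoint train/validation/test partition of a sample table."""

    train: pd.DataFrame
    validation: pd.DataFrame
    test: pd.DataFrame
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


def split(
    samples: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.50, 0.25, 0.25),
    seed: int = 0,
) -> SplitDataset:
    """Uniformly random seeded train/validation/test partition.

    Validation and test sizes are floored; the remainder goes to train.
    """
    if min(fractions) <= 0:
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(samples)
    if n < 4:
        raise ValueError(f"need at least 4 samples to split, got {n}")
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx = np.sort(order[:n_val])
    test_idx = np.sort(order[n_val : n_val + n_test])
    train_idx = np.sort(order[n_val + n_test :])
    return SplitDataset(
        train=samples.iloc[train_idx],
        validation=samples.iloc[val_idx],
        test=samples.iloc[test_idx],
        seed=int(seed),
    )
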