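"""Spatial error analyses of gaze estimates.

Per-sample errors are the Euclidean offsets between ground-truth and
estimated screen points, reported both in pixels and in degrees of visual
angle (converted per sample through the width-based formula, then
summarized). Spatial structure is probed three ways: a per-region mean
error map on a 160 px tiling with single-pass neighbor fill for empty
regions, an ordinary-least-squares regression of error on eccentricity
(distance from screen center), and a 2D Gaussian kernel density estimate
of the (dx, dy) offsets on a 400 x 400 grid with 12 density levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ScreenGeometry, eccentricity, px_error_to_dva, tile_screen

__all__ = [
    "mean_error_px",
    "error_histogram",
    "region_error_map",
    "eccentricity_regression",
    "offset_density",
    "ErrorReport",
    "build_error_report",
]


def mean_error_px(deltas) -> float:
    """Mean Euclidean norm of per-sample (dx, dy) offsets.

    This is the mean of the norms, not the norm of the mean offset.
    """
    d = np.atleast_2d(np.asarray(deltas, dtype=float))
    if d.shape[0] == 0:
        raise ValueError("mean error of an empty set is undefined")
    return float(np.mean(np.hypot(d[:, 0], d[:, 1])))


def error_histogram(errors, n_bins: int = 30) -> dict:
    """Relative-frequency histogram of error magnitudes plus their median.

    Bins are equal-width over [0, max(errors)]; frequencies sum to 1.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("cannot histogram an empty error set")
    if np.any(e < 0):
        raise ValueError("error magnitudes must be non-negative")
    upper = float(e.max()) if e.max() > 0 else 1.0
    counts, edges = np.histogram(e, bins=n_bins, range=(0.0, upper))
    return {
        "bin_edges": edges,
        "relative_frequency": counts / e.size,
        "median": float(np.median(e)),
        "n": int(e.size),
    }


def region_error_map(
    targets_px: np.ndarray,
    errors: np.ndarray,
    geom: ScreenGeometry,
    edge_px: float = 160.0,
) -> dict:
    """Per-tile mean error with single-pass neighbor fill for empty tiles.

    Occupied tiles receive the mean error of the samples whose *ground
    truth* falls inside them. Each empty tile is filled with the mean over
    its 8-connected occupied neighbors, computed from the original
    occupied values in a single pass (occupied tiles are never altered).
    Tiles with no occupied neighbor stay NaN and are flagged ``undefined``.
    """
    targets = np.atleast_2d(np.asarray(targets_px, dtype=float))
    errs = np.asarray(errors, dtype=float)
    if len(targets) != len(errs):
        raise ValueError("targets and errors must be row-aligned")
    grid = tile_screen(geom, edge_px)
    values = np.full((grid.n_rows, grid.n_cols), np.nan)
    status = np.full((grid.n_rows, grid.n_cols), "empty", dtype=object)
    cols, rows = grid.tile_index_of(targets[:, 0], targets[:, 1])
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            mask = (rows == r) & (cols == c)
            if mask.any():
                values[r, c] = errs[mask].mean()
                status[r, c] = "observed"
    occupied = status == "observed"
    filled = values.copy()
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            if occupied[r, c]:
                continue
            r0, r1 = max(r - 1, 0), min(r + 2, grid.n_rows)
            c0, c1 = max(c - 1, 0), min(c + 2, grid.n_cols)
            neighbors = values[r0:r1, c0:c1][occupied[r0:r1, c0:c1]]
            if neighbors.size:
                filled[r, c] = neighbors.mean()
                status[r, c] = "filled"
            else:
                status[r, c] = "undefined"
    return {
        "edge_px": float(edge_px),
        "n_cols": grid.n_cols,
        "n_rows": grid.n_rows,
        "mean_error": filled,
        "status": status,
        "grid": grid,
    }


def eccentricity_regression(
    targets_px: np.ndarray,
    errors: np.ndarray,
    geom: ScreenGeometry,
    mode: str = "region",
    edge_px: float = 160.0,
) -> dict:
    """OLS fit of error magnitude on eccentricity from screen center.

    ``mode="region"`` regresses per-tile mean errors on tile-center
    eccentricities (observed tiles only); ``mode="sample"`` uses raw
    samples. The slope p-value is two-sided from the t distribution with
    n - 2 degrees of freedom.
    """
    targets = np.atleast_2d(np.asarray(targets_px, dtype=float))
    errs = np.asarray(errors, dtype=float)
    if mode == "region":
        rmap = region_error_map(targets, errs, geom, edge_px)
        rr, cc = np.nonzero(rmap["status"] == "observed")
        centers = np.column_stack([(cc + 0.5) * edge_px, (rr + 0.5) * edge_px])
        xs = eccentricity(centers, geom)
        ys = rmap["mean_error"][rr, cc]
    elif mode == "sample":
        xs = eccentricity(targets, geom)
        ys = errs
    else:
        raise ValueError(f"unknown regression mode {mode!r}")
    if len(xs) < 3:
        raise ValueError("need at least 3 points for the regression")
    if np.ptp(xs) == 0:
        raise ValueError("degenerate design: all eccentricities identical")
    fit = stats.linregress(xs, ys)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p_value": float(fit.pvalue),
        "r_value": float(fit.rvalue),
        "n": int(len(xs)),
        "mode": mode,
    }


def offset_density(
    deltas: np.ndarray, grid_size: int = 400, n_levels: int = 12
) -> dict:
    """2D Gaussian KDE of (dx, dy) estimation offsets.

    Bandwidth follows Scott's rule. The density is evaluated on a
    ``grid_size`` x ``grid_size`` grid centered on (0, 0) and wide enough
    to hold essentially all probability mass, with ``n_levels`` equally
    spaced density levels. The returned grid integrates to ~1.
    """
    d = np.atleast_2d(np.asarray(deltas, dtype=float))
    if d.shape[0] < 2 or d.shape[1] != 2:
        raise ValueError("need at least 2 (dx, dy) offsets")
    if np.allclose(d, d[0]):
        raise ValueError("all offsets identical: KDE bandwidth is singular")
    kde = stats.gaussian_kde(d.T)  # Scott's rule bandwidth
    sd = np.sqrt(np.diag(kde.covariance))
    half = float(np.max(np.abs(d), axis=0).max() + 4.0 * sd.max())
    axis = np.linspace(-half, half, grid_size)
    xx, yy = np.meshgrid(axis, axis)
    density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
    levels = np.linspace(0.0, float(density.max()), n_levels + 1)[1:]
    step = axis[1] - axis[0]
    return {
        "axis": axis,
        "density": density,
        "levels": levels,
        "bandwidth_factor": float(kde.factor),
        "integral": float(density.sum() * step * step),
        "sd_x": float(d[:, 0].std(ddof=1)),
        "sd_y": float(d[:, 1].std(ddof=1)),
        "mean_dx": float(d[:, 0].mean()),
        "mean_dy": float(d[:, 1].mean()),
    }


@dataclass
class ErrorReport:
    """Bundle of per-sample errors and the summary analyses."""

    per_sample: pd.DataFrame
    median_dva: float
    mean_error_px: float
    histogram: dict
    region_map: dict
    regression: dict
    density: dict
    meta: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        """JSON-serializable summary (omits the full KDE grid)."""
        return {
            "n_samples": int(len(self.per_sample)),
            "median_dva": self.median_dva,
            "mean_error_px": self.mean_error_px,
            "histogram": {
                "bin_edges": self.histogram["bin_edges"].tolist(),
                "relative_frequency": self.histogram["relative_frequency"].tolist(),
                "median": self.histogram["median"],
            },
            "region_map": {
                "edge_px": self.region_map["edge_px"],
                "n_cols": self.region_map["n_cols"],
                "n_rows": self.region_map["n_rows"],
                "mean_error": [
                    [None if np.isnan(v) else float(v) for v in row]
                    for row in self.region_map["mean_error"]
                ],
                "status": self.region_map["status"].tolist(),
            },
            "regression": self.regression,
            "density": {
                k: self.density[k]
                for k in ("bandwidth_factor", "integral", "sd_x", "sd_y", "mean_dx", "mean_dy")
            },
            "meta": self.meta,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2))


def build_error_report(
    truth_px: np.ndarray,
    estimate_px: np.ndarray,
    geom: ScreenGeometry,
    n_bins: int = 30,
    region_edge_px: float = 160.0,
    kde_grid: int = 400,
    kde_levels: int = 12,
    regression_mode: str = "region",
    meta: dict | None = None,
) -> ErrorReport:
    """Compute the full error analysis for a set of gaze estimates."""
    truth = np.atleast_2d(np.asarray(truth_px, dtype=float))
    est = np.atleast_2d(np.asarray(estimate_px, dtype=float))
    if truth.shape != est.shape:
        raise ValueError("truth and estimate tables must be row-aligned")
    deltas = est - truth
    err_px = np.hypot(deltas[:, 0], deltas[:, 1])
    err_dva = px_error_to_dva(err_px, geom)
    per_sample = pd.DataFrame(
        {
            "truth_x_px": truth[:, 0],
            "truth_y_px": truth[:, 1],
            "estimate_x_px": est[:, 0],
            "estimate_y_px": est[:, 1],
            "dx_px": deltas[:, 0],
            "dy_px": deltas[:, 1],
            "error_px": err_px,
            "error_dva": err_dva,
        }
    )
    return ErrorReport(
        per_sample=per_sample,
        median_dva=float(np.median(err_dva)),
        mean_error_px=mean_error_px(deltas),
        histogram=error_histogram(err_dva, n_bins=n_bins),
        region_map=region_error_map(truth, err_px, geom, edge_px=region_edge_px),
        regression=eccentricity_regression(
            truth, err_px, geom, mode=regression_mode, edge_px=region_edge_px
        ),
        density=offset_density(deltas, grid_size=kde_grid, n_levels=kde_levels),
        meta=meta or {},
    )
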