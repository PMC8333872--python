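"""Diagnostic figures for an :class:`~gazekit.evaluation.ErrorReport`.

Renders the standard evaluation views: offset arrows on the screen
outline, the error-magnitude histogram with its median, the per-region
mean-error heatmap, and the offset-density contours.
"""

from __future__ import annotations

from pathlib import Path

from .evaluation import ErrorReport


def render_report_figures(report: ErrorReport, outdir: str | Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    df = report.per_sample

    fig, ax = plt.subplots(figsize=(7, 4.2))
    ax.quiver(
        df["truth_x_px"], df["truth_y_px"], df["dx_px"], df["dy_px"],
        angles="xy", scale_units="xy", scale=1, width=0.002,
    )
    ax.set_xlim(0, report.region_map["n_cols"] * report.region_map["edge_px"])
    ax.invert_yaxis()
    ax.set_title("Estimation offsets (truth -> estimate)")
    ax.set_xlabel("screen x (px)")
    ax.set_ylabel("screen y (px)")
    paths.append(outdir / "offsets_quiver.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    edges = report.histogram["bin_edges"]
    ax.bar(
        edges[:-1], report.histogram["relative_frequency"],
        width=edges[1] - edges[0], align="edge",
    )
    ax.axvline(report.histogram["median"], linestyle="--", color="k")
    ax.set_xlabel("error (dva)")
    ax.set_ylabel("relative frequency")
    ax.set_title(f"median = {report.histogram['median']:.2f} dva")
    paths.append(outdir / "error_histogram.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 3.8))
    im = ax.imshow(report.region_map["mean_error"], cmap="viridis")
    fig.colorbar(im, ax=ax, label="mean error (px)")
    ax.set_title(f"per-region mean error ({report.region_map['edge_px']:.0f} px tiles)")
    paths.append(outdir / "region_error_map.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    axis = report.density["axis"]
    ax.contourf(axis, axis, report.density["density"], levels=report.density["levels"])
    ax.axhline(0, color="w", lw=0.5)
    ax.axvline(0, color="w", lw=0.5)
    ax.invert_yaxis()
    ax.set_xlabel("dx (px)")
    ax.set_ylabel("dy (px)")
    ax.set_title("offset density (KDE)")
    paths.append(outdir / "offset_density.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)
    return paths
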