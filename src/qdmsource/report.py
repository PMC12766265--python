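"""Figure rendering: classified-source map overlays, moment/size versus
depth scatter, and an equal-area (Lambert azimuthal, lower/upper hemisphere)
plot of magnetization directions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .physics import Direction, direction_to_vector, moment_to_diameter

_LABEL_STYLE = {
    "bona_fide": dict(color="red", marker="o"),
    "artifact": dict(color="black", marker="s"),
    "contamination": dict(color="deepskyblue", marker="^"),
    "ambiguous": dict(color="orange", marker="x"),
}


def _equal_area_xy(d: Direction) -> tuple[float, float, bool]:
    """Lambert equal-area projection; returns (x, y, lower_hemisphere)."""
    v = direction_to_vector(d)
    lower = v[2] <= 0  # pointing down into the sample
    # fold onto one hemisphere; rim (rho=1) at inclination 0, center at ±90
    rho = np.sqrt(1.0 - abs(v[2]))
    h = np.hypot(v[0], v[1])
    if h == 0:
        return 0.0, 0.0, bool(lower)
    return float(rho * v[0] / h), float(rho * v[1] / h), bool(lower)


def plot_map_overlay(ax, fmap, records=None, clip_sigma: float = 6.0):
    vals = fmap.values
    finite = vals[np.isfinite(vals)]
    scale = clip_sigma * (1.4826 * np.median(np.abs(finite - np.median(finite))) + 1e-30)
    extent = [0, fmap.n_cols * fmap.pixel_size, 0, fmap.n_rows * fmap.pixel_size]
    im = ax.imshow(vals, cmap="RdBu_r", vmin=-scale, vmax=scale, extent=extent,
                   origin="upper")
    if records:
        for rec in records:
            style = _LABEL_STYLE.get(rec.label, _LABEL_STYLE["ambiguous"])
            ax.scatter(*rec.sample_frame_xy, facecolors="none",
                       edgecolors=style["color"], marker=style["marker"], s=80,
                       linewidths=1.2)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    return im


def plot_moment_depth(ax, records):
    for rec in records:
        style = _LABEL_STYLE.get(rec.label, _LABEL_STYLE["ambiguous"])
        for fit in (rec.fit1, rec.fit2):
            if fit is None:
                continue
            ax.scatter(moment_to_diameter(fit.moment_magnitude), fit.depth,
                       color=style["color"], marker=style["marker"], s=30, alpha=0.8)
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_xlabel("equivalent magnetite diameter (nm)")
    ax.set_ylabel("depth below sensing layer (µm)")


def plot_directions(ax, directions: list[Direction], mean=None, alpha95=None):
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="k", lw=1))
    for d in directions:
        x, y, lower = _equal_area_xy(d)
        ax.scatter(x, y, facecolors="k" if lower else "none", edgecolors="k", s=40)
    if mean is not None:
        x, y, _ = _equal_area_xy(mean)
        ax.scatter(x, y, marker="*", color="tab:blue", s=200, zorder=5)
        if alpha95 is not None and np.isfinite(alpha95):
            # draw the confidence cone as a circle of directions at alpha95
            ring = []
            mu = direction_to_vector(mean)
            helper = np.array([1.0, 0, 0]) if abs(mu[0]) < 0.9 else np.array([0, 1.0, 0])
            e1 = np.cross(mu, helper)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(mu, e1)
            a = np.radians(alpha95)
            for phi in np.linspace(0, 2 * np.pi, 120):
                v = np.cos(a) * mu + np.sin(a) * (np.cos(phi) * e1 + np.sin(phi) * e2)
                from .physics import vector_to_direction

                x, y, _ = _equal_area_xy(vector_to_direction(v))
                ring.append((x, y))
            ring = np.array(ring)
            ax.plot(ring[:, 0], ring[:, 1], color="tab:blue", lw=1)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.annotate("N (dec 0)", (0, 1.02), ha="center")


def render_figures(result, outdir: Path) -> list[Path]:
    """Standard figure set for a pipeline result."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, axes = plt.subplots(1, 2, figsize=(12, 4.2))
    plot_map_overlay(axes[0], result.pair.map1, result.records)
    axes[0].set_title("acquisition 1, classified sources")
    plot_map_overlay(axes[1], result.pair.map2)
    axes[1].set_title("acquisition 2")
    p = outdir / "maps_overlay.png"
    fig.savefig(p, dpi=140, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    plot_moment_depth(ax, result.records)
    p = outdir / "size_vs_depth.png"
    fig.savefig(p, dpi=140, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    bona = [r for r in result.records if r.label == "bona_fide"]
    if len(bona) >= 1:
        from .stats import fisher_mean

        dirs = [r.mean_direction for r in bona]
        fr = fisher_mean(dirs) if len(dirs) >= 3 else None
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        plot_directions(
            ax, dirs,
            mean=fr.mean if fr else None,
            alpha95=fr.alpha95 if fr else None,
        )
        p = outdir / "directions_equal_area.png"
        fig.savefig(p, dpi=140, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths


def render_from_run_dir(run_dir: Path) -> list[Path]:
    """Re-render figures from a serialized pipeline run directory."""
    import pandas as pd

    from . import io as qio

    run_dir = Path(run_dir)
    df = pd.read_csv(run_dir / "sources.csv")
    fmap = qio.read_fieldmap(run_dir / "phantom" / "map1.tif")
    outdir = run_dir / "figures"
    outdir.mkdir(exist_ok=True)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    plot_map_overlay(ax, fmap)
    for row in df.itertuples():
        style = _LABEL_STYLE.get(row.label, _LABEL_STYLE["ambiguous"])
        ax.scatter(row.x_um, row.y_um, facecolors="none",
                   edgecolors=style["color"], marker=style["marker"], s=80)
    p = outdir / "maps_overlay.png"
    fig.savefig(p, dpi=140, bbox_inches="tight")
    plt.close(fig)
    return [p]
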