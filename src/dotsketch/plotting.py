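"""Static heatmap rendering of identity matrices.

Identity values from the threshold t to 100 are discretized into equal-width
bins and drawn with a discrete palette; cells below t stay uncolored
(background).  Square plots draw the full matrix in genomic coordinates;
triangular plots (self matrices only) rotate the upper triangle so the main
diagonal becomes the baseline, the convention for repeat-array figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps
from matplotlib.colors import BoundaryNorm, ListedColormap, to_rgb

from .identity import IdentityMatrix
from .kmers import ValidationError

# high-contrast presets for colorblind accessibility
_PRESETS = {
    "high_contrast": [
        "#000000", "#004949", "#009292", "#FF6DB6", "#FFB6DB", "#490092",
        "#006DDB", "#B66DFF", "#6DB6FF", "#B6DBFF", "#920000",
    ],
    "warm_cool": [
        "#313695", "#4575B4", "#74ADD1", "#ABD9E9", "#E0F3F8", "#FFFFBF",
        "#FEE090", "#FDAE61", "#F46D43", "#D73027", "#A50026",
    ],
}


@dataclass
class PlotConfig:
    """Rendering options for a static identity heatmap."""

    threshold: float = 86.0
    palette: str | list[str] = "viridis"
    bins: int = 11
    style: str = "square"  # square | triangular
    output_format: str = "png"  # png | pdf
    dpi: int = 150
    figsize: tuple[float, float] = (7.0, 6.0)

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValidationError(f"bins must be >= 2, got {self.bins}")
        if self.style not in ("square", "triangular"):
            raise ValidationError(f"style must be square or triangular, got {self.style!r}")
        if self.output_format.lower() not in ("png", "pdf"):
            raise ValidationError(f"format must be png or pdf, got {self.output_format!r}")

    def colors(self) -> list[tuple[float, float, float]]:
        """One RGB color per identity bin."""
        if isinstance(self.palette, (list, tuple)):
            named = list(self.palette)
            if len(named) != self.bins:
                raise ValidationError(
                    f"explicit palette has {len(named)} colors for {self.bins} bins"
                )
            return [to_rgb(c) for c in named]
        if self.palette in _PRESETS:
            preset = _PRESETS[self.palette]
            idx = np.linspace(0, len(preset) - 1, self.bins).round().astype(int)
            return [to_rgb(preset[i]) for i in idx]
        cmap = colormaps[self.palette]
        return [cmap(x)[:3] for x in np.linspace(0.0, 1.0, self.bins)]


def _si_formatter(val: float, _pos=None) -> str:
    for div, suffix in ((1e9, " Gbp"), (1e6, " Mbp"), (1e3, " kbp")):
        if abs(val) >= div:
            return f"{val / div:g}{suffix}"
    return f"{val:g} bp"


def discrete_colormap(config: PlotConfig):
    """Discrete bin colormap and norm over [t, 100]; below t is uncolored.

    The top boundary is nudged above 100 so a perfect-identity cell falls in
    the highest bin rather than out of range.
    """
    cmap = ListedColormap(config.colors())
    cmap.set_under((1.0, 1.0, 1.0, 0.0))  # below-threshold cells uncolored
    boundaries = np.linspace(config.threshold, 100.0, config.bins + 1)
    boundaries[-1] = np.nextafter(100.0, np.inf)
    norm = BoundaryNorm(boundaries, config.bins)
    return cmap, norm


_discrete_cmap = discrete_colormap


def render_static(
    matrix: IdentityMatrix, config: PlotConfig | None = None, path: str | Path = "plot.png"
) -> Path:
    """Render a matrix to an image file; pure consumer, never mutates values."""
    config = config or PlotConfig(threshold=matrix.threshold)
    if config.style == "triangular" and not matrix.self_plot:
        raise ValidationError("triangular style is only valid for self plots")
    path = Path(path)
    cmap, norm = _discrete_cmap(config)
    w = matrix.window_size
    n_rows, n_cols = matrix.values.shape
    fig, ax = plt.subplots(figsize=config.figsize)
    try:
        if config.style == "square":
            extent = (
                matrix.x_offset,
                matrix.x_offset + n_cols * w,
                matrix.y_offset,
                matrix.y_offset + n_rows * w,
            )
            ax.imshow(
                matrix.values,
                cmap=cmap,
                norm=norm,
                origin="lower",
                extent=extent,
                interpolation="nearest",
                aspect="auto",
            )
            ax.set_ylabel(matrix.y_name)
            ax.yaxis.set_major_formatter(_si_formatter)
        else:
            _draw_triangle(ax, matrix, cmap, norm)
        ax.set_xlabel(matrix.x_name)
        ax.xaxis.set_major_formatter(_si_formatter)
        mappable = plt.cm.ScalarMappable(cmap=cmap, norm=norm)
        fig.colorbar(mappable, ax=ax, label="% identity", ticks=norm.boundaries)
        fig.tight_layout()
        fig.savefig(path, dpi=config.dpi, format=config.output_format.lower(),
                    metadata=_stable_metadata(config.output_format))
    finally:
        plt.close(fig)
    return path


def _stable_metadata(fmt: str) -> dict:
    # strip creation timestamps so identical configs give identical bytes
    if fmt.lower() == "pdf":
        return {"CreationDate": None}
    return {"Software": "dotsketch"}


def _draw_triangle(ax, matrix: IdentityMatrix, cmap, norm) -> None:
    """Upper triangle rotated 45°: diagonal on the baseline, apex up."""
    r = matrix.values.shape[0]
    w = matrix.window_size
    # rotate cell corners (x, y) -> ((x + y)/2, (y - x)/2); keep j >= i
    quads_x, quads_y, vals = [], [], []
    for i in range(r):
        for j in range(i, r):
            v = matrix.values[i, j]
            if v < matrix.threshold:
                continue
            corners = [(j, i), (j + 1, i), (j + 1, i + 1), (j, i + 1)]
            quads_x.append([(x + y) / 2 * w for x, y in corners])
            quads_y.append([(x - y) / 2 * w for x, y in corners])
            vals.append(v)
    from matplotlib.collections import PolyCollection

    polys = [list(zip(qx, qy)) for qx, qy in zip(quads_x, quads_y)]
    coll = PolyCollection(polys, array=np.array(vals), cmap=cmap, norm=norm,
                          edgecolors="none")
    ax.add_collection(coll)
    ax.set_xlim(matrix.x_offset, matrix.x_offset + r * w)
    ax.set_ylim(0, r * w / 2)
    ax.set_yticks([])
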