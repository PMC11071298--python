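"""Containment-based ANI estimation and identity-matrix assembly.

The fraction of interval A's k-mers contained in interval B is estimated
from their modimizer sketches with a FracMinHash bias correction in the
denominator:

    c(A, B) = |MOD_s(A) ∩ MOD_s(B)| / (|MOD_s(A)| * (1 - (1 - 1/s)^|A|))

where |A| is A's distinct k-mer count.  Under a per-base binomial mutation
model the containment of k-mers decays as (ANI/100)^k, so percent identity
is recovered as ANI = 100 * c^(1/k).

Windows that are "out of register" (similar sequence split across a window
boundary) would have their containment understated; the second interval is
therefore expanded by w/2 on each side before intersection.  Because B does
not appear in the denominator, expansion never biases the estimate downward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kmers import HashStream, ValidationError
from .sketch import (
    HierarchicalIndex,
    ModimizerSketch,
    SketchLayer,
    filter_modimizers,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 86.0
DEFAULT_EXPANSION = 1.0


@dataclass(frozen=True)
class ContainmentEstimate:
    """Bias-corrected containment of A in B, clamped to [0, 1]."""

    value: float
    intersection_size: int
    denominator_size: int  # |MOD_s(A)| at the common sparsity
    correction: float  # 1 - (1 - 1/s)^|A|
    sparsity: int  # common effective sparsity used


@dataclass
class IdentityMatrix:
    """Grid of percent-identity estimates between window pairs.

    ``values[i, j]`` compares the i-th window on the y sequence with the
    j-th window on the x sequence; entries below the threshold are 0.  Cell
    sides are ``window_size`` bases; offsets give the genomic coordinate of
    cell (0, 0).  Carries full provenance in ``metadata``.
    """

    values: np.ndarray  # float64, shape (rY, rX) — here rX==cols, rY==rows
    x_name: str
    y_name: str
    window_size: int
    x_offset: int
    y_offset: int
    self_plot: bool
    threshold: float
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def containment(
    sketch_a: ModimizerSketch,
    sketch_b: ModimizerSketch | np.ndarray,
    b_sparsity: int | None = None,
) -> ContainmentEstimate:
    """Bias-corrected containment of sketch_a's interval in sketch_b's.

    If the two sketches were built at different effective sparsities, the
    denser one is re-filtered to the sparser one's s (valid by the subset
    property) and the correction uses that common s.  ``sketch_b`` may be a
    raw sorted hash array (e.g. an expanded interval) with ``b_sparsity``.
    """
    if isinstance(sketch_b, ModimizerSketch):
        b_hashes, s_b = sketch_b.hashes, sketch_b.sparsity
    else:
        if b_sparsity is None:
            raise ValidationError("b_sparsity required when sketch_b is a raw array")
        b_hashes, s_b = sketch_b, b_sparsity
    s = max(sketch_a.sparsity, s_b)
    a_hashes = sketch_a.refilter(s)
    if s > s_b:
        b_hashes = filter_modimizers(b_hashes, s)
    if a_hashes.shape[0] == 0:
        logger.warning(
            "empty sketch for interval %s; containment undefined, reporting 0",
            sketch_a.interval,
        )
        return ContainmentEstimate(0.0, 0, 0, 1.0, s)
    inter = np.intersect1d(a_hashes, b_hashes, assume_unique=True)
    correction = 1.0 - (1.0 - 1.0 / s) ** sketch_a.distinct_count if s > 1 else 1.0
    raw = inter.shape[0] / (a_hashes.shape[0] * correction)
    return ContainmentEstimate(
        value=min(1.0, max(0.0, raw)),
        intersection_size=int(inter.shape[0]),
        denominator_size=int(a_hashes.shape[0]),
        correction=correction,
        sparsity=s,
    )


def ani_from_containment(c: float, k: int) -> float:
    """Percent identity 100 * c^(1/k); 0 at c = 0."""
    if not 0.0 <= c <= 1.0:
        raise ValidationError(f"containment must be in [0, 1], got {c}")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if c == 0.0:
        return 0.0
    return 100.0 * c ** (1.0 / k)


def expand_interval(
    interval: tuple[int, int], w: int, factor: float, bound: int
) -> tuple[int, int]:
    """Extend an interval by factor * w/2 on each side, clamped to [0, bound)."""
    if factor < 0:
        raise ValidationError(f"expansion factor must be >= 0, got {factor}")
    pad = int(factor * w / 2)
    start, end = interval
    return (max(0, start - pad), min(bound, end + pad))


def _expanded_hashes(
    stream: HashStream, interval: tuple[int, int], w: int, factor: float, s: int
) -> np.ndarray:
    """Sorted modimizers of the expanded interval at sparsity s, on demand."""
    b_exp = expand_interval(interval, w, factor, stream.n_positions)
    return filter_modimizers(stream.distinct(*b_exp), s)


def cell_identity(
    sketch_a: ModimizerSketch,
    sketch_b: ModimizerSketch,
    stream_b: HashStream,
    w: int,
    k: int,
    expansion_factor: float = DEFAULT_EXPANSION,
) -> float:
    """Directional percent identity of window A against expanded window B'.

    B' is sketched from B's hash stream at B's effective sparsity; the
    containment denominator is A's (unexpanded) sketch, so expansion can
    only help.
    """
    if expansion_factor == 0:
        est = containment(sketch_a, sketch_b)
    else:
        b_exp = _expanded_hashes(
            stream_b, sketch_b.interval, w, expansion_factor, sketch_b.sparsity
        )
        est = containment(sketch_a, b_exp, b_sparsity=sketch_b.sparsity)
    return ani_from_containment(est.value, k)


def _pair_value(
    sk_i: ModimizerSketch,
    sk_j: ModimizerSketch,
    exp_i: np.ndarray,
    exp_j: np.ndarray,
    k: int,
    direction: str,
) -> float:
    """max/xy/yx combination of the two directional ANI estimates."""
    if direction in ("max", "xy"):
        est_ij = containment(sk_i, exp_j, b_sparsity=sk_j.sparsity)
        v_ij = ani_from_containment(est_ij.value, k)
        if direction == "xy":
            return v_ij
    if direction in ("max", "yx"):
        est_ji = containment(sk_j, exp_i, b_sparsity=sk_i.sparsity)
        v_ji = ani_from_containment(est_ji.value, k)
        if direction == "yx":
            return v_ji
    return max(v_ij, v_ji)


def _expanded_cache(
    layer: SketchLayer, stream: HashStream, expansion_factor: float
) -> list[np.ndarray]:
    if expansion_factor == 0:
        return [sk.hashes for sk in layer.sketches]
    return [
        _expanded_hashes(stream, sk.interval, layer.window_size, expansion_factor, sk.sparsity)
        for sk in layer.sketches
    ]


def self_matrix(
    index: HierarchicalIndex,
    level: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    expansion_factor: float = DEFAULT_EXPANSION,
) -> IdentityMatrix:
    """Symmetric self-identity matrix at one hierarchy level.

    Each unordered pair takes the max of the two directional estimates;
    entries below the threshold are zeroed and the diagonal is forced to 100.
    """
    layer = index.layer(level)
    sketches = layer.sketches
    expanded = _expanded_cache(layer, index.stream, expansion_factor)
    r = layer.r
    values = np.zeros((r, r), dtype=np.float64)
    for i in range(r):
        values[i, i] = 100.0
        for j in range(i + 1, r):
            v = _pair_value(
                sketches[i], sketches[j], expanded[i], expanded[j], index.k, "max"
            )
            if v >= threshold:
                values[i, j] = values[j, i] = v
    return IdentityMatrix(
        values=values,
        x_name=index.record_name,
        y_name=index.record_name,
        window_size=layer.window_size,
        x_offset=0,
        y_offset=0,
        self_plot=True,
        threshold=threshold,
        metadata=_matrix_metadata(index, layer, expansion_factor, index.n, index.n),
    )


def comparative_matrix(
    index_x: HierarchicalIndex,
    index_y: HierarchicalIndex,
    level: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    expansion_factor: float = DEFAULT_EXPANSION,
    direction: str = "max",
) -> IdentityMatrix:
    """Identity matrix between two sequences at one hierarchy level.

    Both indices must share k, hash seed and target sketch size, otherwise
    their sketches are not comparable.  ``direction`` selects max of both
    directional estimates (default), or the x-in-y / y-in-x direction alone.
    """
    for attr in ("k", "seed", "target_sketch"):
        if getattr(index_x, attr) != getattr(index_y, attr):
            raise ValidationError(
                f"indices differ in {attr}: "
                f"{getattr(index_x, attr)} vs {getattr(index_y, attr)}"
            )
    if direction not in ("max", "xy", "yx"):
        raise ValidationError(f"direction must be max/xy/yx, got {direction!r}")
    lx, ly = index_x.layer(level), index_y.layer(level)
    if lx.window_size != ly.window_size:
        raise ValidationError("layers have mismatched window sizes")
    exp_x = _expanded_cache(lx, index_x.stream, expansion_factor)
    exp_y = _expanded_cache(ly, index_y.stream, expansion_factor)
    values = np.zeros((ly.r, lx.r), dtype=np.float64)
    for i in range(ly.r):  # rows: y windows
        for j in range(lx.r):  # cols: x windows
            v = _pair_value(
                ly.sketches[i], lx.sketches[j], exp_y[i], exp_x[j], index_x.k, direction
            )
            if v >= threshold:
                values[i, j] = v
    return IdentityMatrix(
        values=values,
        x_name=index_x.record_name,
        y_name=index_y.record_name,
        window_size=lx.window_size,
        x_offset=0,
        y_offset=0,
        self_plot=False,
        threshold=threshold,
        metadata=_matrix_metadata(index_x, lx, expansion_factor, index_x.n, index_y.n),
    )


def _matrix_metadata(
    index: HierarchicalIndex, layer: SketchLayer, expansion_factor: float,
    x_len: int, y_len: int,
) -> dict:
    meta = index.params()
    meta.update(
        {
            "level": layer.level,
            "window": layer.window_size,
            "sparsity": layer.sparsity,
            "expansion_factor": expansion_factor,
            "x_len": x_len,
            "y_len": y_len,
        }
    )
    return meta


def select_layer(
    index: HierarchicalIndex, viewport_bases: int, display_cells: int
) -> int:
    """Coarsest level whose window count across the viewport covers the display.

    Chosen such that the number of matrix cells along the viewport is at
    least the number of pixels to draw; falls back to the finest level.
    """
    if viewport_bases < 1 or display_cells < 1:
        raise ValidationError("viewport and display size must be >= 1")
    for level in range(index.n_layers - 1, -1, -1):
        w = index.layer(level).window_size
        if viewport_bases // w >= display_cells:
            return level
    return 0
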