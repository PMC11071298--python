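"""Modimizer sketches and the hierarchical multi-resolution index.

A *modimizer* sketch of a window keeps the distinct canonical k-mer hashes
divisible by the sparsity s (a power of two): with s = 2^d these are exactly
the hashes whose d least-significant bits are zero, a context-independent
fractional-minhash sample.  For a window of w positions of random sequence
the expected sketch size is m = w/s.

Because MOD_{2s}(A) is always a subset of MOD_s(A), coarser sketches can be
sampled from finer ones without rescanning the sequence.  The hierarchical
index stacks layers with geometrically growing window size and sparsity,
keeping total storage linear in sequence length.

Low-complexity windows can yield far fewer than m modimizers; sketching is
then *adaptive*: the sparsity is halved until the sketch reaches half the
expected size or s hits 1 (every distinct k-mer kept).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .kmers import (
    DEFAULT_K,
    DEFAULT_SEED,
    HashStream,
    SequenceRecord,
    ValidationError,
    canonical_hashes,
    partition_windows,
    window_size_for_resolution,
)

logger = logging.getLogger(__name__)

DEFAULT_SKETCH_SIZE = 1_000
DEFAULT_RESOLUTION = 1_000


def _is_pow2(s: int) -> bool:
    return s >= 1 and (s & (s - 1)) == 0


@dataclass
class ModimizerSketch:
    """Sampled hash set of one window.

    ``hashes`` is sorted and duplicate-free; every element is divisible by
    the effective ``sparsity``.  ``distinct_count`` is the number of distinct
    valid canonical k-mer hashes in the window before sampling, used by the
    containment bias correction.
    """

    interval: tuple[int, int]  # half-open k-mer position range
    sparsity: int  # effective s (may be below nominal after adaptation)
    hashes: np.ndarray  # sorted uint64
    distinct_count: int

    def __post_init__(self) -> None:
        if not _is_pow2(self.sparsity):
            raise ValidationError(f"sparsity must be a power of two, got {self.sparsity}")

    @property
    def size(self) -> int:
        return int(self.hashes.shape[0])

    def refilter(self, s: int) -> np.ndarray:
        """Hashes re-sampled at a coarser sparsity s (subset property)."""
        if s < self.sparsity:
            raise ValidationError(
                f"cannot refilter sparsity {self.sparsity} sketch to denser s={s}"
            )
        if s == self.sparsity:
            return self.hashes
        return filter_modimizers(self.hashes, s)


def filter_modimizers(hashes: np.ndarray, s: int) -> np.ndarray:
    """Keep hashes divisible by s (s = 2^d: d low bits zero)."""
    if not _is_pow2(s):
        raise ValidationError(f"sparsity must be a power of two, got {s}")
    if s == 1:
        return hashes
    return hashes[(hashes & np.uint64(s - 1)) == 0]


def modimizer_sketch(
    values: np.ndarray, s: int, interval: tuple[int, int] = (0, 0)
) -> ModimizerSketch:
    """Sketch one window's hash values at fixed sparsity s.

    ``values`` are the window's valid canonical hashes (any order, possibly
    with multiplicities); sketching operates on the distinct set.
    """
    distinct = np.unique(np.asarray(values, dtype=np.uint64))
    return ModimizerSketch(
        interval=interval,
        sparsity=s,
        hashes=filter_modimizers(distinct, s),
        distinct_count=int(distinct.shape[0]),
    )


def adaptive_sketch(
    values: np.ndarray,
    nominal_s: int,
    m: float,
    interval: tuple[int, int] = (0, 0),
) -> ModimizerSketch:
    """Sketch with sparsity halved until |sketch| >= ceil(m/2) or s == 1.

    m is the expected modimizer count for this window (window length / s at
    nominal sparsity); the floor of half that expectation guards repetitive
    windows whose distinct k-mer set is small.
    """
    if m < 1:
        raise ValidationError(f"target sketch size must be >= 1, got {m}")
    distinct = np.unique(np.asarray(values, dtype=np.uint64))
    threshold = math.ceil(m / 2)
    s = nominal_s
    if not _is_pow2(s):
        raise ValidationError(f"sparsity must be a power of two, got {s}")
    hashes = filter_modimizers(distinct, s)
    while hashes.shape[0] < threshold and s > 1:
        s //= 2
        hashes = filter_modimizers(distinct, s)
    if s < nominal_s:
        logger.info(
            "adaptive sparsity: window [%d, %d) reduced s %d -> %d (sketch %d, target %d)",
            interval[0],
            interval[1],
            nominal_s,
            s,
            hashes.shape[0],
            threshold,
        )
    return ModimizerSketch(
        interval=interval,
        sparsity=s,
        hashes=hashes,
        distinct_count=int(distinct.shape[0]),
    )


def derive_parameters(
    n: int,
    r: int,
    m: int = DEFAULT_SKETCH_SIZE,
    k: int = DEFAULT_K,
    rounding: str = "floor",
) -> tuple[int, int]:
    """Window size and sparsity realizing resolution r and sketch size ~m.

    w = ceil((n - k + 1)/r); s is w/m rounded to a power of two.  With
    ``rounding="floor"`` (default) the exponent is floored so the expected
    sketch size w/s is at least m; ``"ceil"`` trades accuracy for speed.
    Returns s = 1 when w <= m.
    """
    if r < 1 or m < 1:
        raise ValidationError("resolution and sketch size must be >= 1")
    w = window_size_for_resolution(max(1, n - k + 1), r)
    s = sparsity_for(w, m, rounding=rounding)
    return w, s


def sparsity_for(w: int, m: int, rounding: str = "floor") -> int:
    """Power-of-two sparsity for window size w and target sketch size m."""
    if w <= m:
        return 1
    exponent = math.log2(w / m)
    if rounding == "floor":
        d = math.floor(exponent)
    elif rounding == "ceil":
        d = math.ceil(exponent)
    else:
        raise ValidationError(f"rounding must be 'floor' or 'ceil', got {rounding!r}")
    return 2 ** max(0, d)


def layer_count(n: int, base_window: int, r_min: int = DEFAULT_RESOLUTION) -> int:
    """Number of hierarchy layers: largest l with 2^(l-1)*ŵ <= n / r_min.

    Layers are added while the coarsened window still yields at least r_min
    windows across the sequence; always at least 1.
    """
    if base_window < 1 or r_min < 1:
        raise ValidationError("base window and minimum resolution must be >= 1")
    l = 1
    while (2**l) * base_window * r_min <= n:
        l += 1
    return l


@dataclass
class SketchLayer:
    """All window sketches at one (window size, sparsity) level."""

    level: int
    window_size: int  # k-mer positions per window
    sparsity: int  # nominal s for this level
    sketches: list[ModimizerSketch]

    @property
    def r(self) -> int:
        return len(self.sketches)

    def total_hashes(self) -> int:
        return sum(sk.size for sk in self.sketches)


@dataclass
class HierarchicalIndex:
    """Multi-resolution modimizer index of one sequence.

    Level 0 is the finest layer (base window ŵ, base sparsity ŝ); each
    coarser level doubles both.  The raw hash stream is retained so expanded
    intervals can be sketched on demand.
    """

    record_name: str
    n: int  # sequence length in bases
    k: int
    seed: int
    target_sketch: int  # m̂
    base_window: int  # ŵ
    base_sparsity: int  # ŝ
    layers: list[SketchLayer]
    stream: HashStream

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer(self, level: int) -> SketchLayer:
        if not 0 <= level < len(self.layers):
            raise ValidationError(
                f"level {level} out of range (index has {len(self.layers)} layers)"
            )
        return self.layers[level]

    def params(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "sketch_size": self.target_sketch,
            "base_window": self.base_window,
            "base_sparsity": self.base_sparsity,
        }


def _build_level0(
    stream: HashStream, base_window: int, base_sparsity: int
) -> SketchLayer:
    part = partition_windows(stream.n_positions, base_window)
    sketches = []
    for start, end in part.intervals:
        vals = stream.hashes[start:end][stream.valid[start:end]]
        m = (end - start) / base_sparsity
        sketches.append(
            adaptive_sketch(vals, base_sparsity, max(1.0, m), interval=(start, end))
        )
    return SketchLayer(
        level=0, window_size=base_window, sparsity=base_sparsity, sketches=sketches
    )


def _merge_level(
    stream: HashStream, child: SketchLayer, level: int
) -> SketchLayer:
    """Build the next coarser layer by merging adjacent child sketches.

    The parent sketch at nominal sparsity 2s is sampled from the union of
    its two children via the divisibility test (never rescanning the
    sequence); if the result is undersized, the adaptive rule re-sketches
    from the raw stream slice.
    """
    w = child.window_size * 2
    s = child.sparsity * 2
    sketches: list[ModimizerSketch] = []
    kids = child.sketches
    for i in range(0, len(kids), 2):
        pair = kids[i : i + 2]
        start = pair[0].interval[0]
        end = pair[-1].interval[1]
        union = np.union1d(*(p.hashes for p in pair)) if len(pair) == 2 else pair[0].hashes
        hashes = filter_modimizers(union, s)
        # distinct count of the merged window, for the bias correction
        distinct = stream.distinct(start, end)
        m = (end - start) / s
        if hashes.shape[0] < math.ceil(max(1.0, m) / 2):
            sketches.append(
                adaptive_sketch(distinct, s, max(1.0, m), interval=(start, end))
            )
        else:
            sketches.append(
                ModimizerSketch(
                    interval=(start, end),
                    sparsity=s,
                    hashes=hashes,
                    distinct_count=int(distinct.shape[0]),
                )
            )
    return SketchLayer(level=level, window_size=w, sparsity=s, sketches=sketches)


def build_hierarchy(
    record: SequenceRecord,
    k: int = DEFAULT_K,
    base_window: int | None = None,
    target_sketch: int = DEFAULT_SKETCH_SIZE,
    r_min: int = DEFAULT_RESOLUTION,
    seed: int = DEFAULT_SEED,
    rounding: str = "floor",
    stream: HashStream | None = None,
) -> HierarchicalIndex:
    """Build the full multi-resolution index for one sequence.

    ``base_window`` defaults to the window realizing resolution r_min at the
    finest level.  Coarser layers are added while at least r_min windows
    remain (layer_count rule); a sequence shorter than two base windows
    yields a single-layer index.
    """
    n = len(record)
    if n < k:
        raise ValidationError(f"sequence {record.name!r} shorter than k={k}")
    if stream is None:
        stream = canonical_hashes(record, k=k, seed=seed)
    npos = stream.n_positions
    if base_window is None:
        base_window = window_size_for_resolution(npos, r_min)
    if base_window < 1:
        raise ValidationError("base window must be >= 1")
    base_sparsity = sparsity_for(base_window, target_sketch, rounding=rounding)

    n_layers = layer_count(n, base_window, r_min)
    if base_window * 2 > npos and n_layers > 1:
        logger.warning(
            "sequence %s has fewer than two base windows; single-layer index",
            record.name,
        )
        n_layers = 1

    layers = [_build_level0(stream, base_window, base_sparsity)]
    for level in range(1, n_layers):
        layers.append(_merge_level(stream, layers[-1], level))
    return HierarchicalIndex(
        record_name=record.name,
        n=n,
        k=k,
        seed=seed,
        target_sketch=target_sketch,
        base_window=base_window,
        base_sparsity=base_sparsity,
        layers=layers,
        stream=stream,
    )
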