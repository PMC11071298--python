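"""Sequence input and canonical k-mer hash streams.

A DNA sequence is decomposed into its overlapping k-mers; each k-mer and
its reverse complement are hashed and the smaller of the two hash values is
kept, making the stream strand-neutral.  Hashing packs the k-mer into a
64-bit integer (2 bits per base, so k <= 32) and applies a MurmurHash3-style
finalizer, which is bijective for a fixed seed.  Positions whose k-mer
contains an ambiguous base (anything outside A/C/G/T) are flagged invalid
and excluded from all downstream sketches.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_K = 21
DEFAULT_SEED = 42

# base codes: A=0 C=1 G=2 T=3, 4 marks ambiguous
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class FastaParseError(ValueError):
    """Malformed FASTA content."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (uppercased; name is the first header token)."""

    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class HashStream:
    """Canonical k-mer hashes for every start position of one sequence.

    ``hashes[i]`` is min(h(kmer_i), h(revcomp(kmer_i))); ``valid[i]`` is False
    when the k-mer overlaps an ambiguous base.  ``n_positions == n - k + 1``.
    """

    k: int
    seed: int
    hashes: np.ndarray  # uint64, shape (n - k + 1,)
    valid: np.ndarray  # bool, same shape

    @property
    def n_positions(self) -> int:
        return int(self.hashes.shape[0])

    def distinct(self, start: int, end: int) -> np.ndarray:
        """Sorted distinct valid canonical hashes in [start, end)."""
        sl = self.hashes[start:end]
        return np.unique(sl[self.valid[start:end]])


@dataclass(frozen=True)
class WindowPartition:
    """Tiling of k-mer positions into consecutive windows of size w.

    All windows have length exactly w except possibly the trailing one;
    together they cover [0, n_positions) without gaps or overlap.
    """

    w: int
    intervals: tuple[tuple[int, int], ...]

    @property
    def r(self) -> int:
        return len(self.intervals)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA (plain or gzip) into records, in file order.

    Sequences are uppercased and names truncated at the first whitespace.
    Raises ``FastaParseError`` on malformed content and ``ValidationError``
    on duplicate names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as fh:
        # reject sequence data appearing before any header
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first header"
                )
            break
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            name = rec.id
            if name in seen:
                raise ValidationError(f"duplicate sequence name: {name!r}")
            seen.add(name)
            records.append(SequenceRecord(name=name, seq=str(rec.seq).upper()))
    return records


def _fmix64(x: np.ndarray, seed: int) -> np.ndarray:
    """MurmurHash3 64-bit finalizer, vectorized; bijective for fixed seed."""
    x = x.astype(np.uint64, copy=True)
    x ^= np.uint64((seed * 0x9E3779B97F4A7C15) % (1 << 64))
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xFF51AFD7ED558CCD)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xC4CEB9FE1A85EC53)
    x ^= x >> np.uint64(33)
    return x


def hash_kmer_integers(packed: np.ndarray, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Hash 2-bit-packed k-mer integers to uniform 64-bit values."""
    return _fmix64(np.asarray(packed, dtype=np.uint64), seed)


def canonical_hashes(
    record: SequenceRecord | str, k: int = DEFAULT_K, seed: int = DEFAULT_SEED
) -> HashStream:
    """Decompose a sequence into its canonical k-mer hash stream.

    Each position yields min(h(kmer), h(reverse_complement(kmer))), so the
    stream's set of valid hashes is invariant under reverse complementing
    the input.  Requires 1 <= k <= min(len(seq), 32).
    """
    seq = record.seq if isinstance(record, SequenceRecord) else record
    n = len(seq)
    if k <= 0:
        raise ValidationError(f"k must be positive, got {k}")
    if k > 32:
        raise ValidationError(f"k must be <= 32 (2-bit packing), got {k}")
    if k > n:
        raise ValidationError(f"k={k} exceeds sequence length {n}")

    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    npos = n - k + 1
    bad = codes >= 4
    # window validity via prefix sums of ambiguous-base indicators
    cs = np.concatenate(([0], np.cumsum(bad, dtype=np.int64)))
    valid = (cs[k:] - cs[:-k]) == 0

    c64 = codes.astype(np.uint64)
    c64[bad] = 0  # arbitrary filler; these positions are masked out
    fwd = np.zeros(npos, dtype=np.uint64)
    rev = np.zeros(npos, dtype=np.uint64)
    rc = np.uint64(3) - c64
    two = np.uint64(2)
    for j in range(k):
        fwd = (fwd << two) | c64[j : j + npos]
    for j in range(k - 1, -1, -1):
        rev = (rev << two) | rc[j : j + npos]
    hashes = np.minimum(_fmix64(fwd, seed), _fmix64(rev, seed))
    return HashStream(k=k, seed=seed, hashes=hashes, valid=valid)


def partition_windows(n_positions: int, w: int) -> WindowPartition:
    """Tile [0, n_positions) into windows of size w; trailing partial kept."""
    if w < 1:
        raise ValidationError(f"window size must be >= 1, got {w}")
    if n_positions < 1:
        raise ValidationError("no k-mer positions to partition")
    if w > n_positions:
        logger.warning(
            "window size %d exceeds number of positions %d; using one window",
            w,
            n_positions,
        )
        return WindowPartition(w=w, intervals=((0, n_positions),))
    starts = range(0, n_positions, w)
    intervals = tuple((s, min(s + w, n_positions)) for s in starts)
    return WindowPartition(w=w, intervals=intervals)


def window_size_for_resolution(n_positions: int, r: int) -> int:
    """Window size w = ceil(n_positions / r) realizing a target resolution."""
    if r < 1:
        raise ValidationError(f"resolution must be >= 1, got {r}")
    return math.ceil(n_positions / r)
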