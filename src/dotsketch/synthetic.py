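"""Deterministic synthetic sequences with known repeat structure.

Generates alpha-satellite-like higher-order repeat (HOR) arrays — a tandem
unit of several ~171 bp monomers, copied with a controlled per-base
substitution rate — plus offset-repeat geometries, so every estimator and
plot path is testable with analytically known expected identities.

Divergence is substitution-only (expected pairwise ANI stays closed-form);
structural variation enters only through explicit monomer deletions, so
containment truth remains exact.  All generators are pure functions of
their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmers import SequenceRecord, ValidationError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_dna(length: int, seed: int | np.random.Generator = 0) -> str:
    """Uniform i.i.d. ACGT string of the given length."""
    if length < 0:
        raise ValidationError(f"length must be >= 0, got {length}")
    if length == 0:
        return ""
    rng = _rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate_substitutions(
    seq: str, p: float, seed: int | np.random.Generator = 0
) -> str:
    """Independently replace each base with a *different* base w.p. p."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"substitution rate must be in [0, 1], got {p}")
    if len(seq) == 0 or p == 0.0:
        return seq
    rng = _rng(seed)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    base_idx = np.zeros(len(codes), dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        base_idx[codes == b] = i
    hit = rng.random(len(codes)) < p
    # shift by 1..3 mod 4 guarantees a different base
    shift = rng.integers(1, 4, size=len(codes)).astype(np.uint8)
    new_idx = (base_idx + shift) % 4
    codes[hit] = _BASES[new_idx[hit]]
    return codes.tobytes().decode("ascii")


@dataclass(frozen=True)
class HORSpec:
    """Blueprint for a synthetic higher-order-repeat tandem array.

    Defaults mimic human alpha satellite: 171 bp monomers, 12 monomers per
    HOR unit (~2 kb).  ``per_copy_substitution_rate`` mutates each HOR copy
    independently from the shared consensus.  ``indel_spec`` deletes whole
    monomers from named copies, e.g. ``[(2, 2)]`` drops the last two
    monomers of copy 2 — the exact-containment outlier geometry.
    """

    monomer_length: int = 171
    monomers_per_hor: int = 12
    hor_copies: int = 5
    per_copy_substitution_rate: float = 0.0
    indel_spec: tuple[tuple[int, int], ...] = ()
    flank_length: int = 5_000
    seed: int = 0
    name: str = "synthetic_hor_array"

    @property
    def hor_length(self) -> int:
        return self.monomer_length * self.monomers_per_hor


def expected_pairwise_ani(p: float) -> float:
    """Nominal ANI between two copies each mutated at rate p from consensus.

    A site differs if exactly one copy mutated (2p(1-p)) or both mutated to
    different bases (p^2 * 2/3).
    """
    diff = 2.0 * p * (1.0 - p) + (2.0 / 3.0) * p * p
    return 100.0 * (1.0 - diff)


def make_hor_array(spec: HORSpec) -> tuple[SequenceRecord, pd.DataFrame]:
    """Build flank + mutated HOR copies + flank, with a coordinate truth table.

    Returns the record and a DataFrame with one row per copy (columns:
    ``copy, start, end, n_monomers``) plus the array-wide attributes
    ``expected_pairwise_ani`` and ``hor_length`` in ``df.attrs``.
    """
    for copy_idx, n_del in spec.indel_spec:
        if not 0 <= copy_idx < spec.hor_copies:
            raise ValidationError(f"indel_spec references nonexistent copy {copy_idx}")
        if not 0 < n_del <= spec.monomers_per_hor:
            raise ValidationError(f"cannot delete {n_del} of {spec.monomers_per_hor} monomers")
    rng = np.random.default_rng(spec.seed)
    consensus = random_dna(spec.hor_length, rng)
    deletions = dict(spec.indel_spec)
    parts = [random_dna(spec.flank_length, rng)]
    rows = []
    pos = spec.flank_length
    p = spec.per_copy_substitution_rate
    for c in range(spec.hor_copies):
        copy_seq = mutate_substitutions(consensus, p, rng)
        n_mono = spec.monomers_per_hor - deletions.get(c, 0)
        copy_seq = copy_seq[: n_mono * spec.monomer_length]
        parts.append(copy_seq)
        rows.append({"copy": c, "start": pos, "end": pos + len(copy_seq), "n_monomers": n_mono})
        pos += len(copy_seq)
    parts.append(random_dna(spec.flank_length, rng))
    record = SequenceRecord(name=spec.name, seq="".join(parts))
    truth = pd.DataFrame(rows)
    truth.attrs["expected_pairwise_ani"] = expected_pairwise_ani(p)
    truth.attrs["hor_length"] = spec.hor_length
    truth.attrs["pairwise_identity"] = _realized_identity(record.seq, truth)
    return record, truth


def _realized_identity(seq: str, truth: pd.DataFrame) -> np.ndarray:
    """Exact percent identity between copies over their shared prefix.

    Deletions truncate copies at the end, so the aligned region is the
    shorter copy's full length; this is the per-pair ground truth the
    containment estimator should recover.
    """
    copies = [
        np.frombuffer(seq[row.start : row.end].encode(), dtype=np.uint8)
        for row in truth.itertuples()
    ]
    n = len(copies)
    ident = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            L = min(len(copies[i]), len(copies[j]))
            matches = int((copies[i][:L] == copies[j][:L]).sum())
            ident[i, j] = ident[j, i] = 100.0 * matches / L
    return ident


def make_offset_pair(
    unit_length: int = 10_000, seed: int = 0, name: str = "offset_pair"
) -> tuple[SequenceRecord, dict]:
    """Two identical units out of register by half a window (worst case).

    Layout (w = unit_length): unit U at [0, w), random spacer of w/2, U
    again at [1.5w, 2.5w), random tail of w/2.  With windows of size w the
    first window is exactly U while the second copy straddles windows 1 and
    2, each holding half of it — so unexpanded containment of window 0 in
    either is ~0.5, and window expansion by w/2 recovers ~1.0.
    """
    rng = np.random.default_rng(seed)
    unit = random_dna(unit_length, rng)
    seq = unit + random_dna(unit_length // 2, rng) + unit + random_dna(unit_length // 2, rng)
    layout = {
        "window": unit_length,
        "in_register_window": 0,
        "straddling_windows": (1, 2),
        "unit_starts": (0, unit_length + unit_length // 2),
    }
    return SequenceRecord(name=name, seq=seq), layout


def write_fasta(records, path) -> None:
    """Write records as an uncompressed FASTA fixture (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")
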