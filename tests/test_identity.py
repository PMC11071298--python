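"""Containment estimation, ANI conversion and identity-matrix assembly."""

import math

import numpy as np
import pytest

from dotsketch.identity import (
    ani_from_containment,
    cell_identity,
    comparative_matrix,
    containment,
    expand_interval,
    select_layer,
    self_matrix,
)
from dotsketch.kmers import SequenceRecord, ValidationError, canonical_hashes
from dotsketch.sketch import (
    ModimizerSketch,
    build_hierarchy,
    modimizer_sketch,
    sparsity_for,
)
from dotsketch.synthetic import HORSpec, make_hor_array, mutate_substitutions, random_dna

_COMP = str.maketrans("ACGT", "TGCA")


def exact_containment(seq_a: str, seq_b: str, k: int) -> float:
    """Brute-force oracle: canonical k-mer string sets, |A∩B| / |A|."""

    def kmers(seq):
        out = set()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            out.add(min(km, km.translate(_COMP)[::-1]))
        return out

    a, b = kmers(seq_a), kmers(seq_b)
    return len(a & b) / len(a)


def sketch_of(seq: str, s: int, k: int = 21) -> ModimizerSketch:
    stream = canonical_hashes(seq, k=k)
    return modimizer_sketch(stream.hashes[stream.valid], s)


class TestContainment:
    def test_identical_sketches_full_density(self):
        sk = modimizer_sketch(np.arange(100, dtype=np.uint64), 1)
        est = containment(sk, sk)
        assert est.value == 1.0 and est.correction == 1.0

    def test_disjoint_sketches(self):
        a = modimizer_sketch(np.arange(0, 50, dtype=np.uint64), 1)
        b = modimizer_sketch(np.arange(100, 150, dtype=np.uint64), 1)
        assert containment(a, b).value == 0.0

    def test_bias_correction_closed_form(self):
        """Correction denominator matches |MOD_s(A)|(1-(1-1/s)^|A|) exactly."""
        # 250 multiples of 4 shared by both sketches, |A| = 4000 distinct
        a = ModimizerSketch((0, 4000), 4, np.arange(0, 1000, 4, dtype=np.uint64), 4000)
        b = ModimizerSketch((0, 4000), 4, np.arange(0, 1000, 4, dtype=np.uint64), 4000)
        est = containment(a, b)
        expected_correction = 1.0 - (1.0 - 0.25) ** 4000
        assert est.correction == pytest.approx(expected_correction, rel=1e-12)
        assert est.value == pytest.approx(min(1.0, 1.0 / expected_correction))

    def test_small_set_correction_inflates_estimate(self):
        # |A| = 4: sizeable probability a distinct k-mer is never sampled
        a = ModimizerSketch((0, 10), 4, np.array([0, 4], dtype=np.uint64), 4)
        b = ModimizerSketch((0, 10), 4, np.array([0], dtype=np.uint64), 4)
        est = containment(a, b)
        corr = 1.0 - 0.75**4
        assert est.value == pytest.approx(min(1.0, 0.5 / corr))

    def test_empty_denominator_reports_zero(self):
        a = ModimizerSketch((0, 10), 4, np.array([], dtype=np.uint64), 0)
        b = modimizer_sketch(np.arange(8, dtype=np.uint64), 1)
        assert containment(a, b).value == 0.0

    def test_mixed_sparsity_refilters_to_common(self):
        a = modimizer_sketch(np.arange(0, 64, dtype=np.uint64), 2)
        b = modimizer_sketch(np.arange(0, 64, dtype=np.uint64), 8)
        est = containment(a, b)
        assert est.sparsity == 8
        assert est.denominator_size == 8  # multiples of 8 below 64

    def test_oracle_equivalence_at_full_density(self, rng):
        """s=1 hash containment equals exact k-mer set containment."""
        for trial in range(12):
            base = random_dna(5_000, rng)
            other = mutate_substitutions(base, p=rng.choice([0.0, 0.005, 0.02, 0.3]), seed=rng)
            est = containment(sketch_of(base, 1), sketch_of(other, 1))
            assert est.value == pytest.approx(exact_containment(base, other, 21), abs=1e-12)


class TestAniFromContainment:
    @pytest.mark.parametrize(
        "c,k,expected",
        [
            (1.0, 21, 100.0),
            (0.0, 21, 0.0),
            (0.9, 21, 100.0 * math.exp(math.log(0.9) / 21)),  # 99.4996...
            (0.5, 10, 100.0 * 0.5**0.1),
        ],
    )
    def test_binomial_inversion(self, c, k, expected):
        assert ani_from_containment(c, k) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ani_from_containment(1.5, 21)


class TestExpandInterval:
    def test_symmetric_expansion(self):
        assert expand_interval((100, 200), w=100, factor=1.0, bound=10_000) == (50, 250)

    def test_clamped_at_sequence_start(self):
        assert expand_interval((0, 100), w=100, factor=1.0, bound=10_000) == (0, 150)

    def test_zero_factor_is_identity(self):
        assert expand_interval((40, 80), w=40, factor=0.0, bound=100) == (40, 80)


@pytest.fixture(scope="module")
def offset_index():
    from dotsketch.synthetic import make_offset_pair

    rec, layout = make_offset_pair(10_000, seed=3)
    idx = build_hierarchy(rec, base_window=layout["window"], target_sketch=1_000, r_min=1)
    return idx, layout


class TestCellIdentity:
    def test_self_cell_is_100(self, offset_index):
        idx, _ = offset_index
        sk = idx.layer(0).sketches[0]
        assert cell_identity(sk, sk, idx.stream, 10_000, idx.k, 0.0) == 100.0

    def test_out_of_register_rescued_by_expansion(self, offset_index):
        """Half-window offset halves raw containment; expansion recovers it."""
        idx, layout = offset_index
        layer = idx.layer(0)
        a = layer.sketches[layout["in_register_window"]]
        b = layer.sketches[layout["straddling_windows"][0]]
        raw = containment(a, b).value
        assert raw == pytest.approx(0.5, abs=0.05)
        ani = cell_identity(a, b, idx.stream, layer.window_size, idx.k, 1.0)
        assert (ani / 100.0) ** idx.k == pytest.approx(1.0, abs=0.05)

    def test_expansion_is_monotone(self, offset_index):
        """Growing the expansion factor never lowers the estimate."""
        idx, layout = offset_index
        layer = idx.layer(0)
        a = layer.sketches[0]
        b = layer.sketches[1]
        vals = [
            cell_identity(a, b, idx.stream, layer.window_size, idx.k, f)
            for f in (0.0, 0.25, 0.5, 1.0, 2.0)
        ]
        assert all(v1 >= v0 - 1e-12 for v0, v1 in zip(vals, vals[1:]))


class TestSelfMatrix:
    def test_symmetric_unit_diagonal(self):
        rec = SequenceRecord("r", random_dna(60_000, seed=5))
        idx = build_hierarchy(rec, base_window=6_000, target_sketch=500, r_min=1)
        mat = self_matrix(idx, level=0, threshold=80.0)
        assert np.array_equal(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 100.0)

    def test_random_sequence_has_no_off_diagonal_signal(self):
        """Chance 21-mer collisions cannot reach an 80% identity floor."""
        rec = SequenceRecord("r", random_dna(200_000, seed=6))
        idx = build_hierarchy(rec, base_window=10_000, target_sketch=500, r_min=1)
        mat = self_matrix(idx, level=0, threshold=80.0, expansion_factor=0.0)
        off = mat.values[~np.eye(mat.values.shape[0], dtype=bool)]
        assert np.all(off == 0.0)

    def test_expansion_only_touches_adjacent_cells(self):
        """Doubling B makes expanded neighbors overlap A (containment ~1/2);
        beyond the first off-diagonal, random sequence stays empty."""
        rec = SequenceRecord("r", random_dna(200_000, seed=6))
        idx = build_hierarchy(rec, base_window=10_000, target_sketch=500, r_min=1)
        mat = self_matrix(idx, level=0, threshold=80.0, expansion_factor=1.0)
        r = mat.values.shape[0]
        for i in range(r):
            for j in range(r):
                if abs(i - j) > 1:
                    assert mat.values[i, j] == 0.0
                elif abs(i - j) == 1:
                    assert mat.values[i, j] == pytest.approx(
                        100.0 * 0.5 ** (1 / 21), abs=0.5
                    )

    def test_hor_array_block_identity_tracks_mutation_rate(self):
        """Estimated window identities recover the realized copy divergence."""
        spec = HORSpec(hor_copies=6, per_copy_substitution_rate=0.01,
                       flank_length=0, seed=9)
        rec, truth = make_hor_array(spec)
        w = spec.hor_length
        idx = build_hierarchy(rec, base_window=w, target_sketch=1_000, r_min=1)
        # expansion off: expanded windows would union in neighboring copies
        mat = self_matrix(idx, level=0, threshold=80.0, expansion_factor=0.0)
        expected = truth.attrs["pairwise_identity"]
        off = ~np.eye(mat.values.shape[0], dtype=bool)
        # per-cell: sketch noise at m~1000; mean: estimator unbiasedness
        assert np.abs(mat.values[off] - expected[off]).max() < 0.6
        assert np.abs(mat.values[off] - expected[off]).mean() < 0.25
        # nominal divergence 2p(1-p)+2p^2/3 is itself within fixture noise
        assert np.mean(expected[off]) == pytest.approx(
            truth.attrs["expected_pairwise_ani"], abs=1.0
        )


class TestEstimatorCalibration:
    def test_mean_ani_tracks_substitution_rate(self, rng):
        """ANI from containment inverts the k-mer survival curve (200 kb pairs)."""
        k, m = 21, 1_000
        for p in (0.002, 0.01, 0.02):
            anis = []
            for _ in range(8):
                base = random_dna(200_000, rng)
                mut = mutate_substitutions(base, p, rng)
                s = sparsity_for(len(base) - k + 1, m)
                est = containment(sketch_of(base, s, k), sketch_of(mut, s, k))
                anis.append(ani_from_containment(est.value, k))
            assert np.mean(anis) == pytest.approx(100.0 * (1.0 - p), abs=0.3)

    def test_accuracy_degrades_with_sparsity(self, rng):
        """Smaller sketches (higher s) spread the ANI estimate."""
        k, p = 21, 0.01
        spreads = {}
        for m in (100, 1_000):
            anis = []
            for _ in range(12):
                base = random_dna(100_000, rng)
                mut = mutate_substitutions(base, p, rng)
                s = sparsity_for(len(base) - k + 1, m)
                est = containment(sketch_of(base, s, k), sketch_of(mut, s, k))
                anis.append(ani_from_containment(est.value, k))
            spreads[m] = np.std(anis)
        assert spreads[100] > spreads[1_000]


class TestIndelInsensitivity:
    def test_truncated_hor_copy_still_fully_contained(self):
        """A 10-of-12-monomer copy is contained in the canonical unit."""
        spec = HORSpec(hor_copies=3, per_copy_substitution_rate=0.0,
                       indel_spec=((1, 2),), flank_length=1_000, seed=4)
        rec, truth = make_hor_array(spec)
        short = truth.iloc[1]
        canon = truth.iloc[0]
        stream = canonical_hashes(rec.seq, k=21)
        short_sk = modimizer_sketch(stream.distinct(short.start, short.end - 20), 1,
                                    (short.start, short.end))
        canon_sk = modimizer_sketch(stream.distinct(canon.start, canon.end - 20), 1,
                                    (canon.start, canon.end))
        ani = ani_from_containment(containment(short_sk, canon_sk).value, 21)
        assert ani >= 99.5


class TestComparativeMatrix:
    def test_identical_sequences_have_unit_diagonal_band(self):
        seq = random_dna(50_000, seed=8)
        ix = build_hierarchy(SequenceRecord("x", seq), base_window=5_000,
                             target_sketch=500, r_min=1)
        iy = build_hierarchy(SequenceRecord("y", seq), base_window=5_000,
                             target_sketch=500, r_min=1)
        mat = comparative_matrix(ix, iy, level=0, threshold=80.0)
        assert np.all(np.diag(mat.values) == pytest.approx(100.0, abs=0.2))

    def test_reverse_complement_gives_antidiagonal(self):
        """Canonical hashing makes the comparison strand-neutral."""
        seq = random_dna(50_000, seed=8)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        ix = build_hierarchy(SequenceRecord("x", seq), base_window=5_000,
                             target_sketch=500, r_min=1)
        iy = build_hierarchy(SequenceRecord("y", rc), base_window=5_000,
                             target_sketch=500, r_min=1)
        mat = comparative_matrix(ix, iy, level=0, threshold=80.0)
        assert np.all(np.diag(np.fliplr(mat.values)) >= 99.0)

    def test_unrelated_sequences_all_zero(self):
        ix = build_hierarchy(SequenceRecord("x", random_dna(40_000, seed=1)),
                             base_window=5_000, target_sketch=500, r_min=1)
        iy = build_hierarchy(SequenceRecord("y", random_dna(40_000, seed=2)),
                             base_window=5_000, target_sketch=500, r_min=1)
        mat = comparative_matrix(ix, iy, level=0, threshold=80.0)
        assert np.all(mat.values == 0.0)

    def test_mismatched_parameters_rejected(self):
        seq = random_dna(40_000, seed=1)
        ix = build_hierarchy(SequenceRecord("x", seq), k=21, base_window=5_000,
                             target_sketch=500, r_min=1)
        iy = build_hierarchy(SequenceRecord("y", seq), k=19, base_window=5_000,
                             target_sketch=500, r_min=1)
        with pytest.raises(ValidationError, match="k"):
            comparative_matrix(ix, iy)


@pytest.fixture(scope="module")
def index():
    rec = SequenceRecord("r", random_dna(2_000_000, seed=7))
    return build_hierarchy(rec, base_window=4_000, target_sketch=250, r_min=100)


class TestSelectLayer:
    def test_full_viewport_uses_top_layer(self, index):
        assert select_layer(index, index.n, 100) == index.n_layers - 1

    def test_halved_viewport_steps_one_level_finer(self, index):
        top = select_layer(index, index.n, 100)
        assert select_layer(index, index.n // 2, 100) == top - 1

    def test_tiny_viewport_falls_back_to_finest(self, index):
        assert select_layer(index, 10_000, 100) == 0
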