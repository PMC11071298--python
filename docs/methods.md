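# Methods

## Estimation model

A window is represented by the set of its distinct canonical k-mer hashes
(sets, not multisets: copy number inside a window is deliberately
invisible). For windows A and B at sparsity s the containment of A in B is
estimated from modimizer sketches as

    c(A, B) = |MOD_s(A) ∩ MOD_s(B)| / ( |MOD_s(A)| · (1 − (1 − 1/s)^|A|) )

with |A| the distinct k-mer count of A. The correction term is the
probability that a k-mer of A is sampled at all under fractional
minhashing; without it, containment is systematically underestimated when
|A| is small (repetitive windows). Estimates can exceed 1 on small
sketches and are clamped to [0, 1] before conversion.

Identity follows from a per-site binomial mutation model: a k-mer survives
between two sequences iff none of its k sites differ, so the surviving
fraction is (ANI/100)^k and

    ANI(A, B) = 100 · c(A, B)^(1/k).

Because containment has no set operation in its denominator, it measures
the similarity of the *shared* sequence: large insertions, deletions or
copy-number differences between A and B are not penalized. A truncated
repeat unit whose monomers are fully contained in a canonical unit scores
~100 even though a global aligner would report a large indel. This is a
feature for satellite arrays (it isolates the point-mutation rate from
structural turnover) and a caveat when a penalty for structural change is
wanted.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 21 | k-mer length (bases). Smaller k is more sensitive to diverged repeats but loses specificity to chance collisions; 21 keeps the chance-collision floor far below usable thresholds. Limited to ≤ 32 by 2-bit packing. |
| r | 1,000 | resolution: windows per matrix axis; w = ceil((n−k+1)/r). |
| m | 1,000 | target sketch size per window; s = w/m rounded down to a power of two, so the realized expectation is ≥ m (a `rounding="ceil"` option trades accuracy for speed). |
| t | 86 | identity threshold (%). Cells below t are stored as 0 and rendered uncolored. Estimates degrade quickly below ~80% identity because few k-mers survive (at 80% identity only 0.8^21 ≈ 0.9% of 21-mers are shared). |
| expansion factor | 1.0 | B is widened by factor·w/2 per side before intersection. 1.0 covers the worst case of a match diagonal starting mid-window; 0 disables expansion. |
| seed | 42 | hash seed; sketches from different seeds are incomparable, so the seed is embedded in all output metadata and validated on reuse. |

Sparsity is restricted to powers of two so membership is a check of the
d = log2(s) low bits and so coarser sketches are strict subsets of finer
ones (hashes divisible by 2s are divisible by s). That subset property is
what lets each hierarchy level be sampled from the union of its two child
sketches instead of rescanning the sequence; levels are added while at
least r_min windows remain, i.e. the layer count is the largest l with
2^(l−1)·ŵ·r_min ≤ n. The geometric decay of per-level storage keeps the
whole index O(n).

### Adaptive sparsity

If a window yields fewer than half its expected modimizer count
(ceil(m/2), with m = (end−start)/s so trailing partial windows are treated
uniformly), s is halved and the window re-filtered until the floor is met
or s = 1. When two sketches at different effective sparsities meet, the
denser is re-filtered to the common (sparser) s and the bias correction
uses that s. A parent layer window whose child-union sample is undersized
is re-sketched adaptively from the raw hash stream; this is the one place
the hierarchy touches the stream again, and it preserves the subset
sampling everywhere the floor is not binding.

## Hashing

k-mers are 2-bit packed and passed, together with the packed reverse
complement, through a seeded 64-bit MurmurHash3-style finalizer (xor-shift
and odd-constant multiplies); the smaller of the two values is kept. The
finalizer is bijective for a fixed seed, so for k ≤ 32 distinct canonical
k-mers never collide — full-density (s = 1) hash-set containment equals
exact k-mer-set containment, which the test suite exploits by checking the
estimator against brute-force string-set containment. K-mers overlapping
any non-ACGT character are masked out entirely rather than hashed with a
substitute, avoiding spurious identity between N-runs; windows that are
all Ns have empty sketches and report 0 (uncolored) with a logged warning.

## Coordinates and output

Internally everything is 0-based half-open in k-mer start positions; BED
output converts to base coordinates (the final window's end is clamped to
the sequence length). The pairwise BED dialect is 7 columns — query
name/start/end, reference name/start/end, perID — gzip-compressed with a
`#` header embedding all parameters as JSON; self plots emit only the
upper triangle unless `--full-bed` is given. perID is written with
shortest round-trip float formatting so reading the file back reproduces
the stored matrix exactly. The binary container is a numpy `.npz` with a
JSON metadata entry; loading validates a format version and optionally
k/seed compatibility. CLI region strings are 1-based inclusive
(samtools convention) and converted at the boundary.

## Synthetic data

`dotsketch.synthetic` emulates satellite-array structure: a random
consensus higher-order repeat unit (default 12 monomers × 171 bp,
alpha-satellite-like) tandem-copied, each copy independently mutated at a
per-base substitution rate p, optionally with whole monomers deleted from
named copies, flanked by random sequence. Truth tables carry each copy's
coordinates, the nominal expected pairwise identity
(100·(1 − 2p(1−p) − 2p²/3), both copies mutated from the consensus) and
the *realized* pairwise identity computed from the emitted sequences —
at 2 kb copies the binomial noise of the fixture itself (sd ≈ 0.3 points
per pair) exceeds the estimator's error, so calibration tests compare
against realized truth. Offset fixtures place two identical units half a
window out of register, the worst case for window segmentation.

What the generator does not emulate: unequal crossover dynamics, GC bias,
monomer-level phylogenetic structure, or real mutation spectra. Passing
tests therefore demonstrate the estimator's statistical behavior
(calibration, adaptive floor, expansion rescue, indel insensitivity) on
substitution-diverged repeats, not concordance with alignment tools on
real centromeres.

## Numerical and design choices

* Window expansion makes the *first* off-diagonal of any self matrix score
  ~100·0.5^(1/k) ≈ 96.8%, because an expanded neighbor physically overlaps
  half of A. This is inherent to unconditional doubling of B and visible
  as a slightly thickened diagonal; disable expansion if it matters.
* Comparative matrices use max of both directional estimates by default
  (configurable `direction={max,xy,yx}`), making plots invariant to
  swapping the axes; self matrices always symmetrize with max.
* Problem sizes in the test suite are chosen for quick, repeatable runs:
  calibration uses 200 kb pairs (the containment denominator then holds
  ~10^5 distinct k-mers, ample for a ±0.3-point check of the mean over 20
  replicates), hierarchy equality uses a 2 Mb sequence with three layers.
* Sketches are stored as sorted uint64 arrays; intersections are
  merge-scans (`np.intersect1d` with unique inputs). Matrix assembly is
  O(r²·m); r = 1,000 matrices take a few minutes in pure Python/numpy,
  r ≤ 200 is interactive.
* Empty-sketch denominators (all-N or empty windows) return containment 0
  with a warning rather than NaN.
* Ties and edges: power-of-two rounding of sparsity floors the exponent;
  expansion pads are floored to integers; expanded intervals clamp to
  sequence bounds.

## Limitations

* Identity below ~t = 80% is unreliable (few surviving k-mers); the
  default threshold (86%) stays above that floor.
* No gapped alignment is performed anywhere; per-cell values carry no
  base-level alignment detail.
* Sequences shorter than one window collapse to a single cell; k is
  capped at 32 by the packed representation.
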