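# dotsketch

Alignment-free identity heatmaps of genomic repeats, built from
hierarchical **modimizer** (fractional minhash) sketches.

Large tandem repeat arrays — centromeric alpha satellite, rDNA, segmental
duplications — are best understood through a *self-identity dot plot*: a
heatmap whose cell (i, j) is the percent identity between genomic windows
i and j of the same (or two different) sequences. Alignment-based heatmaps
are slow and behave poorly inside repeats; `dotsketch` instead estimates
identity from k-mer sketches, so runtime depends on the matrix resolution
rather than sequence length, and a multi-resolution index supports zooming
without recomputation.

## Method

Each sequence is decomposed into canonical k-mers (the smaller of the
hashes of a k-mer and its reverse complement; default k = 21) and
partitioned into r non-overlapping windows of w k-mer positions
(default resolution r = 1,000). A window A is sketched by its
**modimizers** — distinct hashes divisible by a power-of-two sparsity s —
giving an expected sketch size m = w/s (default m = 1,000). The fraction
of A contained in B is estimated with a FracMinHash bias correction:

    c(A, B) = |MOD_s(A) ∩ MOD_s(B)| / ( |MOD_s(A)| · (1 − (1 − 1/s)^|A|) )

where |A| is A's distinct k-mer count, and converted to average
nucleotide identity under a per-site binomial mutation model:

    ANI(A, B) = 100 · c(A, B)^(1/k)

Self matrices store max(ANI(A,B), ANI(B,A)); cells below a threshold t
(default 86%) are left uncolored. Two refinements matter in practice:

* **Window expansion** — B is extended by w/2 on each side before
  intersection, so similar sequence "out of register" with the window grid
  is not underscored. B never enters the denominator, so expansion cannot
  bias the estimate downward.
* **Adaptive sparsity** — in low-complexity windows the sparsity is halved
  until the sketch holds at least half its expected size (or s = 1), so
  satellite arrays with tiny distinct k-mer sets stay comparable.
* **Hierarchy** — layers with window/sparsity doubled per level are sampled
  from the previous layer's sketches (MOD_{2s}(A) ⊆ MOD_s(A_L) ∪ MOD_s(A_R)),
  keeping total storage linear; a zoom query picks the coarsest layer with
  at least one cell per display pixel.

No external data is needed: `dotsketch.synthetic` generates tandem-repeat
arrays (171 bp monomers, 12-monomer higher-order repeat units, controlled
substitution rates and monomer deletions) with exact truth tables.

## Worked example

```sh
python examples/self_identity_hor.py
```

builds a six-copy HOR array (each ~2 kb copy carrying ~1% substitutions
from a shared consensus) and prints:

```
array: 12,312 bp, 6 HOR copies of 2052 bp
matrix: 6x6 windows of 2,052 bases
off-diagonal identity: mean 98.52%, range [97.73, 99.01]%
realized copy divergence (truth): mean 98.40%
wrote hor_self.bed.gz and hor_self.png
```

The off-diagonal window identities recover the realized pairwise
divergence of the simulated copies (two copies each 1% diverged from a
consensus differ by ~2%, hence ~98% identity). The BED file holds one row
per cell at or above the threshold; the PNG is the discrete-binned
heatmap. The other scripts in `examples/` demonstrate window expansion
(`offset_rescue.py`: containment 0.52 → 1.00), comparative plots and
strand neutrality (`comparative_plot.py`), the zoom hierarchy
(`zoom_layers.py`) and estimator calibration (`ani_calibration.py`,
mean ANI within a few hundredths of 100(1−p) for p ≤ 0.02).

The same pipeline is available as a thin CLI:

```sh
dotsketch static genome.fa -o out            # self plot per sequence
dotsketch static a.fa b.fa --compare -o out  # plus all pairwise plots
dotsketch query genome.fa --region-x chr1:1-2000000 --display-cells 500 -o out
```

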