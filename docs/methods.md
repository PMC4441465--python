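# Methods

## Model and pipeline

`modmap` measures relatedness between DNA sequences through the oligomer
composition encoded in their Chaos Game Representation (CGR) images. The
pipeline is CGR encoding → pairwise DSSIM image distances → classical
(Torgerson) multidimensional scaling, with Kruskal Stress-1 as the map
quality statistic. The method assumes only that each sequence is long
enough to populate its CGR (a few kilobases give a well-defined image at
k = 9); it makes no homology, synteny or equal-length assumptions, which is
what makes it applicable to arbitrary mixtures of genomes.

## CGR encoding

Corners A (0,0), C (0,1), G (1,1), T (1,0) — clockwise from bottom-left,
y up. The plotting iteration is p₀ = (0.5, 0.5), pᵢ = (pᵢ₋₁ + corner(sᵢ))/2.
At resolution 2ᵏ × 2ᵏ the pixel of a k-mer is obtained from its letters'
quadrant half-bits (x-bit 1 for G/T, y-bit 1 for C/G), the *last* letter
contributing the most significant bit; rows are flipped once so row 0 is
the top of the raster (standard image convention).

Two facts drive the implementation:

* The final trajectory point after reading a k-mer lies strictly inside
  that k-mer's cell — the residual of the start point lies in (0, 2⁻ᵏ) —
  so floor quantization is exact and no boundary tie-breaking is needed.
* The first k−1 trajectory points carry the start-point transient and can
  land in cells of k-mers that never occur. Encoding therefore enumerates
  the sliding k-mer window directly; the trajectory is retained only as a
  verification oracle (tests check that the black-pixel set equals the
  quantized trajectory points pᵢ for i ≥ k) and for plotting.

Pixels are 8-bit: black 0 for occurring k-mers, white 255 otherwise.
Default k = 9 (512 × 512). An optional count-weighted mode maps log-scaled
k-mer counts onto 0–255; it is not used by any test and is off by default.
Reverse complements are not merged. Trade-off in k: larger k resolves
longer oligomers but needs longer sequences to populate the raster.

## DSSIM

SSIM is computed per window position as
[(2μ_Aμ_B + C₁)(2σ_AB + C₂)] / [(μ_A² + μ_B² + C₁)(σ_A² + σ_B² + C₂)],
with C₃ = C₂/2 folding the structure term into the two-term form. Fixed
conventions, all recorded in the run manifest because they shift values at
the 3rd–4th decimal:

* 11 × 11 window, Gaussian weights σ = 1.5 (normalised, separable),
  K₁ = 0.01, K₂ = 0.03, dynamic range L = 255 — the canonical reference
  parameterisation of the index.
* Weighted moments use the normalised window; population (not sample)
  covariance normalisation.
* Only windows fully inside the image contribute ("valid" borders); the
  result is the plain mean of the local map.
* No pre-filtering or downsampling: CGR pixel identity is meaningful and
  downsampling would merge k-mers.
* Images enter as 8-bit intensities (black = 0), never as {0,1} booleans.

The distance is Δ = 1 − mean SSIM ∈ [0, 2]. For typical genomic CGR pairs
distances fall in (0, 1); values slightly above 1 correspond to weakly
negative mean SSIM and are expected behaviour, not errors.

`pairwise_distances` precomputes per-image window means and variances so
each pair costs one windowed cross-moment; tests assert equality with the
brute-force pair loop, and the implementation is cross-checked against
both a naive per-window summation (to 1e-10) and scikit-image's
`structural_similarity` with matching options.

## Classical MDS and Stress-1

Double centering B = −½ J (Δ∘Δ) J, eigendecomposition, coordinates from
the q algebraically largest eigenpairs scaled by √λ. DSSIM matrices are
generally non-Euclidean, so negative eigenvalues occur; they are clamped
to zero for coordinates (standard Torgerson treatment) and reported in
full in the diagnostics. Eigenvalues within a relative 1e-12 of zero are
treated as non-positive so exactly low-rank configurations get exactly
zero deficient axes (with a warning). Eigenvector signs are fixed —
largest-magnitude entry of each column positive — so maps are reproducible
across runs and platforms; the embedding is otherwise unique only up to
rotation/reflection.

Stress-1 uses disparities f(Δ) = aΔ + b fitted by unconstrained OLS of map
distances on input distances over unordered pairs (b may be nonzero, a may
be negative on pathological inputs). Stress is evaluated **before** the
per-axis scaling onto [−1, 1]: that scaling is anisotropic and would change
the map distances, so the order (stress, then scale) is fixed. Degenerate
cases: all input distances equal → (a, b) = (0, mean d) with a warning;
all map points coincident (zero denominator, e.g. identical sequences) →
σ₁ defined as 0 with a warning. An axis with max = min scales to all
zeros. q defaults to 2; q = 3 is supported for 3-D maps.

## Synthetic data

Two generators, both seeded explicitly (default seed 0):

* **Trinucleotide-preserving shuffle.** The sequence is an Eulerian path
  on the order-2 de Bruijn multigraph (nodes = dinucleotides, one edge per
  overlapping trinucleotide occurrence). A uniform random Eulerian path
  from the same start node is sampled by drawing a multiplicity-weighted
  random last-exit arborescence into the walk's terminal dinucleotide
  (rejection until the picks form an arborescence — this terminates with
  probability 1 since the terminal node is reachable from every node of
  the walk) and then permuting each node's remaining out-edges uniformly.
  This preserves length and all 3-mer counts *exactly*, not merely in
  expectation, which is the stronger and more faithful reading of
  "same trinucleotide frequencies"; fixing the start node guarantees an
  Eulerian path exists on the original edge multiset.
* **Markov families.** Order-0/1/2 chains; each family's transition rows
  are (1 − divergence)·base + divergence·own with base and own rows
  Dirichlet(1) draws, so divergence ∈ [0, 1] interpolates from identical
  generative laws to independent ones. Defaults used in the end-to-end
  validation: 4 families × 5 sequences of length 20,000 at order 2 and
  divergence 0.5 — long enough to populate a k = 9 CGR and a moderate,
  realistic level of compositional divergence between families.

What the simulator emulates — and what it does not: it reproduces
species-like differences in oligomer usage, which is exactly the signal
the method reads, but real mitochondrial genomes have gene order, strand
asymmetry, repeats and selection-driven structure that a Markov chain does
not. Passing the end-to-end tests shows the pipeline separates sequences
by generative law; it does not by itself certify taxonomic accuracy on
real genomes, which additionally requires the real sequence records.

## Numerical choices

* All image arithmetic in float64; SSIM on identical arrays returns
  exactly 1 (numerator and denominator are computed identically), so the
  self-distance is exactly 0.
* Distance matrices are persisted at full precision (`%.17g`, re-read with
  round-trip float parsing) so reruns are byte-identical; displayed values
  are rounded to 4 decimals.
* Mean distance in the manifest is over unordered pairs i < j, diagonal
  excluded.
* Rank listings break distance ties lexicographically by id.
* Problem sizes in the test suite (sequence lengths ≤ 20 kb, ≤ 20
  sequences end-to-end, SSIM oracle images 16 × 16) are chosen so each
  property is exercised at full fidelity while the whole suite runs in
  well under a minute of compute per module.

## Known limitations

* DSSIM compresses large and small image differences into a narrow range
  of values near 1 for distant genomes; for deep taxonomic comparisons a
  distance with more dynamic range may separate clusters better.
* Classical MDS on non-Euclidean DSSIM matrices discards the negative part
  of the spectrum; the Stress-1 report (and the full eigenvalue spectrum
  in the diagnostics) is the honest record of that distortion.
* Non-ACGT symbols are deleted, not randomised — deterministic and exact
  for pixel semantics, but it shortens sequences with many ambiguity
  codes.
* No NCBI fetching: reproducing published mitochondrial distance values
  requires supplying the corresponding genome records as FASTA inputs.
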