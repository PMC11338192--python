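# Methods

## The zonation model

spotzone classifies spatial transcriptomics spots into ordinal
compartmental zones by their relative distance from the boundary
between two tissue classes — in the motivating application, liver
metastases ("tumor", indicator 1) embedded in hepatic parenchyma
(indicator 0). The method makes no use of expression for the zonation
itself: it is a purely geometric smoothing of a binary occupancy
lattice.

For each sample independently, spots are placed on a dense integer
lattice spanning the bounding box of their array coordinates. Occupied
cells carry the binary tissue indicator; everything else — off-tissue
positions and, on the hex-packed Visium array, the unoccupied
checkerboard positions (row + col odd) — is missing. Two moving
averages of the indicator are computed over square Chebyshev windows of
side `2*delta + 1` with `delta = 2` and `delta = 3` (two and three
layers of surrounding spots), and combined into a composite score:

    tumor score       s_T = 2 * MA_2(T) + 1 * MA_3(T),   masked to tumor spots
    parenchyma score  s_P = 2 * MA_2(P) + 0.1 * MA_3(P), masked to parenchyma spots

where `T` is the tumor indicator and `P = 1 - T`. Deep inside a tissue
both windows are pure, so the scores saturate at 3 (tumor) and 2.1
(parenchyma); near the boundary the window means fall off, so the score
is a monotone proxy for distance from the interface. Each side is then
cut into four ordinal bands by descending thresholds — `M1=2.96,
M2=2.7, M3=2.3` on the tumor side and `L1=2.095, L2=1.91, L3=1.7` on
the parenchyma side — implemented as half-open intervals `(lo, hi]`.
The eight bands are named `Zone_A` (inner tumor) through `Zone_H`
(distant parenchyma). With a 100 µm spot pitch the default cuts make
each intermediate zone about one spot layer (≈100 µm) thick; supplying
more cuts and names yields finer zonations (useful at Visium HD
resolution, where the same barcode encodes the bin's row and column).

### Numerical and design choices

- **Missing-aware means.** Window means ignore missing cells (a cell
  whose entire window is missing stays missing). On a hex lattice half
  of all positions are unoccupied, so counting them as zeros would
  halve every score; ignoring them makes homogeneous regions saturate
  exactly at the weight sum regardless of layout.
- **Edges.** By default the window is clipped at the lattice border and
  the mean is taken over the in-bounds cells, so a corner spot deep in
  tumor still scores 3. The alternative `edge_policy="missing"` blanks
  cells within `delta` of a border.
- **Interval semantics.** Thresholding uses `(lo, hi]` intervals,
  equivalent to applying the descending sequence of `> cut` tests; a
  property test verifies equivalence with literal sequential in-place
  overwriting on 1,000 random score grids.
- **Joins by key, never by order.** Zone labels are merged back onto
  the spot table by `(sample_id, barcode)`. An unmatched barcode is an
  error rather than a silently defaulted zone.
- **Coordinates are 0-based** with explicit grid offsets, so array
  coordinate 0 and translated lattices round-trip exactly (zonation is
  translation invariant; verified by test).
- **Per-sample independence.** Windows never cross sample borders.
- Degenerate inputs: a sample that is entirely one tissue is entirely
  `Zone_A` (or `Zone_H`); duplicate lattice coordinates and non-integer
  coordinates are errors naming the offending barcodes.

### A known geometric quirk

On an idealized straight boundary in a fully occupied lattice the
parenchyma score jumps from ≈1.67 (first parenchyma layer region) to
≈2.09 two layers out, skipping the `(1.7, 1.91]` interval: `Zone_F` is
unattainable on that exact geometry while `Zone_E` is two layers thick.
Real boundaries are curved and sampled on a hex lattice, which spreads
scores across all intervals. The default cuts are kept as published;
the eight-interval partition itself is exercised directly in the tests.

## QC and normalization

Before profiling, spots are filtered on the number of detected genes
(strictly greater than 500) and the percentage of mitochondrial counts
(strictly less than 20%, genes matched by the anchored prefix `mt-`);
an `inclusive` switch relaxes both to non-strict. Expression is
library-size log-normalized, `ln(1 + 10^4 * c / total)`. The upstream
protocol delegates this formula to its toolchain without writing it
out; the form used here is that toolchain's documented default, and all
downstream scoring operates on these log-normalized values.

## Zone profiling

- **Tissue labeling from signatures** (plumbing for datasets without
  curated cluster labels): a spot is called tumor when the mean
  log-normalized expression of a tumor marker set (e.g. *Epcam, Cdh1,
  Cldn7*) strictly exceeds that of a parenchyma set (*Alb, Fabp1,
  Apob, Car3*); ties go to parenchyma with a warning.
- **Module scores.** Genes are ranked by mean expression and split into
  `nbin = 24` equal-frequency bins (ties and the in-bin draw order
  resolve by gene name, making the score invariant to gene order in the
  matrix). For each signature gene, `nctrl = 100` control genes are
  drawn from its bin with an explicitly seeded generator, with
  replacement only when the bin is smaller than `nctrl`; the score is
  mean(signature) − mean(all drawn controls, multiplicity kept). This
  keeps the draw contract simple and exactly reproducible; the common
  implementation instead deduplicates the pooled control set, which
  changes scores by a small amount but not their centering (a property
  test confirms random in-bin signatures score zero in expectation).
- **Differential expression.** One-vs-rest two-sided Wilcoxon rank-sum
  per gene on `group_zone` labels (e.g. `parRes_Zone_B`). Midranks with
  the tie-corrected variance and a continuity correction are used for
  the normal approximation; when both sides have ≤ 8 spots and the gene
  has no ties, the exact null is enumerated. Note the approximation's
  intrinsic accuracy: against exact enumeration it agrees within 0.02
  for group sizes 5–8 but can deviate by up to ≈0.04 at sizes 3–4,
  a property of the discrete null, not of the implementation.
  Fold changes are `log2((mean(expm1(x)) + 1) / (mean(expm1(y)) + 1))`
  (pseudocount 1 on the de-logged means; fold-change conventions differ
  between published toolchain versions and this one is fixed and
  documented). `pct` columns are the percentage of spots with value
  > 0. p-values are Benjamini–Hochberg adjusted within each label.
- **Summaries.** Median fold change (`FC = 2^avg_log2FC`) per gene ×
  zone × group, and median module score per signature × zone × group,
  each with the per-name minimum attached — the protocol's plotting
  tables.

## The synthetic generator

`spotzone.simulate` emulates the study's data shape: a hex lattice on a
78 × 128 coordinate box (4,992 spots, matching a ~5,000-spot Visium
capture area) at 100 µm pitch with a contiguous tumor region
(half-plane, disk, multi-disk or grown random blob). Labels are region
membership, optionally corrupted by independent Bernoulli flips —
noise is placed at the label level rather than in expression so that
geometry tests stay exact. The signed Chebyshev lattice distance to the
region boundary is recorded as ground truth. Counts are negative
binomial (dispersion `theta = 2`, i.e. moderately overdispersed) with
lognormal library sizes (median 8,000, σ = 0.35), tumor/parenchyma
marker programs up 8-fold in their own tissue, mitochondrial genes
(`mt-` prefixed) pinned to a 5% share of every spot's rate, and
gradient genes whose mean rises 6-fold from tumor interior to distant
parenchyma. These levels are ordinary for fresh-frozen Visium liver
sections; all are spec parameters, and byte-level reproducibility from
(spec, seed) is tested.

What the generator does *not* emulate: spatial autocorrelation of
expression beyond the planted programs, segmentation errors correlated
along the boundary, platform artifacts (diffusion halos, permeabilization
gradients), or realistic gene–gene correlation. Passing tests therefore
demonstrate correctness of the lattice arithmetic, the threshold logic
and the statistical machinery under the stated model — not robustness
to every failure mode of real tissue sections.

## Problem sizes

Tests and the acceptance script run on lattices of 20×20 to 40×40 fully
occupied spots (the scale at which every expected value is known in
closed form) and on the default 4,992-spot hex lattice for generator
contracts; the full suite completes in well under a minute.
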