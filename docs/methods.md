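# Methods

`imcpheno` implements a complete desk-scale workflow for immune-focused
multiplexed imaging data (imaging mass cytometry, MIBI and similar
ion-counting platforms): per-channel artifact correction, label-mask
single-cell measurement, a two-stage semi-supervised phenotyper, comparison
statistics between a raw and an artifact-corrected dataset, and a
ground-truth simulator that renders multiplexed ROIs with all three artifact
classes planted and logged.

## Artifact correction

Each antibody channel is a 2-D grid of non-negative ion counts.  Three
corrections are applied per channel, always in the order spillover ->
denoise -> aggregate removal; each step can be switched off per channel and
per acquisition batch.

**Channel spillover.**  A contaminating "source" channel (isotopic impurity,
oxide formation) is turned into a binary mask: its counts are capped at
`cap_threshold` (suppressing the influence of very bright pixels on the mask
extent), blurred with an isotropic Gaussian whose standard deviation is
`gauss_radius` pixels (reflection boundaries), and binarized with a strict
greater-than comparison at `binarize_threshold`.  A fixed `removal_value` is
then subtracted, clamped at zero, from every target-channel pixel under the
mask.  The source channel is used *only* to build the mask; the target's own
counts are otherwise untouched.  Several sources may correct the same target
(corrections compose, and all masks are built from the uncorrected input
channels so channel order cannot matter).

Interpretation choices the operator definitions leave open, fixed here:
binarization maps ties to 0 (strict `>`); the Gaussian "radius" is the
kernel standard deviation in pixels; boundary handling is reflection.

**Denoising.**  Counts strictly below `floor_threshold` are zeroed
(an optional erosion variant applies a local-minimum filter over the window
before thresholding, for parity with the named library filter; default off).
The floored image is then smoothed with a uniform filter over a
`window_size x window_size` window and the floored counts are retained
wherever the local mean is positive; the smoothed image itself is never
emitted, so true counts are preserved and the step cannot amplify.  Note
that for a non-negative image every surviving pixel lies inside its own
window, so the support test is binding only where the floor has already
zeroed the pixel -- in practice the floor dominates, and the support test is
kept for contract fidelity (it is implemented with a maximum filter, which is
exactly equivalent to "window mean > 0" for non-negative input and avoids
float round-off).

**Aggregate (hot pixel) removal.**  The channel is blurred (`blur_radius`;
0 = exact), binarized (default: any positive value), and connected
components are labelled at 8- (default) or 4-connectivity.  Components with
fewer than `size_threshold` pixels are treated as antibody aggregates and
their *original* pixels set to zero; larger structures are untouched.
`size_threshold = 0` is a no-op.

Invariants: every operator preserves non-negativity; every operator except
the internal mask-construction blur is pixelwise non-increasing, and so is
the composite.

**Batch parameterization.**  Parameters resolve per (batch, channel):
channel override > batch override > defaults, so distinct staining batches
(e.g. clinical outcome groups) can carry distinct settings.

## Single-cell measurement

Segmentation is external; it enters as an integer label mask (0 =
background).  Per positive label the table records the arithmetic mean of
each channel over the label's pixels, the pixel-count area and the
unweighted (row, col) centroid, 0-based.  The mean (not the sum) is the
aggregation statistic.  Spatial neighbor pairs are defined by centroid
Euclidean distance below a threshold (mask-contact adjacency is out of
scope).

## Two-stage phenotyping

**Scaling.**  Raw per-cell means are variance-stabilized with
`asinh(x / cofactor)` (cofactor 5, the cytometry convention; a literal
arcsine on inputs clipped to [0, 1] is available behind a flag) and z-scored
per channel.  Channels that are constant to within float tolerance
standardize to zero rather than NaN.  For raw-vs-processed comparisons both
tables can be standardized with pooled channel statistics so their scaled
values share one scale.

**Ranking and dominant lineage.**  Each cell is summarized by its k
highest-scoring markers (k = 3 by default; individual rules may widen the
window, e.g. top-5 for mouse macrophages) and by the lineage marker with the
highest scaled value.  Ties break by panel order, making the whole stage
deterministic.

**Metacluster rules.**  A rule set is an *ordered* list of rules plus a
fallback label.  A rule matches when the cell's dominant lineage equals the
rule's lineage (or the rule accepts any), all scaled-threshold conditions
hold, no excluded marker appears in the top-k, and (if stated) at least one
required marker does.  First match wins; unmatched cells receive the
fallback by negative selection (hepatocytes in the human liver panel, "other
non-immune" in the mouse panel).  "Positive expression" means scaled value
strictly above 0; individual rules may raise that threshold (the plasma-cell
rule uses CD138 > 1 to separate plasma cells from CD138-bearing parenchyma).
Both default trees ship as editable JSON: the human tree defines 10 labels
from 10 lineage markers (7 flagged immune), the mouse tree defines 11 labels
from 16 lineage markers with 7 flagged immune (an NK-cell branch keyed to
CD161 completes the graphically-specified tree).  Exclusion sets are
deliberately conservative: the B-cell rule carries the full published
exclusion list, while T-cell and macrophage rules tolerate macrophage/T
co-occurrence in the top-3, reflecting the known lateral-spillover behavior
of irregularly shaped macrophages; in particular the macrophage rules carry
no exclusions at all, because in a heavily contaminated raw dataset
channel-level spillover can push an excluded marker into the top-3 of the
*entire* macrophage population at once.

**SOM subclustering.**  Within one metacluster (optionally pre-split by a
marker threshold, e.g. CD163 for M1/M2), a Kohonen map (default 10x10) is
trained online on the chosen functional markers: Euclidean best-matching
unit, Gaussian grid neighborhood, learning rate decaying linearly from 0.5
to 0.01 and neighborhood radius from max(grid)/2 to 0.2 over 10 epochs, the
codebook initialized from randomly drawn data rows.  The final neighborhood
radius matters: with a larger one, interpolating nodes park between
well-separated clusters and capture stray cells.  Node codebook vectors are
then merged agglomeratively (average linkage, Euclidean) into exactly
`n_clusters` consensus clusters (default 9), and each cell inherits its
node's cluster.  Everything downstream of the seed is deterministic.
Cluster annotation stays human-in-the-loop: a merge map sends cluster ids to
labels (ids sharing a label merge; the sentinel `exclude` flags cells
without dropping them), and labeled results are folded back into the master
table with integrity checks (no cell in two results, counts conserved).

## Comparison statistics

All statistics operate on annotated tables and define "positive" as scaled
expression > 0.  Per (phenotype, marker): positive-rate percent and its
relative change between datasets (conventional `100*(after-before)/before`
by default; an alternate form dividing the percentage-point difference by
the total raw cell count is selectable, since both conventions appear in the
source material and they disagree).  Specificity ratio: positive rate inside
a phenotype over the positive rate in its complement (+inf when the
complement rate is zero, NaN when undefined).  Median fold change:
processed-over-raw median expression per phenotype and marker.  Mixed
phenotype rate: percent of all cells whose top-k contains both markers of a
conflict pair with both positive (defaults: CD20+CD4, CD20+CD8, CD3+CD20 for
human).  Composition: per-phenotype percent of cells plus the median across
samples of per-sample proportions.

## Synthetic data

The simulator defines the package's study conditions.

**Rendered ROIs** (`simulate_roi`): cells are rasterized disks (radius 4-6
px) placed by rejection sampling with a one-pixel gap; each cell draws a
phenotype from the prevalence weights and emits, per channel, independent
Poisson counts around that phenotype's signature mean, plus a small constant
pedestal (0.5 counts) on every cell pixel.  The pedestal keeps each cell
body one fully 8-connected positive component in every channel, so
size-thresholding separates cells from aggregates exactly rather than
probabilistically; logged truth means include it.  Channel crosstalk adds
Poisson(alpha x source) to each target (ion-count thinning, computed from
pre-spill channels, independent across targets).  Background is sparse
low-intensity speckle off cells; aggregates are 1-6 px blobs of high
Poisson amplitude (default mean 60) placed with a one-pixel margin from
cells and from each other, every pixel logged.  The default human fixture
injects crosstalk from the dominant macrophage channel into the nine other
lineage channels, from the endothelial channel into both macrophage
channels, and from the two T-cell channels into CD20 -- reproducing both
inflated off-phenotype positive rates and mixed B/T top-marker phenotypes in
the uncorrected branch.  `recommended_settings` derives matched correction
parameters (removal value = coefficient x peak source mean; floor 1.5;
blur-0 aggregate removal sized just above the largest blob) from a
simulation config.

**Expression tables** (`simulate_expression_table`): per-cell marker values
are signature mean plus Gaussian noise with sd = `noise_sd * sqrt(mean)`,
clipped at zero -- heteroscedastic in the ion-counting sense, so
`noise_sd = 1` (the default) matches Poisson variance and a uniform sd does
not drown low-abundance channels.  A contamination fraction (default 5%)
of cells receives a second phenotype's lineage marker added at full
strength, the mixed-phenotype ground truth.

The default human signature matrix keys each of ten phenotypes to one of the
ten lineage markers (hepatocytes are baseline-everywhere, exercising the
negative-selection fallback); co-markers follow stylized liver immunology
(e.g. Kupffer-like CD11b-low macrophages).  What the generator does *not*
emulate: realistic tissue morphology, nucleus/membrane compartments,
segmentation errors, cell-contact lateral spillover, or marker correlations
beyond the phenotype means -- so passing tests demonstrate the correctness
and directional behavior of the algorithms under controlled artifact
injection, not performance on real tissue.

## Numerical and reproducibility choices

Strict `>` comparisons throughout (binarization, positivity, splits); ties
in ranking and argmax break by panel order; zero-variance channels scale to
0 with a relative float tolerance; undefined statistics return NaN and a
zero specificity denominator returns +inf rather than raising.  All
randomness flows from explicit integer seeds through `numpy` Generators;
the full pipeline is a pure function of (inputs, configuration, seed), and
its manifest records input hashes, parameters and package version so a
rerun reproduces byte-identical CSVs.

Problem sizes used by the test and acceptance suites: 3000-cell expression
tables and 224x224-px ROIs with 200 cells over the 22-marker human panel,
five replicate seeds per claim.

## Known limitations

The rule trees beyond the published B-cell example are conservative
completions and are meant to be edited per panel.  The phenotyper's accuracy
floor at default noise (~0.92) is dominated by the negative-selection
fallback absorbing baseline cells whose strongest lineage z-score flips
positive, plus deliberately mislabeled contaminated cells -- raising rule
thresholds trades this against sensitivity, which is a per-dataset decision.
The SOM is a minimal online implementation; it is deterministic and
recovers well-separated structure exactly, but no claim is made about parity
with any particular published SOM implementation's codebooks.  The `.mcd`
binary format is not parsed; inputs are single-channel TIFFs.
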