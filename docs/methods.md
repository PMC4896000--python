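# Methods

This note documents the models, parameters, and design choices behind
`cytopheno`: what each stage computes, why the defaults are what they are,
and what the synthetic benchmark does and does not establish about real data.

## 1. Per-cell masks and features

Each event is a four-channel image (brightfield, nuclear stain, TFEB, LAMP1)
of one cell. Pixel size defaults to 0.5 µm (a 40× imaging-cytometry objective
class) and is required to express areas in µm²; it is configurable everywhere.

**Masks.**

* *Default mask*: global Otsu threshold, 3×3 binary closing, largest
  connected component. Vendor "default masks" are proprietary; this
  deterministic, parameter-free stand-in is a contract of this package, not a
  claim of bit-equivalence with instrument software. For brightfield the
  channel is inverted first (cells are dark on a bright field).
* *Cell* = default mask of the TFEB channel OR the brightfield default mask
  eroded by 5 px (disk element).
* *Nucleus* = the 70% threshold mask of the nuclear stain, intersected with
  the cell. The threshold mask is the smallest set of brightest pixels whose
  summed intensity reaches 70% of the channel total, pixels admitted in
  descending intensity with all cutoff ties included. The
  fraction-of-maximum-intensity alternative was rejected: for peaked signals
  it selects almost nothing. The intersection with the cell mask is enforced
  so the mask algebra (nucleus ⊆ cell, cytoplasm = cell AND NOT nucleus)
  holds exactly.
* *Cytoplasm* = cell AND NOT nucleus.
* *Eroded ("underestimated") compartments* for the Mean Pixel Nuc/Cyto
  ratio: nucleus eroded by `erosion_px` (default 2, disk element) and
  cell-eroded AND NOT nucleus-dilated, so boundary pixels can contaminate
  neither compartment. The erosion depth is configurable; 2 px keeps a
  usable cytoplasmic rim at typical cell sizes while removing the mixed
  boundary band.

**Background** is estimated per channel as the mean intensity outside a
3-px dilation of the cell mask and subtracted per pixel with clipping at 0.
With the background forced to zero, compartment intensities are exactly
additive (the masks partition the cell and clipping acts per pixel).

**Features**: summed background-subtracted intensities and areas per
compartment; concentrations = intensity/area (0 for an empty compartment);
nuclear percentage = 100 × nuclear/cell intensity; Mean Pixel Nuc/Cyto =
mean background-subtracted TFEB pixel over the eroded nucleus divided by the
same over the eroded cytoplasm. If an eroded compartment is empty the ratio
is NaN and the event is flagged (`mpnc_degenerate`) — a ratio fabricated
from an empty compartment is meaningless, and flagged events are meant to be
excluded from clustering.

**Max Contour Position** (lysosomal radial position): the cell mask is
partitioned into `n_rings` (default 8) equal-width rings of the
boundary-distance transform, normalized to depth 0 at the boundary and 1 at
the deepest point. The reported value is 1 − (center depth of the ring with
the highest mean background-subtracted intensity): ≈ 0 for perinuclear
signal, ≈ 1 for peripheral signal. Ties resolve to the more central ring.
Eight rings balance radial resolution against per-ring pixel counts at
typical cell diameters (~30 px). A channel with no signal inside the mask
returns NaN and sets `mcp_undefined`.

**Gating** retains single, in-focus cells: brightfield-mask area within
[50, 400] µm², best-fit-ellipse aspect ratio (minor/major) ≥ 0.6 (touching
cell pairs form elongated masks), and a gradient-RMS focus floor given either
absolutely or as a batch percentile.

## 2. Density-normalized clustering

Clustering features are variance-stabilized with `asinh(x / cofactor)`,
cofactor 5 — the standard cytometry transform at this scale. Local density
of each event is the number of events (including itself) within radius
`density_approx_factor` (1.5) × the median nonzero nearest-neighbor distance
over a seeded subsample of ≤ 2000 events. Using the nearest *distinct*
neighbor makes the density estimate well behaved on data with exact
duplicates (duplicating every event exactly doubles every density).
`neighborhood_size` (5) is carried in the parameter set for parity with the
conventional parameter block but does not enter the density formula, which is
fully specified by the approximation factor.

Downsampling keeps event *i* with probability min(1, TD/density_i); the
target density TD is found by bisection so the expected retained count equals
`target_remaining` (20 000). If more than `max_pooled` (50 000) events are
pooled, a uniform pre-subsample is applied first. This inverse-density rule
thins dense majority phenotypes while preserving rare ones — on a 95:5
mixture at 50% retention the minority share of the retained set roughly
doubles.

K-means (k-means++ initialization, 10 restarts, best inertia, fixed seed)
runs on the retained events; every event — retained or not — is then assigned
to its nearest centroid in transformed space (ties to the lowest centroid
index). Nearest-centroid upsampling was chosen over nearest-retained-neighbor
as the simpler, refit-free rule consistent with reusing the model on new
data. With k = 3 clusters are labeled Inactive < Medium < Active by
ascending training mean of the ranking feature (default Mean Pixel
Nuc/Cyto); other k fall back to generic labels. A fitted model is persisted
as versioned JSON and applied to new conditions without refitting.

## 3. Model assessment and selection

The paper-style soundness criteria are stated qualitatively in the source
analysis; the quantifications here are this package's:

* **Criterion 1 (reproducibility)**: per cluster, the mean over
  (treatment, time) of the across-replicate SD (ddof = 1) of its fraction
  must not exceed 0.10. The threshold is generous relative to the shipped
  replicate jitter (which produces metrics ≈ 0.01–0.02) and is configurable.
* **Criterion 2 (non-redundancy)**: for each cluster pair, the Pearson
  correlation between replicate-averaged fraction time courses concatenated
  across treatments; a pair is redundant at r ≥ +0.9. Only positive
  co-movement counts: fractions are compositional, so complementary clusters
  are necessarily anticorrelated and a sign-blind rule would reject every
  valid model. Constant time courses leave the correlation undefined; such
  pairs are noted, not flagged.
* **Separation**: adjacent clusters (by ranking-feature mean) must differ in
  that feature — two-sided Wilcoxon rank-sum on seeded 1000-cell subsamples,
  p ≤ 0.001.
* **Unimodality**: each cluster's ranking-feature distribution (seeded
  1000-cell subsample) must be unimodal, assessed by counting modes of a
  Gaussian KDE whose peaks must exceed 5% relative prominence. This encodes
  the phenotype-assessment step — within-cluster feature distributions of a
  sound model are well behaved — and is what rejects *under*-clustering:
  with too few clusters two phenotypes merge into one visibly bimodal
  cluster, while criterion 2 rejects *over*-clustering (split halves of one
  phenotype co-move with r ≈ 1). Neither criterion 1 nor criterion 2 can
  reject under-clustering on reproducible data (with two clusters the pair
  correlation is exactly −1), so without this check the search would always
  prefer the smallest k.

Among passing candidates the selection is minimal: fewest features, then
smallest k, then lowest worst-cluster criterion-1 metric. If nothing passes,
the search returns the full report with no selection.

Inter-cluster statistics use the two-sided Wilcoxon rank-sum (normal
approximation with tie correction, no continuity correction — identical
samples give p = 1 exactly) for non-normal features such as the ratio and
Max Contour Position, and Student's two-tailed t-test for concentration-type
features, on seeded 1000-cell subsamples, with raw p-values by default
(Benjamini–Hochberg behind a flag). Time-point comparisons use replicate
means as the testing unit (n = replicate count); per-cell testing would
inflate significance and is deliberately not offered as the default.

**Decomposition check**: the predicted mean response
Σ_clusters fraction × cluster mean reproduces the direct event mean exactly
when cluster means are computed per condition (a weighted-mean identity that
holds for any labeling); with global cluster means the residual is reported
as a diagnostic bounded by the within-cluster drift of condition means. Both
modes are provided since either convention is defensible.

**Region annotation** segments each treatment's time axis at sign changes of
the replicate-averaged Active-fraction derivative (zero differences inherit
the previous trend). It is a reporting convenience with no effect on any
statistic.

## 4. The synthetic benchmark

The generator draws each cell's phenotype from treatment- and time-specific
mixture weights, then its features from phenotype-level distributions:
(ln ratio, concentration) bivariate normal, LAMP1 concentration and Max
Contour Position independent normals (MCP truncated to [0, 1]), nuclear/cell
area fraction normal (clipped to [0.1, 0.6]). Ratios are lognormal within a
phenotype because they are positive and right-skewed in cytometry data.

Defaults define the study conditions: 10 000 cells per (treatment, time,
replicate) — the acquisition target of the emulated protocol, with a "fast"
profile of 2000 matching its post-gating floor — 3 replicates, 7 time points
(0–15 h), and three treatments: a fresh-medium-like inactivation
(Inactive 45% → ~93% at 0.5 h, partial recovery to 21/76/3% by 15 h), an
mTOR-inhibitor-like activation (Active 9% → 57% at 1.5 h → 8% at 15 h), and
a nutrient-deprivation-like biphasic response (Active 9 → 45 → 15 → 35%:
activation wave, re-inactivation, second wave). Baseline composition is
45/46/9% Inactive/Medium/Active everywhere.

Phenotype-level numeric means are calibration choices (the emulated study
reports them only graphically): ratio modes 0.8/1.5/2.8 with log-SD 0.10 —
well separated on the arcsinh scale so the phenotypes are recoverable —
TFEB concentration means 85/100/130 (SD 20/25/35) with within-phenotype
correlation 0.4, chosen once via the closed-form mixture moments
(`pooled_moments`) so the pooled baseline correlation between log ratio and
concentration is ≈ 0.53; MCP means 0.72/0.65/0.52 (SD 0.20) give a pooled
MCP–log-ratio correlation of ≈ −0.25 (Active cells have the most perinuclear
lysosomes); Active LAMP1 concentration is 17% above the other phenotypes.
Replicate variability is logit-scale Gaussian jitter of the weight vector
(SD 0.05, zeros preserved, renormalized on the simplex) — a few-percentage-
point inter-replicate spread comparable to triplicate imaging-cytometry
experiments.

In image mode each cell renders as a dark brightfield ellipse on a bright
field, a nuclear disk, a two-level TFEB field realizing the sampled
nucleus/cytoplasm ratio over a constant background of 5, and 12 LAMP1 point
spots placed at the mask depth realizing the sampled MCP, plus optional
Gaussian pixel noise (SD 2). With zero noise, the mask chain recovers the
rendered geometry exactly (uniform disks tie at the 70% threshold cutoff, so
the whole nucleus is selected) and extracted ratios match the generating
values to well under 5%.

**What the benchmark does not show.** No optics are simulated (PSF, spectral
cross-talk, deconvolution), phenotypes are exactly lognormal/normal with
time-invariant shapes, cells are isolated ellipses (doublets appear only in
dedicated gating fixtures), and mixture weights change only through the
specified trajectories. Passing tests therefore demonstrates correctness of
the algorithms and recoverability under the stated generative structure —
not robustness to segmentation errors, staining variation, or phenotype
drift in real experiments.

## 5. Numerical and reproducibility choices

All randomness flows from explicit seeds: per-condition generator streams
are derived from the config seed via seed sequences; clustering, subsampling,
and statistical subsamples take seeds from their parameter blocks. The
`run-all` bundle and acceptance outputs contain no timestamps; manifests
record the config hash, seed, and SHA-256 of every file, making a rerun
byte-identical. Degenerate inputs are handled explicitly rather than by
exception where the event itself is at fault: empty cell masks are flagged
as gating failures, empty eroded compartments and signal-free MCP events are
flagged NaN, and all-identical point sets receive uniform density. Bisection
for the target density runs 80 iterations (ample for float64); nearest-
centroid and labeling ties have fixed, documented resolutions (lowest
centroid index; larger cluster first).

FCS I/O is a minimal FCS 3.1 list-mode implementation (little-endian float32,
one parameter per feature, condition metadata as keywords and as companion
delimited columns) written for this package; delimited tables are
tab-separated UTF-8 with "." decimals. Problem sizes in the shipped tests
follow the study conditions above; the full default pipeline (630 000 cells,
six candidate models) completes in well under a minute on one CPU.
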