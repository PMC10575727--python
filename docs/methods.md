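# Methods

This note documents the models, conventions and numerical choices
behind each analysis, what the synthetic generators do and do not
emulate, and the known limitations.

## Prominence-based cell counting

Counting treats a fluorescence channel as terrain: a regional maximum
is reported when its height exceeds, by strictly more than the
prominence parameter *h*, the level at which its superlevel-set
component merges with terrain containing a higher summit (for the
global summit of a connected region, the reference level is the
regional minimum, so a constant image has no countable maxima). This is
the h-maxima criterion and matches the "prominence" semantics of the
interactive Find Maxima tools common in microscopy practice.
Implementation: pixels are activated in descending intensity order
under a union–find; a component dying at a merge records its
prominence exactly. Equal-height summits whose connecting saddle lies
within *h* of the top collapse into one reported maximum, as they do
under morphological h-maxima reconstruction.

Each surviving summit plateau is reported as a single point: the
plateau pixel nearest the plateau centroid, with raster-order
tie-breaks. A raw centroid can fall off a non-convex plateau (and
outside a tissue mask), so a member pixel is used instead; for the
overwhelmingly common single-pixel maximum the two coincide.

Defaults: nuclei are counted at prominence 15 after the DAPI channel is
contrast-stretched to [0, 255] (0.1–99.9 percentile stretch — robust to
hot pixels; "histogram normalization" has no unique definition, this is
ours); secretory markers are counted on their native scales at
prominences 40 (p-EGFR) and 100 (chromogranin A). Counting is covariant
under common rescaling of image and prominence. The marker/nucleus
fraction may mathematically exceed 1 on pathological input; it is then
returned with a warning rather than clipped.

The tissue-marker pairing (p-EGFR ↔ tuft vs. chromogranin A ↔
enteroendocrine) is configuration, not code: both channels are counted
identically and labels are the caller's.

## Brush-border continuity (skeleton Feret caliper)

The brush-border channel is thresholded (Otsu on the masked pixels by
default; a fixed threshold can be supplied), binarized and reduced to a
1-px-wide 8-connected skeleton. Side branches shorter than 10 px
(measured as pixels along the branch, endpoint to the first junction)
are pruned iteratively until stable, and whole components shorter than
the minimum are discarded — both suppress background speckle. Each
remaining fragment is scored by its maximum Feret caliper, the largest
Euclidean distance between member pixel centres (computed on the convex
hull for large fragments; identical to all-pairs brute force). The
distribution of calipers — and especially its mean — is the continuity
metric: a continuous brush border yields few long fragments, a
fragmented one many short fragments. Whether analysis should be
restricted to an epithelial mask is left to the caller; no mask is
applied by default.

## Channel cross-correlation

Pearson correlation is computed over all pixels inside the tissue mask
(all pixels when no mask is given) for every channel pair; the matrix
is symmetric with unit diagonal and is invariant to affine rescaling of
any channel. A zero-variance channel has no defined correlation: its
off-diagonal entries are NaN with a warning, and clustering requires
those channels to be dropped explicitly. Hierarchical clustering uses
average linkage on the distance 1 − r (a common default for
correlation matrices; the linkage method is a parameter), returning the
dendrogram leaf order and merge tree.

## Short-circuit current analysis

ΔIsc is response minus the mean over a 60 s pre-event baseline. Two
response conventions are exposed: *plateau* (mean over the final third
of a 180 s response window) for sustained cAMP-driven secretion
(forskolin), and *peak* (maximum within the window) for transient
Ca²⁺-driven secretion (carbachol). These per-agonist defaults are a
declared convention — canonical secretagogue kinetics — not a published
protocol. ΔIsc is invariant to adding a constant to the whole trace.

Dose–response fitting uses the four-parameter logistic in log₁₀ dose
with floor and ceiling bounded to [0, 100] percent inhibition by
default (physical bounds, overrideable), initialized from the data
range and the geometric mid-dose. Fits are refused with fewer than four
distinct positive doses or a constant response; optimizer failure
returns a flagged, parameterless result. Combined forskolin+carbachol
stimulation is treated as a single event in cumulative-dose runs.
TEER is treated as externally measured metadata, not derived from
traces.

## Intracellular pH and NHE activity

The probe signal (a precomputed emission ratio or a single intensity
series — both are one scalar) is calibrated by least squares as an
affine map signal → pH from nigericin/K⁺ clamp segments at pH 6, 7, 8.
Three points cannot constrain a sigmoid, hence the affine model over
this range; clamp means must be strictly monotone in pH or calibration
fails. The valid signal range is the min–max of the clamp samples;
conversions outside it are returned but flagged as extrapolated.

NHE activity after Na⁺ re-addition: ΔpH is the mean pH over the final
10% of the recovery window minus the mean over the 30 s before
re-addition; the initial rate is the least-squares slope over the first
60 s of recovery (≥ 5 samples required). The window conventions are
declared here, not prescribed by any protocol. The inhibitor-corrected
ΔpH (test minus paired NHE-inhibitor condition) is floored at 0 with a
flag when negative. Note the fitted "initial rate" of an exponential
recovery is a secant slope over the rate window and thus a downward-
biased estimate of the instantaneous initial rate; it is intended for
between-condition comparison, not as a rate constant.

## Enteroid swelling

Objects are segmented per frame (integer input is taken as a label
mask; float images are Otsu-thresholded), hole-filled, and filtered by
minimum area (50 px²) and circularity 4πA/P² ≥ 0.6 (drops
lumen-collapsed or irregular debris; both configurable). Tracking is
greedy nearest-centroid with a 20 px displacement gate; an object
jumping farther ends its track. "Diameter" is the equivalent circular
diameter 2√(A/π) — robust for near-spherical enteroids — and the
swelling readout is d(t)/d(t₀), exactly 1 at t₀ by construction.
Percent inhibition is defined on the swelling increment (ratio − 1) so
that a non-swelling enteroid contributes zero, and is undefined when
the agonist arm does not swell. Both per-enteroid ratio distributions
and group summaries (median, IQR) are emitted.

## Rescue transcriptomics

The pipeline consumes standard DE tables (gene, log₂FC, FDR-adjusted
p, baseMean) produced by an established DE engine upstream; no DE model
is fitted here. The rescue filter keeps genes with adjusted p below the
cutoff (0.05 in both contrasts — the treatment-side cutoff is not
separately specified anywhere authoritative, so the baseline cutoff is
reused) and strictly opposite-signed fold changes; zero fold changes
and genes absent from either table are excluded (no imputation). A
third contrast (healthy+drug vs healthy) is carried and reported but is
not part of the predicate. Prioritization thresholds (|log₂FC| ≥ 1,
FDR < 0.05, baseMean ≥ 10, applied to the treatment contrast) are
package defaults with no externally fixed values, and ranking is by
descending |treatment log₂FC|, ties by ascending
treatment FDR then gene id. qPCR fold changes follow 2^−ΔΔCt with
per-sample housekeeping normalization (GAPDH by default), which makes
them invariant to any constant Cq shift within a sample.

## Synthetic generators

The generators exist so that every analysis can be tested against
planted truth without external data; their defaults *are* the modeled
disease and drug conditions.

* **Images**: isotropic Gaussian spots (nuclei/markers) with a minimum
  separation so planted counts are resolvable; ribbons as dilated line
  segments with recorded endpoint lengths; correlated channels as a
  standardized mixture hitting a target Pearson r in expectation;
  additive Gaussian noise clipped at zero (background-corrected
  intensities are non-negative). No PSF, no photobleaching, no
  autofluorescence — passing tests show metric correctness, not
  robustness to optics.
* **Isc traces**: sustained responses rise exponentially (τ ≈ 10–20 s)
  to their amplitude; transient responses follow an alpha function
  peaking at the amplitude. Dose runs rescale the stimulated component
  to the residual fraction given by the true 4PL (floor 0, ceiling
  80%, IC₅₀ 30 µM, slope 1) at each cumulative dose; trace noise is 5%
  of the stimulated amplitude. The SGLT1 protocol plants a
  phlorizin-sensitive component of 10 µA/cm² (control) vs 4 µA/cm²
  (disease) — the 60% deficit — over a 2 µA/cm² insensitive component.
  Baselines, taus and noise levels are chosen as physiologically
  reasonable, not reported values.
* **pH traces**: acidified Na⁺-free plateau (pH 6.6), exponential
  recovery of magnitude ΔpH (healthy 0.5, disease 0.05; inhibitor
  scales to 10%) at rate 0.02 s⁻¹, then three clamp segments; signal is
  an affine map of pH (slope 0.25 per unit) plus noise (sd 0.005
  ≈ 0.02 pH).
* **Swelling**: non-overlapping disks (radius 10–16 px, 20 objects in a
  512² frame) grown per timepoint by a diameter factor; defaults plant
  agonist growth 1.4 (healthy) / 1.3 (MVID) at 1 h and inhibitor arms
  at 40% / 50% reduction of the increment. The agonist-level growth is
  a package choice; the inhibition percentages are the modeled drug
  effects, and the percent-inhibition readout cancels the former.
  Default masks are noise-free (per-object growth jitter is exposed but
  off), so recovery tests measure discretization only.
* **DE tables**: 2,000 genes with 50 planted rescue genes (|log₂FC|
  ≈ N(2, 0.4) truncated at 1.2, opposite signs across contrasts,
  adjusted p log-uniform in [10⁻⁶, 10⁻²], baseMean ≥ 50); null genes
  draw adjusted p uniformly and independently per contrast, so they
  pass the filter at the nominal ~0.05² × P(opposite sign) rate. The
  tables are simulated directly — no read-level simulation, no
  correlation structure between genes.

Every generator is deterministic given its seed, and each dataset
round-trips through the package's writers/readers losslessly (images as
multi-page TIFF + channel sidecar, traces/tables as tab-delimited text,
truth as YAML).

## Verification strategy and problem sizes

Three bespoke computations are verified against independent brute-force
oracles implementing the same definition by a different route: maxima
prominences via explicit superlevel-set merge simulation over
descending levels, Feret calipers via pure-Python all-pairs distances,
and the rescue filter via a row-by-row predicate. The test suite checks
exact agreement on 100 random 64×64 grids, 100 random pixel
components, and 20 random 10⁴-gene tables. End-to-end recovery runs use
20 seeds for dose–response, SGLT1 and ΔpH targets and 3–5 seeds for
swelling (whose noise-free masks leave only placement randomness);
these sizes give stable medians while keeping the whole suite under a
minute of compute for the recovery tests.

## Limitations

* The prominence counter reports one point per summit; touching cells
  whose saddle lies within the prominence merge into one count, as in
  any h-maxima method.
* Skeleton spur pruning is heuristic for dense junction clusters;
  skeletons of very blobby regions are not meaningful continuity
  fragments regardless of pruning.
* Greedy nearest-centroid tracking has no motion model and will swap
  labels if objects approach within the gate between frames.
* The affine pH calibration is only as good as the 6–8 clamp range;
  probes are sigmoidal far from their pKa, and extrapolated values are
  flagged for that reason.
* All recovery results quantify performance on the generator's
  idealized data; they bound, but do not establish, performance on real
  microscopy or electrophysiology.
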