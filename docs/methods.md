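# Methods

`sisterres` quantifies how far the two sister chromatids of a replicated
chromosome have separated into distinct territories, from two kinds of
data: fluorescence image stacks in which exactly one sister per chromosome
carries a nucleotide-analogue label, and sister-phased Hi-C contact tables
in which each intra-chromosomal contact is classed *cis* (within one
chromatid) or *trans* (between the sisters). This note describes the
models, the tunable parameters, and the choices made where the design was
genuinely open.

## Image-based separation score

Per cell, the central z-slice is the intensity-weighted center of mass of
the DNA (Hoechst) channel; an 11-slice window (5 above, 5 below, clipped
at stack boundaries) is analysed. Each slice's DNA channel is segmented by
Otsu thresholding; border-touching components are removed (cells whose
chromatin touches the image border are re-scored in a second pass with
border clearing off, recorded per cell), and components below
`min_object_size` are discarded. Within the mask, the Spearman rank
correlation (average ranks on ties) between the DNA stain and the
single-sister label gives one coefficient per slice; the per-cell
statistic is the mean over valid slices. Slices with fewer than 3 mask
pixels or zero variance in either channel are skipped, not scored zero —
a correlation is undefined there.

Per-cell means are mapped to the separation score by the affine
normalization anchored on two reference conditions: cells with **both**
sisters labelled (label ∝ DNA, maximal correlation — score 0) and
prometaphase cells with **one** sister labelled and sisters separated
(score 1). Scores of other conditions may legitimately fall outside
[0, 1].

Parameters: `min_object_size` defaults to 1,000 px, appropriate for
~50 nm super-resolution pixels on whole cells; analyses of the small
synthetic fields in this package's tests use 64 px. The window half-width
(5) and the threshold method are configurable.

## Line-profile analysis

Profiles are drawn perpendicular to an SMC (cohesin/condensin) axis,
always oriented from the labelled chromatid to the unlabelled one, 5
pixels wide, and sampled in three channels (axis protein, label, DNA).
Each channel is min/max-normalized. Because only one sister is labelled,
the unlabelled sister's profile is estimated by the subtraction rule:
where normalized label exceeds normalized DNA the label is subtracted,
elsewhere the DNA value is kept, and the result is renormalized. Each
channel is then smoothed by a least-squares polynomial (degree 10, capped
at ⌊n/3⌋ — higher degrees resolve the labelled-sister remnant into a
spurious second peak and reject valid profiles) and peaks are taken as
local maxima of the fitted curve on a 10× dense grid with prominence
≥ 0.1 and height ≥ 0.2 on the [0, 1] scale. Profiles are accepted only
with peak counts (axis, label, DNA−label) of (1, 1, 1) for single axes or
(2, 1, 1) for split axes; rejected profiles are reported with the reason,
never dropped.

Measurements: the sister peak-to-peak distance |pos(DNA−label peak) −
pos(label peak)|; and the signed radial displacement pos(nearest axis
peak) − pos(label peak), positive when the label peak lies outward (on
the labelled-chromatid side) of its nearest axis. An exact tie between
two split axes is broken toward the lower-position axis and flagged.
Mean curves are built by re-centering each profile on its axis anchor
(the single axis peak, or the midpoint of the two) and averaging on a
common grid with the median native spacing.

Per-cell summaries aggregate manually measured lengths: % split axis =
100·split/(split+single) per cell, and the 0/1/2-sister-labelled fragment
percentages, which sum to 100 per cell by construction.

## Image phantoms

The generator renders a replicated chromosome as two parallel tubes with
Gaussian cross-section (`tube_sigma`, default 200 nm — FWHM ≈ 0.47 µm,
the width of a mitotic chromatid) following a cubic-spline centerline,
displaced ±`separation_d`/2 along the in-plane normal. Deposited path
mass is arclength-weighted so curvature does not bias sister brightness.
The DNA channel sums both tubes; the label channel holds one or both; the
SMC channel is a thinner ridge (80 nm) at the midline or at both tube
centers. An anisotropic Gaussian PSF (σ 90 nm laterally, 250 nm axially,
approximating processed super-resolution confocal data) is applied to the
noiseless expectation; Poisson shot noise and additive Gaussian read
noise (sd 10 counts) come last. Voxels default to 50×50×150 nm (x, y, z),
fields to 72×72×13.

One deliberate piece of assay physics: the DNA stain is partially
quenched on analogue-substituted DNA (the basis of classic "harlequin"
differential chromatid staining), so labelled sisters are rendered dimmer
in the DNA channel by `label_quench` (default 0.5). This asymmetry is
what lets the subtraction rule isolate the unlabelled sister; on a
perfectly symmetric noiseless phantom the rule would retain the labelled
peak's far flank and the peak-to-peak distance would be biased low. With
both sisters labelled the quench is a uniform gain, so the two-sister
control keeps label exactly proportional to DNA.

What the phantoms do not emulate: whole-cell chromatin (one chromosome
per field, so absolute SCC values are not comparable to whole-cell data —
only the normalized score is), replication-timing structure along the
chromosome, optical aberrations beyond a Gaussian PSF, and chromatic
shift. Passing tests therefore validate the estimators' geometry and
statistics, not instrument-specific behaviour.

Populations randomize centerline orientation (uniform in-plane rotation)
and per-channel amplitude (±10 % by default) from per-cell sub-streams of
one seed; everything is reproducible bit-for-bit given the seed.

## Genomic resolution score

For a phased contact table, contacts at distance > 1 kb are binned into
log-spaced distance bins (factor 2^(1/3), i.e. three bins per octave,
from 1 kb), pooled genome-wide. Bin counts are divided by bin span (bp)
and by the **combined** cis+trans qualifying total, so the cis/trans
ratio of a bin equals its count ratio — per-phase normalization would
distort the ratio by the global phase imbalance. When several samples are
compared they are first downsampled without replacement to the smallest
qualifying total, deterministically per seed.

The ratio is interpolated with a cubic spline against log10 distance on
a 500-point grid, smoothed with a Savitzky–Golay filter (window 5, order
2 — declared defaults; the underlying study does not print its values),
and scanned from short to long range for the first point at or below the
threshold (default 1.25, slightly above noise); the crossing is linearly
interpolated between grid points. Curves already at/below threshold at
short range report `never_above_threshold` (resolution 0); curves that
never descend report `never_crossed`.

## Contact simulator

Contacts are drawn with genomic distance s from a power-law density
∝ s^(−α) (α = 1.0, the canonical interphase Hi-C decay) on [1 kb,
100 Mb] via inverse-CDF sampling, placed uniformly along chromosomes
(three chromosomes of 200/150/100 Mb by default), and phased cis with
probability R(s)/(1+R(s)) for the exponential ratio model
R(s) = 1 + (R0 − 1)·e^(−s/λ) (defaults R0 = 2, λ = 5 Mb). This form is a
convenient monotone stand-in for empirical ratio curves and gives the
closed-form crossover s* = λ·ln((R0 − 1)/(t − 1)) used as the recovery
oracle; the default model puts s* at 5·ln 4 ≈ 6.93 Mb for t = 1.25.
Distance, chromosome and phase draws use independent sub-streams of one
seed.

## Numerical choices and problem sizes

Validation uses populations of 8 phantom cells per condition and
simulated tables of 10^6 contacts (20 seeds for the recovery study) —
sizes at which the binomial error of a ratio bin near the crossover is
well under the ~4 % discretization error of the binning + spline + filter
chain. The Spearman implementation is checked against an explicit
rank-then-Pearson construction to 10^−12 on random masks up to 100
pixels. Degenerate inputs (constant channels, empty masks, empty bins,
curves that never cross) are reported as explicit statuses or rejection
reasons rather than numbers.

## Known limitations

- The separation score's absolute SCC scale depends on mask content;
  only the anchored score is comparable across conditions.
- The peak-to-peak estimator carries a small inward bias (a few tens of
  nm at 500 nm separation with these widths) from the unquenched residue
  of the labelled sister; it stays within one 50 nm sampling step across
  the validated range.
- The resolution score depends mildly on the declared bin/spline/filter
  settings; they are config, echoed beside every result.
- Watershed seeding uses distance-transform maxima with a minimum
  separation; deeply overlapping nuclei may still merge.
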