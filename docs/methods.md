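# Methods

This note documents the models behind `bypassflow`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that affect results.

## Channel model and coordinates

The culture channel is a straight lumen of radius 1.25 mm (the cover
semicircle plus the semicircular channel moulded into a 1 mm collagen
layer is treated as one circular lumen).  The axial coordinate has its
origin directly below the branch/cover intersection and runs positive
toward the right Luer.  The 50 mm main channel is split 29.45 mm
(left-Luer side) / 20.55 mm (right); the source drawings are ambiguous
about which side carries which length, so both are plain config fields.

Velocity conversion is `v = Q / (π r²)`; with the pump settings this
gives 5.09 cm/s (15 mL/min) and 0.170 cm/s (0.5 mL/min).  The Reynolds
number uses ρ = 1020 kg/m³ and μ = 3.5 mPa·s (medium thickened with
xanthan gum) with the lumen diameter as characteristic length:
Re = ρvD/μ ≈ 37 at peak velocity.  CFD post-processing of the same
device has been reported with Re ≈ 39; the characteristic scales behind
that value are not stated, so this package reports the formula value
and notes the discrepancy rather than matching it.

Four 2-mm half-open sampling windows define the regimes: DS = [−2, 0)
and HS = [0, 2) mm flank the origin.  ST starts 15 mm from the left
Luer ([−14.45, −12.45) mm).  The literal placement "30 mm to the right
Luer" for PF is geometrically infeasible on a 20.55 mm right limb
(it lands left of the origin), so PF is placed 10 mm downstream of the
origin ([10, 12) mm), centred in the physiological-flow zone; both
offsets are config values, and `default_windows` raises when a window
does not fit the channel.

## Synthetic WSS fields

Each regime is a biased axial sinusoid plus an independent transverse
sinusoid in the node's tangent frame:

    τ_axial(t) = A (b + sin 2πt/T),   τ_transverse(t) = C sin 2πt/T.

Closed forms: with m(b) = (2/π)(b·asin b + √(1−b²)) for b ≤ 1 (m = b
beyond), the transverse-free TAWSS is A·m(b), OSI is ½(1 − b/m(b)), and
TransWSS is exactly 2C/π for any A, b.  Calibration solves b from the
OSI map by Brent root-finding, sets A = TAWSS/m(b) and C = π·TransWSS/2,
then polishes (A, b) by bounded least squares against 2048-step
quadrature when the transverse term perturbs TAWSS/OSI.  An OSI target
of 0 is emitted as an effectively constant waveform (bias 10⁶).
Infeasible triples (TransWSS > TAWSS, OSI ≥ 0.5, a transverse component
with OSI 0) raise a calibration error.

Default per-regime targets (dyne/cm²) are the region means of the wall
statistics this generator emulates: ST (1.5e-6, OSI 0.42), DS (0.11,
0.20), HS (0.35, 0.08), PF (0.32, 0.06).  Published tables for such
channels sometimes print TransWSS values that are negative or exceed
TAWSS, which is impossible under its definition (the integrand is an
absolute value and a projection bounds it by TAWSS); the defaults here
are therefore chosen consistent with the definition while preserving
the qualitative ordering — HS 0.10, DS 0.04, PF 0.02, ST 0.  The same
tables can print Log(RRT) rows inconsistent with the pointwise identity
RRT = 1/((1−2·OSI)·TAWSS_Pa); this package computes the identity.

Fields are blended across window edges by a cosine ramp over ±0.2 mm,
so adjacent DS/HS waveforms cross-fade instead of jumping.  Node-to-node
heterogeneity is a multiplicative jitter of 2% (1σ) on each regime's
amplitude — wall fields from a smooth solver vary gently at this scale.
Jitter is the only randomness; the core waveforms are deterministic.

What the generator does not emulate: velocity fields, recirculation
eddies, flow separation/reattachment, wall compliance.  It matches wall
metric statistics only, which is exactly what the downstream metric and
classification code consumes.

## Metrics and classification

Cycle integrals use the trapezoidal rule with periodic closure; on the
uniform grid this equals the sample mean, and for the smooth waveform
family it converges spectrally (halving the step changes metrics well
below 0.1%).  RRT converts TAWSS to Pa (×0.1) first; denominators below
10⁻¹² Pa are capped at 10¹² 1/Pa and flagged.  TransWSS needs a defined
cycle-mean direction; when |∫τ dt| < 10⁻⁹·max(1, ∫|τ| dt) the node
reports 0 with a "mean direction undefined" flag instead of picking an
arbitrary axis.

Regime classification is a decision list with config-driven thresholds:
ST if TAWSS < 0.01 dyne/cm²; DS if OSI > 0.15 and TAWSS below the field
median; HS if TAWSS ≥ the field's 75th percentile and TransWSS ≥ 0.05
dyne/cm²; else PF.  The transverse condition is what separates HS from
PF when their TAWSS distributions overlap.  On the default synthetic
field (2048 nodes) the list recovers ~97% of generator labels; the
residual errors sit in the DS/HS cosine-ramp transition where blended
waveforms are genuinely intermediate.

## Synthetic monolayers

Cells are regions of an anisotropic Voronoi tessellation: seed points
from anisotropic Poisson-disk dart throwing, each carrying its own
orientation and axis ratio; pixels join the seed of smallest Mahalanobis
distance in the seed's own ellipse metric.  This matches the Voronoi
assumption of the segmentation chain and makes the ground truth exact —
per-cell ellipse statistics are measured from the label map itself, so
"truth" is the realized tessellation, not the sampled parameters.

Per-regime presets (orientation spread as folded-normal σ matched to a
target median alignment; log-normal axis ratio matched to target median
and IQR): PF median alignment 7.43°, ratio 2.46; DS uniform orientations
(median 45° by symmetry), ratio 1.50; HS 23.93°, 1.66; ST 22.36°, 2.27.
Uniform orientations are drawn by stratified sampling (one draw per
stratum of [−90°, 90°), shuffled), so the realized population median
tracks 45° closely even at n = 500 — the presets are calibration
targets, and the generator is built to hit them rather than to add
sampling noise on top.  The eccentricity/ratio pairs are mutually
consistent through e = √(1 − 1/r²).

Rendering: VE-cadherin ridges on tessellation edges — continuous for AJ
edges, dashed (2.5 µm dashes, 1.0 µm gaps) for FAJ edges; F-actin as
parallel bands offset ±1 µm for AJ and perpendicular 2–4 µm stubs every
1.2 µm crossing FAJ edges; elliptical nuclei scaled 0.35× from each
cell's ellipse.  Junction classes are assigned by randomized
length-stratified selection so the realized FAJ length fraction matches
the requested `faj_fraction` to within about one segment length.  Noise
is Poisson (gain snr²) plus Gaussian read noise (σ = 0.3/snr); default
peak SNR 8, typical of confocal practice.  Default pixel size 0.3 µm/px
(≈40× confocal) and a default cell area of 1200 µm²; neither is reported
for the source data, so both are declared, not inferred.  At pixel sizes
much coarser than ~0.4 µm/px the 1 µm AJ F-actin offset is no longer
resolvable and junction classification degrades by construction.

Not emulated: PSF/optical sectioning, 3D stacks, vWF biology, free-form
(non-tessellation) cell shapes, real staining variability.  Passing
tests on these images therefore demonstrate that the analysis chain
recovers known structure at realistic contrast and noise — not that it
handles every artifact of real microscopy.

## Morphometry

Nuclei: gaussian-mean local threshold (51 px window, offset 0.15 of the
robust max), hole filling, a lower size filter at 30 µm², then watershed
on the smoothed distance transform (σ = 2 px) with h-maxima seed
suppression (h = 0.6 µm).  Smoothing the distance map is what prevents
boundary noise from seeding spurious splits in elongated nuclei.
Cells: watershed from nuclei seeds on a cost image combining normalized
VE-cadherin intensity with a small (0.05) normalized seed-distance term;
with a flat channel this degenerates to the geometric Voronoi partition.

Shape uses the second-central-moment ellipse; orientation is reported in
degrees CCW from the image x-axis (the flow axis) in [−90, 90), and
alignment is the acute axis-to-flow angle in [0, 90].  The profile
extractor emits ~150 features per cell in a fixed, documented order
(`profile_feature_names`): 12 intensity statistics, 12 co-occurrence
texture statistics (6 properties × 2 offsets, 16 grey levels within the
cell mask), 14 moment invariants (7 normalized central + 7 Hu), 4 radial
ring fractions, 3 colocalization statistics per channel pair (Pearson
within mask, two Manders fractions), and a 10-feature shape block — per
channel where applicable.  Border-touching cells are excluded by
default.  Feature counts in published high-content pipelines vary with
software version; the schema here is fixed and versioned by the package
instead.

## Profiling

Z-score normalization drops constant columns with a report.  Factor
analysis is principal-axis factoring: SMC-initialized communalities
iterated on the reduced correlation matrix; the factor count is the
smallest k whose leading correlation-matrix eigenvalues sum to the
variance target (default 80%), the convention most statistical packages
print as "% of total variance".  No rotation is applied by default, so
recovery of a planted structure is only expected when factor strengths
are distinguishable (near-degenerate eigenvalues leave the factor basis
rotationally indeterminate — the recovery tests plant distinct block
strengths for exactly this reason).  Scores are Thurstone regression
scores.

LDA uses the SVD solver (no singularity issues with fewer factors than
cells); reported accuracy, confusion and per-class recall come from
stratified 5-fold cross-validated predictions, not the training fit.
Biplot attribution follows the score-plot convention: for each class
pair, factors are ranked by |cos| between their coefficient vector and
the centroid-difference direction in the plotted discriminant plane.
Note the ranking is by direction only; a factor with negligible
coefficient magnitude can still rank high if its direction happens to
align, so magnitudes should be read off the biplot alongside the rank.

## Junction analysis

Tracing: gaussian smoothing, Li threshold, morphological closing with a
0.6 µm radius (bridges FAJ dashes without distorting the ridge), 
skeletonization, branch-point removal, and path-ordering of each
branch-free component; segments shorter than 2 µm are dropped.
Classification per segment: the local F-actin orientation is the
intensity-weighted structure-tensor orientation in a 2 µm band around
the segment; the overlap fraction is the fraction of segment pixels
within 1 px of F-actin thresholded at 0.45 of its robust maximum
(a Manders-style overlap on the segment).  FAJ requires ≥ 60° to the
tangent and overlap ≥ 0.5; AJ requires ≤ 30° and overlap < 0.5;
everything else — including segments with no F-actin in the band — is
left unclassified and excluded from the ratio.  The angle and overlap
thresholds encode qualitative parallel/perpendicular/overlap definitions
and are all exposed in config.

The FAJ ratio is Σ length(FAJ) / Σ length(AJ ∪ FAJ).  Whether such a
ratio should be pooled per location or averaged per cell is ambiguous in
practice, so both modes exist (`per_cell=` with a cell label map);
pooled is the default.

## Problem sizes and determinism

Default analysis sizes — 2048 wall nodes × 200 time steps, 100-cell
monolayers at 0.3 µm/px, n = 500 truth-only populations, 800-sample
factor recovery — were chosen so the full test suite and the acceptance
script each complete in minutes on a single core while keeping every
statistical check well-powered.  All randomness flows through explicit
integer seeds (`numpy.random.default_rng`); a run is reproducible from
its emitted YAML config alone, and the same seed yields bit-identical
fields and images.

## Known limitations

- The pump's actual inlet waveform (a tooth-like pattern) is not
  tabulated anywhere usable; the sinusoid family is a declared stand-in
  matched on cycle statistics, not on waveform shape.
- Wall-metric tables derived from full 3D CFD are not reproducible here
  by construction (no Navier–Stokes solver is included, deliberately);
  only the generator's calibrated statistics are.
- Real-image morphology medians serve as generator calibration targets;
  nothing here validates the analysis chain against wet-lab images.
- The regime classifier's HS rule depends on a TransWSS threshold; on
  fields whose HS zone lacks a transverse component it will merge HS
  into PF.
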