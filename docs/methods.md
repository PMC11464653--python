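# Methods

This note documents the models, conventions and numerical choices behind
cralekit, in the order the analysis runs.

## CT densitometry

**Gas/tissue decomposition.** A voxel's attenuation maps linearly between
pure gas (−1000 HU) and water-density tissue (0 HU): gas fraction
`−HU/1000` (HU clipped to [−1000, 0]) and tissue fraction `1 + HU/1000`
(HU clipped to [−1000, +100]).  Tissue fraction is capped at 1.0, i.e.
voxels denser than water (0 < HU ≤ 100, e.g. partial-volume blood) count
as pure tissue of density 1 g/mL; this keeps the conservation identity
gas + tissue = 1 exact for every in-range voxel, so lung volume always
equals gas volume plus tissue mass at unit density.  Lung weight in grams
is tissue volume × 1 g/mL.

**Aeration compartments.** The four printed integer ranges
(hyper −1000..−901, normal −900..−501, poor −500..−101, non −100..+100)
leave sub-integer values undefined; internally the bins are half-open
with boundaries at the midpoints (−900.5, −500.5, −100.5), which
preserves every integer's printed class and gives float values (possible
after noise) a deterministic home.  Values outside [−1000, +100] inside
the mask are excluded from the compartment fractions but clipped into the
gas/weight sums, with the count reported — segmentation is supposed to
exclude vessels and effusion, and clipping is the honest fallback when it
does not.

**Mean density.** Computed as per-slice mean HU weighted by in-mask slice
area.  With uniform voxel dimensions this is identical to the plain voxel
mean; the implementation asserts that equivalence on every call.

**Gravitational bands.** Within each cranio-caudal slice, the in-mask
ventro-dorsal extent is split into three equal-height bands (ventral,
ventro-dorsal, dorsal) using fractional boundaries
(`band = floor(3·(row−lo)/extent)`), so no remainder rows exist and the
bands partition the mask exactly.  Bands are per-slice rather than
defined on a whole-thorax box: each slice's own dorso-ventral span is
what gravity acts across in a supine subject.  The ventro-dorsal axis is
the second array axis by convention, index increasing toward dorsal
(dorsal = dependent in dorsal recumbency), re-declarable per volume.
The gradient is `(ventral − dorsal)/ventral × 100` on signed HU, so a
denser dorsal region under a negative ventral mean yields a positive
percentage.

**Ten-slice protocol.** The most cranial and caudal slices containing
mask plus eight evenly spaced slices between them are selected; ideal
real-valued positions map to the nearest unused integer index with ties
resolved toward the cranial end (this single rule implements
round-half-cranial and deterministically re-spreads collisions).  Each
slice is analysed with the standard densitometry, converted to linear
densities (mL gas/mm, g/mm, mm² area), linearly interpolated along the
cranio-caudal axis with constant extension over the outer half-slices,
and integrated by the trapezoid rule over the full mask span.  The
estimate is exact whenever per-slice quantities vary linearly between
samples; on smooth ellipsoidal phantoms it stays within ~1.3% of the
full-volume computation.  A regression-based extrapolation variant is
not implemented; whole-volume analysis is the default and the ten-slice
mode is opt-in.

**CRALE criterion.** Mean lung density ≥ −500 HU, inclusive.

## Respiratory mechanics

**Model context.** The trace generator drives a two-compartment linear
system: `Pes = V/Ccw + compressions`, `Paw = R·V̇ + V/CL + Pes + PEEP`,
with a triangular volume-controlled breath (VT 500 mL, 10/min, I:E 1:1,
ZEEP during CPR) and a raised-cosine compression pulse train (102/min,
duty cycle 0.50 — the rate and duty of a piston compression device).
Compression amplitude is parameterised directly in cmH2O of esophageal
pressure because no validated depth→pressure transfer exists; ventilation
and compressions run on independent phases (unsynchronized).  Occlusions
(≥ 5 s) freeze volume and zero flow.

**Cycle detection.** Pes is band-passed 0.5–5 Hz (zero-phase 2nd-order
Butterworth), separating ~1.7 Hz compressions from ~0.17 Hz ventilation;
peaks require a prominence of 25% of the filtered signal's IQR, floored
at 1 cmH2O.  The floor matches the occlusion-test noise floor and rejects
the small band-pass residue of the ventilation waveform: a "compression"
that moves Pes by less than 1 cmH2O is not a compression.  Detected rates
outside 50–150/min set a warning flag.

**ΔPes.** Per cycle (midpoint-to-midpoint windows around each peak) the
Pes minimum, maximum and swing are computed; the reported epoch value is
the mean of per-cycle swings (the aggregation behind one-value-per-epoch
plots; mean rather than median, recorded in the output).  Extremes are
taken after local-quadratic Savitzky–Golay smoothing over 0.13 s: raw
min/max of a noisy signal are biased outward, while a second-order fit
preserves the curved pulse peak.  The window length balances residual
noise-extremum bias against peak attenuation and was calibrated on the
waveform simulator at its default conditions (amplitude ~15 cmH2O, noise
SD 0.2 cmH2O), leaving a relative bias below 0.5% — an order of magnitude
under the 3% recovery tolerance.  `smooth_s=0` gives raw extremes, exact
on noiseless signals.

**Plateaus and partitioning.** Occlusion windows must last ≥ 5 s.  The
signal is smoothed over 0.25 s, its slope estimated over the same span,
and the plateau is the mean of the final 0.5 s of the longest stable
suffix (|dP/dt| < 0.5 cmH2O/s); slope estimates within two smoothing
widths of the window end are edge-dominated and excluded from the
stability scan (the tail mean covers them).  From an
inspiratory/expiratory plateau pair: ΔPrs = Pplat − PEEPtot,
ΔPcw = Pes_insp − Pes_exp, ΔPL = ΔPrs − ΔPcw, and compliances VT/ΔP.
Because ΔPL is defined by subtraction, ΔPrs = ΔPL + ΔPcw and
1/Crs = 1/CL + 1/Ccw hold identically; non-positive driving pressures
raise an error naming the offending partition.

**Occlusion test.** ΔPes/ΔPaw over an occluded-compression window must
lie in [0.8, 1.2] as printed (the source text's "10–20%" phrasing is
internally inconsistent with its own numeric interval; the numbers win).
ΔPaw below 1 cmH2O means no compression was delivered and is an error.

**Coronary perfusion pressure.** Per compression cycle, the diastolic
instant is the aortic-pressure minimum within the cycle (the
decompression trough); CPP subtracts the right-atrial pressure at the
same sample.  Airway/esophageal pressures are cmH2O, vascular pressures
mmHg, with converters provided.

## Oxygen transport

Contents use `C = k1·Hb·SO2 + k2·PO2` with k1 = 1.34 mL/g and
k2 = 0.003 mL/dL/mmHg; end-capillary content assumes equilibration with
alveolar gas, `PAO2 = FiO2·(Pb − PH2O) − PaCO2/RQ` (Pb 760, PH2O 47,
RQ 0.8) at capillary saturation 1.0.  All constants are configurable and
embedded in every output record, since different laboratories use
slightly different values.  DO2 = CO·CaO2·10 and VO2 = CO·(CaO2−CvO2)·10
(CO in L/min, contents mL/dL).  Shunt values pushed outside [0, 1] by
measurement noise are clipped and flagged rather than rejected.  Hb is
handled in g/dL (porcine-physiologic 7–9 g/dL; a g/L label on such values
is treated as a units typo by the reader, flagged explicitly).

The blood-gas generator solves the admixture equation
`CaO2 = s·CvO2 + (1−s)·CcO2` jointly with the Fick relation
`CvO2 = CaO2 − VO2/(10·CO)` in closed form
(`CaO2 = CcO2 − s·v/(1−s)`), then emits saturation/tension pairs that
reproduce the exact contents, so zero-noise panels invert to the true
shunt to machine precision.  A total shunt (s = 1) forces CaO2 = CvO2
and cannot sustain positive VO2; the generator rejects that combination
and handles s = 1 with VO2 = 0 as the degenerate limit (the Berggren
ratio is then 0/0 and the constructed value is reported directly).
Infeasible VO2 (CvO2 ≤ 0) is an error.

## Stereology

The grid is a regular √n × √n lattice, centered with half-pitch margins
(100 points by default); a uniformly translated random-offset mode exists
for formally unbiased sampling, but the fixed grid mirrors the
software-overlaid grid of routine practice.  Hemorrhage is a class of its
own and by default not part of "overall tissue" when computing the
alveolar-tissue percentage (overall tissue − non-acinar points, over
total points); a toggle includes it.  Point counts of a class with true
area fraction f have binomial standard error √(f(1−f)/n), which the
acceptance checks use as the reference band.  Random non-overlapping
fields of view can be sampled with a seeded generator.

## Synthetic data: what it emulates, and what it does not

The CT phantom is two ellipsoidal lungs in an air background with a
soft-tissue rim (+40 HU) so masked analysis is exercised against
realistic out-of-mask values.  The in-mask field is
`base_mean + edema_shift + slope·(depth − depth_mean)`: centring the
gradient on the mask's mean depth makes the in-mask mean equal
`base_mean + edema_shift` exactly, so density regimes are dialled in
directly (defaults: −549 HU baseline-like mean, 150 HU/depth gradient;
an edema shift of ~225 HU reproduces a −324 HU post-CPR-like mean).
Truth (volume, gas, weight, band means, compartment fractions) is
computed from the noiseless field before noise; noise is then added
in-mask and values clipped to [−1000, +100].  Real lungs have
heterogeneous parenchyma, vessels, airways and segmentation error — none
of which the phantom contains — so passing recovery tests demonstrates
correctness of the estimator chain, not robustness to anatomy.

Waveforms come from the linear two-compartment model above; real CPR
traces contain cardiac oscillations, leaks, nonlinear compliance and
catheter artifacts that the generator omits.  The histology generator
thresholds a Gaussian-smoothed noise field at quantiles of the requested
fractions, giving contiguous blobs whose realized (not requested) pixel
fractions are recorded as truth.

Cohorts mirror the experimental timeline — baseline CT, compression
epochs alternating mechanical/manual strategies (mechanical stronger),
blood gases during CC and post-ROSC, post CT, necropsy — with epoch
durations scaled to 30 s and phantom grids of ~10⁵ voxels so a full
5-animal analysis runs in seconds; rates, amplitudes and physiological
couplings are unchanged by this scaling.  Edema severity is linked to
compression amplitude by construction
(`edema = 36 + 8·amplitude + N(0, 10)` HU over amplitudes 14–30 cmH2O),
which is the dependency the association analysis must recover; an
`edema_scale = 0` configuration provides the negative control (no animal
may be flagged CRALE).  Post-CPR lung compliance falls with edema
severity; ex-vivo weight is CT-truth weight with 3% noise; wet-to-dry
rises with severity.

## Statistics

Associations are Pearson r with the two-sided t-transform p and the
least-squares line; series shorter than 3, non-finite values or zero
variance are errors.  Within-animal contrasts use a paired t-test or
Wilcoxon signed-rank (caller's choice, recorded in the result); a
constant zero difference is degenerate and reported with p = 1 by
convention.  Mixed-effects models, repeated-measures ANOVA and FDR
post-hoc procedures are deliberately out of scope — the report exports
tidy per-epoch tables for external statistics tools.

## Determinism

Every generator takes explicit parameters plus one seed and draws from a
single `numpy` Generator per call; cohort generation derives per-animal
sub-seeds from the cohort seed.  Identical (params, seed) give
bit-identical arrays, and a cohort analysis rerun under the same seed
produces a byte-identical JSON report (keys sorted, no timestamps).

## Problem sizes

The acceptance script uses a 256×128×64 phantom grid (~5×10⁵ lung
voxels) for recovery, ≤ 24³ grids for the per-voxel oracle, 18-s traces
at 100 Hz for mechanics, 100 histology images at 256² for coverage, and
a 5-animal cohort at 48×36×36 with three 20-s compression epochs —
sizes chosen so the whole script completes in seconds while every
estimator still operates far from small-sample regimes.

## Known limitations

- The depth→pressure physics of chest compressions is not modelled;
  compression amplitude is a free parameter in cmH2O.
- The Reske-style extrapolation implements the interpolation variant
  only.
- No oxyhemoglobin dissociation curve: saturations are inputs, so the
  gas generator emits (SO2, PO2) pairs that are content-consistent but
  not curve-consistent.
- Stereology assumes class maps as input; no stain processing or
  segmentation of raw histology images.
- The CPP "diastolic instant" is defined as the decompression-phase
  aortic minimum, one of several defensible readings during continuous
  compressions.
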