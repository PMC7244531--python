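# Methods

## Geometry and conventions

All coordinates are continuous, in nm, in the 2D image plane; no pixel grid
is modeled. The template microtubule's centerline is obtained by averaging
its tracked polyline over the recorded frames (templates are imaged for
50–100 frames while immobilized): each frame's polyline is normalized in
digitization order, resampled at uniform arc-length fractions to a common
vertex count, and averaged vertex-wise. Arc-length resampling before
averaging is this package's choice; it makes the average well defined when
frames are digitized with different vertex counts.

The **sideways distance** of a transport-microtubule center point is its
distance to the nearest point of the centerline, signed positive when the
point lies to the *left* of the centerline orientation — "left" meaning
+90° counterclockwise from the direction of transport motion in a
right-handed x–y frame. The orientation comes from event metadata (the
minus-end direction of the template, toward which transport microtubules
move). Projections falling beyond either end of the centerline by more than
one local segment length are flagged out-of-span and excluded from
statistics; sideways distances beyond a 200 nm gate (about twice the largest
physically possible projection for this geometry) are treated as tracking
outliers and dropped.

With this sign convention, **right-handed** helical motion corresponds to
the azimuthal phase decreasing with forward motion, and a right-handed event
blocked at a ridge is pinned on the right-hand side: sideways distance
−R, where R = (d_template + d_transport)/2 + δ is the helical-path radius
(43 nm for 25 nm microtubules and an 18 nm motor extension δ).

**Polarity**: an event is classified *parallel* (locked) when its net
longitudinal displacement is below 300 nm, otherwise *antiparallel*
(sliding). Statistics (histograms, pooled means) are computed on raw,
unsmoothed corrected data; the 20-frame centered rolling mean is applied
only for display and to seed extrema detection.

## Registration

Stage drift per channel is the per-frame mean displacement of fiducial
beads from their positions at the first frame (the reference frame); beads
missing from more than 20% of a channel's frames are excluded with a
warning. Raw per-frame offsets are used (no temporal smoothing). The
inter-channel color offset is a nonreflective similarity (translation,
rotation, isotropic scale) fitted in closed form (Umeyama/Procrustes with
the determinant constrained positive) to drift-corrected, time-averaged
bead positions, mapping far-red onto red coordinates. Drift is removed
before the transform is estimated because drift is per-channel and
per-frame while the color offset is static. Corrections are applied once —
drift subtraction, then the far-red mapping — and a `corrected` flag guards
against double application (the operation is not idempotent).

## Helix analysis

Extrema of x(s) are detected per contiguous valley segment (rotations never
span a ridge; segments are cut at ridge boundaries, so partial rotations at
segment edges are excluded). The trajectory measurements that are done by
eye on real data are automated as follows:

1. The dominant period P̂ of x(s) is taken from the FFT of the trace
   resampled onto a uniform s grid, refined by parabolic interpolation.
   A segment is considered rotating only when the spectral peak stands
   above the median spectral power by a factor of 10 and the corresponding
   amplitude exceeds 3× the noise level (noise is estimated robustly as
   1.4826·MAD of second differences / √6, which cancels the smooth signal).
2. Peak finding runs on a detection-smoothed trace whose rolling window is
   capped at ~P̂/6 (and at the 20-frame display window) so that short-pitch
   events are neither attenuated nor displaced. Maxima and minima are found
   separately with a minimum same-type separation of 0.7·P̂ — same-type
   extrema sit one full pitch apart, so this admits every true extremum
   while suppressing noise peaks; strict alternation is then enforced by
   dropping the lower-prominence member of any same-type adjacent pair.
3. Each extremum's position is refined by a quadratic fit to the smoothed
   trace over ±P̂/8, and its amplitude by a quadratic fit to the *raw*
   trace over ±P̂/12 evaluated at the refined position. Evaluating the fit
   at a fixed position (rather than at its own vertex) keeps the amplitude
   linear in the data and hence unbiased under noise; the quadratic
   truncation error is below 1% of the amplitude, which is why "exact"
   noiseless recovery is asserted at 1% in the tests.

Per rotation (a same-type extremum triple), pitch = arc length between the
outer pair and diameter = mean |x_max − x_min| over the two inner
opposite-type pairs; event values average the rotations, and diameters are
reported only for events with ≥2 complete turns. Velocity is endpoint-based
(end-to-end); a regression slope would be less noisy but the endpoint
definition matches how these events are conventionally reported. The
contour velocity uses a fixed default helix radius r = 43 nm.

**Handedness** uses the ridge-locking rule: the sign of the mean sideways
distance over ridge-region frames (negative ⇒ right-handed), requiring at
least 10 ridge frames and a mean exceeding 3 standard errors. A frame is
labeled "ridge" when the transport *footprint* (center ± half the transport
length) overlaps a ridge interval, since clamping persists until the entire
filament has left the ridge. No valley-only rule is offered: a 1D
sinusoidal projection x(s) is identical for left- and right-handed helices,
so without ridge locking (or z-information) the chirality is genuinely
undetermined, and the package says so.

## Motor-extension model

Concentric cylinders: a transport microtubule revolving about a template at
motor extension δ has helical-path diameter D = d_template + d_transport +
2δ and extreme projected sideways distance |x| = (d_template +
d_transport)/2 + δ. Both inversions are exact arithmetic; microtubule
diameters default to 25 nm (outer diameter) and are configurable. The
side-distance report also emits the value obtained after rounding the
measured |x| to the nearest nm, since the two conventions differ (45.5 →
20.5 vs 46 → 21).

Parallel (locked) events bind at a fixed azimuth θ; with θ uniform on
[0, 2π) the projection x = R sinθ has the arcsine density 1/(π√(R²−x²)),
bimodal with integrable singularities at ±R. Histogram bins are centered on
integer multiples of the bin width so the modal 5-nm bins at R = 45.5 nm
sit at ±45 nm. The discrete 13/14-protofilament azimuthal lattice is
approximated by the continuous uniform; a flag samples 14 equispaced
azimuths instead for sensitivity analysis.

## FLIC rotation

Traces are linearly detrended; the period is the first peak of the
unbiased-normalized autocorrelation that reaches the 0.2 gate (falling back
to the highest peak, which then fails the gate), refined by parabolic
interpolation and limited to lags ≤ N/2. The estimate is cross-checked
against the parabolic-refined dominant spectral peak; disagreement beyond
25% marks the trace non-periodic. The 0.2 autocorrelation gate is a
package decision mirroring the qualitative periodic/non-periodic
classification used for such assays; it is exposed in the configuration.
The generator's speckle model is a generic sinusoidal modulation
I(t) = I₀(1 + m sin(2πt/T + φ₀)) + noise — the physical FLIC
intensity-versus-height transfer function is deliberately not modeled
because only periodicity, not absolute height, is quantified. Group
comparisons of rotational pitches use scipy's two-sample two-sided
Mann–Whitney U-test (exact for small tie-free samples, tie-corrected
normal approximation otherwise).

## Bootstrap statistics

All distribution parameters are estimated by bootstrap-of-median: N
measurements resampled with replacement N-at-a-time, 1000 repetitions;
reported as μ (mean of the bootstrap medians) ± σ (their SD), with
intervals μ ± 3σ (nominal 99%). Pitch and diameter summaries pool one
value per event; sideways-distance summaries pool per-frame points. Seeds
are derived per call from a master seed for reproducible reports.

## Synthetic scene

The generator emits what a filament-tracking program would produce — per
frame localizations, not images: a straight template polyline (vertex
spacing 500 nm, emitted for the first 60 frames, matching the 50–100-frame
template acquisition), fiducial beads in both channels, and the transport
center point in the far-red channel. Defaults encode the study conditions:
25 nm microtubules, 18 nm motor extension (R = 43 nm), pitches drawn from
0.5–3 µm in cohorts, sliding at 100 nm/s sampled at 5 frames/s, 1.8 µm
transport length, ridge clamping applied instantaneously while any part of
the footprint overlaps a ridge. Localization noise is isotropic Gaussian,
default SD 10 nm per coordinate — a typical subpixel tracking precision,
chosen here as a free parameter since tracking precision is
instrument-specific. Far-red coordinates pass through a configurable
similarity distortion; beads and filaments share a linear stage drift.

Not emulated: template curvature and thermal fluctuation of the suspended
segment, motor stepping stochasticity, z-dependent defocus or intensity,
flip events around surface-immobilized templates, and the discrete
protofilament lattice of the helical path. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to every artifact of real tracking data.

## Problem sizes and numerical choices

Monte-Carlo sizes used by the test suite (chosen to give stable medians
while keeping the default run to a few minutes): recovery grid of 5 pitches
× 3 noise levels × 100 seeds with ~3.4 turns per event; 200-seed FLIC
recovery at SNR 2; 200-cohort bootstrap coverage at n = 50; 1000-rep
type-I-error simulation. Degenerate inputs are rejected explicitly
(non-positive pitch/velocity, ridge intervals outside the template span,
rotation periods at or below two frames, fewer than three matched beads,
fewer than two samples for a bootstrap). Ties in extrema alternation are
broken by prominence. Histogram bin centers are anchored at integer
multiples of the bin width.

## Known limitations

- All quantities are xy-projections; no z-reconstruction is attempted.
- Handedness requires ridge-locked segments (see above).
- The extrema detector assumes a quasi-sinusoidal x(s) with a dominant
  period per valley segment; strongly aperiodic "erratic" events are
  reported as non-rotating rather than measured.
- Drift correction references the first frame, so bead localization noise
  in that frame propagates as a constant offset (mitigated by the number of
  beads, visible in the registration translation error).
- The pipeline analyzes events independently; no hierarchical sharing of
  information across events on the same template is attempted.
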