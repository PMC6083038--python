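# Methods

`axotrace` quantifies two complementary read-outs of projection connectivity:
the density of fluorescently labelled axons in 3D confocal stacks, and the
decomposition of pooled synaptic size distributions (miniature-EPSC peak
amplitudes, synaptic-puncta surface areas) into small/medium/large
populations.  This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic validation data do and do not show
about real recordings.

## Axon tracing

### Seed selection

Tracing starts from seed points generated in five steps: (1) the stack is
projected onto the x-y plane by the maximum over z; (2) the projection is
band-thresholded with user-chosen lower and upper intensity bounds — the one
interactive step; the upper bound removes saturated structures such as somata
and debris; (3) the foreground is scored by an exact Euclidean distance
transform, so pixels on the axonal medial axis carry the highest local
values; (4) seed (x, y) positions are local maxima of the distance map within
N x N windows (default N = 5 px); (5) the seed z is the brightest plane of
that column.

Two conventions needed fixing where the procedure is under-determined:

- *Boundary scoring.* "Boundary" is 8-connected: a foreground pixel touching
  background even diagonally scores exactly 1 (plain Euclidean distance would
  give sqrt(2) for a diagonal-only contact); interior pixels keep the exact
  Euclidean distance.  The image border itself is not treated as background.
- *Plateau handling.* On a noise-free straight axon the medial-axis distance
  scores form a plateau, and a strict-maximum rule would collapse the whole
  plateau to a single seed at its lexicographic end — typically the axon tip,
  where tracing cannot start because the local geometry is not tubular.
  Window maxima are therefore thinned by deterministic greedy non-maximum
  suppression (descending score, ties toward smaller (y, x)): plateaus yield
  seeds spaced by the window, so every axon receives interior seeds, and the
  output is still fully deterministic.

A geometric limit worth knowing: an axon running exactly perpendicular to
the x-y plane projects to a single point and cannot be seeded from the
projection.  The benchmark suite keeps its steepest tube at ~84 degrees for
this reason; real stacks are acquired so that axons of interest run mostly
in-plane.

### Vectorial tracking

The stack is first convolved with an isotropic-in-pixels Gaussian of scale
`sigma` (default 5 px) to make it differentiable; larger `sigma` suppresses
noise but merges nearby tortuous segments.  The validation phantoms use
`sigma` = 3 px, matched to their thin (w = 3 px) tubes.  At each point the
3 x 3 Hessian of the smoothed volume G is estimated by unit-spacing central
differences (G is interpolated with cubic splines at off-grid positions) and
eigen-decomposed.  For a bright tube the two large negative eigenvalues are
cross-sectional and the near-zero eigenvalue's eigenvector points along the
axis.  "Tubular" is operationalised with two scale-free ratios:
`|l1|/|l3| <= 0.25` (flatness) and `min(|l2|,|l3|)/max(|l2|,|l3|) >= 0.5`
(roundness), both dimensionless so the test is invariant to intensity
rescaling.

The `hessian_window` parameter (default 9 px, chosen to span the axon
cross-section plus surrounding background) sets the boundary margin and the
radius of the medial-correction search disc.  The derivatives themselves use
unit spacing: on the analytic tube profile `exp(-2 r^2 / w^2)` smoothed at
`sigma` = 2 the unit-spacing estimate is within ~3% of the closed-form
curvature, whereas differencing across the full window would underestimate it
by ~40%.

Tracing marches bidirectionally from each seed (a seed usually sits
mid-axon) in steps of 1 px along the minor eigenvector, sign-matched to the
previous direction.  After each step the point is re-centred by sampling G on
a disc (radius = window/2, 0.5 px spacing, ties toward the centre) in the
plane normal to the travel direction and moving to the intensity maximum —
after smoothing, the centerline is the brightest in-plane point.  A trace
terminates on: loss of tubularity (this ends traces a few pixels short of
tube end caps, the main source of missing length), smoothed intensity below a
floor, approach within window/2 of a volume face, entry into a voxel claimed
by an earlier trace, re-entry into its own voxel more than a few steps back
(loop guard), or the step budget.

The intensity floor defaults to half the smoothed intensity at the seed.  An
absolute threshold carried over from the seeding stage would not transfer:
smoothing attenuates a thin tube's peak by roughly `s^2 / (s^2 + sigma^2)`
with `s = w/2` (5-12x for the geometries here), so a raw-scale floor applied
to G would stop every trace immediately.  The relative default adapts to that
attenuation; an explicit absolute floor can still be passed.

`trace_all` processes seeds in descending distance-score order.  Each
accepted trace claims its visited voxels dilated by 1 voxel; later seeds on
claimed voxels are skipped, so one axon yields one trace even though the
plateau seeding places several seeds on it.  Traces shorter than `min_nodes`
(default 5) nodes are discarded as stubs — at SNR 5 a handful of noise
seeds pass the initial tubularity test but die within a few steps.

All smoothing, derivatives and steps are in pixel units on the (possibly
anisotropic) voxel grid; positions convert to micrometres only when the
polyline is emitted, using the voxel-centre convention (position =
(index + 0.5) * voxel_size).  Axonal density is the summed polyline length
divided by the physical stack volume, in um/um^3.

## Mixture decomposition

Pooled per-event values are binned with the Freedman-Diaconis rule,
`binwidth = 2 IQR / n^(1/3)`, using Tukey hinges (median of each half,
median shared when n is odd) for the quartiles; the hinge convention is
isolated in one function (`tukey_hinges`).  The histogram is normalised to a
probability density and fitted with

    y = y0 + sum_i  A_i / (w_i sqrt(pi/2)) * exp(-2 (x - xc_i)^2 / w_i^2),

the area-parameterised Gaussian: each component integrates exactly to A_i,
so component areas are population fractions directly.  Fitting is nonlinear
least squares (trust-region reflective through lmfit) with A > 0, w > 0 and
centers constrained to the data range.  When the histogram comes from
samples, residuals are weighted by the per-bin Poisson SD
(sqrt(max(count, 1)) on the density scale), so the minimised objective is
the classical chi-square statistic; for histograms of unknown provenance the
weights are 1 and the objective reduces to the plain SSE (always reported
separately).  Initialisation is a deterministic weighted k-means partition
of the bins, so fits are reproducible bit for bit.

Model selection fits k = 1..4 components.  Each richer fit is attempted both
fresh and warm-started from the previous fit plus one negligible component
placed at the worst residual; the better of the two is kept, which makes the
chi-square trail non-increasing in k.  A richer fit is accepted when its
chi-square drop passes the partial F-test for nested least-squares models
(alpha = 0.01; three extra parameters always absorb some residual noise, so
the drop must beat their cost — the same judgement as watching the adjusted
r-square stop improving) and no component of the richer fit holds less than
1% of the total area.  The comparison runs against the last *accepted* fit,
so a degenerate intermediate fit cannot strand the selection.  alpha = 0.01
rather than 0.05 because up to three sequential probes multiply the false-
acceptance risk; on the three-population validation generator this selects
k = 3 in 100/100 replicates while k = 4 is essentially never accepted.
Single-Gaussian data still draw a spurious second component in roughly 15%
of replicates — an inherent cost of sequential testing on binned data, worth
knowing when interpreting a marginal extra component.  The four-component
probe is always run and reported even when rejected.

Cutoffs between adjacent accepted components are the crossing points of
their offset-free scaled densities between the two centers (solved in closed
form from the log-quadratic; midpoint fallback with a warning when the
densities do not cross).  Values below the first cutoff are "small", and so
on; for negative-going amplitudes, classification uses magnitudes (both
values and cutoffs), so "large" means large magnitude.  Empty strata report
NaN proportions rather than zeros.

## Electrophysiology features

Passive properties from a hyperpolarising test step: Cm = Q/dV (pC/mV
reported in pF), Gm = Iss/dV (pA/mV = nS), Rs = dV/Ip (mV/pA reported in
MOhm).  These are plain ratios and stay exact on exact (Fraction) inputs.
Recordings whose Rs rises more than 30% over its initial value are flagged
for exclusion.

Event detection subtracts a slow median baseline (51 ms window on a ~1 kHz
decimated copy, re-interpolated — robust while events occupy less than half
the window, and exactly invariant to DC offsets), smooths lightly
(Gaussian, 0.2 ms), and takes local extrema beyond the signed threshold with
`find_peaks`, requiring prominence of at least the threshold magnitude
(rejects noise wiggles on decay tails of larger events) and a refractory
spacing (default 2 ms, just above the rise time, so Poisson-overlapped
events are not needlessly merged).

Per-event features: the peak is re-localised on a lightly smoothed copy
within +-0.5 ms and measured against the median of a 1 ms baseline window
ending 2 ms before the peak; the 10-90% rise time interpolates linearly
between samples on the rising phase; the weighted decay is the
amplitude-weighted time constant (A1 tau1 + A2 tau2)/(A1 + A2) of a
bi-exponential fit from the peak (25 ms window), falling back to a single
exponential when the second component carries <2% of the amplitude or the
two constants differ by <5%, and reporting None when no fit converges.
"Weighted decay" has no universal definition; the amplitude-weighted
bi-exponential tau is the common choice for synaptic currents and is the one
implemented.  Instantaneous frequency is the reciprocal inter-event
interval assigned to the later event.

The frequency-versus-stimulation-rate relation is ordinary least squares
with the slope's standard error and 5%/95% confidence limits (Student t on
n - 2 dof); the mean-response confidence band uses the textbook
`s * sqrt(1/n + (x - xbar)^2 / Sxx)` form.

## Synthetic data and what it shows

Phantom tubes are rendered with intensity `peak * exp(-2 d^2 / w^2)` where d
is the pixel-space distance to the centerline — the same Gaussian form as
the mixture kernel, so the on-axis Hessian eigenvalues have the closed form
used by the tracer tests (after smoothing at `sigma`, the cross-sectional
curvature is `-(s^2/(s^2+sigma^2)) / (s^2+sigma^2)` with `s = w/2`).
Straight tubes use exact point-segment distances; curved tubes sample the
curve at 0.1 px and query a KD-tree, bounding the distance error at 0.05 px.
Overlapping tubes blend by maximum.  Noise is additive Gaussian read noise
plus optional Poisson shot noise, applied after rendering and clipped at
zero; the benchmark suite uses peak-SNR 5 for its noisy condition,
bracketing the low end of confocal practice.  The benchmark suite
(`benchmark_phantoms`) holds ten geometries — near-axial lines, obliques, a
parallel pair, three helices, a Bezier arc — in 0.25 um isotropic voxels
with w = 3 px tubes at peak 200 over background 10.

Mixture samples draw multinomial component counts and Gaussian values per
component (width w means SD w/2, matching the fit kernel).  Synthetic mEPSC
traces place difference-of-exponential events (0.5 ms rise; 2 and 8 ms
decays split 60/40, weighted decay ~5.6 ms) at Poisson times with amplitudes
from a three-population mixture (centers -5/-12/-22 pA, fractions
31/41/28%) over 1 pA Gaussian noise at 20 kHz — a quiet whole-cell
recording.  All generators are pure functions of spec + seed.

What passing these validations does *not* show: phantoms have homogeneous
tube brightness, no branching, no crossing tubes closer than the smoothing
scale, and no depth-dependent attenuation or PSF anisotropy beyond voxel
anisotropy, so real-stack performance depends on threshold choices the way
the interactive step intends.  Synthetic events never superimpose within a
fraction of a millisecond and their kinetics are stationary; real mEPSC
trains violate both at high rates.  The mixture generator produces genuinely
Gaussian populations; real amplitude distributions can be skewed, in which
case component counts should be read as descriptive.

## Problem sizes used in validation

The shipped tests and the reproduction script run the ten-phantom benchmark
twice (clean and SNR 5; largest volume 10^6 voxels), five-phantom density
recovery, 100-replicate mixture decomposition at n = 5000, 100 random
16 x 16 distance-transform oracles and 100 binwidth oracles, and one
100 s / 20 kHz synthetic recording (~1000 events) — sizes chosen so the
whole validation completes in a few minutes on a laptop-class machine while
keeping every statistical bound meaningful.
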