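# axotrace

Quantitative building blocks for functional connectomics of labelled
projection pathways: semi-automatic tracing of fluorescently labelled axons
in 3D confocal stacks with axonal density measurement, decomposition of
pooled synaptic size distributions into small/medium/large populations, and
miniature-EPSC analysis for the matching functional read-out.

The package is aimed at labs that image virus-labelled axons (e.g.
corticofugal projections) and record the corresponding quantal synaptic
currents, and want the anatomical and functional size distributions measured
with one consistent set of algorithms.

## What it computes

**Axon tracing.** Seeds are generated from the maximum-intensity projection:
band thresholding (the one interactive step), an exact Euclidean distance
transform whose ridges follow axonal medial axes, local maxima in N x N
windows, and per-seed z from the brightest plane.  From each seed the axon is
tracked in 3D through the Gaussian-smoothed volume G: the eigenvalues
(l1, l2, l3, sorted by magnitude) of the local Hessian identify bright tubes
(`l2 ~ l3 << 0`, `l1 ~ 0`), the minor eigenvector gives the axon direction,
and after each step the point is re-centred on the medial axis via the
intensity maximum in the normal plane.  Axonal density is total centerline
length over imaged volume (um/um^3).

**Mixture decomposition.**  All-point histograms (Freedman-Diaconis bin
width `2 IQR / n^(1/3)`) are fitted with sums of one to four
area-parameterised Gaussians

    y = y0 + sum_i A_i / (w_i sqrt(pi/2)) exp(-2 (x - xc_i)^2 / w_i^2)

by (Poisson-weighted) least squares; chi-square model selection with a
nested-model F-test and a <1%-area rejection rule picks the component count;
component areas give population fractions, density crossings give size
cutoffs, and values are classified small/medium/large (by magnitude for
negative-going amplitudes).

**Electrophysiology.**  Passive membrane formulas (Cm = Q/dV, Gm = Iss/dV,
Rs = dV/Ip) with the 30% series-resistance exclusion rule; mEPSC detection
(median-baseline subtraction, thresholded prominent extrema) with per-event
peak amplitude, 10-90% rise time, amplitude-weighted bi-exponential decay
and instantaneous frequency; and the event-frequency versus
stimulation-rate regression with confidence limits.

**Synthetic data.**  Ground-truthed generators for every input: tubular
image phantoms with analytic centerlines and arc lengths, Gaussian-mixture
samples, and synthetic voltage-clamp traces with Poisson-timed
bi-exponential events.

## Worked example

Resolving three synaptic populations from pooled amplitudes
(`examples/mixture_decomposition.py`):

```
bin width (Freedman-Diaconis): 1.740 pA
chi-square trail: k=1: 4676.43  k=2: 1387.03  k=3: 12.52  k=4: 4.27
accepted model: 3 Gaussians (adjusted r^2 = 0.9998)
  center  -21.94 pA  width  2.19  area fraction 27.7 %
  center  -12.00 pA  width  2.24  area fraction 40.5 %
  center   -5.00 pA  width  2.24  area fraction 31.8 %
cutoffs between populations: -17.07, -8.46 pA
size-class proportions: small 31.8 %, medium 40.5 %, large 27.7 %
```

The chi-square trail collapses up to the true component count (the
generator used fractions 31/41/28% at centers -5/-12/-22 pA) and flattens
after it; the fourth component is probed but rejected.  The recovered area
fractions and the per-value classification agree with the generating split
to about one point.

Tracing a helical axon phantom and recovering its density
(`examples/trace_phantom.py`):

```
traces found:        1
traced length:       38.8 um (analytic 41.0 um)
axonal density:      0.00337 um/um^3 (analytic 0.00356)
relative error:      5.4 %
```

A few percent of length is lost at the tube end caps where the geometry
stops looking tubular.  See `examples/` for the mEPSC pipeline and passive
membrane properties as well.

## Command line

The same stages are exposed as a thin CLI for batch work:

```sh
axotrace simulate phantom --seed 1 --out phantom/
axotrace trace --in phantom/phantom.tif --lower 70 --upper 1e6 \
         --voxel-size 0.25,0.25,0.25 --out traces/
axotrace density --in traces/ --stack phantom/phantom.tif \
         --voxel-size 0.25,0.25,0.25
axotrace fitmix --in values.tsv --max-k 4 --out fit.json --cutoffs --classify
axotrace events --in trace.tsv --rate 20000 --threshold -8 --out events.tsv
```

Exit codes: 0 success, 1 user error, 2 internal error; outputs are written
atomically and are byte-identical for identical inputs and seed.

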