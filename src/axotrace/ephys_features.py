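"""Passive membrane properties, mEPSC detection and per-event features,
and the event-frequency versus stimulation-rate regression.

Sign conventions: inward synaptic currents are negative (pA) and detection
thresholds are signed accordingly.  Membrane formulas use whole-cell test
pulses: ``Cm = Q / dV`` (charge of the capacitive transient over the voltage
step), ``Gm = Iss / dV`` (steady-state current over the step) and
``Rs = dV / Ip`` (step over the peak capacitive current).  Unit bookkeeping:
pC/mV = nF (reported in pF), pA/mV = nS, mV/pA = GOhm (reported in MOhm).
All three are plain ratios, so exact (e.g. Fraction) inputs give exact
outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal, stats

__all__ = [
    "CurrentTrace",
    "EventFeatures",
    "PassiveMembrane",
    "RegressionResult",
    "passive_membrane",
    "rs_exclusion",
    "detect_events",
    "event_features",
    "extract_features",
    "frequency_rate_regression",
]

log = logging.getLogger(__name__)


@dataclass
class CurrentTrace:
    """A voltage-clamp current recording (pA) at a fixed sampling rate (Hz)."""

    samples: np.ndarray
    sampling_rate: float
    stimulus_times: Optional[np.ndarray] = None  # s

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1D array of currents (pA)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class EventFeatures:
    """Features of one detected miniature synaptic event."""

    time: float  # s, at the event peak
    peak_amplitude: float  # pA, signed, relative to local baseline
    rise_10_90: Optional[float]  # ms
    weighted_decay: Optional[float]  # ms, amplitude-weighted bi-exponential tau
    instantaneous_frequency: Optional[float] = None  # Hz, 1 / preceding interval


@dataclass(frozen=True)
class PassiveMembrane:
    """Whole-cell passive properties: capacitance, conductance, series resistance."""

    Cm: float  # pF
    Gm: float  # nS
    Rs: float  # MOhm


def passive_membrane(Q, dV, Iss, Ip) -> PassiveMembrane:
    """Compute Cm, Gm, Rs from a hyperpolarising test step.

    Parameters: Q in pC, dV in mV, Iss in pA, Ip in pA.  Exact inputs
    (``fractions.Fraction``) give exact outputs.
    """
    if dV == 0:
        raise ValueError("dV must be nonzero")
    if Ip == 0:
        raise ValueError("Ip must be nonzero")
    Cm = (Q / dV) * 1000  # pC/mV = nF -> pF
    Gm = Iss / dV  # pA/mV = nS
    Rs = (dV / Ip) * 1000  # mV/pA = GOhm -> MOhm
    if Cm <= 0 or Gm <= 0 or Rs <= 0:
        raise ValueError("passive properties must be positive; check input signs")
    return PassiveMembrane(Cm=Cm, Gm=Gm, Rs=Rs)


def rs_exclusion(rs_series: Sequence[float], max_increase: float = 0.30) -> bool:
    """True (exclude the recording) iff Rs rose by more than ``max_increase``.

    The rise is judged against the first value of the series.
    """
    rs = list(rs_series)
    if len(rs) < 2:
        raise ValueError("need at least 2 Rs values")
    if any(r <= 0 for r in rs):
        raise ValueError("Rs values must be positive")
    return max(rs) / rs[0] > 1 + max_increase


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def _baseline(trace: CurrentTrace, window_ms: float = 51.0) -> np.ndarray:
    """Slow median baseline (robust to events occupying < half the window).

    The trace is decimated to ~1 kHz before median filtering and linearly
    re-interpolated, which keeps the filter cheap on long high-rate records.
    """
    x = trace.samples
    ds = max(1, int(round(trace.sampling_rate / 1000.0)))
    xd = x[::ds]
    size = max(3, int(round(window_ms / (1000.0 * ds / trace.sampling_rate))) | 1)
    med = ndimage.median_filter(xd, size=size, mode="nearest")
    idx = np.arange(0, x.size, ds)
    return np.interp(np.arange(x.size), idx, med)


def detect_events(
    trace: CurrentTrace,
    threshold: float,
    refractory: float = 2.0,
    smooth_ms: float = 0.2,
) -> np.ndarray:
    """Detect miniature-event peaks crossing ``threshold`` pA.

    Local extrema of the baseline-subtracted, lightly smoothed trace beyond
    the (signed) threshold, separated by at least ``refractory`` ms;
    deterministic and invariant to DC offsets.  Peaks must also be prominent
    by at least the threshold magnitude, which rejects noise wiggles riding
    on the decay tail of a larger event.  Returns sample indices of the
    peaks (on the smoothed trace; feature extraction re-localises them).
    """
    if threshold == 0:
        raise ValueError("threshold must be nonzero (sign sets event polarity)")
    y = trace.samples - _baseline(trace)
    if smooth_ms > 0:
        y = ndimage.gaussian_filter1d(y, sigma=smooth_ms * trace.sampling_rate / 1000.0)
    if threshold < 0:
        y = -y
    distance = max(1, int(round(refractory * trace.sampling_rate / 1000.0)))
    peaks, _ = signal.find_peaks(
        y, height=abs(threshold), prominence=abs(threshold), distance=distance
    )
    return peaks


# ---------------------------------------------------------------------------
# Per-event features
# ---------------------------------------------------------------------------

def _crossing_time(t: np.ndarray, y: np.ndarray, level: float) -> Optional[float]:
    """Last upward |y| crossing of ``level`` before the end, linearly interpolated."""
    above = np.abs(y) >= abs(level)
    if not above.any():
        return None
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return float(t[0]) if above[0] else None
    i = idx[-1]
    y0, y1 = abs(y[i]), abs(y[i + 1])
    frac = (abs(level) - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(t[i] + frac * (t[i + 1] - t[i]))


def _biexp(t, a1, tau1, a2, tau2):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def _fit_weighted_decay(t_ms: np.ndarray, y_norm: np.ndarray) -> Optional[float]:
    """Amplitude-weighted tau (ms) from a bi-exponential fit of the decay.

    ``y_norm`` is the decay normalised to ~1 at the peak.  Falls back to a
    single exponential when the second component is degenerate; returns None
    when no fit converges.
    """
    if t_ms.size < 6:
        return None
    # crude initial tau from the 1/e point
    below = np.flatnonzero(y_norm < math.exp(-1))
    tau_guess = float(t_ms[below[0]]) if below.size else float(t_ms[-1] / 2)
    tau_guess = max(tau_guess, 1e-2)
    try:
        popt, _ = optimize.curve_fit(
            _biexp,
            t_ms,
            y_norm,
            p0=[0.6, 0.6 * tau_guess, 0.4, 2.0 * tau_guess],
            bounds=([0, 1e-3, 0, 1e-3], [10, 500, 10, 500]),
            maxfev=5000,
        )
        a1, tau1, a2, tau2 = popt
        total = a1 + a2
        if total <= 0:
            raise RuntimeError("degenerate amplitudes")
        if min(a1, a2) / total < 0.02 or abs(tau1 - tau2) / max(tau1, tau2) < 0.05:
            raise RuntimeError("second component degenerate")
        return float((a1 * tau1 + a2 * tau2) / total)
    except (RuntimeError, ValueError):
        pass
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            t_ms,
            y_norm,
            p0=[1.0, tau_guess],
            bounds=([0, 1e-3], [10, 500]),
            maxfev=5000,
        )
        return float(popt[1])
    except (RuntimeError, ValueError):
        return None


def event_features(
    trace: CurrentTrace,
    index: int,
    baseline_ms: float = 1.0,
    baseline_gap_ms: float = 2.0,
    decay_window_ms: float = 25.0,
    smooth_ms: float = 0.1,
) -> EventFeatures:
    """Extract peak, 10-90% rise time and weighted decay for one event.

    The local baseline is the median of a ``baseline_ms`` window ending
    ``baseline_gap_ms`` before the peak.  The peak is re-localised on a
    lightly smoothed copy (Gaussian, ``smooth_ms``; set 0 to disable) within
    +-0.5 ms of the detection index.  Rise times interpolate linearly between
    samples; the decay is fitted with a bi-exponential and summarised by the
    amplitude-weighted time constant.  Features that cannot be measured are
    returned as None.
    """
    sr = trace.sampling_rate
    n = trace.samples.size
    win = int(round((baseline_ms + baseline_gap_ms + decay_window_ms + 10.0) * sr / 1000.0))
    lo = max(0, index - win)
    hi = min(n, index + win)
    x = trace.samples[lo:hi].astype(float)
    if smooth_ms > 0:
        x = ndimage.gaussian_filter1d(x, sigma=smooth_ms * sr / 1000.0, mode="nearest")
    pk_local = index - lo

    b_gap = int(round(baseline_gap_ms * sr / 1000.0))
    b_len = max(1, int(round(baseline_ms * sr / 1000.0)))
    b_hi = max(1, pk_local - b_gap)
    b_lo = max(0, b_hi - b_len)
    baseline = float(np.median(x[b_lo:b_hi]))

    y = x - baseline
    half = max(1, int(round(0.5 * sr / 1000.0)))
    sl = slice(max(0, pk_local - half), min(x.size, pk_local + half + 1))
    rel = np.argmax(np.abs(y[sl]))
    pk_local = sl.start + int(rel)
    peak = float(y[pk_local])

    # rise: walk the rising phase back from the peak
    t = np.arange(x.size) / sr * 1000.0  # ms
    rise_seg = slice(b_lo, pk_local + 1)
    t10 = _crossing_time(t[rise_seg], y[rise_seg], 0.10 * peak)
    t90 = _crossing_time(t[rise_seg], y[rise_seg], 0.90 * peak)
    rise = None
    if t10 is not None and t90 is not None and t90 > t10:
        rise = float(t90 - t10)

    # decay: fit from the peak forward
    d_hi = min(x.size, pk_local + int(round(decay_window_ms * sr / 1000.0)))
    decay = None
    if peak != 0 and d_hi - pk_local >= 6:
        t_ms = (np.arange(pk_local, d_hi) - pk_local) / sr * 1000.0
        decay = _fit_weighted_decay(t_ms, y[pk_local:d_hi] / peak)

    return EventFeatures(
        time=(lo + pk_local) / sr,
        peak_amplitude=peak,
        rise_10_90=rise,
        weighted_decay=decay,
    )


def extract_features(
    trace: CurrentTrace, indices: Sequence[int], **kwargs
) -> pd.DataFrame:
    """Per-event feature table with instantaneous frequency.

    The instantaneous frequency is the reciprocal inter-event interval,
    assigned to the later event of each pair (NaN for the first event).
    """
    feats = [event_features(trace, int(i), **kwargs) for i in indices]
    times = np.array([f.time for f in feats])
    inst = np.full(times.size, np.nan)
    if times.size > 1:
        inst[1:] = 1.0 / np.diff(times)
    return pd.DataFrame(
        {
            "time_s": times,
            "peak_amplitude_pa": [f.peak_amplitude for f in feats],
            "rise_10_90_ms": [f.rise_10_90 for f in feats],
            "weighted_decay_ms": [f.weighted_decay for f in feats],
            "instantaneous_frequency_hz": inst,
        }
    )


# ---------------------------------------------------------------------------
# Frequency vs stimulation-rate regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares of event frequency on stimulation rate."""

    slope: float  # Hz per Hz
    intercept: float  # Hz
    r_squared: float
    slope_stderr: float
    intercept_stderr: float
    slope_conf: Tuple[float, float]  # 5% / 95% limits
    intercept_conf: Tuple[float, float]
    n: int

    def conf_band(self, x) -> Tuple[np.ndarray, np.ndarray]:
        """5%/95% confidence limits of the fitted mean at ``x``."""
        x = np.asarray(x, dtype=float)
        yhat = self.intercept + self.slope * x
        # reconstruct the band from the stored fit quantities
        tcrit = stats.t.ppf(0.95, self.n - 2)
        if self.slope_stderr > 0:
            sxx = (self._s() / self.slope_stderr) ** 2
        else:
            sxx = np.inf
        se = self._s() * np.sqrt(1.0 / self.n + (x - self._xbar()) ** 2 / sxx)
        return yhat - tcrit * se, yhat + tcrit * se

    # internal fit state for the band (set at construction time)
    def _s(self) -> float:
        return object.__getattribute__(self, "_resid_sd")

    def _xbar(self) -> float:
        return object.__getattribute__(self, "_x_mean")


def frequency_rate_regression(points: Sequence[Tuple[float, float]]) -> RegressionResult:
    """OLS of mEPSC frequency (Hz) on optical stimulation rate (Hz).

    Returns the slope (Hz/Hz) with its standard error, r^2 and 5%/95%
    confidence limits for slope and intercept.  Needs >= 3 points over >= 2
    distinct rates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (rate, frequency) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("all stimulation rates identical; slope is undefined")
    res = stats.linregress(x, y)
    n = x.size
    tcrit = stats.t.ppf(0.95, n - 2)  # two-sided 5%/95% limits
    out = RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
        slope_conf=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        intercept_conf=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        n=n,
    )
    resid = y - (res.intercept + res.slope * x)
    dof = n - 2
    object.__setattr__(out, "_resid_sd", float(np.sqrt(np.sum(resid**2) / dof)) if dof else 0.0)
    object.__setattr__(out, "_x_mean", float(np.mean(x)))
    return out
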