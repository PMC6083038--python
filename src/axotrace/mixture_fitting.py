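"""Sum-of-Gaussians decomposition of all-point amplitude/size histograms.

The same pipeline resolves small/medium/large populations in miniature-EPSC
peak-amplitude distributions (pA, negative) and in synaptic-puncta
surface-area distributions (um^2, positive):

1. pool the per-event values and build a probability-density histogram with
   the Freedman-Diaconis bin width ``2 * IQR / n**(1/3)`` (Tukey-hinge
   quartiles);
2. fit the binned density with a sum of one to four area-parameterised
   Gaussians plus an offset,
   ``y = y0 + sum_i A_i / (w_i sqrt(pi/2)) * exp(-2 (x - xc_i)^2 / w_i^2)``,
   by nonlinear least squares (each component integrates exactly to A_i);
3. escalate the component count while the chi-square drops by more than a
   relative tolerance and no component's area falls below 1% of the total;
4. report component area fractions, inter-component cutoff values (crossing
   points of the component densities), and small/medium/large class labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

__all__ = [
    "BinSpec",
    "GaussianComponent",
    "MixtureFit",
    "DensityHistogram",
    "tukey_hinges",
    "fd_binwidth",
    "build_histogram",
    "gauss_sum",
    "fit_gauss_sum",
    "select_model",
    "component_fractions",
    "size_cutoffs",
    "classify_sizes",
]

log = logging.getLogger(__name__)

_SQRT_HALF_PI = np.sqrt(np.pi / 2.0)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinSpec:
    """Histogram bin layout from the Freedman-Diaconis rule."""

    bin_width: float
    edges: np.ndarray
    n: int
    iqr: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def tukey_hinges(samples: Sequence[float]) -> Tuple[float, float]:
    """Lower and upper hinge (median of each half, median shared when n odd)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples for hinges")
    half = (n + 1) // 2
    lower = x[:half]
    upper = x[n - half:]
    return float(np.median(lower)), float(np.median(upper))


def fd_binwidth(samples: Sequence[float]) -> BinSpec:
    """Freedman-Diaconis bin width ``2 * IQR / n**(1/3)`` with whole-bin edges.

    Edges start at the sample minimum and advance in whole bins until the
    maximum is covered.  A zero IQR (heavily tied data) is an error: choose an
    explicit bin width instead.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for the Freedman-Diaconis rule")
    q1, q3 = tukey_hinges(x)
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError(
            "IQR is zero; the Freedman-Diaconis rule is undefined - "
            "supply an explicit bin width"
        )
    bw = 2.0 * iqr / x.size ** (1.0 / 3.0)
    lo, hi = float(np.min(x)), float(np.max(x))
    n_bins = max(1, int(np.ceil((hi - lo) / bw - 1e-12)))
    edges = lo + bw * np.arange(n_bins + 1)
    return BinSpec(bin_width=float(bw), edges=edges, n=int(x.size), iqr=float(iqr))


@dataclass(frozen=True)
class DensityHistogram:
    """A probability-density histogram (integrates to ~1 over its bins)."""

    centers: np.ndarray
    density: np.ndarray
    bin_width: float
    bins: Optional[BinSpec] = None

    def bin_sigma(self) -> np.ndarray:
        """Per-bin density SD from Poisson counting statistics.

        Available when the histogram was built from samples (``bins`` carries
        the sample count); a histogram of unknown provenance gets unit
        weights, reducing the weighted chi-square to the plain SSE.
        """
        if self.bins is None:
            return np.ones_like(self.density)
        n, bw = self.bins.n, self.bin_width
        counts = self.density * n * bw
        return np.sqrt(np.maximum(counts, 1.0)) / (n * bw)


def build_histogram(samples: Sequence[float], bins: Optional[BinSpec] = None) -> DensityHistogram:
    """All-point density histogram of pooled per-event values."""
    x = np.asarray(samples, dtype=float)
    if bins is None:
        bins = fd_binwidth(x)
    counts, _ = np.histogram(x, bins=bins.edges)
    density = counts / (x.size * bins.bin_width)
    return DensityHistogram(
        centers=bins.centers, density=density, bin_width=bins.bin_width, bins=bins
    )


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianComponent:
    """One area-parameterised Gaussian: area A, width w, center xc."""

    area: float
    width: float
    center: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            self.area
            / (self.width * _SQRT_HALF_PI)
            * np.exp(-2.0 * (x - self.center) ** 2 / self.width**2)
        )


def gauss_sum(x, y0: float, components: Sequence[GaussianComponent]) -> np.ndarray:
    """Offset plus the sum of the component densities at ``x``."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, float(y0), dtype=float)
    for comp in components:
        out += comp.density(x)
    return out


@dataclass
class MixtureFit:
    """Result of one sum-of-Gaussians least-squares fit.

    ``chi_square`` is the minimised objective: the Poisson-weighted sum of
    squared bin residuals when bin counts are known, otherwise the plain SSE
    (which is always reported separately as ``sse``).
    """

    y0: float
    components: List[GaussianComponent]  # sorted by center
    chi_square: float
    reduced_chi_square: float
    sse: float  # unweighted sum of squared density residuals
    adjusted_r2: float
    converged: bool
    message: str = ""
    histogram: Optional[DensityHistogram] = None

    @property
    def k(self) -> int:
        return len(self.components)

    def model(self, x) -> np.ndarray:
        return gauss_sum(x, self.y0, self.components)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _kmeans_init(centers: np.ndarray, weights: np.ndarray, k: int, bw: float):
    """Deterministic 1D weighted k-means on bin centers -> initial components."""
    mass = weights / weights.sum()
    cdf = np.cumsum(mass)
    # quantile-based deterministic initialisation
    qs = (np.arange(k) + 0.5) / k
    mu = np.array([centers[np.searchsorted(cdf, q, side="left").clip(0, len(centers) - 1)] for q in qs])
    mu = np.sort(mu)
    for _ in range(100):
        # assign bins to the nearest center
        d = np.abs(centers[:, None] - mu[None, :])
        lab = np.argmin(d, axis=1)
        new_mu = mu.copy()
        for j in range(k):
            sel = lab == j
            if mass[sel].sum() > 0:
                new_mu[j] = np.average(centers[sel], weights=mass[sel])
        if np.allclose(new_mu, mu):
            break
        mu = np.sort(new_mu)
    comps = []
    d = np.abs(centers[:, None] - mu[None, :])
    lab = np.argmin(d, axis=1)
    for j in range(k):
        sel = lab == j
        m = float(mass[sel].sum())
        if m <= 0:
            m = 1.0 / k
            sd = bw
            c = float(mu[j])
        else:
            c = float(np.average(centers[sel], weights=mass[sel]))
            var = float(np.average((centers[sel] - c) ** 2, weights=mass[sel]))
            sd = max(np.sqrt(var), bw / 2.0)
        comps.append(GaussianComponent(area=max(m, 1e-6), width=2.0 * sd, center=c))
    return comps


def _make_params(
    y0: float,
    comps: Sequence[GaussianComponent],
    xlo: float,
    xhi: float,
    bw: float,
    ymax: float,
) -> Parameters:
    params = Parameters()
    params.add("y0", value=max(y0, 0.0), min=0.0, max=max(ymax, 1e-30))
    for i, c in enumerate(comps):
        params.add(f"A{i}", value=c.area, min=1e-12)
        params.add(f"w{i}", value=max(c.width, bw / 4.0), min=bw / 10.0, max=4.0 * (xhi - xlo))
        params.add(f"xc{i}", value=float(np.clip(c.center, xlo, xhi)), min=xlo, max=xhi)
    return params


def _params_to_components(params, k: int) -> Tuple[float, List[GaussianComponent]]:
    comps = [
        GaussianComponent(
            area=float(params[f"A{i}"].value),
            width=float(params[f"w{i}"].value),
            center=float(params[f"xc{i}"].value),
        )
        for i in range(k)
    ]
    comps.sort(key=lambda c: c.center)
    return float(params["y0"].value), comps


def fit_gauss_sum(
    histogram: DensityHistogram,
    k: int,
    init: Optional[Tuple[float, Sequence[GaussianComponent]]] = None,
) -> MixtureFit:
    """Least-squares fit of ``k`` Gaussians (plus offset) to a density histogram.

    Deterministic given the data and ``init`` (default initialisation is a
    deterministic weighted k-means partition of the bins).  Constraints:
    A > 0, w > 0, centers inside the data range.  Non-convergence or a
    degenerate histogram is flagged on the returned fit, never silent.
    """
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    x = np.asarray(histogram.centers, dtype=float)
    y = np.asarray(histogram.density, dtype=float)
    sigma = histogram.bin_sigma()
    bw = float(histogram.bin_width)
    n_bins = x.size
    n_par = 1 + 3 * k
    occupied = int(np.count_nonzero(y))

    if init is None:
        y0_init, comps_init = 0.0, _kmeans_init(x, np.maximum(y, 0) + 1e-300, k, bw)
    else:
        y0_init, comps_init = float(init[0]), list(init[1])
        if len(comps_init) != k:
            raise ValueError("init must provide exactly k components")

    if n_bins < n_par or occupied < min(n_par, 2):
        resid0 = gauss_sum(x, y0_init, comps_init) - y
        fit = MixtureFit(
            y0=y0_init,
            components=sorted(comps_init, key=lambda c: c.center),
            chi_square=float(np.sum((resid0 / sigma) ** 2)),
            reduced_chi_square=np.inf,
            sse=float(np.sum(resid0**2)),
            adjusted_r2=-np.inf,
            converged=False,
            message=f"degenerate histogram: {n_bins} bins / {occupied} occupied "
            f"for {n_par} parameters",
            histogram=histogram,
        )
        return fit

    params = _make_params(y0_init, comps_init, float(x.min()), float(x.max()), bw, float(y.max()))

    def residual(p):
        comps = [
            GaussianComponent(p[f"A{i}"].value, p[f"w{i}"].value, p[f"xc{i}"].value)
            for i in range(k)
        ]
        return (gauss_sum(x, p["y0"].value, comps) - y) / sigma

    with warnings.catch_warnings():
        # lmfit emits RuntimeWarnings computing parameter correlations when a
        # component sits at a bound; the fit itself is unaffected
        warnings.simplefilter("ignore", RuntimeWarning)
        result = minimize(residual, params, method="least_squares")
    y0, comps = _params_to_components(result.params, k)
    resid = gauss_sum(x, y0, comps) - y
    chi = float(np.sum((resid / sigma) ** 2))
    sse = float(np.sum(resid**2))
    sst = float(np.sum(((y - y.mean()) / sigma) ** 2))
    r2 = 1.0 - chi / sst if sst > 0 else -np.inf
    dof = n_bins - n_par
    adj_r2 = 1.0 - (1.0 - r2) * (n_bins - 1) / dof if dof > 0 else -np.inf
    return MixtureFit(
        y0=y0,
        components=comps,
        chi_square=chi,
        reduced_chi_square=chi / dof if dof > 0 else np.inf,
        sse=sse,
        adjusted_r2=adj_r2,
        converged=bool(result.success),
        message="" if result.success else str(result.message),
        histogram=histogram,
    )


def _warm_init(fit: MixtureFit, histogram: DensityHistogram):
    """Previous fit's components plus a negligible extra one at the worst bin."""
    resid = histogram.density - fit.model(histogram.centers)
    idx = int(np.argmax(resid))
    extra = GaussianComponent(
        area=1e-8, width=2.0 * histogram.bin_width, center=float(histogram.centers[idx])
    )
    return fit.y0, list(fit.components) + [extra]


def select_model(
    histogram: DensityHistogram,
    max_k: int = 4,
    alpha: float = 0.01,
    min_fraction: float = 0.01,
) -> Tuple[MixtureFit, List[MixtureFit]]:
    """Fit k = 1..max_k Gaussians and pick the accepted component count.

    Each k > 1 is fitted both fresh and warm-started from the previous fit
    (previous components plus a negligible new one), keeping the better
    chi-square, which makes the chi-square trail non-increasing in k.

    A richer fit is accepted over the current one when its chi-square drop is
    statistically significant by the partial F-test for nested least-squares
    models at level ``alpha`` (three extra parameters always absorb some
    residual noise, so the drop must beat the cost of the added parameters -
    the same judgement as monitoring the adjusted r-square for "no further
    improvement") and when no component of the richer fit holds less than
    ``min_fraction`` of the total area.  All probed fits are returned as the
    trail, including rejected ones (the four-component probe is always run).
    """
    from scipy import stats as _stats

    trail: List[MixtureFit] = []
    prev: Optional[MixtureFit] = None
    for k in range(1, max_k + 1):
        candidates = [fit_gauss_sum(histogram, k)]
        if prev is not None and prev.converged:
            candidates.append(fit_gauss_sum(histogram, k, init=_warm_init(prev, histogram)))
        best = min(candidates, key=lambda f: f.chi_square)
        trail.append(best)
        prev = best

    n_bins = histogram.centers.size
    accepted = trail[0]
    for fit in trail[1:]:
        if not fit.converged:
            continue
        d_par = 3 * (fit.k - accepted.k)
        dof = n_bins - (1 + 3 * fit.k)
        if dof < 1 or fit.chi_square >= accepted.chi_square:
            continue
        if fit.chi_square <= 0:
            p_value = 0.0
        else:
            f_stat = ((accepted.chi_square - fit.chi_square) / d_par) / (fit.chi_square / dof)
            p_value = float(_stats.f.sf(f_stat, d_par, dof))
        fracs = component_fractions(fit)
        if p_value < alpha and bool(np.all(fracs >= min_fraction)):
            accepted = fit
    return accepted, trail


def component_fractions(fit: MixtureFit) -> np.ndarray:
    """Component areas as fractions of the total area (sum to 1)."""
    areas = np.array([c.area for c in fit.components], dtype=float)
    return areas / areas.sum()


# ---------------------------------------------------------------------------
# Size classes
# ---------------------------------------------------------------------------

def _pair_cutoff(c1: GaussianComponent, c2: GaussianComponent) -> float:
    """Crossing point of two scaled component densities between their centers."""
    if c1.center == c2.center:
        raise ValueError("components have identical centers; no cutoff exists")
    lo, hi = sorted((c1.center, c2.center))
    a1, a2 = 2.0 / c1.width**2, 2.0 / c2.width**2
    # log equality: ln(A1/w1) - a1 (x-c1)^2 = ln(A2/w2) - a2 (x-c2)^2
    const = np.log((c1.area / c1.width) / (c2.area / c2.width))
    A = a2 - a1
    B = -2.0 * (a2 * c2.center - a1 * c1.center)
    C = a2 * c2.center**2 - a1 * c1.center**2 + const
    if abs(A) < 1e-300:
        if B == 0:
            roots = np.array([])
        else:
            roots = np.array([-C / B])
    else:
        disc = B * B - 4.0 * A * C
        roots = (
            np.array([])
            if disc < 0
            else np.array([(-B - np.sqrt(disc)) / (2 * A), (-B + np.sqrt(disc)) / (2 * A)])
        )
    inside = [r for r in roots if lo < r < hi]
    if inside:
        return float(min(inside, key=lambda r: abs(r - 0.5 * (lo + hi))))
    warnings.warn(
        "component densities do not cross between centers "
        f"({c1.center:.3g}, {c2.center:.3g}); using the midpoint",
        stacklevel=2,
    )
    return 0.5 * (c1.center + c2.center)


def size_cutoffs(fit: MixtureFit) -> np.ndarray:
    """Cutoffs between adjacent components (k - 1 ascending values).

    Each cutoff is the crossing point of the two adjacent offset-free
    component densities between their centers, i.e. the value at which a
    sample becomes more likely to come from the larger population.
    """
    if fit.k < 2:
        raise ValueError("cutoffs need at least 2 components")
    comps = sorted(fit.components, key=lambda c: c.center)
    return np.array([_pair_cutoff(a, b) for a, b in zip(comps[:-1], comps[1:])])


_DEFAULT_LABELS = {2: ["small", "large"], 3: ["small", "medium", "large"]}


def classify_sizes(
    values: Sequence[float],
    cutoffs: Sequence[float],
    strata: Optional[Sequence] = None,
    use_magnitude: bool = False,
    labels: Optional[Sequence[str]] = None,
    stratum_order: Optional[Sequence] = None,
):
    """Assign each value to a size class and report per-class proportions.

    ``value < c1`` is the smallest class, ``c1 <= value < c2`` the next, and
    so on.  For negative-going amplitude data pass ``use_magnitude=True``:
    both the values and the cutoffs (fitted on the negative axis) are mapped
    to magnitudes, so "large" means large magnitude.  With ``strata`` (e.g.
    soma/dendrite
    compartment tags) proportions are reported per stratum; an empty stratum
    yields NaN proportions, not zeros.

    Returns
    -------
    (labels, proportions)
        Per-value class labels (list of str) and a pandas Series (or
        DataFrame when stratified, rows = strata) of proportions per class.
    """
    v = np.asarray(values, dtype=float)
    cut = np.asarray(cutoffs, dtype=float)
    if use_magnitude:
        v = np.abs(v)
        cut = np.abs(cut)
    cut = np.sort(cut)
    n_classes = cut.size + 1
    if labels is None:
        labels = _DEFAULT_LABELS.get(n_classes, [f"class_{i}" for i in range(n_classes)])
    labels = list(labels)
    if len(labels) != n_classes:
        raise ValueError(f"need {n_classes} labels, got {len(labels)}")
    idx = np.digitize(v, cut, right=False)
    assigned = [labels[i] for i in idx]

    if strata is None:
        if v.size == 0:
            props = pd.Series(np.nan, index=labels)
        else:
            counts = pd.Series(assigned).value_counts()
            props = counts.reindex(labels).fillna(0.0) / v.size
        return assigned, props

    df = pd.DataFrame({"label": assigned, "stratum": list(strata)})
    all_strata = list(stratum_order) if stratum_order is not None else list(pd.unique(df["stratum"]))
    table = (
        df.groupby("stratum")["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=labels, fill_value=0.0)
        .reindex(index=all_strata)  # strata with no values -> NaN rows, not 0
    )
    return assigned, table
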