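"""Single-molecule TIRF photobleaching stoichiometry.

Surface-tethered RNA molecules carrying GFP-tagged protein are imaged until
every fluorophore bleaches.  Because complexes with zero bound proteins are
invisible, the number of bleaching steps per complex follows a *truncated*
binomial law::

    P(i | n, theta) = C(n, i) theta^i (1 - theta)^(n - i) / (1 - (1 - theta)^n),
    i = 1..n

where ``n`` is the number of specific binding sites on the RNA and ``theta``
the fractional occupancy of a site.  Three estimators of ``n`` are provided,
mirroring the standard repertoire of subunit-counting analyses:

1. :class:`TruncatedBinomialModel` — Pearson chi-square fit of the
   step-count histogram over candidate ``n`` (default 2..8), minimising over
   ``theta`` for each candidate.
2. :class:`LinearizationModel` — for binomial counts the quantity
   ``i * P_i / P_(i-1)`` is linear in ``i`` with slope ``-theta/(1-theta)``
   and intercept ``(n+1) * theta/(1-theta)``; an ordinary least-squares line
   through those points yields ``n`` and ``theta`` in closed form.
3. :class:`EmissionMixtureModel` — the total emission of a complex carrying
   ``i`` fluorophores of exponentially distributed individual emission is
   Erlang(``i``); the empirical cumulative distribution of total emissions is
   fitted by the truncated-binomial-weighted Erlang mixture CDF.

All three follow the Model/Results idiom: construct the model from data,
call :meth:`fit`, inspect the returned results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.spatial import cKDTree

from .exceptions import (
    DomainError,
    InsufficientDataError,
    NonBinomialShapeError,
)

__all__ = [
    "IntensityTrace",
    "StepCountHistogram",
    "SpotSet",
    "truncated_binomial_pmf",
    "count_bleach_steps",
    "total_emission",
    "TruncatedBinomialModel",
    "TruncatedBinomialResults",
    "LinearizationModel",
    "LinearizationResults",
    "SingleStepEmissionFit",
    "EmissionMixtureModel",
    "EmissionMixtureResults",
    "fit_truncated_binomial",
    "linearization_fit",
    "fit_single_step_emission",
    "fit_emission_mixture",
    "colocalization_fraction",
]

#: Number of acquisition bins recorded in the RNA-dye channel before the GFP
#: channel is switched on; GFP analysis uses bins at or after this index.
DEFAULT_DYE_BINS = 30


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class IntensityTrace:
    """Background-corrected intensity time series for one complex.

    Parameters
    ----------
    complex_id : str
        Identifier of the surface-tethered complex.
    intensities : ndarray
        Per-bin intensity, arbitrary units; may dip below zero after
        background correction.
    bin_ms : float
        Bin duration in milliseconds (200 ms in the reference acquisition
        protocol: 500 bins of 200 ms).
    """

    complex_id: str
    intensities: np.ndarray
    bin_ms: float = 200.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise DomainError("trace must be a 1-D series with >= 2 bins")
        if not self.bin_ms > 0:
            raise DomainError("bin_ms must be positive")

    def gfp_segment(self, dye_bins: int = DEFAULT_DYE_BINS) -> np.ndarray:
        """Bins after the dye pre-acquisition window."""
        if dye_bins < 0 or self.intensities.size - dye_bins < 2:
            raise InsufficientDataError(
                f"trace of {self.intensities.size} bins has no usable GFP "
                f"segment after a {dye_bins}-bin dye window"
            )
        return self.intensities[dye_bins:]


@dataclass
class StepCountHistogram:
    """Occurrences of i = 1, 2, ... photobleaching steps over N complexes."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        cleaned: dict[int, int] = {}
        for i, c in self.counts.items():
            i, c = int(i), int(c)
            if i < 1:
                raise DomainError("step counts start at i = 1 (zero-step complexes are invisible)")
            if c < 0:
                raise DomainError("occurrences must be non-negative")
            if c:
                cleaned[i] = cleaned.get(i, 0) + c
        self.counts = dict(sorted(cleaned.items()))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def max_steps(self) -> int:
        if not self.counts:
            raise InsufficientDataError("empty step-count histogram")
        return max(self.counts)

    def as_vector(self, n: int) -> np.ndarray:
        """Observed counts as a dense vector over i = 1..n."""
        v = np.zeros(n, dtype=float)
        for i, c in self.counts.items():
            if i <= n:
                v[i - 1] = c
        return v

    @classmethod
    def from_step_counts(cls, steps) -> "StepCountHistogram":
        """Build from per-complex step counts, dropping zero-step entries."""
        vals, cnts = np.unique(np.asarray(steps, dtype=int), return_counts=True)
        return cls({int(i): int(c) for i, c in zip(vals, cnts) if i >= 1})


@dataclass
class SpotSet:
    """Detected spot coordinates from one imaging channel."""

    coordinates: np.ndarray
    channel: str = "GFP"

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.size and self.coordinates.shape[1] != 2:
            raise DomainError("coordinates must be (x, y) pairs")
        if self.coordinates.size and not np.all(np.isfinite(self.coordinates)):
            raise DomainError("spot coordinates must be finite")


# ---------------------------------------------------------------------------
# Truncated binomial pmf
# ---------------------------------------------------------------------------

def truncated_binomial_pmf(n: int, theta: float) -> np.ndarray:
    """Probability of observing i = 1..n bound fluorophores.

    Binomial(n, theta) conditioned on at least one success; complexes with
    no bound protein carry no GFP and are never selected for analysis.
    """
    if n < 1:
        raise DomainError(f"number of sites must be >= 1, got {n}")
    if not 0.0 < theta < 1.0:
        raise DomainError(f"occupancy must lie strictly in (0, 1), got {theta}")
    i = np.arange(1, n + 1)
    pmf = stats.binom.pmf(i, n, theta)
    return pmf / (1.0 - (1.0 - theta) ** n)


# ---------------------------------------------------------------------------
# Step detection
# ---------------------------------------------------------------------------

def _robust_noise_sd(y: np.ndarray) -> float:
    # MAD of first differences; /sqrt(2) because differencing doubles the
    # variance, 0.6745 converts MAD to sigma for Gaussian noise.
    d = np.diff(y)
    return float(np.median(np.abs(d - np.median(d))) / (0.6745 * np.sqrt(2.0)))


def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Best single changepoint of a piecewise-constant fit.

    Returns (index, sse_reduction): splitting y into y[:index], y[index:].
    """
    T = y.size
    c1 = np.cumsum(y)
    c2 = np.cumsum(y * y)
    total = c2[-1] - c1[-1] ** 2 / T
    k = np.arange(1, T)
    left = c2[k - 1] - c1[k - 1] ** 2 / k
    right = (c2[-1] - c2[k - 1]) - (c1[-1] - c1[k - 1]) ** 2 / (T - k)
    sse = left + right
    j = int(np.argmin(sse))
    return j + 1, float(total - sse[j])


def _segment(y: np.ndarray, penalty: float, min_size: int = 1) -> list[int]:
    """Binary segmentation: changepoint indices (split positions) of y."""
    out: list[int] = []
    stack = [(0, y.size)]
    while stack:
        a, b = stack.pop()
        if b - a < 2 * min_size:
            continue
        j, gain = _best_split(y[a:b])
        if gain > penalty and min_size <= j <= (b - a) - min_size:
            out.append(a + j)
            stack.append((a, a + j))
            stack.append((a + j, b))
    return sorted(out)


def count_bleach_steps(
    trace: IntensityTrace,
    dye_bins: int = DEFAULT_DYE_BINS,
    k_sigma: float = 3.0,
    penalty_scale: float = 3.0,
    resolve_multiplicity: bool = True,
) -> int:
    """Count downward photobleaching steps in the GFP segment of a trace.

    The segment is segmented into piecewise-constant levels by penalised
    least-squares binary segmentation (penalty ``penalty_scale * sigma^2 *
    log T`` per changepoint, with ``sigma`` a robust noise estimate from
    first differences).  Downward level changes exceeding ``k_sigma * sigma``
    are counted as bleaching steps.  When ``resolve_multiplicity`` is set,
    the unit step height is estimated as the median of the smallest cluster
    of significant drops (within 1.5x of the minimum) and each drop
    contributes ``round(drop / unit)`` steps, so two fluorophores bleaching
    within the same bin are still counted as two.

    Deterministic for fixed parameters.
    """
    y = trace.gfp_segment(dye_bins)
    sigma = _robust_noise_sd(y)
    penalty = penalty_scale * sigma * sigma * np.log(y.size)
    cps = _segment(y, penalty)
    bounds = [0, *cps, y.size]
    levels = np.array(
        [float(np.mean(y[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
    )
    drops = -np.diff(levels)
    threshold = k_sigma * sigma
    sig = drops[drops > threshold]
    if sig.size == 0:
        return 0
    if not resolve_multiplicity:
        return int(sig.size)
    unit = float(np.median(sig[sig <= 1.5 * sig.min()]))
    if unit <= 0:
        return int(sig.size)
    return int(np.sum(np.maximum(1, np.rint(sig / unit)).astype(int)))


def total_emission(trace: IntensityTrace, dye_bins: int = DEFAULT_DYE_BINS) -> float:
    """Sum of background-corrected GFP-segment intensities for one complex."""
    return float(np.sum(trace.gfp_segment(dye_bins)))


# ---------------------------------------------------------------------------
# Chi-square fit of the step-count histogram
# ---------------------------------------------------------------------------

_THETA_LO, _THETA_HI = 1e-3, 1.0 - 1e-3


def _pearson_chisq(observed: np.ndarray, expected: np.ndarray) -> float:
    """Pearson chi-square with the sparse tail pooled into one cell.

    The contiguous run of largest-i cells whose expected count falls below 1
    is merged with the preceding cell, avoiding division blow-ups from a
    sparse tail.  Only tail cells are pooled, and never below two cells in
    total: pooling a *head* cell (low expectation but possibly large
    observed count) would let a parameter value hide gross disagreement
    inside the pooled cell, and a fully pooled table has no degrees of
    freedom left.
    """
    n = expected.size
    j = n
    while j > 1 and expected[j - 1] < 1.0:
        j -= 1
    start = max(j - 1, 1)  # merged cell never swallows the first cell
    if start < n - 1:
        obs = np.append(observed[:start], observed[start:].sum())
        exp = np.append(expected[:start], expected[start:].sum())
    else:
        obs, exp = observed, expected
    return float(np.sum((obs - exp) ** 2 / exp))


@dataclass
class TruncatedBinomialResults:
    """Chi-square estimate of site number and occupancy.

    Attributes
    ----------
    n_hat : int
        Candidate site number with minimal chi-square.
    theta_hat : float
        Occupancy minimising chi-square at ``n_hat``.
    chisq : float
        The minimised chi-square at (``n_hat``, ``theta_hat``).
    chisq_profile : dict
        Candidate n -> minimised chi-square.
    theta_profile : dict
        Candidate n -> argmin theta.
    """

    n_hat: int
    theta_hat: float
    chisq: float
    chisq_profile: dict[int, float]
    theta_profile: dict[int, float]
    n_obs: int
    method: str = "chisq"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_hat": self.n_hat,
            "theta_hat": self.theta_hat,
            "chisq": self.chisq,
            "chisq_profile": {str(k): v for k, v in self.chisq_profile.items()},
            "n_complexes": self.n_obs,
        }

    def summary(self) -> str:
        lines = [
            "Truncated-binomial chi-square fit",
            f"  complexes analysed : {self.n_obs}",
            f"  sites n̂           : {self.n_hat}",
            f"  occupancy θ̂       : {self.theta_hat:.3f}",
            f"  min chi-square     : {self.chisq:.4g}",
            "  chi-square profile :",
        ]
        for n, c in sorted(self.chisq_profile.items()):
            marker = " <-- min" if n == self.n_hat else ""
            lines.append(f"    n = {n}: chi2 = {c:.4g} (theta = {self.theta_profile[n]:.3f}){marker}")
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Chi-square versus candidate site number."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ns = sorted(self.chisq_profile)
        ax.plot(ns, [self.chisq_profile[n] for n in ns], "o-")
        ax.axvline(self.n_hat, ls="--", color="grey")
        ax.set_xlabel("candidate number of sites n")
        ax.set_ylabel(r"min$_\theta$ $\chi^2$")
        return ax


class TruncatedBinomialModel:
    """Fit a step-count histogram by the truncated binomial distribution.

    For each candidate site number n the Pearson chi-square between observed
    occurrences and ``N * pmf(i | n, theta)`` is minimised over the occupancy
    theta; the n giving the overall minimum is the site-number estimate.

    Parameters
    ----------
    hist : StepCountHistogram
    n_range : iterable of int, default 2..8
        Candidate site numbers.
    """

    def __init__(self, hist: StepCountHistogram, n_range=range(2, 9)):
        if hist.total < 1:
            raise InsufficientDataError("empty step-count histogram")
        self.hist = hist
        self.n_range = sorted(int(n) for n in n_range)
        if not self.n_range:
            raise DomainError("empty candidate range for n")

    def _chisq_at(self, n: int, theta: float) -> float:
        expected = self.hist.total * truncated_binomial_pmf(n, theta)
        return _pearson_chisq(self.hist.as_vector(n), expected)

    def fit(self, grid_points: int = 199) -> TruncatedBinomialResults:
        max_i = self.hist.max_steps
        candidates = [n for n in self.n_range if n >= max_i]
        if not candidates:
            raise DomainError(
                f"observed up to {max_i} steps but all candidate n are smaller"
            )
        chisq_profile: dict[int, float] = {}
        theta_profile: dict[int, float] = {}
        grid = np.linspace(_THETA_LO, _THETA_HI, grid_points)
        for n in candidates:
            coarse = [self._chisq_at(n, t) for t in grid]
            j = int(np.argmin(coarse))
            lo = grid[max(j - 1, 0)]
            hi = grid[min(j + 1, grid.size - 1)]
            res = optimize.minimize_scalar(
                lambda t: self._chisq_at(n, t),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            best = min(float(res.fun), coarse[j])
            theta = float(res.x) if res.fun <= coarse[j] else float(grid[j])
            chisq_profile[n] = best
            theta_profile[n] = theta
        # parsimony tie-break: smallest n among chi-square minima within 1e-9
        cmin = min(chisq_profile.values())
        n_hat = min(n for n, c in chisq_profile.items() if c <= cmin + 1e-9)
        return TruncatedBinomialResults(
            n_hat=n_hat,
            theta_hat=theta_profile[n_hat],
            chisq=chisq_profile[n_hat],
            chisq_profile=chisq_profile,
            theta_profile=theta_profile,
            n_obs=self.hist.total,
        )


def fit_truncated_binomial(hist: StepCountHistogram, n_range=range(2, 9)) -> TruncatedBinomialResults:
    """Convenience wrapper: ``TruncatedBinomialModel(hist, n_range).fit()``."""
    return TruncatedBinomialModel(hist, n_range).fit()


# ---------------------------------------------------------------------------
# Linearization estimator
# ---------------------------------------------------------------------------

@dataclass
class LinearizationResults:
    """Line fit of i*P_i/P_(i-1) versus i.

    For exact binomial proportions the identity
    ``i P_i / P_(i-1) = (n + 1) theta/(1-theta) - i theta/(1-theta)``
    holds, so slope s and intercept b give ``theta = -s/(1-s)`` and
    ``n = -b/s - 1``.
    """

    points: list[tuple[int, float]]
    slope: float
    intercept: float
    n_hat: int
    n_raw: float
    theta_hat: float
    method: str = "linearization"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_hat": self.n_hat,
            "n_raw": self.n_raw,
            "theta_hat": self.theta_hat,
            "slope": self.slope,
            "intercept": self.intercept,
            "points": [[i, y] for i, y in self.points],
        }

    def summary(self) -> str:
        pts = ", ".join(f"({i}, {y:.3f})" for i, y in self.points)
        return (
            "Linearization fit of i*P_i/P_(i-1) vs i\n"
            f"  points    : {pts}\n"
            f"  slope     : {self.slope:.4f}\n"
            f"  intercept : {self.intercept:.4f}\n"
            f"  sites n̂  : {self.n_hat} (raw {self.n_raw:.2f})\n"
            f"  occupancy θ̂ : {self.theta_hat:.3f}"
        )

    def plot(self, ax=None):
        """The ratio points and the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = [p[0] for p in self.points]
        ax.plot(x, [p[1] for p in self.points], "o")
        xs = np.linspace(min(x) - 0.5, max(x) + 0.5, 2)
        ax.plot(xs, self.intercept + self.slope * xs, "-")
        ax.set_xlabel("number of bleaching steps i")
        ax.set_ylabel(r"$i\,P_i/P_{i-1}$")
        return ax


class LinearizationModel:
    """Closed-form site-number estimator from successive occurrence ratios.

    Uses only i >= 2 (the zero-step occurrence is unobservable) and requires
    both P_i and P_(i-1) to be positive.  The line is fitted by unweighted
    ordinary least squares.
    """

    def __init__(self, hist: StepCountHistogram):
        self.hist = hist
        pts = []
        for i in sorted(hist.counts):
            if i >= 2 and hist.counts.get(i, 0) > 0 and hist.counts.get(i - 1, 0) > 0:
                pts.append((i, i * hist.counts[i] / hist.counts[i - 1]))
        self.points = pts

    def fit(self) -> LinearizationResults:
        if len(self.points) < 2:
            raise InsufficientDataError(
                f"need >= 2 eligible (i, i*P_i/P_(i-1)) points, got {len(self.points)}"
            )
        x = np.array([p[0] for p in self.points], dtype=float)
        y = np.array([p[1] for p in self.points], dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            raise NonBinomialShapeError(
                "non-negative slope: occurrence ratios do not decrease with i "
                "as a binomial occupancy model requires"
            )
        theta_hat = -slope / (1.0 - slope)
        n_raw = -intercept / slope - 1.0
        return LinearizationResults(
            points=self.points,
            slope=float(slope),
            intercept=float(intercept),
            n_hat=int(round(n_raw)),
            n_raw=float(n_raw),
            theta_hat=float(theta_hat),
        )


def linearization_fit(hist: StepCountHistogram) -> LinearizationResults:
    """Convenience wrapper: ``LinearizationModel(hist).fit()``."""
    return LinearizationModel(hist).fit()


# ---------------------------------------------------------------------------
# Emission-distribution estimators
# ---------------------------------------------------------------------------

def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.sort(values)
    p = (np.arange(1, x.size + 1) - 0.5) / x.size
    return x, p


@dataclass
class SingleStepEmissionFit:
    """Exponential CDF fit to total emissions of one-step complexes."""

    mu_hat: float
    sse: float
    n_obs: int
    #: mean squared CDF residual above 0.01 marks a distribution that is not
    #: credibly exponential (e.g. degenerate or heavily censored data)
    poor_fit: bool

    def summary(self) -> str:
        flag = "  [WARNING: poor fit — data not well described by an exponential]" if self.poor_fit else ""
        return (
            f"Single-fluorophore emission fit (n = {self.n_obs}): "
            f"mu = {self.mu_hat:.4g}, sse = {self.sse:.3g}{flag}"
        )


def fit_single_step_emission(emissions, min_obs: int = 10) -> SingleStepEmissionFit:
    """Estimate the mean total emission of a single fluorophore.

    Least-squares fit of the empirical cumulative distribution of one-step
    complex emissions to ``1 - exp(-x / mu)``.  Non-positive values are
    discarded before fitting (background correction can push a few below
    zero).
    """
    values = np.asarray(list(emissions), dtype=float)
    values = values[values > 0]
    if values.size < min_obs:
        raise InsufficientDataError(
            f"need >= {min_obs} positive emissions, got {values.size}"
        )
    x, p = _ecdf(values)

    def sse(mu: float) -> float:
        return float(np.sum((p - (1.0 - np.exp(-x / mu))) ** 2))

    mean = float(np.mean(x))
    res = optimize.minimize_scalar(
        sse, bounds=(mean / 20.0, mean * 20.0), method="bounded",
        options={"xatol": 1e-8 * mean},
    )
    mu_hat = float(res.x)
    final = sse(mu_hat)
    return SingleStepEmissionFit(
        mu_hat=mu_hat,
        sse=final,
        n_obs=int(values.size),
        poor_fit=bool(final / values.size > 0.01),
    )


@dataclass
class EmissionMixtureResults:
    """Erlang-mixture CDF fit of the full emission distribution."""

    n_hat: int
    mu_hat: float
    theta_used: float
    sse: float
    sse_profile: dict[int, float]
    mu_profile: dict[int, float]
    n_obs: int
    method: str = "emission"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_hat": self.n_hat,
            "mu_hat": self.mu_hat,
            "theta_used": self.theta_used,
            "sse": self.sse,
            "sse_profile": {str(k): v for k, v in self.sse_profile.items()},
            "n_emissions": self.n_obs,
        }

    def summary(self) -> str:
        lines = [
            "Erlang-mixture emission fit",
            f"  emissions analysed : {self.n_obs}",
            f"  occupancy used     : {self.theta_used:.3f}",
            f"  sites n̂           : {self.n_hat}",
            f"  single-GFP mean μ̂ : {self.mu_hat:.4g}",
            f"  SSE                : {self.sse:.4g}",
        ]
        return "\n".join(lines)


class EmissionMixtureModel:
    """Fit total-emission data by a truncated-binomial Erlang mixture.

    A complex with i bound fluorophores emits the sum of i independent
    exponential totals, i.e. an Erlang(i) variate with mean ``i * mu``.  The
    model CDF is ``F(x) = sum_i w_i(n, theta) ErlangCDF(x; i, mu)`` with
    truncated-binomial weights; n is chosen to minimise the sum of squared
    deviations from the empirical CDF.  The occupancy is taken from the
    bleaching-step analysis; mu is refined around the single-step estimate.
    """

    def __init__(self, emissions, theta: float, mu: float, n_range=range(1, 9)):
        self.emissions = np.asarray(list(emissions), dtype=float)
        self.emissions = self.emissions[self.emissions > 0]
        if self.emissions.size == 0:
            raise InsufficientDataError("no positive emissions to fit")
        if not 0.0 < theta < 1.0:
            raise DomainError(f"occupancy must lie in (0, 1), got {theta}")
        if not mu > 0:
            raise DomainError(f"mean single-fluorophore emission must be positive, got {mu}")
        self.theta = float(theta)
        self.mu0 = float(mu)
        self.n_range = sorted(int(n) for n in n_range)
        if not self.n_range or self.n_range[0] < 1:
            raise DomainError("candidate n must be >= 1")

    def _sse(self, n: int, mu: float, x: np.ndarray, p: np.ndarray) -> float:
        w = truncated_binomial_pmf(n, self.theta)
        F = np.zeros_like(x)
        for i, wi in enumerate(w, start=1):
            F += wi * stats.gamma.cdf(x, a=i, scale=mu)
        return float(np.sum((p - F) ** 2))

    def fit(self, refine_mu: bool = True) -> EmissionMixtureResults:
        x, p = _ecdf(self.emissions)
        sse_profile: dict[int, float] = {}
        mu_profile: dict[int, float] = {}
        for n in self.n_range:
            if refine_mu:
                res = optimize.minimize_scalar(
                    lambda m: self._sse(n, m, x, p),
                    bounds=(self.mu0 / 3.0, self.mu0 * 3.0),
                    method="bounded",
                    options={"xatol": 1e-6 * self.mu0},
                )
                mu_profile[n] = float(res.x)
                sse_profile[n] = float(res.fun)
            else:
                mu_profile[n] = self.mu0
                sse_profile[n] = self._sse(n, self.mu0, x, p)
        smin = min(sse_profile.values())
        n_hat = min(n for n, s in sse_profile.items() if s <= smin * (1 + 1e-9))
        return EmissionMixtureResults(
            n_hat=n_hat,
            mu_hat=mu_profile[n_hat],
            theta_used=self.theta,
            sse=sse_profile[n_hat],
            sse_profile=sse_profile,
            mu_profile=mu_profile,
            n_obs=int(self.emissions.size),
        )


def fit_emission_mixture(emissions, theta: float, mu: float, n_range=range(1, 9)) -> EmissionMixtureResults:
    """Convenience wrapper: ``EmissionMixtureModel(...).fit()``."""
    return EmissionMixtureModel(emissions, theta, mu, n_range).fit()


# ---------------------------------------------------------------------------
# Colocalization
# ---------------------------------------------------------------------------

def colocalization_fraction(rna: SpotSet, gfp: SpotSet, radius_px: float) -> float:
    """Fraction of RNA-channel spots with a GFP-channel partner within radius.

    Pairs are matched greedily by increasing distance; each GFP spot is used
    at most once.
    """
    if radius_px <= 0:
        raise DomainError("radius must be positive")
    n_rna = rna.coordinates.shape[0] if rna.coordinates.size else 0
    if n_rna == 0:
        raise InsufficientDataError("empty RNA spot set")
    n_gfp = gfp.coordinates.shape[0] if gfp.coordinates.size else 0
    if n_gfp == 0:
        return 0.0
    tree = cKDTree(gfp.coordinates)
    pairs = []
    for ri, coord in enumerate(rna.coordinates):
        for gi in tree.query_ball_point(coord, radius_px):
            d = float(np.hypot(*(coord - gfp.coordinates[gi])))
            pairs.append((d, ri, gi))
    pairs.sort()
    used_rna: set[int] = set()
    used_gfp: set[int] = set()
    for _, ri, gi in pairs:
        if ri in used_rna or gi in used_gfp:
            continue
        used_rna.add(ri)
        used_gfp.add(gi)
    return len(used_rna) / n_rna
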