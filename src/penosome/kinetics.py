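"""Autocatalytic rate extraction from fluorescence kinetic profiles.

The procedure mirrors how PEN DNA autocatalysis is quantified from EvaGreen
time series.  The logistic model

    A(x) = L / (1 + exp(k (x - x0)))

is fit to the early part of the curve only, because product inhibition and
substrate degradation make the late phase depart from exponential growth.
As printed, the model is a decreasing sigmoid for k > 0, so growth curves fit
with k < 0; the reported rate is |k|.

The fit window [0, t_f] is found from the data themselves: the discrete
differences of the signal between consecutive time points peak at the
inflection; a Gaussian a1*exp(-((x-b1)/c1)^2) fit to the difference series
gives the "midpoint to decay"

    t_f = b1 + c1 * sqrt(ln(a1 / f)),   f = a1/2 by default,

i.e. the positive-side time where the growth increment has fallen to half its
maximum.  When the Gaussian step fails (flat trace, truncated growth) a fixed
fallback window is used instead and recorded as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import warnings

import numpy as np
from scipy import optimize, stats


def _curve_fit(f, x, y, p0, **kw):
    """curve_fit without the covariance warning (we never use the covariance)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, _ = optimize.curve_fit(f, x, y, p0=p0, **kw)
    return popt

from .errors import ConfigError, NormalizationError, NumericalError, WindowError
from .traces import KineticTrace, common_grid


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class GaussianDiffFit:
    a1: float
    b1: float
    c1: float
    converged: bool
    f_half: float = 0.0

    def __post_init__(self):
        self.f_half = self.a1 / 2.0 if np.isfinite(self.a1) else 0.0


@dataclass
class LogisticFit:
    L: float
    k: float              # signed, as printed (negative for growth)
    x0: float
    t_f: float
    rate: float           # |k| (min^-1), or |k|*L/4 in slope mode
    window_source: Literal["gaussian", "fallback"]
    rate_mode: Literal["k", "slope"] = "k"
    quality: float = np.nan   # RMS residual over the fit window
    no_growth: bool = False


RateEstimate = LogisticFit


@dataclass
class LinearRateFit:
    slope: float
    intercept: float
    stderr_slope: float
    r_squared: float


@dataclass
class PopulationSummary:
    n: int
    median: float
    q1: float
    q3: float
    lower_adjacent: float
    upper_adjacent: float
    outside_points: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def normalize_trace(trace: KineticTrace, mode: str = "minmax",
                    t_ref: float | None = None) -> KineticTrace:
    """Normalize a trace either to its value at a reference time
    (``to_point``) or to the [baseline, plateau] -> [0, 1] range
    (``minmax``, baseline = mean of the first 5 samples, plateau = max)."""
    A = trace.A
    if mode == "to_point":
        if t_ref is None:
            raise ConfigError("to_point normalization needs t_ref")
        ref = A[int(np.argmin(np.abs(trace.t - t_ref)))]
        if ref <= 0:
            raise NormalizationError("reference value must be > 0")
        return trace.with_signal(A / ref, normalized=True)
    if mode == "minmax":
        # baseline window: first 5 samples, shrunk for very short traces
        nb = min(5, max(1, len(A) // 5))
        base = float(np.mean(A[:nb]))
        top = float(np.max(A))
        if top <= base:
            raise NormalizationError("max must exceed baseline for minmax")
        return trace.with_signal((A - base) / (top - base), normalized=True)
    raise ConfigError(f"unknown normalization mode {mode!r}")


def difference_series(trace: KineticTrace) -> tuple[np.ndarray, np.ndarray]:
    """Discrete differences Delta_i = A_{i+1} - A_i at interval midpoints."""
    if len(trace) < 3:
        raise ConfigError("difference series needs >= 3 samples")
    d = np.diff(trace.A)
    tm = 0.5 * (trace.t[:-1] + trace.t[1:])
    return tm, d


def _mad_sigma(x: np.ndarray) -> float:
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _smooth_and_floor(A: np.ndarray) -> tuple[np.ndarray, float]:
    """5-point moving average and a MAD-based noise floor (with a tiny
    relative floor so noiseless data do not divide by zero)."""
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(A, kernel, mode="same")
    smooth[:2] = smooth[2]
    smooth[-2:] = smooth[-3]
    noise = _mad_sigma(A - smooth)
    floor = max(noise, 1e-9 * max(float(np.max(np.abs(A))), 1.0))
    return smooth, floor


def _rise_above_start(A: np.ndarray) -> tuple[float, float]:
    """Growth excursion above the starting signal, and the noise floor.

    A switched-off compartment whose pre-loaded primer signal only decays has
    zero rise even though its total excursion is large; "growth" means the
    signal climbs above where it started.
    """
    smooth, floor = _smooth_and_floor(A)
    start = max(float(A[0]), float(smooth[0]))
    return float(smooth.max() - start), floor


def fit_gaussian_difference(t_mid: np.ndarray, d: np.ndarray) -> GaussianDiffFit:
    """Least-squares Gaussian fit to the difference series.

    ``converged`` is False when the solver fails or when the fitted amplitude
    does not clear twice the MAD-based noise level of the series (scale-free
    no-growth criterion).
    """
    t_mid = np.asarray(t_mid, float)
    d = np.asarray(d, float)
    if d.size < 3 or np.max(d) <= 0:
        return GaussianDiffFit(np.nan, np.nan, np.nan, converged=False)
    a0 = float(np.max(d))
    b0 = float(t_mid[np.argmax(d)])
    c0 = float((t_mid[-1] - t_mid[0]) / 8.0) or 1.0

    def model(x, a1, b1, c1):
        return a1 * np.exp(-(((x - b1) / c1) ** 2))

    try:
        popt = _curve_fit(model, t_mid, d, p0=[a0, b0, c0], maxfev=20000)
    except (RuntimeError, ValueError):
        return GaussianDiffFit(np.nan, np.nan, np.nan, converged=False)
    a1, b1, c1 = popt
    c1 = abs(c1)
    noise = _mad_sigma(d - model(t_mid, a1, b1, c1))
    ok = (a1 > 0 and c1 > 0 and np.isfinite([a1, b1, c1]).all()
          and a1 > 2.0 * noise)
    return GaussianDiffFit(float(a1), float(b1), float(c1), converged=bool(ok))


def midpoint_to_decay(fit: GaussianDiffFit, f: float | None = None) -> float:
    """Positive-side time where the Gaussian falls to f (default a1/2):
    t_f = b1 + c1*sqrt(ln(a1/f)).  Natural log, forced by inverting the
    Gaussian's exponential."""
    if not fit.converged:
        raise NumericalError("cannot invert an unconverged Gaussian fit")
    if f is None:
        f = fit.a1 / 2.0
    if not (0 < f <= fit.a1):
        raise ConfigError("threshold f must satisfy 0 < f <= a1")
    return float(fit.b1 + fit.c1 * np.sqrt(np.log(fit.a1 / f)))


def _logistic(x, L, k, x0):
    return L / (1.0 + np.exp(np.clip(k * (x - x0), -500, 500)))


def fit_logistic(trace: KineticTrace, t_f: float,
                 rate_mode: Literal["k", "slope"] = "k",
                 window_source: Literal["gaussian", "fallback"] = "gaussian",
                 ) -> LogisticFit:
    """Fit the printed logistic form over samples with t <= t_f.

    L is fixed to 1 for normalized traces and free otherwise.  ``rate_mode``
    selects the reported rate: |k| in min^-1, or the maximum growth slope
    |k|*L/4 (RFU min^-1) used for unnormalized compartment traces.
    """
    sel = trace.t <= t_f
    t = trace.t[sel]
    A = trace.A[sel]
    if t.size < 5:
        raise WindowError(f"fit window [0, {t_f:g}] holds {t.size} < 5 samples")

    span = float(A.max() - A.min())
    base = float(np.mean(A[: min(5, len(A))]))
    if span <= 0 or span <= 1e-12 * max(abs(base), 1.0):
        return LogisticFit(L=np.nan, k=np.nan, x0=np.nan, t_f=t_f, rate=0.0,
                           window_source=window_source, rate_mode=rate_mode,
                           no_growth=True)

    fix_L = trace.normalized
    L0 = 1.0 if fix_L else float(A.max())
    half = A.min() + 0.5 * (L0 - A.min())
    x0_0 = float(t[np.argmin(np.abs(A - half))])
    slope = float(np.max(np.diff(A) / np.diff(t)))
    k0 = -4.0 * slope / L0 if slope > 0 else -0.01

    try:
        if fix_L:
            popt = _curve_fit(lambda x, k, x0: _logistic(x, 1.0, k, x0), t, A,
                              p0=[k0, x0_0], maxfev=20000)
            L, k, x0 = 1.0, *popt
        else:
            popt = _curve_fit(_logistic, t, A, p0=[L0, k0, x0_0], maxfev=20000)
            L, k, x0 = popt
    except (RuntimeError, ValueError):
        return LogisticFit(L=np.nan, k=np.nan, x0=np.nan, t_f=t_f, rate=np.nan,
                           window_source=window_source, rate_mode=rate_mode,
                           no_growth=False, quality=np.nan)
    resid = A - _logistic(t, L, k, x0)
    rate = abs(k) if rate_mode == "k" else abs(k) * abs(L) / 4.0
    return LogisticFit(L=float(L), k=float(k), x0=float(x0), t_f=float(t_f),
                       rate=float(rate), window_source=window_source,
                       rate_mode=rate_mode,
                       quality=float(np.sqrt(np.mean(resid ** 2))))


def estimate_rate(trace: KineticTrace, fallback_t_f: float | None = None,
                  normalize: str | None = None,
                  rate_mode: Literal["k", "slope"] = "k") -> RateEstimate:
    """Full rate-extraction pipeline for one trace.

    Optional normalization, difference series, Gaussian fit, midpoint-to-decay
    window, then the windowed logistic fit.  Falls back to ``fallback_t_f``
    (default: 60% of the trace duration) when the Gaussian route fails or
    lands outside the sampled times.
    """
    work = trace
    if normalize:
        try:
            work = normalize_trace(trace, mode=normalize)
        except NormalizationError:
            # flat trace: nothing to normalize, nothing to fit
            return LogisticFit(L=np.nan, k=np.nan, x0=np.nan,
                               t_f=float(trace.t[-1]), rate=0.0,
                               window_source="fallback", rate_mode=rate_mode,
                               no_growth=True)
    if fallback_t_f is None:
        fallback_t_f = float(trace.t[0] + 0.6 * (trace.t[-1] - trace.t[0]))

    rise, floor = _rise_above_start(work.A)
    if rise <= 5.0 * floor:
        # no growth above the starting signal: switched-off / control trace
        return LogisticFit(L=np.nan, k=np.nan, x0=np.nan,
                           t_f=fallback_t_f, rate=0.0,
                           window_source="fallback", rate_mode=rate_mode,
                           no_growth=True)

    t_mid, d = difference_series(work)
    gfit = fit_gaussian_difference(t_mid, d)
    t_f, source = fallback_t_f, "fallback"
    if gfit.converged:
        cand = midpoint_to_decay(gfit)
        if work.t[0] < cand <= work.t[-1] and np.sum(work.t <= cand) >= 5:
            t_f, source = cand, "gaussian"
    try:
        return fit_logistic(work, t_f, rate_mode=rate_mode, window_source=source)
    except WindowError:
        if source == "gaussian":
            return fit_logistic(work, fallback_t_f, rate_mode=rate_mode,
                                window_source="fallback")
        raise


# ---------------------------------------------------------------------------
# derived analyses
# ---------------------------------------------------------------------------

def rate_vs_template_slope(points: Iterable[tuple[float, float]]) -> LinearRateFit:
    """Ordinary least squares of rate against template concentration: the
    compartmentalisation effect size dr/d[T]."""
    pts = np.asarray(list(points), dtype=float)
    if pts.shape[0] < 3:
        raise ConfigError("need >= 3 (template, rate) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ConfigError("template concentrations are degenerate")
    res = stats.linregress(x, y)
    return LinearRateFit(slope=float(res.slope), intercept=float(res.intercept),
                         stderr_slope=float(res.stderr),
                         r_squared=float(res.rvalue ** 2))


def tukey_summary(values: Sequence[float]) -> PopulationSummary:
    """Median/quartiles with Tukey 1.5*IQR adjacent values and outside points."""
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size == 0:
        raise ConfigError("empty group")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    outside = v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)]
    return PopulationSummary(n=int(v.size), median=float(med), q1=float(q1),
                             q3=float(q3), lower_adjacent=float(inside.min()),
                             upper_adjacent=float(inside.max()),
                             outside_points=[float(x) for x in outside])


def population_kinetics(traces: Sequence[KineticTrace],
                        fallback_t_f: float | None = None,
                        rate_mode: Literal["k", "slope"] = "k",
                        normalize: str | None = None):
    """Mean +/- sd profile of a trace group plus Tukey box statistics of the
    per-trace fitted rates.

    Returns ``(t, mean, sd, rates, PopulationSummary)``.  Traces on different
    grids are linearly resampled onto the first trace's grid.
    """
    if not traces:
        raise ConfigError("empty trace group")
    try:
        t = common_grid(traces)
        M = np.vstack([tr.A for tr in traces])
    except ConfigError:
        t = traces[0].t
        M = np.vstack([np.interp(t, tr.t, tr.A) for tr in traces])
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1) if len(traces) > 1 else np.zeros_like(mean)
    rates = [estimate_rate(tr, fallback_t_f=fallback_t_f, rate_mode=rate_mode,
                           normalize=normalize) for tr in traces]
    fitted = [r.rate for r in rates if np.isfinite(r.rate)]
    summary = tukey_summary(fitted) if fitted else None
    return t, mean, sd, rates, summary


def classify_profile(trace: KineticTrace, flat_snr: float = 5.0,
                     pulse_drop: float = 0.2) -> str:
    """Classify a kinetic profile as ``flat``, ``sigmoidal`` or ``pulse``.

    A 5-point moving average suppresses noise; the residual MAD estimates the
    noise floor.  Flat: total excursion below ``flat_snr`` times the noise.
    Pulse: the maximum is followed by a sustained decline of at least
    ``pulse_drop`` of the peak excursion.  Otherwise sigmoidal.
    """
    if len(trace) < 10:
        raise ConfigError("classification needs >= 10 samples")
    A = trace.A
    smooth, floor = _smooth_and_floor(A)
    excursion = float(smooth.max() - smooth.min())
    rise, _ = _rise_above_start(A)
    # flat = no growth: either nothing happens at all, or a pre-loaded signal
    # only decays (switched-off compartment)
    if excursion <= flat_snr * floor or rise <= flat_snr * floor:
        return "flat"
    i_peak = int(np.argmax(smooth))
    peak = smooth[i_peak]
    if i_peak < len(smooth) - 1:
        tail_min = float(np.min(smooth[i_peak:]))
        if (peak - tail_min) >= pulse_drop * rise:
            return "pulse"
    return "sigmoidal"
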