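"""FRAP analysis: normalization, recovery fitting, diffusion and partition.

The recovery of a bleached region is modelled as

    I(t) = 1                                  for t <  t0
    I(t) = 1 - A * exp(-(t - t0)/tau)         for t >= t0

with t0 the first post-bleach time point.  When the data plateau below full
recovery the model is extended with a free plateau C (chosen over the fixed
C = 1 form by an F-test on the nested fits at the 5% level) and the immobile
fraction is

    immobile = 1 - (C - I(t0+)) / (1 - I(t0+)),

the share of the bleached signal that never returns.  The apparent diffusion
coefficient follows the half-time relation D = 0.88 r^2 / (4 tau ln 2) with r
the bleach-spot radius; it supports comparisons between conditions, not
absolute transport measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ConfigError, NormalizationError, UnidentifiableError
from .synth.frap import FrapTrace


@dataclass
class FrapFit:
    A: float                     # bleach depth
    tau: float                   # s
    t0: float                    # s
    plateau: float               # fitted long-time limit
    immobile_fraction: float
    immobile_fraction_last: float   # same, from the last measured points
    residual_rms: float
    model: str = "fixed_plateau"    # or "free_plateau"


@dataclass
class DiffusionEstimate:
    D: float                     # um^2/s
    D_sd: float
    r: float                     # um
    n_events: int


@dataclass
class PartitionMeasurement:
    F_in: float
    F_out: float
    K: float


def normalize_frap(raw, background, reference, mode: str = "standard",
                   whole_droplet_signal=None, t=None, t0: float = 0.0) -> FrapTrace:
    """Double normalization of a bleached-region intensity series.

    I = (raw - background) / (reference - background), rescaled by its
    pre-bleach mean; ``whole_droplet`` mode additionally divides by the
    background-corrected whole-droplet series first (used when the whole
    droplet is bleached and refilled from outside).
    """
    raw = np.asarray(raw, float)
    background = np.asarray(background, float)
    reference = np.asarray(reference, float)
    if raw.shape != background.shape or raw.shape != reference.shape:
        raise ConfigError("raw, background and reference must share a grid")
    denom = reference - background
    if np.any(denom <= 0):
        raise NormalizationError("reference must exceed background everywhere")
    I = (raw - background) / denom
    if mode == "whole_droplet":
        if whole_droplet_signal is None:
            raise ConfigError("whole_droplet mode needs the droplet series")
        wd = np.asarray(whole_droplet_signal, float) - background
        if np.any(wd <= 0):
            raise NormalizationError("whole-droplet signal must exceed background")
        I = I / wd
    elif mode != "standard":
        raise ConfigError(f"unknown FRAP normalization mode {mode!r}")
    t = np.arange(len(I), dtype=float) if t is None else np.asarray(t, float)
    pre = I[t < t0]
    if pre.size == 0 or np.mean(pre) <= 0:
        raise NormalizationError("no usable pre-bleach samples")
    I = I / np.mean(pre)
    return FrapTrace(t=t, I=I, t0=t0, mode=mode)


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Fit the exponential recovery model to the post-bleach samples.

    Requires >= 3 pre-bleach and >= 10 post-bleach samples.  Raises an
    unidentifiability error when no bleach is detectable (post-bleach minimum
    above 0.95).
    """
    t = np.asarray(trace.t, float)
    I = np.asarray(trace.I, float)
    pre = t < trace.t0
    post = ~pre
    if pre.sum() < 3 or post.sum() < 10:
        raise ConfigError("need >= 3 pre-bleach and >= 10 post-bleach samples")
    tp = t[post]
    Ip = I[post]
    if Ip.min() > 0.95:
        raise UnidentifiableError("no bleach detected (post-bleach minimum > 0.95)")

    t0 = float(tp[0])   # first post-bleach sample defines the bleach instant
    A0 = 1.0 - float(Ip.min())
    # tau init: time to recover halfway between the minimum and the late level
    late = float(np.mean(Ip[-max(3, len(Ip) // 10):]))
    half = Ip.min() + 0.5 * (late - Ip.min())
    above = np.nonzero(Ip >= half)[0]
    tau0 = max(float(tp[above[0]] - t0), (tp[1] - tp[0])) if above.size else float(tp[-1] - t0)

    def _decay(x, tau):
        return np.exp(np.clip(-(x - t0) / tau, -500.0, 500.0))

    def model2(x, A, tau):
        return 1.0 - A * _decay(x, tau)

    def model3(x, A, tau, C):
        return C - A * _decay(x, tau)

    p2, _ = optimize.curve_fit(model2, tp, Ip, p0=[A0, tau0], maxfev=20000)
    r2 = Ip - model2(tp, *p2)
    ss2 = float(np.sum(r2 ** 2))
    try:
        p3, _ = optimize.curve_fit(model3, tp, Ip, p0=[p2[0], p2[1], 1.0],
                                   maxfev=20000)
        ss3 = float(np.sum((Ip - model3(tp, *p3)) ** 2))
    except (RuntimeError, ValueError):
        p3, ss3 = None, np.inf

    use_free = False
    n = len(tp)
    scale = float(np.mean(Ip ** 2))
    if p3 is not None and ss3 < ss2 and n > 4:
        # guard the denominator so an exactly-zero ss3 (noiseless data the
        # free model fits perfectly) still selects the free plateau, while
        # an already-perfect fixed fit never does
        eps = 1e-15 * n * scale
        F = (ss2 - ss3) / (max(ss3, eps) / (n - 3))
        if F > 0 and stats.f.sf(F, 1, n - 3) < 0.05:
            use_free = True

    if use_free:
        amp, tau, C = (float(v) for v in p3)
        ss = ss3
        model_name = "free_plateau"
    else:
        amp, tau = (float(v) for v in p2)
        C = 1.0
        ss = ss2
        model_name = "fixed_plateau"
    tau = abs(tau)
    I_post0 = C - amp
    A = 1.0 - I_post0   # bleach depth: drop at the bleach instant
    mobile = (C - I_post0) / (1.0 - I_post0) if I_post0 < 1.0 else 1.0
    immobile = float(np.clip(1.0 - mobile, 0.0, 1.0))
    # alternative estimate from the tail of the data rather than the fit
    last = float(np.mean(Ip[-max(3, len(Ip) // 10):]))
    mobile_last = (last - I_post0) / (1.0 - I_post0) if I_post0 < 1.0 else 1.0
    immobile_last = float(np.clip(1.0 - mobile_last, 0.0, 1.0))
    return FrapFit(A=A, tau=tau, t0=t0, plateau=C, immobile_fraction=immobile,
                   immobile_fraction_last=immobile_last,
                   residual_rms=float(np.sqrt(ss / n)), model=model_name)


def diffusion_coefficient(tau: float, r: float) -> float:
    """Apparent diffusion coefficient D = 0.88 r^2 / (4 tau ln 2), um^2/s."""
    if tau <= 0 or r <= 0:
        raise ConfigError("tau and r must be > 0")
    return 0.88 * r ** 2 / (4.0 * tau * np.log(2.0))


def aggregate_frap(fits, r: float) -> DiffusionEstimate:
    """Mean and sample sd of per-event diffusion coefficients at spot radius r."""
    fits = list(fits)
    if len(fits) < 2:
        raise ConfigError("need >= 2 bleaching events to aggregate")
    D = np.array([diffusion_coefficient(f.tau, r) for f in fits])
    return DiffusionEstimate(D=float(D.mean()), D_sd=float(D.std(ddof=1)),
                             r=float(r), n_events=len(fits))


def partition_coefficient(F_in: float, F_out: float) -> PartitionMeasurement:
    """Sequestration ratio K = F_in / F_out (raw intensities, no background
    removal)."""
    if F_out <= 0:
        raise ConfigError("F_out must be > 0")
    return PartitionMeasurement(F_in=float(F_in), F_out=float(F_out),
                                K=float(F_in) / float(F_out))
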