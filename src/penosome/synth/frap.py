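"""Synthetic FRAP traces: step bleach followed by exponential recovery with an
optional immobile fraction.

The generated trace is already on the normalized scale (pre-bleach intensity
1).  For t >= t0,

    I(t) = plateau - (plateau - (1 - A)) * exp(-(t - t0)/tau),
    plateau = 1 - A * immobile_fraction,

so the signal drops to 1 - A at the bleach and recovers with time constant
tau towards a plateau depressed by the immobile share of the bleached
molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigError


@dataclass
class FrapTrace:
    t: np.ndarray          # s
    I: np.ndarray          # normalized intensity
    t0: float              # bleach time, s
    mode: str = "standard"  # or "whole_droplet"


def synthesize_frap_trace(A: float, tau: float, immobile_fraction: float = 0.0,
                          t0: float = 0.0, t_grid=None, noise_sd: float = 0.0,
                          seed: int = 0) -> tuple[FrapTrace, dict]:
    """Generate one FRAP trace and its ground truth.

    A is the bleach depth (0-1), tau the recovery time constant in seconds.
    ``t_grid`` must span t0; default is 3 s of pre-bleach and 8 tau of
    recovery sampled at tau/20.
    """
    if not (0.0 <= A <= 1.0):
        raise ConfigError("A must lie in [0, 1]")
    if tau <= 0:
        raise ConfigError("tau must be > 0")
    if not (0.0 <= immobile_fraction <= 1.0):
        raise ConfigError("immobile_fraction must lie in [0, 1]")
    if t_grid is None:
        # grid contains t0 exactly: the first post-bleach sample is the
        # bleach instant, matching the fitting convention
        dt = tau / 20.0
        npre = max(4, int(np.ceil(3.0 / dt)))
        npost = int(np.ceil(8.0 * tau / dt))
        t_grid = t0 + dt * np.arange(-npre, npost)
    t_grid = np.asarray(t_grid, dtype=float)
    if not (t_grid.min() < t0 <= t_grid.max()):
        raise ConfigError("t_grid must span t0")

    plateau = 1.0 - A * immobile_fraction
    I = np.ones_like(t_grid)
    post = t_grid >= t0
    I[post] = plateau - (plateau - (1.0 - A)) * np.exp(-(t_grid[post] - t0) / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        I = I + rng.normal(0.0, noise_sd, size=I.shape)
    truth = {"A": A, "tau": tau, "immobile_fraction": immobile_fraction,
             "t0": t0, "plateau": plateau}
    return FrapTrace(t=t_grid, I=I, t0=t0), truth
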