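"""Mechanistic two-compartment model of PEN DNA reactions in proteinosomes.

The PEN (Polymerase / Exonuclease / Nickase) toolkit runs short-DNA reaction
nodes: an *autocatalytic* node whose template turns substrate strand s into
more of itself, and a *linear* node whose template produces a different strand.
Proteinosomes fix the template at a high internal concentration (0.12 uM by
default) while substrate strands and enzymes exchange with the dilute outer
phase through the porous membrane.

The model is deliberately lumped.  Production on a template T follows a
saturating form with product inhibition (the primer can occupy both template
ends at high concentration), degradation by exonuclease is Michaelis-type, and
membrane transport is first-order exchange:

    v_prod(s; T) = k_pol * P * T * s/(K_m + s) * 1/(1 + s/K_i)
    v_deg(s)     = k_exo * E * s/(K_exo + s)

Inside compartment j (substrate s_j, template T_j):

    ds_j/dt = v_prod(s_j; T_j) - v_deg(s_j) + k_ex (s_out - s_j)

and in the outer phase, with V_j the compartment volumes:

    ds_out/dt = -v_deg(s_out) + sum_j (V_j / V_out) k_ex (s_j - s_out)

For a two-node network the linear node produces the autocatalytic node's
substrate s2 from its own substrate s1 at rate v_lin = k_pol*P*T1*s1/(K_m+s1);
s1 itself is consumed only by the exonuclease (templated catalysis does not
consume the primer).

The fluorescence observable mimics an intercalating double-strand dye:
duplex(s; T) = T*s/(K_m+s) + c_ext*s (template occupancy plus an
extended-strand contribution), reported as F = F0 + alpha*duplex.

Integration is fixed-step classical RK4 with a post-step clamp of tiny
negative round-off values to zero; anything below -1e-9 nM or non-finite
raises an integration error naming the offending time.

All concentrations are nanomolar internally; template inputs are micromolar
to match how the experiments are described.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ..errors import ConfigError, IntegrationError, LayoutError
from ..traces import KineticTrace, TraceSet

_NEG_TOL_NM = 1e-9  # nM; more negative than this aborts integration


@dataclass(frozen=True)
class CompartmentModelParams:
    """Rate constants and observation parameters of the lumped PEN model.

    The defaults are chosen so that the reference buffer reaction (1 uM
    template, 12.8 U/mL polymerase == P = 1) grows at ~0.1 min^-1 and the
    compartmentalised reaction at nM total template is switched off within
    the 0.6-9.6 nM exonuclease window; they are illustrative, not fitted.
    """

    k_pol: float = 5.0e-3   # min^-1 per nM template (times occupancy)
    K_m: float = 50.0       # nM, primer half-saturation on the template
    K_i: float = 100.0      # nM, product-inhibition constant
    k_exo: float = 0.4      # min^-1 per nM exonuclease
    K_exo: float = 50.0     # nM, degradation half-saturation
    k_ex: float = 0.03      # min^-1, effective membrane exchange of substrate
    P: float = 1.0          # polymerase activity (1 = 12.8 U/mL reference)
    E: float = 0.6          # nM exonuclease
    seq: float = 5.7        # polymerase enrichment inside proteinosomes
    alpha: float = 10.0     # RFU per nM duplex
    F0: float = 50.0        # RFU baseline
    c_ext: float = 0.1      # extended-strand duplex coefficient

    def __post_init__(self) -> None:
        for name in ("k_pol", "k_exo", "k_ex", "P", "E", "seq", "alpha"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.K_m <= 0 or self.K_exo <= 0 or self.K_i <= 0:
            raise ConfigError("K_m, K_i and K_exo must be > 0")

    # -- rate laws -----------------------------------------------------
    def v_prod(self, s, T_nM, enrich: float = 1.0):
        s = np.maximum(s, 0.0)
        return (self.k_pol * self.P * enrich * T_nM
                * s / (self.K_m + s) / (1.0 + s / self.K_i))

    def v_lin(self, s1, T1_nM, enrich: float = 1.0):
        """Linear-node production of the downstream substrate (no product
        inhibition: the product is a different strand)."""
        s1 = np.maximum(s1, 0.0)
        return self.k_pol * self.P * enrich * T1_nM * s1 / (self.K_m + s1)

    def v_deg(self, s):
        s = np.maximum(s, 0.0)
        return self.k_exo * self.E * s / (self.K_exo + s)

    def duplex(self, s, T_nM, s_extra=0.0):
        s = np.maximum(s, 0.0)
        return T_nM * s / (self.K_m + s) + self.c_ext * (s + s_extra)

    def fluorescence(self, duplex_nM):
        return self.F0 + self.alpha * duplex_nM


@dataclass(frozen=True)
class PopulationSpec:
    """One proteinosome population in a network layout."""

    node_kind: Literal["linear", "autocatalytic"]
    T_in: float = 0.12          # uM internal template (calibrated value)
    n_compartments: int = 1
    radius_um: float | Sequence[float] = 12.1
    loading_rsd: float = 0.0    # % per-droplet template variability
    loading_shape: Literal["normal", "lognormal"] = "normal"
    label: str = ""

    def radii(self) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.radius_um, dtype=float))
        if r.size == 1:
            r = np.full(self.n_compartments, float(r[0]))
        if r.size != self.n_compartments:
            raise LayoutError("radius_um length must match n_compartments")
        if np.any(r <= 0):
            raise LayoutError("radii must be positive")
        return r


@dataclass(frozen=True)
class NetworkLayout:
    populations: tuple[PopulationSpec, ...]
    volume_fraction: float = 0.005   # total compartment volume / sample volume

    def __post_init__(self) -> None:
        if not (0.0 < self.volume_fraction < 1.0):
            raise LayoutError("volume_fraction must lie strictly in (0, 1)")
        if not self.populations or any(p.n_compartments < 1 for p in self.populations):
            raise LayoutError("each population needs n_compartments >= 1")
        if any(p.T_in < 0 for p in self.populations):
            raise LayoutError("T_in must be >= 0")

    @property
    def n_total(self) -> int:
        return sum(p.n_compartments for p in self.populations)

    def total_template_nM(self) -> float:
        """Total template in the dispersion, nM (volume-weighted over
        populations, scaled by the overall volume fraction)."""
        vols = np.concatenate([p.radii() ** 3 for p in self.populations])
        T = np.concatenate([np.full(p.n_compartments, p.T_in * 1e3)
                            for p in self.populations])
        return float(self.volume_fraction * np.sum(vols * T) / np.sum(vols))


def _check_grid(duration: float, dt: float) -> np.ndarray:
    if duration <= 0 or dt <= 0:
        raise ConfigError("duration and dt must be > 0")
    if dt > duration / 10:
        raise ConfigError("dt must be <= duration/10")
    n = int(round(duration / dt))
    return np.linspace(0.0, n * dt, n + 1)


def _rk4(deriv, y0: np.ndarray, t_grid: np.ndarray, substeps: int = 1) -> np.ndarray:
    """Classical RK4 on a fixed grid; clamps round-off negatives to zero."""
    y = np.array(y0, dtype=float)
    out = np.empty((len(t_grid), len(y)))
    out[0] = y
    for i in range(len(t_grid) - 1):
        h = (t_grid[i + 1] - t_grid[i]) / substeps
        t = t_grid[i]
        for _ in range(substeps):
            k1 = deriv(t, y)
            k2 = deriv(t + h / 2, y + h / 2 * k1)
            k3 = deriv(t + h / 2, y + h / 2 * k2)
            k4 = deriv(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            if not np.all(np.isfinite(y)):
                raise IntegrationError(t)
            if np.any(y < -_NEG_TOL_NM):
                raise IntegrationError(t, f"negative state {y.min():.3e} nM")
            np.clip(y, 0.0, None, out=y)
        out[i + 1] = y
    return out


def simulate_bulk_reaction(params: CompartmentModelParams, template_conc: float,
                           primer0: float, duration: float, dt: float,
                           *, substeps: int = 1) -> KineticTrace:
    """Single-phase (buffer) autocatalytic reaction.

    Parameters: ``template_conc`` in uM, ``primer0`` in nM, times in minutes.
    Returns the fluorescence trace F(t) = F0 + alpha * duplex(s(t)).
    """
    t_grid = _check_grid(duration, dt)
    T_nM = template_conc * 1e3

    def deriv(_t, y):
        s = y[0]
        return np.array([params.v_prod(s, T_nM) - params.v_deg(s)])

    s = _rk4(deriv, np.array([primer0], dtype=float), t_grid, substeps)[:, 0]
    F = params.fluorescence(params.duplex(s, T_nM))
    return KineticTrace(t=t_grid, A=F, compartment_id="bulk", population="bulk",
                        template_uM=template_conc, exonuclease_nM=params.E)


def simulate_compartment_network(params: CompartmentModelParams, layout: NetworkLayout,
                                 primer0_outside: float, duration: float, dt: float,
                                 seed: int = 0, *,
                                 primer_species: Literal["auto", "s1", "s2"] = "auto",
                                 substeps: int = 1) -> TraceSet:
    """Coupled compartments + outer phase, one or two reaction nodes.

    The supplied primer is assumed pre-equilibrated across the membrane at
    t = 0 (membrane passage of a 20-mer takes seconds, far below the minutes
    frame interval), so each compartment starts at ``primer0_outside`` too.
    ``primer_species`` selects which strand the outside primer is; ``auto``
    means s1 when any linear population is present, else s2.
    """
    t_grid = _check_grid(duration, dt)
    rng = np.random.default_rng(seed)

    kinds, T_nM, radii, labels = [], [], [], []
    for ip, pop in enumerate(layout.populations):
        r = pop.radii()
        T_pop = np.full(pop.n_compartments, pop.T_in * 1e3)
        if pop.loading_rsd > 0:
            sd = pop.loading_rsd / 100.0
            if pop.loading_shape == "normal":
                T_pop = T_pop * np.maximum(rng.normal(1.0, sd, size=T_pop.size), 0.0)
            else:
                sigma2 = np.log1p(sd ** 2)
                T_pop = T_pop * rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=T_pop.size)
        kinds += [pop.node_kind] * pop.n_compartments
        labels += [pop.label or pop.node_kind] * pop.n_compartments
        T_nM.append(T_pop)
        radii.append(r)
    T_nM = np.concatenate(T_nM)
    radii = np.concatenate(radii)
    n = len(T_nM)
    is_lin = np.array([k == "linear" for k in kinds])

    # compartment volume shares; outer phase is the rest of a unit sample
    vols = radii ** 3
    V_j = layout.volume_fraction * vols / vols.sum()
    V_out = 1.0 - layout.volume_fraction
    w = V_j / V_out

    if primer_species == "auto":
        primer_species = "s1" if is_lin.any() else "s2"

    # state: [s1_out, s2_out, s1_1..s1_n, s2_1..s2_n]
    y0 = np.zeros(2 * n + 2)
    if primer_species == "s1":
        y0[0] = primer0_outside
        y0[2:2 + n] = primer0_outside
    else:
        y0[1] = primer0_outside
        y0[2 + n:] = primer0_outside

    T_lin = np.where(is_lin, T_nM, 0.0)
    T_auto = np.where(~is_lin, T_nM, 0.0)
    kex = params.k_ex

    def deriv(_t, y):
        s1_out, s2_out = y[0], y[1]
        s1 = y[2:2 + n]
        s2 = y[2 + n:]
        prod2_auto = params.v_prod(s2, T_auto, enrich=params.seq)
        prod2_lin = params.v_lin(s1, T_lin, enrich=params.seq)
        ds1 = -params.v_deg(s1) + kex * (s1_out - s1)
        ds2 = prod2_auto + prod2_lin - params.v_deg(s2) + kex * (s2_out - s2)
        ds1_out = -params.v_deg(s1_out) + np.sum(w * kex * (s1 - s1_out))
        ds2_out = -params.v_deg(s2_out) + np.sum(w * kex * (s2 - s2_out))
        return np.concatenate(([ds1_out, ds2_out], ds1, ds2))

    Y = _rk4(deriv, y0, t_grid, substeps)
    s1_t = Y[:, 2:2 + n]
    s2_t = Y[:, 2 + n:]

    traces: list[KineticTrace] = []
    for j in range(n):
        if is_lin[j]:
            dup = params.duplex(s1_t[:, j], T_nM[j], s_extra=s2_t[:, j])
        else:
            dup = params.duplex(s2_t[:, j], T_nM[j], s_extra=s1_t[:, j])
        traces.append(KineticTrace(
            t=t_grid, A=params.fluorescence(dup),
            compartment_id=f"c{j:03d}", population=labels[j],
            template_uM=T_nM[j] / 1e3, exonuclease_nM=params.E))
    dup_out = params.c_ext * (Y[:, 0] + Y[:, 1])
    traces.append(KineticTrace(t=t_grid, A=params.fluorescence(dup_out),
                               compartment_id="bulk", population="bulk",
                               template_uM=0.0, exonuclease_nM=params.E))
    truth = {"params": params, "layout": layout, "primer_species": primer_species,
             "s1": s1_t, "s2": s2_t, "s1_out": Y[:, 0], "s2_out": Y[:, 1],
             "T_nM": T_nM, "radii_um": radii}
    return TraceSet(traces=traces, time_grid=t_grid, seed=seed, truth=truth)


def sample_proteinosome_population(n: int, mean_radius: float, rsd: float,
                                   shape: Literal["normal", "lognormal"] = "normal",
                                   seed: int = 0) -> np.ndarray:
    """Sample droplet radii (um) with the requested arithmetic mean and RSD.

    Mirrors the two preparation routes: microfluidic proteinosomes are
    near-monodisperse and normally distributed (RSD ~ 14%), bulk-emulsion
    ones polydisperse and log-normal (RSD ~ 48%).  Normal sampling rejects
    non-positive draws; log-normal parameters are solved so the arithmetic
    mean and RSD match the request.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if mean_radius <= 0:
        raise ConfigError("mean_radius must be > 0")
    if not (0 <= rsd < 100):
        raise ConfigError("rsd must lie in [0, 100)")
    rng = np.random.default_rng(seed)
    if rsd == 0:
        return np.full(n, float(mean_radius))
    sd = mean_radius * rsd / 100.0
    if shape == "normal":
        out = np.empty(0)
        while out.size < n:
            draw = rng.normal(mean_radius, sd, size=max(n - out.size, 16))
            out = np.concatenate([out, draw[draw > 0]])
        return out[:n]
    if shape == "lognormal":
        sigma2 = np.log1p((sd / mean_radius) ** 2)
        mu = np.log(mean_radius) - sigma2 / 2
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    raise ConfigError(f"unknown shape {shape!r}")
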