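"""Reusable in-silico studies over the simulator and the analysis pipeline.

Each function sets up one computational experiment — parameter-recovery
benchmarks, the segmentation benchmark, the exonuclease switch-off and
template sweeps, and the two-node communication network — runs it through the
package's own analysis code, and returns summary numbers.  The analysis
drivers, the test suite and the acceptance script all call these functions so
every reported number comes from the same code path.

Problem sizes default to desk scale (tens of traces, tens of frames); every
study takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import frap as frapmod
from . import imaging, kinetics
from .synth import (CompartmentModelParams, NetworkLayout, PopulationSpec,
                    simulate_bulk_reaction, simulate_compartment_network,
                    synthesize_frap_trace)
from .traces import KineticTrace

DEFAULT_E_SWEEP_NM = (0.6, 2.4, 4.8, 9.6)
DEFAULT_TEMPLATE_SWEEP_NM = (0.20, 0.41, 0.81, 1.63)


# ---------------------------------------------------------------------------
# rate-extraction benchmarks
# ---------------------------------------------------------------------------

def _logistic_trace(k: float, n: int = 150, noise_sd: float = 0.0,
                    rng: np.random.Generator | None = None) -> KineticTrace:
    """Noisy sample of the printed logistic form with rate |k|, scaled so the
    curve spans onset, inflection and saturation."""
    x0 = 10.0 / k
    t = np.linspace(0.0, x0 + 8.0 / k, n)
    A = 1.0 / (1.0 + np.exp(-k * (t - x0)))
    if noise_sd > 0 and rng is not None:
        A = A + rng.normal(0.0, noise_sd, size=n)
    return KineticTrace(t=t, A=A, normalized=True)


def rate_recovery_study(n_traces: int = 100, noise_sd: float = 0.0,
                        k_range: tuple[float, float] = (0.01, 0.5),
                        seed: int = 0) -> dict:
    """Recover logistic rates over a k grid; returns relative-error stats."""
    rng = np.random.default_rng(seed)
    ks = np.linspace(k_range[0], k_range[1], n_traces)
    errs = []
    for k in ks:
        tr = _logistic_trace(float(k), noise_sd=noise_sd, rng=rng)
        est = kinetics.estimate_rate(tr)
        errs.append(abs(est.rate - k) / k)
    errs = np.array(errs)
    return {"n": n_traces, "noise_sd": noise_sd,
            "max_rel_err": float(errs.max()),
            "median_rel_err": float(np.median(errs))}


def window_inversion_study(n: int = 1000, seed: int = 0) -> dict:
    """Closed-form midpoint-to-decay versus numerical inversion of the
    Gaussian at its half maximum (positive side)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n):
        a1 = rng.uniform(0.1, 10.0)
        b1 = rng.uniform(-50.0, 200.0)
        c1 = rng.uniform(0.5, 50.0)
        fit = kinetics.GaussianDiffFit(a1, b1, c1, converged=True)
        closed = kinetics.midpoint_to_decay(fit, a1 / 2.0)
        g = lambda x: a1 * np.exp(-(((x - b1) / c1) ** 2)) - a1 / 2.0
        numeric = optimize.brentq(g, b1, b1 + 10.0 * c1, xtol=1e-13, rtol=1e-15)
        worst = max(worst, abs(closed - numeric))
    return {"n": n, "max_abs_err": float(worst)}


# ---------------------------------------------------------------------------
# FRAP benchmarks
# ---------------------------------------------------------------------------

def frap_recovery_study(n_traces: int = 100, noise_sd: float = 0.02,
                        seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    tau_err, A_err = [], []
    for i in range(n_traces):
        A = rng.uniform(0.4, 1.0)
        tau = rng.uniform(2.0, 10.0)
        im = rng.uniform(0.0, 0.4)
        tr, _ = synthesize_frap_trace(A, tau, im, t0=0.0, noise_sd=noise_sd,
                                      seed=seed * 100003 + i)
        fit = frapmod.fit_recovery(tr)
        tau_err.append(abs(fit.tau - tau) / tau)
        A_err.append(abs(fit.A - A) / A)
    return {"n": n_traces,
            "tau_median_rel_err": float(np.median(tau_err)),
            "A_median_rel_err": float(np.median(A_err))}


def frap_diffusion_study(D_true: float = 8.0, r_um: float = 2.0,
                         n_events: int = 20, noise_sd: float = 0.02,
                         seed: int = 0) -> dict:
    """Twenty bleaching events at a known diffusion coefficient, fitted and
    aggregated back to D."""
    tau = 0.88 * r_um ** 2 / (4.0 * D_true * np.log(2.0))
    fits = []
    for i in range(n_events):
        tr, _ = synthesize_frap_trace(0.8, tau, 0.0, t0=0.0,
                                      noise_sd=noise_sd, seed=seed * 7919 + i)
        fits.append(frapmod.fit_recovery(tr))
    agg = frapmod.aggregate_frap(fits, r_um)
    return {"n": n_events, "D_true": D_true, "D_mean": agg.D, "D_sd": agg.D_sd}


# ---------------------------------------------------------------------------
# segmentation benchmark
# ---------------------------------------------------------------------------

def _render_disk(img, cx, cy, r_px, value):
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2] = value


def _render_ellipse(img, cx, cy, a_px, b_px, value):
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    img[((xx - cx) / a_px) ** 2 + ((yy - cy) / b_px) ** 2 <= 1.0] = value


def segmentation_benchmark(n_frames: int = 50, seed: int = 0,
                           pixel_size: float = 0.5,
                           frame_shape: tuple[int, int] = (300, 300),
                           noise_frac: float = 0.05,
                           signal: float = 100.0) -> dict:
    """Detection benchmark with in-range disks plus decoys.

    Each frame carries four disks with diameters inside the 17-25 um window,
    one small (10 um) and one large (40 um) decoy disk, and one 3:1 ellipse
    of in-range equivalent diameter; noise is ``noise_frac`` of the signal.
    Reports recall on the in-range disks and how many accepted objects fall
    outside the size window (should be none).
    """
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    found, total, out_of_range = 0, 0, 0
    for _ in range(n_frames):
        img = np.zeros(frame_shape)
        placed = []   # (cx, cy, r_px)

        def place(r_px):
            for _ in range(500):
                cx = rng.uniform(r_px + 5, w - r_px - 5)
                cy = rng.uniform(r_px + 5, h - r_px - 5)
                if all(np.hypot(cx - x, cy - y) > r_px + r + 6
                       for x, y, r in placed):
                    placed.append((cx, cy, r_px))
                    return cx, cy
            return None

        true_centres = []
        for _ in range(4):
            d_um = rng.uniform(18.0, 24.0)
            r_px = d_um / 2.0 / pixel_size
            pos = place(r_px)
            if pos:
                _render_disk(img, *pos, r_px, signal)
                true_centres.append((*pos, r_px))
        for d_um in (10.0, 40.0):   # decoys outside the size window
            pos = place(d_um / 2.0 / pixel_size)
            if pos:
                _render_disk(img, *pos, d_um / 2.0 / pixel_size, signal)
        # 3:1 ellipse with in-range equivalent diameter (fails circularity)
        a_px = 10.0 * np.sqrt(3.0) / pixel_size
        b_px = 10.0 / np.sqrt(3.0) / pixel_size
        pos = place(a_px)
        if pos:
            _render_ellipse(img, *pos, a_px, b_px, signal)

        img = img + rng.normal(0.0, noise_frac * signal, size=img.shape)
        recs = imaging.segment_proteinosomes(img, pixel_size)
        total += len(true_centres)
        for cx, cy, r_px in true_centres:
            if any(np.hypot(rec.centroid[0] / pixel_size - cx,
                            rec.centroid[1] / pixel_size - cy) < r_px
                   for rec in recs):
                found += 1
        for rec in recs:
            if not (17.0 <= 2 * rec.radius <= 25.0):
                out_of_range += 1
    return {"n_frames": n_frames, "n_true": total, "n_found": found,
            "recall": found / total if total else float("nan"),
            "out_of_range_accepts": out_of_range}


# ---------------------------------------------------------------------------
# compartment-vs-bulk studies
# ---------------------------------------------------------------------------

def _autocat_layout(total_template_nM: float, n_compartments: int = 4,
                    T_in_uM: float = 0.12) -> NetworkLayout:
    vf = total_template_nM / (T_in_uM * 1e3)
    return NetworkLayout(
        (PopulationSpec("autocatalytic", T_in=T_in_uM,
                        n_compartments=n_compartments),),
        volume_fraction=vf)


@dataclass
class SwitchoffResult:
    E_levels: tuple
    compartment_all_flat: list[bool]
    compartment_rates: list[float]
    bulk_rates: list[float]
    switchoff_E: float | None       # lowest E with every compartment flat


def switchoff_study(E_levels=DEFAULT_E_SWEEP_NM,
                    total_template_nM: float = 0.6,
                    bulk_template_uM: float = 1.0,
                    duration_min: float = 500.0, dt_min: float = 1.0,
                    seed: int = 0) -> SwitchoffResult:
    """Exonuclease sweep in the compartment system and in buffer.

    In the dispersion the total template is nanomolar, so production and
    degradation are commensurate and the reaction can be fully switched off;
    in buffer the micromolar template keeps production ahead at every tested
    exonuclease level.
    """
    all_flat, comp_rates, bulk_rates = [], [], []
    for E in E_levels:
        params = CompartmentModelParams(E=E)
        layout = _autocat_layout(total_template_nM)
        ts = simulate_compartment_network(params, layout, 1.0, duration_min,
                                          dt_min, seed=seed)
        comps = ts.compartment_traces()
        ests = [kinetics.estimate_rate(tr, rate_mode="slope") for tr in comps]
        flats = [kinetics.classify_profile(tr) == "flat" for tr in comps]
        all_flat.append(all(flats))
        comp_rates.append(float(np.median([e.rate for e in ests])))
        bulk = simulate_bulk_reaction(params, bulk_template_uM, 1.0,
                                      duration_min, dt_min)
        bulk_rates.append(kinetics.estimate_rate(bulk, rate_mode="k",
                                                 normalize="minmax").rate)
    switch = None
    for E, flat in zip(E_levels, all_flat):
        if flat:
            switch = float(E)
            break
    return SwitchoffResult(tuple(E_levels), all_flat, comp_rates, bulk_rates,
                           switch)


def template_sweep_study(totals_nM=DEFAULT_TEMPLATE_SWEEP_NM,
                         duration_min: float = 500.0, dt_min: float = 1.0,
                         seed: int = 0) -> dict:
    """Compartment rates across total template (droplet density) levels."""
    med_rates = []
    for tot in totals_nM:
        layout = _autocat_layout(float(tot))
        ts = simulate_compartment_network(CompartmentModelParams(), layout,
                                          1.0, duration_min, dt_min, seed=seed)
        rates = [kinetics.estimate_rate(tr, rate_mode="slope").rate
                 for tr in ts.compartment_traces()]
        med_rates.append(float(np.median(rates)))
    diffs = np.diff(med_rates)
    fit = kinetics.rate_vs_template_slope(
        [(t / 1e3, r) for t, r in zip(totals_nM, med_rates)])
    return {"totals_nM": tuple(totals_nM), "median_rates": med_rates,
            "monotone_nondecreasing": bool(np.all(diffs >= 0)),
            "slope_rfu_min_uM": fit.slope}


# ---------------------------------------------------------------------------
# two-node network study
# ---------------------------------------------------------------------------

def _onset_time(tr: KineticTrace, frac: float = 0.1) -> float:
    A = tr.A
    rise = A.max() - A[0]
    if rise <= 0:
        return float(tr.t[-1])
    idx = np.nonzero(A - A[0] >= frac * rise)[0]
    return float(tr.t[idx[0]]) if idx.size else float(tr.t[-1])


def two_node_study(T1_scales=(0.25, 0.5, 1.0), n2: int = 4, n1_ref: int = 8,
                   primer_s1_nM: float = 50.0, vf_ref: float = 0.01,
                   duration_min: float = 450.0, dt_min: float = 1.0,
                   seed: int = 0) -> dict:
    """Linear node (population 1) feeding an autocatalytic node (population 2).

    Population 2 is held constant while the population-1 count scales with
    ``T1_scales`` (the T1:T2 template ratio).  Also runs the no-population-1
    control with only the linear node's substrate supplied.
    """
    results = {"scales": tuple(T1_scales), "pop1_class": [], "pop2_class": [],
               "pop2_median_rate": [], "pop1_peak_time": [],
               "pop2_onset_time": []}
    for scale in T1_scales:
        n1 = max(1, int(round(n1_ref * scale)))
        vf = vf_ref * (n1 + n2) / (n1_ref + n2)
        layout = NetworkLayout((
            PopulationSpec("linear", n_compartments=n1, label="pop1"),
            PopulationSpec("autocatalytic", n_compartments=n2, label="pop2")),
            volume_fraction=vf)
        ts = simulate_compartment_network(CompartmentModelParams(), layout,
                                          primer_s1_nM, duration_min, dt_min,
                                          seed=seed)
        groups = ts.by_population()
        cls1 = [kinetics.classify_profile(tr) for tr in groups["pop1"]]
        cls2 = [kinetics.classify_profile(tr) for tr in groups["pop2"]]
        rates = [kinetics.estimate_rate(tr, rate_mode="k").rate
                 for tr in groups["pop2"]]
        results["pop1_class"].append(max(set(cls1), key=cls1.count))
        results["pop2_class"].append(max(set(cls2), key=cls2.count))
        results["pop2_median_rate"].append(float(np.median(rates)))
        tr1 = groups["pop1"][0]
        results["pop1_peak_time"].append(float(tr1.t[int(np.argmax(tr1.A))]))
        results["pop2_onset_time"].append(_onset_time(groups["pop2"][0]))

    # control: no linear node, only its substrate S1 supplied outside
    layout = NetworkLayout((PopulationSpec("autocatalytic", n_compartments=n2,
                                           label="pop2"),),
                           volume_fraction=vf_ref * n2 / (n1_ref + n2))
    ts = simulate_compartment_network(CompartmentModelParams(), layout,
                                      primer_s1_nM, duration_min, dt_min,
                                      seed=seed, primer_species="s1")
    ctrl = ts.by_population()["pop2"]
    results["control_class"] = [kinetics.classify_profile(tr) for tr in ctrl]
    results["control_rates"] = [kinetics.estimate_rate(tr).rate for tr in ctrl]
    rates = results["pop2_median_rate"]
    results["rate_monotone_increasing"] = bool(np.all(np.diff(rates) > 0))
    results["rate_ratio_largest_vs_smallest"] = (
        rates[-1] / rates[0] if rates[0] > 0 else float("inf"))
    return results


# ---------------------------------------------------------------------------
# printed-number worked examples
# ---------------------------------------------------------------------------

def worked_examples() -> dict:
    """Small closed-form computations on published summary numbers: the
    polydisperse size RSD, the dispersion-wide template concentration, the
    Gaussian fit-window endpoint, the FRAP diffusion relation, and the
    polymerase sequestration ratio."""
    rsd_bulk = 100.0 * 11.4 / 24.0
    total_nM = imaging.total_template_concentration(0.005, 1.0, 0.12)
    fit = kinetics.GaussianDiffFit(2.0, 10.0, 4.0, converged=True)
    t_f = kinetics.midpoint_to_decay(fit, 1.0)
    D = frapmod.diffusion_coefficient(1.0, 2.0)
    K = frapmod.partition_coefficient(57.0, 10.0).K
    return {"size_rsd_bulk_pct": rsd_bulk, "total_template_nM": total_nM,
            "gaussian_window_t_f_min": t_f, "diffusion_D_um2_s": D,
            "sequestration_K": K}
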