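"""End-to-end orchestration: simulate -> segment -> extract -> fit-kinetics
(-> fit-frap) -> report, with a checksummed run manifest.

All randomness derives from the single config seed, so identical configs
produce byte-identical CSV outputs and identical manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, frap as frapmod, imaging, kinetics
from .config import PipelineConfig
from .errors import InputError, PenosomeError
from .io import read_frap_csv, read_image_stack, write_image_stack, write_traces
from .synth import (CompartmentModelParams, NetworkLayout, PopulationSpec,
                    sample_proteinosome_population, simulate_compartment_network,
                    synthesize_image_stack)

log = logging.getLogger("penosome")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: list = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, str], wall_s: float):
        self.stages.append({"stage": name, "outputs": outputs,
                            "wall_s": round(wall_s, 3)})

    def checksums(self) -> dict[str, str]:
        out = {}
        for st in self.stages:
            out.update(st["outputs"])
        return out

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config_hash": self.config_hash, "version": self.version,
             "stages": self.stages}, indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    """Tracks a stage's outputs; renames them to *.partial on failure."""

    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name
        self.outputs: list[Path] = []

    def __enter__(self):
        self._t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def track(self, path) -> Path:
        p = Path(path)
        self.outputs.append(p)
        return p

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            sums = {str(p): _sha256(p) for p in self.outputs if p.exists()}
            self.manifest.add_stage(self.name, sums,
                                    time.perf_counter() - self._t0)
            log.info("stage %s: done (%d outputs)", self.name, len(sums))
            return False
        for p in self.outputs:
            if p.exists():
                p.rename(p.with_name(p.name + ".partial"))
        log.error("stage %s: failed: %s", self.name, exc)
        if not isinstance(exc, PenosomeError):
            raise PenosomeError(f"stage {self.name} failed: {exc}") from exc
        return False


def run_pipeline(config: PipelineConfig) -> RunManifest:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = config.model_dump_json()
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        version=__version__)
    rng_seed = config.seed
    log.info("pipeline start, seed=%d", rng_seed)

    sim = config.simulate
    seg = config.segment
    params = CompartmentModelParams(**config.model.model_dump())

    truth_df = None
    if sim.enabled:
        with _Stage(manifest, "simulate") as st:
            radii = sample_proteinosome_population(
                sim.n_compartments, sim.mean_radius_um, sim.radius_rsd_pct,
                sim.radius_shape, seed=rng_seed)
            # keep the rendered droplets inside the segmentation size window
            layout = NetworkLayout(
                (PopulationSpec("autocatalytic", T_in=sim.template_uM,
                                n_compartments=sim.n_compartments,
                                radius_um=tuple(radii)),),
                volume_fraction=sim.volume_fraction)
            ts = simulate_compartment_network(
                params, layout, sim.primer0_nM, sim.duration_min, sim.dt_min,
                seed=rng_seed)
            stack, truth_df = synthesize_image_stack(
                radii, None, ts, seg.pixel_size_um, seg.frame_shape,
                noise_sd=sim.noise_sd_rfu, seed=rng_seed + 1)
            stack_path = st.track(outdir / "stack.tif")
            write_image_stack(stack, stack_path, gain=None,
                              frame_interval_min=sim.dt_min)
            truth_df.to_csv(st.track(outdir / "ground_truth.csv"), index=False,
                            float_format="%.12g")
            write_traces(ts.traces, st.track(outdir / "simulated_traces.csv"))
    else:
        if not config.stack_tiff:
            raise InputError("simulation disabled and no stack_tiff given")
        stack_path = Path(config.stack_tiff)
        if not stack_path.exists():
            raise InputError(f"input stack not found: {stack_path}")

    with _Stage(manifest, "segment") as st:
        stack, meta = read_image_stack(stack_path)
        records = imaging.segment_proteinosomes(
            stack[0], seg.pixel_size_um, seg.blur_sigma_px,
            seg.threshold_method, seg.circularity_range, seg.diameter_range_um)
        rec_df = pd.DataFrame(
            [{"id": r.id, "x_um": r.centroid[0], "y_um": r.centroid[1],
              "radius_um": r.radius, "area_um2": r.area,
              "circularity": r.circularity} for r in records])
        rec_df.to_csv(st.track(outdir / "records.csv"), index=False,
                      float_format="%.12g")

    with _Stage(manifest, "extract") as st:
        dt = float(meta.get("frame_interval_min", seg.frame_interval_min))
        traces = imaging.extract_traces(stack, records, frame_interval_min=dt)
        write_traces(traces, st.track(outdir / "extracted_traces.csv"))

    with _Stage(manifest, "fit-kinetics") as st:
        kin = config.kinetics
        rows = []
        for tr in traces:
            dur = tr.t[-1] - tr.t[0]
            est = kinetics.estimate_rate(
                tr, fallback_t_f=tr.t[0] + kin.fallback_fraction * dur,
                normalize=kin.normalize, rate_mode=kin.rate_mode)
            rows.append({"compartment_id": tr.compartment_id,
                         "rate": est.rate, "k": est.k, "L": est.L,
                         "x0": est.x0, "t_f": est.t_f,
                         "window_source": est.window_source,
                         "no_growth": est.no_growth,
                         "profile": kinetics.classify_profile(tr)})
        pd.DataFrame(rows).to_csv(st.track(outdir / "rates.csv"), index=False,
                                  float_format="%.12g")

    if config.frap.enabled:
        with _Stage(manifest, "fit-frap") as st:
            fb = config.frap
            if not fb.input_csv:
                raise InputError("frap.enabled requires frap.input_csv")
            df = read_frap_csv(fb.input_csv)
            fits = []
            for roi, sub in ([(None, df)] if "event" not in df.columns
                             else df.groupby("event")):
                tr = frapmod.normalize_frap(
                    sub["roi"], sub["background"], sub["reference"],
                    mode=fb.mode,
                    whole_droplet_signal=sub.get("whole_droplet"),
                    t=sub["t_s"].to_numpy(float), t0=fb.t0_s)
                fits.append(frapmod.fit_recovery(tr))
            out = pd.DataFrame([{
                "A": f.A, "tau_s": f.tau, "plateau": f.plateau,
                "immobile_fraction": f.immobile_fraction,
                "D_um2_s": frapmod.diffusion_coefficient(f.tau, fb.spot_radius_um),
                "model": f.model} for f in fits])
            out.to_csv(st.track(outdir / "frap_fits.csv"), index=False,
                       float_format="%.12g")

    with _Stage(manifest, "report") as st:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        if traces:
            t, mean, sd, _, _ = kinetics.population_kinetics(traces)
            ax.fill_between(t, mean - sd, mean + sd, alpha=0.3, label="±1 sd")
            ax.plot(t, mean, lw=2, label=f"mean of {len(traces)} droplets")
            ax.legend()
        ax.set_xlabel("time (min)")
        ax.set_ylabel("fluorescence (RFU)")
        fig.tight_layout()
        fig.savefig(st.track(outdir / "kinetics.png"), dpi=110)
        plt.close(fig)

    manifest.write(outdir / "manifest.json")
    log.info("pipeline done: %d stages", len(manifest.stages))
    return manifest
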