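"""CSV and TIFF readers/writers.

Trace CSV schema: time_min, signal_rfu, compartment_id, population,
template_uM, exonuclease_nM — one row per compartment and time point, time in
minutes strictly increasing within a compartment.  FRAP CSV schema: t_s, roi,
reference, background[, whole_droplet], time in seconds.  Image stacks are
multi-page TIFF, one page per time point, 16-bit unsigned, with the intensity
gain and frame interval recorded in the image description.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InputError
from .traces import KineticTrace

_TRACE_COLUMNS = ["time_min", "signal_rfu", "compartment_id", "population",
                  "template_uM", "exonuclease_nM"]


def write_traces(traces: Sequence[KineticTrace], path) -> None:
    rows = []
    for tr in traces:
        for t, a in zip(tr.t, tr.A):
            rows.append((t, a, tr.compartment_id, tr.population,
                         tr.template_uM, tr.exonuclease_nM))
    df = pd.DataFrame(rows, columns=_TRACE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_traces(path) -> list[KineticTrace]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"trace file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from None
    missing = [c for c in _TRACE_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for opt, default in (("compartment_id", "bulk"), ("population", "bulk"),
                         ("template_uM", 0.0), ("exonuclease_nM", 0.0)):
        if opt not in df.columns:
            df[opt] = default
    traces = []
    for cid, sub in df.groupby("compartment_id", sort=False):
        t = sub["time_min"].to_numpy(float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = int(sub.index[bad[0] + 1]) + 2  # header + 1-based
            raise FormatError(f"{path}: non-increasing time for "
                              f"compartment {cid!r}", row=row)
        traces.append(KineticTrace(
            t=t, A=sub["signal_rfu"].to_numpy(float),
            compartment_id=str(cid), population=str(sub["population"].iloc[0]),
            template_uM=float(sub["template_uM"].iloc[0]),
            exonuclease_nM=float(sub["exonuclease_nM"].iloc[0])))
    return traces


def write_image_stack(stack: np.ndarray, path, gain: float | None = None,
                      frame_interval_min: float = 3.0) -> float:
    """Write a (frames, H, W) stack as 16-bit multi-page TIFF.

    Float stacks are scaled by ``gain`` (default: fills the 16-bit range);
    integer stacks are written as-is with gain 1.  Returns the gain used.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise InputError("image stack must be (frames, H, W)")
    if np.issubdtype(stack.dtype, np.integer):
        data = stack.astype(np.uint16)
        gain = 1.0
    else:
        if gain is None:
            top = float(stack.max())
            gain = 65535.0 / top if top > 0 else 1.0
        data = np.clip(np.round(stack * gain), 0, 65535).astype(np.uint16)
    meta = {"gain": gain, "frame_interval_min": frame_interval_min}
    tifffile.imwrite(path, data, description=json.dumps(meta),
                     photometric="minisblack")
    return gain


def read_image_stack(path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF; returns (float stack in RFU, metadata)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"image stack not found: {path}")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    gain = float(meta.get("gain", 1.0))
    if data.ndim == 2:
        data = data[None]
    return data.astype(float) / gain, meta


def read_frap_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"FRAP file not found: {path}")
    df = pd.read_csv(path)
    needed = {"t_s", "roi", "reference", "background"}
    missing = sorted(needed - set(df.columns))
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["t_s"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise FormatError(f"{path}: non-increasing t_s", row=int(bad[0]) + 3)
    return df
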