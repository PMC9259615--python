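"""Synthetic time-lapse microscopy of proteinosome dispersions.

Renders each compartment as a filled disk of uniform interior intensity equal
to its kinetic-trace value at that frame, over a zero background, with
additive Gaussian read noise.  The real droplets show membrane-edge
enrichment which this generator deliberately omits; the images exist to
exercise the segmentation filters, not to look pretty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import ConfigError, PlacementError
from ..traces import TraceSet, common_grid

_MAX_PLACEMENT_TRIES = 2000


def _auto_positions(radii_um: np.ndarray, frame_shape: tuple[int, int],
                    pixel_size: float, rng: np.random.Generator,
                    margin_um: float = 2.0) -> np.ndarray:
    """Rejection-sample non-overlapping disk centres (um coordinates)."""
    h_um = frame_shape[0] * pixel_size
    w_um = frame_shape[1] * pixel_size
    if np.any(2 * (radii_um + margin_um) > min(h_um, w_um)):
        raise PlacementError("a compartment does not fit in the frame")
    centres: list[np.ndarray] = []
    for r in radii_um:
        for _ in range(_MAX_PLACEMENT_TRIES):
            x = rng.uniform(r + margin_um, w_um - r - margin_um)
            y = rng.uniform(r + margin_um, h_um - r - margin_um)
            c = np.array([x, y])
            if all(np.linalg.norm(c - c2) > r + r2 + margin_um
                   for c2, r2 in zip(centres, radii_um)):
                centres.append(c)
                break
        else:
            raise PlacementError(
                f"could not place {len(radii_um)} disks after "
                f"{_MAX_PLACEMENT_TRIES} tries; frame too crowded")
    return np.array(centres)


def synthesize_image_stack(radii, positions, traces: TraceSet, pixel_size: float,
                           frame_shape: tuple[int, int] = (512, 512),
                           noise_sd: float = 0.0, seed: int = 0):
    """Render a (frames, H, W) float stack plus its ground-truth table.

    Parameters
    ----------
    radii : sequence of um radii, one per compartment trace.
    positions : (n, 2) array of (x_um, y_um) centres, or None for automatic
        non-overlapping placement.
    traces : TraceSet whose compartment traces supply per-frame intensities.
    pixel_size : um per pixel.
    noise_sd : additive Gaussian noise, RFU.

    Returns ``(stack, truth)`` where truth is a DataFrame with one row per
    compartment and frame: id, frame, x_um, y_um, radius_um, true_intensity.
    """
    if pixel_size <= 0:
        raise ConfigError("pixel_size must be > 0")
    radii = np.asarray(radii, dtype=float)
    comp = traces.compartment_traces()
    if len(comp) != len(radii):
        raise ConfigError("need one radius per compartment trace")
    t_grid = common_grid(comp) if comp else traces.time_grid
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = _auto_positions(radii, frame_shape, pixel_size, rng)
    positions = np.asarray(positions, dtype=float)

    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    # pixel centres in um; origin top-left, x = column
    x_um = (xx + 0.5) * pixel_size
    y_um = (yy + 0.5) * pixel_size

    masks = []
    for (cx, cy), r in zip(positions, radii):
        masks.append((x_um - cx) ** 2 + (y_um - cy) ** 2 <= r ** 2)

    n_frames = len(t_grid)
    stack = np.zeros((n_frames, h, w), dtype=float)
    rows = []
    for j, (tr, m, (cx, cy), r) in enumerate(zip(comp, masks, positions, radii)):
        for f in range(n_frames):
            stack[f][m] = tr.A[f]
            rows.append({"id": j, "frame": f, "x_um": cx, "y_um": cy,
                         "radius_um": r, "true_intensity": tr.A[f],
                         "population": tr.population})
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    truth = pd.DataFrame(rows)
    return stack, truth
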