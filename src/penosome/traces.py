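"""Kinetic trace container shared by the simulator, the image pipeline and the
rate-extraction code.

A :class:`KineticTrace` is one compartment's (or the bulk phase's) fluorescence
time series together with the experimental metadata needed downstream: which
population the compartment belongs to, the template concentration it reports
on, and the exonuclease concentration of the run.  Times are minutes, signals
relative fluorescence units (RFU) unless ``normalized`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError


@dataclass
class KineticTrace:
    t: np.ndarray                      # min, strictly increasing
    A: np.ndarray                      # RFU (dimensionless if normalized)
    compartment_id: str = "bulk"
    population: str = "bulk"
    template_uM: float = 0.0           # template concentration the trace reports on
    exonuclease_nM: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.t.ndim != 1 or self.A.shape != self.t.shape:
            raise ConfigError("trace t and A must be 1-D arrays of equal length")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ConfigError("trace times must be strictly increasing")
        if not np.all(np.isfinite(self.A)):
            raise ConfigError("trace signal contains non-finite values")

    def __len__(self) -> int:
        return len(self.t)

    def with_signal(self, A: np.ndarray, *, normalized: bool | None = None) -> "KineticTrace":
        out = replace(self, A=np.asarray(A, dtype=float))
        if normalized is not None:
            out.normalized = normalized
        return out


@dataclass
class TraceSet:
    """All traces from one simulated (or measured) experiment.

    ``traces`` holds one entry per compartment plus one for the bulk phase;
    every trace shares ``time_grid``.  ``truth`` records the generating
    parameters for round-trip tests.
    """

    traces: list[KineticTrace]
    time_grid: np.ndarray
    seed: int | None = None
    truth: dict = field(default_factory=dict)

    def by_population(self) -> dict[str, list[KineticTrace]]:
        groups: dict[str, list[KineticTrace]] = {}
        for tr in self.traces:
            groups.setdefault(tr.population, []).append(tr)
        return groups

    def compartment_traces(self) -> list[KineticTrace]:
        return [tr for tr in self.traces if tr.population != "bulk"]


def common_grid(traces: Sequence[KineticTrace]) -> np.ndarray:
    """Shared time grid of a group, or raise if grids differ."""
    t0 = traces[0].t
    for tr in traces[1:]:
        if len(tr.t) != len(t0) or not np.allclose(tr.t, t0):
            raise ConfigError("traces do not share a time grid")
    return t0
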