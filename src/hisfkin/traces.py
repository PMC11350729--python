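"""Time-series containers: observable models, traces and trace sets."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .util import ValidationError

DEFAULT_DEAD_TIME = 0.002  # s, typical stopped-flow instrument


@dataclass
class ObservableModel:
    """Linear readout mapping species concentrations to an instrument signal.

    signal(t) = baseline + sum_i responses[i] * [X_i](t), recorded only for
    t >= dead_time. ``obscured_fraction`` is the fraction of total signal
    change that must be lost before the first recorded point for a trace to
    be flagged as dead-time-obscured (0.86 ~ 1 - e^-2, i.e. a 1000 s^-1
    relaxation with a 2 ms dead time).
    """

    baseline: float = 0.0
    responses: dict[str, float] = field(default_factory=dict)
    dead_time: float = DEFAULT_DEAD_TIME
    obscured_fraction: float = 0.86

    def __post_init__(self):
        if self.dead_time < 0:
            raise ValidationError("dead_time must be >= 0")
        if not any(r != 0 for r in self.responses.values()):
            raise ValidationError("observable needs at least one nonzero response")


@dataclass(eq=False)
class Trace:
    """One recorded (or simulated) stopped-flow transient."""

    time: np.ndarray  # s, strictly increasing, first point >= dead time
    signal: np.ndarray
    totals: dict[str, float] = field(default_factory=dict)  # uM per moiety, post-mix
    observable: str = "fluorescence"  # or "absorbance"
    mix: dict | None = None  # {"syringes": [{species: total uM}...], "fractions": [...]}
    dead_time: float = DEFAULT_DEAD_TIME
    sigma: float | None = None  # noise estimate, signal units
    dead_time_obscured: bool = False
    label: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.signal = np.asarray(self.signal, float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise ValidationError("time and signal must be equal-length 1-d arrays")
        if not np.all(np.diff(self.time) > 0):
            bad = int(np.argmin(np.diff(self.time) > 0)) + 2
            raise ValidationError(f"time not strictly increasing (first offence near row {bad})")
        if any(v < 0 for v in self.totals.values()):
            raise ValidationError("negative concentration totals")
        if self.observable not in ("fluorescence", "absorbance"):
            raise ValidationError(f"unknown observable type {self.observable!r}")

    def __len__(self) -> int:
        return self.time.size

    @property
    def initial_state(self) -> dict[str, float] | None:
        """Explicit per-species initial concentrations, if recorded."""
        return self.extra.get("initial_species")


@dataclass(eq=False)
class TraceSet:
    """An ordered collection of traces fitted together."""

    traces: list[Trace]
    name: str = ""

    def __iter__(self):
        return iter(self.traces)

    def __len__(self):
        return len(self.traces)

    def __getitem__(self, i):
        return self.traces[i]

    def data_hash(self) -> str:
        """Hash of the numeric content, used to guard model comparisons."""
        h = hashlib.sha256()
        for tr in self.traces:
            h.update(np.ascontiguousarray(tr.time).tobytes())
            h.update(np.ascontiguousarray(tr.signal).tobytes())
        return h.hexdigest()[:16]
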