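"""Core process-data containers for fed-batch culture records.

A :class:`ProcessRecord` holds everything measured on one bioreactor batch:
sampled concentrations for the analyte panel, viable cell density (VCD),
viability, reactor volume, and the discrete feed/sampling event log together
with the feed-stream compositions.  Times are in days; concentrations in g/l;
VCD in 1e6 cells/ml; volumes in ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five metabolites measured by the at-line FLEX analyzer.
FLEX_ANALYTES = ("glucose", "lactate", "glutamine", "glutamate", "ammonium")

#: Remaining amino-acid panel (everything but glutamine/glutamate, which are FLEX).
AMINO_ACID_ANALYTES = (
    "alanine", "arginine", "asparagine", "aspartate", "cysteine", "glycine",
    "histidine", "isoleucine", "leucine", "lysine", "methionine",
    "phenylalanine", "proline", "serine", "threonine", "tryptophan",
    "tyrosine", "valine",
)

#: Product titer (monoclonal antibody), tracked like any other extracellular analyte.
PRODUCT_ANALYTE = "titer"

#: The full measured concentration panel (24 analytes).
ALL_ANALYTES = FLEX_ANALYTES + AMINO_ACID_ANALYTES + (PRODUCT_ANALYTE,)

#: Exchange-rate panel: growth plus every concentration analyte (25 rates).
GROWTH_RATE_NAME = "growth"
RATE_PANEL = (GROWTH_RATE_NAME,) + ALL_ANALYTES

#: Analytes excluded from growth-network feature construction.
GROWTH_NN_EXCLUDED = ("glucose", "lactate", "ammonium")


@dataclass(frozen=True)
class FeedEvent:
    """A bolus addition of one feed stream."""

    time_d: float
    stream: str
    volume_ml: float

    def __post_init__(self) -> None:
        if self.volume_ml < 0:
            raise ValueError(f"feed volume must be >= 0, got {self.volume_ml}")


@dataclass(frozen=True)
class SampleEvent:
    """Volume withdrawn for at-line analytics (no concentration change)."""

    time_d: float
    volume_ml: float


@dataclass
class ProcessRecord:
    """One fed-batch culture: measurements plus the reactor event log.

    Concentrations recorded at an event time reflect the *post-event* state
    (the sample is taken after feed addition).
    """

    batch_id: str
    media_group: int
    times_d: np.ndarray
    concentrations: pd.DataFrame  # index: times_d, columns: analytes, g/l
    vcd: np.ndarray               # 1e6 cells/ml
    viability: np.ndarray         # fraction in [0, 1]
    volume_ml: np.ndarray         # post-event reactor volume at each sampling time
    feed_events: list[FeedEvent] = field(default_factory=list)
    sample_events: list[SampleEvent] = field(default_factory=list)
    feed_compositions: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_d, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be a strictly increasing 1-d array")
        self.times_d = t
        for name in ("vcd", "viability", "volume_ml"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} must match sampling-time grid")
            setattr(self, name, arr)
        if len(self.concentrations) != len(t):
            raise ValueError("concentration table must match sampling-time grid")

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations.columns)

    def events_between(self, t0: float, t1: float) -> list[FeedEvent]:
        """Feed events with t0 < time <= t1 (post-event convention)."""
        return [e for e in self.feed_events if t0 < e.time_d <= t1]

    def feed_concentration(self, stream: str, analyte: str) -> float:
        if stream not in self.feed_compositions:
            raise KeyError(f"no composition recorded for feed stream {stream!r}")
        return float(self.feed_compositions[stream].get(analyte, 0.0))

    def series(self, analyte: str) -> np.ndarray:
        return self.concentrations[analyte].to_numpy(dtype=float)


def feed_schedule_from_record(record: ProcessRecord):
    """Callable ``(t0, t1) -> [(volume_ml, composition-or-None), ...]``.

    Returns the bolus additions (with their stream compositions) and sample
    withdrawals (composition ``None``) with ``t0 < t <= t1``, in within-time
    order: withdrawal first, then feeds in event-log order.
    """
    def schedule(t0: float, t1: float):
        out = []
        times = sorted({e.time_d for e in record.feed_events
                        if t0 < e.time_d <= t1}
                       | {s.time_d for s in record.sample_events
                          if t0 < s.time_d <= t1})
        for t in times:
            for s in record.sample_events:
                if np.isclose(s.time_d, t):
                    out.append((s.volume_ml, None))
            for e in record.feed_events:
                if np.isclose(e.time_d, t):
                    out.append((e.volume_ml,
                                record.feed_compositions.get(e.stream, {})))
        return out
    return schedule
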