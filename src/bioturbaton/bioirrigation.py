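"""Bioirrigation from an inert tracer in the overlying water.

Burrow-dwelling fauna flush their burrows with overlying water; an inert
tracer (sodium bromide) added to the water column is drawn into the
sediment in proportion to that activity.  The statistic is simply the
absolute concentration change over the incubation window:

    delta[Br-] = [Br-](t1) - [Br-](t0)      (mg L^-1)

More negative values indicate stronger bioirrigation.  Optionally a
faunal-free control drift can be subtracted, and the change can be
normalised per hour of incubation; neither is applied by default (the
convention is an absolute change over a fixed 8 h window).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["TracerMeasurement", "delta_br", "delta_br_table"]


@dataclass(frozen=True)
class TracerMeasurement:
    """Start/end tracer concentrations for one aquarium."""

    aquarium_id: str
    t0_conc: float  # mg L^-1
    t1_conc: float  # mg L^-1
    duration_h: float = 8.0
    control_drift: float | None = None  # mg L^-1 over the same window

    def __post_init__(self) -> None:
        if self.t0_conc < 0 or self.t1_conc < 0:
            raise ValueError("tracer concentrations must be >= 0")
        if not self.duration_h > 0:
            raise ValueError("duration must be positive")


def delta_br(m: TracerMeasurement, per_hour: bool = False) -> float:
    """Tracer concentration change (mg L^-1, or mg L^-1 h^-1 if per_hour)."""
    d = m.t1_conc - m.t0_conc
    if m.control_drift is not None:
        d -= m.control_drift
    return d / m.duration_h if per_hour else d


def delta_br_table(df: pd.DataFrame, per_hour: bool = False) -> pd.DataFrame:
    """Vectorised delta_br over a table with columns
    aquarium_id, t0_conc, t1_conc, duration_h [, control_drift]."""
    out = []
    for rec in df.to_dict("records"):
        m = TracerMeasurement(
            aquarium_id=str(rec["aquarium_id"]),
            t0_conc=float(rec["t0_conc"]),
            t1_conc=float(rec["t1_conc"]),
            duration_h=float(rec.get("duration_h", 8.0)),
            control_drift=(
                float(rec["control_drift"])
                if "control_drift" in rec and pd.notna(rec["control_drift"])
                else None
            ),
        )
        out.append({"aquarium_id": m.aquarium_id, "delta_br_mgL": delta_br(m, per_hour)})
    return pd.DataFrame(out)
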