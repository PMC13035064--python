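"""Table and volume I/O with schema validation.

The canonical table dialect is TSV (UTF-8, header row, 1-based stimulus
indices); CSV is accepted on read.  Malformed rows raise
:class:`EventTableError` naming the offending line and column.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventTableError",
    "EVENT_COLUMNS",
    "read_events",
    "write_events",
    "read_stack",
    "write_stack",
]

EVENT_COLUMNS = (
    "larva_id",
    "stimulus_index",
    "responded",
    "response_class",
    "latency_ms",
    "turn_angle_deg",
    "max_ang_vel_deg_per_ms",
    "distance_mm",
)

_KINEMATIC_COLS = ("latency_ms", "turn_angle_deg", "max_ang_vel_deg_per_ms", "distance_mm")


class EventTableError(ValueError):
    """A response-event table violated the documented schema."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def validate_events(events: pd.DataFrame, *, source: str = "<table>") -> None:
    """Validate a response-event table against the schema invariants."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise EventTableError(f"{source}: missing columns {missing}")
    # header is line 1; data row i sits at line i + 2
    for i, row in enumerate(events.itertuples(index=False)):
        line = i + 2
        idx = row.stimulus_index
        if not float(idx).is_integer() or int(idx) < 1:
            raise EventTableError(
                f"{source}:{line}: column 'stimulus_index' must be a 1-based "
                f"integer, got {idx!r}"
            )
        responded = bool(row.responded)
        cls = row.response_class
        if responded:
            if cls not in ("SLC", "LLC"):
                raise EventTableError(
                    f"{source}:{line}: column 'response_class' must be SLC or "
                    f"LLC on responded rows, got {cls!r}"
                )
            for col in _KINEMATIC_COLS:
                v = getattr(row, col)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    raise EventTableError(
                        f"{source}:{line}: column {col!r} must be present on "
                        "responded rows"
                    )
        else:
            if cls != "none":
                raise EventTableError(
                    f"{source}:{line}: column 'response_class' must be 'none' "
                    f"on non-responded rows, got {cls!r}"
                )
            for col in _KINEMATIC_COLS:
                v = getattr(row, col)
                if v is not None and not (isinstance(v, float) and math.isnan(v)):
                    raise EventTableError(
                        f"{source}:{line}: column {col!r} must be absent on "
                        "non-responded rows"
                    )


def read_events(path) -> pd.DataFrame:
    """Read and validate a response-event TSV/CSV table."""
    path = Path(path)
    events = pd.read_csv(path, sep=_sep_for(path))
    # optional string metadata: empty cells mean "untreated"/blank, not NaN
    for col in ("compound_id", "day_id", "group_id", "genotype_a", "genotype_b"):
        if col in events.columns:
            events[col] = events[col].fillna("")
    validate_events(events, source=str(path))
    events["responded"] = events["responded"].astype(bool)
    events["stimulus_index"] = events["stimulus_index"].astype(int)
    return events


def write_events(events: pd.DataFrame, path) -> None:
    """Validate and write a response-event table (TSV by default)."""
    validate_events(events)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_csv(path, sep=_sep_for(path), index=False)


def write_stack(volume: np.ndarray, path) -> None:
    """Write a 3-D volume (or a stack of them) as a multi-page TIFF."""
    import tifffile

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, np.asarray(volume, dtype=np.float32), photometric="minisblack"
    )


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF volume."""
    import tifffile

    return np.asarray(tifffile.imread(path))
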