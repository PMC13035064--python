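"""Stimulus schedules for the acoustic startle assays.

Two assays are supported:

* the drug-screen assay: 60 stimuli, a prepulse-inhibition (PPI) phase of
  30 stimuli cycling low / high / paired at 20 s inter-stimulus intervals
  (ISIs), followed by 30 high-intensity stimuli at 1.5 s ISIs; and
* the habituation assay: 50 stimuli, ten low then ten high at 30 s ISIs,
  followed by 30 high-intensity stimuli at 3 s ISIs.

A schedule carries named stimulus-index windows (1-based) that define every
behavioral statistic computed downstream (baseline initiation, habituation,
PPI, kinematics).  ISIs are onset-to-onset; the first stimulus is at t = 0.

A "paired" presentation (a low prepulse followed 400 ms later by a high
pulse) occupies a single stimulus index.  The indexed event is the scored
high pulse; its ``prepulse_time_s`` records the onset of the low prepulse,
always 0.400 s earlier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "StimulusEvent",
    "AssaySchedule",
    "build_screen_schedule",
    "build_habituation_schedule",
    "get_window",
    "PREPULSE_LEAD_S",
]

#: Lead time of the low prepulse before its paired high pulse (seconds).
PREPULSE_LEAD_S = 0.400

INTENSITIES = ("low", "high")
PHASES = ("ppi", "prehab", "habituation")


@dataclass(frozen=True)
class StimulusEvent:
    """One indexed acoustic stimulus presentation.

    For paired presentations the event is the scored high pulse and
    ``prepulse_pair_id``/``prepulse_time_s`` describe the accompanying low
    prepulse delivered :data:`PREPULSE_LEAD_S` seconds earlier.
    """

    index: int
    time_s: float
    intensity: str
    phase: str
    prepulse_pair_id: int | None = None

    @property
    def is_paired(self) -> bool:
        return self.prepulse_pair_id is not None

    @property
    def prepulse_time_s(self) -> float | None:
        if self.prepulse_pair_id is None:
            return None
        return self.time_s - PREPULSE_LEAD_S


class UnknownWindowError(KeyError):
    """Raised when a window name is not defined for a schedule."""


@dataclass(frozen=True)
class AssaySchedule:
    """An ordered stimulus list plus the named index windows over it."""

    name: str
    events: tuple[StimulusEvent, ...]
    windows: Mapping[str, frozenset[int]]

    def __post_init__(self) -> None:
        indices = [e.index for e in self.events]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError("event indices must be consecutive 1..N")
        times = [e.time_s for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        for e in self.events:
            if e.intensity not in INTENSITIES:
                raise ValueError(f"bad intensity {e.intensity!r}")
            if e.phase not in PHASES:
                raise ValueError(f"bad phase {e.phase!r}")
        all_idx = set(indices)
        for wname, widx in self.windows.items():
            if not set(widx) <= all_idx:
                raise ValueError(f"window {wname!r} references unknown indices")

    @property
    def n_stimuli(self) -> int:
        return len(self.events)

    def window(self, name: str) -> frozenset[int]:
        """Return the index set of a named window (immutable)."""
        try:
            return self.windows[name]
        except KeyError:
            available = ", ".join(sorted(self.windows))
            raise UnknownWindowError(
                f"unknown window {name!r}; available windows: {available}"
            ) from None

    def event(self, index: int) -> StimulusEvent:
        return self.events[index - 1]

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: index, time_s, intensity, phase, prepulse_pair_id."""
        return pd.DataFrame(
            {
                "index": [e.index for e in self.events],
                "time_s": [e.time_s for e in self.events],
                "intensity": [e.intensity for e in self.events],
                "phase": [e.phase for e in self.events],
                "prepulse_pair_id": [e.prepulse_pair_id for e in self.events],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None) -> str | None:
        doc = {
            "name": self.name,
            "events": [
                {
                    "index": e.index,
                    "time_s": e.time_s,
                    "intensity": e.intensity,
                    "phase": e.phase,
                    "prepulse_pair_id": e.prepulse_pair_id,
                }
                for e in self.events
            ],
            "windows": {k: sorted(v) for k, v in self.windows.items()},
        }
        text = json.dumps(doc, indent=2)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, path) -> "AssaySchedule":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        events = tuple(
            StimulusEvent(
                index=e["index"],
                time_s=e["time_s"],
                intensity=e["intensity"],
                phase=e["phase"],
                prepulse_pair_id=e.get("prepulse_pair_id"),
            )
            for e in doc["events"]
        )
        windows = {k: frozenset(v) for k, v in doc["windows"].items()}
        return cls(name=doc["name"], events=events, windows=windows)


def _window(idx: Iterable[int]) -> frozenset[int]:
    return frozenset(int(i) for i in idx)


def build_screen_schedule() -> AssaySchedule:
    """The 60-stimulus drug-screen assay.

    Stimuli 1-30 form the PPI phase at 20 s ISIs, cycling low (1, 4, ...),
    high (2, 5, ...) and paired low+high (3, 6, ...) ten times each.
    Stimuli 31-60 form the habituation phase: high intensity at 1.5 s ISIs.
    """
    events: list[StimulusEvent] = []
    pair_id = 0
    for i in range(1, 31):
        slot_onset = 20.0 * (i - 1)
        kind = (i - 1) % 3
        if kind == 0:
            events.append(StimulusEvent(i, slot_onset, "low", "ppi"))
        elif kind == 1:
            events.append(StimulusEvent(i, slot_onset, "high", "ppi"))
        else:
            pair_id += 1
            # scored high pulse; the low prepulse fires at slot onset
            events.append(
                StimulusEvent(
                    i, slot_onset + PREPULSE_LEAD_S, "high", "ppi", pair_id
                )
            )
    t = events[-1].time_s
    for i in range(31, 61):
        t += 1.5
        events.append(StimulusEvent(i, t, "high", "habituation"))

    baseline_low = _window(range(1, 29, 3))
    baseline_high = _window(range(2, 30, 3))
    paired_high = _window(range(3, 31, 3))
    windows = {
        "baseline_low": baseline_low,
        "baseline_high": baseline_high,
        "paired_high": paired_high,
        "baseline_all": baseline_low | baseline_high,
        "hab_all": _window(range(31, 61)),
        "hab_41_50": _window(range(41, 51)),
        "hab_51_60": _window(range(51, 61)),
    }
    return AssaySchedule("screen", tuple(events), windows)


def build_habituation_schedule() -> AssaySchedule:
    """The 50-stimulus habituation assay.

    Pre-habituation phase: stimuli 1-10 low then 11-20 high, 30 s ISIs.
    Habituation phase: stimuli 21-50 high at 3 s ISIs.
    """
    events: list[StimulusEvent] = []
    t = 0.0
    for i in range(1, 21):
        intensity = "low" if i <= 10 else "high"
        events.append(StimulusEvent(i, t, intensity, "prehab"))
        t += 30.0
    t = events[-1].time_s
    for i in range(21, 51):
        t += 3.0
        events.append(StimulusEvent(i, t, "high", "habituation"))

    windows = {
        "prehab_low": _window(range(1, 11)),
        "prehab_high": _window(range(11, 21)),
        "prehab_all": _window(range(1, 21)),
        "hab_all": _window(range(21, 51)),
        "hab_final": _window(range(41, 51)),
    }
    return AssaySchedule("habituation", tuple(events), windows)


def get_window(schedule: AssaySchedule, name: str) -> frozenset[int]:
    """Look up a named stimulus-index window on a schedule."""
    return schedule.window(name)


def build_schedule(name: str) -> AssaySchedule:
    """Build a schedule by assay name ("screen" or "habituation")."""
    if name == "screen":
        return build_screen_schedule()
    if name == "habituation":
        return build_habituation_schedule()
    raise ValueError(f"unknown assay {name!r}; expected 'screen' or 'habituation'")
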