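"""Per-larva behavioral statistics over an assay schedule.

Initiation percentages, habituation and PPI percentages (ratio statistics
reported as 100 x (1 - late/first)), kinematic means, the non-responder
exclusion rule, and group mean +/- SEM aggregation.

Habituation and PPI are computed per larva and then averaged over larvae.
Larvae whose denominator window has zero SLC initiations have an undefined
ratio and are dropped from that metric (never substituted with 0 or 100);
dropped counts are reported by :func:`group_summary`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .schedule import AssaySchedule

__all__ = [
    "SLC_LATENCY_BOUNDARY_MS",
    "classify_response",
    "exclude_nonresponders",
    "initiation_percent",
    "habituation_percent",
    "ppi_percent",
    "kinematic_summary",
    "summarize_cohort",
    "group_summary",
]

logger = logging.getLogger(__name__)

#: Latency boundary separating short- from long-latency C-bends (ms).
SLC_LATENCY_BOUNDARY_MS = 15.0

KINEMATIC_COLUMNS = ("turn_angle_deg", "max_ang_vel_deg_per_ms", "distance_mm")


def classify_response(
    latency_ms: float | None,
    responded: bool,
    boundary_ms: float = SLC_LATENCY_BOUNDARY_MS,
) -> str:
    """Classify a response as SLC, LLC or none by movement latency."""
    if not responded:
        if latency_ms is not None and not (
            isinstance(latency_ms, float) and math.isnan(latency_ms)
        ):
            raise ValueError("latency must be absent when responded is False")
        return "none"
    if latency_ms is None or (
        isinstance(latency_ms, float) and math.isnan(latency_ms)
    ):
        raise ValueError("latency must be present when responded is True")
    if latency_ms < 0:
        raise ValueError(f"negative latency {latency_ms}")
    return "SLC" if latency_ms < boundary_ms else "LLC"


def _check_coverage(events: pd.DataFrame, schedule: AssaySchedule) -> None:
    expected = set(range(1, schedule.n_stimuli + 1))
    gaps = {}
    for larva_id, sub in events.groupby("larva_id", sort=False):
        missing = expected - set(sub["stimulus_index"].astype(int))
        if missing:
            gaps[larva_id] = sorted(missing)
    if gaps:
        detail = "; ".join(
            f"{lid}: missing stimuli {idx}" for lid, idx in sorted(gaps.items())
        )
        raise ValueError(f"incomplete event tables: {detail}")


def exclude_nonresponders(
    events: pd.DataFrame, schedule: AssaySchedule
) -> tuple[list[str], list[str]]:
    """Split larvae into kept and excluded by the non-responder rule.

    A larva failing to initiate any movement to 60% or more of the assay's
    stimuli is excluded (a tie at exactly 60% is excluded).  Returns
    ``(kept_ids, excluded_ids)`` in first-appearance order.
    """
    _check_coverage(events, schedule)
    threshold = 0.60 * schedule.n_stimuli
    kept, excluded = [], []
    for larva_id, sub in events.groupby("larva_id", sort=False):
        n_failed = int((~sub["responded"].astype(bool)).sum())
        (excluded if n_failed >= threshold else kept).append(larva_id)
    return kept, excluded


def _mask(events: pd.DataFrame, indices: Iterable[int]) -> pd.DataFrame:
    return events[events["stimulus_index"].isin(set(indices))]


def initiation_percent(
    events: pd.DataFrame, indices: Iterable[int], response_filter: str = "SLC"
) -> float:
    """Initiation percentage for one larva over a stimulus window.

    ``response_filter`` is ``"SLC"`` (short-latency C-bends only) or
    ``"any"`` (all movement initiations).  Returns
    100 x initiations / window size.
    """
    indices = set(indices)
    if not indices:
        raise ValueError("empty stimulus index set")
    sub = _mask(events, indices)
    if response_filter == "SLC":
        count = int((sub["response_class"] == "SLC").sum())
    elif response_filter == "any":
        count = int(sub["responded"].astype(bool).sum())
    else:
        raise ValueError(f"response_filter must be 'SLC' or 'any', got {response_filter!r}")
    return 100.0 * count / len(indices)


def _slc_rate(events: pd.DataFrame, indices: set[int]) -> tuple[int, float]:
    sub = _mask(events, indices)
    count = int((sub["response_class"] == "SLC").sum())
    return count, count / len(indices)


def habituation_percent(
    events: pd.DataFrame,
    first_window: Iterable[int],
    late_window: Iterable[int],
) -> float | None:
    """Habituation percentage: 100 x (1 - late SLC rate / first SLC rate).

    Undefined (``None``) when the larva initiated no SLCs in the first
    window; may be negative (facilitation) and is not clamped.
    """
    first_window, late_window = set(first_window), set(late_window)
    if not first_window or not late_window:
        raise ValueError("windows must be non-empty")
    if first_window & late_window:
        raise ValueError("habituation windows must not overlap")
    first_count, first_rate = _slc_rate(events, first_window)
    if first_count == 0:
        return None
    _, late_rate = _slc_rate(events, late_window)
    return 100.0 * (1.0 - late_rate / first_rate)


def ppi_percent(
    events: pd.DataFrame,
    paired_high: Iterable[int],
    unpaired_high: Iterable[int],
) -> float | None:
    """PPI percentage: 100 x (1 - paired SLC rate / unpaired SLC rate).

    Undefined (``None``) when the larva initiated no SLCs to unpaired
    high-intensity stimuli.
    """
    paired_high, unpaired_high = set(paired_high), set(unpaired_high)
    if not paired_high or not unpaired_high:
        raise ValueError("windows must be non-empty")
    if paired_high & unpaired_high:
        raise ValueError("paired and unpaired windows must not overlap")
    unpaired_count, unpaired_rate = _slc_rate(events, unpaired_high)
    if unpaired_count == 0:
        return None
    _, paired_rate = _slc_rate(events, paired_high)
    return 100.0 * (1.0 - paired_rate / unpaired_rate)


def kinematic_summary(
    events: pd.DataFrame, indices: Iterable[int]
) -> dict[str, float] | None:
    """Per-larva kinematic means over responded stimuli in a window.

    Returns ``None`` when the larva made no responses in the window.
    """
    indices = set(indices)
    if not indices:
        raise ValueError("empty stimulus index set")
    sub = _mask(events, indices)
    sub = sub[sub["responded"].astype(bool)]
    if sub.empty:
        return None
    return {col: float(sub[col].mean()) for col in KINEMATIC_COLUMNS}


# ----------------------------------------------------------- cohort summary

_SCREEN_METRIC_WINDOWS = {
    "init": ("baseline_low", "baseline_high"),
    "habituation": (("hab_41_50", "baseline_high"), ("hab_51_60", "baseline_high")),
    "ppi": ("paired_high", "baseline_high"),
    "kinematics": "baseline_high",
}


def summarize_cohort(
    events: pd.DataFrame, schedule: AssaySchedule
) -> pd.DataFrame:
    """Per-larva behavioral summaries for a cohort under one schedule.

    Applies the exclusion rule first; excluded larvae appear with
    ``excluded=True`` and no metric values.  For the screen schedule the
    habituation percentage is reported twice (windows 41-50 and 51-60, each
    against the ten unpaired baseline high-intensity stimuli) along with a
    PPI percentage; for the habituation schedule a single habituation value
    (final ten stimuli against the ten pre-habituation high stimuli).
    """
    kept, excluded = exclude_nonresponders(events, schedule)
    if schedule.name == "screen":
        low_w = schedule.window("baseline_low")
        high_w = schedule.window("baseline_high")
        hab_windows = {
            "hab_pct_41_50": (schedule.window("hab_41_50"), high_w),
            "hab_pct_51_60": (schedule.window("hab_51_60"), high_w),
        }
        ppi_windows = (schedule.window("paired_high"), high_w)
        kin_window = high_w
    elif schedule.name == "habituation":
        low_w = schedule.window("prehab_low")
        high_w = schedule.window("prehab_high")
        hab_windows = {
            "hab_pct_final": (schedule.window("hab_final"), high_w)
        }
        ppi_windows = None
        kin_window = high_w
    else:
        raise ValueError(f"no metric windows defined for schedule {schedule.name!r}")

    # vectorized evaluation on (larva x stimulus) matrices; semantically
    # identical to calling the per-larva functions larva by larva (tested)
    m = schedule.n_stimuli
    codes, larva_ids = pd.factorize(events["larva_id"], sort=False)
    order = np.lexsort((events["stimulus_index"].to_numpy(), codes))
    n = len(larva_ids)
    cls = events["response_class"].to_numpy()[order].reshape(n, m)
    resp = events["responded"].to_numpy(dtype=bool)[order].reshape(n, m)
    slc = cls == "SLC"

    def cols(window: Iterable[int]) -> np.ndarray:
        return np.fromiter((i - 1 for i in sorted(window)), dtype=int)

    low_c, high_c = cols(low_w), cols(high_w)
    excluded_mask = (~resp).sum(axis=1) >= 0.60 * m

    data: dict[str, object] = {"larva_id": larva_ids}
    meta_cols = [
        c
        for c in ("genotype_a", "genotype_b", "compound_id", "dose_um", "day_id", "group_id")
        if c in events.columns
    ]
    for c in meta_cols:
        data[c] = events[c].to_numpy()[order].reshape(n, m)[:, 0]
    data["excluded"] = excluded_mask

    def masked(values: np.ndarray) -> np.ndarray:
        return np.where(excluded_mask, np.nan, values)

    data["slc_init_low_pct"] = masked(100.0 * slc[:, low_c].mean(axis=1))
    data["slc_init_high_pct"] = masked(100.0 * slc[:, high_c].mean(axis=1))
    data["any_init_low_pct"] = masked(100.0 * resp[:, low_c].mean(axis=1))
    data["any_init_high_pct"] = masked(100.0 * resp[:, high_c].mean(axis=1))

    first_count = slc[:, high_c].sum(axis=1)
    first_rate = first_count / len(high_c)
    for name, (late, _first) in hab_windows.items():
        late_rate = slc[:, cols(late)].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            hab = 100.0 * (1.0 - late_rate / first_rate)
        data[name] = masked(np.where(first_count > 0, hab, np.nan))
    if ppi_windows is not None:
        paired_rate = slc[:, cols(ppi_windows[0])].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ppi = 100.0 * (1.0 - paired_rate / first_rate)
        data["ppi_pct"] = masked(np.where(first_count > 0, ppi, np.nan))

    kin_c = cols(kin_window)
    resp_kin = resp[:, kin_c]
    any_resp = resp_kin.any(axis=1)
    for col in KINEMATIC_COLUMNS:
        vals = events[col].to_numpy(dtype=float)[order].reshape(n, m)[:, kin_c]
        with np.errstate(invalid="ignore"):
            means = np.where(
                any_resp,
                np.nansum(np.where(resp_kin, vals, 0.0), axis=1)
                / np.maximum(resp_kin.sum(axis=1), 1),
                np.nan,
            )
        data[f"kin_{col}"] = masked(means)
    summary = pd.DataFrame(data)
    n_excluded = len(excluded)
    if n_excluded:
        logger.info(
            "excluded %d of %d larvae by the 60%% non-response rule",
            n_excluded,
            len(kept) + n_excluded,
        )
    return summary


def group_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SEM per metric over non-excluded larvae.

    Undefined per-larva values (NaN, from dropped ratio metrics or absent
    kinematics) are skipped per metric; ``n`` reports the count actually
    used.  SEM is NaN when n = 1.
    """
    if "excluded" in summaries.columns:
        usable = summaries[~summaries["excluded"].astype(bool)]
    else:
        usable = summaries
    if usable.empty:
        raise ValueError("all larvae excluded; no group summary possible")
    metric_cols = [
        c
        for c in usable.columns
        if c.startswith(("slc_", "any_", "hab_", "ppi_", "kin_"))
    ]
    records = []
    for col in metric_cols:
        values = pd.to_numeric(usable[col], errors="coerce").dropna()
        n = len(values)
        n_dropped = len(usable) - n
        mean = float(values.mean()) if n else float("nan")
        sem = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        records.append(
            {"metric": col, "mean": mean, "sem": sem, "n": n, "n_dropped": n_dropped}
        )
        if n_dropped:
            logger.info("metric %s: dropped %d larvae with undefined values", col, n_dropped)
    return pd.DataFrame(records)
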