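"""Voxelwise group-difference mapping on registered ratio volumes.

Each voxel is compared between two groups of stacks with a Mann-Whitney U
test (normal approximation, mid-ranks with tie-corrected variance, no
continuity correction).  The signed z-score is positive where group B is
stochastically larger.  Significance is controlled by Benjamini-Hochberg
FDR over all voxels; ROI summaries report the significant-|z| sum
("signal"), the mean z over significant voxels, and significant-voxel
counts, plus a density-ratio label enrichment score where values > 1
indicate relative enrichment of signal inside a label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ZMap",
    "ROIMask",
    "mann_whitney_z",
    "voxelwise_map",
    "fdr_mask",
    "roi_signal",
    "label_enrichment",
]


@dataclass(frozen=True)
class ROIMask:
    """A named boolean region-of-interest volume."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 3:
            raise ValueError("ROI mask must be 3-D")


@dataclass(frozen=True)
class ZMap:
    """Signed voxelwise z-score volume with its FDR significance mask."""

    z_volume: np.ndarray
    p_volume: np.ndarray
    sig_mask: np.ndarray | None = None
    fdr_q: float | None = None

    def with_fdr(self, q: float) -> "ZMap":
        """Return a copy with the significance mask set at FDR level q."""
        mask = fdr_mask(self.p_volume, q)
        return ZMap(self.z_volume, self.p_volume, mask, q)


def _rank_stats(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized U_b, mean and SD of U under H0 for stacked samples.

    ``a`` has shape (n_a, V) and ``b`` (n_b, V); statistics are computed
    independently per column using mid-ranks and the tie-corrected variance.
    Zero-variance columns (all values tied) get sigma = 0.
    """
    n_a, v = a.shape
    n_b = b.shape[0]
    n = n_a + n_b
    pooled = np.concatenate([a, b], axis=0)
    ranks = stats.rankdata(pooled, axis=0)
    u_b = ranks[n_a:].sum(axis=0) - n_b * (n_b + 1) / 2.0

    # tie correction: sum(t^3 - t) over tie groups, per column
    ordered = np.sort(pooled, axis=0)
    new_group = np.ones_like(ordered, dtype=bool)
    new_group[1:] = ordered[1:] != ordered[:-1]
    tie_term = np.zeros(v)
    tied_cols = np.flatnonzero(~new_group.all(axis=0))
    for col in tied_cols:
        starts = np.flatnonzero(new_group[:, col])
        lengths = np.diff(np.append(starts, n))
        tie_term[col] = float(np.sum(lengths.astype(float) ** 3 - lengths))

    mu = n_a * n_b / 2.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var = np.clip(var, 0.0, None)
    return u_b, np.full(v, mu), np.sqrt(var)


def mann_whitney_z(a, b) -> float:
    """Signed Mann-Whitney z for two samples.

    ``z = (U_b - mu_U) / sigma_U`` with mid-ranks, tie-corrected variance
    and no continuity correction; positive when group ``b`` is
    stochastically larger than group ``a``.  Zero-variance input (all
    values identical) yields z = 0.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    u_b, mu, sigma = _rank_stats(a[:, None], b[:, None])
    if sigma[0] == 0.0:
        return 0.0
    return float((u_b[0] - mu[0]) / sigma[0])


def voxelwise_map(group_a: np.ndarray, group_b: np.ndarray) -> ZMap:
    """Apply :func:`mann_whitney_z` independently at every voxel.

    ``group_a`` and ``group_b`` are arrays of shape (n_stacks, Z, Y, X)
    with matching volume dimensions.  Returns the signed z volume and the
    two-sided normal-approximation p volume (no significance mask yet).
    """
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    if group_a.ndim != 4 or group_b.ndim != 4:
        raise ValueError("stack groups must be 4-D: (n_stacks, Z, Y, X)")
    if group_a.shape[1:] != group_b.shape[1:]:
        raise ValueError(
            f"volume shapes differ: {group_a.shape[1:]} vs {group_b.shape[1:]}"
        )
    if group_a.shape[0] < 3 or group_b.shape[0] < 3:
        raise ValueError("need at least 3 stacks per group")
    shape = group_a.shape[1:]
    flat_a = group_a.reshape(group_a.shape[0], -1)
    flat_b = group_b.reshape(group_b.shape[0], -1)
    u_b, mu, sigma = _rank_stats(flat_a, flat_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (u_b - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)
    p = np.where(sigma > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return ZMap(z.reshape(shape), p.reshape(shape))


def fdr_mask(p_volume: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask over all voxels at FDR level q."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    p = np.asarray(p_volume, dtype=float)
    if p.size == 0:
        return np.zeros_like(p, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return rejected.reshape(p.shape)


def _require_sig(zmap: ZMap) -> np.ndarray:
    if zmap.sig_mask is None:
        raise ValueError("ZMap has no significance mask; call with_fdr(q) first")
    return np.asarray(zmap.sig_mask, dtype=bool)


def roi_signal(zmap: ZMap, roi: ROIMask) -> dict[str, float]:
    """Summaries of significant signal inside an ROI.

    ``signal`` is the sum of |z| over significant voxels of the ROI's
    dominant sign (the sign holding the larger share of significant-|z|
    mass); ``mean_z`` is the literal mean z over all significant voxels in
    the ROI, and ``n_sig`` their count.
    """
    sig = _require_sig(zmap)
    mask = roi.mask
    if mask.shape != zmap.z_volume.shape:
        raise ValueError("ROI shape does not match z volume")
    if not mask.any():
        raise ValueError(f"ROI {roi.name!r} is empty")
    z = zmap.z_volume
    in_roi = sig & mask
    n_sig = int(in_roi.sum())
    if n_sig == 0:
        return {"signal": 0.0, "mean_z": 0.0, "n_sig": 0}
    z_sig = z[in_roi]
    pos_mass = float(np.abs(z_sig[z_sig > 0]).sum())
    neg_mass = float(np.abs(z_sig[z_sig < 0]).sum())
    dominant = z_sig > 0 if pos_mass >= neg_mass else z_sig < 0
    return {
        "signal": float(np.abs(z_sig[dominant]).sum()),
        "mean_z": float(z_sig.mean()),
        "n_sig": n_sig,
    }


def label_enrichment(zmap: ZMap, label: ROIMask, brain: ROIMask) -> float | None:
    """Density ratio of significant |z| inside a label versus the brain.

    ``(sum |z| over significant label voxels / label size) /
    (sum |z| over significant brain voxels / brain size)``; values > 1
    indicate relative enrichment.  ``None`` when the brain mask holds no
    significant signal.
    """
    sig = _require_sig(zmap)
    label_mask = label.mask
    brain_mask = brain.mask
    if label_mask.shape != zmap.z_volume.shape or brain_mask.shape != zmap.z_volume.shape:
        raise ValueError("mask shapes must match the z volume")
    if np.any(label_mask & ~brain_mask):
        raise ValueError("label mask must lie inside the brain mask")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if not label_mask.any():
        raise ValueError("label mask is empty")
    abs_z = np.abs(zmap.z_volume)
    brain_signal = float(abs_z[sig & brain_mask].sum())
    if brain_signal == 0.0:
        return None
    brain_density = brain_signal / int(brain_mask.sum())
    label_density = float(abs_z[sig & label_mask].sum()) / int(label_mask.sum())
    return label_density / brain_density


def roi_summary_table(
    zmap: ZMap, rois: list[ROIMask], brain: ROIMask | None = None
) -> pd.DataFrame:
    """Tabulate per-ROI signal (and optional label enrichment vs brain)."""
    records = []
    for roi in rois:
        row: dict[str, object] = {"roi": roi.name}
        row.update(roi_signal(zmap, roi))
        if brain is not None:
            row["enrichment"] = label_enrichment(zmap, roi, brain)
        records.append(row)
    return pd.DataFrame(records)
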