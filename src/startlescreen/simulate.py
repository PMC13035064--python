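"""Synthetic behavioral cohorts, compound libraries, and brain stacks.

The generator emulates the statistical structure the analysis stages assume:

* Bernoulli short-latency C-bend (SLC) startle responses with
  intensity-dependent baseline rates (defaults calibrated so low-intensity
  stimuli elicit ~25% SLC responses and high-intensity stimuli ~75%);
* exponential habituation decay during short-ISI stimulation whose
  magnitude depends on genotype capacity and a dose-scaled drug shift;
* prepulse suppression of SLC initiation on paired presentations;
* long-latency C-bends (LLCs) filling in total-movement probability;
* latency-separated SLC/LLC classes and Gaussian kinematics;
* a fraction of non-responder larvae; and
* daily screen structure with treated groups plus two non-treated
  control groups per day.

All stochastic outputs are exactly reproducible from (inputs, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .quantify import CrossSpec, parse_genotype, punnett_expected
from .schedule import AssaySchedule

__all__ = [
    "LarvaMeta",
    "DrugEffect",
    "BehaviorModelConfig",
    "ConfigError",
    "DEFAULT_CROSS",
    "classify_genotype",
    "make_metas",
    "simulate_cohort",
    "simulate_screen_day",
    "make_library",
    "simulate_brain_stacks",
    "sphere_mask",
]

#: The screen cross: parent 1 heterozygous at locus a / homozygous mutant at
#: locus b, parent 2 the converse.  Yields four offspring classes at 25% each.
DEFAULT_CROSS = CrossSpec("+/-;-/-", "-/-;+/-")

GENOTYPE_CLASSES = ("wildtype", "heterozygous", "double_mutant")


class ConfigError(ValueError):
    """Invalid behavior-model configuration."""


@dataclass(frozen=True)
class LarvaMeta:
    """Identity and grouping metadata for one larva."""

    larva_id: str
    genotype_a: str
    genotype_b: str
    treatment: tuple[str, float] | None = None
    day_id: str = "day1"
    group_id: str = "g1"

    @property
    def genotype(self) -> str:
        return f"{self.genotype_a};{self.genotype_b}"


@dataclass(frozen=True)
class DrugEffect:
    """Additive shifts a compound applies to habituation capacity and
    prepulse suppression, per unit reference dose."""

    habituation_shift: float = 0.0
    ppi_shift: float = 0.0


def classify_genotype(genotype_a: str, genotype_b: str) -> str:
    """Map a two-locus genotype onto a capacity class.

    Both loci homozygous mutant -> ``double_mutant``; both loci homozygous
    wild type -> ``wildtype``; anything else -> ``heterozygous``.
    """
    (a1, a2), (b1, b2) = parse_genotype(f"{genotype_a};{genotype_b}")
    a = {a1, a2}
    b = {b1, b2}
    if a == {"-"} and b == {"-"}:
        return "double_mutant"
    if a == {"+"} and b == {"+"}:
        return "wildtype"
    return "heterozygous"


def _default_h_g() -> dict[str, float]:
    return {"wildtype": 0.85, "heterozygous": 0.55, "double_mutant": 0.25}


def _default_ppi_g() -> dict[str, float]:
    return {"wildtype": 0.60, "heterozygous": 0.35, "double_mutant": 0.15}


def _default_latency() -> dict[str, tuple[float, float, float, float]]:
    # (mean, sd, lower, upper) ms; SLC/LLC separated by the 15 ms boundary
    return {
        "SLC": (8.0, 2.0, 2.0, 14.0),
        "LLC": (28.0, 6.0, 16.0, math.inf),
    }


def _default_kinematics() -> dict[str, dict[str, tuple[float, float]]]:
    return {
        "wildtype": {
            "turn_angle_deg": (130.0, 25.0),
            "max_ang_vel_deg_per_ms": (28.0, 6.0),
            "distance_mm": (3.5, 0.8),
        },
        "heterozygous": {
            "turn_angle_deg": (115.0, 25.0),
            "max_ang_vel_deg_per_ms": (25.0, 6.0),
            "distance_mm": (3.0, 0.8),
        },
        "double_mutant": {
            "turn_angle_deg": (95.0, 25.0),
            "max_ang_vel_deg_per_ms": (22.0, 6.0),
            "distance_mm": (2.2, 0.8),
        },
    }


@dataclass
class BehaviorModelConfig:
    """Parameters of the synthetic response generator.

    Baseline SLC probabilities are the assay design targets (25% SLC to
    low-intensity, 75% to high-intensity stimuli); any-movement baselines,
    genotype capacities and kinematics are generator choices documented in
    the defaults.
    """

    p_slc_low: float = 0.25
    p_slc_high: float = 0.75
    p_any_low: float = 0.50
    p_any_high: float = 0.95
    h_g: dict[str, float] = field(default_factory=_default_h_g)
    ppi_g: dict[str, float] = field(default_factory=_default_ppi_g)
    tau: float = 8.0
    drug_effects: dict[str, DrugEffect] = field(default_factory=dict)
    reference_dose_um: float = 1.0
    latency: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_latency
    )
    kinematics: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_kinematics
    )
    nonresponder_fraction: float = 0.05
    nonresponder_scale: float = 0.2
    day_effect_sd: float = 0.0

    def validate(self) -> None:
        probs = {
            "p_slc_low": self.p_slc_low,
            "p_slc_high": self.p_slc_high,
            "p_any_low": self.p_any_low,
            "p_any_high": self.p_any_high,
            "nonresponder_fraction": self.nonresponder_fraction,
            "nonresponder_scale": self.nonresponder_scale,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.tau <= 0:
            raise ConfigError(f"tau must be > 0, got {self.tau}")
        for mapping, label in ((self.h_g, "h_g"), (self.ppi_g, "ppi_g")):
            for key, v in mapping.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{label}[{key!r}] must be in [0, 1]")
        for cls, (mu, sd, lo, hi) in self.latency.items():
            if sd < 0:
                raise ConfigError(f"latency sd for {cls} must be >= 0")
            if lo >= hi:
                raise ConfigError(f"latency bounds for {cls} must satisfy lo < hi")
        for gclass, metrics in self.kinematics.items():
            for metric, (mu, sd) in metrics.items():
                if sd < 0:
                    raise ConfigError(
                        f"kinematic sd for {gclass}/{metric} must be >= 0"
                    )
        if self.reference_dose_um <= 0:
            raise ConfigError("reference_dose_um must be > 0")
        if self.day_effect_sd < 0:
            raise ConfigError("day_effect_sd must be >= 0")


def _lookup(mapping: Mapping[str, float], genotype_a: str, genotype_b: str) -> float:
    """Per-genotype parameter lookup: exact genotype key, then class key."""
    key = f"{genotype_a};{genotype_b}"
    if key in mapping:
        return mapping[key]
    return mapping[classify_genotype(genotype_a, genotype_b)]


def make_metas(
    n: int,
    *,
    seed: int | np.random.Generator,
    cross: CrossSpec = DEFAULT_CROSS,
    treatment: tuple[str, float] | None = None,
    day_id: str = "day1",
    group_id: str = "g1",
    id_prefix: str = "larva",
) -> list[LarvaMeta]:
    """Draw ``n`` larvae with genotypes at the cross's expected ratios."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    expected = punnett_expected(cross)
    genotypes = sorted(expected)
    p = np.array([expected[g] for g in genotypes])
    draws = rng.choice(len(genotypes), size=n, p=p)
    metas = []
    for i, k in enumerate(draws):
        ga, gb = genotypes[k].split(";")
        metas.append(
            LarvaMeta(
                larva_id=f"{id_prefix}{i + 1:04d}",
                genotype_a=ga,
                genotype_b=gb,
                treatment=treatment,
                day_id=day_id,
                group_id=group_id,
            )
        )
    return metas


def _effective_params(
    meta: LarvaMeta, config: BehaviorModelConfig
) -> tuple[float, float]:
    """(h_eff, ppi_eff) for one larva, combining genotype and treatment."""
    h = _lookup(config.h_g, meta.genotype_a, meta.genotype_b)
    ppi = _lookup(config.ppi_g, meta.genotype_a, meta.genotype_b)
    if meta.treatment is not None:
        compound_id, dose = meta.treatment
        effect = config.drug_effects.get(compound_id)
        if effect is not None:
            scale = dose / config.reference_dose_um
            h += effect.habituation_shift * scale
            ppi += effect.ppi_shift * scale
    return float(np.clip(h, 0.0, 1.0)), float(np.clip(ppi, 0.0, 1.0))


def _truncnorm_draw(
    rng: np.random.Generator,
    mu: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mu)
    a = (lo - mu) / sd
    b = (hi - mu) / sd if math.isfinite(hi) else math.inf
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def simulate_cohort(
    schedule: AssaySchedule,
    metas: Sequence[LarvaMeta],
    config: BehaviorModelConfig,
    seed: int,
) -> pd.DataFrame:
    """Simulate per-stimulus responses for a cohort of larvae.

    Returns a long-format table with one row per (larva, stimulus):
    response class, latency, kinematics (present only when the larva
    responded) and the larva's metadata.  Deterministic given
    (schedule, metas, config, seed).
    """
    if not metas:
        raise ValueError("metas must be non-empty")
    config.validate()
    rng = np.random.default_rng(seed)

    n = len(metas)
    m = schedule.n_stimuli
    events = schedule.events

    is_high = np.array([e.intensity == "high" for e in events])
    is_paired = np.array([e.is_paired for e in events])
    is_hab = np.array([e.phase == "habituation" for e in events])
    # j counts habituation stimuli 1..k within the short-ISI phase
    hab_j = np.cumsum(is_hab) * is_hab
    decay = np.where(is_hab, np.exp(-hab_j / config.tau), 1.0)

    # per-day baseline shift on the logit scale (off by default)
    day_ids = sorted({meta.day_id for meta in metas})
    day_shift = {d: 0.0 for d in day_ids}
    if config.day_effect_sd > 0:
        shifts = rng.normal(0.0, config.day_effect_sd, size=len(day_ids))
        day_shift = dict(zip(day_ids, shifts))

    def shifted(p: float, delta: float) -> float:
        if delta == 0.0 or p in (0.0, 1.0):
            return p
        return float(expit(logit(p) + delta))

    p_slc = np.empty((n, m))
    p_any = np.empty((n, m))
    for i, meta in enumerate(metas):
        h_eff, ppi_eff = _effective_params(meta, config)
        delta = day_shift[meta.day_id]
        base_slc = np.where(
            is_high,
            shifted(config.p_slc_high, delta),
            shifted(config.p_slc_low, delta),
        )
        base_any = np.where(
            is_high,
            shifted(config.p_any_high, delta),
            shifted(config.p_any_low, delta),
        )
        row = base_slc * ((1.0 - h_eff) + h_eff * decay)
        row = np.where(is_paired, base_slc * (1.0 - ppi_eff), row)
        p_slc[i] = row
        p_any[i] = base_any

    nonresponder = rng.random(n) < config.nonresponder_fraction
    scale = np.where(nonresponder, config.nonresponder_scale, 1.0)[:, None]
    p_slc = p_slc * scale
    p_any = np.maximum(p_any * scale, p_slc)

    slc = rng.random((n, m)) < p_slc
    with np.errstate(divide="ignore", invalid="ignore"):
        p_llc_cond = np.where(p_slc < 1.0, (p_any - p_slc) / (1.0 - p_slc), 0.0)
    p_llc_cond = np.clip(p_llc_cond, 0.0, 1.0)
    llc = (~slc) & (rng.random((n, m)) < p_llc_cond)
    responded = slc | llc

    latency = np.full((n, m), np.nan)
    for cls, mask in (("SLC", slc), ("LLC", llc)):
        k = int(mask.sum())
        if k:
            mu, sd, lo, hi = config.latency[cls]
            latency[mask] = _truncnorm_draw(rng, mu, sd, lo, hi, k)

    kin = {
        "turn_angle_deg": np.full((n, m), np.nan),
        "max_ang_vel_deg_per_ms": np.full((n, m), np.nan),
        "distance_mm": np.full((n, m), np.nan),
    }
    gclass = np.array(
        [classify_genotype(meta.genotype_a, meta.genotype_b) for meta in metas]
    )
    for metric, out in kin.items():
        draws = np.empty((n, m))
        for cls in np.unique(gclass):
            rows = gclass == cls
            mu, sd = config.kinematics[cls][metric]
            draws[rows] = rng.normal(mu, sd, size=(int(rows.sum()), m))
        out[responded] = np.clip(draws, 0.0, None)[responded]

    response_class = np.where(slc, "SLC", np.where(llc, "LLC", "none"))

    idx = np.arange(1, m + 1)
    frames = {
        "larva_id": np.repeat([meta.larva_id for meta in metas], m),
        "stimulus_index": np.tile(idx, n),
        "responded": responded.ravel(),
        "response_class": response_class.ravel(),
        "latency_ms": latency.ravel(),
        "turn_angle_deg": kin["turn_angle_deg"].ravel(),
        "max_ang_vel_deg_per_ms": kin["max_ang_vel_deg_per_ms"].ravel(),
        "distance_mm": kin["distance_mm"].ravel(),
        "genotype_a": np.repeat([meta.genotype_a for meta in metas], m),
        "genotype_b": np.repeat([meta.genotype_b for meta in metas], m),
        "compound_id": np.repeat(
            [meta.treatment[0] if meta.treatment else "" for meta in metas], m
        ),
        "dose_um": np.repeat(
            [meta.treatment[1] if meta.treatment else np.nan for meta in metas], m
        ),
        "day_id": np.repeat([meta.day_id for meta in metas], m),
        "group_id": np.repeat([meta.group_id for meta in metas], m),
    }
    return pd.DataFrame(frames)


def simulate_screen_day(
    n_compounds: int,
    group_size: int,
    config: BehaviorModelConfig,
    seed: int,
    *,
    schedule: AssaySchedule | None = None,
    day_id: str = "day1",
    cross: CrossSpec = DEFAULT_CROSS,
    compound_ids: Sequence[str] | None = None,
    dose_um: float = 1.0,
    n_control_groups: int = 2,
) -> tuple[dict[str, pd.DataFrame], list[pd.DataFrame]]:
    """One experimental day: treated groups plus non-treated control groups.

    Each compound is administered to one group of ``group_size`` larvae
    (mixed genotypes at the cross's expected ratios); ``n_control_groups``
    (two, by design) groups are left untreated.  Returns
    ``(treated_by_compound, control_tables)``.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if n_compounds < 0:
        raise ValueError("n_compounds must be >= 0")
    config.validate()
    if schedule is None:
        from .schedule import build_screen_schedule

        schedule = build_screen_schedule()
    if compound_ids is None:
        compound_ids = [f"C{i + 1:04d}" for i in range(n_compounds)]
    elif len(compound_ids) != n_compounds:
        raise ValueError("compound_ids length must equal n_compounds")

    root = np.random.SeedSequence(seed)
    child_seeds = root.spawn(n_compounds + n_control_groups)

    treated: dict[str, pd.DataFrame] = {}
    for i, compound_id in enumerate(compound_ids):
        rng = np.random.default_rng(child_seeds[i])
        metas = make_metas(
            group_size,
            seed=rng,
            cross=cross,
            treatment=(compound_id, dose_um),
            day_id=day_id,
            group_id=f"{day_id}:{compound_id}",
            id_prefix=f"{day_id}_{compound_id}_",
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        treated[compound_id] = simulate_cohort(schedule, metas, config, sub_seed)

    controls: list[pd.DataFrame] = []
    for j in range(n_control_groups):
        rng = np.random.default_rng(child_seeds[n_compounds + j])
        metas = make_metas(
            group_size,
            seed=rng,
            cross=cross,
            treatment=None,
            day_id=day_id,
            group_id=f"{day_id}:ctrl{j + 1}",
            id_prefix=f"{day_id}_ctrl{j + 1}_",
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        controls.append(simulate_cohort(schedule, metas, config, sub_seed))
    return treated, controls


def make_library(
    n_compounds: int,
    class_sizes: Mapping[str, int],
    seed: int,
    *,
    other_class: str = "other",
) -> pd.DataFrame:
    """Assign each of ``n_compounds`` compounds one biological target class.

    ``class_sizes`` fixes the number of compounds per named class; the
    remainder are labeled ``other_class``.  Assignment order is shuffled
    reproducibly under ``seed``.
    """
    total_named = sum(class_sizes.values())
    if any(v < 0 for v in class_sizes.values()):
        raise ValueError("class sizes must be non-negative")
    if total_named > n_compounds:
        raise ValueError(
            f"class sizes sum to {total_named} > n_compounds = {n_compounds}"
        )
    labels: list[str] = []
    for cls, count in class_sizes.items():
        labels.extend([cls] * count)
    labels.extend([other_class] * (n_compounds - total_named))
    rng = np.random.default_rng(seed)
    labels = [labels[i] for i in rng.permutation(n_compounds)]
    return pd.DataFrame(
        {
            "compound_id": [f"C{i + 1:04d}" for i in range(n_compounds)],
            "target_class": labels,
        }
    )


# ------------------------------------------------------------ brain stacks

def sphere_mask(
    shape: tuple[int, int, int], center: tuple[float, float, float], radius: float
) -> np.ndarray:
    """Boolean spherical ROI mask inside a volume of the given shape."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        (zz - center[0]) ** 2
        + (yy - center[1]) ** 2
        + (xx - center[2]) ** 2
    )
    return d2 <= radius**2


def simulate_brain_stacks(
    shape: tuple[int, int, int],
    n_per_group: int,
    effect_rois: Sequence[tuple[np.ndarray, float]],
    noise_sd: float,
    seed: int,
    *,
    baseline: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Two groups of synthetic registered ratio volumes with planted effects.

    Group A voxels are ``baseline`` plus Gaussian noise; group B adds each
    ROI's shift inside its mask.  Returns
    ``(group_a, group_b, masks)`` with group arrays of shape
    ``(n_per_group, *shape)`` and the generating masks for recovery tests.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError("shape must be three positive integers")
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    masks = []
    for mask, _shift in effect_rois:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(
                f"effect ROI shape {mask.shape} does not match volume {shape}"
            )
        masks.append(mask)

    rng = np.random.default_rng(seed)
    group_a = baseline + rng.normal(0.0, noise_sd, size=(n_per_group, *shape))
    group_b = baseline + rng.normal(0.0, noise_sd, size=(n_per_group, *shape))
    for mask, (_, shift) in zip(masks, effect_rois):
        group_b[:, mask] += shift
    return group_a, group_b, masks
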