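"""Screen-level hit calling and target-class enrichment.

Control distributions are built by pooling the per-group averages of
non-treated control groups across experimental days; each treated group's
readout is standardized as

    z = (treated mean - control mean) / control SD

and thresholded at the one-sided 99% standard-normal quantile (2.326).
Enrichment of hit compounds within annotated target classes is assessed by
one-sided Fisher's exact tests on 2x2 tables at alpha = 0.05 (no
multiple-testing correction by default; Benjamini-Hochberg optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ControlDistribution",
    "CompoundResult",
    "EnrichmentResult",
    "control_distribution",
    "zscore",
    "critical_value",
    "call_hits",
    "fisher_exact_2x2",
    "enrich_targets",
]

READOUTS = (
    "hab_pct_41_50",
    "hab_pct_51_60",
    "ppi_pct",
    "any_init_low_pct",
    "any_init_high_pct",
    "slc_init_low_pct",
    "slc_init_high_pct",
)


@dataclass(frozen=True)
class ControlDistribution:
    """Pooled distribution of non-treated control group averages."""

    readout: str
    group_means: tuple[float, ...]
    mean: float
    sd: float
    gaussian_fit: tuple[float, float, float] | None = None  # display only

    @property
    def n_groups(self) -> int:
        return len(self.group_means)


@dataclass
class CompoundResult:
    """Per-compound, per-readout screen result."""

    compound_id: str
    readout: str
    treated_mean: float
    z: float
    dose_um: float | None = None
    hit_increase: bool = False
    hit_decrease: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    """One target class's 2x2 enrichment test among hit compounds."""

    target_class: str
    hits_in_class: int
    hits_out: int
    nonhits_in_class: int
    nonhits_out: int
    p_value: float
    significant: bool

    @property
    def total(self) -> int:
        return (
            self.hits_in_class
            + self.hits_out
            + self.nonhits_in_class
            + self.nonhits_out
        )


def control_distribution(
    group_means: Sequence[float],
    readout: str,
    *,
    fit_gaussian: bool = False,
) -> ControlDistribution:
    """Pool control group averages into a readout's null distribution.

    ``mean`` is the sample mean and ``sd`` the sample standard deviation
    (ddof=1) of the group-level averages.  With ``fit_gaussian`` a normal
    density is fitted to the histogram for display; the fit never affects
    z-scores.
    """
    values = np.asarray(list(group_means), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 control group averages")
    if np.isnan(values).any():
        raise ValueError("control group averages contain NaN")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate control distribution: zero variance")
    fit = None
    if fit_gaussian:
        counts, edges = np.histogram(values, bins="auto")
        centers = 0.5 * (edges[:-1] + edges[1:])
        # least-squares Gaussian (amplitude, mu, sigma) on the histogram
        from scipy.optimize import curve_fit

        def gauss(x, a, mu, sigma):
            return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

        try:
            popt, _ = curve_fit(
                gauss, centers, counts, p0=(counts.max(), mean, sd), maxfev=5000
            )
            fit = (float(popt[0]), float(popt[1]), float(abs(popt[2])))
        except RuntimeError:
            fit = None
    return ControlDistribution(
        readout=readout,
        group_means=tuple(float(v) for v in values),
        mean=mean,
        sd=sd,
        gaussian_fit=fit,
    )


def zscore(treated_mean: float, control: ControlDistribution) -> float:
    """Standardize a treated group mean against the control distribution."""
    return (treated_mean - control.mean) / control.sd


def critical_value(alpha_one_sided: float) -> float:
    """Standard-normal upper quantile at 1 - alpha (one-sided threshold)."""
    if not 0.0 < alpha_one_sided < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha_one_sided}")
    return float(stats.norm.ppf(1.0 - alpha_one_sided))


def call_hits(
    results: Iterable[CompoundResult],
    readout: str,
    direction: str = "increase",
    alpha: float = 0.01,
) -> list[CompoundResult]:
    """Flag compounds whose z-score crosses the one-sided threshold.

    The comparison is inclusive: z exactly at the threshold is a hit.
    Returns the flagged results (each mutated with its hit flag set).
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    threshold = critical_value(alpha)
    hits = []
    for result in results:
        if result.readout != readout:
            continue
        if direction == "increase":
            is_hit = result.z >= threshold
            result.hit_increase = result.hit_increase or is_hit
        else:
            is_hit = result.z <= -threshold
            result.hit_decrease = result.hit_decrease or is_hit
        if is_hit:
            hits.append(result)
    return hits


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p-value for the table
    [[a, b], [c, d]].

    With margins fixed, the cell ``a`` follows a hypergeometric law; the
    returned value is the upper-tail probability P(X >= a).
    """
    counts = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in counts):
        raise ValueError(f"counts must be non-negative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    n = a + b + c + d
    # X ~ Hypergeom(N=n, K=a+b, n=a+c); P(X >= a)
    return float(stats.hypergeom.sf(a - 1, n, a + b, a + c))


def enrich_targets(
    hits: Iterable[str],
    library: pd.DataFrame,
    alpha: float = 0.05,
    *,
    two_sided: bool = False,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Per-class enrichment of hit compounds by Fisher's exact test.

    ``library`` maps ``compound_id`` to ``target_class``.  For each class a
    2x2 table (hit/non-hit x in/out of class) is built and a one-sided
    enrichment p-value computed (``two_sided`` switches to the two-sided
    test).  Classes with p below ``alpha`` are flagged; optional
    Benjamini-Hochberg correction across classes is off by default.
    """
    hits = set(hits)
    compounds = set(library["compound_id"])
    unknown = hits - compounds
    if unknown:
        raise ValueError(f"hit compounds not in library: {sorted(unknown)}")
    by_class = library.groupby("target_class")["compound_id"].apply(set)
    results = []
    p_values = []
    for target_class, members in by_class.items():
        hits_in = len(hits & members)
        hits_out = len(hits) - hits_in
        nonhits_in = len(members) - hits_in
        nonhits_out = len(compounds) - len(members) - hits_out
        if two_sided:
            p = float(
                stats.fisher_exact(
                    [[hits_in, hits_out], [nonhits_in, nonhits_out]],
                    alternative="two-sided",
                )[1]
            )
        else:
            p = fisher_exact_2x2(hits_in, hits_out, nonhits_in, nonhits_out)
        p_values.append(p)
        results.append(
            EnrichmentResult(
                target_class=str(target_class),
                hits_in_class=hits_in,
                hits_out=hits_out,
                nonhits_in_class=nonhits_in,
                nonhits_out=nonhits_out,
                p_value=p,
                significant=False,
            )
        )
    if bh_correct and results:
        from statsmodels.stats.multitest import multipletests

        rejected, _, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
        flags = list(rejected)
    else:
        flags = [p < alpha for p in p_values]
    return [
        EnrichmentResult(
            target_class=r.target_class,
            hits_in_class=r.hits_in_class,
            hits_out=r.hits_out,
            nonhits_in_class=r.nonhits_in_class,
            nonhits_out=r.nonhits_out,
            p_value=r.p_value,
            significant=bool(flag),
        )
        for r, flag in zip(results, flags)
    ]


def score_compounds(
    treated_means: dict[str, float],
    control: ControlDistribution,
    doses: dict[str, float] | None = None,
) -> list[CompoundResult]:
    """Z-score every treated group mean against a control distribution."""
    results = []
    for compound_id, treated_mean in treated_means.items():
        results.append(
            CompoundResult(
                compound_id=compound_id,
                readout=control.readout,
                treated_mean=float(treated_mean),
                z=zscore(float(treated_mean), control),
                dose_um=None if doses is None else doses.get(compound_id),
            )
        )
    return results
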