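"""Small quantification utilities.

Background-corrected fluorescence, technical-replicate averaging for ELISA
concentrations, expected two-locus offspring ratios by gamete enumeration,
and predictive values (PPV/NPV) of a binary classifier from confusion counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

__all__ = [
    "FluorMeasurement",
    "CrossSpec",
    "ConfusionCounts",
    "corrected_fluorescence",
    "average_replicates",
    "punnett_expected",
    "classifier_metrics",
]


@dataclass(frozen=True)
class FluorMeasurement:
    """Raw inputs for background correction of an ROI fluorescence signal.

    ``integrated_density`` is the summed intensity in the ROI (arbitrary
    units), ``roi_area`` and ``brain_area`` are in pixels², and
    ``background_mean`` is mean background fluorescence per pixel.
    """

    integrated_density: float
    roi_area: float
    background_mean: float
    brain_area: float

    def __post_init__(self) -> None:
        if self.roi_area <= 0:
            raise ValueError("roi_area must be > 0")
        if self.brain_area <= 0:
            raise ValueError("brain_area must be > 0")
        if self.integrated_density < 0:
            raise ValueError("integrated_density must be >= 0")


def corrected_fluorescence(m: FluorMeasurement) -> tuple[float, float]:
    """Background-corrected fluorescence.

    Returns ``(total_corrected, per_area)`` where
    ``total_corrected = integrated_density - roi_area * background_mean``
    and ``per_area = total_corrected / brain_area``.
    """
    total = m.integrated_density - m.roi_area * m.background_mean
    return total, total / m.brain_area


def average_replicates(values: Sequence[float], expected_n: int = 3) -> float:
    """Arithmetic mean of technical replicates.

    Warns if the replicate count differs from ``expected_n`` (three
    technical replicates per reported sample is the standard design).
    """
    values = list(values)
    if not values:
        raise ValueError("at least one replicate value is required")
    if len(values) != expected_n:
        warnings.warn(
            f"expected {expected_n} technical replicates, got {len(values)}",
            stacklevel=2,
        )
    return sum(values) / len(values)


# --------------------------------------------------------------- genetics

_ALLELES = ("+", "-")


def _parse_locus(locus: str) -> tuple[str, str]:
    parts = locus.split("/")
    if len(parts) != 2 or any(a not in _ALLELES for a in parts):
        raise ValueError(
            f"malformed locus genotype {locus!r}; expected e.g. '+/-' with "
            "alleles '+' or '-'"
        )
    return parts[0], parts[1]


def parse_genotype(genotype: str) -> tuple[tuple[str, str], tuple[str, str]]:
    """Parse a two-locus genotype string like ``'+/-;-/-'``."""
    loci = genotype.split(";")
    if len(loci) != 2:
        raise ValueError(
            f"malformed genotype {genotype!r}; expected two ';'-separated loci"
        )
    return _parse_locus(loci[0]), _parse_locus(loci[1])


def _canonical_locus(a: str, b: str) -> str:
    # heterozygotes written '+/-' regardless of parental phase
    return "/".join(sorted((a, b)))


@dataclass(frozen=True)
class CrossSpec:
    """A cross between two parents with genotypes at two unlinked loci."""

    parent1: str
    parent2: str

    def __post_init__(self) -> None:
        parse_genotype(self.parent1)
        parse_genotype(self.parent2)


def _gametes(genotype: str) -> list[tuple[str, str]]:
    (a1, a2), (b1, b2) = parse_genotype(genotype)
    return list(itertools.product((a1, a2), (b1, b2)))


def punnett_expected(cross: CrossSpec) -> dict[str, float]:
    """Expected offspring genotype probabilities by gamete enumeration.

    Both loci assort independently; each parent contributes one of its four
    (allele-a, allele-b) gametes with equal probability.  Probabilities are
    exact rationals converted to float and sum to 1.
    """
    g1 = _gametes(cross.parent1)
    g2 = _gametes(cross.parent2)
    counts: dict[str, int] = {}
    for (a1, b1), (a2, b2) in itertools.product(g1, g2):
        genotype = f"{_canonical_locus(a1, a2)};{_canonical_locus(b1, b2)}"
        counts[genotype] = counts.get(genotype, 0) + 1
    total = len(g1) * len(g2)
    return {g: float(Fraction(c, total)) for g, c in sorted(counts.items())}


# ------------------------------------------------------------- classifier

@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts for a binary classifier."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def classifier_metrics(c: ConfusionCounts) -> tuple[float | None, float | None]:
    """Positive and negative predictive value, as percentages.

    ``ppv = 100 * tp / (tp + fp)``; ``npv = 100 * tn / (tn + fn)``.  A metric
    with a zero denominator is undefined and returned as ``None``.
    """
    ppv = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    npv = 100.0 * c.tn / (c.tn + c.fn) if (c.tn + c.fn) > 0 else None
    return ppv, npv
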