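"""Hypergeometric gamete and dihaploid dosage model (no double reduction).

A polysomic parent of ploidy ``p`` carrying ``n`` copies of an allele
transmits ``k`` copies to a gamete (or, for a tetraploid, to an induced
dihaploid) by sampling ``p/2`` of its ``p`` chromosomes without
replacement:

    P(Gk) = Σₙ P(Pn) · C(n, k) · C(p − n, p/2 − k) / C(p, p/2)

Binomial coefficients with out-of-range arguments are zero, so the sum
needs no index guards.  Double reduction (sister alleles ending up in the
same gamete through multivalent segregation) is ignored.

The model answers two breeding questions: the fraction of dihaploids
induced from a tetraploid population that are homozygous or heterozygous
for a deleterious allele, and the fraction of selfed progeny of a
heterozygote that expresses a recessive trait (1/4 for a diploid).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DosageDistribution",
    "GameteDosageDist",
    "gamete_dosage_dist",
    "selfing_recessive_fraction",
    "dihaploid_class_fractions",
]

_TOL = 1e-9


@dataclass(frozen=True)
class DosageDistribution:
    """Allele-dosage distribution of a parent (or parent population)."""

    ploidy: int
    probs: tuple[float, ...]  # P(Pn) for n = 0..ploidy

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if len(self.probs) != self.ploidy + 1:
            raise ValueError(f"probs must have length ploidy+1 = {self.ploidy + 1}")
        arr = np.asarray(self.probs, dtype=float)
        if (arr < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(arr.sum() - 1.0) > _TOL:
            raise ValueError(f"probabilities sum to {arr.sum():.12f}, not 1")

    @classmethod
    def from_counts(cls, counts: Mapping[int, int] | Sequence[int], ploidy: int = 4) -> "DosageDistribution":
        """Normalise a dosage histogram (dosage → number of individuals)."""
        probs = np.zeros(ploidy + 1)
        if isinstance(counts, Mapping):
            items = counts.items()
        else:
            items = enumerate(counts)
        for d, n in items:
            if not 0 <= d <= ploidy:
                raise ValueError(f"dosage {d} outside [0, {ploidy}]")
            if n < 0:
                raise ValueError("counts must be non-negative")
            probs[d] += n
        total = probs.sum()
        if total <= 0:
            raise ValueError("histogram is empty")
        return cls(ploidy=ploidy, probs=tuple(probs / total))

    @classmethod
    def fixed(cls, dosage: int, ploidy: int = 4) -> "DosageDistribution":
        probs = [0.0] * (ploidy + 1)
        probs[dosage] = 1.0
        return cls(ploidy=ploidy, probs=tuple(probs))


@dataclass(frozen=True)
class GameteDosageDist:
    """P(Gk) for k = 0..p/2 copies carried by a gamete."""

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if (arr < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(arr.sum() - 1.0) > _TOL:
            raise ValueError("gamete probabilities must sum to 1")


def gamete_dosage_dist(parent: DosageDistribution) -> GameteDosageDist:
    """Gamete dosage probabilities by hypergeometric transmission."""
    p = parent.ploidy
    if p % 2 != 0 or p < 2:
        raise ValueError("parental ploidy must be even and >= 2")
    h = p // 2
    denom = comb(p, h)
    probs = []
    for k in range(h + 1):
        total = 0.0
        for n, pn in enumerate(parent.probs):
            if pn == 0.0:
                continue
            total += pn * comb(n, k) * comb(p - n, h - k) / denom
        probs.append(total)
    return GameteDosageDist(probs=tuple(probs))


def selfing_recessive_fraction(parent: DosageDistribution) -> float:
    """Fraction of selfed progeny homozygous for the (recessive) allele.

    Two independent gametes must each carry only mutant alleles at the
    locus, i.e. dosage p/2.  For a diploid heterozygote this is
    (1/2)² = 1/4 of the S1.
    """
    g = gamete_dosage_dist(parent)
    return g.probs[-1] ** 2


def dihaploid_class_fractions(parent: DosageDistribution) -> dict[str, float]:
    """Dihaploid genotype fractions induced from a tetraploid population.

    A dihaploid is genetically one gamete of its tetraploid parent, so
    the fractions are P(G2) (homozygous mutant), P(G1) (heterozygous
    carrier) and P(G0) (free of the allele).
    """
    if parent.ploidy != 4:
        raise ValueError("dihaploid induction is defined for tetraploid parents")
    g = gamete_dosage_dist(parent)
    return {
        "homozygous_mutant": g.probs[2],
        "heterozygous": g.probs[1],
        "free": g.probs[0],
    }
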