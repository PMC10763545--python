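"""Diploid meiosis with crossover shortage and first-division restitution.

The simulator follows chromatids through the two meiotic divisions of a
diploid meiocyte.  A wild-type meiosis forms a bivalent for every
chromosome (held together by at least one crossover) and yields a tetrad
of four balanced reduced gametes.  In a crossover-shortage (desynaptic)
meiosis only ``b`` of the ``n`` chromosomes form a bivalent; the remaining
univalents travel intact to a random pole at anaphase I, so a reduced
gamete is balanced only when every univalent pair happens to split — the
closed form ``(1/2)**(n - b)``.

First-division restitution (FDR) is modelled as a whole-meiosis event: the
two metaphase-II plates fuse, the entire chromosome complement undergoes a
single equational division, and a dyad of two unreduced (2n) gametes is
produced.  Because restitution re-unites both meiosis-I poles, FDR gametes
are balanced regardless of how univalents had segregated, and they retain
parental heterozygosity everywhere except distal to a crossover.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "GenomeSpec",
    "MeiosisParams",
    "ParentGenome",
    "Gamete",
    "prob_balanced_reduced",
    "enumerate_balanced_fraction",
    "balanced_fraction_mc",
    "simulate_meiosis",
    "simulate_pool",
    "gamete_heterozygosity",
]

REDUCED = "reduced"
UNREDUCED = "unreduced"
WILD_TYPE = "wild_type"
CO_SHORTAGE = "co_shortage"


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome layout: marker and centromere positions in map units [0, 1].

    Parameters
    ----------
    n_chrom:
        Haploid chromosome number ``n`` (12 for potato).
    marker_pos:
        Per chromosome, strictly increasing marker positions in [0, 1].
    centromere_pos:
        Per chromosome, relative centromere position in [0, 1].  Defaults
        to 0 (acrocentric), which only matters for which chromatid keeps
        which centromere after a crossover.
    """

    n_chrom: int
    marker_pos: tuple[tuple[float, ...], ...]
    centromere_pos: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")
        if len(self.marker_pos) != self.n_chrom:
            raise ValueError("marker_pos must have one tuple per chromosome")
        if not self.centromere_pos:
            object.__setattr__(self, "centromere_pos", (0.0,) * self.n_chrom)
        if len(self.centromere_pos) != self.n_chrom:
            raise ValueError("centromere_pos must have one entry per chromosome")
        for c, positions in enumerate(self.marker_pos):
            arr = np.asarray(positions, dtype=float)
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise ValueError(f"marker positions outside [0, 1] on chromosome {c}")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"marker positions not strictly increasing on chromosome {c}")
        for c, pos in enumerate(self.centromere_pos):
            if not 0.0 <= pos <= 1.0:
                raise ValueError(f"centromere position outside [0, 1] on chromosome {c}")

    @classmethod
    def uniform(cls, n_chrom: int = 12, n_markers: int = 25, centromere: float = 0.0) -> "GenomeSpec":
        """Evenly spaced markers on every chromosome."""
        pos = tuple(np.linspace(0.0, 1.0, n_markers))
        return cls(
            n_chrom=n_chrom,
            marker_pos=tuple(pos for _ in range(n_chrom)),
            centromere_pos=(centromere,) * n_chrom,
        )


@dataclass(frozen=True)
class MeiosisParams:
    """Meiosis mode and restitution parameters.

    ``bivalent_count`` is the number ``b`` of chromosomes that still form a
    bivalent in a crossover-shortage meiosis (ignored in wild type, where
    every chromosome pairs).  ``fdr_prob`` is the per-meiosis probability
    that meiosis II is restituted into a dyad of unreduced gametes.
    ``co_per_bivalent`` crossovers are placed uniformly on each bivalent
    (default 1, the obligate crossover).
    """

    mode: str = WILD_TYPE
    bivalent_count: int | None = None
    fdr_prob: float = 0.0
    co_per_bivalent: int = 1

    def __post_init__(self) -> None:
        if self.mode not in (WILD_TYPE, CO_SHORTAGE):
            raise ValueError(f"unknown meiosis mode: {self.mode!r}")
        if not 0.0 <= self.fdr_prob <= 1.0:
            raise ValueError("fdr_prob must be in [0, 1]")
        if self.co_per_bivalent < 1:
            raise ValueError("co_per_bivalent must be a positive integer")
        if self.mode == CO_SHORTAGE and self.bivalent_count is None:
            raise ValueError("co_shortage mode requires bivalent_count")

    def resolve_bivalents(self, n_chrom: int) -> int:
        b = n_chrom if self.mode == WILD_TYPE else int(self.bivalent_count)  # type: ignore[arg-type]
        if not 0 <= b <= n_chrom:
            raise ValueError(f"bivalent count {b} outside [0, {n_chrom}]")
        return b


@dataclass
class ParentGenome:
    """Phased diploid parent: two homolog allele vectors per chromosome."""

    spec: GenomeSpec
    haplotypes: tuple[tuple[np.ndarray, np.ndarray], ...]

    def __post_init__(self) -> None:
        if len(self.haplotypes) != self.spec.n_chrom:
            raise ValueError("haplotypes must have one pair per chromosome")
        for c, (h0, h1) in enumerate(self.haplotypes):
            m = len(self.spec.marker_pos[c])
            if len(h0) != m or len(h1) != m:
                raise ValueError(f"haplotype length mismatch on chromosome {c}")

    @classmethod
    def fully_heterozygous(cls, spec: GenomeSpec) -> "ParentGenome":
        """Parent heterozygous (alleles 0/1) at every marker."""
        haps = tuple(
            (
                np.zeros(len(spec.marker_pos[c]), dtype=np.int8),
                np.ones(len(spec.marker_pos[c]), dtype=np.int8),
            )
            for c in range(spec.n_chrom)
        )
        return cls(spec=spec, haplotypes=haps)

    def heterozygous_mask(self, c: int) -> np.ndarray:
        h0, h1 = self.haplotypes[c]
        return np.asarray(h0) != np.asarray(h1)


@dataclass
class Gamete:
    """A meiotic product: per-chromosome copy numbers and allele content.

    ``alleles[c]`` has shape ``(copy_number[c], n_markers_c)``; a balanced
    gamete carries one copy of every chromosome when reduced and two when
    unreduced.
    """

    copy_number: np.ndarray
    alleles: tuple[np.ndarray, ...]
    ploidy_class: str
    meiosis_id: int = 0

    @property
    def balanced(self) -> bool:
        expected = 2 if self.ploidy_class == UNREDUCED else 1
        return bool(np.all(self.copy_number == expected))


def prob_balanced_reduced(n: int, b: int) -> float:
    """Closed-form probability that a reduced gamete is balanced.

    With ``b`` bivalents segregating properly and ``n - b`` univalents
    each moving to a random pole, a spore receives exactly one copy of
    every chromosome with probability ``(1/2)**(n - b)``.
    """
    if int(n) != n or int(b) != b:
        raise ValueError("n and b must be integers")
    n, b = int(n), int(b)
    if n < 1 or b < 0 or b > n:
        raise ValueError(f"require 1 <= n and 0 <= b <= n, got n={n}, b={b}")
    return 0.5 ** (n - b)


def enumerate_balanced_fraction(n: int, b: int) -> Fraction:
    """Exact balanced-gamete fraction by exhaustive univalent enumeration.

    Each of the ``n - b`` univalents (both sister chromatids together)
    independently moves to pole 0 or pole 1; a pole is balanced when every
    chromosome is represented exactly once there.  Intended as an
    independent oracle for small ``n - b``.
    """
    if b > n or b < 0 or n < 1:
        raise ValueError("require 1 <= n and 0 <= b <= n")
    u = n - b
    if u == 0:
        return Fraction(1)
    balanced = 0
    total = 0
    # poles[i], poles[u + i] are the destinations of the two homologs of
    # univalent chromosome i.
    for poles in itertools.product((0, 1), repeat=2 * u):
        total += 1
        if all(poles[i] != poles[u + i] for i in range(u)):
            balanced += 1
    return Fraction(balanced, total)


def balanced_fraction_mc(
    n: int, b: int, n_meioses: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> float:
    """Monte-Carlo fraction of balanced reduced gametes (vectorised).

    Simulates only the univalent pole assignments, which fully determine
    whether the reduced products of a meiosis are balanced; all four
    spores of one meiosis share the outcome.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if b > n or b < 0:
        raise ValueError("require 0 <= b <= n")
    u = n - b
    if u == 0:
        return 1.0
    pole0 = rng.integers(0, 2, size=(n_meioses, u))
    pole1 = rng.integers(0, 2, size=(n_meioses, u))
    return float(np.mean(np.all(pole0 != pole1, axis=1)))


def _do_crossovers(
    chromatids: list[np.ndarray],
    origins: list[int],
    positions: np.ndarray,
    centromere: float,
    n_co: int,
    rng: np.random.Generator,
) -> None:
    """Apply ``n_co`` crossovers in place between non-sister chromatids.

    ``chromatids`` holds four allele vectors: indices 0/1 are the sisters
    of homolog 0, indices 2/3 of homolog 1.  A crossover at map position x
    exchanges marker alleles at positions > x between one chromatid of
    each homolog; the centromere stays with its physical location, so the
    centromere origins swap when the centromere lies distal to x.
    """
    for _ in range(n_co):
        x = rng.random()
        i = int(rng.integers(0, 2))
        j = 2 + int(rng.integers(0, 2))
        distal = positions > x
        tmp = chromatids[i][distal].copy()
        chromatids[i][distal] = chromatids[j][distal]
        chromatids[j][distal] = tmp
        if centromere > x:
            origins[i], origins[j] = origins[j], origins[i]


def simulate_meiosis(
    parent: ParentGenome,
    params: MeiosisParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    meiosis_id: int = 0,
) -> list[Gamete]:
    """Simulate one meiosis; returns a tetrad (or an FDR dyad) of gametes."""
    if rng is None:
        rng = np.random.default_rng(seed)
    spec = parent.spec
    n = spec.n_chrom
    b = params.resolve_bivalents(n)

    if params.mode == WILD_TYPE:
        bivalent_set = set(range(n))
    else:
        bivalent_set = set(rng.choice(n, size=b, replace=False).tolist()) if b else set()

    # Per chromosome: four chromatids (allele vectors), their centromere
    # origins, and the MI pole of each chromatid.
    all_chromatids: list[list[np.ndarray]] = []
    all_origins: list[list[int]] = []
    all_poles: list[list[int]] = []
    for c in range(n):
        h0, h1 = parent.haplotypes[c]
        chromatids = [np.array(h0), np.array(h0), np.array(h1), np.array(h1)]
        origins = [0, 0, 1, 1]
        positions = np.asarray(spec.marker_pos[c], dtype=float)
        if c in bivalent_set:
            _do_crossovers(chromatids, origins, positions, spec.centromere_pos[c], params.co_per_bivalent, rng)
            orientation = int(rng.integers(0, 2))
            poles = [orientation if o == 0 else 1 - orientation for o in origins]
        else:
            # Intact univalent: both sisters of a homolog to the same pole.
            p0 = int(rng.integers(0, 2))
            p1 = int(rng.integers(0, 2))
            poles = [p0 if o == 0 else p1 for o in origins]
        all_chromatids.append(chromatids)
        all_origins.append(origins)
        all_poles.append(poles)

    fdr = rng.random() < params.fdr_prob

    def _equational_split(member_idx: list[list[int]]) -> list[list[list[int]]]:
        """Split each sister group randomly into two products."""
        products: list[list[list[int]]] = [[], []]
        for c in range(n):
            got: list[list[int]] = [[], []]
            for group in member_idx[c]:
                order = rng.permutation(len(group))
                # Sister groups always hold two chromatids; one to each product.
                got[0].append(group[order[0]])
                got[1].append(group[order[1]])
            products[0].append(got[0])
            products[1].append(got[1])
        return products

    def _groups_at(pole: int | None) -> list[list[list[int]]]:
        """Sister-chromatid groups (by centromere origin) per chromosome."""
        groups: list[list[list[int]]] = []
        for c in range(n):
            per_origin: dict[int, list[int]] = {}
            for idx in range(4):
                if pole is not None and all_poles[c][idx] != pole:
                    continue
                per_origin.setdefault(all_origins[c][idx], []).append(idx)
            groups.append(list(per_origin.values()))
        return groups

    def _build(chromatid_idx: list[list[int]], ploidy_class: str) -> Gamete:
        copy = np.array([len(chromatid_idx[c]) for c in range(n)], dtype=int)
        alleles = tuple(
            np.vstack([all_chromatids[c][i] for i in chromatid_idx[c]])
            if chromatid_idx[c]
            else np.empty((0, len(spec.marker_pos[c])), dtype=np.int8)
            for c in range(n)
        )
        return Gamete(copy_number=copy, alleles=alleles, ploidy_class=ploidy_class, meiosis_id=meiosis_id)

    if fdr:
        # Fused metaphase-II plates: the whole complement divides equationally.
        products = _equational_split(_groups_at(None))
        return [_build(p, UNREDUCED) for p in products]

    gametes: list[Gamete] = []
    for pole in (0, 1):
        for p in _equational_split(_groups_at(pole)):
            gametes.append(_build(p, REDUCED))
    return gametes


def simulate_pool(
    parent: ParentGenome,
    params: MeiosisParams,
    n_meioses: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Gamete]:
    """Simulate ``n_meioses`` meioses and return the flattened gamete pool."""
    if rng is None:
        rng = np.random.default_rng(seed)
    pool: list[Gamete] = []
    for i in range(n_meioses):
        pool.extend(simulate_meiosis(parent, params, rng=rng, meiosis_id=i))
    return pool


def gamete_heterozygosity(g: Gamete, parent: ParentGenome) -> float:
    """Fraction of the parent's heterozygous loci retained in a 2n gamete.

    A heterozygous marker is retained when the unreduced gamete carries
    both parental alleles there.  Reduced gametes have no meaningful
    heterozygosity retention and raise a ``ValueError``.
    """
    if g.ploidy_class != UNREDUCED:
        raise ValueError("heterozygosity retention is defined for unreduced gametes only")
    if not g.balanced:
        raise ValueError("gamete must be balanced (copy number 2 everywhere)")
    het_total = 0
    retained = 0
    for c in range(parent.spec.n_chrom):
        mask = parent.heterozygous_mask(c)
        het_total += int(mask.sum())
        a = g.alleles[c]
        retained += int(np.sum((a[0] != a[1]) & mask))
    if het_total == 0:
        raise ValueError("parent has no heterozygous loci")
    return retained / het_total
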