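"""Allele-diagnostic k-mer tag sets and k-mer based dosage genotyping.

A short window around a diagnostic polymorphism (a SNP, an insertion
footprint, or the two junctions of a transposon insertion) is k-merised:
every k-mer overlapping the focal positions tags that allele.  Tag sets
are curated against a variety panel — k-mers present in nearly all
varieties lack specificity and are dropped.  Per variety, allele presence
is called from the curated tags, and the dosage of a biallelic site in an
autotetraploid is estimated from the ratio of the two alleles' k-mer
frequencies (summarised as the median count over each tag set).

All k-mers are stored canonically (the lexicographic minimum of a k-mer
and its reverse complement), so counting and matching are strand-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlleleTagSet",
    "DosageCall",
    "DOSAGE_CLASSES",
    "revcomp",
    "canonical",
    "kmerize",
    "build_tag_kmers",
    "curate_specificity",
    "call_presence",
    "estimate_dosage",
    "panel_maf",
    "extract_reads_with_kmers",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DOSAGE_CLASSES = ("nulliplex", "simplex", "duplex", "triplex", "quadruplex")

# KmerDB: variety_id -> {canonical k-mer -> count}
KmerDB = Mapping[str, Mapping[str, int]]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmerize(seq: str, k: int) -> list[str]:
    """All canonical k-mers of a sequence, in positional order."""
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    return [canonical(seq[i : i + k]) for i in range(len(seq) - k + 1)]


@dataclass(frozen=True)
class AlleleTagSet:
    """Canonical k-mers diagnostic for one allele.

    ``focal_span`` is the 0-based half-open position range within
    ``window_seq`` that every tag k-mer must overlap.
    """

    allele_name: str
    window_seq: str
    focal_span: tuple[int, int]
    k: int
    kmers: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.window_seq) < self.k:
            raise ValueError("window shorter than k")
        s, e = self.focal_span
        if not (0 <= s < e <= len(self.window_seq)):
            raise ValueError("focal_span outside the window")

    def with_kmers(self, kmers: Iterable[str]) -> "AlleleTagSet":
        return AlleleTagSet(self.allele_name, self.window_seq, self.focal_span, self.k, frozenset(kmers))


def build_tag_kmers(
    window_seq: str,
    focal_span: tuple[int, int],
    k: int = 31,
    allele_name: str = "",
) -> AlleleTagSet:
    """Tag set from every window k-mer overlapping the focal span.

    A 39-nt window with a central focal SNP yields 9 k-mers at k=31; a
    67-nt window around a 7-bp central footprint yields 37 before
    curation.
    """
    if len(window_seq) < k:
        raise ValueError(f"window length {len(window_seq)} < k={k}")
    s, e = focal_span
    kmers = []
    for i in range(len(window_seq) - k + 1):
        if i < e and i + k > s:  # [i, i+k) overlaps [s, e)
            kmers.append(canonical(window_seq[i : i + k]))
    return AlleleTagSet(allele_name, window_seq, (s, e), k, frozenset(kmers))


def kmer_prevalence(kmer: str, panel: KmerDB) -> float:
    n = sum(1 for counts in panel.values() if kmer in counts)
    return n / len(panel)


def curate_specificity(tags: AlleleTagSet, panel: KmerDB, max_prevalence: float = 0.9) -> AlleleTagSet:
    """Drop tag k-mers present in more than ``max_prevalence`` of varieties.

    Such k-mers occur in shared repeats or conserved flanking sequence
    and carry no allele information.  Raises when no k-mer survives.
    """
    if not panel:
        raise ValueError("panel is empty")
    kept = {km for km in tags.kmers if kmer_prevalence(km, panel) <= max_prevalence}
    if not kept:
        raise ValueError(f"tag set {tags.allele_name!r} fully removed by curation")
    return tags.with_kmers(kept)


def call_presence(
    tags: AlleleTagSet,
    variety_kmers: Mapping[str, int],
    min_count: int = 2,
) -> tuple[str, frozenset[str]]:
    """Presence call for one variety: ``full``, ``partial`` or ``absent``.

    ``full`` when every tag k-mer reaches ``min_count`` (default 2, which
    suppresses single sequencing-error k-mers), ``absent`` when none does,
    ``partial`` otherwise (with the found subset).
    """
    if not tags.kmers:
        raise ValueError("empty tag set")
    found = frozenset(km for km in tags.kmers if variety_kmers.get(km, 0) >= min_count)
    if len(found) == len(tags.kmers):
        return "full", found
    if not found:
        return "absent", found
    return "partial", found


@dataclass(frozen=True)
class DosageCall:
    variety_id: str
    ratio: float | None
    dosage: int | None
    dosage_class: str

    @property
    def is_call(self) -> bool:
        return self.dosage is not None


def _median_count(tags: AlleleTagSet, variety_kmers: Mapping[str, int]) -> float:
    return float(np.median([variety_kmers.get(km, 0) for km in sorted(tags.kmers)]))


def _ratio_to_dosage(ratio: float, ploidy: int) -> int:
    # Nearest integer, exact ties resolved toward the lower dosage.
    x = ploidy * ratio
    d = int(math.ceil(x - 0.5))
    return min(max(d, 0), ploidy)


def estimate_dosage(
    tags_a: AlleleTagSet,
    tags_b: AlleleTagSet,
    variety_kmers: Mapping[str, int],
    ploidy: int = 4,
    variety_id: str = "",
) -> DosageCall:
    """Integer dosage of allele A from the two alleles' k-mer frequencies.

    ratio = median(A counts) / (median(A counts) + median(B counts));
    dosage = round(ploidy × ratio) with ties toward the lower class.  A
    zero denominator yields a no-call.
    """
    med_a = _median_count(tags_a, variety_kmers)
    med_b = _median_count(tags_b, variety_kmers)
    denom = med_a + med_b
    if denom <= 0:
        return DosageCall(variety_id, None, None, "no_call")
    ratio = med_a / denom
    dosage = _ratio_to_dosage(ratio, ploidy)
    if ploidy == 4:
        cls = DOSAGE_CLASSES[dosage]
    else:
        cls = str(dosage)
    return DosageCall(variety_id, ratio, dosage, cls)


def panel_maf(dosage_counts: Mapping[int, int], ploidy: int = 4) -> float:
    """Dosage-weighted allele frequency over a polyploid panel.

    ``Σ(dosage × n_varieties) / (ploidy × Σ n_varieties)``.
    """
    if not dosage_counts:
        raise ValueError("empty dosage counts")
    total = sum(dosage_counts.values())
    if total <= 0:
        raise ValueError("dosage counts sum to zero")
    if any(d < 0 or d > ploidy for d in dosage_counts):
        raise ValueError("dosage outside [0, ploidy]")
    if any(n < 0 for n in dosage_counts.values()):
        raise ValueError("negative variety counts")
    return sum(d * n for d, n in dosage_counts.items()) / (ploidy * total)


def extract_reads_with_kmers(
    reads: Iterable[tuple[str, str]],
    kmers: Iterable[str],
    k: int | None = None,
) -> list[tuple[str, str]]:
    """Reads containing any query k-mer in either orientation.

    ``reads`` is an iterable of (read_id, sequence) pairs; matching is
    canonical, so a read carrying the reverse complement of a query
    k-mer is returned too.
    """
    query = {canonical(km) for km in kmers}
    if not query:
        return []
    if k is None:
        lengths = {len(km) for km in query}
        if len(lengths) != 1:
            raise ValueError("query k-mers have mixed lengths; pass k explicitly")
        k = lengths.pop()
    out = []
    for read_id, seq in reads:
        if len(seq) < k:
            continue
        if any(canonical(seq[i : i + k]) in query for i in range(len(seq) - k + 1)):
            out.append((read_id, seq))
    return out
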