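"""Bulked-mutant loss-of-function variant funnel.

Variants called on a bulk of phenotyped mutants are funnelled through
three independent predicates:

1. quality: QUAL ≥ 20 and 8 ≤ DP ≤ 40 (the complement — low QUAL or DP
   out of range — is the exclusion mask);
2. parent concordance: the same (chrom, pos, ref, alt) must be called
   with passing quality in at least one parent;
3. LOF fixation: a loss-of-function annotation with a DP4 quad showing no
   forward and no reverse read supporting the reference allele, i.e. the
   null allele is fixed in the bulk.

Retained variants are rolled up per gene, flagging genes annotated with
reproduction (GO:0000003) or cell cycle (GO:0007049) terms as candidates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "LOF_EFFECTS",
    "CANDIDATE_GO_TERMS",
    "quality_filter",
    "parent_concordance_filter",
    "lof_fixed_filter",
    "gene_rollup",
    "run_funnel",
]

logger = logging.getLogger(__name__)

LOF_EFFECTS = frozenset(
    {
        "frameshift_variant",
        "stop_gained",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
    }
)

# reproduction, cell cycle
CANDIDATE_GO_TERMS = frozenset({"GO:0000003", "GO:0007049"})


@dataclass(frozen=True)
class VariantRecord:
    """One VCF variant (single ALT) with the fields the funnel consumes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None = None
    dp: int | None = None
    dp4: tuple[int, int, int, int] | None = None  # ref-fwd, ref-rev, alt-fwd, alt-rev
    effect: str | None = None
    lof: bool = False
    gene_id: str | None = None
    info: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based VCF coordinate)")
        if self.dp4 is not None and any(x < 0 for x in self.dp4):
            raise ValueError("DP4 entries must be non-negative")
        if self.lof and not self.effect:
            raise ValueError("lof=True requires an effect annotation")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def quality_filter(
    vs: Iterable[VariantRecord],
    min_qual: float = 20.0,
    min_dp: int = 8,
    max_dp: int = 40,
) -> list[VariantRecord]:
    """Keep records with QUAL ≥ min_qual and min_dp ≤ DP ≤ max_dp.

    Boundary values pass.  Records missing QUAL or DP are excluded and
    counted in the log.
    """
    kept: list[VariantRecord] = []
    n_missing = 0
    for v in vs:
        if v.qual is None or v.dp is None:
            n_missing += 1
            continue
        if v.qual >= min_qual and min_dp <= v.dp <= max_dp:
            kept.append(v)
    if n_missing:
        logger.info("quality_filter: %d records excluded for missing QUAL/DP", n_missing)
    return kept


def parent_concordance_filter(
    bulk: Iterable[VariantRecord],
    parents: Sequence[Sequence[VariantRecord]],
    filter_parents: bool = True,
    **quality_kwargs,
) -> list[VariantRecord]:
    """Keep bulk records also called in at least one parent.

    Parent call sets are keyed by (chrom, pos, ref, alt); by default the
    parent-side calls must themselves pass :func:`quality_filter`
    (``filter_parents=False`` accepts any parent call).
    """
    parent_keys: set[tuple[str, int, str, str]] = set()
    for pset in parents:
        calls = quality_filter(pset, **quality_kwargs) if filter_parents else list(pset)
        parent_keys.update(v.key for v in calls)
    if not parent_keys:
        logger.warning("parent_concordance_filter: no usable parent calls; result is empty")
        return []
    return [v for v in bulk if v.key in parent_keys]


def lof_fixed_filter(vs: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep LOF variants fixed in the bulk per DP4.

    Fixation means neither forward nor reverse reads support the
    reference allele while at least one read supports the alternative.
    All-zero DP4 quads are uninformative and excluded.
    """
    kept: list[VariantRecord] = []
    n_uninformative = 0
    for v in vs:
        if not v.lof or v.dp4 is None:
            continue
        rf, rr, af, ar = v.dp4
        if rf == 0 and rr == 0 and af + ar == 0:
            n_uninformative += 1
            continue
        if rf == 0 and rr == 0 and af + ar > 0:
            kept.append(v)
    if n_uninformative:
        logger.info("lof_fixed_filter: %d records with all-zero DP4 excluded", n_uninformative)
    return kept


def gene_rollup(vs: Iterable[VariantRecord], annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene variant counts with descriptions and candidate flags.

    ``annotation`` maps gene_id → description / GO terms (comma-separated
    in a ``go_terms`` column).  Genes annotated with a reproduction or
    cell-cycle GO term are flagged ``candidate``.  Unknown gene ids get an
    empty description.
    """
    counts = Counter(v.gene_id or "" for v in vs)
    rows = []
    for gene_id, n in sorted(counts.items()):
        description, go_terms = "", ""
        if annotation is not None and gene_id in annotation.index:
            description = str(annotation.at[gene_id, "description"])
            go_terms = str(annotation.at[gene_id, "go_terms"])
        gos = {g.strip() for g in go_terms.split(",") if g.strip()}
        rows.append(
            {
                "gene_id": gene_id,
                "n_variants": n,
                "description": description,
                "go_terms": go_terms,
                "candidate": bool(gos & CANDIDATE_GO_TERMS),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_variants", "description", "go_terms", "candidate"])


def run_funnel(
    bulk: Sequence[VariantRecord],
    parents: Sequence[Sequence[VariantRecord]],
    annotation: pd.DataFrame | None = None,
    filter_parents: bool = True,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Apply quality → parent concordance → LOF fixation, then roll up genes."""
    retained = quality_filter(bulk)
    retained = parent_concordance_filter(retained, parents, filter_parents=filter_parents)
    retained = lof_fixed_filter(retained)
    return retained, gene_rollup(retained, annotation)
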