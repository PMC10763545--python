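"""Synthetic-data generators with known ground truth.

Every input the analysis chain consumes can be generated here with its
truth recorded alongside, so that parameter-recovery tests have an exact
oracle:

* an F1 outcross population with phased parental haplotypes (female
  h1/h2, male h3/h4), a recessive causal locus, marker-to-marker
  recombination and the asymmetric phenotype error model observed for
  pollen-based classification (wild types are nearly always classified
  correctly, mutants are often unclassified or misread as wild type);
* a tetraploid variety panel with per-variety k-mer count sets for two
  SNP-tagging windows and an insertion-footprint window, Poisson
  sequencing noise, rare error k-mers and a shared-repeat contaminant
  that overlaps part of the footprint window (to exercise curation);
* a trio of VCFs (mutant bulk plus two parents) whose records span every
  filter stratum of the loss-of-function funnel, with the planted truth
  set being exactly the quality-passing, parent-shared, fixed LOF
  variants.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .kmers import AlleleTagSet, build_tag_kmers, kmerize
from .lofbulk import VariantRecord
from .qtl import F1Population

__all__ = [
    "SynthConfig",
    "SimulatedF1",
    "PanelSim",
    "VcfSim",
    "make_f1_population",
    "make_variety_panel",
    "make_vcf_fixture",
    "random_seq",
]

_BASES = np.array(list("ACGT"))


def random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


@dataclass(frozen=True)
class SynthConfig:
    """Defaults pinned to the observed study design.

    Population: 1,345 phenotyped F1 individuals, causal recessive locus
    at 1.15 Mb on chromosome 8.  Phenotype error model: 0.5% of true wild
    types misread as mutant, 44% of classified mutants misread as wild
    type, and 59% / 23.2% of mutants / wild types left unclassified.
    Panel: 134 tetraploid varieties with dosage histogram
    {0: 55, 1: 45, 2: 26, 3: 8}, 20× sequencing coverage per allele copy
    and a 1% error-k-mer rate.
    """

    # F1 population
    n_individuals: int = 1345
    n_chrom: int = 2
    markers_per_chrom: int = 100
    marker_spacing: int = 50_000
    causal_chrom: str = "chr08"
    causal_pos: int = 1_150_000
    recomb_rate: float = 0.01
    fp_rate: float = 0.005  # wild type observed as mutant
    fn_rate: float = 0.44  # mutant observed as wild type
    mutant_unclassified: float = 0.59
    wt_unclassified: float = 0.232
    # tetraploid k-mer panel
    panel_size: int = 134
    dosage_hist: tuple[tuple[int, int], ...] = ((0, 55), (1, 45), (2, 26), (3, 8))
    coverage_per_copy: float = 20.0
    kmer_error_rate: float = 0.01
    k: int = 31
    snp_window: int = 39
    footprint_window: int = 67
    footprint_len: int = 7
    n_footprint_full: int = 21
    n_footprint_partial: int = 1
    n_partial_kmers: int = 2
    n_contaminant: int = 6
    n_background_kmers: int = 20
    # VCF fixture strata (per-gene fixed-LOF counts give 6 variants / 4 genes)
    vcf_chrom: str = "chr08"
    n_pass_background: int = 60
    n_low_qual: int = 10
    n_dp_out: int = 10
    n_parent_absent: int = 4
    n_lof_unfixed: int = 14
    fixed_lof_per_gene: tuple[tuple[str, int], ...] = (
        ("gene_YTH", 2),
        ("gene_hAT", 2),
        ("gene_NBARC", 1),
        ("gene_MSH4", 1),
    )

    def __post_init__(self) -> None:
        for name in ("fp_rate", "fn_rate", "mutant_unclassified", "wt_unclassified", "kmer_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if sum(n for _, n in self.dosage_hist) != self.panel_size:
            raise ValueError("dosage histogram must sum to panel_size")


class SimulatedF1(NamedTuple):
    population: F1Population
    true_phenotype: pd.Series  # 1 mutant, 0 wild type
    observed_phenotype: pd.Series  # 1 / 0 / NaN (unclassified)
    causal_marker: str


def _chrom_names(cfg: SynthConfig) -> list[str]:
    names = [cfg.causal_chrom]
    i = 1
    while len(names) < cfg.n_chrom:
        cand = f"chr{i:02d}"
        if cand not in names:
            names.append(cand)
        i += 1
    return names


def make_f1_population(cfg: SynthConfig | None = None, seed: int | None = None,
                       rng: np.random.Generator | None = None) -> SimulatedF1:
    """Simulate the F1 outcross with a recessive causal locus.

    Both parents are heterozygous carriers, so the h1h3 allele
    combination at the causal marker (expected in 1/4 of offspring) is
    the recessive mutant genotype.  Inheritance is simulated
    marker-to-marker with a constant per-interval recombination rate and
    no interference; the observed phenotype applies the unclassified and
    misclassification rates per true class.
    """
    cfg = cfg or SynthConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = cfg.n_individuals
    m = cfg.markers_per_chrom
    chroms = _chrom_names(cfg)
    positions = (np.arange(m) + 1) * cfg.marker_spacing  # 1-based bp

    if cfg.causal_pos not in positions:
        raise ValueError(
            f"causal_pos {cfg.causal_pos} is not on the marker grid "
            f"(spacing {cfg.marker_spacing}, {m} markers)"
        )

    marker_rows = []
    geno_blocks = []
    causal_marker = None
    for chrom in chroms:
        ids = [f"{chrom}_m{j + 1}" for j in range(m)]
        for mid, pos in zip(ids, positions):
            marker_rows.append({"marker": mid, "chrom": chrom, "pos_bp": int(pos), "origin": "integrated"})
        # One inheritance vector per parent: 0/1 haplotype choice per marker.
        inh = []
        for _parent in range(2):
            start = rng.integers(0, 2, size=n)
            switches = rng.random((n, m - 1)) < cfg.recomb_rate
            steps = np.concatenate([start[:, None], switches.astype(int)], axis=1)
            inh.append(np.cumsum(steps, axis=1) % 2)
        mat = np.where(inh[0] == 0, "h1", "h2")
        pat = np.where(inh[1] == 0, "h3", "h4")
        codes = np.char.add(mat, pat)
        geno_blocks.append(pd.DataFrame(codes, columns=ids))
        if chrom == cfg.causal_chrom:
            causal_marker = ids[int(np.where(positions == cfg.causal_pos)[0][0])]

    markers = pd.DataFrame(marker_rows).set_index("marker")
    genotypes = pd.concat(geno_blocks, axis=1)
    genotypes.index = pd.Index([f"ind{i + 1:04d}" for i in range(n)], name="individual")
    pop = F1Population(markers=markers, genotypes=genotypes)

    assert causal_marker is not None
    true_phen = pd.Series(
        (genotypes[causal_marker] == "h1h3").astype(int), index=genotypes.index, name="true"
    )

    observed = true_phen.astype(float).copy()
    u = rng.random(n)
    flip = rng.random(n)
    is_mut = true_phen.to_numpy() == 1
    unclass = np.where(is_mut, u < cfg.mutant_unclassified, u < cfg.wt_unclassified)
    flipped = np.where(is_mut, flip < cfg.fn_rate, flip < cfg.fp_rate)
    obs = np.where(flipped, 1 - true_phen.to_numpy(), true_phen.to_numpy()).astype(float)
    obs[unclass] = np.nan
    observed = pd.Series(obs, index=genotypes.index, name="observed")

    return SimulatedF1(pop, true_phen, observed, causal_marker)


class PanelSim(NamedTuple):
    panel: dict[str, dict[str, int]]  # variety -> canonical k-mer -> count
    truth: pd.DataFrame  # variety, dosage_c, footprint
    tags: dict[str, AlleleTagSet]  # raw (uncurated) tag sets
    contaminant_kmers: frozenset[str]
    partial_kmers: frozenset[str]


def make_variety_panel(cfg: SynthConfig | None = None, seed: int | None = None,
                       rng: np.random.Generator | None = None) -> PanelSim:
    """Simulate per-variety k-mer counts for a tetraploid panel.

    Each variety carries a known dosage d of the mutant-tagging SNP
    allele C (and 4 − d of allele T); tag-k-mer counts are Poisson with
    mean dosage × coverage.  A subset of C carriers also carries the
    insertion footprint haplotype; its 67-nt window shares
    ``n_contaminant`` k-mers with a repeat present in every variety, so
    specificity curation must remove exactly those.  One variety gets a
    partial footprint signal (only ``n_partial_kmers`` k-mers), mimicking
    a rearranged footprint allele.
    """
    cfg = cfg or SynthConfig()
    if rng is None:
        rng = np.random.default_rng(seed)

    half = cfg.snp_window // 2
    base = list(random_seq(cfg.snp_window, rng))
    base[half] = "C"
    window_c = "".join(base)
    base[half] = "T"
    window_t = "".join(base)
    fp_start = (cfg.footprint_window - cfg.footprint_len) // 2
    window_fp = random_seq(cfg.footprint_window, rng)

    tags = {
        "MSH4_777:C": build_tag_kmers(window_c, (half, half + 1), cfg.k, "MSH4_777:C"),
        "MSH4_777:T": build_tag_kmers(window_t, (half, half + 1), cfg.k, "MSH4_777:T"),
        "footprint": build_tag_kmers(window_fp, (fp_start, fp_start + cfg.footprint_len), cfg.k, "footprint"),
    }

    fp_positional = []
    for km in kmerize(window_fp, cfg.k):  # positional order, deduplicated
        if km in tags["footprint"].kmers and km not in fp_positional:
            fp_positional.append(km)
    contaminant = frozenset(fp_positional[: cfg.n_contaminant])
    curated_fp = [km for km in fp_positional if km not in contaminant]
    partial_kmers = frozenset(curated_fp[: cfg.n_partial_kmers])

    dosages = np.concatenate([[d] * n for d, n in cfg.dosage_hist])
    rng.shuffle(dosages)
    varieties = [f"var{i + 1:03d}" for i in range(cfg.panel_size)]

    carriers = [v for v, d in zip(varieties, dosages) if d >= 1]
    fp_full = set(carriers[: cfg.n_footprint_full])
    fp_partial = set(carriers[cfg.n_footprint_full : cfg.n_footprint_full + cfg.n_footprint_partial])

    cov = cfg.coverage_per_copy
    all_tag_kmers = sorted(set().union(*(t.kmers for t in tags.values())))
    panel: dict[str, dict[str, int]] = {}
    truth_rows = []
    for v, d in zip(varieties, dosages):
        counts: dict[str, int] = {}

        def _add(km: str, lam: float) -> None:
            c = int(rng.poisson(lam))
            if c > 0:
                counts[km] = counts.get(km, 0) + c

        for km in sorted(tags["MSH4_777:C"].kmers):
            if d > 0:
                _add(km, d * cov)
        for km in sorted(tags["MSH4_777:T"].kmers):
            if d < 4:
                _add(km, (4 - d) * cov)
        if v in fp_full:
            for km in sorted(tags["footprint"].kmers):
                if km not in contaminant:
                    _add(km, cov)
        elif v in fp_partial:
            for km in sorted(partial_kmers):
                _add(km, cov)
        for km in sorted(contaminant):
            _add(km, 4 * cov)
        # sequencing-error k-mers: spurious singletons on absent tags
        for km in all_tag_kmers:
            if km not in counts and rng.random() < cfg.kmer_error_rate:
                counts[km] = 1
        for _ in range(cfg.n_background_kmers):
            _add(random_seq(cfg.k, rng), 2 * cov)
        panel[v] = counts
        fp_state = "full" if v in fp_full else ("partial" if v in fp_partial else "absent")
        truth_rows.append({"variety": v, "dosage_c": int(d), "footprint": fp_state})

    truth = pd.DataFrame(truth_rows).set_index("variety")
    return PanelSim(panel, truth, tags, contaminant, partial_kmers)


class VcfSim(NamedTuple):
    bulk: list[VariantRecord]
    parents: tuple[list[VariantRecord], list[VariantRecord]]
    annotation: pd.DataFrame
    truth: list[tuple[str, int, str, str]]  # keys of the planted causal set


def _rand_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    return str(ref), str(alt)


def make_vcf_fixture(cfg: SynthConfig | None = None, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> VcfSim:
    """Plant bulk/parent variant sets spanning every funnel stratum.

    Strata: quality-passing non-LOF background, low-QUAL, DP out of
    range, fixed LOF absent from both parents, unfixed LOF, and the truth
    set of fixed LOF variants shared with a parent, distributed over the
    configured genes.  The funnel must return exactly the truth set.
    """
    cfg = cfg or SynthConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    chrom = cfg.vcf_chrom
    bg_genes = ["gene_bg1", "gene_bg2", "gene_bg3", "gene_bg4"]

    n_total = (
        cfg.n_pass_background
        + cfg.n_low_qual
        + cfg.n_dp_out
        + cfg.n_parent_absent
        + cfg.n_lof_unfixed
        + sum(n for _, n in cfg.fixed_lof_per_gene)
    )
    positions = np.sort(rng.choice(np.arange(1_000, 1_900_000), size=n_total, replace=False))
    pos_iter = iter(int(p) for p in positions)

    bulk: list[VariantRecord] = []
    parent_a: list[VariantRecord] = []
    parent_b: list[VariantRecord] = []
    truth: list[tuple[str, int, str, str]] = []

    def _qual_ok() -> float:
        # integer-valued QUALs survive the float32 round-trip of VCF exactly
        return float(rng.integers(30, 200))

    def _dp_ok() -> int:
        return int(rng.integers(10, 38))

    def _parent_copy(v: VariantRecord) -> VariantRecord:
        return VariantRecord(
            chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
            qual=_qual_ok(), dp=_dp_ok(),
            dp4=(int(rng.integers(3, 10)), int(rng.integers(3, 10)),
                 int(rng.integers(3, 10)), int(rng.integers(3, 10))),
            effect=v.effect, lof=v.lof, gene_id=v.gene_id,
        )

    def _share_with_parents(v: VariantRecord) -> None:
        which = int(rng.integers(0, 3))  # parent A, parent B, or both
        if which in (0, 2):
            parent_a.append(_parent_copy(v))
        if which in (1, 2):
            parent_b.append(_parent_copy(v))

    def _bg_gene() -> str:
        return bg_genes[int(rng.integers(0, len(bg_genes)))]

    for _ in range(cfg.n_pass_background):
        ref, alt = _rand_snv(rng)
        v = VariantRecord(chrom, next(pos_iter), ref, alt, qual=_qual_ok(), dp=_dp_ok(),
                          dp4=(int(rng.integers(2, 8)), int(rng.integers(2, 8)),
                               int(rng.integers(2, 8)), int(rng.integers(2, 8))),
                          effect="synonymous_variant", lof=False, gene_id=_bg_gene())
        bulk.append(v)
        _share_with_parents(v)

    for _ in range(cfg.n_low_qual):
        ref, alt = _rand_snv(rng)
        v = VariantRecord(chrom, next(pos_iter), ref, alt, qual=float(rng.integers(0, 20)), dp=_dp_ok(),
                          dp4=(0, 0, 5, 5), effect="stop_gained", lof=True, gene_id=_bg_gene())
        bulk.append(v)
        _share_with_parents(v)

    for _ in range(cfg.n_dp_out):
        ref, alt = _rand_snv(rng)
        dp = int(rng.choice([int(rng.integers(1, 8)), int(rng.integers(41, 90))]))
        v = VariantRecord(chrom, next(pos_iter), ref, alt, qual=_qual_ok(), dp=dp,
                          dp4=(0, 0, 4, 4), effect="frameshift_variant", lof=True, gene_id=_bg_gene())
        bulk.append(v)
        _share_with_parents(v)

    for _ in range(cfg.n_parent_absent):
        ref, alt = _rand_snv(rng)
        v = VariantRecord(chrom, next(pos_iter), ref, alt, qual=_qual_ok(), dp=_dp_ok(),
                          dp4=(0, 0, 6, 7), effect="frameshift_variant", lof=True, gene_id=_bg_gene())
        bulk.append(v)  # deliberately not shared with either parent

    for _ in range(cfg.n_lof_unfixed):
        ref, alt = _rand_snv(rng)
        v = VariantRecord(chrom, next(pos_iter), ref, alt, qual=_qual_ok(), dp=_dp_ok(),
                          dp4=(int(rng.integers(1, 6)), int(rng.integers(0, 6)), 6, 6),
                          effect="stop_gained", lof=True, gene_id=_bg_gene())
        bulk.append(v)
        _share_with_parents(v)

    for gene, n_var in cfg.fixed_lof_per_gene:
        for _ in range(n_var):
            ref, alt = _rand_snv(rng)
            effect = "frameshift_variant" if rng.random() < 0.5 else "stop_gained"
            v = VariantRecord(chrom, next(pos_iter), ref, alt, qual=_qual_ok(), dp=_dp_ok(),
                              dp4=(0, 0, int(rng.integers(4, 15)), int(rng.integers(4, 15))),
                              effect=effect, lof=True, gene_id=gene)
            bulk.append(v)
            _share_with_parents(v)
            truth.append(v.key)

    bulk.sort(key=lambda v: v.pos)
    parent_a.sort(key=lambda v: v.pos)
    parent_b.sort(key=lambda v: v.pos)

    ann_rows = [
        {"gene_id": "gene_YTH", "description": "YTH family protein", "go_terms": ""},
        {"gene_id": "gene_hAT", "description": "hAT transposon superfamily", "go_terms": ""},
        {"gene_id": "gene_NBARC", "description": "NB-ARC disease resistance protein", "go_terms": ""},
        {"gene_id": "gene_MSH4", "description": "MutS-like protein 4", "go_terms": "GO:0000003,GO:0007049"},
        {"gene_id": "gene_bg1", "description": "unknown protein", "go_terms": ""},
        {"gene_id": "gene_bg2", "description": "kinase-like protein", "go_terms": ""},
        {"gene_id": "gene_bg3", "description": "unknown protein", "go_terms": ""},
        {"gene_id": "gene_bg4", "description": "pentatricopeptide repeat protein", "go_terms": ""},
    ]
    annotation = pd.DataFrame(ann_rows).set_index("gene_id")
    return VcfSim(bulk, (parent_a, parent_b), annotation, truth)
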