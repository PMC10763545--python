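# Methods

## Meiosis model

A diploid meiocyte is simulated at chromatid resolution: each homolog
contributes two sister chromatids carrying allele vectors at the marker
positions of a `GenomeSpec` (map units in [0, 1] per chromosome).

* **Bivalents.** In wild-type mode every chromosome forms a bivalent; in
  crossover-shortage mode `b` chromosomes are re-drawn uniformly per
  meiosis (the cytology reports "about one bivalent per meiocyte" without
  identity, so identity is not persistent). Each bivalent receives exactly
  `co_per_bivalent` crossovers (default 1, the obligate crossover) at
  positions uniform on [0, 1], between one randomly chosen chromatid of
  each homolog. No chiasma interference or CO landscape is modelled.
* **Univalents** travel intact (both sisters together) to a random pole at
  anaphase I. This is what produces the `(1/2)^(n−b)` closed form for a
  balanced reduced gamete, and the simulator's Monte-Carlo fraction is
  tested against both that closed form and an exhaustive enumeration of
  pole assignments for small `n`.
* **FDR** is a whole-meiosis event with probability `fdr_prob`: the two
  metaphase-II plates fuse and the complete complement divides
  equationally into a dyad. Each dyad member receives one chromatid from
  every centromere-origin pair, so FDR gametes are always balanced and
  retain heterozygosity everywhere except distal to a crossover, where
  retention drops to 1/2. With a single uniformly placed CO on one of 12
  chromosomes the expected retention is (11 + 3/4)/12 ≈ 0.979, which the
  test suite checks against a per-locus transmission argument.
* Second-division restitution is **not** simulated; an SDR-like gamete
  (two sister chromatids) can be constructed directly and serves as the
  zero-retention reference in ordering tests. Literature values for
  retention under specific CO/centromere maps (e.g. ~94% for
  crossover-shortage FDR) depend on unspecified map assumptions, so the
  simulator asserts only orderings (no-CO FDR = 1 > with-CO FDR > SDR).

## Pollen rendering and classification

Grains are drawn with replacement from a gamete pool. Balanced gametes
stain; unbalanced reduced gametes are unstained except with probability
`aneuploid_stainable_prob` (aneuploid cytoplasm that takes the stain).
Diameters are normal per ploidy class, truncated at zero: reduced mean
22 µm, unreduced mean 15% larger, both with CV 4%; grains above 23 µm are
scored as 2n.

Two rendering defaults are package choices where only qualitative guidance
exists:

* **CV 4%** rather than a looser spread: with the stated 15% mean offset a
  CV much above ~4.5% would push >5% of 2n grains below the 23 µm cutoff,
  which would contradict the cutoff's use as a reliable 2n discriminator
  and make the strict wild-type rule misfire on true mutants.
* **`aneuploid_stainable_prob` = 0.003** per grain. Mutant samples are
  observed to show up to ~3% of their *stained* grains as small; because
  mutant stainability is itself low (only FDR products stain), a per-grain
  probability of 0.3% reproduces that 2–3% share. A per-grain value of
  0.03 would make small grains ~20% of stained ones and is inconsistent
  with the strict 5% rule ever calling a mutant.

The dichotomous key: stainability < 5% → `unknown`; small stained grains
present (lenient: ≥ 1 grain; strict: > 5% of stained grains, exclusive
boundary) → `wild_type`; large stained grains alongside small unstained
grains → `co_shortage`; otherwise `undetermined`. The 5% stainability floor
is computed over all grains. Sampling four ~50-grain fields of view is
emulated by the 200-grain default. Under these defaults the lenient rule
misses roughly half of simulated mutants (false negatives) while wild-type
false positives are ~0 — the qualitative asymmetry the strict rule was
introduced to fix; the strict rule still misses a minority of mutants whose
samples contain few stained grains, and the error rates are reported by the
test suite rather than assumed away.

## QTL scan

The additive model is ordinary least squares of the 0/1 phenotype on one
or two binary haplotype indicators, with the model F-test p-value (capped
at −log10 p = 300). Least squares on a binary response was chosen over
logistic regression to keep the permutation null cheap and exact;
a cross-check against `statsmodels` OLS is part of the unit tests.
Missing genotypes are dropped marker-wise; markers with fewer than two
observed genotype classes are reported NA. Permutation thresholds permute
the phenotype vector as a whole (N = 1,000, α = 0.05 by default) and take
the (1 − α) quantile of genome-wide maxima; empirical genome-wide type-I
error on null data is verified to sit in [0.02, 0.10].

Recombinant interval logic (recessive trait, mutant class h1h3):
individuals with exactly one unambiguous breakpoint separating an h1h3
segment from another combination constrain the locus — mutants to their
h1h3 segment, wild types to its complement; the candidate interval is the
intersection, reported half-open in bp (breakpoint placed at the first
marker of the new phase). Phenotype calls that contradict recessive
inheritance at a reference marker (normally the scan peak) can be blanked
first with `curate_recessive_conflicts`; without this curation the
intersection of constraints from misclassified individuals is typically
empty, which raises rather than returning a silently wrong interval.
Intervals are 1-based half-open internally and exported as 0-based
half-open BED.

## LOF funnel

The quoted bcftools-style expression `%QUAL < 20 || DP > 40 || DP < 8` is
read as an **exclusion** mask (low quality or depth out of range), since a
literal "high-confidence" reading would keep only bad calls; boundary
values (QUAL = 20, DP = 8 or 40) are retained. Parent concordance keys on
(chrom, pos, ref, alt) and by default applies the same quality filter to
the parent calls (a flag disables it, since the source protocol is
ambiguous about the parent side). Fixation requires `DP4[0] = DP4[1] = 0`
with at least one ALT read; all-zero quads are uninformative. LOF status
is consumed from the annotation (`LOF` tag or effect keyword in
{frameshift_variant, stop_gained, splice_acceptor_variant,
splice_donor_variant, start_lost}); effect prediction is not
re-implemented. Multi-allelic records are split per ALT at read time with
DP4 applied as given. The three predicates are independent, so the funnel
is order-invariant — a property the tests verify on the synthetic fixture.

## k-mer dosage

Tag sets take every k-mer (k = 31, canonical = lexicographic min with the
reverse complement) of a window that overlaps the focal positions: 9 tags
from a 39-nt SNP window, 37 from a 67-nt window around a 7-bp footprint.
Specificity curation drops tags present in more than 90% of panel
varieties ("nearly all"); this is meaningful for minor-allele tags — tags
of a major allele (e.g. the wild-type SNP allele, present in every
variety of the panel) are legitimately ubiquitous and are used uncurated.
Presence requires each tag to reach count ≥ 2 (suppressing single
sequencing-error k-mers); the per-tag-set count summary is the **median**
(robust to individual error or repeat k-mers; the source protocol does not
state its summary). Dosage = round(ploidy × ratio) with exact ties toward
the lower class (conservative and deterministic). Panel allele frequency
is the dosage-weighted mean over varieties.

## Gamete dosage model

Binomial coefficients with out-of-range arguments are zero, so the
hypergeometric sum needs no guards; results are tested against exhaustive
enumeration of all C(p, p/2) gamete draws for p ∈ {2, 4, 6} and against
Monte-Carlo sampling. Double reduction is excluded by design (no α
parameter). Evaluating the model on the *discretised* panel histogram
{0: 55, 1: 45, 2: 26, 3: 8} gives 6.2% homozygous and 32.7% heterozygous
dihaploids; published figures of 6.4%/33.5% derive from per-variety
continuous dosage estimates that are not public, so the implementation
reproduces the formula exactly on given inputs and does not force those
printed values.

## Synthetic generators: what a green test establishes

* **F1 population** (default N = 1,345; two chromosomes × 100 markers at
  50 kb; causal marker at 1.15 Mb on chr08): both parents are carriers, so
  h1h3 at the causal marker (≈ 1/4 of offspring) is mutant. Inheritance is
  marker-to-marker with per-interval recombination 0.01 and no
  interference. The phenotype error model uses the observed rates — 0.5%
  wild-type→mutant, 44% mutant→wild-type among classified, 59%/23.2%
  unclassified for mutants/wild types. Note these published rates were
  measured on a population whose mutant-genotype fraction was ~30% (not
  the Mendelian 25% the generator plants), so observed *counts* here echo
  the generator's own arithmetic, not the published totals; recovery tests
  (peak within two markers of the causal locus in ≥ 95/100 replicates,
  interval containing the locus in 50/50 clean replicates) are the
  meaningful checks.
* **Variety panel** (134 tetraploids, dosage histogram {55, 45, 26, 8},
  20× coverage per allele copy, Poisson counts, 1% spurious singleton
  k-mers, 21 full-footprint carriers, one partial carrier with 2 tags, 6
  footprint tags contaminated by a ubiquitous repeat): establishes
  curation (37 → 31), presence calls and ≥ 95% dosage-class recovery — not
  the behaviour of real repeat landscapes or GC-biased coverage.
* **VCF trio**: strata cover every funnel predicate (60 passing non-LOF,
  10 low-QUAL, 10 DP out of range, 4 parent-absent fixed LOF, 14 unfixed
  LOF, 6 fixed LOF over 4 genes); the funnel must return exactly the
  planted six. Integer QUAL values are used so records survive the float32
  round-trip of VCF exactly.

All generators are bit-reproducible given a seed; truth tables are emitted
alongside every fixture.

## Known limitations

* No double reduction, no chiasma interference, no female-meiosis
  cytokinesis specifics; megaspore-side FDR is out of scope.
* The QTL model is a linear probability model; with severe class
  imbalance its F-test is approximate (the permutation threshold, not the
  nominal p-value, carries the inference).
* k-mer handling is window-scale: no on-disk k-mer database formats and
  no genome-scale counting performance work.
* Real-data quantities that require the deposited sequencing data (peak
  position 1.15 Mb, the 1.9 Mb interval, 26,327/24/6 funnel counts,
  70/21/79 panel carrier counts) are replaced by the parameter-recovery
  properties above.
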