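# coshort

A toolkit for the genetics of **crossover shortage** (desynapsis) in potato:
the recessive meiotic defect in which most homologous chromosomes fail to
retain a crossover, fall apart into univalents, and segregate at random
during meiosis I. On its own this sterilises a diploid clone; combined with
first-division restitution (FDR) it instead produces uniform, highly
heterozygous unreduced (2n) pollen — a double-edged sword for breeders.

The package re-implements the full computational chain used to study such a
locus, exercisable end to end on synthetic data with known ground truth:

| module | what it does |
|---|---|
| `coshort.meiosis` | diploid meiosis with `b` bivalents, random univalent segregation, FDR dyads; closed form `(1/2)^(n-b)` for balanced reduced gametes; heterozygosity transmission of 2n gametes |
| `coshort.pollen` | renders gamete pools into stained/unstained pollen samples and classifies them with a dichotomous key (23 µm 2n-size cutoff, 5% stainability floor, lenient/strict wild-type rules) |
| `coshort.qtl` | single-marker additive regression for a binary trait in an F1 outcross (h1/h2 × h3/h4 haplotype codes), permutation thresholds, genotype×phenotype mosaic tables, recombinant-based interval delimitation |
| `coshort.lofbulk` | bulked-mutant loss-of-function funnel: QUAL/DP filter, parent concordance, DP4 fixation (`ref-fwd = ref-rev = 0`), per-gene roll-up with GO candidate flags |
| `coshort.kmers` | allele-diagnostic canonical k-mer tag sets (k=31), panel specificity curation, presence calls, and frequency-ratio allele dosage in autotetraploids |
| `coshort.dosage` | hypergeometric gamete/dihaploid dosage model without double reduction |
| `coshort.synth` | synthetic F1 populations, tetraploid k-mer panels and VCF trios with machine-readable truth |
| `coshort.io`, `coshort.cli` | TSV/VCF/FASTA readers and writers, umbrella `coshort` CLI |

## The models in brief

**Balanced-gamete probability.** With `n` haploid chromosomes of which `b`
still form bivalents, each of the `n − b` univalents moves to a random pole
at anaphase I, so a reduced gamete carries one copy of every chromosome with
probability `(1/2)^(n−b)`. For potato (`n = 12`) with one residual bivalent
this is `1/2048` — fewer than one balanced reduced gamete in two thousand,
hence sterility. FDR restitution rescues fertility: the fused metaphase-II
plates divide the whole complement equationally, so every dyad member is a
balanced 2n gamete regardless of how univalents had segregated.

**Gamete/dihaploid dosage.** A tetraploid parent carrying `n` copies of an
allele transmits `k` copies to a gamete (equivalently, to an induced
dihaploid) hypergeometrically:

```
P(Gk) = Σₙ P(Pn) · C(n,k) · C(p−n, p/2−k) / C(p, p/2)
```

**Binary QTL scan.** Per marker, the 0/1 phenotype is regressed on a
maternal (h1 vs h2) and/or paternal (h3 vs h4) indicator; the model F-test
p-value is reported as −log10 p, with genome-wide significance from the
(1 − α) quantile of per-permutation maxima.

## Worked example

Dihaploid prospects of a 134-variety tetraploid panel in which 55 varieties
are nulliplex, 45 simplex, 26 duplex and 8 triplex for a deleterious allele:

```
$ coshort gamete-dosage --ploidy 4 --counts 55,45,26,8
P(G0)   0.610697
P(G1)   0.327114
P(G2)   0.062189
dihaploids: 6.2% homozygous, 32.7% heterozygous
```

Read: ~6.2% of dihaploids induced from this panel would be homozygous for
the allele (crossover-shortage sterile once selfed) and ~32.7% would be
carriers. The same histogram gives a dosage-weighted allele frequency of
`(45 + 2·26 + 3·8) / (4·134) = 22.6%`.

Simulating twenty thousand crossover-shortage meioses (one bivalent, 20%
FDR):

```
$ coshort simulate-meiosis --n 12 --b 1 --fdr 0.2 --reps 20000 --seed 7 --out pool.tsv
72042 gametes (7990 balanced) -> pool.tsv
```

Almost all balanced gametes are the unreduced dyad products (2 per FDR
meiosis ≈ 8,000); balanced *reduced* gametes appear at the expected ~1/2048
of the ~64,000 reduced products.

Other subcommands: `classify-pollen`, `scan-qtl`, `filter-lof`,
`kmer-dosage`, `make-synth` (synthetic fixtures with ground truth); every
stochastic subcommand requires `--seed`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the package, the panel-wide allele frequency implied
by the printed dosage-class counts and the reciprocal balanced-gamete
probability for `n = 12, b = 1` (cross-checked against a 10⁶-meiosis
Monte-Carlo run), writing one JSON object per target.

See `docs/methods.md` for model assumptions, parameter defaults and the
limits of what the synthetic generators establish.
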