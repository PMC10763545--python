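"""Binary-trait single-marker scan, permutation threshold, mosaic, interval."""

import numpy as np
import pandas as pd
import pytest

from coshort.qtl import (
    F1Population,
    curate_recessive_conflicts,
    genotype_phenotype_table,
    permutation_threshold,
    recombinant_interval,
    single_marker_scan,
)
from coshort.synth import SynthConfig, make_f1_population


def make_pop(codes_by_marker, positions=None, chrom="chr08", origin="integrated"):
    """Population from {marker: list-of-codes}; individuals ind0, ind1, ..."""
    marker_ids = list(codes_by_marker)
    n = len(next(iter(codes_by_marker.values())))
    positions = positions or [(i + 1) * 1_000_000 for i in range(len(marker_ids))]
    markers = pd.DataFrame(
        {"chrom": chrom, "pos_bp": positions, "origin": origin},
        index=pd.Index(marker_ids, name="marker"),
    )
    genotypes = pd.DataFrame(codes_by_marker, index=[f"ind{i}" for i in range(n)])
    return F1Population(markers=markers, genotypes=genotypes)


def recessive_pop(n, rng, n_markers=1):
    codes = rng.choice(["h1h3", "h1h4", "h2h3", "h2h4"], size=(n, n_markers))
    pop = make_pop({f"m{j}": codes[:, j] for j in range(n_markers)})
    phen = pd.Series((codes[:, 0] == "h1h3").astype(float), index=pop.individuals)
    return pop, phen


def test_perfect_association_exceeds_threshold(rng):
    """A marker fully predicting a recessive phenotype is unambiguous at n=400."""
    pop, phen = recessive_pop(400, rng)
    res = single_marker_scan(pop, phen)
    thr = permutation_threshold(pop, phen, n_perm=200, alpha=0.05, seed=1)
    assert res.table["neglog10p"].iloc[0] > thr
    assert res.table["neglog10p"].iloc[0] > 50


def test_null_marker_rarely_significant(rng):
    """Phenotype independent of the marker: -log10 p < 2 in ~99% of draws."""
    codes = rng.choice(["h1h3", "h1h4", "h2h3", "h2h4"], size=963)
    pop = make_pop({"m0": codes})
    hits = 0
    n_draws = 300
    for _ in range(n_draws):
        phen = pd.Series(rng.integers(0, 2, size=963).astype(float), index=pop.individuals)
        res = single_marker_scan(pop, phen)
        hits += res.table["neglog10p"].iloc[0] < 2
    assert hits / n_draws > 0.95


def test_scan_invariant_to_joint_haplotype_relabeling(rng):
    pop, phen = recessive_pop(300, rng, n_markers=3)
    swap = {"h1h3": "h2h4", "h2h4": "h1h3", "h1h4": "h2h3", "h2h3": "h1h4"}
    pop2 = F1Population(markers=pop.markers.copy(), genotypes=pop.genotypes.replace(swap))
    r1 = single_marker_scan(pop, phen)
    r2 = single_marker_scan(pop2, phen)
    np.testing.assert_allclose(r1.table["neglog10p"], r2.table["neglog10p"], rtol=1e-9)


def test_association_monotone_in_sample_size(rng):
    values = []
    for n in (100, 400, 1000):
        pop, phen = recessive_pop(n, np.random.default_rng(99))
        values.append(single_marker_scan(pop, phen).table["neglog10p"].iloc[0])
    assert values[0] < values[1] < values[2]


def test_scan_matches_statsmodels_ols(rng):
    """Independent route: statsmodels OLS F-test agrees marker by marker."""
    import statsmodels.api as sm

    pop, _ = recessive_pop(120, rng, n_markers=4)
    phen = pd.Series(rng.integers(0, 2, 120).astype(float), index=pop.individuals)
    res = single_marker_scan(pop, phen)
    for marker in pop.markers.index:
        codes = pop.genotypes[marker]
        X = np.column_stack([
            np.array([c[:2] == "h2" for c in codes], dtype=float),
            np.array([c[2:] == "h4" for c in codes], dtype=float),
        ])
        fit = sm.OLS(phen.to_numpy(), sm.add_constant(X)).fit()
        assert res.table.loc[marker, "neglog10p"] == pytest.approx(-np.log10(fit.f_pvalue), rel=1e-6)


def test_parental_only_markers_use_single_indicator(rng):
    n = 200
    mat = rng.choice(["h1", "h2"], size=n)
    pop = make_pop({"m0": mat}, origin="maternal")
    phen = pd.Series((mat == "h1").astype(float), index=pop.individuals)
    res = single_marker_scan(pop, phen)
    assert res.table["neglog10p"].iloc[0] > 30


def test_constant_phenotype_raises(rng):
    pop, _ = recessive_pop(50, rng)
    with pytest.raises(ValueError):
        single_marker_scan(pop, pd.Series(np.ones(50), index=pop.individuals))


def test_all_missing_marker_is_nan(rng):
    pop, phen = recessive_pop(60, rng, n_markers=2)
    genotypes = pop.genotypes.copy()
    genotypes["m1"] = np.nan
    pop = F1Population(markers=pop.markers, genotypes=genotypes)
    res = single_marker_scan(pop, phen)
    assert np.isnan(res.table.loc["m1", "neglog10p"])
    assert np.isfinite(res.table.loc["m0", "neglog10p"])


def test_permutation_threshold_alpha_and_stability(rng):
    pop, phen = recessive_pop(200, rng, n_markers=4)
    thr_1 = permutation_threshold(pop, phen, n_perm=200, alpha=1.0, seed=7)
    thr_05 = permutation_threshold(pop, phen, n_perm=200, alpha=0.05, seed=7)
    assert 0 <= thr_1 <= thr_05
    thr_a = permutation_threshold(pop, phen, n_perm=500, alpha=0.05, seed=8)
    thr_b = permutation_threshold(pop, phen, n_perm=1000, alpha=0.05, seed=8)
    assert abs(thr_a - thr_b) < 0.2


def test_permutation_small_n_warns(rng):
    pop, phen = recessive_pop(80, rng)
    with pytest.warns(UserWarning):
        permutation_threshold(pop, phen, n_perm=50, alpha=0.05, seed=1)


def test_genomewide_type_i_error_calibrated():
    """Nominal alpha = 0.05: empirical genome-wide error within [0.02, 0.10]."""
    cfg = SynthConfig(
        n_individuals=200, markers_per_chrom=40, n_chrom=2, causal_pos=1_000_000,
        fp_rate=0, fn_rate=0, mutant_unclassified=0, wt_unclassified=0,
    )
    pop = make_f1_population(cfg, seed=42).population
    rng = np.random.default_rng(7)
    hits = 0
    n_rep = 150
    for _ in range(n_rep):
        y = pd.Series(rng.integers(0, 2, len(pop.individuals)).astype(float), index=pop.individuals)
        res = single_marker_scan(pop, y)
        thr = permutation_threshold(pop, y, n_perm=300, alpha=0.05, rng=rng)
        hits += res.table["neglog10p"].max() > thr
    assert 0.02 <= hits / n_rep <= 0.10


def test_mosaic_perfect_penetrance(rng):
    pop, phen = recessive_pop(400, rng)
    tab = genotype_phenotype_table(pop, "m0", phen)
    assert tab.loc["h1h3", "mutant"] > 0
    for cls in ("h1h4", "h2h3", "h2h4"):
        assert tab.loc[cls, "mutant"] == 0
    assert tab["unclassified"].sum() == 0


def test_mosaic_echoes_false_negative_rate():
    """With a 44% mutant-to-wild-type error, the h1h3 row splits ~56:44."""
    sim = make_f1_population(SynthConfig(), seed=21)
    tab = genotype_phenotype_table(sim.population, sim.causal_marker, sim.observed_phenotype)
    classified = tab.loc["h1h3", "mutant"] + tab.loc["h1h3", "wild_type"]
    frac_mut = tab.loc["h1h3", "mutant"] / classified
    sd = np.sqrt(0.56 * 0.44 / classified)
    assert abs(frac_mut - 0.56) < 4 * sd


def test_mosaic_empty_phenotype_all_unclassified(rng):
    pop, _ = recessive_pop(100, rng)
    phen = pd.Series(np.nan, index=pop.individuals)
    tab = genotype_phenotype_table(pop, "m0", phen)
    assert tab["unclassified"].sum() == 100
    assert tab[["wild_type", "mutant"]].to_numpy().sum() == 0


def test_recombinant_interval_hand_worked():
    """A mutant recombining h1h3 -> h1h4 at 2 Mb bounds the locus to [0, 2 Mb)."""
    pop = make_pop(
        {
            "m1": ["h1h3", "h1h3"],
            "m2": ["h1h4", "h1h3"],  # ind0 breaks between 1 and 2 Mb
            "m3": ["h1h4", "h1h3"],
        },
        positions=[1_000_000, 2_000_000, 3_000_000],
    )
    phen = pd.Series([1.0, 1.0], index=pop.individuals)
    lo, hi = recombinant_interval(pop, phen, "chr08")
    assert (lo, hi) == (0, 2_000_000)


def test_recombinant_interval_wild_type_excludes_segment():
    # wild-type carrying h1h3 on the left: locus must be right of the breakpoint
    pop = make_pop(
        {"m1": ["h1h3"], "m2": ["h2h3"], "m3": ["h2h3"]},
        positions=[1_000_000, 2_000_000, 3_000_000],
    )
    phen = pd.Series([0.0], index=pop.individuals)
    lo, hi = recombinant_interval(pop, phen, "chr08")
    assert (lo, hi) == (2_000_000, 3_000_001)


def test_recombinant_interval_no_recombinants_warns():
    pop = make_pop(
        {"m1": ["h1h3", "h2h4"], "m2": ["h1h3", "h2h4"]},
        positions=[1_000_000, 2_000_000],
    )
    phen = pd.Series([1.0, 0.0], index=pop.individuals)
    with pytest.warns(UserWarning):
        lo, hi = recombinant_interval(pop, phen, "chr08")
    assert (lo, hi) == (0, 2_000_001)


def test_curation_blanks_conflicting_calls_and_rescues_interval():
    """Misclassified individuals are blanked; the interval then succeeds."""
    sim = make_f1_population(SynthConfig(), seed=55)
    obs = sim.observed_phenotype
    curated = curate_recessive_conflicts(sim.population, obs, sim.causal_marker)
    codes = sim.population.genotypes[sim.causal_marker]
    kept = curated.dropna()
    assert ((kept == 1) == (codes[kept.index] == "h1h3")).all()
    assert curated.notna().sum() < obs.notna().sum()  # some calls were blanked
    lo, hi = recombinant_interval(sim.population, curated, "chr08")
    assert lo <= 1_150_000 < hi


def test_interval_contains_scan_peak_on_clean_data():
    cfg = SynthConfig(n_individuals=500, fp_rate=0, fn_rate=0, mutant_unclassified=0, wt_unclassified=0)
    sim = make_f1_population(cfg, seed=33)
    res = single_marker_scan(sim.population, sim.observed_phenotype)
    peak_pos = sim.population.markers.at[res.peak_marker, "pos_bp"]
    lo, hi = recombinant_interval(sim.population, sim.observed_phenotype, "chr08")
    assert lo <= peak_pos < hi
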