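"""Tag-set construction, curation, presence calls, dosage and read extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coshort.kmers import (
    build_tag_kmers,
    call_presence,
    canonical,
    curate_specificity,
    estimate_dosage,
    extract_reads_with_kmers,
    kmerize,
    panel_maf,
    revcomp,
)
from coshort.synth import random_seq

DNA = st.text(alphabet="ACGT", min_size=31, max_size=40)


def test_revcomp_and_canonical_involution():
    assert revcomp("ACGT") == "ACGT"
    assert revcomp("AAAC") == "GTTT"
    assert canonical("GTTT") == canonical("AAAC") == "AAAC"


@given(seq=DNA)
def test_canonical_is_strand_invariant(seq):
    k = 31
    assert kmerize(seq, k) == [canonical(s) for s in kmerize(revcomp(seq), k)][::-1]


def test_tag_set_sizes():
    rng = np.random.default_rng(0)
    w39 = random_seq(39, rng)
    assert len(build_tag_kmers(w39, (19, 20), k=31).kmers) == 9
    w67 = random_seq(67, rng)
    assert len(build_tag_kmers(w67, (30, 37), k=31).kmers) == 37
    w31 = random_seq(31, rng)
    assert len(build_tag_kmers(w31, (15, 16), k=31).kmers) == 1


def test_tag_set_focal_span_restricts():
    rng = np.random.default_rng(1)
    w = random_seq(80, rng)
    # focal base at position 0: only the first window overlaps it
    assert len(build_tag_kmers(w, (0, 1), k=31).kmers) == 1


def test_tag_set_window_too_short():
    with pytest.raises(ValueError):
        build_tag_kmers("ACGT" * 7, (0, 1), k=31)  # 28 nt < k


def test_curation_removes_ubiquitous_kmers(panel_sim):
    tags = panel_sim.tags["footprint"]
    assert len(tags.kmers) == 37
    curated = curate_specificity(tags, panel_sim.panel)
    assert len(curated.kmers) == 31  # the 6 shared-repeat k-mers are gone
    assert curated.kmers.isdisjoint(panel_sim.contaminant_kmers)


def test_curation_prevalence_rule():
    tags = build_tag_kmers(random_seq(31, np.random.default_rng(2)), (15, 16), k=31)
    km = next(iter(tags.kmers))
    everywhere = {f"v{i}": {km: 5} for i in range(134)}
    with pytest.raises(ValueError):  # 134/134 > 0.9 -> nothing left
        curate_specificity(tags, everywhere)
    rare = {f"v{i}": ({km: 5} if i < 10 else {}) for i in range(134)}
    assert curate_specificity(tags, rare).kmers == tags.kmers


def test_presence_calls(panel_sim):
    curated = curate_specificity(panel_sim.tags["footprint"], panel_sim.panel)
    truth = panel_sim.truth
    full_v = truth[truth.footprint == "full"].index[0]
    partial_v = truth[truth.footprint == "partial"].index[0]
    absent_v = truth[truth.footprint == "absent"].index[0]
    assert call_presence(curated, panel_sim.panel[full_v])[0] == "full"
    state, found = call_presence(curated, panel_sim.panel[partial_v])
    assert state == "partial" and found == panel_sim.partial_kmers
    assert call_presence(curated, panel_sim.panel[absent_v])[0] == "absent"


def test_presence_empty_tags_raise(panel_sim):
    empty = panel_sim.tags["footprint"].with_kmers([])
    with pytest.raises(ValueError):
        call_presence(empty, {})


@pytest.fixture(scope="module")
def snp_tags():
    rng = np.random.default_rng(3)
    base = list(random_seq(39, rng))
    base[19] = "C"
    a = build_tag_kmers("".join(base), (19, 20), k=31, allele_name="A")
    base[19] = "T"
    b = build_tag_kmers("".join(base), (19, 20), k=31, allele_name="B")
    return a, b


@pytest.mark.parametrize("true_dosage", [0, 1, 2, 3, 4])
def test_dosage_exact_in_noise_free_limit(snp_tags, true_dosage):
    a, b = snp_tags
    counts = {km: true_dosage * 25 for km in a.kmers}
    counts.update({km: (4 - true_dosage) * 25 for km in b.kmers})
    counts = {km: c for km, c in counts.items() if c > 0}
    call = estimate_dosage(a, b, counts)
    assert call.dosage == true_dosage


def test_dosage_examples_and_tie_break(snp_tags):
    a, b = snp_tags
    call = estimate_dosage(a, b, {km: 10 for km in a.kmers} | {km: 30 for km in b.kmers})
    assert call.ratio == pytest.approx(0.25) and call.dosage == 1 and call.dosage_class == "simplex"
    call = estimate_dosage(a, b, {km: 40 for km in b.kmers})
    assert call.ratio == 0.0 and call.dosage_class == "nulliplex"
    # ratio 0.375 -> 4 x 0.375 = 1.5: exact tie resolved toward the lower dosage
    call = estimate_dosage(a, b, {km: 3 for km in a.kmers} | {km: 5 for km in b.kmers})
    assert call.dosage == 1
    # zero denominator -> no call
    call = estimate_dosage(a, b, {})
    assert call.dosage is None and call.dosage_class == "no_call"


def test_presence_full_implies_positive_ratio(panel_sim, snp_tags):
    a, b = snp_tags
    counts = {km: 20 for km in a.kmers} | {km: 40 for km in b.kmers}
    state, _ = call_presence(a, counts)
    assert state == "full"
    assert estimate_dosage(a, b, counts).ratio > 0


def test_panel_maf_values():
    assert panel_maf({0: 55, 1: 45, 2: 26, 3: 8}) == pytest.approx(121 / 536)
    assert round(100 * panel_maf({0: 55, 1: 45, 2: 26, 3: 8}), 1) == 22.6
    assert panel_maf({0: 99}) == 0.0
    assert panel_maf({4: 7}) == 1.0
    with pytest.raises(ValueError):
        panel_maf({})
    with pytest.raises(ValueError):
        panel_maf({5: 3})


@given(scale=st.integers(min_value=1, max_value=50))
def test_panel_maf_scaling_invariance(scale):
    base = {0: 5, 1: 4, 2: 3, 3: 2, 4: 1}
    scaled = {d: n * scale for d, n in base.items()}
    assert panel_maf(scaled) == pytest.approx(panel_maf(base))


def test_extract_reads_with_kmers():
    rng = np.random.default_rng(4)
    query = random_seq(31, rng)
    reads = [(f"r{i}", random_seq(100, rng)) for i in range(3000)]
    planted_ids = set()
    for i in rng.choice(3000, size=12, replace=False):
        rid, seq = reads[i]
        insert = query if rng.random() < 0.5 else revcomp(query)  # either orientation
        reads[i] = (rid, seq[:40] + insert + seq[71:])
        planted_ids.add(rid)
    out = extract_reads_with_kmers(reads, [query])
    assert {rid for rid, _ in out} == planted_ids
    assert extract_reads_with_kmers(reads[:5], ["A" * 31]) == []
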