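"""Codon counting, relative frequencies f_i and usage ratios r_i."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phagetools import (
    CodonUsageTable,
    ValidationError,
    count_codons,
    ratio_report,
    relative_frequencies,
    usage_ratios,
)
from phagetools.codons import (
    CLASS_HOST_HIGHER,
    CLASS_PHAGE_HIGHER,
    CLASS_SIMILAR,
    CLASS_UNDEFINED,
    CODONS,
    ratios_to_frame,
)


def naive_tally(seqs, drop_start=True):
    """Independent string-slicing oracle for codon counting."""
    counts, skipped = Counter(), 0
    for s in seqs:
        s = str(s).upper()
        triplets = [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]
        if drop_start:
            triplets = triplets[1:]
        for t in triplets:
            if set(t) <= set("ACGT"):
                counts[t] += 1
            else:
                skipped += 1
    return counts, skipped


def table_from_counts(genome_id, mapping, total=None):
    """Build a CodonUsageTable directly from a codon->frequency mapping."""
    f = dict.fromkeys(CODONS, 0.0)
    f.update(mapping)
    return CodonUsageTable(genome_id=genome_id, f=f, total_codons=total or 1)


@pytest.mark.parametrize(
    "drop_start,expected,total",
    [(True, {"CCA": 1, "TAA": 1}, 2), (False, {"ATG": 1, "CCA": 1, "TAA": 1}, 3)],
)
def test_count_codons_start_removal(drop_start, expected, total):
    c = count_codons(["ATGCCATAA"], drop_start=drop_start)
    assert c.total == total
    assert {k: v for k, v in c.counts.items() if v} == expected


def test_count_codons_skips_ambiguous_triplets():
    c = count_codons(["ATGCCNTAA"], drop_start=True)
    assert c.counts["TAA"] == 1 and c.total == 1
    assert c.n_skipped_codons == 1


def test_count_codons_empty_input():
    c = count_codons([])
    assert c.total == 0 and c.n_cds_used == 0


def test_count_codons_matches_naive_oracle():
    """200 random CDS sets of <=30 codons: exact agreement with the oracle."""
    rng = np.random.default_rng(42)
    alphabet = np.array(list("ACGTN"))
    for _ in range(200):
        n_cds = rng.integers(1, 6)
        seqs = [
            "".join(rng.choice(alphabet, p=[0.24] * 4 + [0.04], size=3 * rng.integers(2, 31)))
            for _ in range(n_cds)
        ]
        drop = bool(rng.integers(2))
        got = count_codons(seqs, drop_start=drop)
        want, skipped = naive_tally(seqs, drop_start=drop)
        assert {k: v for k, v in got.counts.items() if v} == dict(want)
        assert got.n_skipped_codons == skipped


def test_relative_frequencies_simple_and_uniform():
    c = count_codons(["ATGCCATAA"])
    t = relative_frequencies(c, genome_id="x")
    assert t.f["CCA"] == 0.5 and t.f["TAA"] == 0.5
    assert sum(v for v in t.f.values()) == pytest.approx(1.0, abs=1e-9)

    uniform = count_codons([c * 10 for c in CODONS], drop_start=False)
    tu = relative_frequencies(uniform)
    assert all(v == pytest.approx(1 / 64) for v in tu.f.values())


def test_relative_frequencies_zero_total_is_undefined():
    t = relative_frequencies(count_codons([]))
    assert all(math.isnan(v) for v in t.f.values())
    with pytest.raises(ValidationError):
        usage_ratios(t, t)


def test_pseudocount_gives_finite_ratios_everywhere():
    t1 = relative_frequencies(count_codons(["ATGCCATAA"] * 5), pseudocount=1)
    t2 = relative_frequencies(count_codons(["ATGGGGTAA"] * 5), pseudocount=1)
    r = usage_ratios(t1, t2)
    assert all(not math.isnan(v) for v in r.r.values())


def test_self_ratio_is_one():
    cds = ["ATGCCATTTAAATAA", "ATGAGAGGGTAA"]
    t = relative_frequencies(count_codons(cds), genome_id="s")
    r = usage_ratios(t, t)
    for c in CODONS:
        if t.f[c] > 0:
            assert r.r[c] == pytest.approx(1.0)
            assert r.clazz[c] == CLASS_SIMILAR
        else:
            assert r.clazz[c] == CLASS_UNDEFINED


def test_ratio_arithmetic_and_undefined_handling():
    phage = table_from_counts("p", {"CCA": 0.02, "AAA": 0.98})
    host = table_from_counts("h", {"CCA": 0.01, "AAA": 0.99})
    r = usage_ratios(phage, host)
    assert r.r["CCA"] == pytest.approx(2.0)
    assert r.clazz["CCA"] == CLASS_PHAGE_HIGHER
    assert r.clazz["GGG"] == CLASS_UNDEFINED  # host f = 0
    assert "GGG" not in r.rank
    assert sorted(r.rank.values()) == list(range(1, r.n_defined + 1))


def test_classification_boundaries_exact():
    """r = 1.1 is phage_higher, r = 0.9 is similar, just below 0.9 is host_higher."""
    host = table_from_counts("h", {"AAA": 0.5, "CCC": 0.5})
    # 0.55/0.5 and 0.45/0.5 are exactly 1.1 and 0.9 in binary floating point
    phage = table_from_counts("p", {"AAA": 0.55, "CCC": 0.45})
    r = usage_ratios(phage, host)
    assert r.r["AAA"] == 1.1 and r.clazz["AAA"] == CLASS_PHAGE_HIGHER
    assert r.r["CCC"] == 0.9 and r.clazz["CCC"] == CLASS_SIMILAR

    below = table_from_counts("p", {"AAA": 0.55, "CCC": math.nextafter(0.45, 0)})
    assert usage_ratios(below, host).clazz["CCC"] == CLASS_HOST_HIGHER


@given(st.integers(0, 2**32 - 1))
def test_reciprocal_ratios_multiply_to_one(seed):
    rng = np.random.default_rng(seed)
    mk = lambda: relative_frequencies(
        count_codons(
            ["".join(rng.choice(list("ACGT"), size=3 * rng.integers(5, 30)))
             for _ in range(5)],
            drop_start=False,
        )
    )
    a, b = mk(), mk()
    rab, rba = usage_ratios(a, b), usage_ratios(b, a)
    for c in CODONS:
        if a.f[c] > 0 and b.f[c] > 0:
            assert rab.r[c] * rba.r[c] == pytest.approx(1.0, abs=1e-9)


def test_scale_invariance_under_cds_duplication():
    cds = ["ATGCCATTTAAATAA", "ATGAGAGGGTAA"]
    t1 = relative_frequencies(count_codons(cds))
    t2 = relative_frequencies(count_codons(cds * 3))
    assert t1.f == t2.f


def test_ratio_report_partitions_and_tie_rule():
    mapping_h = {c: 1 / 20 for c in CODONS[:20]}
    host = table_from_counts("h", mapping_h)
    phage = table_from_counts("p", mapping_h)  # all ratios equal 1
    r = usage_ratios(phage, host)
    rep = ratio_report(r, k=10)
    assert sorted(rep["codon"]) == sorted(CODONS[:20])
    assert len(set(rep["codon"])) == 20
    # all-equal ratios: top-k is the first k codons alphabetically
    assert list(rep[rep["end"] == "top"]["codon"]) == sorted(CODONS[:20])[:10]

    with pytest.raises(ValidationError):
        ratio_report(r, k=11)
    with pytest.raises(ValidationError):
        ratio_report(r, k=0)


def test_extreme_enrichment_hits_first_and_last_rank():
    base = {c: 1 / 20 for c in CODONS[:20]}
    host = table_from_counts("h", base)
    shifted = dict(base)
    shifted["AAC"] = base["AAC"] * 3
    shifted["AAG"] = base["AAG"] / 3
    z = sum(shifted.values())
    phage = table_from_counts("p", {c: v / z for c, v in shifted.items()})
    r = usage_ratios(phage, host)
    assert r.rank["AAC"] == 1
    assert r.rank["AAG"] == r.n_defined


def test_ratios_frame_has_all_64_codons(enriched_pair):
    host, phage, _ = enriched_pair
    from phagetools import extract_cds

    r = usage_ratios(
        relative_frequencies(count_codons(extract_cds(phage)), genome_id="p"),
        relative_frequencies(count_codons(extract_cds(host)), genome_id="h"),
    )
    frame = ratios_to_frame(r)
    assert len(frame) == 64
    assert set(frame["class"]).issubset(
        {CLASS_PHAGE_HIGHER, CLASS_SIMILAR, CLASS_HOST_HIGHER, CLASS_UNDEFINED}
    )
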