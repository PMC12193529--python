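"""Codon counting, RSCU, reference tables, CAI and positional GC."""

import math
import random

import pytest

from mitocomp.codon_usage import (
    CodonCounts,
    DegenerateReferenceError,
    GeneticCode,
    InvalidInputError,
    ReferenceTable,
    TableParseError,
    ALL_CODONS,
    cai,
    cai_weights,
    codon_counts,
    gc_by_position,
    read_reference_table,
    rscu,
    sliding_window_cai,
)


def test_table5_structure(code5):
    assert len(code5.sense_codons) == 62
    assert code5.stop_codons == frozenset({"TAA", "TAG"})
    assert code5.codon_to_aa["TGA"] == "W"
    assert code5.codon_to_aa["ATA"] == "M"
    assert code5.codon_to_aa["AGA"] == "S"
    assert len(code5.families["L"]) == 6
    assert len(code5.families["S"]) == 8  # UCN plus AGN under table 5


# ---------------------------------------------------------------------------
# Codon counting
# ---------------------------------------------------------------------------


def test_codon_counts_stop_and_trailing_rules(code5):
    c = codon_counts("TTATTATAA", code5)
    assert c.counts["TTA"] == 2
    assert c.counts.get("TAA", 0) == 1       # tallied but not a sense codon
    assert c.sense_counts(code5)["TTA"] == 2
    assert "TAA" not in c.sense_counts(code5)
    assert c.n_codons_excluded == 0

    c = codon_counts("TTATT", code5)
    assert c.counts["TTA"] == 1 and c.n_codons_excluded == 1

    c = codon_counts("TTNTTA", code5)
    assert c.counts["TTA"] == 1 and c.n_codons_excluded == 1


def test_codon_counts_too_short(code5):
    with pytest.raises(InvalidInputError):
        codon_counts("AT", code5)


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


def test_rscu_formula_limits(code5):
    leu = code5.families["L"]
    only_tta = CodonCounts("x", {"TTA": 9}, 0)
    table = rscu(only_tta, code5).rscu
    assert table["TTA"] == pytest.approx(6.0)
    assert all(table[c] == 0.0 for c in leu if c != "TTA")

    uniform = CodonCounts("x", {c: 5 for c in leu}, 0)
    assert all(rscu(uniform, code5).rscu[c] == pytest.approx(1.0) for c in leu)

    mixed = CodonCounts("x", {"TTA": 3, "TTG": 1, "CTA": 2}, 0)
    assert rscu(mixed, code5).rscu["TTA"] == pytest.approx(3.0)  # 3*6/6


@pytest.mark.parametrize("table_id", [5, 1])
def test_rscu_family_sums_equal_family_size(table_id):
    code = GeneticCode.from_table_id(table_id)
    rng = random.Random(table_id)
    for _ in range(25):
        counts = CodonCounts("r", {c: rng.randrange(0, 40)
                                   for c in code.sense_codons}, 0)
        table = rscu(counts, code).rscu
        assert set(table) == set(code.sense_codons)
        for aa, fam in code.families.items():
            total = sum(counts.counts.get(c, 0) for c in fam)
            s = sum(table[c] for c in fam)
            if total > 0:
                assert s == pytest.approx(len(fam), abs=1e-9)
            else:
                assert all(math.isnan(table[c]) for c in fam)


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------


def test_reference_table_uniform_and_rna_mapping():
    text = "\n".join(f"{c} 1.0" for c in ALL_CODONS)
    ref = read_reference_table(text)
    freqs = ref.frequencies()
    assert all(f == pytest.approx(1 / 64) for f in freqs.values())

    ref = read_reference_table("UUA 12.3 1234\nUUU 5.0 777\n")
    assert ref.raw["TTA"] == 1234.0  # bare count preferred over per-thousand
    assert ref.raw["TTT"] == 777.0
    assert "TTA" not in ref.missing and "GGG" in ref.missing


def test_reference_table_kazusa_quadruplets():
    text = "UUU 17.6(714298)  UCU 15.2(617315)\nUUA  7.7(311881)  UCA 12.2(496448)\n"
    ref = read_reference_table(text)
    assert ref.raw["TTT"] == 714298.0
    assert ref.raw["TCA"] == 496448.0


def test_reference_table_parse_errors():
    with pytest.raises(TableParseError):
        read_reference_table("garbage 123 junk\n")
    with pytest.raises(TableParseError):
        read_reference_table("")


# ---------------------------------------------------------------------------
# CAI weights
# ---------------------------------------------------------------------------


def _ref_from(values: dict[str, float]) -> ReferenceTable:
    return ReferenceTable(raw=values)


def test_cai_weights_definitions(code5):
    phe = code5.families["F"]  # TTT, TTC
    ref = _ref_from({phe[0]: 10.0, phe[1]: 10.0})
    w = cai_weights(_pad(ref, code5), code5).w
    assert w[phe[0]] == 1.0 and w[phe[1]] == 1.0

    ref = _ref_from({phe[0]: 2.0, phe[1]: 8.0})
    w = cai_weights(_pad(ref, code5), code5).w
    assert w[phe[1]] == 1.0 and w[phe[0]] == pytest.approx(0.25)


def test_cai_weights_pseudocount_for_zero_frequency(code5):
    phe = code5.families["F"]
    ref = _pad(_ref_from({phe[0]: 5.0, phe[1]: 0.0}), code5)
    w = cai_weights(ref, code5).w
    assert w[phe[0]] == 1.0
    assert w[phe[1]] == pytest.approx(0.5 / 5.0)


def test_cai_weights_degenerate_family(code5):
    ref = _ref_from({c: 1.0 for c in code5.sense_codons})
    for c in code5.families["F"]:
        ref.raw[c] = 0.0
    with pytest.raises(DegenerateReferenceError):
        cai_weights(ref, code5)


def _pad(ref: ReferenceTable, code) -> ReferenceTable:
    for c in code.sense_codons:
        ref.raw.setdefault(c, 1.0)
    return ref


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------


def _random_weights(code, seed):
    rng = random.Random(seed)
    ref = ReferenceTable(raw={c: rng.uniform(0.5, 50.0)
                              for c in code.sense_codons})
    return cai_weights(ref, code)


def test_cai_is_one_for_maximal_codons(code5):
    weights = _random_weights(code5, 1)
    best = {code5.codon_to_aa[c]: c for c in code5.sense_codons
            if weights.w[c] == 1.0}
    gene = "".join(best[aa] for aa in ("F", "L", "K", "G", "W") for _ in range(4))
    assert cai(gene, weights, code5) == pytest.approx(1.0)


def test_cai_two_codon_geometric_mean(code5):
    phe = code5.families["F"]
    ref = _pad(_ref_from({phe[0]: 2.0, phe[1]: 8.0}), code5)
    weights = cai_weights(ref, code5)
    gene = phe[0] + phe[1]  # w = 0.25 and 1.0
    assert cai(gene, weights, code5) == pytest.approx(0.5)  # sqrt(0.25)


def test_cai_matches_geometric_mean_oracle(code5):
    rng = random.Random(9)
    weights = _random_weights(code5, 2)
    for _ in range(50):
        codons = [rng.choice(code5.sense_codons) for _ in range(100)]
        gene = "".join(codons)
        # independent oracle: product-then-root in linear space
        prod = 1.0
        for c in codons:
            prod *= weights.w[c]
        expected = prod ** (1.0 / len(codons))
        assert cai(gene, weights, code5) == pytest.approx(expected, abs=1e-12)


def test_cai_scale_invariance_for_positive_tables(code5):
    rng = random.Random(3)
    raw = {c: rng.uniform(1.0, 30.0) for c in code5.sense_codons}
    w1 = cai_weights(ReferenceTable(raw=dict(raw)), code5).w
    w2 = cai_weights(ReferenceTable(raw={c: 7.0 * v for c, v in raw.items()}),
                     code5).w
    assert all(w1[c] == pytest.approx(w2[c], abs=1e-12) for c in w1)


def test_cai_invariant_under_codon_permutation(code5):
    rng = random.Random(4)
    weights = _random_weights(code5, 5)
    codons = [rng.choice(code5.sense_codons) for _ in range(60)]
    shuffled = codons[:]
    rng.shuffle(shuffled)
    assert cai("".join(codons), weights, code5) == pytest.approx(
        cai("".join(shuffled), weights, code5), abs=1e-12)


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------


def test_window_equals_gene_for_homogeneous_and_exact_length(code5):
    weights = _random_weights(code5, 6)
    gene = "TTA" * 150  # homogeneous: every window = gene value
    prof = sliding_window_cai(gene, weights, code5)
    assert all(v == pytest.approx(prof.gene_cai) for v in prof.window_cai)

    gene100 = "".join(random.Random(7).choice(code5.sense_codons)
                      for _ in range(100))
    prof = sliding_window_cai(gene100, weights, code5)
    assert len(prof.window_cai) == 1
    assert prof.window_cai[0] == pytest.approx(prof.gene_cai, abs=1e-12)
    assert prof.peak_cai == max(prof.window_cai)


def test_window_peak_localizes_high_adaptiveness_block(code5):
    phe = code5.families["F"]
    ref = _pad(_ref_from({phe[0]: 1.0, phe[1]: 100.0}), code5)
    weights = cai_weights(ref, code5)
    low, high = phe[0], phe[1]
    gene = low * 150 + high * 100 + low * 150
    prof = sliding_window_cai(gene, weights, code5)
    peak_at = prof.window_starts[prof.window_cai.index(prof.peak_cai)]
    assert peak_at == 150
    assert prof.peak_cai == pytest.approx(cai(high * 100, weights, code5))


def test_short_gene_gets_single_whole_gene_window(code5):
    weights = _random_weights(code5, 8)
    gene = "TTATTC" * 5  # 10 codons
    prof = sliding_window_cai(gene, weights, code5)
    assert len(prof.window_cai) == 1
    assert prof.window_cai[0] == pytest.approx(prof.gene_cai, abs=1e-12)


# ---------------------------------------------------------------------------
# Positional GC
# ---------------------------------------------------------------------------


def test_gc_by_position_pure_cases():
    p = gc_by_position("GCGCGC")
    assert (p.gc1, p.gc2, p.gc3) == (1.0, 1.0, 1.0)
    p = gc_by_position("ATATAT")
    assert (p.gc1, p.gc2, p.gc3) == (0.0, 0.0, 0.0)
    assert p.gc12 == 0.0


def test_gc_by_position_enumeration_oracle(code5):
    rng = random.Random(11)
    codons = [rng.choice(code5.sense_codons) for _ in range(10)]
    cds = "".join(codons)
    expect = [sum(1 for c in codons if c[i] in "GC") / len(codons)
              for i in range(3)]
    p = gc_by_position(cds)
    assert (p.gc1, p.gc2, p.gc3) == tuple(pytest.approx(e) for e in expect)
    assert p.gc12 == pytest.approx((p.gc1 + p.gc2) / 2, abs=1e-15)
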