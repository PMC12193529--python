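"""Parsing, nomenclature, extraction and gene-order encoding."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitocomp.genome_io import (
    ANCESTRAL_ORDER,
    ANCESTRAL_SIGNATURE,
    GENE_INDEX,
    PCG_CONCAT_ORDER,
    AmbiguousGeneError,
    AnnotatedMitogenome,
    GeneFeature,
    GeneOrderSignature,
    MissingGeneError,
    ParseError,
    UnknownGeneError,
    canonicalize_gene_name,
    compare_gene_order,
    concatenate_pcgs,
    extract_gene,
    gene_order_signature,
    parse_genbank,
    reverse_complement,
    write_genbank,
)

from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


# ---------------------------------------------------------------------------
# Nomenclature
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("raw,expected", [
    ("COI", "cox1"),
    ("cox1", "cox1"),
    ("COXIII", "cox3"),
    ("ND4L", "nad4l"),
    ("NADH dehydrogenase subunit 5", "nad5"),
    ("cytb", "cob"),
    ("CYTB", "cob"),
    ("16S ribosomal RNA", "rrnL"),
    ("l-rRNA", "rrnL"),
    ("12S rRNA", "rrnS"),
    ("tRNA-Ile", "trnI"),
    ("trnQ", "trnQ"),
    ("tRNA-Ser2", "trnS2"),
    ("trnL1", "trnL1"),
    ("tRNA-Leu(UUR)", "trnL2"),
    ("tRNA-Ser(AGN)", "trnS1"),
    ("D-loop", "CR"),
    ("control region", "CR"),
])
def test_canonicalize_synonym_dialects(raw, expected):
    assert canonicalize_gene_name(raw) == expected


def test_canonicalize_serine_by_anticodon():
    assert canonicalize_gene_name("tRNA-Ser", anticodon="gct") == "trnS1"
    assert canonicalize_gene_name("tRNA-Ser", anticodon="uga") == "trnS2"
    assert canonicalize_gene_name("tRNA-Leu", anticodon="tag") == "trnL1"


def test_canonicalize_rejects_unknown_and_ambiguous():
    with pytest.raises(UnknownGeneError):
        canonicalize_gene_name("hypothetical protein")
    with pytest.raises(UnknownGeneError):
        canonicalize_gene_name("")
    with pytest.raises(AmbiguousGeneError):
        canonicalize_gene_name("tRNA-Ser")


# ---------------------------------------------------------------------------
# GenBank round trip
# ---------------------------------------------------------------------------


def test_generator_roundtrip_preserves_everything(sim_genome, sim_genbank_text):
    genome, _ = sim_genome
    parsed = parse_genbank(sim_genbank_text)
    assert parsed.sequence == genome.sequence
    assert parsed.is_circular
    original = {f.canonical_name: (f.start, f.end, f.strand)
                for f in genome.features}
    roundtrip = {f.canonical_name: (f.start, f.end, f.strand)
                 for f in parsed.features}
    assert roundtrip == original
    assert len(parsed.features) == 38  # 37 genes + CR
    # a second serialize/parse cycle is bit-stable on the data
    again = parse_genbank(write_genbank(parsed))
    assert again.sequence == parsed.sequence


def test_parse_reads_minus_strand_from_complement(sim_genbank_text):
    parsed = parse_genbank(sim_genbank_text)
    assert parsed.feature("trnQ").strand == -1
    assert parsed.feature("cox1").strand == +1


def test_parse_rejects_non_genbank_text():
    with pytest.raises(ParseError):
        parse_genbank(">seq1\nACGT\n")


def test_parse_infers_control_region_from_largest_gap(sim_genome):
    genome, _ = sim_genome
    no_cr = AnnotatedMitogenome(
        genome.identifier, genome.organism, genome.sequence, True,
        [f for f in genome.features if f.canonical_name != "CR"])
    reparsed = parse_genbank(write_genbank(no_cr))
    cr = reparsed.feature("CR")
    truth = genome.feature("CR")
    assert (cr.start, cr.end) == (truth.start, truth.end)


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------


def _tiny_genome(seq, features):
    return AnnotatedMitogenome("TEST1", "test organism", seq, True, features)


def test_extract_plus_strand_verbatim():
    seq = random_dna(60, seed=1)
    g = _tiny_genome(seq, [GeneFeature("trnI", 10, 19, +1, "tRNA")])
    assert extract_gene(g, "trnI") == seq[10:19]


def test_extract_minus_strand_reverse_complements():
    seq = "ATGAAA" + random_dna(30, seed=2)
    g = _tiny_genome(seq, [GeneFeature("trnQ", 0, 6, -1, "tRNA")])
    assert extract_gene(g, "trnQ") == "TTTCAT"


def test_extract_wrapping_feature_spans_origin():
    seq = random_dna(16362, seed=3)
    g = _tiny_genome(seq, [GeneFeature("nad2", 16300, 50, +1, "PCG",
                                       wraps_origin=True)])
    got = extract_gene(g, "nad2")
    assert got == seq[16300:] + seq[:50]
    assert len(got) == (16362 - 16300) + 50


def test_missing_gene_raises():
    g = _tiny_genome("ACGT", [])
    with pytest.raises(MissingGeneError):
        extract_gene(g, "cox1")


@given(dna)
def test_reverse_complement_is_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------


def test_concatenation_matches_truth_and_conserves_length(sim_genome):
    genome, truth = sim_genome
    concat = concatenate_pcgs(genome)
    expected = "".join(truth.gene_sequences[g] for g in PCG_CONCAT_ORDER)
    assert concat == expected
    assert len(concat) == sum(len(truth.gene_sequences[g])
                              for g in PCG_CONCAT_ORDER)


def test_concatenation_ignores_chromosomal_placement(sim_genome):
    genome, _ = sim_genome
    # rotating the genome moves every gene but must not change the concat
    shift = 5000
    seq = genome.sequence
    n = len(seq)
    rotated_feats = []
    for f in genome.features:
        s, e = (f.start + shift) % n, (f.end + shift) % n
        wraps = s > e or (s + f.length(n) > n)
        rotated_feats.append(GeneFeature(f.canonical_name, s,
                                         (s + f.length(n)) % n or n if not wraps else e,
                                         f.strand, f.gene_class, wraps))
    rotated = AnnotatedMitogenome("ROT", genome.organism,
                                  seq[-shift:] + seq[:-shift], True,
                                  rotated_feats)
    assert concatenate_pcgs(rotated) == concatenate_pcgs(genome)


def test_concatenate_names_missing_pcg(sim_genome):
    genome, _ = sim_genome
    partial = AnnotatedMitogenome(
        "PART", genome.organism, genome.sequence, True,
        [f for f in genome.features if f.canonical_name != "nad3"])
    with pytest.raises(MissingGeneError, match="nad3"):
        concatenate_pcgs(partial)


# ---------------------------------------------------------------------------
# Gene order
# ---------------------------------------------------------------------------


def _oracle_breakpoints(sig, ref):
    """Independent adjacency-set oracle: brute-force signed circular pairs."""
    present = {g for g, _ in sig.entries}
    ref_entries = [(g, s) for g, s in ref.entries if g in present]

    def adjacencies(entries):
        out = set()
        for i in range(len(entries)):
            (g1, s1), (g2, s2) = entries[i], entries[(i + 1) % len(entries)]
            out.add(min((s1 * g1, s2 * g2), (-s2 * g2, -s1 * g1)))
        return out

    return len(adjacencies(list(sig.entries)) - adjacencies(ref_entries))


def test_ancestral_signature_is_identity(sim_genome):
    genome, _ = sim_genome
    sig = gene_order_signature(genome)
    assert sig == ANCESTRAL_SIGNATURE
    rep = compare_gene_order(sig, ANCESTRAL_SIGNATURE)
    assert rep.is_identical
    assert rep.breakpoint_count == 0
    assert rep.missing_genes == () and rep.inverted_genes == ()


def test_signature_rotates_to_trnI():
    # same circular order deposited starting elsewhere must normalize
    entries = list(ANCESTRAL_SIGNATURE.entries)
    rotated = GeneOrderSignature(tuple(entries[10:] + entries[:10]))
    assert compare_gene_order(rotated).breakpoint_count == 0


def test_adjacent_swap_gives_three_breakpoints():
    entries = list(ANCESTRAL_SIGNATURE.entries)
    entries[0], entries[1] = entries[1], entries[0]  # trnI <-> trnQ
    sig = GeneOrderSignature(tuple(entries))
    assert sig.entries[0][0] == GENE_INDEX["trnQ"]
    assert sig.entries[1][0] == GENE_INDEX["trnI"]
    rep = compare_gene_order(sig)
    assert rep.breakpoint_count == 3
    assert rep.breakpoint_count == _oracle_breakpoints(sig, ANCESTRAL_SIGNATURE)
    assert not rep.is_identical


def test_single_inversion_flips_orientation_and_breaks_two_adjacencies():
    nad5 = GENE_INDEX["nad5"]
    assert nad5 == 24  # trnI=1, trnQ=2, ... in the ancestral numbering
    entries = [(g, -s if g == nad5 else s) for g, s in ANCESTRAL_SIGNATURE.entries]
    sig = GeneOrderSignature(tuple(entries))
    rep = compare_gene_order(sig)
    assert rep.inverted_genes == ("nad5",)
    assert rep.breakpoint_count == _oracle_breakpoints(sig, ANCESTRAL_SIGNATURE)
    assert rep.breakpoint_count == 2


def test_missing_gene_reported():
    entries = tuple((g, s) for g, s in ANCESTRAL_SIGNATURE.entries
                    if g != GENE_INDEX["trnR"])
    rep = compare_gene_order(GeneOrderSignature(entries))
    assert rep.missing_genes == ("trnR",)
    assert not rep.is_identical


def test_generator_writes_the_inversion_truth(sim_genome):
    # flip nad5 in the generator spec and confirm the signature reports it
    from dataclasses import replace

    from mitocomp.synthetic_data import SyntheticSpec, simulate_mitogenome

    order = tuple((n, -s if n == "nad5" else s) for n, s in ANCESTRAL_ORDER)
    genome, _ = simulate_mitogenome(replace(SyntheticSpec(seed=7),
                                            gene_order=order))
    rep = compare_gene_order(gene_order_signature(genome))
    assert rep.inverted_genes == ("nad5",)
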