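import random

import pytest
from hypothesis import settings

from mitocomp.codon_usage import GeneticCode
from mitocomp.genome_io import PCG_CONCAT_ORDER, write_fasta, write_genbank
from mitocomp.synthetic_data import (
    SyntheticSpec,
    make_reference_table,
    simulate_mitogenome,
    simulate_study_set,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def code5() -> GeneticCode:
    return GeneticCode.from_table_id(5)


@pytest.fixture(scope="session")
def code1() -> GeneticCode:
    return GeneticCode.from_table_id(1)


@pytest.fixture(scope="session")
def sim_genome():
    """One simulated mitogenome in the ancestral order, with its truth."""
    return simulate_mitogenome(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def sim_genbank_text(sim_genome) -> str:
    return write_genbank(sim_genome[0])


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A 5-genome study directory with taxonomy, reference table and CDS set."""
    root = tmp_path_factory.mktemp("study")
    gdir = root / "genomes"
    gdir.mkdir()
    code = GeneticCode.from_table_id(5)
    sets = simulate_study_set(5, base_seed=100)
    for g, _ in sets:
        (gdir / f"{g.identifier}.gb").write_text(write_genbank(g))
    ref_genome, ref_truth = simulate_mitogenome(SyntheticSpec(seed=999))
    (root / "reference_cds.fasta").write_text(write_fasta(
        {gene: ref_truth.gene_sequences[gene] for gene in PCG_CONCAT_ORDER}))
    ref_text, _ = make_reference_table(2.0, code, seed=7)
    (root / "reference_table.txt").write_text(ref_text)
    lines = ["genome_id\tsubfamily\ttribe"]
    for i, (g, _) in enumerate(sets):
        lines.append(f"{g.identifier}\tSub{i % 2}\tTribe{i % 2}")
    (root / "taxonomy.tsv").write_text("\n".join(lines) + "\n")
    return root


def random_dna(n: int, seed: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))
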