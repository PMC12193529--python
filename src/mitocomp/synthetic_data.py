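"""Synthetic annotated mitogenomes with known ground truth.

The generator emits circular ~15-17 kb genomes carrying the full insect
complement -- 13 PCGs, 22 tRNAs, 2 rRNAs and a control region -- in a
configurable gene order (ancestral by default), with configurable
whole-genome AT%, AT/GC skew, and a controllable codon-usage bias toward
A/T-ending codons.  Everything an analysis stage measures (composition,
order, per-gene sequences, divergence counts) is recorded in a truth object,
so each stage can be verified without downloading real records.

Composition control.  Each genomic region is sampled from per-position base
distributions whose mixture equals the target composition, so the genome
hits AT% and both skews in expectation:

* PCGs are generated codon-by-codon from a distribution over the sense
  codons of the configured code fitted by iterative proportional fitting
  (IPF) to per-position marginals.  The codon bias moves A/T mass from
  positions 1-2 to position 3 while preserving the per-gene AT% target,
  mimicking the third-position A/T preference of insect mitogenomes.
* Genes annotated on the minus strand are sampled from complemented
  marginals so the deposited (forward) strand matches the targets.
* tRNAs, rRNAs and the control region are i.i.d. base draws from the target
  distribution.

The only deterministic departures from the targets are each PCG's fixed
start (ATG) and stop (TAA) codons -- 78 nt in a ~16 kb genome.

Randomness is controlled by a single seed, split per gene with a
counter-based scheme (seed, gene index), so adding or resizing one gene
never perturbs the sequence of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .codon_usage import GeneticCode
from .genome_io import (
    ANCESTRAL_ORDER,
    GENE_INDEX,
    AnnotatedMitogenome,
    GeneFeature,
    GeneOrderSignature,
    INDEX_GENE,
    MitocompError,
    gene_class,
    reverse_complement,
)

_BASES = ("A", "C", "G", "T")


class InfeasibleSpecError(MitocompError):
    """The requested composition targets cannot be realized."""


# Drosophila-like default gene lengths (nt); PCG lengths are multiples of 3
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "cox1": 1536, "cox2": 687, "cox3": 786, "cob": 1137,
    "nad1": 939, "nad2": 1023, "nad3": 354, "nad4": 1338,
    "nad4l": 288, "nad5": 1719, "nad6": 522, "atp6": 678, "atp8": 159,
    "rrnL": 1326, "rrnS": 789,
    "trnI": 65, "trnQ": 69, "trnM": 68, "trnW": 67, "trnC": 65,
    "trnY": 66, "trnL2": 66, "trnK": 70, "trnD": 67, "trnG": 65,
    "trnA": 67, "trnR": 65, "trnN": 66, "trnS1": 67, "trnE": 66,
    "trnF": 65, "trnH": 66, "trnT": 65, "trnP": 66, "trnS2": 68,
    "trnL1": 65, "trnV": 72,
}

#: ceiling on the third-position A/T fraction under maximal bias
_AT3_CEILING = 0.97


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one simulated mitogenome.

    Defaults emulate a typical tephritid fly mitogenome: ~15.9 kb, 74% AT,
    adenine-biased AT skew (+0.066) and cytosine-biased GC skew (-0.2265) on
    the deposited strand, with a moderate third-position A/T codon bias.
    """

    seed: int = 0
    genome_length_target: int = 15900
    at_percent_target: float = 74.0
    at_skew_target: float = 0.066
    gc_skew_target: float = -0.2265
    gene_order: tuple[tuple[str, int], ...] = ANCESTRAL_ORDER
    gene_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    codon_bias_strength: float = 1.0
    omega_target: float = 0.2
    divergence: float = 0.3
    table_id: int = 5

    def with_order(self, signature: GeneOrderSignature) -> "SyntheticSpec":
        order = tuple((INDEX_GENE[g], s) for g, s in signature.entries)
        return replace(self, gene_order=tuple(
            (INDEX_GENE[g] if isinstance(g, int) else g, s)
            for g, s in signature.entries))

    def validate(self) -> None:
        if not (0.0 < self.at_percent_target < 100.0):
            raise InfeasibleSpecError(
                f"AT% target must lie in (0, 100): {self.at_percent_target}")
        for name, s in (("AT", self.at_skew_target), ("GC", self.gc_skew_target)):
            if not (-1.0 < s < 1.0):
                raise InfeasibleSpecError(f"|{name} skew| must be < 1: {s}")
        for g, ln in self.gene_lengths.items():
            if gene_class(g) == "PCG" and ln % 3:
                raise InfeasibleSpecError(f"PCG {g} length {ln} not a multiple of 3")
            if ln < 3:
                raise InfeasibleSpecError(f"gene {g} length {ln} too short")
        if self.codon_bias_strength < 0:
            raise InfeasibleSpecError("codon bias strength must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth stored alongside a simulated genome."""

    spec: SyntheticSpec
    gene_sequences: dict[str, str]          # coding-sense sequences
    order: tuple[tuple[str, int], ...]
    base_counts: dict[str, int]
    at_percent: float
    at_skew: float
    gc_skew: float


# ---------------------------------------------------------------------------
# Base and codon distributions
# ---------------------------------------------------------------------------


def base_probabilities(at_fraction: float, at_skew: float,
                       gc_skew: float) -> dict[str, float]:
    """Per-base probabilities realizing an AT fraction and both skews."""
    gc = 1.0 - at_fraction
    p = {
        "A": at_fraction * (1.0 + at_skew) / 2.0,
        "T": at_fraction * (1.0 - at_skew) / 2.0,
        "G": gc * (1.0 + gc_skew) / 2.0,
        "C": gc * (1.0 - gc_skew) / 2.0,
    }
    if min(p.values()) < 0:
        raise InfeasibleSpecError(f"negative base probability from targets: {p}")
    return p


def _complement_probs(p: dict[str, float]) -> dict[str, float]:
    return {"A": p["T"], "T": p["A"], "G": p["C"], "C": p["G"]}


def pcg_position_marginals(spec: SyntheticSpec, strand: int
                           ) -> list[dict[str, float]]:
    """Per-codon-position base distributions for PCG sampling.

    The codon bias lifts the third-position A/T fraction toward the ceiling
    as 1 - exp(-bias); positions 1-2 compensate so the per-gene AT% equals
    the genome target.  Minus-strand marginals are complemented so the
    deposited strand keeps the genome-level targets.
    """
    at = spec.at_percent_target / 100.0
    boost = 1.0 - math.exp(-spec.codon_bias_strength)
    at3 = at + (_AT3_CEILING - at) * boost if _AT3_CEILING > at else at
    at12 = (3.0 * at - at3) / 2.0
    if at12 <= 0.01:
        raise InfeasibleSpecError(
            f"codon bias {spec.codon_bias_strength} incompatible with "
            f"AT% {spec.at_percent_target}")
    p12 = base_probabilities(at12, spec.at_skew_target, spec.gc_skew_target)
    p3 = base_probabilities(at3, spec.at_skew_target, spec.gc_skew_target)
    marginals = [p12, dict(p12), p3]
    if strand == -1:
        marginals = [_complement_probs(m) for m in marginals]
    return marginals


def fit_codon_distribution(marginals: list[dict[str, float]],
                           code: GeneticCode,
                           max_iter: int = 500,
                           tol: float = 1e-10) -> dict[str, float]:
    """IPF a sense-codon distribution to per-position base marginals.

    Starts from the independent product restricted to sense codons and
    cycles position-wise rescaling until every marginal matches within
    ``tol``.  Stops are excluded from the support, which is what makes the
    fit necessary at all.
    """
    codons = sorted(code.sense_codons)
    q = np.array([marginals[0][c[0]] * marginals[1][c[1]] * marginals[2][c[2]]
                  for c in codons], dtype=float)
    if q.sum() <= 0:
        raise InfeasibleSpecError("marginals put no mass on sense codons")
    q /= q.sum()
    pos_idx = [
        {b: np.array([j for j, c in enumerate(codons) if c[i] == b])
         for b in _BASES}
        for i in range(3)
    ]
    for _ in range(max_iter):
        err = 0.0
        for i in range(3):
            for b in _BASES:
                idx = pos_idx[i][b]
                cur = q[idx].sum()
                want = marginals[i][b]
                err = max(err, abs(cur - want))
                if cur > 0 and want > 0:
                    q[idx] *= want / cur
                elif cur > 0:
                    q[idx] = 0.0
            q /= q.sum()
        if err < tol:
            return dict(zip(codons, q))
    raise InfeasibleSpecError(
        f"codon marginals infeasible under table {code.table_id} "
        f"(IPF residual {err:.2e})")


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


def _gene_rng(spec: SyntheticSpec, counter: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, counter])


def _sample_bases(rng: np.random.Generator, probs: dict[str, float],
                  n: int) -> str:
    p = np.array([probs[b] for b in _BASES])
    p /= p.sum()
    return "".join(np.array(_BASES)[rng.choice(4, size=n, p=p)])


def _sample_pcg(rng: np.random.Generator, dist: dict[str, float],
                n_codons: int) -> str:
    codons = sorted(dist)
    p = np.array([dist[c] for c in codons])
    p /= p.sum()
    body = rng.choice(len(codons), size=n_codons - 2, p=p)
    return "ATG" + "".join(codons[i] for i in body) + "TAA"


def simulate_mitogenome(spec: SyntheticSpec
                        ) -> tuple[AnnotatedMitogenome, TruthRecord]:
    """Emit one annotated circular mitogenome plus its ground truth."""
    spec.validate()
    code = GeneticCode.from_table_id(spec.table_id)
    whole_probs = base_probabilities(spec.at_percent_target / 100.0,
                                     spec.at_skew_target, spec.gc_skew_target)
    dist_plus = fit_codon_distribution(pcg_position_marginals(spec, +1), code)
    dist_minus = fit_codon_distribution(pcg_position_marginals(spec, -1), code)

    gene_sequences: dict[str, str] = {}
    forward_parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for name, strand in spec.gene_order:
        length = spec.gene_lengths[name]
        cls = gene_class(name)
        rng = _gene_rng(spec, GENE_INDEX[name])
        if cls == "PCG":
            dist = dist_plus if strand == +1 else dist_minus
            coding = _sample_pcg(rng, dist, length // 3)
            locus = coding if strand == +1 else reverse_complement(coding)
        else:
            probs = whole_probs
            locus = _sample_bases(rng, probs, length)
            coding = locus if strand == +1 else reverse_complement(locus)
        gene_sequences[name] = coding
        forward_parts.append(locus)
        features.append(GeneFeature(name, pos, pos + length, strand, cls))
        pos += length

    cr_length = spec.genome_length_target - pos
    if cr_length < 100:
        raise InfeasibleSpecError(
            f"genome length target {spec.genome_length_target} leaves "
            f"{cr_length} nt for the control region (need >= 100)")
    rng = _gene_rng(spec, 38)  # CR counter follows the 37 genes
    cr_seq = _sample_bases(rng, whole_probs, cr_length)
    forward_parts.append(cr_seq)
    features.append(GeneFeature("CR", pos, pos + cr_length, +1, "CR"))
    gene_sequences["CR"] = cr_seq

    sequence = "".join(forward_parts)
    genome = AnnotatedMitogenome(
        identifier=f"SYN{spec.seed % 10**7:07d}",
        organism="Synthetica exempli (simulated tephritid-like mitogenome)",
        sequence=sequence, is_circular=True, features=features)

    counts = {b: sequence.count(b) for b in _BASES}
    at = counts["A"] + counts["T"]
    gc = counts["G"] + counts["C"]
    truth = TruthRecord(
        spec=spec, gene_sequences=gene_sequences, order=tuple(spec.gene_order),
        base_counts=counts,
        at_percent=100.0 * at / (at + gc),
        at_skew=(counts["A"] - counts["T"]) / at,
        gc_skew=(counts["G"] - counts["C"]) / gc)
    return genome, truth


def simulate_study_set(n: int, base_seed: int = 0,
                       spec: SyntheticSpec | None = None,
                       **overrides) -> list[tuple[AnnotatedMitogenome, TruthRecord]]:
    """n independent genomes with consecutive seeds from one base spec."""
    template = spec or SyntheticSpec()
    out = []
    for k in range(n):
        s = replace(template, seed=base_seed + k, **overrides)
        out.append(simulate_mitogenome(s))
    return out


# ---------------------------------------------------------------------------
# Divergence simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivergenceTruth:
    synonymous: int
    nonsynonymous: int

    @property
    def total(self) -> int:
        return self.synonymous + self.nonsynonymous


def simulate_divergence(cds: str, omega_target: float, divergence: float,
                        code: GeneticCode, seed: int
                        ) -> tuple[str, DivergenceTruth]:
    """Mutate a CDS to a target divergence with a controlled Ka/Ks.

    Single-nucleotide substitutions are proposed uniformly; a proposal is
    accepted with probability min(1, omega) when nonsynonymous and
    min(1, 1/omega) when synonymous (both 1 at omega = 1), and proposals
    creating stop codons are always rejected.  This differential acceptance
    tilts the realized Nd/Sd toward the target rate ratio on either side of
    neutrality.  The number of accepted substitutions is Poisson with mean
    ``divergence`` per codon.  Realized synonymous/nonsynonymous counts are
    returned as truth.
    """
    if omega_target < 0 or divergence < 0:
        raise InfeasibleSpecError("omega and divergence must be >= 0")
    seq = list(cds.upper().replace("U", "T"))
    n = len(seq) - len(seq) % 3
    n_codons = n // 3
    if n_codons == 0:
        raise InfeasibleSpecError("CDS shorter than one codon")
    rng = np.random.default_rng([seed, 7919])
    target = int(rng.poisson(divergence * n_codons))
    p_nonsyn = min(1.0, omega_target)
    p_syn = min(1.0, 1.0 / omega_target) if omega_target > 0 else 1.0
    syn = nonsyn = 0
    accepted = 0
    guard = 0
    max_proposals = max(10_000, 1000 * target)
    while accepted < target and guard < max_proposals:
        guard += 1
        site = int(rng.integers(0, n))
        codon_i = site // 3
        old_codon = "".join(seq[3 * codon_i:3 * codon_i + 3])
        if old_codon not in code.codon_to_aa:
            continue  # never touch stops or ambiguity
        old_base = seq[site]
        new_base = _BASES[int(rng.integers(0, 4))]
        if new_base == old_base:
            continue
        pos = site % 3
        new_codon = old_codon[:pos] + new_base + old_codon[pos + 1:]
        if code.is_stop(new_codon):
            continue
        is_syn = code.codon_to_aa[new_codon] == code.codon_to_aa[old_codon]
        p_accept = p_syn if is_syn else p_nonsyn
        if rng.random() >= p_accept:
            continue
        seq[site] = new_base
        accepted += 1
        if is_syn:
            syn += 1
        else:
            nonsyn += 1
    return "".join(seq), DivergenceTruth(synonymous=syn, nonsynonymous=nonsyn)


# ---------------------------------------------------------------------------
# Reference codon-usage tables
# ---------------------------------------------------------------------------

_FAMILY_COUNT_SCALE = 1_000_000  # large counts keep serialization rounding tiny


def make_reference_table(bias: float, code: GeneticCode, seed: int
                         ) -> tuple[str, dict[str, float]]:
    """Kazusa-format reference table with A/T-third-position preference.

    Within each synonymous family, frequencies are Dirichlet draws with
    concentration 1 + bias on A/T-ending codons and 1 elsewhere; bias 0
    gives exchangeable (near-uniform in expectation) families.  Returns the
    serialized text plus the exact generating frequency vector (per codon,
    normalized within family).
    """
    if bias < 0:
        raise InfeasibleSpecError("bias must be >= 0")
    rng = np.random.default_rng([seed, 104729])
    counts: dict[str, int] = {}
    freqs: dict[str, float] = {}
    for aa, fam in code.families.items():
        alpha = np.array([1.0 + (bias if c[2] in "AT" else 0.0) for c in fam])
        p = rng.dirichlet(alpha) if len(fam) > 1 else np.array([1.0])
        fam_total = _FAMILY_COUNT_SCALE * len(fam)
        for c, pi in zip(fam, p):
            freqs[c] = float(pi)
            counts[c] = max(1, int(round(pi * fam_total)))
    total = sum(counts.values())
    lines = [f"# synthetic codon usage table (seed={seed}, bias={bias}, "
             f"table={code.table_id})"]
    entries = []
    for codon in sorted(counts):
        per_thousand = 1000.0 * counts[codon] / total
        entries.append(f"{codon.replace('T', 'U')} {per_thousand:5.1f}({counts[codon]:8d})")
    for i in range(0, len(entries), 4):
        lines.append("  ".join(entries[i:i + 4]))
    return "\n".join(lines) + "\n", freqs


# ---------------------------------------------------------------------------
# Fixture export
# ---------------------------------------------------------------------------


def truth_table(truth: TruthRecord):
    """Per-gene truth TSV: gene, strand, length, coding-sense sequence."""
    import pandas as pd

    order = {name: i for i, (name, _) in enumerate(truth.order)}
    strands = dict(truth.order)
    rows = [{
        "gene": name,
        "strand": strands.get(name, +1),
        "length": len(seq),
        "sequence": seq,
    } for name, seq in sorted(truth.gene_sequences.items(),
                              key=lambda kv: order.get(kv[0], 99))]
    return pd.DataFrame(rows, columns=["gene", "strand", "length", "sequence"])
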