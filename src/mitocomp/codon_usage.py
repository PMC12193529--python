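"""Codon counting, RSCU, CAI (with sliding windows) and positional GC.

Relative synonymous codon usage (RSCU) is the observed count of a codon
divided by its expected count under uniform use within its synonymous family:

    RSCU(c) = count(c) * |family(c)| / sum(count over family(c))

The codon adaptation index (CAI, Sharp & Li 1987) is the geometric mean of
relative adaptiveness values w over the codons of a gene, where within each
synonymous family w(c) = f(c)/max f for reference frequencies f.  Genes are
profiled with a sliding window of 100 codons (300 bp) at a 1-codon step to
locate locally well-adapted stretches.

Synonymous family structure is always derived from an NCBI translation
table, never hard-coded; the default is table 5 (invertebrate mitochondrial:
TGA = Trp, ATA = Met, AGA/AGG = Ser; stops TAA/TAG, hence 62 sense codons).
Because family structure differs between table 5 and the standard code, the
table is explicit configuration on every operation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .genome_io import MitocompError

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


class InvalidInputError(MitocompError):
    """CDS shorter than one codon or otherwise unusable."""


class DegenerateReferenceError(MitocompError):
    """A synonymous family is entirely absent from the reference table."""


class TableParseError(MitocompError):
    """A codon-usage reference table could not be parsed."""


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table with synonymous families derived from it."""

    table_id: int
    codon_to_aa: dict[str, str]          # sense codons only
    start_codons: frozenset[str]
    stop_codons: frozenset[str]
    families: dict[str, tuple[str, ...]]  # amino acid -> codons

    @classmethod
    def from_table_id(cls, table_id: int = 5) -> "GeneticCode":
        try:
            t = CodonTable.unambiguous_dna_by_id[table_id]
        except KeyError:
            raise MitocompError(f"unknown NCBI translation table {table_id}") from None
        codon_to_aa = dict(t.forward_table)
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = codon_to_aa.get(codon)
            if aa is not None:
                fams.setdefault(aa, []).append(codon)
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            start_codons=frozenset(t.start_codons),
            stop_codons=frozenset(t.stop_codons),
            families={aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())},
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c in self.codon_to_aa)

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, cds: str) -> str:
        out = []
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            if codon in self.codon_to_aa:
                out.append(self.codon_to_aa[codon])
            elif codon in self.stop_codons:
                out.append("*")
            else:
                out.append("X")
        return "".join(out)


INVERTEBRATE_MITO = 5
STANDARD = 1


def _normalize_cds(cds: str) -> str:
    return cds.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# Codon counting
# ---------------------------------------------------------------------------


@dataclass
class CodonCounts:
    """Codon tallies for one gene or concatenation.

    ``counts`` covers all 64 codons including stops; RSCU and CAI read only
    the sense entries.  ``n_codons_excluded`` counts codons skipped for
    ambiguity plus any trailing incomplete codon (mito mRNAs commonly end in
    an incomplete stop completed by polyadenylation); stops are counted but
    kept out of the sense statistics.
    """

    label: str
    counts: dict[str, int]
    n_codons_excluded: int

    def sense_counts(self, code: GeneticCode) -> dict[str, int]:
        return {c: self.counts.get(c, 0) for c in code.sense_codons}

    def total_sense(self, code: GeneticCode) -> int:
        return sum(self.sense_counts(code).values())

    def add(self, other: "CodonCounts") -> "CodonCounts":
        merged = dict(self.counts)
        for c, n in other.counts.items():
            merged[c] = merged.get(c, 0) + n
        return CodonCounts(self.label, merged,
                           self.n_codons_excluded + other.n_codons_excluded)


def codon_counts(cds: str, code: GeneticCode, label: str = "") -> CodonCounts:
    """Count codons in frame 0; ambiguous and trailing-partial codons excluded."""
    cds = _normalize_cds(cds)
    if len(cds) < 3:
        raise InvalidInputError(f"CDS shorter than one codon: {len(cds)} nt")
    counts: dict[str, int] = {}
    excluded = 0
    n_full = len(cds) // 3
    if len(cds) % 3:
        excluded += 1  # trailing 1-2 nt
    for i in range(n_full):
        codon = cds[3 * i:3 * i + 3]
        if any(b not in "ACGT" for b in codon):
            excluded += 1
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(label=label, counts=counts, n_codons_excluded=excluded)


def codon_list(cds: str, code: GeneticCode) -> list[str]:
    """Countable sense codons of a CDS in gene order (stops/ambiguity dropped)."""
    cds = _normalize_cds(cds)
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if codon in code.codon_to_aa:
            out.append(codon)
    return out


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


@dataclass
class RSCUTable:
    label: str
    rscu: dict[str, float]  # sense codon -> value; NaN when family unused


def rscu(counts: CodonCounts, code: GeneticCode) -> RSCUTable:
    """RSCU(c) = count(c) * family size / family total; NaN for unused families."""
    values: dict[str, float] = {}
    sense = counts.sense_counts(code)
    for aa, fam in code.families.items():
        total = sum(sense[c] for c in fam)
        for c in fam:
            values[c] = math.nan if total == 0 else sense[c] * len(fam) / total
    return RSCUTable(label=counts.label, rscu=values)


def rscu_matrix(tables: list[RSCUTable], code: GeneticCode):
    """Codon-by-label RSCU matrix, rows grouped by encoded amino acid."""
    import pandas as pd

    rows = []
    for aa, fam in code.families.items():
        for codon in fam:
            row = {"amino_acid": aa, "codon": codon}
            for t in tables:
                row[t.label] = t.rscu.get(codon, math.nan)
            rows.append(row)
    return pd.DataFrame(rows).set_index(["amino_acid", "codon"])


# ---------------------------------------------------------------------------
# Reference codon-usage tables and CAI weights
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Per-codon usage from a Kazusa-style table, on its original scale."""

    raw: dict[str, float]          # codon -> count (or per-thousand frequency)
    missing: tuple[str, ...] = ()  # codons absent from the input, filled as 0
    provenance: str = ""

    def frequencies(self) -> dict[str, float]:
        total = sum(self.raw.values())
        if total <= 0:
            raise DegenerateReferenceError("reference table sums to zero")
        return {c: v / total for c, v in self.raw.items()}


_TABLE_ENTRY = re.compile(
    r"\b([ACGTUacgtu]{3})\b[\s:]+([0-9]+(?:\.[0-9]+)?)"
    r"(?:\s*\(\s*([0-9]+)\s*\)"                      # Kazusa "(count)" style
    r"|[ \t]+([0-9]+)(?=[ \t]+[ACGTUacgtu]{3}\b|[ \t]*$))?")  # bare triple


def read_reference_table(text: str, provenance: str = "") -> ReferenceTable:
    """Parse a Kazusa-format codon table or a two-column codon/count TSV.

    Accepts ``UUU 17.6(714298)`` quadruplet layouts and plain
    ``TTT<TAB>714298`` lines; RNA codons are stored under their DNA key.
    When a parenthesized raw count is present it is preferred over the
    per-thousand frequency.
    """
    raw: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        matches = list(_TABLE_ENTRY.finditer(stripped))
        if not matches:
            if any(ch.isdigit() for ch in stripped):
                raise TableParseError(
                    f"line {lineno}: unparseable table line: {stripped!r}")
            continue  # header text without numbers
        for m in matches:
            codon = m.group(1).upper().replace("U", "T")
            count = m.group(3) or m.group(4)
            value = float(count) if count is not None else float(m.group(2))
            if codon in raw:
                raise TableParseError(
                    f"line {lineno}: codon {codon} listed twice")
            raw[codon] = value
    if not raw:
        raise TableParseError("no codon entries found")
    missing = tuple(c for c in ALL_CODONS if c not in raw)
    for c in missing:
        raw[c] = 0.0
    return ReferenceTable(raw=raw, missing=missing, provenance=provenance)


@dataclass
class CAIWeights:
    """Relative adaptiveness w in (0, 1]; max within each family is 1."""

    w: dict[str, float]
    provenance: str = ""


#: pseudocount substituted for zero-frequency reference codons before
#: normalization (standard Sharp-Li practice; keeps every w > 0)
ZERO_FREQUENCY_PSEUDOCOUNT = 0.5


def cai_weights(reference: ReferenceTable, code: GeneticCode,
                pseudocount: float = ZERO_FREQUENCY_PSEUDOCOUNT) -> CAIWeights:
    """w(c) = f(c)/max f within each synonymous family of the code."""
    w: dict[str, float] = {}
    for aa, fam in code.families.items():
        vals = {c: reference.raw.get(c, 0.0) for c in fam}
        fam_max = max(vals.values())
        if fam_max <= 0:
            raise DegenerateReferenceError(
                f"family {aa} ({', '.join(fam)}) absent from reference table")
        for c, v in vals.items():
            adj = v if v > 0 else pseudocount
            w[c] = min(adj / fam_max, 1.0)
    return CAIWeights(w=w, provenance=reference.provenance)


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------


def _countable(codons: list[str], code: GeneticCode) -> list[str]:
    # codons of single-codon families carry no usage information and are
    # excluded from the geometric mean (none exist under table 5)
    return [c for c in codons if len(code.family_of(c)) > 1]


def cai(cds: str, weights: CAIWeights, code: GeneticCode) -> float:
    """Geometric mean of w over counted sense codons; NaN when none count."""
    codons = _countable(codon_list(cds, code), code)
    if not codons:
        return math.nan
    log_sum = sum(math.log(weights.w[c]) for c in codons)
    return math.exp(log_sum / len(codons))


@dataclass
class CAIProfile:
    genome_id: str
    gene: str
    window_starts: list[int] = field(default_factory=list)  # codon index
    window_cai: list[float] = field(default_factory=list)
    gene_cai: float = math.nan
    peak_cai: float = math.nan


def sliding_window_cai(cds: str, weights: CAIWeights, code: GeneticCode,
                       window_codons: int = 100, step_codons: int = 1,
                       genome_id: str = "", gene: str = "") -> CAIProfile:
    """Windowed CAI trajectory along a gene (default 100 codons, step 1).

    Genes shorter than the window yield a single whole-gene window.  The
    window statistic is the geometric mean of w over the countable codons
    inside the window, computed in the log domain via a prefix sum.
    """
    codons = _countable(codon_list(cds, code), code)
    profile = CAIProfile(genome_id=genome_id, gene=gene)
    if not codons:
        return profile
    logs = [math.log(weights.w[c]) for c in codons]
    prefix = [0.0]
    for v in logs:
        prefix.append(prefix[-1] + v)
    n = len(codons)
    w = min(window_codons, n)
    starts = list(range(0, n - w + 1, step_codons))
    for s in starts:
        profile.window_starts.append(s)
        profile.window_cai.append(math.exp((prefix[s + w] - prefix[s]) / w))
    profile.gene_cai = math.exp(prefix[n] / n)
    profile.peak_cai = max(profile.window_cai)
    return profile


# ---------------------------------------------------------------------------
# GC by codon position
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PositionalGC:
    gc1: float
    gc2: float
    gc3: float

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


def gc_by_position(cds: str, code: GeneticCode | None = None) -> PositionalGC:
    """Per-codon-position G+C fraction over complete unambiguous codons.

    The terminal stop codon (when the code is given) is excluded, matching
    the sense-codon scope of the usage statistics.
    """
    cds = _normalize_cds(cds)
    codons = [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    codons = [c for c in codons if all(b in "ACGT" for b in c)]
    if code is not None and codons and code.is_stop(codons[-1]):
        codons = codons[:-1]
    if not codons:
        raise InvalidInputError("no complete unambiguous codons")
    gc = [0, 0, 0]
    for codon in codons:
        for i, b in enumerate(codon):
            if b in "GC":
                gc[i] += 1
    n = len(codons)
    return PositionalGC(gc[0] / n, gc[1] / n, gc[2] / n)
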