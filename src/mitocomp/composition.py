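"""Nucleotide composition and strand-asymmetry (AT/GC skew) statistics.

Metazoan mitochondrial strands are compositionally asymmetric; the skew
statistics

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

quantify that asymmetry on the deposited (heavy) strand.  Skews are computed
at four levels: the whole genome, the 13 concatenated PCGs, the concatenated
rRNAs/tRNAs, and individual genes.  IUPAC ambiguity letters are tallied as
"other" and excluded from every ratio, which keeps skews within [-1, 1] and
reproducible across records with different ambiguity burdens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _stats

from .genome_io import (
    PCG_CONCAT_ORDER,
    RRNA_CONCAT_ORDER,
    TRNA_CONCAT_ORDER,
    AnnotatedMitogenome,
    MitocompError,
    concatenate_genes,
    extract_gene,
)


class InvalidSequenceError(MitocompError):
    """The sequence contains a non-IUPAC character."""


class UndefinedCorrelationError(MitocompError):
    """Pearson correlation is undefined (zero variance or n < 2)."""


_IUPAC = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class BaseCounts:
    a: int
    t: int
    g: int
    c: int
    other: int

    @property
    def unambiguous(self) -> int:
        return self.a + self.t + self.g + self.c

    @property
    def total(self) -> int:
        return self.unambiguous + self.other


@dataclass(frozen=True)
class SkewRecord:
    """Composition and skew of one sequence at one analysis level."""

    genome_id: str
    dataset_label: str
    a: int
    t: int
    g: int
    c: int
    other: int
    at_percent: float
    at_skew: float  # NaN when A + T == 0
    gc_skew: float  # NaN when G + C == 0


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float


def base_counts(seq: str) -> BaseCounts:
    """Case-insensitive A/T/G/C counts; ambiguity letters tallied as other."""
    if not seq:
        raise InvalidSequenceError("empty sequence")
    s = seq.upper()
    bad = set(s) - _IUPAC
    if bad:
        raise InvalidSequenceError(
            f"non-IUPAC character(s): {', '.join(sorted(bad))}")
    a, t, g, c = s.count("A"), s.count("T"), s.count("G"), s.count("C")
    return BaseCounts(a, t, g, c, len(s) - a - t - g - c)


def at_skew(seq: str) -> float:
    """(A - T)/(A + T); NaN when the denominator is zero."""
    b = base_counts(seq)
    if b.a + b.t == 0:
        return math.nan
    return (b.a - b.t) / (b.a + b.t)


def gc_skew(seq: str) -> float:
    """(G - C)/(G + C); NaN when the denominator is zero."""
    b = base_counts(seq)
    if b.g + b.c == 0:
        return math.nan
    return (b.g - b.c) / (b.g + b.c)


def at_percent(seq: str) -> float:
    """A+T as a percentage of unambiguous bases."""
    b = base_counts(seq)
    if b.unambiguous == 0:
        return math.nan
    return 100.0 * (b.a + b.t) / b.unambiguous


def skew_record(genome_id: str, label: str, seq: str) -> SkewRecord:
    b = base_counts(seq)
    at = math.nan if b.a + b.t == 0 else (b.a - b.t) / (b.a + b.t)
    gc = math.nan if b.g + b.c == 0 else (b.g - b.c) / (b.g + b.c)
    pct = math.nan if b.unambiguous == 0 else 100.0 * (b.a + b.t) / b.unambiguous
    return SkewRecord(genome_id, label, b.a, b.t, b.g, b.c, b.other,
                      pct, at, gc)


#: analysis levels mirroring the four data sets of the study design
SKEW_LEVELS = ("whole_genome", "pcg_concat", "rrna_concat", "trna_concat",
               "per_pcg", "per_trna")


def skew_table(genomes: list[AnnotatedMitogenome],
               level: str) -> list[SkewRecord]:
    """One SkewRecord per genome (concatenated levels) or per genome x gene.

    Concatenations use the fixed plus/plus gene orders; individual genes are
    measured on their coding-sense (oriented) sequences.
    """
    if level not in SKEW_LEVELS:
        raise MitocompError(f"unknown skew level {level!r}; "
                            f"choose from {SKEW_LEVELS}")
    records: list[SkewRecord] = []
    for g in genomes:
        if level == "whole_genome":
            records.append(skew_record(g.identifier, "whole_genome", g.sequence))
        elif level == "pcg_concat":
            seq = concatenate_genes(g, _require(g, PCG_CONCAT_ORDER))
            records.append(skew_record(g.identifier, "pcg_concat", seq))
        elif level == "rrna_concat":
            seq = concatenate_genes(g, _require(g, RRNA_CONCAT_ORDER))
            records.append(skew_record(g.identifier, "rrna_concat", seq))
        elif level == "trna_concat":
            seq = concatenate_genes(g, _require(g, TRNA_CONCAT_ORDER))
            records.append(skew_record(g.identifier, "trna_concat", seq))
        elif level == "per_pcg":
            for name in _require(g, PCG_CONCAT_ORDER):
                records.append(skew_record(g.identifier, f"pcg:{name}",
                                           extract_gene(g, name)))
        elif level == "per_trna":
            for name in _require(g, TRNA_CONCAT_ORDER):
                records.append(skew_record(g.identifier, f"trna:{name}",
                                           extract_gene(g, name)))
    return records


def _require(genome: AnnotatedMitogenome, order: tuple[str, ...]) -> tuple[str, ...]:
    from .genome_io import MissingGeneError

    missing = [n for n in order if not genome.has(n)]
    if missing:
        raise MissingGeneError(
            f"{genome.identifier}: missing gene(s) for skew level: "
            f"{', '.join(missing)}")
    return order


def pearson(xs, ys) -> CorrelationResult:
    """Product-moment correlation of two equal-length samples."""
    xs = list(xs)
    ys = list(ys)
    if len(xs) != len(ys):
        raise UndefinedCorrelationError("samples differ in length")
    if len(xs) < 2:
        raise UndefinedCorrelationError("need at least 2 points")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise UndefinedCorrelationError("zero variance in one sample")
    r = float(_stats.pearsonr(xs, ys).statistic)
    return CorrelationResult(n=len(xs), r=r)


def skew_dataframe(records: list[SkewRecord]):
    import pandas as pd

    return pd.DataFrame(
        [{
            "genome_id": r.genome_id, "dataset_label": r.dataset_label,
            "A": r.a, "T": r.t, "G": r.g, "C": r.c, "other": r.other,
            "at_percent": r.at_percent, "at_skew": r.at_skew,
            "gc_skew": r.gc_skew,
        } for r in records],
        columns=["genome_id", "dataset_label", "A", "T", "G", "C", "other",
                 "at_percent", "at_skew", "gc_skew"])
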