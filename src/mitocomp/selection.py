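"""Pairwise Ka/Ks by Nei-Gojobori (1986) counting and neutrality-plot fits.

The NG86 method counts, for every codon, the fraction of single-nucleotide
mutations at each position that are synonymous (mutations creating stop
codons are excluded from the denominator), giving fractional synonymous (S)
and nonsynonymous (N) site totals with S + N = 3 per codon.  Observed
differences between a codon pair are apportioned by averaging, with equal
weight, over all minimal mutational pathways between the two codons that do
not pass through a stop codon.  Proportions pS = Sd/S and pN = Nd/N are
corrected for multiple hits with the Jukes-Cantor formula
d = -3/4 ln(1 - 4p/3), and the ratio omega = Ka/Ks summarizes selection:
< 1 purifying, ~1 neutral, > 1 positive.

The neutrality plot regresses GC content at codon positions 1+2 (GC12) on
position 3 (GC3) across species.  A slope near 1 means directional mutation
pressure moves all positions together; a slope near 0 means selection holds
the amino-acid-changing positions in place.  The slope is read as the
mutational-pressure fraction and its complement as the selection fraction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats as _stats

from .codon_usage import GeneticCode, PositionalGC, _normalize_cds
from .genome_io import MitocompError


class InvalidCodonError(MitocompError):
    """Site counting was asked for a stop or ambiguous codon."""


class AlignmentError(MitocompError):
    """Sequences are not codon-aligned / length-compatible."""


class NoDataError(MitocompError):
    """No comparable codon columns remain after alignment and cleaning."""


class SaturationError(MitocompError):
    """A difference proportion reached the Jukes-Cantor pole (p >= 3/4)."""


class UndefinedFitError(MitocompError):
    """The neutrality regression is undefined (n < 3 or zero GC3 variance)."""


_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Site counting
# ---------------------------------------------------------------------------


def ng86_site_counts(codon: str, code: GeneticCode, exact: bool = False
                     ) -> tuple[float, float] | tuple[Fraction, Fraction]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    At each of the three positions the synonymous fraction is
    s_i / (3 - stops_i): the share of single-nucleotide mutations that
    preserve the amino acid, with mutations to stop codons excluded from the
    denominator.  Each position contributes exactly one site, so the two
    counts always sum to 3.  With ``exact`` the result is returned as exact
    rationals.
    """
    codon = _normalize_cds(codon)
    if codon not in code.codon_to_aa:
        raise InvalidCodonError(f"not a sense codon of table "
                                f"{code.table_id}: {codon!r}")
    aa = code.codon_to_aa[codon]
    syn = Fraction(0)
    for i in range(3):
        n_syn = 0
        n_valid = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1:]
            if code.is_stop(mutant):
                continue
            n_valid += 1
            if code.codon_to_aa[mutant] == aa:
                n_syn += 1
        if n_valid:
            syn += Fraction(n_syn, n_valid)
    nonsyn = 3 - syn
    if exact:
        return syn, nonsyn
    return float(syn), float(nonsyn)


# ---------------------------------------------------------------------------
# Pathway counting between two codons
# ---------------------------------------------------------------------------


def ng86_pathway_counts(c1: str, c2: str, code: GeneticCode
                        ) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) differences between two codons.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are skipped, and each step of the surviving
    pathways is classified by whether it preserves the amino acid.  If every
    pathway is blocked by a stop (possible only for 3-fold differences), all
    pathways are used with stop intermediates scored as nonsynonymous steps.
    """
    c1, c2 = _normalize_cds(c1), _normalize_cds(c2)
    for c in (c1, c2):
        if c not in code.codon_to_aa:
            raise InvalidCodonError(f"not a sense codon: {c!r}")
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(skip_stops: bool):
        totals = []
        for order in itertools.permutations(diff):
            cur = c1
            steps = []
            blocked = False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if code.is_stop(nxt):
                    if skip_stops:
                        blocked = True
                        break
                    steps.append(False)  # nonsense step scored nonsynonymous
                else:
                    steps.append(code.codon_to_aa.get(cur) ==
                                 code.codon_to_aa.get(nxt))
                cur = nxt
            if not blocked:
                totals.append(steps)
        return totals

    pathways = walk(skip_stops=True) or walk(skip_stops=False)
    sd = sum(sum(1 for s in p if s) for p in pathways) / len(pathways)
    nd = sum(sum(1 for s in p if not s) for p in pathways) / len(pathways)
    return sd, nd


# ---------------------------------------------------------------------------
# Pairwise estimate
# ---------------------------------------------------------------------------


@dataclass
class KaKsEstimate:
    gene: str
    pair: tuple[str, str]
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float          # NaN when saturated
    Ka: float          # NaN when saturated
    ratio: float       # NaN when Ks == 0 or saturated
    codons_compared: int
    saturated: bool = False


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -3/4 ln(1 - 4p/3); raises at p >= 3/4."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError(f"difference proportion {p:.4f} >= 3/4")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(cds_a: str, cds_b: str, code: GeneticCode,
                  gene: str = "", pair: tuple[str, str] = ("a", "b")
                  ) -> KaKsEstimate:
    """NG86 Ka/Ks for a codon-aligned pair of coding sequences.

    Sites are averaged over the two sequences; codon pairs containing
    ambiguity or stops are skipped (run :func:`codon_align_and_clean`
    beforehand to remove gap columns).  Saturated proportions (p >= 3/4) are
    reported on the estimate rather than raised.
    """
    a, b = _normalize_cds(cds_a), _normalize_cds(cds_b)
    if len(a) != len(b):
        raise AlignmentError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise AlignmentError(f"length {len(a)} is not a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca not in code.codon_to_aa or cb not in code.codon_to_aa:
            continue
        sa, na = ng86_site_counts(ca, code)
        sb, nb = ng86_site_counts(cb, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = ng86_pathway_counts(ca, cb, code)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise NoDataError("no comparable codons")
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    saturated = False
    try:
        Ks = jukes_cantor(pS) if not math.isnan(pS) else math.nan
    except SaturationError:
        Ks, saturated = math.nan, True
    try:
        Ka = jukes_cantor(pN) if not math.isnan(pN) else math.nan
    except SaturationError:
        Ka, saturated = math.nan, True
    ratio = Ka / Ks if (not saturated and Ks and Ks > 0
                        and not math.isnan(Ka)) else math.nan
    return KaKsEstimate(gene=gene, pair=pair, S_sites=S, N_sites=N,
                        Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
                        ratio=ratio, codons_compared=n_codons,
                        saturated=saturated)


# ---------------------------------------------------------------------------
# Codon-aware pairwise alignment
# ---------------------------------------------------------------------------


def codon_align_and_clean(cds_a: str, cds_b: str, code: GeneticCode
                          ) -> tuple[str, str]:
    """Protein-guided codon alignment with gap/ambiguity columns removed.

    The two CDS are translated, globally aligned with BLOSUM62, and the
    alignment is back-threaded onto codons; columns containing gaps,
    ambiguity or stops are dropped.  Raises :class:`NoDataError` when the
    proteins share no significant similarity (negative alignment score) or
    no columns survive cleaning.
    """
    a, b = _normalize_cds(cds_a), _normalize_cds(cds_b)
    a = a[:len(a) - len(a) % 3]
    b = b[:len(b) - len(b) % 3]
    if not a or not b:
        raise AlignmentError("empty coding sequence")
    # strip terminal stops before translating
    if a[-3:] in code.stop_codons:
        a = a[:-3]
    if b[-3:] in code.stop_codons:
        b = b[:-3]
    pa, pb = code.translate(a), code.translate(b)
    if pa == pb and len(a) == len(b):
        cleaned = _clean_columns(a, b, code)
        if not cleaned[0]:
            raise NoDataError("no codon columns survive cleaning")
        return cleaned

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    alignment = aligner.align(pa, pb)[0]
    if alignment.score < 0:
        raise NoDataError("no significant protein-level similarity")
    out_a: list[str] = []
    out_b: list[str] = []
    for (s1, e1), (s2, e2) in zip(*alignment.aligned):
        for k in range(e1 - s1):
            out_a.append(a[3 * (s1 + k): 3 * (s1 + k) + 3])
            out_b.append(b[3 * (s2 + k): 3 * (s2 + k) + 3])
    cleaned = _clean_columns("".join(out_a), "".join(out_b), code)
    if not cleaned[0]:
        raise NoDataError("no codon columns survive cleaning")
    return cleaned


def _clean_columns(a: str, b: str, code: GeneticCode) -> tuple[str, str]:
    keep_a: list[str] = []
    keep_b: list[str] = []
    for i in range(0, min(len(a), len(b)), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca in code.codon_to_aa and cb in code.codon_to_aa:
            keep_a.append(ca)
            keep_b.append(cb)
    return "".join(keep_a), "".join(keep_b)


# ---------------------------------------------------------------------------
# Neutrality plot
# ---------------------------------------------------------------------------


@dataclass
class NeutralityFit:
    gene: str
    n_species: int
    slope: float
    intercept: float
    r_squared: float

    @property
    def mutation_pressure_pct(self) -> float:
        return self.slope * 100.0

    @property
    def selection_pct(self) -> float:
        return (1.0 - self.slope) * 100.0


def neutrality_fit(points: list[PositionalGC], gene: str = "") -> NeutralityFit:
    """Ordinary least squares of GC12 on GC3 across species for one gene."""
    if len(points) < 3:
        raise UndefinedFitError(f"{gene}: need >= 3 points, got {len(points)}")
    gc3 = [p.gc3 for p in points]
    gc12 = [p.gc12 for p in points]
    if max(gc3) == min(gc3):
        raise UndefinedFitError(f"{gene}: zero variance in GC3")
    fit = _stats.linregress(gc3, gc12)
    return NeutralityFit(gene=gene, n_species=len(points),
                         slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue) ** 2)


def slope_standard_error(points: list[PositionalGC]) -> float:
    gc3 = [p.gc3 for p in points]
    gc12 = [p.gc12 for p in points]
    return float(_stats.linregress(gc3, gc12).stderr)


# ---------------------------------------------------------------------------
# Gene retention by evolutionary rate
# ---------------------------------------------------------------------------


def select_high_rate_genes(estimates: list[KaKsEstimate],
                           threshold: float = 0.9) -> list[str]:
    """Genes whose mean defined Ka/Ks across species reaches the threshold.

    The default 0.9 keeps near-neutral genes alongside those above 1.
    """
    by_gene: dict[str, list[float]] = {}
    for e in estimates:
        if not math.isnan(e.ratio):
            by_gene.setdefault(e.gene, []).append(e.ratio)
    return sorted(g for g, vals in by_gene.items()
                  if vals and sum(vals) / len(vals) >= threshold)


def kaks_dataframe(estimates: list[KaKsEstimate]):
    import pandas as pd

    return pd.DataFrame(
        [{
            "gene": e.gene, "query_id": e.pair[0], "reference_id": e.pair[1],
            "S_sites": e.S_sites, "N_sites": e.N_sites, "Sd": e.Sd,
            "Nd": e.Nd, "pS": e.pS, "pN": e.pN, "Ks": e.Ks, "Ka": e.Ka,
            "ratio": e.ratio, "codons_compared": e.codons_compared,
            "saturated": e.saturated,
        } for e in estimates],
        columns=["gene", "query_id", "reference_id", "S_sites", "N_sites",
                 "Sd", "Nd", "pS", "pN", "Ks", "Ka", "ratio",
                 "codons_compared", "saturated"])


def neutrality_dataframe(fits: list[NeutralityFit]):
    import pandas as pd

    return pd.DataFrame(
        [{
            "gene": f.gene, "n_species": f.n_species, "slope": f.slope,
            "intercept": f.intercept, "r_squared": f.r_squared,
            "mutation_pressure_pct": f.mutation_pressure_pct,
            "selection_pct": f.selection_pct,
        } for f in fits],
        columns=["gene", "n_species", "slope", "intercept", "r_squared",
                 "mutation_pressure_pct", "selection_pct"])
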