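"""Reading, canonicalising and slicing annotated mitochondrial genomes.

Insect mitogenomes are small circular molecules (~15-17 kb) carrying a nearly
universal set of 37 genes -- 13 protein-coding genes (PCGs), 22 tRNAs and two
rRNAs -- plus one large non-coding control region (CR).  Public annotations
spell gene names in many dialects (``COI``/``COX1``/``cox1``, ``CYTB``/``cob``,
``16S``/``rrnL`` ...), so every record is funnelled through a canonical
37-name nomenclature before any statistic is computed.

Internally all coordinates are 0-based half-open on the forward (deposited)
strand; GenBank's 1-based inclusive locations are converted at the boundary.
A feature may wrap the origin of the circular molecule, in which case
``start > end`` and extraction uses modular indexing -- the sequence is never
doubled, so whole-genome composition statistics see the true length.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mitocomp")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class MitocompError(Exception):
    """Base class for all package errors."""


class ParseError(MitocompError):
    """A record could not be parsed as a GenBank/FASTA flat file."""


class AnnotationConflictError(MitocompError):
    """Two independent features claim the same canonical gene."""


class UnknownGeneError(MitocompError):
    """A feature label could not be mapped to the 37-gene nomenclature."""


class AmbiguousGeneError(UnknownGeneError):
    """A serine/leucine tRNA copy could not be disambiguated."""


class MissingGeneError(MitocompError):
    """A required gene is absent from a genome."""


# ---------------------------------------------------------------------------
# Canonical nomenclature and the ancestral insect gene order
# ---------------------------------------------------------------------------

#: the ancestral insect mitochondrial gene order (control region excluded),
#: listed in chromosomal order starting at trnI, with heavy(+)/light(-) strand.
ANCESTRAL_ORDER: tuple[tuple[str, int], ...] = (
    ("trnI", +1), ("trnQ", -1), ("trnM", +1), ("nad2", +1), ("trnW", +1),
    ("trnC", -1), ("trnY", -1), ("cox1", +1), ("trnL2", +1), ("cox2", +1),
    ("trnK", +1), ("trnD", +1), ("atp8", +1), ("atp6", +1), ("cox3", +1),
    ("trnG", +1), ("nad3", +1), ("trnA", +1), ("trnR", +1), ("trnN", +1),
    ("trnS1", +1), ("trnE", +1), ("trnF", -1), ("nad5", -1), ("trnH", -1),
    ("nad4", -1), ("nad4l", -1), ("trnT", +1), ("trnP", -1), ("nad6", +1),
    ("cob", +1), ("trnS2", +1), ("nad1", -1), ("trnL1", -1), ("rrnL", -1),
    ("trnV", -1), ("rrnS", -1),
)

#: numerical gene index, 1..37, assigned by position in the ancestral order
#: (trnI = 1, trnQ = 2, ...).
GENE_INDEX: dict[str, int] = {name: i + 1 for i, (name, _) in enumerate(ANCESTRAL_ORDER)}
INDEX_GENE: dict[int, str] = {v: k for k, v in GENE_INDEX.items()}

PCG_NAMES = frozenset(
    {"atp6", "atp8", "cox1", "cox2", "cox3", "cob",
     "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6"}
)
RRNA_NAMES = frozenset({"rrnL", "rrnS"})
TRNA_NAMES = frozenset(n for n, _ in ANCESTRAL_ORDER) - PCG_NAMES - RRNA_NAMES
ALL_GENE_NAMES = frozenset(n for n, _ in ANCESTRAL_ORDER)

#: fixed plus/plus concatenation order for the PCG data set
PCG_CONCAT_ORDER: tuple[str, ...] = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)
#: fixed plus/plus concatenation order for the tRNA data set (ancestral order)
TRNA_CONCAT_ORDER: tuple[str, ...] = tuple(
    n for n, _ in ANCESTRAL_ORDER if n in TRNA_NAMES
)
RRNA_CONCAT_ORDER: tuple[str, ...] = ("rrnL", "rrnS")


def gene_class(name: str) -> str:
    if name in PCG_NAMES:
        return "PCG"
    if name in RRNA_NAMES:
        return "rRNA"
    if name in TRNA_NAMES:
        return "tRNA"
    if name == "CR":
        return "CR"
    raise UnknownGeneError(f"not a canonical gene name: {name!r}")


# one-letter <- three-letter amino-acid codes, for tRNA labels
_AA3 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}

# anticodon -> copy for the duplicated serine/leucine tRNAs
# (invertebrate mito set: S1 decodes AGN, S2 UCN, L1 CUN, L2 UUR)
_SL_ANTICODON = {
    "gct": "trnS1", "gcu": "trnS1",
    "tga": "trnS2", "uga": "trnS2",
    "tag": "trnL1", "uag": "trnL1",
    "taa": "trnL2", "uaa": "trnL2",
}
# codon-family shorthand sometimes written in labels: tRNA-Leu(UUR) etc.
_SL_FAMILY = {"agn": "trnS1", "ucn": "trnS2", "tcn": "trnS2",
              "cun": "trnL1", "ctn": "trnL1", "uur": "trnL2", "ttr": "trnL2"}


def _build_synonyms() -> dict[str, str]:
    syn: dict[str, str] = {}

    def add(name: str, *labels: str) -> None:
        for lab in labels:
            syn[re.sub(r"[^a-z0-9]", "", lab.lower())] = name

    add("cox1", "cox1", "coxi", "coi", "co1", "mtco1",
        "cytochrome c oxidase subunit 1", "cytochrome c oxidase subunit I",
        "cytochrome oxidase subunit 1", "cytochrome oxidase subunit I")
    add("cox2", "cox2", "coxii", "coii", "co2", "mtco2",
        "cytochrome c oxidase subunit 2", "cytochrome c oxidase subunit II")
    add("cox3", "cox3", "coxiii", "coiii", "co3", "mtco3",
        "cytochrome c oxidase subunit 3", "cytochrome c oxidase subunit III")
    add("cob", "cob", "cytb", "cyb", "mtcyb", "cytochrome b",
        "cytochrome b apoenzyme")
    add("atp6", "atp6", "atpase6", "atpase subunit 6",
        "atp synthase f0 subunit 6", "atp synthase subunit 6")
    add("atp8", "atp8", "atpase8", "atpase subunit 8",
        "atp synthase f0 subunit 8", "atp synthase subunit 8")
    for i in (1, 2, 3, 4, 5, 6):
        add(f"nad{i}", f"nad{i}", f"nd{i}", f"nadh{i}",
            f"nadh dehydrogenase subunit {i}")
    add("nad4l", "nad4l", "nd4l", "nadh4l", "nadh dehydrogenase subunit 4l")
    add("rrnL", "rrnl", "16s", "lrrna", "l-rrna", "16s rrna",
        "16s ribosomal rna", "large subunit ribosomal rna", "rnr2", "mtrnr2")
    add("rrnS", "rrns", "12s", "srrna", "s-rrna", "12s rrna",
        "12s ribosomal rna", "small subunit ribosomal rna", "rnr1", "mtrnr1")
    add("CR", "cr", "d-loop", "dloop", "control region", "a+t rich region",
        "at rich region", "at-rich region", "putative control region")
    # tRNAs: trnX, trnaX, tRNA-Xxx dialects
    for aa3, letter in _AA3.items():
        name = f"trn{letter}"
        if letter in ("S", "L"):
            name = f"trn{letter}?"  # ambiguous copy, resolved later
            add(name, f"trn{letter}", f"trna{aa3}", f"trna{letter}")
            add(f"trn{letter}1", f"trn{letter}1", f"trna{aa3}1", f"trna{letter}1")
            add(f"trn{letter}2", f"trn{letter}2", f"trna{aa3}2", f"trna{letter}2")
        else:
            add(name, f"trn{letter}", f"trna{aa3}", f"trna{letter}")
    return syn


_SYNONYMS = _build_synonyms()


def canonicalize_gene_name(raw: str, anticodon: str | None = None,
                           allow_ambiguous: bool = False) -> str:
    """Map an annotation label onto the canonical 37-gene nomenclature.

    Lookup is case-insensitive and tolerant of punctuation.  The duplicated
    serine and leucine tRNAs are disambiguated by an explicit copy number in
    the label, a codon-family tag (``tRNA-Leu(UUR)``), or the ``anticodon``
    argument; if none applies, :class:`AmbiguousGeneError` is raised unless
    ``allow_ambiguous`` permits the placeholder ``trnS?``/``trnL?`` to pass
    through (the GenBank parser then resolves copies positionally).
    """
    if not raw or not raw.strip():
        raise UnknownGeneError("empty gene label")
    s = raw.strip()
    hint = None
    m = re.search(r"\(([A-Za-z]{3})\)", s)
    if m:
        hint = m.group(1).lower()
        s = re.sub(r"\(.*?\)", "", s)
    key = re.sub(r"[^a-z0-9]", "", s.lower())
    name = _SYNONYMS.get(key)
    if name is None:
        raise UnknownGeneError(f"unrecognized gene label: {raw!r}")
    if name in ("trnS?", "trnL?"):
        for h in (anticodon.lower() if anticodon else None, hint):
            if h is None:
                continue
            resolved = _SL_ANTICODON.get(h) or _SL_FAMILY.get(h)
            if resolved and resolved[3] == name[3]:
                return resolved
        if allow_ambiguous:
            return name
        raise AmbiguousGeneError(
            f"cannot assign {raw!r} to copy 1 or 2 without an anticodon")
    return name


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One named gene on the forward strand of a (circular) mitogenome."""

    canonical_name: str
    start: int          # 0-based
    end: int            # half-open; may be < start when wrapping the origin
    strand: int         # +1 heavy strand, -1 light strand
    gene_class: str     # PCG / tRNA / rRNA / CR
    wraps_origin: bool = False

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return (genome_length - self.start) + self.end
        return self.end - self.start


@dataclass
class AnnotatedMitogenome:
    """A circular nucleotide sequence plus its canonical feature list."""

    identifier: str
    organism: str
    sequence: str
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"{self.identifier}: empty sequence")
        n = len(self.sequence)
        seen: dict[str, GeneFeature] = {}
        for f in self.features:
            if not (0 <= f.start < n and 0 <= f.end <= n):
                raise ParseError(
                    f"{self.identifier}: feature {f.canonical_name} outside "
                    f"[0,{n}): start={f.start}, end={f.end}")
            if f.canonical_name in seen:
                raise AnnotationConflictError(
                    f"{self.identifier}: duplicated gene {f.canonical_name}: "
                    f"{seen[f.canonical_name]} vs {f}")
            seen[f.canonical_name] = f
            if f.gene_class == "PCG" and f.length(n) < 3:
                raise ParseError(
                    f"{self.identifier}: PCG {f.canonical_name} shorter than one codon")
        self._by_name = seen

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        try:
            return self._by_name[name]
        except KeyError:
            raise MissingGeneError(
                f"{self.identifier}: gene {name} not annotated") from None

    def has(self, name: str) -> bool:
        return name in self._by_name

    def gene_names(self) -> list[str]:
        return [f.canonical_name for f in self.features]


@dataclass(frozen=True)
class GeneOrderSignature:
    """Numerical gene order: (index 1..37, orientation) from trnI, CR excluded."""

    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        idx = [g for g, _ in self.entries]
        if len(idx) != len(set(idx)):
            raise MitocompError("gene index repeated in order signature")
        if len(idx) > 37:
            raise MitocompError("order signature longer than 37 genes")

    def genes(self) -> list[str]:
        return [INDEX_GENE[g] for g, _ in self.entries]


ANCESTRAL_SIGNATURE = GeneOrderSignature(
    tuple((GENE_INDEX[name], strand) for name, strand in ANCESTRAL_ORDER)
)


@dataclass(frozen=True)
class RearrangementReport:
    is_identical: bool
    missing_genes: tuple[str, ...]
    breakpoint_count: int
    inverted_genes: tuple[str, ...]
    translocated_genes: tuple[str, ...]


# ---------------------------------------------------------------------------
# GenBank parsing
# ---------------------------------------------------------------------------

# feature priority when a gene is annotated twice (gene + CDS pairs are the
# norm in RefSeq records; the typed feature wins)
_TYPE_PRIORITY = {"CDS": 2, "tRNA": 2, "rRNA": 2, "gene": 1,
                  "D-loop": 2, "misc_feature": 0}


def _feature_label(f: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "standard_name", "label"):
        if key in f.qualifiers and f.qualifiers[key]:
            return str(f.qualifiers[key][0])
    return None


def _feature_anticodon(f: SeqFeature) -> str | None:
    vals = f.qualifiers.get("anticodon")
    if not vals:
        return None
    m = re.search(r"seq\s*:\s*([a-zA-Z]{3})", vals[0])
    if m:
        return m.group(1).lower()
    m = re.fullmatch(r"\(?([a-zA-Z]{3})\)?", vals[0].strip())
    return m.group(1).lower() if m else None


def _location_to_coords(loc, seq_len: int) -> tuple[int, int, int, bool]:
    """Return (start, end, strand, wraps_origin) in 0-based half-open form."""
    strand = +1 if (loc.strand or 1) >= 0 else -1
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # an origin-spanning join has one part ending at the sequence end and
        # one starting at 0
        if (len(parts) == 2 and int(parts[0].start) == 0
                and int(parts[1].end) == seq_len):
            return int(parts[1].start), int(parts[0].end), strand, True
        # contiguous join (rare in mito annotations): merge if touching
        if all(int(parts[i].end) == int(parts[i + 1].start)
               for i in range(len(parts) - 1)):
            return int(parts[0].start), int(parts[-1].end), strand, False
        raise ParseError(f"unsupported compound location: {loc}")
    return int(loc.start), int(loc.end), strand, False


def _resolve_sl_copies(entries: list[dict]) -> None:
    """Positionally resolve trnS?/trnL? placeholders against the ancestral order."""
    resolved_at = {e["name"]: e["start"] for e in entries
                   if e["name"] in ALL_GENE_NAMES}
    # ancestral chromosomal predecessor of each copy
    pred = {"trnS1": "trnN", "trnS2": "cob", "trnL1": "nad1", "trnL2": "cox1"}
    placeholders = [e for e in entries if e["name"] in ("trnS?", "trnL?")]
    for letter in "SL":
        ph = [e for e in placeholders if e["name"] == f"trn{letter}?"]
        if not ph:
            continue
        taken = {e["name"] for e in entries}
        free = [c for c in (f"trn{letter}1", f"trn{letter}2") if c not in taken]
        assigned: set[int] = set()
        for e in ph:
            best = None
            for copy in free:
                p = pred[copy]
                if p in resolved_at and copy not in {entries[i]["name"] for i in assigned}:
                    # does the nearest preceding resolved gene match the
                    # ancestral predecessor of this copy?
                    preceding = [n for n, s in resolved_at.items()
                                 if s < e["start"]]
                    if preceding and max(preceding, key=lambda n: resolved_at[n]) == p:
                        best = copy
                        break
            if best is None and free:
                best = free[0]
            if best is None:
                raise AmbiguousGeneError(
                    f"cannot place {e['label']!r}: both copies already assigned")
            logger.warning("resolved %r positionally to %s", e["label"], best)
            e["name"] = best
            free.remove(best)


def parse_genbank_record(rec: SeqRecord) -> AnnotatedMitogenome:
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise ParseError(f"{rec.id}: record has no sequence")
    is_circular = rec.annotations.get("topology", "circular") == "circular"

    entries: list[dict] = []
    for f in rec.features:
        if f.type not in _TYPE_PRIORITY or f.type == "source":
            continue
        label = _feature_label(f)
        if f.type == "D-loop":
            label = label or "D-loop"
        if label is None:
            continue
        try:
            name = canonicalize_gene_name(
                label, anticodon=_feature_anticodon(f), allow_ambiguous=True)
        except UnknownGeneError:
            if f.type in ("CDS", "tRNA", "rRNA"):
                raise UnknownGeneError(
                    f"{rec.id}: unrecognized {f.type} label {label!r}") from None
            continue  # unnamed misc/gene features are ignored
        try:
            start, end, strand, wraps = _location_to_coords(f.location, len(seq))
        except ParseError as exc:
            raise ParseError(f"{rec.id}: {exc}") from None
        entries.append({"name": name, "label": label, "start": start,
                        "end": end, "strand": strand, "wraps": wraps,
                        "priority": _TYPE_PRIORITY[f.type], "type": f.type})

    _resolve_sl_copies(entries)

    # dedupe gene/CDS pairs by priority; true conflicts raise
    chosen: dict[str, dict] = {}
    for e in entries:
        prev = chosen.get(e["name"])
        if prev is None or e["priority"] > prev["priority"]:
            chosen[e["name"]] = e
        elif e["priority"] == prev["priority"] and (
                (e["start"], e["end"]) != (prev["start"], prev["end"])):
            raise AnnotationConflictError(
                f"{rec.id}: gene {e['name']} annotated twice: "
                f"{prev['type']} [{prev['start']},{prev['end']}) vs "
                f"{e['type']} [{e['start']},{e['end']})")

    features = [
        GeneFeature(canonical_name=e["name"], start=e["start"], end=e["end"],
                    strand=e["strand"], gene_class=gene_class(e["name"]),
                    wraps_origin=e["wraps"])
        for e in chosen.values()
    ]
    features.sort(key=lambda f: f.start)
    genome = AnnotatedMitogenome(
        identifier=rec.id, organism=rec.annotations.get("organism", rec.description),
        sequence=seq, is_circular=is_circular, features=features)
    return _ensure_control_region(genome)


def _ensure_control_region(genome: AnnotatedMitogenome) -> AnnotatedMitogenome:
    """Annotate the largest unannotated gap as the control region if absent."""
    if genome.has("CR") or not genome.features:
        return genome
    n = genome.length
    feats = sorted(genome.features, key=lambda f: f.start)
    best = None
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        gap_start = f.end if not f.wraps_origin else f.end
        gap_end = nxt.start
        gap_len = (gap_end - gap_start) % n
        if gap_len >= 50 and (best is None or gap_len > best[2]):
            best = (gap_start % n, gap_end, gap_len)
    if best is None:
        return genome
    start, _, gap_len = best
    stop = start + gap_len
    wraps = stop > n
    cr = GeneFeature("CR", start, stop - n if wraps else stop,
                     +1, "CR", wraps_origin=wraps)
    logger.info("%s: control region inferred at [%d,%d)", genome.identifier,
                cr.start, cr.end)
    return AnnotatedMitogenome(genome.identifier, genome.organism,
                               genome.sequence, genome.is_circular,
                               feats + [cr])


def parse_genbank(text: str) -> AnnotatedMitogenome:
    """Parse a single-record GenBank flat file into an annotated mitogenome."""
    genomes = parse_genbank_multi(text)
    if len(genomes) != 1:
        raise ParseError(f"expected one LOCUS record, found {len(genomes)}")
    return genomes[0]


def parse_genbank_multi(text: str) -> list[AnnotatedMitogenome]:
    if "LOCUS" not in text.split("\n", 1)[0] and not text.lstrip().startswith("LOCUS"):
        first = text.strip().splitlines()[0] if text.strip() else "<empty>"
        raise ParseError(f"not a GenBank flat file; first line: {first!r}")
    try:
        records = list(SeqIO.parse(io.StringIO(text), "genbank"))
    except ValueError as exc:
        raise ParseError(f"malformed GenBank record: {exc}") from None
    if not records:
        raise ParseError("no LOCUS record found")
    return [parse_genbank_record(r) for r in records]


# ---------------------------------------------------------------------------
# GenBank serialization
# ---------------------------------------------------------------------------

_PRODUCT = {
    "cox1": "cytochrome c oxidase subunit I",
    "cox2": "cytochrome c oxidase subunit II",
    "cox3": "cytochrome c oxidase subunit III",
    "cob": "cytochrome b",
    "atp6": "ATP synthase F0 subunit 6",
    "atp8": "ATP synthase F0 subunit 8",
    "nad1": "NADH dehydrogenase subunit 1",
    "nad2": "NADH dehydrogenase subunit 2",
    "nad3": "NADH dehydrogenase subunit 3",
    "nad4": "NADH dehydrogenase subunit 4",
    "nad4l": "NADH dehydrogenase subunit 4L",
    "nad5": "NADH dehydrogenase subunit 5",
    "nad6": "NADH dehydrogenase subunit 6",
    "rrnL": "16S ribosomal RNA",
    "rrnS": "12S ribosomal RNA",
}
_TRNA_PRODUCT = {f"trn{letter}": f"tRNA-{aa3.capitalize()}"
                 for aa3, letter in _AA3.items()}
_TRNA_PRODUCT.update({
    "trnS1": "tRNA-Ser", "trnS2": "tRNA-Ser",
    "trnL1": "tRNA-Leu", "trnL2": "tRNA-Leu",
})
_SL_WRITE_ANTICODON = {"trnS1": "gct", "trnS2": "tga",
                       "trnL1": "tag", "trnL2": "taa"}


def write_genbank(genome: AnnotatedMitogenome) -> str:
    """Serialize a genome back to GenBank flat-file text."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.identifier,
                    name=genome.identifier[:16], description=genome.organism)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.is_circular else "linear"
    rec.annotations["organism"] = genome.organism
    n = genome.length
    for f in sorted(genome.features, key=lambda f: f.start):
        if f.wraps_origin:
            loc = CompoundLocation([
                SimpleLocation(f.start, n, strand=f.strand),
                SimpleLocation(0, f.end, strand=f.strand),
            ])
        else:
            loc = SimpleLocation(f.start, f.end, strand=f.strand)
        quals = {"gene": [f.canonical_name]}
        if f.gene_class == "PCG":
            rec.features.append(SeqFeature(loc, type="gene",
                                           qualifiers=dict(quals)))
            quals["product"] = [_PRODUCT[f.canonical_name]]
            quals["transl_table"] = ["5"]
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        elif f.gene_class == "tRNA":
            quals["product"] = [_TRNA_PRODUCT[f.canonical_name]]
            if f.canonical_name in _SL_WRITE_ANTICODON:
                quals["anticodon"] = [
                    f"(pos:complement({f.start + 1}..{f.start + 3}),"
                    f"aa:Xxx,seq:{_SL_WRITE_ANTICODON[f.canonical_name]})"]
            rec.features.append(SeqFeature(loc, type="tRNA", qualifiers=quals))
        elif f.gene_class == "rRNA":
            quals["product"] = [_PRODUCT[f.canonical_name]]
            rec.features.append(SeqFeature(loc, type="rRNA", qualifiers=quals))
        else:  # CR
            rec.features.append(SeqFeature(
                loc, type="D-loop",
                qualifiers={"note": ["putative control region"]}))
    out = io.StringIO()
    SeqIO.write(rec, out, "genbank")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Sequence extraction and concatenation
# ---------------------------------------------------------------------------


def extract_gene(genome: AnnotatedMitogenome, name: str) -> str:
    """Return the gene's sequence oriented 5'->3' in coding sense.

    Minus-strand genes are reverse-complemented; origin-wrapping features are
    concatenated across the origin using modular indexing.
    """
    f = genome.feature(name)
    if f.wraps_origin:
        raw = genome.sequence[f.start:] + genome.sequence[:f.end]
    else:
        raw = genome.sequence[f.start:f.end]
    return reverse_complement(raw) if f.strand == -1 else raw


def concatenate_genes(genome: AnnotatedMitogenome,
                      order: tuple[str, ...] | list[str]) -> str:
    return "".join(extract_gene(genome, name) for name in order)


def concatenate_pcgs(genome: AnnotatedMitogenome,
                     order: tuple[str, ...] | list[str] = PCG_CONCAT_ORDER) -> str:
    """Concatenate the 13 PCGs in coding sense, in the given fixed order."""
    missing = [g for g in order if not genome.has(g)]
    if missing:
        raise MissingGeneError(
            f"{genome.identifier}: missing PCG(s): {', '.join(missing)}")
    return concatenate_genes(genome, order)


# ---------------------------------------------------------------------------
# Gene order
# ---------------------------------------------------------------------------


def gene_order_signature(genome: AnnotatedMitogenome) -> GeneOrderSignature:
    """Chromosomal gene order as (index, orientation) pairs starting at trnI.

    The circular order is rotated so gene 1 (trnI) leads when present; the
    control region is excluded.  Genes absent from the genome are simply
    absent from the signature.
    """
    feats = [f for f in sorted(genome.features, key=lambda f: f.start)
             if f.canonical_name != "CR"]
    entries = [(GENE_INDEX[f.canonical_name], f.strand) for f in feats]
    indices = [g for g, _ in entries]
    if 1 in indices:
        k = indices.index(1)
        entries = entries[k:] + entries[:k]
    return GeneOrderSignature(tuple(entries))


def _signed_adjacencies(entries: tuple[tuple[int, int], ...]) -> set[tuple[int, int]]:
    """Signed circular adjacencies; (a, b) is identified with (-b, -a)."""
    adj = set()
    n = len(entries)
    for i in range(n):
        g1, s1 = entries[i]
        g2, s2 = entries[(i + 1) % n]
        a, b = s1 * g1, s2 * g2
        adj.add(min((a, b), (-b, -a)))
    return adj


def compare_gene_order(sig: GeneOrderSignature,
                       reference: GeneOrderSignature = ANCESTRAL_SIGNATURE
                       ) -> RearrangementReport:
    """Compare a gene order against a reference (default: ancestral insect).

    Breakpoints are circular signed adjacencies present in ``sig`` but absent
    from the reference after restriction to the shared gene set, the simplest
    reproducible statistic that detects the inversion/translocation/deletion
    rearrangement classes.
    """
    sig_genes = {g for g, _ in sig.entries}
    ref_orient = {g: s for g, s in reference.entries}
    missing = tuple(INDEX_GENE[g] for g, _ in reference.entries
                    if g not in sig_genes)
    inverted = tuple(INDEX_GENE[g] for g, s in sig.entries
                     if g in ref_orient and s != ref_orient[g])

    reduced_ref = tuple((g, s) for g, s in reference.entries if g in sig_genes)
    ref_adj = _signed_adjacencies(reduced_ref)
    sig_adj = _signed_adjacencies(sig.entries)
    breakpoints = len(sig_adj - ref_adj)

    # genes whose both flanking adjacencies are broken and whose orientation
    # is unchanged read as translocated rather than inverted in place
    broken = sig_adj - ref_adj
    broken_genes: dict[int, int] = {}
    for a, b in broken:
        for x in (abs(a), abs(b)):
            broken_genes[x] = broken_genes.get(x, 0) + 1
    translocated = tuple(
        INDEX_GENE[g] for g, s in sig.entries
        if broken_genes.get(g, 0) >= 2 and INDEX_GENE[g] not in inverted)

    identical = (breakpoints == 0 and not missing and not inverted
                 and not translocated and len(sig.entries) == len(reference.entries))
    return RearrangementReport(
        is_identical=identical, missing_genes=missing,
        breakpoint_count=breakpoints, inverted_genes=inverted,
        translocated_genes=translocated)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def gene_table(genomes: list[AnnotatedMitogenome]):
    """Per-gene coordinate table: genome_id, gene, index, start, end, strand."""
    import pandas as pd

    rows = []
    for g in genomes:
        for f in sorted(g.features, key=lambda f: f.start):
            rows.append({
                "genome_id": g.identifier,
                "gene": f.canonical_name,
                "index": GENE_INDEX.get(f.canonical_name, 0),
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
            })
    return pd.DataFrame(rows, columns=["genome_id", "gene", "index",
                                       "start", "end", "strand"])


def write_fasta(records: dict[str, str]) -> str:
    out = []
    for name, seq in records.items():
        out.append(f">{name}")
        for i in range(0, len(seq), 70):
            out.append(seq[i:i + 70])
    return "\n".join(out) + "\n"


def read_fasta(text: str) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                records[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            if name is None:
                raise ParseError(f"FASTA sequence before header: {line!r}")
            chunks.append(line.strip().upper())
    if name is not None:
        records[name] = "".join(chunks)
    if not records:
        raise ParseError("no FASTA records found")
    return records
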