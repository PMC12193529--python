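"""Orchestration of the full comparative-mitogenomics study.

Loads a set of annotated mitogenomes, runs the four analyses
(composition/skew, RSCU, CAI, Ka/Ks + neutrality), encodes gene orders
against the ancestral insect arrangement, and exports the concatenated
PCG+rRNA supermatrix.  Outputs are plain TSV and FASTA for diffability;
plots are optional.  A run is deterministic given its config and seed;
malformed input genomes are excluded with a logged reason rather than
aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codon_usage import (
    GeneticCode,
    cai_weights,
    codon_counts,
    gc_by_position,
    read_reference_table,
    rscu,
    rscu_matrix,
    sliding_window_cai,
)
from .composition import SKEW_LEVELS, pearson, skew_dataframe, skew_table
from .genome_io import (
    ANCESTRAL_SIGNATURE,
    PCG_CONCAT_ORDER,
    RRNA_CONCAT_ORDER,
    AnnotatedMitogenome,
    MitocompError,
    MissingGeneError,
    compare_gene_order,
    concatenate_genes,
    extract_gene,
    gene_order_signature,
    gene_table,
    parse_genbank_multi,
    read_fasta,
    write_fasta,
)
from .selection import (
    codon_align_and_clean,
    kaks_dataframe,
    neutrality_dataframe,
    neutrality_fit,
    ng86_pairwise,
    select_high_rate_genes,
)

logger = logging.getLogger("mitocomp")

SUPERMATRIX_ORDER = PCG_CONCAT_ORDER + RRNA_CONCAT_ORDER


class ConfigError(MitocompError):
    """The run configuration is invalid or incomplete."""


class MissingTaxonomyError(MitocompError):
    """Genomes lack a subfamily/tribe assignment in the taxonomy table."""


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)   # GenBank files or dirs
    taxonomy: str | None = None                       # TSV genome_id, subfamily, tribe
    reference_table: str | None = None                # Kazusa-style codon usage
    reference_cds: str | None = None                  # multi-FASTA, one CDS per PCG
    code_id: int = 5
    window_codons: int = 100
    step_codons: int = 1
    kaks_threshold: float = 0.9
    outdir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    plots: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key = value text config; '#' starts a comment."""
        cfg = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key == "input":
                cfg.inputs.append(value)
            elif key in ("taxonomy", "reference_table", "reference_cds",
                         "outdir", "log_level"):
                setattr(cfg, key, value)
            elif key in ("code_id", "window_codons", "step_codons", "seed"):
                setattr(cfg, key, int(value))
            elif key == "kaks_threshold":
                cfg.kaks_threshold = float(value)
            elif key == "plots":
                cfg.plots = value.lower() in ("1", "true", "yes")
            else:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        return cfg

    def validate(self) -> None:
        if not self.inputs:
            raise ConfigError("no input genomes configured")
        for p in self.inputs:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        for name in ("taxonomy", "reference_table", "reference_cds"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        GeneticCode.from_table_id(self.code_id)  # raises for unsupported ids


@dataclass
class ResultBundle:
    run_dir: Path
    genomes: list[AnnotatedMitogenome]
    exclusions: dict[str, str]
    tables: dict[str, pd.DataFrame]
    supermatrix: dict[str, str]
    manifest: dict


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------


def load_genomes(paths: list[str | Path]
                 ) -> tuple[list[AnnotatedMitogenome], dict[str, str]]:
    """Parse every GenBank file under the given files/directories.

    Returns (genomes, exclusions); a malformed file is excluded with its
    error message rather than failing the whole run.
    """
    files: list[Path] = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            files.extend(sorted(q for q in p.iterdir()
                                if q.suffix.lower() in (".gb", ".gbk", ".genbank")))
        else:
            files.append(p)
    genomes: list[AnnotatedMitogenome] = []
    exclusions: dict[str, str] = {}
    for f in files:
        try:
            genomes.extend(parse_genbank_multi(f.read_text()))
        except MitocompError as exc:
            logger.warning("excluding %s: %s", f.name, exc)
            exclusions[f.name] = str(exc)
    genomes.sort(key=lambda g: g.identifier)
    return genomes, exclusions


def load_taxonomy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "subfamily"}
    if not required <= set(df.columns):
        raise ConfigError(
            f"taxonomy table needs columns {sorted(required)}; "
            f"found {list(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def run_skew_stage(genomes: list[AnnotatedMitogenome]) -> dict[str, pd.DataFrame]:
    return {f"skew_{level}": skew_dataframe(skew_table(genomes, level))
            for level in SKEW_LEVELS}


def run_rscu_stage(genomes: list[AnnotatedMitogenome],
                   code: GeneticCode) -> pd.DataFrame:
    tables = []
    for g in genomes:
        counts = codon_counts(
            "".join(extract_gene(g, n) for n in PCG_CONCAT_ORDER),
            code, label=g.identifier)
        tables.append(rscu(counts, code))
    return rscu_matrix(tables, code).reset_index()


def run_cai_stage(genomes: list[AnnotatedMitogenome], code: GeneticCode,
                  reference_text: str, window: int = 100, step: int = 1
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    weights = cai_weights(read_reference_table(reference_text), code)
    profile_rows = []
    summary_rows = []
    for g in genomes:
        for gene in PCG_CONCAT_ORDER:
            prof = sliding_window_cai(extract_gene(g, gene), weights, code,
                                      window_codons=window, step_codons=step,
                                      genome_id=g.identifier, gene=gene)
            summary_rows.append({
                "genome_id": g.identifier, "gene": gene,
                "gene_cai": prof.gene_cai, "peak_cai": prof.peak_cai,
                "n_windows": len(prof.window_cai),
            })
            for s, v in zip(prof.window_starts, prof.window_cai):
                profile_rows.append({
                    "genome_id": g.identifier, "gene": gene,
                    "window_start_codon": s, "cai": v,
                })
    return (pd.DataFrame(profile_rows,
                         columns=["genome_id", "gene", "window_start_codon", "cai"]),
            pd.DataFrame(summary_rows,
                         columns=["genome_id", "gene", "gene_cai", "peak_cai",
                                  "n_windows"]))


def run_kaks_stage(genomes: list[AnnotatedMitogenome], code: GeneticCode,
                   reference_cds: dict[str, str],
                   reference_id: str = "reference") -> pd.DataFrame:
    estimates = []
    for g in genomes:
        for gene in PCG_CONCAT_ORDER:
            if gene not in reference_cds or not g.has(gene):
                continue
            try:
                a, b = codon_align_and_clean(extract_gene(g, gene),
                                             reference_cds[gene], code)
                estimates.append(ng86_pairwise(
                    a, b, code, gene=gene, pair=(g.identifier, reference_id)))
            except MitocompError as exc:
                logger.warning("Ka/Ks skipped for %s/%s: %s",
                               g.identifier, gene, exc)
    return kaks_dataframe(estimates)


def run_neutrality_stage(genomes: list[AnnotatedMitogenome],
                         code: GeneticCode,
                         genes: list[str]) -> pd.DataFrame:
    fits = []
    for gene in genes:
        points = [gc_by_position(extract_gene(g, gene), code)
                  for g in genomes if g.has(gene)]
        try:
            fits.append(neutrality_fit(points, gene=gene))
        except MitocompError as exc:
            logger.warning("neutrality fit skipped for %s: %s", gene, exc)
    return neutrality_dataframe(fits)


def run_gene_order_stage(genomes: list[AnnotatedMitogenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        sig = gene_order_signature(g)
        rep = compare_gene_order(sig, ANCESTRAL_SIGNATURE)
        rows.append({
            "genome_id": g.identifier,
            "n_genes": len(sig.entries),
            "is_identical": rep.is_identical,
            "breakpoints": rep.breakpoint_count,
            "missing_genes": ",".join(rep.missing_genes),
            "inverted_genes": ",".join(rep.inverted_genes),
            "translocated_genes": ",".join(rep.translocated_genes),
            "signature": " ".join(f"{'+' if s > 0 else '-'}{i}"
                                  for i, s in sig.entries),
        })
    return pd.DataFrame(rows, columns=["genome_id", "n_genes", "is_identical",
                                       "breakpoints", "missing_genes",
                                       "inverted_genes", "translocated_genes",
                                       "signature"])


def export_supermatrix(genomes: list[AnnotatedMitogenome]
                       ) -> tuple[dict[str, str], dict[str, str]]:
    """Unaligned 13 PCG + 2 rRNA concatenations, one record per genome."""
    records: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for g in genomes:
        try:
            records[g.identifier] = concatenate_genes(g, SUPERMATRIX_ORDER)
        except MissingGeneError as exc:
            logger.warning("supermatrix: %s", exc)
            excluded[g.identifier] = str(exc)
    return records, excluded


def summarize_by_group(table: pd.DataFrame, taxonomy: pd.DataFrame,
                       value_columns: list[str],
                       group_column: str = "subfamily") -> pd.DataFrame:
    """Per-group (and overall) mean +/- sample SD of the given statistics.

    Sample SD (n-1 denominator) is blank for single-member groups.
    """
    mapped = set(taxonomy["genome_id"])
    unmapped = sorted(set(table["genome_id"]) - mapped)
    if unmapped:
        raise MissingTaxonomyError(
            f"genomes absent from taxonomy table: {', '.join(unmapped)}")
    merged = table.merge(taxonomy[["genome_id", group_column]], on="genome_id")
    rows = []
    groups = [(name, sub) for name, sub in merged.groupby(group_column)]
    groups.append(("ALL", merged))
    for name, sub in groups:
        row: dict = {group_column: name, "n": sub["genome_id"].nunique()}
        for col in value_columns:
            vals = sub[col].dropna()
            row[f"{col}_mean"] = vals.mean() if len(vals) else math.nan
            row[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def _next_run_dir(outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    k = 1
    while (outdir / f"run-{k:04d}").exists():
        k += 1
    run_dir = outdir / f"run-{k:04d}"
    run_dir.mkdir()
    return run_dir


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g",
              lineterminator="\n")


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Run every analysis stage and write TSV/FASTA outputs.

    Deterministic given config + seed; each rerun writes into a fresh
    versioned subdirectory of the output directory.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    code = GeneticCode.from_table_id(config.code_id)
    genomes, exclusions = load_genomes(config.inputs)
    if not genomes:
        raise ConfigError("no parseable genomes in the input set")

    run_dir = _next_run_dir(Path(config.outdir))
    tables: dict[str, pd.DataFrame] = {}
    tables["gene_table"] = gene_table(genomes)
    tables.update(run_skew_stage(genomes))
    tables["rscu_matrix"] = run_rscu_stage(genomes, code)
    if config.reference_table:
        ref_text = Path(config.reference_table).read_text()
        prof, summary = run_cai_stage(genomes, code, ref_text,
                                      config.window_codons, config.step_codons)
        tables["cai_profiles"] = prof
        tables["cai_summary"] = summary
    if config.reference_cds:
        ref = read_fasta(Path(config.reference_cds).read_text())
        tables["kaks"] = run_kaks_stage(genomes, code, ref)
        if len(tables["kaks"]):
            from .selection import KaKsEstimate  # noqa: F401  (type reference)

            est = [row for row in tables["kaks"].itertuples()]
            retained = select_high_rate_genes(
                [_row_to_estimate(r) for r in est], config.kaks_threshold)
            tables["neutrality"] = run_neutrality_stage(genomes, code, retained)
    tables["gene_order"] = run_gene_order_stage(genomes)
    supermatrix, sm_excluded = export_supermatrix(genomes)

    if config.taxonomy:
        taxonomy = load_taxonomy(config.taxonomy)
        tables["skew_summary_by_subfamily"] = summarize_by_group(
            tables["skew_whole_genome"], taxonomy,
            ["at_percent", "at_skew", "gc_skew"])

    for name, df in tables.items():
        _write_tsv(df, run_dir / f"{name}.tsv")
    (run_dir / "supermatrix.fasta").write_text(write_fasta(supermatrix))

    whole = tables["skew_whole_genome"]
    try:
        corr = pearson(whole["at_skew"], whole["gc_skew"]).r
    except MitocompError:
        corr = math.nan
    manifest = {
        "package": "mitocomp",
        "version": __version__,
        "seed": config.seed,
        "code_id": config.code_id,
        "n_genomes": len(genomes),
        "genome_ids": [g.identifier for g in genomes],
        "exclusions": exclusions,
        "supermatrix_excluded": sm_excluded,
        "whole_genome_skew_pearson_r": corr,
        "config_hash": hashlib.sha256(
            repr(sorted(vars(config).items())).encode()).hexdigest()[:16],
        "outputs": sorted(f"{n}.tsv" for n in tables) + ["supermatrix.fasta"],
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
    if config.plots:
        from . import plots

        plots.write_all(run_dir, tables)
    return ResultBundle(run_dir=run_dir, genomes=genomes,
                        exclusions=exclusions, tables=tables,
                        supermatrix=supermatrix, manifest=manifest)


def _row_to_estimate(row):
    from .selection import KaKsEstimate

    return KaKsEstimate(
        gene=row.gene, pair=(row.query_id, row.reference_id),
        S_sites=row.S_sites, N_sites=row.N_sites, Sd=row.Sd, Nd=row.Nd,
        pS=row.pS, pN=row.pN, Ks=row.Ks, Ka=row.Ka, ratio=row.ratio,
        codons_compared=row.codons_compared, saturated=row.saturated)
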