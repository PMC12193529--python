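"""Optional figures mirroring the study's standard panels (TSV stays primary)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_skew_scatter(df, path: Path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df["at_skew"], df["gc_skew"], s=18, alpha=0.8)
    ax.set_xlabel("AT skew")
    ax.set_ylabel("GC skew")
    ax.set_title(title)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rscu_heatmap(matrix_df, path: Path) -> None:
    data = matrix_df.set_index("codon").drop(columns=["amino_acid"])
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * data.shape[1]), 10))
    im = ax.imshow(data.to_numpy(dtype=float), aspect="auto", cmap="BuPu")
    ax.set_yticks(range(len(data.index)), data.index, fontsize=5)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="RSCU")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cai_profiles(profiles_df, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    for (gid, gene), sub in profiles_df.groupby(["genome_id", "gene"]):
        ax.plot(sub["window_start_codon"], sub["cai"], lw=0.6, alpha=0.6)
    ax.set_xlabel("window start (codon)")
    ax.set_ylabel("CAI (100-codon window)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_kaks_box(kaks_df, path: Path) -> None:
    groups = [(g, sub["ratio"].dropna().tolist())
              for g, sub in kaks_df.groupby("gene")]
    groups = [(g, v) for g, v in groups if v]
    if not groups:
        return
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot([v for _, v in groups], tick_labels=[g for g, _ in groups])
    ax.axhline(1.0, ls="--", lw=0.8, color="grey")
    ax.set_ylabel("Ka/Ks")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_neutrality(fit_df, points_by_gene, path: Path) -> None:
    genes = list(fit_df["gene"])
    if not genes:
        return
    fig, axes = plt.subplots(1, len(genes), figsize=(3.2 * len(genes), 3.2),
                             squeeze=False)
    for ax, (_, row) in zip(axes[0], fit_df.iterrows()):
        pts = points_by_gene.get(row["gene"], [])
        xs = [p.gc3 for p in pts]
        ys = [p.gc12 for p in pts]
        ax.scatter(xs, ys, s=14)
        if xs:
            lo, hi = min(xs), max(xs)
            ax.plot([lo, hi],
                    [row["intercept"] + row["slope"] * lo,
                     row["intercept"] + row["slope"] * hi], color="crimson")
        ax.set_title(f"{row['gene']} (slope={row['slope']:.2f})", fontsize=9)
        ax.set_xlabel("GC3")
        ax.set_ylabel("GC12")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_all(run_dir: Path, tables: dict) -> None:
    if "skew_whole_genome" in tables:
        plot_skew_scatter(tables["skew_whole_genome"],
                          run_dir / "skew_whole_genome.png", "whole genome")
    if "rscu_matrix" in tables:
        plot_rscu_heatmap(tables["rscu_matrix"], run_dir / "rscu_heatmap.png")
    if "cai_profiles" in tables:
        plot_cai_profiles(tables["cai_profiles"], run_dir / "cai_profiles.png")
    if "kaks" in tables:
        plot_kaks_box(tables["kaks"], run_dir / "kaks_box.png")
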