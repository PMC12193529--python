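# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of `mitocomp`.

## Scope and data model

The unit of analysis is an annotated circular mitogenome: a nucleotide
sequence plus a list of canonical gene features (13 PCGs, 22 tRNAs, 2 rRNAs,
one control region). Internally all coordinates are 0-based half-open on the
deposited (forward/heavy) strand; GenBank's 1-based inclusive locations are
converted at the I/O boundary. Features may wrap the circular origin
(`start > end`), and extraction uses modular indexing rather than sequence
doubling, so whole-genome statistics always see the true molecule length.

Annotation dialects are normalized through a synonym table
(`COI`/`COX1`/`cox1`; `CYTB`/`cob`; `16S`/`rrnL`; `tRNA-Ile`/`trnI`, …).
The duplicated serine and leucine tRNAs are disambiguated in this priority
order: explicit copy number in the label, codon-family tag or anticodon
(`gct` → trnS1, `tga` → trnS2, `tag` → trnL1, `taa` → trnL2), then position
relative to the ancestral order (each copy's ancestral chromosomal
predecessor), with a logged warning; an unresolvable copy is an error.
Records pairing a `gene` feature with a typed CDS/tRNA/rRNA feature dedupe
by feature-type priority; two same-priority features claiming one gene with
different coordinates raise an annotation-conflict error. When no control
region is annotated, the largest unannotated gap (≥ 50 nt) is reported as
CR; the CR is excluded from gene-order analysis and from all gene-level
statistics.

## Composition and skew

Skews are `(A − T)/(A + T)` and `(G − C)/(G + C)` on the deposited strand.
IUPAC ambiguity codes and N are tallied as "other" and excluded from both
numerators and denominators, which keeps the statistics inside [−1, 1] and
independent of a record's ambiguity burden; a zero denominator yields a
missing value (NaN), never zero. Four analysis levels are provided: whole
genome (the full deposited sequence, control region included), the 13 PCGs
concatenated in the fixed plus/plus order (atp6, atp8, cox1, cox2, cox3,
cob, nad1 … nad6), the two rRNAs (rrnL, rrnS), the 22 tRNAs in ancestral
order, and per-gene variants of the PCG and tRNA sets. Individual-gene skews
are computed on coding-sense-oriented sequences. Group summaries report mean
± sample SD (n − 1); the SD is blank for single-member groups.

## Codon usage

Synonymous family structure is always derived from an NCBI translation
table at run time, never hard-coded. The default is table 5 (invertebrate
mitochondrial: TGA = Trp, ATA = Met, AGA/AGG = Ser; stops TAA/TAG), which
has 62 sense codons; the standard code (table 1) is available through the
same configuration for users whose reference tables are nuclear. Note that
neither table has exactly 60 sense codons — a count sometimes quoted in the
applied literature — so the package always reports the configured code's
full sense set rather than silently dropping codons.

Codon counting fixes the reading frame at 0, drops a trailing partial codon
(mitochondrial mRNAs commonly end in an incomplete stop completed by
polyadenylation), excludes codons containing ambiguity, and tallies stop
codons separately from the sense statistics.

**RSCU** is `count · family_size / family_total`; families with zero total
are reported as undefined rather than zero, so absence of an amino acid is
distinguishable from uniform usage.

**CAI** follows Sharp & Li: within each family, relative adaptiveness
`w(c) = f(c)/max f` from a reference usage table; the gene score is the
geometric mean of `w` over counted sense codons (computed in the log
domain). Zero-frequency reference codons receive a pseudocount of 0.5 on the
table's input scale before normalization, so no `w` is ever zero; the
consequence is that exact scale invariance of the reference table holds only
for strictly positive tables. Codons of single-codon families carry no usage
information and are excluded from the mean (none exist under table 5).
Sliding-window profiles use 100-codon (300 bp) windows at a step of one
codon — the finest deterministic, parameter-free choice — with the peak
defined as the maximum windowed value; genes shorter than one window yield a
single whole-gene window. Kazusa-format tables (`UUU 17.6(714298)` style or
plain codon/count columns) are parsed with RNA→DNA mapping; a parenthesized
or bare trailing count is preferred over the per-thousand frequency.

## Selection inference

**NG86 sites.** For each codon, the synonymous fraction at position *i* is
`s_i / (3 − stops_i)`: the share of the single-nucleotide mutations at that
position that preserve the amino acid, with mutations to stop codons
excluded from the denominator. Each position contributes exactly one site,
so every codon contributes S + N = 3, and the pairwise totals satisfy
`S + N = 3 · codons_compared` exactly — a convenient invariant that also
keeps ω estimates comparable across genes with different stop-adjacency.

**NG86 differences.** Codon pairs differing at k positions are resolved by
equal-weight averaging over all k! orderings of the changes, skipping
pathways whose intermediate codons are stops; in the (rare, three-fold)
case where every pathway is blocked, all pathways are used with nonsense
steps scored as nonsynonymous. Sites are averaged over the two sequences.
Proportions pS = Sd/S and pN = Nd/N receive the Jukes–Cantor correction
`d = −¾ ln(1 − 4p/3)`; a proportion at or beyond the pole (p ≥ ¾) marks the
estimate as saturated rather than aborting the run, and ω is undefined when
Ks = 0 (including the identical-sequence case).

**Codon-aware alignment.** Pairs are aligned at the protein level
(global, BLOSUM62, gap open −10 / extend −0.5) and back-threaded onto
codons; columns containing gaps, ambiguity or stops are removed. A negative
protein alignment score, or an empty cleaned alignment, raises a no-data
error instead of producing a meaningless estimate.

**Gene retention.** Genes are retained for neutrality analysis when their
mean defined ω across species reaches 0.9 (configurable) — a deliberate
hair below 1 so that near-neutral genes are analyzed together with those
above 1.

**Neutrality plot.** For each retained gene, GC12 (mean of first- and
second-position G+C) is regressed on GC3 by OLS across species, one point
per species (a per-window variant would be a straightforward extension but
is not implemented). The slope × 100 is reported as the mutational-pressure
percentage and (1 − slope) × 100 as the selection percentage; the two sum to
100 by construction. The fit requires ≥ 3 points and nonzero GC3 variance.

## Gene order

Signatures list genes in chromosomal order starting from trnI (the circular
order is rotated so index 1 leads when present), each as (index 1–37,
orientation ±1), control region excluded. How a deposited record is rotated
is a convention of this package; the encoding itself only fixes trnI = 1,
trnQ = 2, … by ancestral position. Rearrangement against a reference is
summarized by a signed circular breakpoint count: adjacencies (a, b) are
identified with (−b, −a), the reference is restricted to the genes present
in the query, and the count is the number of query adjacencies absent from
the reference. Under this metric an adjacent transposition costs 3
breakpoints and a single-gene inversion costs 2. Missing and
orientation-flipped genes are reported separately; genes with both flanking
adjacencies broken and unchanged orientation are listed as translocated.
This is a simple reproducible statistic chosen to detect the
duplication/deletion/inversion–translocation classes; it is not an
edit-distance estimate of rearrangement events.

## Synthetic data model

The generator's defaults are the study conditions: genome length 15,900 nt,
AT% 74, AT skew +0.066, GC skew −0.2265 on the deposited strand, ancestral
gene order, Drosophila-like gene lengths, codon bias strength 1, ω 0.2, and
divergence 0.3 substitutions per codon.

PCGs are generated codon-by-codon (never base-by-base), which makes the
no-internal-stop constraint and the composition targets jointly satisfiable.
The sampling distribution over sense codons is fitted by iterative
proportional fitting (IPF) to per-position base marginals: the codon-bias
parameter b lifts the third-position A/T fraction to
`AT + (0.97 − AT)(1 − e^{−b})` while positions 1–2 compensate so the
per-gene AT% equals the genome target. Genes annotated on the light strand
are sampled from complemented marginals so the deposited strand keeps the
genome-level targets (equivalently: their coding-sense skews are negated).
tRNAs, rRNAs and the control region are i.i.d. draws from the target base
distribution; the control region absorbs the length budget left by the gene
table (an infeasible-spec error if under 100 nt). Each PCG starts with ATG
and ends with TAA — 78 fixed nt in a ~16 kb genome, the only deterministic
departure from the targets — so realized whole-genome AT% and skews match
the spec in expectation (verified to within 0.5 AT points over 200
replicates in the test suite). A single seed is split per gene by a
counter-based scheme (seed, ancestral gene index), so resizing one gene
never perturbs another's sequence.

The divergence simulator proposes uniform single-nucleotide substitutions
and accepts nonsynonymous proposals with probability min(1, ω) and
synonymous ones with probability min(1, 1/ω); proposals creating stops are
always rejected, and the number of accepted events is Poisson with mean
`divergence` per codon. The two-sided acceptance rule is what lets a single
parameter realize targets on both sides of neutrality (a one-sided rule
caps the realizable ω at 1). Realized synonymous/nonsynonymous counts are
recorded as truth. The divergence default of 0.3 per codon (~10% per site)
is the scale of congeneric insect mitochondrial divergence; it also matters
statistically: the per-pair ω estimate has a small noisy denominator (Sd),
so the mean of per-replicate ratios is upward-biased at very low divergence
— a property of the ratio statistic, not of the counting method, which is
unbiased on pooled counts.

Reference usage tables are built per family as Dirichlet draws with
concentration 1 + bias on A/T-ending codons, serialized in the Kazusa
dialect with large counts so that parsing round-trips the generating
frequencies to ~1e-3.

What the generator does **not** emulate: phylogenetic correlation between
genomes (replicates are i.i.d., no tree), gene overlaps and non-coding
spacers between genes, tRNA secondary structure, within-gene composition
heterogeneity, ambiguity codes, and length variation of the control region
beyond the length budget. Passing tests therefore demonstrate correctness
of the statistics under controlled conditions, not robustness to every
artifact of real RefSeq records.

## Numerical choices and degenerate inputs

* Undefined statistics (zero-denominator skew, unused RSCU family, ω with
  Ks = 0) are NaN/missing, never silently zero.
* Site and pathway counts are computed in exact rational arithmetic
  internally and returned as floats (exact Fractions on request); the test
  suite compares them against exhaustive enumeration oracles exactly.
* CAI and windowed CAI are computed in the log domain with prefix sums;
  window values agree with the direct geometric mean to 1e-12.
* OLS and Pearson statistics delegate to scipy; zero-variance inputs raise
  typed errors before scipy is consulted.
* TSVs are written with `%.10g` floats and fixed column orders; rerunning a
  pipeline with the same config and seed is byte-identical, and each run
  writes into a fresh `run-NNNN` directory so reruns never clobber results.
* No multiple-testing control is applied anywhere: the pipeline performs
  estimation and regression, not families of hypothesis tests.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on synthetic data at
desk scale, chosen as the package's own verification conditions: 5–12
genomes per study set, 300-codon genes with 50 replicates for ω recovery at
ω ∈ {0.2, 1.0, 1.5}, 50-point clouds (σ = 0.01) for neutrality-slope
recovery, 200 replicates for the composition-expectation check, and
exhaustive enumeration over all 62 sense codons and all 62² codon pairs for
the NG86 oracles.
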