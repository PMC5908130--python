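# Methods

`plasmir` re-implements, as a tested library, an analysis workflow for
circulating small RNA profiled in three plasma compartments: whole plasma,
the extracellular-vesicle (EV) fraction, and EV-depleted plasma. Because the
original cohort's raw data are not shipped, a synthetic cohort generator
with known ground truth stands in for it; the generator is first-class,
tested code and its defaults define the conditions under which the
pipeline's statistical properties are demonstrated.

## The generative model

Each of `n_mirna` mature miRNAs (default 600, lengths 19–24 nt) gets:

- **baseline abundance** `a_f`: log-normal (σ = 1.5 on the natural-log
  scale), normalized to sum to 1 over features. Members of the two disease
  clusters are scaled by `cluster_abundance_scale` (default 0.2) before
  normalization: placenta-derived cluster miRNAs are minor species in the
  plasma pool, and keeping their combined share small also keeps plain RPM
  fold-change estimates close to the true per-feature effect (with a large
  affected share, total-count normalization would compress fold changes —
  a compositional artifact the real data do not show).
- **EV share** `s_f ~ Beta(partition_alpha, partition_beta)` (defaults 2, 3;
  mean 0.4, matching the observation that more miRNA resides outside EVs),
  shifted additively by `sorting_u_boost` (default 0.15) when the mature
  sequence ends in U and by `motif_boost` (default 0.10) when it contains
  `sorting_motif` (default GGAG), clamped to [0, 1]. This encodes the two
  sequence-dependent EV-sorting mechanisms reported for exosomal miRNA.
- **disease multiplier**: `2^effect_log2fc` (default −1, i.e. a halving) for
  an `effect_fraction` (default 0.8) of each cluster's members, 1 elsewhere.
  The effect is multiplicative and shared across compartments.

Compartment abundances are additive by construction: EV = `a·s·m`,
EV-depleted = `a·(1−s)·m`, whole plasma = their sum. Sequencing a
compartment at nominal depth D first thins D binomially by the compartment's
share of total plasma RNA, then draws feature counts multinomially, so
expected EV + EV-depleted counts equal expected whole-plasma counts at equal
nominal depth.

**References.** Two clusters of 52 and 50 precursor loci (104 and 100
mature 5p/3p sequences) are laid out contiguously on their own synthetic
chromosomes (named chr14/chr19 after the biological clusters they emulate);
background miRNAs are spread over twelve further chromosomes. Every mature
sequence is embedded at its annotated genomic locus; twenty decoy
transcripts (200–500 nt) contain no mature sequence on either strand.

**Reads.** Raw reads follow the 4N degenerate-adapter library structure:
4 i.i.d. random nt + mature sequence + 4 i.i.d. random nt + 3′ adapter,
truncated to the machine read length (default 50). Substitution errors only
(default 0.001/base): the mapper's tiers are mismatch counts and miRNA-length
reads make indels a secondary concern. A `junk_fraction` (default 0.05) of
reads is replaced by homopolymers, dinucleotide repeats or pure adapter
dimers. Quality strings are constant — the preprocessing filter is
complexity-based, so quality variation is not the generator's job. Real 4N
adapters retain some ligation bias; modelling that is out of scope.

The count-level fast path (`simulate_count_matrix`) draws the same
multinomial counts a perfect preprocessing+mapping run would recover,
skipping read synthesis; it is used for statistical calibration where
per-read simulation adds only runtime, and a test pins it to the read-level
simulator's truth sidecar.

## Preprocessing

Adapter search returns the leftmost position where a prefix of the adapter
matches with mismatch rate ≤ 0.1 over an overlap ≥ 5 nt (3′ partial
overlaps allowed). The bulk path anchors on an exact 10-nt adapter-prefix
occurrence and verifies the full overlap; reads whose adapter carries an
error in the probe region fall back to the exhaustive scan, so the fast
path loses only pathological cases where a spurious tolerant match precedes
the anchored one (probability ≈ 4·10⁻¹⁰ per read for random inserts).

After adapter removal, 4 nt are stripped from each insert end (the
degenerate bases; they are not used as UMIs — the emulated protocol does
not deduplicate). Classification order: adapter position ≤ 8 → dimer (an
insert shorter than the 8 degenerate bases has no biological content);
insert length outside [15, 40] → length; tandem-repeat coverage ≥ 0.8 for a
unit of 1–3 nt → low complexity. Reads without an adapter are checked for
low complexity on the raw sequence (simulated homopolymer junk has no
adapter), otherwise filed as no-adapter. "Low quality" filtering means the
complexity filter; an optional mean-Phred threshold exists for real data
but is off by default. Every read lands in exactly one category and the
report enforces raw = kept + Σ discards.

## Hierarchical mapping

Gap-free (Hamming) alignment of full-length inserts against reference
windows of equal length, seeded by an exact k-mer index with
`k_eff = min(10, ⌊L/3⌋)`. Two mismatches split a read into three clean
segments whose longest has length ≥ ⌊L/3⌋, so the seeded search provably
finds every hit within two mismatches; a 10⁴-instance test checks exact
equivalence with an exhaustive scan. Mature-miRNA databases are matched
forward-strand only; transcript and genome databases on both strands
(implemented by querying the read's reverse complement against the forward
index — equivalent to indexing both strands).

The cascade is database-major by default: miRNA → transcripts → genome,
each searched at the full 0/1/2-mismatch tolerance, the first database with
a hit claiming the read. The alternative tier-major order (a perfect
transcript hit beats a 2-mismatch miRNA hit) is a config switch; which
order the original in-house pipeline used is not documented, so both are
provided. Within the claiming database only minimum-mismatch hits are kept;
ties get fractional 1/n weights (preserving totals exactly), with an
optional `first` policy for integer counts.

## Quantification and differential abundance

RPM uses all mapped reads as the per-sample denominator by default (feature
plus class rows then sum to exactly 10⁶); a miRNA-mapped-only denominator is
available. Detectability: ≥ 10 reads (inclusive — the two printed variants
of the rule disagree on inclusivity and the tabular wording is used) in
≥ ceil(0.7·n) of a group's samples, evaluated per case/control group; the
test universe is the union of group sets, whose intersection and
group-unique remainders reproduce the shared-plus-unique decomposition used
in the reported detectable totals.

The test statistic is a two-sided Welch t on x = log2(RPM+1) — the source
analysis names no test, so the default is the field's plainest choice, with
a label-permutation option as a robustness check (a test pins Welch to the
permutation p within 0.02 at n = 11 + 11). log2FC is the difference of
group means of x; the +1 pseudocount prevents −∞ at zero counts and biases
low-abundance estimates toward 0, which matters only below ~10 RPM.
Significance = |log2FC| ≥ log2(1.5) AND raw p ≤ 0.05, matching the printed
tables, which report raw p-values; BH q-values are reported alongside but
do not drive the flag. Zero-variance degenerate rows get p = 1 (equal
means) or a tiny p (unequal means).

## EV partition

Separately sequenced EV and EV-depleted libraries lose the between-
compartment scale, so each subject's two libraries are normalized jointly
(one shared factor per subject), which preserves the within-subject
EV:depleted ratio; `ev_share_hat = mean_EV/(mean_EV + mean_depleted)` then
estimates the true share (grid-recovery MAE ≤ 0.05 at depth 10⁶).
Enrichment classes mirror the DE rule on the paired per-subject
log2(x+1) difference (one-sample t against 0), requiring the share estimate
on the consistent side of 0.5 — the source reports terminal-U percentages
without defining its sets, so this operationalization is the package's own
and is configurable. Motif testing counts containment once per sequence
(Fisher 2×2, BH across motifs); sequences are stored as DNA and reported
as RNA.

## Network stage

Targets of the supplied differentially abundant miRNAs are filtered to
tissue-enriched genes, expanded by exactly one PPI hop, and tested for
pathway over-representation with a hypergeometric upper tail
(P(X ≥ k)), BH-corrected — an offline replacement for a web enrichment
tool with the same over-representation semantics. The enrichment universe
defaults to the union of pathway genes (configurable); the final network
keeps miRNA–gene edges whose gene lies in both the expanded set and a
selected pathway. Counts that depend on external database versions are not
reproduction targets; a generated toy dataset (synthetic ids) makes the
stage testable offline.

## Published-table fixture

The study's printed DEmiRNA table ships as a TSV transcribed from the
article text, with a stored checksum and a loader that normalizes
typographic Unicode and validates every printed pair against the study's
own significance criterion. Presence of a compartment pair defines
"significant in that compartment". The transcription carries 161 rows; the
article's prose states slightly larger totals for two compartments and the
union, and the corresponding acceptance assertions are left failing rather
than reconciled by editing data (the tabular source is kept verbatim).

## Problem sizes and numerical choices

Statistical property checks run at the study's arm sizes (11 + 11) with
count-level simulation at depth 10⁶; the read-level end-to-end run uses
10⁵ reads/sample across 66 samples, which this package processes in about
a minute. Null calibration uses 200 features × 50 replicates. Seeds are
explicit everywhere; identical configs give byte-identical outputs.

## What passing tests do and do not show

The generator draws i.i.d. uniform mature sequences, constant qualities,
substitution-only errors, subject-shared EV shares and a single
multiplicative disease effect. Passing recovery tests therefore show the
pipeline is correct and calibrated under this model — not that it overcomes
ligation bias, isomiR heterogeneity, indels, inter-subject partition
variability, or batch structure, none of which the generator emulates.
Known limitations: no UMI deduplication, no spliced or soft-clipped
alignment, no covariate adjustment, and 3′ non-template additions are not
analyzable under the 4N design being emulated.
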