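# Methods

This note documents the models, parameter choices and numerical decisions
behind `viropair`, and what the synthetic-data tests do and do not
demonstrate about real virome data.

## Synthetic paired viromes

The generator emulates a mother–infant virome study: `n_pairs` pairs, each
with a "milk" and an "infant stool" community drawn from a common genome
pool. Defaults: 10 pairs, 20 genomes per sample, genome lengths uniform on
3,000–40,000 nt, GC 0.45 per base (so per-genome GC is binomial around the
target), lognormal(σ = 1.5) abundances normalized to 1, 150 nt single-end
reads, and a planted `shared_fraction = 0.3`: each stool community contains
exactly `round(0.3 × 20)` genomes copied from its paired milk community.
Per-sample richness (20) and read depth (20,000) are desk-scale choices —
real studies sequence millions of reads; nothing in the sharing or
diversity mathematics depends on absolute depth, only on coverage being
sufficient for assembly.

Cross-pair ("background") sharing is controlled separately: a fraction
`background_shared_fraction` of every community is drawn from a small
cosmopolitan sub-pool common to all samples; the remaining genomes are
unique to one sample. Setting `shared_fraction = 0` with a nonzero
background yields a proper null design in which within-pair and
between-pair sharing are identically distributed — the basis of the
type-I-error check.

Reads are allotted multinomially by abundance with uniform start positions
and strands. Substitutions occur independently per base (default 0.001,
Illumina-like); erroneous bases receive low Phred scores (8–20) and correct
bases high ones (35–40), so the mean error implied by the qualities matches
the planted rate and quality truncation interacts with errors the way it
does on real data. The model deliberately omits indels, chimeras and
amplification bias; consequences: assembly tests exercise substitution
tolerance only, and consensus accuracy on real (indel-containing) data
would be lower. All randomness flows through one `numpy` generator seeded
from the config, making outputs byte-identical across runs.

`community_contigs` is a shortcut for contig-level analyses (sharing,
permutation tests, beta diversity): each genome contributes its leading
segment (capped at 6 kb) as a ready-made contig, identically in every
sample carrying it. This skips read simulation and assembly where only the
homology statistics are under study.

## Read QC

Five rules in fixed order, each read counted against the first rule that
removes it: (1) truncate at the first base with Phred < 30 — a truncated
read falling below the minimum length is removed here; (2) remove reads
with ≥ 8 consecutive identical bases; (3) remove reads < 50 nt or > 300 nt
(50 and 300 themselves are retained); (4) remove reads with any non-ACGT
base; (5) optionally remove reads with a local-alignment hit to a host
reference at E < 10⁻⁵. Truncation (rather than whole-read discard) is the
default reading of quality trimming; a discard mode is provided
(`truncate=False`). The host screen runs last because it is by far the
most expensive rule. The cascade is idempotent: its output passes
unchanged through a second application.

## Assembly

A greedy overlap-layout-consensus assembler built around two stringent
thresholds: overlaps qualify at ≥ 98% identity over ≥ 50% of the shorter
read (75 nt for 150 nt reads), and contigs < 2,000 nt are removed before
any downstream analysis. Candidate overlaps are nominated by shared
canonical 21-mers (k-mers occurring > 200 times are skipped as repeats)
and verified as gapless alignments at the implied diagonal. Verified
overlaps are merged greedily — longest first, ties by higher identity then
input order — into layout frames; a merge that would place a read
inconsistently with its existing pose is skipped, so each read belongs to
at most one contig and read counts are conserved. Consensus is per-column
majority, ties broken by summed base quality then alphabetically. Reads
left in single-read layouts are reported as unassembled and excluded from
downstream spectra (an option can append them as singletons).

This is not a general-purpose assembler: no indel-aware consensus, no
repeat resolution, no scaffolding. It is sufficient for the
substitution-only simulator and makes the two printed thresholds — the
scientifically meaningful content — explicit and testable.

## Local alignment and E-values

Two engines behind one interface. Sequence pairs ≤ 1 kb go through exact
affine-gap Smith–Waterman (match +2, mismatch −3, gap open −5, extend −2;
a gap of length L costs open + (L−1)·extend). Longer pairs use
seed-and-extend: shared canonical 21-mers vote for diagonals, and on each
of the top 32 diagonals the optimal *gapless* segment is found exactly by
a maximum-subarray scan. Gapless extension is exact for the
substitution-only regime the stringent thresholds target; alignments
needing gaps on multi-kb sequences would be under-scored, which is the
main caveat when applying the aligner to real diverged homologs.

E-values use the ungapped Karlin–Altschul form E = K·m·n·e^(−λS) with the
per-pair search space m·n (not a database-wide effective space). λ is
solved from Σ pᵢpⱼe^(λsᵢⱼ) = 1 at uniform base composition (λ ≈ 0.634 for
the default scores); K defaults to 0.1. The thresholds used throughout
(10⁻⁵ host screen, 10⁻¹⁰ cross-virome, 10⁻²⁰ homolog clustering) are
therefore internally consistent rather than numerically identical to
BLAST; on clear positives (hundreds of identical bases) and clear
negatives (no shared 21-mer) the two agree at threshold level, which is
all the pipeline uses.

## HVDI

Within a sample, contigs with a best hit at E < 10⁻²⁰ spanning ≥ 50% of
the shorter contig are joined; connected components are viruses; isolated
contigs are singular viruses. Member read counts are pooled and the
Shannon index (natural log; base-2 optional) of the pooled spectrum is the
HVDI, with the component count reported as a genotype-richness proxy.
Homology edges are treated as undirected — direction cannot change
connected components. Pooling two categories never increases Shannon
entropy, so collapsing split contigs can only lower (or preserve) the
estimate relative to the raw contig spectrum, which is the intended
correction.

## Sharing

**Co-assembly attribution**: reads of both samples are pooled with source
labels, co-assembled, and each retained contig is classified shared when
every source contributes ≥ `min_reads_each` reads (default 1 — the
threshold is a genuinely open choice and is configurable). The planted
shared fraction (defined over infant genomes) is recovered by
shared / (shared + stool-only) contig counts.

**Permutation test**: statistic = fraction of `n_sampled_contigs` (1,000)
contigs drawn from one sample with ≥ 1 stringent homolog in the partner
sample; sampling is without replacement when enough contigs exist, with
replacement otherwise (either way the statistic estimates the same
per-contig sharing probability). The null (10,000 iterations) draws random
milk(i)–stool(j) combinations with i ≠ j, excluding only the true pairing;
p = #(null ≥ observed)/N with no pseudo-count, displayed as "< 1/N" at
zero. Per-contig homolog flags are memoized per sample combination, so
iterations cost only resampling. The summary table reports within-pair
sharing as the mean ± SD over repeated resampled evaluations averaged over
both directions (milk→stool and stool→milk), and between-pair sharing over
random cross combinations; ± values are resampling SDs.

## Beta diversity, taxonomy, statistics

The feature vector of sample i holds, for every sample j, the fraction of
i's contigs with a hit in j at E < 10⁻¹⁰ (diagonal 1; a binary
presence/absence mode is provided since the exact feature construction is
an open choice). Bray–Curtis Σ|x−y|/Σ(x+y) on these rows feeds classical
PCoA: double-center −½D², eigendecompose, scale eigenvectors by √λ.
Negative eigenvalues are dropped with their summed magnitude reported (no
Cailliez correction — the simplest defensible default); requesting more
axes than positive eigenvalues truncates with a warning.

Taxonomy parses 12-column tabular hit records: best hit per contig =
lowest E, ties by higher bitscore then first record; best hits at
E ≥ 10⁻²⁰ leave the contig unassigned. Family → phage/eukaryotic rollup
uses an editable packaged TSV. Group comparisons: two-tailed two-sample
t-test, or Mann–Whitney U (exact when combined n ≤ 20, normal
approximation with tie correction otherwise). GC summaries report
per-sample median and quartiles of contig GC.

## Problem sizes in tests and the acceptance script

Checks run on desk-scale designs chosen to keep the statistics
well-powered: 4 pairs × 25 genomes (3 kb contigs) for the permutation
headline; 50 replicate null studies at 400 iterations each for the type-I
check; 17 genomes × 400 reads (~8,000 pooled reads) for co-assembly
recovery; 5 genomes at 30× for HVDI recovery (30× makes coverage gaps
> 75 nt vanishingly rare, so each genome assembles into one contig); one
3 kb genome at 20× for assembler recovery. Passing these demonstrates
internal correctness and parameter recovery under the simulator's
assumptions — substitution-only errors, no conserved genes shared between
"different" viruses, no database incompleteness — not performance on real
viromes, where homology thresholds interact with genuine biological
mosaicism (e.g. related phages sharing modules).

## Known limitations

- Gapless extension under-scores diverged homologs needing indels.
- The assembler's majority consensus has no indel handling; real-data
  contigs would require a dedicated assembler (the thresholds, not the
  engine, are the point).
- E-values are per-pair, not BLAST-compatible beyond threshold level.
- `estimated viral genotypes` richness curves and translated (TBLASTX)
  search are out of scope; the hit-table fixture stands in for the latter
  (and is labelled synthetic).
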