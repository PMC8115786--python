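# Methods

This note documents the models, rules and numerical choices behind
`methylmem`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design and notation

Thirteen conditions cover the acclimation experiment: fresh plants (F, F4,
F18 at the initial, 4-week and 18-week growth stages), the slow soil-drying
acclimation treatment itself (SD), acclimated plants after rehydration (A,
A4, A18), and each state under rapid air-dehydration (FD, AD, F4D, A4D,
F18D, A18D). Eight contrasts drive the analysis, written
numerator/denominator: SD/F, A/SD, FD/F, AD/A, F4D/F4, A4D/A4, F18D/F18,
A18D/A18. Methylation direction ("hyper"/"hypo") and expression direction
("up"/"down") are always relative to the numerator.

Coordinates are 1-based inclusive internally (GFF3 convention); BED output
converts to 0-based half-open at the writer and nowhere else. The promoter
is the 2-kb strand-aware flank 5′ of the protein-coding span (`flank_bp`
configurable); the downstream flank mirrors it 3′; both are clipped at
contig bounds. When a gene has several transcripts, the one with the
longest summed exon length defines the gene-level exon chain.

## Methylation statistics

**Site level.** `level = meth_reads / total_reads` at one cytosine. Sites
are *not* collapsed across strands: a CG on the plus strand and its partner
on the minus strand are independent observations. A configurable coverage
floor (default 4 reads in every sample involved) gates all comparative
statistics; the value is a pragmatic guard against degenerate 2×2 tables,
since site-level read-count filters are a convention rather than something
the data dictate.

**mC calls.** Whether a covered site is "methylated" at all is decided by a
one-sided binomial test of the methylated-read count against a bisulfite
non-conversion error rate (default 0.005), methylated iff p < 0.05. The
per-context mC frequency is the percentage of covered sites called
methylated. The headline "mean methylation level" per context is computed
over called-mC sites (this is the convention under which plant CG levels
land in the high-70s/low-80s percent range); the all-site mean is also
reported.

**DMCs.** Fisher's exact test on [[meth_A, unmeth_A], [meth_B, unmeth_B]],
two-sided by the minimum-likelihood rule (sum the probabilities of all
tables no more likely than the observed one). The batch implementation
computes hypergeometric weights as exact integers per unique table margin
and compares them exactly — no epsilon, no log-space rounding — so p-values
differ from a literal enumeration only by one final float division. A site
is a DMC iff p < 0.05 **and** |Δlevel| ≥ 0.20.

**DMRs (seed-and-extend).** Within one context on one contig, sites sorted
by position:

1. *Seed:* a window of 5 consecutive sites in which every neighbour gap is
   ≤ 200 bp, at least 4 sites share one sign of Δlevel = level_num −
   level_den (Δ = 0 counts for neither side), and the exact two-sided
   Wilcoxon rank-sum test of the window's denominator levels vs numerator
   levels gives p < 0.05.
2. *Extension:* 3′ only, one site at a time; a site must match the seed's
   majority sign (Δ = 0 terminates), lie ≤ 200 bp from the previous member,
   and the test re-run on the extended member set must still give
   p < 0.05; the first failure stops extension and the failing site is not
   a member.
3. *Emission:* the region spans the first to last member; direction is
   hyper iff the members' mean numerator level exceeds the denominator
   mean; scanning resumes at the first site past the emitted region, so
   regions never overlap.

If both signs somehow reach the trend quorum in one window (impossible at
the 4-of-5 default, possible under other settings) the more frequent sign
wins and an exact tie skips the window — a deterministic rule the
brute-force reference mirrors.

The Wilcoxon p must be exact at n = 5 vs 5 — the normal approximation is
badly wrong there — and methylation levels tie constantly (they are ratios
of small integers). The test is therefore the exact conditional mid-rank
test: with doubled integer ranks, p = P(|W − E[W]| ≥ |w_obs − E[W]|) over
all C(n, n_A) assignments, computed by full enumeration when C(n, n_A) ≤
20 000, by an exact dynamic programme over rank sums up to n = 120 pooled
observations, and by a tie-corrected continuity-corrected normal
approximation beyond (never reached at acceptance scales). For equal group
sizes the conditional distribution is symmetric, so this equals the usual
2·min(tail) convention whenever ties are absent — a property the tests
exploit by cross-checking against `scipy.stats.mannwhitneyu(method="exact")`.

No multiplicity adjustment is applied to DMR seeds (the published rule uses
a raw alpha); the consequence — a substantial rate of short borderline
calls under the null — is measured, not hidden: the acceptance benchmarks
report false DMRs per Mb on a matched null genome at alphas 0.05/0.01/0.001
and check the rate is non-increasing as alpha tightens.

**Region aggregation and metagene profiles.** Region methylation is the
unweighted mean of covered context-site levels inside an interval, reported
missing below 3 sites. Metagene curves bin the 2-kb flanks into fixed
100-bp bins and length-normalise gene bodies into 20 bins, orienting
everything 5′→3′ and tracking exonic and intronic cytosines separately;
per-bin values pool sites across all genes of an expression class (low:
FPKM ≤ 1, medium: 1 < FPKM ≤ 100, high: FPKM > 100, on replicate-averaged
FPKM).

## Expression and differential expression

FPKM = count / (exonic kb) / (mapped fragments in millions); library totals
default to column sums, under which Σ FPKM·kb = 10⁶ exactly.

The built-in DE test is deliberately a documented, moment-based
approximation rather than a re-implementation of a published DE package
(external DE tables import as first-class inputs, and the DEG rule —
fold change ≥ 2 and BH-adjusted p ≤ 0.05, boundaries inclusive — is always
re-applied to them):

* median-of-ratios size factors (geometric-mean reference over genes
  observed in every sample; library-size fallback otherwise);
* per-gene NB dispersion by method of moments on pooled within-group
  variance, floored at 0.01;
* Wald statistic on the log difference of normalised group means with a
  delta-method standard error, pseudo-count 1 for zero handling, standard
  normal reference;
* BH adjustment across genes; all-zero genes get p = 1 and log2FC = 0.

The normal reference was chosen over a small-sample t reference after
measuring both: the t(4) variant destroys power against 8-fold planted
effects at n = 3 without improving null behaviour, while the normal variant
keeps the BH-significant fraction under the complete null well below
nominal (the calibration benchmark re-measures this on every run). The test
tracks DESeq2 closely on simulated data (a pydeseq2 cross-check test
asserts fold-change agreement) but makes no claim of numerical parity.

## Memory classification

Pure set logic over per-contrast DEG flags, direction-aware, with
"no significant change or opposite response" encoded literally (an
opposite-direction DEG does not disqualify; a same-direction DEG does):

* **RDT-specific:** same-direction DEG in AD/A and A4D/A4; none/opposite in
  A18D/A18, FD/F, F4D/F4, F18D/F18.
* **Mid-term memory:** RDT-specific ∩ same-direction DEG in SD/F.
* **Short-term memory:** same-direction in AD/A and SD/F; none/opposite in
  A4D/A4, A18D/A18, FD/F, F4D/F4.
* **Long-term:** same-direction in AD/A, A4D/A4 and A18D/A18 with
  none/opposite in FD/F, F4D/F4, F18D/F18 (the "specific" set); the memory
  subset additionally same-direction in SD/F. The three control contrasts
  are an explicit design choice — the long-term definition names the
  acclimated contrasts, and symmetry with the other categories fixes the
  exclusions.

Short, mid and long are mutually exclusive by construction; genes meeting
the RDT criteria without pre-induction are reported as `rdt_specific`.
Genes absent from a contrast's table are treated as flag = none with a
logged warning; a missing contrast table is an error naming the contrast.

## Promoter–expression coupling and MRGs

Promoter classes per sample and context use linear-interpolation ("type 7")
quartiles over genes with data, with strict inequalities as the definitions
read: methylated strictly above Q3, unmethylated strictly below Q1,
ties intermediate; fewer than 8 genes with data is an error. Expression
between the two tail classes is compared by the same exact rank-sum test
(rank tests are invariant to the log scale used for display).

A gene is an **MRG** in a contrast iff it is an up-DEG whose promoter is
overlapped (≥ 1 bp) by a hypo-DMR, or a down-DEG overlapped by a hyper-DMR,
in CG or CHG — the symmetric contexts that maintenance methylation
propagates; CHH never qualifies. "Significantly changed promoter
methylation" is operationalised as DMR overlap because the DMR is the
significance unit elsewhere in the chain; a DMC-count alternative (≥ 2
promoter DMCs of the needed sign) is provided for sensitivity analysis.
Memory×MRG intersections split MRG sources into acclimation-related (SD/F,
A/SD) and rapid-dehydration (the *D/* contrasts) lists, intersected with
the short- and mid-term memory sets.

Pearson correlations (fold change vs promoter Δlevel; per-sample
methylation metrics vs pathway-gene expression) report r, p and n; n < 3 or
a constant vector is reported missing, and |r| = 1 at n = 3 is flagged as
the degenerate analytic limit with an "insufficient n" warning.

## The synthetic-data generator

What it emulates: a random mini-genome (default 2 × 500 kb, 200 genes with
1–5 exons, non-overlapping, full 2-kb flanks on-contig) whose cytosine
contexts are derived from the sequence on both strands; one pooled WGBS
library per condition — true site levels Beta-distributed around context
baselines CG 0.80, CHG 0.75, CHH 0.16 (inside the per-sample ranges such
studies report), concentration 20/20/50, shared across conditions; shifted-
Poisson coverage (mean 29, min 1) and binomial methylated reads; planted
promoter regions shift the true level by ±0.4 in designated conditions
(clamped to [0.02, 0.98], with a warning when clamping truncates the
shift — unavoidable for hyper shifts near the CG baseline); NB expression
counts (dispersion 0.1, 3 replicates, ±8-fold planted effects) whose
condition patterns encode short/mid/long memory genes, RDT-only genes and
plain DEGs. Planted-truth MRG sets are derived *geometrically* from the
plant: a gene is a truth MRG in a contrast iff it is a planted DEG there
and a planted symmetric-context region of the opposite direction overlaps
its promoter — so incidental overlaps with neighbouring promoters are part
of the truth, not noise.

What it does not emulate: read-level data (no FASTQ, no mapping bias, no
conversion failure beyond the error-rate parameter), TE/repeat structure,
spatial autocorrelation of methylation beyond planted regions, unimodal vs
bimodal site-level mixtures (all sites share one Beta per context, which
makes CG mC frequency near 100% rather than the 36–45% of a real genome
with unmethylated fractions), batch effects, or isoform-level expression.
Passing tests therefore demonstrate algorithmic correctness and calibration
under the stated stochastic model, not robustness to the full messiness of
real bisulfite data.

Determinism: one root seed; stage generators are spawned from
`numpy.random.SeedSequence`, and the pipeline manifest records seed,
thresholds and per-stage counts but no timestamps or paths, so a rerun with
the same seed is byte-identical.

## Problem sizes

The bundled benchmarks run at the sizes the validation claims refer to:
10 000 random tables for the Fisher oracle; 200 randomized ≤ 30-site
contigs for the DMR reference; a 1-Mb genome with 50 planted 8-site regions
(Δ = 0.4, coverage 30) plus a matched null for recovery; the full default
study (≈ 500 k cytosines, 200 genes, 13 conditions) for truth-recovery,
generator-fidelity and determinism checks; 20 × 2000-gene null DE
simulations and 100 × 1000-gene null correlation draws for calibration.

## Known limitations

* The DMR rule at raw alpha is liberal by construction; users wanting
  genome-wide error control should filter the emitted regions (the BED
  score column carries −log10 p) or tighten `dmr_alpha`.
* The built-in DE test is a moment-based approximation; for publication-
  grade DE, import a dedicated tool's table.
* Promoter/flank intervals may overlap neighbouring genes on dense
  contigs; no masking is attempted (matching the plain interval logic of
  the original analysis).
* mC calling against a fixed error rate ignores context-specific
  non-conversion differences.
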