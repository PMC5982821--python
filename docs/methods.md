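# Methods

## Scope and model

`temex` quantifies how context-specific DNA methylation pathways (CMT → CHG,
RdDM → CHH) silence maize genes and TE families. The statistical object is a
matrix of fragment counts over genes and TE families per library, paired with
per-context 100-bp-tile methylation levels per genotype. The package's
contributions are the counting rules for repetitive elements, the
threshold-based calling (DE, DMR, mCHH island) and the association layer;
read trimming and alignment are out of scope (inputs are SAM-convention
records and methratio-style per-cytosine call tables).

## Annotation resolution

TE annotations are nested. Counting requires each base to have a unique
owner, so overlaps are resolved with a deterministic priority: the shorter
element wins contested bases, ties broken lexicographically by element id.
The rationale is biological — nested insertions are younger elements that
physically interrupt the older copy — and practical: the rule is
order-independent and idempotent. Helitrons are removed before resolution
(they capture fragments of other elements and would absorb reads spuriously).
Exon bases are then subtracted from TE ownership, and elements whose every
base disappears stay in the family index flagged `fully_masked`, so family
sizes are unaffected by masking. Coordinates are 0-based half-open
internally; GFF3 conversion happens at the I/O boundary only.

## Read assignment

A fragment (mate pair merged by read id and hit index) is unique with one
reported hit, multi with 2–20; improperly paired fragments and fragments
with more than 20 hits are dropped. On real SAM input, MAPQ ≥ 50 or NH = 1
marks uniqueness, mirroring a `samtools -q 50` filter. Overlap means ≥ 1 bp
intersection with an owned interval; counting is unstranded.

Gene counting is union mode over unique fragments: exactly one gene's exons
overlapped → count; two or more → ambiguous, uncounted. For TE counting, any
fragment with a hit touching a gene exon is excluded (`gene_te_conflict`) —
this is the strictest reading of excluding gene-overlapping reads from TE
expression, chosen to keep gene transcription out of TE counts; it is a
configurable classification in the assignment audit, not a silent drop.
Unique fragments on TE bases credit the element (and its family's
`unique_count`); multi fragments credit a family only when all
TE-overlapping hits fall in that family; hits in two families are ambiguous
and counted nowhere — no fractional (EM-style) allocation is attempted,
matching the discard-ambiguous design of the counting rules themselves.

RPM normalizes to the library's gene + TE family total (not raw library
size), so gene and family RPMs share a denominator and column sums are 10⁶.

## Differential expression

The NB model has variance μ + αμ². Size factors are median-of-ratios over
features with all-positive counts (falling back to total-count ratios).
Per-feature dispersion is method-of-moments from the pooled within-group
variance, clipped at 0, then shrunk toward the experiment-wide mean
dispersion with weight `df_data / (df_data + 20)` — with three replicates a
raw moment estimate has 4 df and is far too noisy for a plug-in Wald test
(chance underestimates inflate type I error to ~0.12; a t reference instead
destroys power because p-values cannot get small at 4 df). The moderation
plays the role dispersion shrinkage plays in the standard count-based DE
packages. The Wald statistic on log fold change (pseudo-count 0.5 in the
ratio) uses a normal reference; measured on seeded synthetic nulls
(2,000 features, 3 vs 3, α = 0.1) the fraction of p < 0.05 is 0.043–0.062,
and planted |log₂FC| = 2 at base mean ≥ 100 is recovered through the
two-contrast consistency rule at ≥ 93 % with no false consistent calls
(these are the quantities `scripts/acceptance.py` recomputes). Raw, not
shrunken, fold changes are compared to the cutoff. FDR is Benjamini–
Hochberg; all cutoffs are strict inequalities. The 40-Mb linked-locus
exclusion applies to genes only — TE families are not point-localized — and
contrasts without a declared locus (non-introgressed backgrounds) pass
through with a warning.

## Methylation tiles, DMRs, islands

Tiles are fixed 100-bp windows per chromosome, the final partial tile
retained. Each called cytosine is its own site (no strand-pairing of
symmetric CG/CHG positions, matching methratio-style output); tile level is
read-weighted: Σ mC / Σ total over the tile's sites in that context.
"2× coverage" is interpreted as mean reads per covered site within the tile
(> 2), required in both genotypes, as is the > 6 site gate — including for
CHH DMRs (the both-genotype requirement was an open choice; requiring both
makes calling symmetric and conservative). "Informative reads" for islands
is the tile's total CHH read count. Boundary comparisons round levels and
differences to 9 decimals first, so a difference of exactly 60.0 points (or
a level of exactly 25 %) is never called despite binary floating-point
representation; thresholds stay strict.

The panel catalog unions reference-vs-genotype pairwise DMRs, deduplicated
by (tile, context) with the contributing genotype pairs retained.

## Association layer

Metaprofiles anchor 100-bp bins at the TSS and at the TTS with 2-kb flanks,
strand-flipped for − genes; gene bodies are sampled in absolute coordinates
(no per-gene rescaling), so short genes contribute to fewer body bins — bin
width is a display choice, and absolute tiles keep the profile faithful to
tile data. The TSS methylation class uses the read-weighted mean over
[TSS, TSS+400) in the transcribed direction: high > 50 %, low < 20 %.
Island proximity is any island tile intersecting the feature span ± 2 kb;
DMR-near-TSS is any DMR tile intersecting [TSS−200, TSS+200). Enrichment is
a 2×2 χ² without continuity correction (counts in intended use are large;
zero expected cells raise an error pointing at exact tests), and
"enriched" additionally requires the set proportion to exceed background.
Epiallele detection is a two-sided Pearson correlation between DMR
methylation and expression across ≥ 4 genotypes; zero-variance vectors are
flagged undefined rather than significant.

## TE family characterization

Size classes: single, small 2–9, medium 10–99, large ≥ 100 members. Mean
LTR similarity is averaged over members of LTR superfamilies only and read
from the annotation (recomputing it would require alignment, out of scope);
GC likewise comes from the annotation or sequence when provided. Distance to
the nearest gene is 0 for overlapping elements. Subset-vs-genome attribute
comparisons use Welch's t-test at p < 0.01. A family's expression pattern is
testable when it has < 10 members and ≥ 50 % of its reads are unique;
`locus_specific` requires one element to hold ≥ 90 % of the unique reads
(the dominance threshold is a package choice, exposed as a parameter —
descriptions of single-member expression give no number) else `coordinate`.

## Synthetic data: what it emulates, what it does not

The generator builds 2 × 300-kb chromosomes (defaults), 60 non-overlapping
genes with 1–3 exons, 20 TE families of exactly `copies_per_family` = 4
copies plus helitrons (~5 % of elements), with ≥ 1 nested insertion pair and
≥ 1 element overlapping a gene exon. Family copies are conceptually exact
sequence duplicates: a shared-body read reports one equally scored hit per
copy (inside intervals the copy still owns), which exercises the assignment
logic without simulating an aligner. A configurable fraction (0.30) of TE
reads instead maps uniquely to one element, standing in for junction/flank-
context reads — with exact copies no body read could ever be unique, yet
element-level analyses require unique reads to exist. Element choice for
unique reads follows a sparse Dirichlet, so single members often dominate.

Counts are NB with α = 0.1 (common RNA-seq practice; variance μ + αμ²) and
planted log₂ fold changes of ±2 applied to the mutant side, planted
baselines kept ≥ 100. Methylation backgrounds are CG 0.80 / CHG 0.65 /
CHH 0.02 with ~8/8/12 sites per 100-bp tile and Poisson(6) per-site coverage.
Planted DMR defaults are CG/CHG 0.85 vs 0.10 and CHH 0.005 vs 0.45, islands
CHH 0.40: each planted level clears its calling gate by ≥ 3 σ of binomial
sampling noise at the default coverage, so recovery tests measure the
caller's logic rather than the noise floor. The epiallele panel plants
bimodal methylation (≈ 0.90 vs ≈ 0.05) with expression silenced on the
methylated side, plus independent null genes.

Not emulated: sequence-level reads, bisulfite conversion chemistry, mapping
error, strand-specific library artifacts, dispersion trends over expression,
and correlated replicates. Passing tests therefore demonstrate correctness
of the counting, calling and association logic under the stated noise
models — not robustness to alignment artifacts in real libraries.

## Problem sizes and determinism

Validation runs use 50,000 read pairs per dataset, 2,000-feature DE tables,
1-Mb chromosomes for the per-base bitmap checks, and 10-genotype panels with
100 planted and 200 null epiallele genes — sizes chosen so the whole suite
and the acceptance script each run in minutes on one CPU while keeping
binomial/NB noise small relative to the planted effects. Every generator
draws from `numpy` Generators seeded as `[seed, stream]`, one stream per
stage, so outputs are byte-identical under a fixed seed and adding reads in
one stage never reshuffles another.

## Known limitations

- The DE engine is a deliberately simplified NB Wald test: no trended
  dispersion over expression strata, no outlier handling or independent
  filtering; its calibration is demonstrated under the generator's constant-α
  conditions.
- The overlap-priority rule (shorter element wins) is one defensible
  resolution; annotations resolved by other tools may assign contested bases
  differently, changing element-level (not family-level) counts.
- Gene-exon-touching reads are wholly excluded from TE counting; a laxer
  hit-level exclusion would retain more multi-mapped TE reads near genes.
- χ² enrichment is inappropriate for very small flag tables; the error
  message points at exact tests, which are not implemented.
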