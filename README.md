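# temex

Gene and transposable-element (TE) family expression analysis for maize DNA
methylation mutants, with tile-based methylome analysis to connect expression
changes to context-specific methylation.

## The problem

Maize mutants of the chromomethylase genes (*Zmet2*, *Zmet5*; maintaining CHG
methylation) and of RdDM components (*Mop1*, *Mop3*; establishing CHH
methylation) perturb the methylome only mildly, so the genes and TE families
they de-silence must be separated from noise, from introgressed flanking
variation, and — for TEs — from the pervasive multi-mapping that repetitive
sequence causes. `temex` implements that analysis chain as a tested library
and CLI:

- **annotation** — builds the disjoint counting annotation: helitrons removed,
  every base owned by exactly one TE element (nested/shorter insertions win
  contested bases), exons subtracted from TE ownership, gene exons merged in.
- **quantify** — hierarchical read assignment: properly-paired unique reads
  (1 hit) count toward gene exons in union mode or toward individual TE
  elements; multi-mapped reads (2–20 hits) count toward a TE family only when
  every TE-overlapping hit lands in that one family; reads touching both gene
  and TE annotation are excluded from TE counting. Family count =
  unique + multi; RPM = count / (gene reads + TE family reads) × 10⁶;
  a feature is expressed when RPM > 1 in ≥ 3 libraries.
- **diffexpr** — per-contrast negative-binomial Wald test (median-of-ratios
  size factors, moderated method-of-moments dispersion), BH FDR; a feature is
  DE when FDR < 0.05 and |log₂FC| > 1, analysis is restricted to features
  called in the same direction in ≥ 2 contrasts of the same pathway
  (CMT or RdDM), and DE genes within 40 Mb of a backcrossed mutation locus
  are excluded as linked.
- **methylation** — per-cytosine calls summarized into 100-bp tiles per
  context (CG/CHG/CHH). DMRs need > 6 sites and > 2× mean site coverage in
  both genotypes plus > 60 percentage-point difference (CG/CHG) or
  < 5 % vs > 25 % (CHH). mCHH islands are tiles with CHH > 25 % on ≥ 10
  informative reads.
- **association** — strand-aware TSS/TTS methylation metaprofiles, gene
  classification by methylation in the first 400 bp past the TSS
  (high > 50 %, low < 20 %), island proximity within the feature ± 2 kb, DMRs
  within ± 200 bp of the TSS, χ² enrichment (p < 0.01), and Pearson
  correlation of DMR methylation with expression across a genotype panel
  (p < 0.05) to detect natural epialleles.
- **te_features** — family size classes (single / small 2–9 / medium 10–99 /
  large ≥ 100), LTR-similarity age proxy, GC content, distance to genes,
  Welch t-tests against the genome-wide distribution, and locus-specific vs
  coordinate expression for small families with ≥ 50 % uniquely assigned
  reads.
- **synthetic** — seeded generators (toy genome, nested/overlapping TE
  annotation, alignments with up to 20 hits per read, NB counts, per-cytosine
  methylation) with planted truth, so every stage is validated end to end
  without downloads.

## Worked example

```bash
temex demo --outdir demo_out
```

runs the whole pipeline on the synthetic dataset (seed 0: two 300-kb
chromosomes, 60 genes, 20 TE families × 4 copies plus helitrons, 50,000 read
pairs, two mutant contrasts with three replicates per side, two genotypes of
methylation calls) and prints

```
demo complete: 23 outputs in demo_out
```

Among the outputs: `dmrs.bed` contains exactly the six planted DMRs, e.g.

```
chr1   91800   91900   CHH   42.4   .
chr1  184600  184700   CHG   72.7   .
chr1  292400  292500   CG    80.5   .
```

(the score column is the methylation difference in percentage points —
72.7 > 60 is why the CHG tile is a DMR), `islands.bed` the four planted mCHH
islands, `consistent_de.tsv` the features up/down in both contrasts, and
`manifest.json` a checksum per output: rerunning with the same seed
reproduces every file byte for byte.

The same stages are available individually (`temex simulate`,
`resolve-annotation`, `quantify`, `de`, `methyl`, `associate`,
`te-features`, `run-all`) on user-supplied GFF3/SAM/TSV inputs.

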