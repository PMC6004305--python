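# bsmeth

Whole-genome bisulfite sequencing (WGBS) methylome analysis for plant
genomes: cytosine-context enumeration, methylation extraction from
bisulfite alignments, genome-scale landscape summaries, differentially
methylated region (DMR) detection, and integration of DMRs with gene
expression and 24-nt siRNA loci — plus a synthetic bisulfite-data
generator with machine-readable ground truth.

The package is aimed at analysts reproducing or stress-testing the
classic plant WGBS workflow: the kind of study that profiles an
allotetraploid crop at ~27x depth across developmental stages without
biological replicates, and asks which genes gain or lose methylation
between stages.

## The analysis in brief

Sodium bisulfite converts unmethylated cytosine to uracil (read as T)
while 5-methylcytosine resists, so at each reference cytosine the
fraction of aligned reads retaining C estimates its methylation level.
Plant cytosines are classified by the two bases 3' of the C on its own
strand — CG, CHG, CHH with H ∈ {A, C, T} — because distinct pathways
maintain each context. `bsmeth` computes, per site and per sample:

* **level** = n_C / (n_C + n_T) over informative reads, and a binary
  methylation call via a one-sided binomial test against the bisulfite
  conversion-failure rate (P(X ≥ n_C | n, r) ≤ α);
* **landscapes** — per-context methylated fractions, level histograms of
  methylated sites, 9-bp neighbourhood base composition, and metagene
  profiles (2-kb flanks in 100-bp bins, bodies rescaled to 20
  proportional bins), optionally stratified by RPKM class;
* **DMRs** between two samples per context. Every emitted region
  satisfies five criteria: (a) ≥ 5 methylated cytosines in at least one
  sample, (b) mean per-site depth > 10 reads in both samples, (c)
  adjacent methylated sites < 200 bp apart, (d) length within
  [40, 10000] bp, and (e) pooled methylation-level fold change ≥ 2 with
  Pearson χ² p ≤ 0.05 on the pooled 2×2 read-count table,
  χ² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d));
* **integration** — DMRs assigned to up2k/body/down2k zones of genes and
  TEs, intersected with differentially expressed genes
  (|log2FC| > 1, FDR < 0.05), and overlapped with 24-nt siRNA loci.

The simulator emulates the study regime these pipelines face: mCG/CG ≈
0.81 and mCHG/CHG ≈ 0.64 with site levels mostly above 90%, mCHH/CHH ≈
0.05 with broad 10–40% levels, Poisson ~27.5x depth, 0.5% conversion
failure, and stage-specific spiked DMRs of known fold — so every claim
the pipeline makes can be scored against truth.

## Worked example

Run the default synthetic study (200-kb genome, two samples, spiked
DMRs) and call DMRs:

```sh
bsmeth run --seed 11 --outdir demo
```

which reports `pipeline complete; 31 outputs in demo`. Key outputs:

* `demo/global_fractions_sample_a.tsv` — per-context methylated-site
  fractions. For seed 11 the CG row reads
  `n_covered=11586  n_methylated=9334  fraction_covered=0.8056`, i.e.
  80.6% of covered CG sites are methylated (the configured regime is
  0.81), with CHG at 0.645.
* `demo/dmrs_sample_b_vs_sample_a.tsv` — called DMRs with pooled counts,
  levels, fold change, χ², p and hyper/hypo direction (for seed 11: 40
  DMRs — 21 CG, 18 CHG, 1 CHH). The first row,
  `chr1 3246 4298 CG … level_a=0.277 level_b=0.716 fold_change=2.58
  chi2=732.9 p=2.0e-161 direction=hyper assoc=down2k:gene004`, marks a
  region whose CG methylation in sample B is 2.6-fold higher than in
  sample A, overlapping the downstream 2-kb zone of gene004.
* `demo/dmr_zones_sample_b_vs_sample_a.tsv` — context × zone
  (up2k/body/down2k) DMR counts.
* `demo/truth.json` — the spiked-region ground truth for scoring.

Each stage is also available separately (`bsmeth sim`, `bsmeth context`,
`bsmeth extract`, `bsmeth landscape`, `bsmeth dmr`, `bsmeth integrate`,
`bsmeth validate`), all driven by the same YAML config.

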