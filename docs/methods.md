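# Methods

This note documents the models, conventions and numerical choices behind
`bsmeth`, and what its synthetic benchmark does and does not establish.

## Coordinates and contexts

All interval arithmetic is 0-based half-open internally; single-position
text reports (cytosine report, count tables, truth levels) are printed
1-based, and interval files are BED. A cytosine's context is the two
bases 3' of it on its own strand: CG if the first downstream base is G
(the second base is irrelevant and may even be missing); CHG/CHH need
both bases; any undecidable position (N, ambiguity code, or sequence
end where a decision is still pending) is NA and excluded from every
downstream denominator. Reverse-strand cytosines (reference G) read
their context on the reverse complement. The 9-bp neighbourhood is
reported 5'→3' on the cytosine's strand with the C at offset 4, N-padded
at sequence ends. CG sites on the two strands of a palindromic CG are
kept separate throughout (a merge would halve CG counts and is not what
per-cytosine reports conventionally do); the DMR caller likewise treats
them as independent sites.

## Extraction and binary calls

A read is informative for forward-strand sites when it derives from the
Watson-converted bisulfite strand (XG tag `CT`; inferred from FLAG
orientation of a directional library when untagged) and for
reverse-strand sites when Crick-converted (`GA`). Bases are compared in
reference orientation: C/T at forward sites, G/A at reverse sites;
anything else feeds an `n_other` channel that never enters levels.
Reads below MAPQ 10 and duplicate-flagged reads are skipped (both
configurable). When proper-pair mates overlap, each fragment contributes
one observation per site and the mate with the higher base quality at
that position wins — overlapping mates are the same molecule, and double
counting would manufacture precision.

The binary methylation call defaults to a one-sided binomial test of
n_meth successes in n_meth+n_unmeth trials against the conversion
failure rate r (default 0.005, α = 0.05, no multiple-testing
correction): a site is methylated when apparent methylation is unlikely
to be conversion failure alone. At 27x this means ≥ 2 methylated reads,
giving a per-site false-call rate of ~0.8% — small, but it visibly
inflates the called fraction of a context that is only ~5% methylated
(CHH), which is why the summary tables report both covered-site and
all-site denominators and why the estimator-recovery benchmark is run
with conversion failure disabled. A permissive "any methylated read"
mode exists for comparison; with r = 0 the binomial mode reduces to it.

## Landscape summaries

Level histograms are taken over methylated (called) sites only, in ten
right-closed bins over (0, 1]; a called site always has level > 0, so
bin edges need no zero bin. Metagene profiles use exact 100-bp flank
bins oriented 5'→3' (20 per 2-kb flank) and 20 proportional body bins.
Body binning distributes each 1-bp site over the bins it overlaps with
integer overlap weights (site interval scaled by the bin count): unlike
midpoint assignment, this makes strand-flip symmetry exact in integer
arithmetic even at bin-edge ties, and per-bin sums use exactly-rounded
summation (`math.fsum`) so mirrored profiles are bit-identical. Per-bin
values pool sites across features (site-weighted); the reported site
weights let a zone mean be reconstituted exactly, and the alternative
per-gene-then-average convention can be layered on top if needed. Empty
bins are NaN with zero weight, never silently zero. Expression classes
partition RPKM as none ≤ 1 < low ≤ 10 < medium < 100 ≤ high; only the
outer boundaries are well attested for this study design, so the
interior boundary at 10 is a declared convention.

## DMR calling

Every emitted region satisfies the five criteria listed in the README:
≥ 5 methylated sites in at least one sample, mean per-site depth
strictly > 10 in both samples, adjacent methylated sites strictly
< 200 bp apart, span (first to last site, inclusive) within
[40, 10000] bp, pooled fold change ≥ 2 and Pearson χ² (df 1, no
continuity correction) p ≤ 0.05. Interpretive choices the criteria
leave open:

* "Difference in methylation levels at least two" is read as a ratio of
  pooled region levels; a zero level is floored at 1/(pooled reads + 1)
  so a fully unmethylated sample can be called against without infinite
  folds. An absolute-difference mode (≥ 0.2) is available by flag.
* The depth rule is applied as mean per-site depth over covered context
  sites in the region, per sample; a strict per-site variant would be
  far more conservative and is left to configuration.
* No multiple-testing correction by default (the criterion is a raw
  p ≤ 0.05); Benjamini–Hochberg across candidates is available by flag.

Candidate search: regions are maximal chains of seed cytosines with all
adjacent gaps < 200 bp. The default seed set is the differential one —
sites methylated in ≥ 1 sample, covered in both, with per-site χ²
p ≤ 0.01 — and chains additionally split where the sign of the per-site
level difference flips, so a region is a run of consistent differential
signal. This is the standard DMC→DMR construction, and it is what makes
regional differences localisable in a context where ~80% of sites are
methylated: chains of *all* methylated sites in such a context merge
into chromosome-scale runs that no 10-kb ceiling can represent. For
sparse methylomes an `all_methylated` seed mode reproduces the literal
methylated-site chaining. Either way the five criteria are re-checked on
the emitted regions against the full methylated-site sets, and an
independent audit routine (`audit_dmrs`) recomputes all five from raw
count tables. Hyper/hypo labels describe the second-listed sample of the
comparison "B:A" relative to the first. The per-site seed α = 0.01 was
chosen so that, under the null, seed sites are rare enough (~1 per
couple of kb) that chains seldom bridge beyond a true region; it is a
sensitivity/precision dial, not a significance claim.

Association assigns a DMR to every (feature, zone) it overlaps by
≥ 1 bp, zones being strand-oriented up2k (2 kb upstream), body, and
down2k; the one-row-per-DMR summary takes the highest-priority zone
(body > up2k > down2k) and the context × zone table counts each DMR
once.

## Simulator

The generator's defaults are the study conditions the pipeline is meant
for: a 200-kb two-chromosome genome at GC 0.34; 20 non-overlapping
stranded genes (0.8–3 kb, ≥ 2 kb clearance, 1–4 exons) and 20 TEs in
four classes (LTR/LINE/SINE/simple, 40/25/20/15%); per-context
methylated-site probabilities 0.81/0.64/0.05 (CG/CHG/CHH); site-level
distributions Beta(45,2) ⊕ Beta(2,2) mixtures for CG (80% high
component) and CHG (70%) and Beta(2,6) truncated below 0.05 for CHH;
Poisson depth with mean 27.48; conversion failure 0.005; sequencing
error 0 by default (a flat substitution rate can be enabled and feeds
`n_other`). Spiked DMRs (20 CG, 15 CHG, 10 CHH per comparison; fold
2.5; spans 200–2000 bp; pairwise disjoint; each required to contain ≥ 5
context sites) act by dividing one sample's levels by the fold — the
lowered sample is B for "hypo" spikes and A for "hyper" — which realises
the configured fold exactly without clipping at 1. An optional
expression coupling sets CHG gene-body levels to ~0.3 for unexpressed
and ~0.05 for expressed genes to reproduce the qualitative
unexpressed-gene CHG elevation; it is off by default so the two samples
differ only through spikes.

Reads, when requested, are 125-bp proper pairs with 250–400 bp inserts
(mates never overlap), each fragment converted on one genome strand
drawn uniformly, emitted pre-aligned with exact coordinates, 125M
CIGARs and XG tags — alignment itself is out of scope, and pre-aligned
emission lets the extractor be tested for exact count reproduction
against the very draws that built the reads.

What the simulator does **not** emulate — and what green tests therefore
do not establish about real data: mappability and coverage bias (its
coverage rate is ~100%, where a real plant genome at 27x shows ~90%),
M-bias along read positions, PCR duplicates, quality-dependent errors,
chromosome-scale methylation gradients, and biological replication (the
mirrored study design had none, so the χ² test treats read sampling as
the only noise source — exactly as fragile on real data as in the
original design). CHH spike recovery is intrinsically poor at fold 2.5
and 27x — per-site differences of 0.2 vs 0.08 are rarely significant —
mirroring the order-of-magnitude-lower CHH DMR counts such studies
report; the recovery benchmark is therefore scored on CG.

## Problem sizes in the benchmark suite

The end-to-end benchmark tests use 1,000 random 1-kb sequences for the
context oracle, the default 200-kb study for extraction round-trip,
fraction recovery and histogram shape, 200 random ≤ 5-kb instances for
the chain oracle, 50 15-kb comparisons for the five-criteria audit, ten
200-kb studies for spike recovery, 10,000 random tables for the χ²
closed form, and 100 random feature sets for the metagene invariants —
sizes chosen so the full suite runs in well under a minute while keeping
every Monte-Carlo margin comfortable.
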