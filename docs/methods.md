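# Methods

## Problem and scope

`exoncnv` implements an exon-resolution somatic copy-number caller for
tumor/normal whole-exome pairs, together with the somatic SNV/indel filter
cascade and summary statistics that typically accompany such an analysis
(mutation rate per Mb, CpG-context transition/transversion rates, gene x
sample recurrence tables, and comparative-Ct qPCR verification of
amplifications). It starts from per-region depth tables and candidate
variant tables — read alignment, variant calling and functional annotation
are upstream tools' jobs and are consumed as inputs.

## Copy-number model

The pipeline proceeds in five stages:

1. **Capture-region preparation.** Exon capture intervals are merged into
   their per-base union (intervals sharing at least one base, or touching
   end-to-start, are merged — probes tile contiguously, so book-ended
   intervals are treated as one region). Regions with GC fraction above a
   threshold (default 0.65) or overlapping a supplied CpG-island BED by at
   least one base are excluded, because PCR amplification, hybrid capture
   and sequencing are systematically biased at high GC. N bases are
   excluded from the GC denominator. No threshold is canonical here; 0.65
   sits above typical exonic GC and below CpG-island GC, and it is
   configurable.

2. **Depth ratios.** For each surviving region j with normal depth at or
   above a floor (default 10x, matching the variant-side coverage floor),
   the ratio r_j = tumor_depth_j / normal_depth_j is computed. Zero tumor
   depth is a legal ratio of 0 (deep deletion), not an error. Optional
   library-size normalization rescales by (total normal)/(total tumor);
   it is **off by default** because the mode-to-ploidy rule below reads
   absolute tumor DNA content out of the ratios, which rescaling erases.

3. **Density mode, ploidy, purity correction.** A Gaussian KDE (Silverman
   bandwidth by default, 512-point grid spanning [0, max ratio + 3h]) is
   fitted to the ratios; the grid value of its global maximum (ties to the
   smaller ratio) is the modal ratio. Since the most common copy state
   dominates the genome, overall ploidy is psi = 2 x mode (a mode of 1.05
   gives psi = 2.1). With tumor purity alpha (malignant cell fraction),
   the expected ratio for copy number c is

       r = (alpha * c + 2 * (1 - alpha)) / 2,

   and each ratio is inverted into a continuous copy number

       c_j = (2 * r_j - 2 * (1 - alpha)) / alpha,

   clipped at 0 because noise can push ratios below the contamination
   floor 1 - alpha. Purity is a user input (default 1.0). As an optional
   extension, `estimate_purity_from_peaks` exploits the fact that
   consecutive integer copy states are spaced alpha/2 apart in ratio
   space: alpha-hat = 2 x median spacing of adjacent density peaks (peaks
   at >= 10% of the maximum, with a small prominence floor). This
   requires at least two resolvable peaks; see *Numerical behaviour*.

4. **Segmentation and calls.** Corrected copy numbers are segmented per
   chromosome by recursive binary segmentation: the candidate breakpoint
   maximizing |mean_L - mean_R| / (s_p sqrt(1/n_L + 1/n_R)) is accepted
   when the statistic reaches a threshold (default 5) with at least
   `min_regions` (default 3) on each side, then both halves recurse. A
   zero pooled variance with unequal means is an infinite statistic (a
   noiseless step always splits); a constant series never splits.
   Segments take the mean copy number of their members; the integer state
   is round-half-up, clipped at 0. Calls against a baseline (diploid by
   default; pass round(psi) for ploidy-relative calling): deletion
   (integer CN <= 0), amplification (>= 5), loss (< baseline), neutral
   (= baseline), gain (> baseline); deletion and amplification take
   precedence. The amplification floor of 5 copies separates focal
   high-level events from ordinary gains; it is a configurable convention,
   not a biological constant. Genes are assigned the call of the segment
   with maximal base overlap (ties to the earlier segment); genes
   overlapping nothing are omitted and counted. The segmentation engine is
   this package's own; the defaults (threshold 5, min_regions 3) were
   fixed against the bundled simulator's noise level at 80-100x coverage.

5. **Somatic filter cascade.** Candidate variants pass a fixed-order,
   first-failure rule chain: exonic/splice region; >= 10x depth in both
   tissues; normal alt reads < 3 (strict); tumor alt reads > 3 (strict);
   tumor genotype quality >= 40 (Phred); indels additionally need >= 4
   supporting reads and an alt fraction >= 0.05 of tumor depth; known
   germline polymorphisms (dbSNP/1000G/GWAS membership flag) are removed
   unless the site is also in COSMIC. The "< 3 / more than 3" thresholds
   are read counts — a frequency cannot meaningfully be 3. The rule order
   is a package choice (cheap checks first); because rejection is
   attributed to the *first* failing rule, an indel with 3 supporting
   reads is logged under the tumor-alt rule even though it would also fail
   the indel-support rule. The per-rule report always conserves totals
   (input = passing + malformed + sum of rejections).

## Summary statistics

Mutation rate is n / (target Mb), with the denominator the **post-merge,
post-exclusion** capture target (recorded in the output metadata). A base
is CpG-context when it is the C of a reference-strand CG dinucleotide or
the following G; context is evaluated on the whole chromosome, so a CG
straddling a region edge still marks its in-target base. CpG rates divide
CpG-context SNVs (split into transitions and transversions) by CpG-context
megabases; with zero CpG bases the rates are undefined and reported as
such. Group summaries are unweighted means of per-sample rates.
Recurrence matrices resolve multi-hit gene/sample cells by precedence
stop-gain > indel > missense. qPCR fold change is 2^(-ddCt) with
dCt = Ct_target - Ct_reference per tissue and ddCt = dCt_tumor - dCt_normal.

## Synthetic data

The simulator generates the full input set from one seed (byte-identical
outputs per seed): a two-chromosome 1 Mb toy genome with 20 kb GC blocks
cycling through {0.35, 0.45, 0.55}, CG-rich islands (expected GC ~0.88)
recorded as a BED, ~5,000 capture regions of 120 bp at 80 bp spacing, and
a default copy-number truth with a triploid block, a 6-copy focal
amplification carrying an FGF19-analog gene, and a single-copy loss
carrying a TP53-analog. Depths are Poisson: normal ~ Poi(D g(gc)),
tumor ~ Poi(D g(gc) r) with D = 97 (a realistic mean exome target depth),
g(gc) = max(0.1, 1 - 2 (gc - 0.4)^2) the unimodal GC-bias curve, and r
the admixture-model expected ratio; optional gamma overdispersion gives a
negative-binomial marginal. Variant tables plant 200 records across
categories covering every cascade rule (e.g. depth 9, normal alt 3, GQ
39, indel fraction 0.04) plus CpG-context transitions/transversions and
COSMIC-rescued sites; allele counts are Binomial(depth, v) with
v = alpha m / (alpha c + 2 (1 - alpha)) for m mutated copies. Every
record's pass/fail label and first failing rule are recorded in the truth
from its realized fields, so borderline stochastic draws are labelled
consistently. qPCR tables shift the tumor target Ct by -log2(k) with
configurable cycle noise.

What the simulator does **not** emulate: mappability and alignment
artifacts, replication-timing and fragment-size coverage waves, subclonal
heterogeneity, sequencing error in allele counts, genotype-likelihood
models behind GQ (GQ is assigned, as the cascade consumes it), and linked
germline haplotypes. Passing recovery tests therefore demonstrates
correctness of the algorithms under their stated model, not robustness to
every artifact of real libraries.

## Numerical behaviour and problem sizes

- KDE: Silverman bandwidth (3n/4)^(-1/5) x sd; an all-identical ratio
  series falls back to a direct kernel evaluation with a small fixed
  bandwidth. The density integrates to 1 within 1e-3 on the truncated
  grid for ratio distributions bounded away from 0.
- Mode precision is one grid step (~0.004 for typical ratio ranges);
  ties break toward the smaller ratio.
- Peak-spacing purity estimation needs the per-state ratio clusters to be
  bimodal: the cluster sd ~ r sqrt(2/D) convolved with the KDE bandwidth
  must stay under half the spacing alpha/2. At alpha = 0.4 (spacing 0.2)
  this requires roughly D >= 330; the recovery checks use 500x with four
  copy states of 1,000 regions each. At routine 80-100x depth the helper
  is unreliable below alpha ~ 0.6 and purity should be supplied.
- The mode-based ploidy estimate carries a small downward bias (~0.05-0.1
  copies at 80x) when flanking copy states are populated: KDE smoothing
  lets the tighter low-ratio cluster pull the argmax left. Recovery
  checks use majority-state profiles at 80x, 5,000 regions.
- Segmentation checks use 1,000-region, 3-segment profiles at 80x over 50
  seeded replicates; end-to-end checks run the full pipeline on ten
  ~5,000-region replicates at purity 0.8. These sizes keep each check in
  seconds while leaving Monte-Carlo margins wide.
- Round-half-up integerization (floor(x + 0.5)) avoids banker's-rounding
  asymmetry at .5 boundaries.

## Known limitations

- Ploidy is anchored to the density mode; genomes whose most common state
  is not the majority by a clear margin (or with mode ambiguity between
  two equally common states) need manual review of the density table.
- No BAF/allele-fraction information is used, so purity/ploidy pairs that
  are ratio-equivalent cannot be disambiguated.
- Binary segmentation with a pooled-SE t statistic assumes roughly
  constant within-segment variance; very short high-amplitude events
  narrower than `min_regions` are invisible by construction.
- The cascade enforces "absent in normal" only through the normal alt
  read-count rule; tumor-in-normal contamination is not modelled.
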