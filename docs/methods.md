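# Methods

## Study design being modelled

The pipeline targets a pooled-haplotype design: a large pedigree in which
19 affected relatives co-inherit one susceptibility haplotype (a 33-Mb
segment of chromosome 3 spanning *ROBO1*, chr3:73,842,243–106,990,161,
treated as a closed interval). Two carriers are sequenced individually at
high depth on one platform; an equimolar pool of all 19 is sequenced at
~19× on another. Haplotype-shared variants are heterozygous in every
carrier, so their pooled allele dosage is 19/38 = 0.5 and the observed
alternative-read count at a site of depth *d* is binomial(*d*, 0.5).
Individual genotypes inside the pool are unobservable; only this aggregate
signal is.

## Synthetic-data generator

The generator emits the inputs the analysis consumes — two individual call
sets (VCF with GT/DP/AD), one pooled call set (VCF with DP/AD, no
genotype), a frequency panel, a known-variant catalog, read-pair tables,
Ct tables and phenotype tables — with planted ground truth.

Model choices:

- **Carrier contributions** are exactly equimolar by default (one weight
  per carrier, 1/19 each); a Dirichlet perturbation of the weights is
  available behind `carrier_dirichlet_alpha` for studying unequal pooling.
- **Depth** is Poisson around the configured means (50× individuals, 19×
  pool). Nothing finer than the average depth is assumed about the real
  library, so the simplest count model is used.
- **Population variants** draw their global MAF log-uniformly on
  [10⁻³, 0.5]; ~30% of them get a founder-population ("FIN") MAF
  multiplied by `finnish_maf_enrichment` (default 4), emulating
  founder-enriched variants that a global-frequency filter alone would
  miss. Carrier genotypes are independent binomial(2, MAF_FIN) draws.
  Population variants are members of the catalog; planted haplotype
  variants are novel.
- **Platform errors** are injected as spurious heterozygous calls confined
  to a single platform — the failure mode the concordance steps of the
  cascade exist to remove. Per platform, the number of spurious calls is
  Poisson(rate × `n_error_opportunities`), with 10,000 opportunity sites
  by default; error sites are placed at distinct positions, so a
  three-platform coincidence (the only route to a false survivor) does
  not occur by construction — consistent with its analytic expectation
  (≤ 10⁻⁵ per run at rate 10⁻³). Base-level sequencing error is not
  modelled; calls, not reads, are the unit of simulation.
- **INDELs** are planted as 1–2-bp haplotype-shared events; a configurable
  fraction (default 0.8) is embedded in simulated homopolymer or
  dinucleotide tandem runs, carried in the truth table as a local sequence
  window so repeat triage needs no genome-wide reference.
- **Read pairs** have Normal(350, 30) insert distances; pairs spanning a
  planted deletion of size *s* are shifted +*s*, insertions −*s* (floored
  at a small positive distance). Default planted deletions are 300 bp and
  1600 bp — sizes representative of the events such a scan must detect.
- **Ct tables** encode an intended fold change *f* by raising the
  knockdown target Ct by −log₂(*f*) cycles over its baseline, with
  Gaussian per-replicate noise, so the ΔΔCt readout recovers *f* exactly
  in the noise-free case. Reference genes (GAPDH at Ct ≈ 20, 18S at
  Ct ≈ 12) are unaffected by the knockdown.
- **Randomness** flows from a single seed through fixed stage ids
  (`numpy` generators seeded with `[seed, stage]`), so any stage can be
  regenerated independently and reruns are byte-identical.

What the generator does *not* emulate: alignment and genotype-calling
artefacts correlated across platforms, depth heterogeneity along the
genome (GC, mappability), linkage between population variants, and
multi-allelic sites. Passing tests therefore demonstrate the correctness
of the filtering logic and estimators under the stated statistical model,
not the error profile of any particular sequencing pipeline.

## Filter cascade

Six set-filters in fixed order: region (closed interval), genotype
concordance between the two individuals, presence in the pool (≥ 1
alternative read), heterozygosity in both individuals (dominant
inheritance), founder-population MAF ≤ 5% (boundary retained; a variant
rare globally but common locally is recorded as "population-enriched"),
and novelty (absent from every supplied catalog; the disjunctive
"absent from at least one" reading is available as `novel_mode="any"`).
Variants are keyed by (chrom, pos, ref, alt) after reference-free left
normalization (common suffix then prefix trimming, keeping one base), so
platforms that pad alleles differently intersect correctly.

The INDEL cascade relaxes concordance to *pool + at least one individual*
— INDEL callers disagree more across platforms — and flags surviving
events of ≤ 2 bp inside a repeat run as `likely_neutral`. Repeat
thresholds are ≥ 5 bases for homopolymers and ≥ 3 units for dinucleotide
tandems: conventional microsatellite minimums, configurable since no
single standard exists.

Every input variant ends as either a survivor or exactly one removal
reason (provenance completeness), and step counts are non-increasing by
construction. The cascade produces no p-values; it is deterministic
filtering, so no multiple-testing correction applies.

## Gene-relative annotation

Coordinates are 1-based inclusive throughout (VCF convention). A gene's 5′
anchor is the transcription start: max exon end on the minus strand, min
exon start on the plus strand. Signed distance is `anchor − pos` (minus
strand) or `pos − anchor` (plus strand): positive inside/downstream of the
5′ end, negative upstream. The *ROBO1* anchor (79,817,059) is derived at
run time from a published intronic position/distance pair rather than
hard-coded as an annotation fact, and reproduces all four published signed
distances; the surrounding exon placeholders in the fixture model are
synthetic and only shape region classification. Classification precedence
is exonic (coding / 5′UTR / 3′UTR by coding-span orientation) > intronic >
upstream (within the window, gene orientation) > intergenic. Upstream
variants additionally carry the display label "Intergenic", matching the
summary-table convention of reporting fine and coarse classes separately.

## Pooled model

AAF = alt_count/depth, displayed with half-up rounding to 2 decimals. The
consistency check builds the central 95% interval of AAF under
binomial(depth, expected) — Monte-Carlo with 10,000 replicates and a
recorded seed by default, exact binomial quantiles as the deterministic
alternative — and reports an inside/outside verdict. The interval width
shrinks as 1/√depth. Coverage summaries report the fraction of positions
with depth ≥ {5, 10, 20, 30}, monotone non-increasing by construction.

## SV scan

Insert statistics are the median and MAD×1.4826 (robust to the discordant
pairs themselves). Pairs with |distance − mean| > z·sd are discordant
(z = 4 by default, chosen for near-zero false positives at desk scale:
2Φ(−4) ≈ 6·10⁻⁵ per pair); deviation sign separates deletion-like from
insertion-like. Same-sign pairs within `max_gap` (default: the insert
mean) of each other join one single-linkage cluster; clusters with
support ≥ `min_support` (default 3) become candidates with size = mean
|deviation| and interval = the outer span of the supporting pairs (inner
breakpoint spans of few pairs can be empty, so the conservative outer span
is reported). Orientation anomalies (inversions) are not typed or
assembled.

## Expression

ΔCt normalizes the replicate-averaged target Ct against the geometric mean
of the reference genes' mean Cts — the literal form of the stated
normalization; the arithmetic-Ct variant (equivalent to a geometric mean
on the expression scale) is available via `method="arithmetic_ct"` and
differs only when reference Cts diverge. ΔΔCt = treated − control, fold
= 2^−ΔΔCt; fold 0.5 ⇔ ΔΔCt = 1 (the half-expression knockdown scenario).
Replicates are averaged before ΔCt. The phenotype trend uses Spearman rank
correlation between expression and the ordinal deficit score with a
seeded 10,000-permutation null interval; constant input yields an
explicit "undefined" verdict rather than a silent zero.

## Problem sizes and determinism

Default simulations use 1000 population SNVs, 40 INDELs, 5000 background
read pairs and 10,000-replicate Monte-Carlo intervals — sizes at which
every property in the test suite is sharp while a full pipeline run takes
a few seconds. The acceptance script repeats the error-robustness check
over 20 seeded replicates. All stochastic tests fix seeds; the pipeline
writes the seed into every output header, and identical configurations
produce byte-identical output trees.

## Known limitations

- Real cascade tallies from the original family genomes are not
  reproducible here (the genomes are not public); the pipeline reproduces
  the report *shapes* and the recomputable printed arithmetic, while
  cascade counts are simulation-dependent.
- The allele-aware motif analysis ships with a constructed demonstration
  8-mer table; scanning against a real PBM table requires supplying it as
  a TSV (`haploscan motif --table ...`), and site counts there are
  sensitive to the enrichment-score threshold (default 0.45, reported in
  output).
- The pooled model assumes one bi-allelic variant per site and ignores
  mapping bias between alleles.
- Gene models are single-transcript (BED12); no codon-level consequence
  prediction is attempted.
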