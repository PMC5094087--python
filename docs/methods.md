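# Methods

## Scope and model

`poolscan` implements a window-based selection scan for pooled resequencing
of a small number of populations (breed pools). The data model is the
biallelic SNP with per-pool read counts: all statistics are functions of
`(ref_reads, alt_reads)` per pool, never of called genotypes, because
Pool-seq provides no individual genotypes. Three signals of a selective
sweep are used:

1. depressed pooled heterozygosity `Hp` in the swept population,
2. elevated pairwise differentiation `FST` between swept and unswept
   populations, and
3. function-altering or promoter variants private to one population.

A fourth, orthogonal analysis validates candidate regions in independent
individuals by comparing carrier-haplotype frequencies across populations.

## Windowed statistics

**Windows.** Fixed 200-kb windows advancing 100 kb per step, per
chromosome, starting at 0. After the last full window, one truncated window
is emitted if any sequence remains beyond it (so every base is covered and
no emitted window is wholly contained in its predecessor); a chromosome
shorter than one window size yields a single whole-chromosome window.
Internally all coordinates are 0-based half-open; VCF (1-based) and GFF3
(1-based inclusive) are converted at the I/O boundary.

**Hp.** `Hp = 2·Σn_MAJ·Σn_MIN/(Σn_MAJ+Σn_MIN)²` where the sums run over the
window's SNPs with nonzero depth in the pool, and major/minor is decided per
SNP per pool from the read counts (exact ties contribute equally and are
valid). Windows with fewer than `min_snps_per_window` (default 10)
informative SNPs yield a missing value, never 0 — a window with no data is
not a window with no diversity. The default of 10 reflects the common rule
of thumb that windowed statistics over fewer than ~10 SNPs are not
interpretable.

**FST.** Per SNP, the two-population Weir–Cockerham (1984) estimator in its
mean-squares form for allele-frequency samples:

```
MSP = n₁(p₁−p̄)² + n₂(p₂−p̄)²            (between populations)
MSG = [n₁p₁(1−p₁) + n₂p₂(1−p₂)] / (n₁+n₂−2)   (within populations)
n_c = (n₁+n₂) − (n₁²+n₂²)/(n₁+n₂)
θ̂  = (MSP − MSG) / (MSP + (n_c−1)·MSG)
```

with `pᵢ` the alternate-read proportion and `nᵢ` the pool's chromosome
count (2 × pool size; 30 by default). θ̂ = 1 at a fixed difference, ≤ 0 for
identical pools, and is undefined (site excluded) where either pool has
zero depth or both pools are monomorphic for the same allele. Negative
per-SNP values are retained in the unweighted window mean: clamping at zero
would bias window averages upward. Hudson's estimator is available via
`fst_estimator="hudson"` so the choice is auditable; sample sizes enter both.

Read proportions are a noisy estimate of the pool allele frequency (binomial
read sampling on top of binomial individual sampling), which inflates MSG
slightly relative to genotype-based sampling; this is a known property of
naive Pool-seq FST and is acceptable here because outliers are taken from
the genome-wide Z distribution of the same quantity, not from its absolute
scale.

**Z-transformation.** `z = (x−μ)/σ` with sample (n−1) σ, computed within
standardisation groups: all autosomal windows pooled, chrX its own group
(its diversity and differentiation distributions are shifted and wider than
the autosomes'). Missing windows are excluded from μ and σ and stay
missing. A degenerate group (constant values, or fewer than two non-missing
windows) raises an error rather than emitting infinities; if a run's
chromosome set lacks a usable chrX group, chrX windows fall back into the
autosomal group.

## Outliers, regions, genes

Outlier windows satisfy `Z(Hp) < −4` (autosomes) / `< −3` (chrX) per pool,
or `Z(FST) > +4` / `> +3` per pool pair. Inequalities are strict: a window
at exactly the cut-off is not an outlier. Overlapping *or book-ended*
outlier windows merge into regions — with half-step sliding windows,
adjacency of outlier windows is the signature of one contiguous signal. A
breed's region set is the interval union of its Hp outlier regions and the
FST outlier regions of every pair involving that breed, with source
provenance (`hp_<breed>`, `fst_<a>_<b>`) accumulated through merging, and
the most extreme Z inside retained as `peak_z`. Merged region sets are
asserted non-overlapping on every output. Genes are assigned to a region
when the gene interval extended by a 100-kb flank overlaps it by at least
1 bp (half-open; a gene exactly book-ended at a region boundary with zero
flank is not assigned). Genome fraction is reported as
`100 · region bp / Σ chromosome lengths` and requires a merged
(non-overlapping) input.

## Filtering and presence

A variant is *present* in a pool iff that pool's depth ≥ 5, its
alternate-supporting reads ≥ 2, and the site quality ≥ 30; it is retained
at all iff present in ≥ 1 pool. "Minimum read depth for identification = 2"
is interpreted as the per-pool alternate-read requirement — the only
reading distinct from the depth filter. Presence is evaluated per pool, not
on the combined alignment. Two deliberate consequences, documented as
limitations:

- a pool with depth < 5 at a site counts as *absent*, not *missing*, so
  low-coverage sites can inflate breed-"unique" sets slightly;
- the strict presence mask governs only the breed-unique set logic. Window
  statistics use retained sites: Hp uses every retained SNP with nonzero
  depth in the pool, and per-SNP FST every retained SNP with nonzero depth
  in both pools of the pair. Requiring the full presence mask (alt ≥ 2)
  in both pools would exclude exactly the fixed-difference sites that FST
  scans exist to find.

Multi-allelic records are skipped (counted in the log): the statistics are
defined for biallelic read counts.

## Breed-unique sets and enrichment

Function-altering classes are missense, stop_gained and stop_lost, parsed
from an `ANN`-style `effect|impact|gene` INFO field; unknown effect strings
map to class `other`. A variant enters the target breed's unique set iff it
is present in the target and absent in *every* background pool (allele
level, not gene level); the gene set is the union of qualifying variants'
genes. Adding a background breed can therefore only shrink a set.
"Promoter" follows the scan's operational definition: within 1 kb outside
either gene bound (up- *or* downstream — unusual for promoters but kept
deliberately), excluding the gene body; a SNP inside gene A may still be a
promoter SNP of a neighbouring gene B. Enrichment is the hypergeometric
upper tail `P(X ≥ k)` per term against a user-supplied term→gene map, with
Benjamini–Hochberg FDR across tested terms and adjusted p < 0.1 flagged
(common GOstat-style settings); the universe defaults to the union of term
genes and is overridable. Empty terms are skipped; query genes outside the
universe are dropped with a warning.

## Haplotype validation

Input is a phased panel (TSV: individual, breed, two allele strings, or the
equivalent). A chromosome carries the reference haplotype iff it matches at
every non-missing site with at most `max_mismatch` mismatches; missing
calls are wildcards by default (`missing_is_mismatch=True` for the strict
alternative). The reference defaults to the modal complete haplotype of the
pooled panel (ties broken lexicographically, deterministic). Frequencies
are carrier *chromosomes* over total chromosomes (2 × genotyped
individuals). Pairwise differences use two-sided Fisher's exact tests on
the 2×2 carrier table, BH-adjusted across the pair set; chi-square is
available behind a flag for comparison. The frequency-difference test is a
design choice — the analysis this mirrors names no test — and Fisher is
exact at these panel sizes.

## Synthetic-data generator

The generator emulates the pooled breed-resequencing design the scan
assumes; its defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_breeds` | 3 | breed pools (VCF sample columns) |
| `pool_size` | 15 | diploids per pool (30 chromosomes) |
| `mean_depth` | 14.4 | Poisson mean reads/site/pool (43.2× combined) |
| `snp_density` | 1/150 bp | expected SNP spacing |
| `fst_drift` | 0.10 | Balding–Nichols F per breed |
| `ann_fraction` | 0.30 | genic SNPs given a synthetic effect annotation |
| sweep intensity | 1.0 | fractional push toward fixation in swept breeds |

Ancestral frequencies are uniform on [0.05, 0.95] — a proxy for the site
frequency spectrum of *ascertained* SNPs (every emitted site was called as a
SNP); breed frequencies follow Balding–Nichols
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with variance `p(1−p)F`, with `F = 0`
honoured exactly as the no-drift limit. Sweeps are planted
deterministically: inside a sweep interval, each swept breed's frequency
moves toward the nearer of {0, 1} by the intensity fraction. This is not a
coalescent model — it produces the *window-scale* Hp/FST signature the scan
targets in seconds, which is all the pipeline needs; it does not produce
realistic linkage disequilibrium, demographic history, sequencing error or
indels, so passing tests say nothing about robustness to those features of
real data. Read counts per pool are `Binomial(depth, pool frequency)` with
`depth ~ Poisson(mean_depth)` and the pool frequency itself binomially
resampled over the pool's 2N chromosomes — the two-stage sampling noise
characteristic of Pool-seq. Site qualities are `N(50, 10)` clipped at 0, so
a realistic few percent of records fail the quality filter.

Each chromosome draws from its own RNG stream derived from the master seed
(`SeedSequence(seed, spawn_key=(chrom index,))`), so generation order cannot
change results and identical configs produce byte-identical VCF/GFF3/BED
output. Toy gene models tile each chromosome (20-kb bodies every 50 kb);
effect annotations are assigned at random to SNPs inside gene bodies.
Optionally, per breed, a set of genes receives one planted missense variant
near-fixed (frequency 0.95) in that breed and absent elsewhere, with the
gene list written as ground truth for variant-set recovery scoring.

## Validation experiments and problem sizes

The standard recovery experiment (`poolscan.experiments`) plants five
400-kb full-intensity sweeps — three private to single breeds, two shared
by pairs — on a 30-Mb toy genome (two 12-Mb autosomes + 6-Mb chrX, ~200k
SNPs) and scores, per seed: the fraction of planted sweeps overlapped by an
Hp outlier region of a swept breed, and pooled over seeds the precision
(detected bp inside truth) and sensitivity (truth bp covered). The 30-Mb
size keeps a five-seed run in a few seconds while giving ~290 autosomal
windows, enough for stable genome-wide μ and σ; at the ±4 thresholds the
experiment recovers 5/5 sweeps per seed with ~0.99 precision. The test
fixtures use a smaller 8.5-Mb cohort for the same reason in miniature:
below ~80 windows the planted sweep itself contaminates μ and σ enough
that the −4 cut-off becomes marginal, which is a real property of the
statistic (outlier contamination of genome-wide moments), not an artifact.

## Numerical and degenerate-input choices

- Missing statistics are NaN end to end (`NA` in TSVs); they never enter
  μ/σ, never qualify as outliers.
- FST denominators ≤ 0 (both pools monomorphic for the same allele) give
  NaN, excluded from window means.
- `z_transform` raises on σ = 0 rather than returning infinities.
- Merging/intersection use exact integer coordinates; intersection totals
  count each overlapping base once per region pair.
- An empty VCF is a valid run: empty region sets, 0 % summaries, exit 0.
- Fisher/hypergeometric p-values come from scipy and are verified against
  exact rational-arithmetic enumeration oracles in the test suite (1e-12).

## Known limitations

- Pool-seq read proportions are used directly as allele frequencies; no
  model-based frequency estimation (e.g. accounting for unequal individual
  contributions to the pool).
- FST is pairwise only; no multi-population global estimator.
- Absence-vs-missing conflation at low depth (above) biases breed-unique
  sets at marginal coverage.
- The generator's independence across sites means no LD, so haplotype-based
  statistics cannot be validated against it; the haplotype module is
  validated on explicit synthetic panels instead.
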