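# poolscan

Selective-sweep scanning for **pooled whole-genome resequencing** (Pool-seq)
of livestock breeds. Given a multi-pool VCF (one sample column per breed
pool, with per-pool read depth `DP` and allelic depths `AD`), gene models and
chromosome lengths, the package computes the two classic windowed scan
statistics, extracts Z-score outlier windows, builds candidate sweep regions
with assigned genes, derives breed-unique function-altering / promoter
variant gene sets with term-enrichment testing, and validates candidate
regions by comparing carrier-haplotype frequencies across populations. A
first-class synthetic-data generator produces Pool-seq cohorts with planted
sweeps so the whole pipeline can be exercised and scored against ground
truth without any external data.

It is aimed at population geneticists running breed-comparison scans where
allele frequencies come from pooled read counts rather than individual
genotypes.

## Statistics

**Pooled heterozygosity** in a window, for one pool (Rubin et al. statistic):

```
Hp = 2 · Σn_MAJ · Σn_MIN / (Σn_MAJ + Σn_MIN)²
```

where `Σn_MAJ` and `Σn_MIN` sum, over the window's SNPs, the reads
supporting each SNP's most and least frequent allele in that pool.
`Hp ∈ [0, 0.5]`; windows swept to near-fixation approach 0.

**Pairwise FST** per SNP uses the two-population Weir–Cockerham (1984)
estimator on allele frequencies taken as alternate-read proportions, with
sample sizes fixed at the pools' chromosome counts (2 × 15 by default):

```
θ̂ = (MSP − MSG) / (MSP + (n_c − 1) · MSG)
```

(`MSP`/`MSG` the between/within-population mean squares, `n_c` the effective
sample size). Per-SNP values are averaged, unweighted and unclamped, over
each window. Hudson's estimator is available behind a switch.

Both statistics are computed in 200-kb windows sliding 100 kb and
**Z-transformed** genome-wide (`z = (x − μ)/σ`, sample σ; autosomes pooled,
chrX standardised separately). Outlier windows — `Z(Hp) < −4` or
`Z(FST) > 4` on autosomes, `±3` on chrX, strict inequalities — merge into
sweep regions; genes within a 100-kb flank are assigned to each region.
Breed-unique variant sets require presence (depth ≥ 5, alt reads ≥ 2,
quality ≥ 30 in that pool) in the target breed and absence in every
background breed; enrichment uses the hypergeometric upper tail with
Benjamini–Hochberg adjustment. Haplotype validation counts carrier
chromosomes matching a reference haplotype per breed and tests pairwise
differences with Fisher's exact test.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data. From the repository root:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_scan_windows.py
python analysis/03_score_recovery.py
```

which prints:

```
simulated 199495 SNPs over 30 Mb; VCF at scratch/cohort/cohort.vcf, truth at results/truth_sweeps.bed
186313/199495 variants retained
breed1: 3 sweep regions, 1.20 Mb (4.00 % of genome)
breed2: 3 sweep regions, 1.20 Mb (4.00 % of genome)
breed3: 3 sweep regions, 1.20 Mb (4.00 % of genome)
5/5 seeds recovered all 5 planted sweeps; detected-bp precision 0.986, truth-bp sensitivity 1.000
```

The cohort is 3 pools of 15 diploids at 14.4× mean depth over a 30-Mb toy
genome with five planted 400-kb sweeps. Each breed's region report counts
the sweeps planted in that breed (singly or shared): breed1 carries three of
the five planted sweeps and the scan recovers exactly those, with ~99 % of
detected bases inside true sweep intervals. `analysis/04` derives
breed-unique gene sets and shows the term loaded with each breed's planted
private missense genes coming out top of the enrichment table
(adjusted p ≈ 1e-8–1e-9); `analysis/05` demonstrates the haplotype-frequency
validation across 8 synthetic populations.

The same pipeline runs from the shell on any conforming VCF/GFF3:

```bash
poolscan simulate --out-dir sim --seed 1 --chrom chr1:10000000 \
    --sweep chr1:2000000-2400000:0:1.0
poolscan scan --config run.yaml
poolscan hapfreq --panel panel.tsv --out-prefix hap
```

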