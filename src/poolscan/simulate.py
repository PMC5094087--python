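"""Synthetic Pool-seq cohort generator with planted selective sweeps.

The generator emulates the design of a pooled breed-resequencing study: a small
number of breed pools (default 3), each a pool of 15 diploid individuals
sequenced to ~14.4x mean depth.  Neutral allele-frequency differentiation
between breeds follows the Balding–Nichols model: given an ancestral frequency
``p`` and a drift parameter ``F``, each breed's frequency is drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)``, whose variance is ``p(1-p)F``.  Selective
sweeps are planted deterministically by pushing the swept breeds' frequencies
toward the nearer of {0, 1} by a configurable intensity, which produces the
window-scale loss of pooled heterozygosity and gain in FST that the scan
targets.

Read counts are generated in two stages mirroring Pool-seq: the pool's allele
frequency is the realised frequency among the ``2 * pool_size`` chromosomes in
the pool (binomial sampling of individuals), and the alternate-read count is
binomial in a Poisson-distributed per-site depth.  Output is a VCF 4.2 with
per-pool DP and AD, a toy GFF3 gene annotation tiling each chromosome, and a
ground-truth BED of planted sweep intervals.

One RNG stream is derived per chromosome from the master seed, so chromosomes
can be generated in any order with identical results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

__all__ = [
    "SweepSpec",
    "SweepTruth",
    "SimulationConfig",
    "SimulatedCohort",
    "CohortPaths",
    "simulate_site_frequencies",
    "sample_pool_reads",
    "simulate_cohort",
    "write_simulated_cohort",
]

_BASES = np.array(["A", "C", "G", "T"])

#: effect classes written into the synthetic ANN field, with sampling weights
_EFFECT_CLASSES = ("synonymous_variant", "missense_variant", "stop_gained", "stop_lost")
_EFFECT_WEIGHTS = (0.55, 0.35, 0.05, 0.05)
_EFFECT_IMPACT = {
    "synonymous_variant": "LOW",
    "missense_variant": "MODERATE",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
}


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: interval (0-based half-open) plus the breeds swept.

    ``intensity`` in (0, 1] is the fraction by which allele frequencies inside
    the interval are moved toward the nearer of {0, 1} in the swept breeds;
    intensity 1.0 fixes every site.
    """

    chrom: str
    start: int
    end: int
    swept_breeds: tuple[int, ...]
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"sweep end must exceed start: {self}")
        if not self.swept_breeds:
            raise ValueError("swept_breeds must be non-empty")
        if not 0 < self.intensity <= 1:
            raise ValueError(f"intensity must be in (0, 1]: {self.intensity}")


@dataclass(frozen=True)
class SweepTruth:
    """Ground-truth sweep intervals against which detection is scored."""

    intervals: tuple[SweepSpec, ...]

    def for_chrom(self, chrom: str) -> list[SweepSpec]:
        return [s for s in self.intervals if s.chrom == chrom]


def _default_chrom_lengths() -> dict[str, int]:
    return {"chr1": 10_000_000, "chr2": 10_000_000, "chrX": 10_000_000}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the pooled resequencing design the scan was built for:
    3 breed pools of 15 diploids each at 14.4x mean depth (43.2x combined),
    with a SNP roughly every 150 bp.
    """

    n_breeds: int = 3
    pool_size: int = 15
    mean_depth: float = 14.4
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    snp_density: float = 1.0 / 150.0
    fst_drift: float = 0.10
    sweeps: list[SweepSpec] = field(default_factory=list)
    ann_fraction: float = 0.30
    #: genes planted per breed carrying breed-private missense variants
    private_missense_per_breed: int = 0
    #: toy gene spacing/length used for the GFF3 annotation
    gene_spacing: int = 50_000
    gene_length: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_breeds < 2:
            raise ValueError("need at least 2 breed pools")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.fst_drift < 1:
            raise ValueError("fst_drift must be in [0, 1)")
        if not 0 <= self.ann_fraction <= 1:
            raise ValueError("ann_fraction must be in [0, 1]")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        for sweep in self.sweeps:
            if sweep.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {sweep.chrom}")
            if sweep.end > self.chrom_lengths[sweep.chrom]:
                raise ValueError(f"sweep {sweep} exceeds chromosome length")
            if max(sweep.swept_breeds) >= self.n_breeds:
                raise ValueError(f"sweep {sweep} names a breed index out of range")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    @property
    def pool_names(self) -> list[str]:
        return [f"breed{i + 1}" for i in range(self.n_breeds)]

    @property
    def truth(self) -> SweepTruth:
        return SweepTruth(tuple(self.sweeps))

    def chrom_rng(self, chrom: str) -> np.random.Generator:
        """Independent stream per chromosome, derived from the master seed."""
        idx = sorted(self.chrom_lengths).index(chrom)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(idx,)))


def simulate_site_frequencies(
    config: SimulationConfig,
    chrom: str,
    pos: int | np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-breed alternate-allele frequencies at one or more sites.

    Ancestral frequency is uniform on [0.05, 0.95] (an ascertained-SNP proxy);
    breed frequencies follow Balding–Nichols around it; sites inside a planted
    sweep are pushed toward the nearer of {0, 1} in the swept breeds.

    Returns an array of shape ``(n_sites, n_breeds)`` (squeezed to
    ``(n_breeds,)`` for a scalar position).
    """
    if chrom not in config.chrom_lengths:
        raise ValueError(f"unknown chromosome {chrom!r}")
    pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    length = config.chrom_lengths[chrom]
    if np.any((pos_arr < 0) | (pos_arr >= length)):
        raise ValueError(f"position outside chromosome {chrom} (length {length})")
    if rng is None:
        rng = config.chrom_rng(chrom)

    n = pos_arr.size
    p = rng.uniform(0.05, 0.95, size=n)
    freqs = _balding_nichols(p, config.fst_drift, config.n_breeds, rng)

    for sweep in config.truth.for_chrom(chrom):
        inside = (pos_arr >= sweep.start) & (pos_arr < sweep.end)
        if not np.any(inside):
            continue
        for b in sweep.swept_breeds:
            f = freqs[inside, b]
            target = np.where(f >= 0.5, 1.0, 0.0)
            freqs[inside, b] = f + sweep.intensity * (target - f)

    if np.isscalar(pos) or np.asarray(pos).ndim == 0:
        return freqs[0]
    return freqs


def _balding_nichols(
    p: np.ndarray, drift: float, n_breeds: int, rng: np.random.Generator
) -> np.ndarray:
    """Breed frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F); F -> 0 returns p."""
    if drift == 0.0:
        return np.repeat(p[:, None], n_breeds, axis=1)
    scale = (1.0 - drift) / drift
    a = p[:, None] * scale
    b = (1.0 - p[:, None]) * scale
    return rng.beta(np.broadcast_to(a, (p.size, n_breeds)), np.broadcast_to(b, (p.size, n_breeds)))


def sample_pool_reads(
    freq: float | np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (ref_reads, alt_reads) for one pool at sites with given frequency.

    The pool's realised allele frequency is the mean over ``2 * pool_size``
    binomially drawn chromosomes; read depth is Poisson(mean_depth) and
    alternate reads binomial in that depth.
    """
    f = np.atleast_1d(np.asarray(freq, dtype=float))
    if np.any((f < 0) | (f > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    n_chrom = 2 * config.pool_size
    pool_freq = rng.binomial(n_chrom, f) / n_chrom
    depth = rng.poisson(config.mean_depth, size=f.shape)
    alt = rng.binomial(depth, pool_freq)
    ref = depth - alt
    if np.isscalar(freq) or np.asarray(freq).ndim == 0:
        return ref[0], alt[0]
    return ref, alt


@dataclass
class ChromData:
    """All simulated per-site data for one chromosome."""

    chrom: str
    pos: np.ndarray  # 0-based site positions, sorted
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    qual: np.ndarray
    freqs: np.ndarray  # (n_sites, n_breeds) true breed frequencies
    ref_reads: np.ndarray  # (n_sites, n_breeds)
    alt_reads: np.ndarray
    ann: list[str | None]  # synthetic effect|impact|gene ANN strings


@dataclass
class SimulatedCohort:
    """In-memory product of one simulation run, plus its ground truth."""

    config: SimulationConfig
    chroms: dict[str, ChromData]
    truth: SweepTruth
    #: gene ids planted with breed-private missense variants, per breed index
    private_genes: dict[int, set[str]]

    @property
    def n_sites(self) -> int:
        return sum(c.pos.size for c in self.chroms.values())

    def gene_models(self) -> list[tuple[str, str, int, int]]:
        """Toy gene models as (gene_id, chrom, start, end), 0-based half-open."""
        out = []
        for chrom in sorted(self.config.chrom_lengths):
            out.extend(_toy_genes(self.config, chrom))
        return out


def _toy_genes(config: SimulationConfig, chrom: str) -> list[tuple[str, str, int, int]]:
    """Gene bodies tiled along a chromosome at fixed spacing."""
    genes = []
    length = config.chrom_lengths[chrom]
    k = 0
    for anchor in range(0, length - config.gene_spacing, config.gene_spacing):
        start = anchor + 10_000
        end = start + config.gene_length
        if end >= length:
            break
        genes.append((f"G_{chrom}_{k:04d}", chrom, start, end))
        k += 1
    return genes


def _site_positions(length: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """SNP positions with geometric inter-site gaps (expected 1/density bp)."""
    expected = int(length * density)
    gaps = rng.geometric(density, size=int(expected * 1.3) + 100)
    pos = np.cumsum(gaps) - 1
    return pos[pos < length]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full simulation and return the in-memory cohort."""
    chroms: dict[str, ChromData] = {}
    private_genes: dict[int, set[str]] = {b: set() for b in range(config.n_breeds)}
    ordered = sorted(config.chrom_lengths)
    for chrom in ordered:
        rng = config.chrom_rng(chrom)
        length = config.chrom_lengths[chrom]
        pos = _site_positions(length, config.snp_density, rng)
        n = pos.size
        freqs = simulate_site_frequencies(config, chrom, pos, rng=rng)

        ref_reads = np.empty((n, config.n_breeds), dtype=np.int64)
        alt_reads = np.empty((n, config.n_breeds), dtype=np.int64)
        for b in range(config.n_breeds):
            ref_reads[:, b], alt_reads[:, b] = sample_pool_reads(freqs[:, b], config, rng)

        ref_idx = rng.integers(0, 4, size=n)
        alt_shift = rng.integers(1, 4, size=n)
        ref_allele = _BASES[ref_idx]
        alt_allele = _BASES[(ref_idx + alt_shift) % 4]
        qual = np.round(np.clip(rng.normal(50.0, 10.0, size=n), 0.0, None), 1)

        ann = _assign_annotations(config, chrom, pos, rng)
        chroms[chrom] = ChromData(
            chrom, pos, ref_allele, alt_allele, qual, freqs, ref_reads, alt_reads, ann
        )

    _plant_private_missense(config, chroms, private_genes)
    return SimulatedCohort(config, chroms, config.truth, private_genes)


def _assign_annotations(
    config: SimulationConfig, chrom: str, pos: np.ndarray, rng: np.random.Generator
) -> list[str | None]:
    """Give a fraction of genic SNPs a synthetic effect|impact|gene annotation."""
    genes = _toy_genes(config, chrom)
    ann: list[str | None] = [None] * pos.size
    if not genes:
        return ann
    starts = np.array([g[2] for g in genes])
    ends = np.array([g[3] for g in genes])
    idx = np.searchsorted(starts, pos, side="right") - 1
    in_gene = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    annotate = in_gene & (rng.random(pos.size) < config.ann_fraction)
    effects = rng.choice(len(_EFFECT_CLASSES), size=pos.size, p=_EFFECT_WEIGHTS)
    for i in np.flatnonzero(annotate):
        eff = _EFFECT_CLASSES[effects[i]]
        gene_id = genes[idx[i]][0]
        ann[i] = f"{eff}|{_EFFECT_IMPACT[eff]}|{gene_id}"
    return ann


def _plant_private_missense(
    config: SimulationConfig,
    chroms: dict[str, ChromData],
    private_genes: dict[int, set[str]],
) -> None:
    """Overwrite selected genic sites with breed-private missense variants.

    For each breed, ``private_missense_per_breed`` distinct genes receive one
    missense SNP that is near-fixed for the alternate allele in that breed and
    absent (frequency 0) in all others, so the breed-unique set logic has a
    known answer to recover.
    """
    if config.private_missense_per_breed <= 0:
        return
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10_000,)))
    all_genes = []
    for chrom in sorted(config.chrom_lengths):
        all_genes.extend(_toy_genes(config, chrom))
    needed = config.private_missense_per_breed * config.n_breeds
    if needed > len(all_genes):
        raise ValueError("not enough toy genes to plant private missense variants")
    chosen = rng.choice(len(all_genes), size=needed, replace=False)
    for j, gidx in enumerate(chosen):
        breed = j % config.n_breeds
        gene_id, chrom, gstart, gend = all_genes[gidx]
        data = chroms[chrom]
        lo, hi = np.searchsorted(data.pos, [gstart, gend])
        if lo == hi:  # no simulated site inside the gene: skip quietly
            continue
        i = int(rng.integers(lo, hi))
        freqs = np.zeros(config.n_breeds)
        freqs[breed] = 0.95
        data.freqs[i] = freqs
        for b in range(config.n_breeds):
            ref, alt = sample_pool_reads(float(freqs[b]), config, rng)
            data.ref_reads[i, b] = ref
            data.alt_reads[i, b] = alt
        data.qual[i] = max(data.qual[i], 40.0)
        data.ann[i] = f"missense_variant|MODERATE|{gene_id}"
        private_genes[breed].add(gene_id)


@dataclass(frozen=True)
class CohortPaths:
    """Files written for one simulated cohort."""

    vcf: Path
    gff3: Path
    truth_bed: Path
    private_genes_tsv: Path


def write_simulated_cohort(
    config: SimulationConfig,
    out_dir: str | Path,
    cohort: SimulatedCohort | None = None,
) -> CohortPaths:
    """Write VCF + GFF3 + truth BED (+ planted-gene TSV) for a simulated cohort.

    Identical configs (including seed) produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = simulate_cohort(config)

    vcf_path = out_dir / "cohort.vcf"
    gff3_path = out_dir / "genes.gff3"
    bed_path = out_dir / "truth_sweeps.bed"
    genes_path = out_dir / "truth_private_genes.tsv"

    _write_vcf(cohort, vcf_path)
    _write_gff3(cohort, gff3_path)
    _write_truth_bed(cohort, bed_path)
    _write_private_genes(cohort, genes_path)
    return CohortPaths(vcf_path, gff3_path, bed_path, genes_path)


def _write_vcf(cohort: SimulatedCohort, path: Path) -> None:
    config = cohort.config
    header = pysam.VariantHeader()
    header.add_line('##source=poolscan-simulate')
    for chrom in sorted(config.chrom_lengths):
        header.contigs.add(chrom, length=config.chrom_lengths[chrom])
    header.add_line(
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Synthetic effect annotation: effect|impact|gene">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'
    )
    for name in config.pool_names:
        header.add_sample(name)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom in sorted(config.chrom_lengths):
            data = cohort.chroms[chrom]
            for i in range(data.pos.size):
                rec = vcf.new_record(
                    contig=chrom,
                    start=int(data.pos[i]),
                    stop=int(data.pos[i]) + 1,
                    alleles=(str(data.ref_allele[i]), str(data.alt_allele[i])),
                    qual=float(data.qual[i]),
                )
                if data.ann[i] is not None:
                    rec.info["ANN"] = data.ann[i]
                for b, name in enumerate(config.pool_names):
                    ref, alt = int(data.ref_reads[i, b]), int(data.alt_reads[i, b])
                    rec.samples[name]["DP"] = ref + alt
                    rec.samples[name]["AD"] = (ref, alt)
                vcf.write(rec)


def _write_gff3(cohort: SimulatedCohort, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, chrom, start, end in cohort.gene_models():
            # GFF3 is 1-based inclusive
            fh.write(
                f"{chrom}\tpoolscan\tgene\t{start + 1}\t{end}\t.\t+\t.\t"
                f"ID={gene_id};Name={gene_id}\n"
            )


def _write_truth_bed(cohort: SimulatedCohort, path: Path) -> None:
    with open(path, "w") as fh:
        for sweep in cohort.truth.intervals:
            breeds = ",".join(str(b) for b in sweep.swept_breeds)
            fh.write(f"{sweep.chrom}\t{sweep.start}\t{sweep.end}\t{breeds}\t{sweep.intensity}\n")


def _write_private_genes(cohort: SimulatedCohort, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("breed_index\tgene_id\n")
        for breed in sorted(cohort.private_genes):
            for gene in sorted(cohort.private_genes[breed]):
                fh.write(f"{breed}\t{gene}\n")
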