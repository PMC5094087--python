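"""End-to-end scan orchestration: read → filter → windows → regions → sets.

One ``run_scan`` call materialises the standard artifacts of the selection
scan under a single output directory: the per-window statistics TSV, per-breed
region BEDs and a region report with assigned genes, breed-unique gene-set
TSVs (with optional enrichment), plus a run log and an echo of the exact
configuration for provenance.  Runs are deterministic given identical inputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from poolscan.vcfio import (
    FilterConfig,
    VariantTable,
    filter_variants,
    read_gene_models,
    read_pool_vcf,
    write_regions_bed,
    write_window_stats_tsv,
)
from poolscan.windows import (
    DEFAULT_MIN_SNPS,
    DEFAULT_WINDOW_SIZE,
    DEFAULT_WINDOW_STEP,
    compute_window_stats,
)
from poolscan.sweeps import (
    DEFAULT_GENE_FLANK,
    ThresholdConfig,
    assign_genes,
    extract_outlier_windows,
    genome_fraction,
    regions_for_breed,
)
from poolscan.variant_sets import (
    TermMap,
    breed_unique_function_altering,
    enrichment_test,
    promoter_variants,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScanResult", "run_scan"]


@dataclass
class RunConfig:
    """Everything one scan run needs; echoed into the output dir verbatim."""

    vcf: str
    gff3: str
    chrom_lengths: dict[str, int]
    pool_names: list[str]
    out_dir: str
    term_map: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    window_size: int = DEFAULT_WINDOW_SIZE
    window_step: int = DEFAULT_WINDOW_STEP
    min_snps_per_window: int = DEFAULT_MIN_SNPS
    fst_estimator: str = "weir-cockerham"
    n_chrom_per_pool: int = 30
    gene_flank: int = DEFAULT_GENE_FLANK
    promoter_flank: int = 1000
    chrx_name: str = "chrX"
    enrichment_p_cutoff: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "thresholds" in raw:
            raw["thresholds"] = ThresholdConfig(**raw["thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ScanResult:
    """Summary of one run; the files live under ``out_dir``."""

    out_dir: Path
    n_variants_raw: int
    n_variants_kept: int
    window_stats: pd.DataFrame
    regions_per_breed: dict[str, list]
    summary: pd.DataFrame


def run_scan(config: RunConfig) -> ScanResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    raw = list(read_pool_vcf(config.vcf, config.pool_names))
    log(f"read {len(raw)} biallelic records from {config.vcf}")
    kept, presence = filter_variants(raw, config.filter)
    log(f"{len(kept)} variants present in >= 1 pool after filtering")

    genes = read_gene_models(config.gff3)
    log(f"{len(genes)} gene models from {config.gff3}")

    table = VariantTable.from_variants(kept, config.pool_names)
    stats = compute_window_stats(
        table,
        config.chrom_lengths,
        size=config.window_size,
        step=config.window_step,
        min_snps=config.min_snps_per_window,
        n_chrom_per_pool=config.n_chrom_per_pool,
        estimator=config.fst_estimator,
        chrx_name=config.chrx_name,
    ) if kept else pd.DataFrame(
        columns=["chrom", "start", "end", "n_snps"]
    )
    write_window_stats_tsv(stats, out_dir / "window_stats.tsv")
    log(f"{len(stats)} windows written to window_stats.tsv")

    regions_per_breed: dict[str, list] = {}
    summary_rows = []
    if not stats.empty and any(c.startswith("z_") for c in stats.columns):
        outliers = extract_outlier_windows(stats, config.thresholds, config.chrx_name)
        for key, wins in outliers.items():
            log(f"{len(wins)} outlier windows for {key}")
        report_rows = []
        for pool in config.pool_names:
            regions = regions_for_breed(outliers, pool)
            regions = assign_genes(regions, genes, flank=config.gene_flank)
            regions_per_breed[pool] = regions
            write_regions_bed(regions, out_dir / f"regions_{pool}.bed")
            total_bp, pct = genome_fraction(regions, config.chrom_lengths)
            summary_rows.append(
                {"breed": pool, "n_regions": len(regions),
                 "total_mb": total_bp / 1e6, "genome_pct": pct}
            )
            log(
                f"{pool}: {len(regions)} regions, {total_bp / 1e6:.2f} Mb "
                f"({pct:.2f} % of genome)"
            )
            for r in regions:
                report_rows.append(
                    {"breed": pool, "chrom": r.chrom, "start": r.start, "end": r.end,
                     "source": ",".join(sorted(r.source)), "peak_z": r.peak_z,
                     "genes": ",".join(r.genes)}
                )
        pd.DataFrame(
            report_rows,
            columns=["breed", "chrom", "start", "end", "source", "peak_z", "genes"],
        ).to_csv(out_dir / "regions_report.tsv", sep="\t", index=False)
    else:
        for pool in config.pool_names:
            regions_per_breed[pool] = []
            write_regions_bed([], out_dir / f"regions_{pool}.bed")
            summary_rows.append(
                {"breed": pool, "n_regions": 0, "total_mb": 0.0, "genome_pct": 0.0}
            )
        log("no windowed statistics computable; empty region sets written")

    term_map = TermMap.from_tsv(config.term_map) if config.term_map else None
    _write_variant_sets(config, kept, presence, genes, term_map, out_dir, log)

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return ScanResult(
        out_dir=out_dir,
        n_variants_raw=len(raw),
        n_variants_kept=len(kept),
        window_stats=stats,
        regions_per_breed=regions_per_breed,
        summary=summary,
    )


def _write_variant_sets(config, kept, presence, genes, term_map, out_dir, log):
    rows = []
    for target in config.pool_names:
        backgrounds = [p for p in config.pool_names if p != target]
        fa = breed_unique_function_altering(
            kept, presence, config.pool_names, target, backgrounds
        )
        prom = promoter_variants(
            kept, presence, genes, config.pool_names, target, backgrounds,
            flank=config.promoter_flank,
        )
        log(
            f"{target}: {len(fa.genes)} genes with unique function-altering "
            f"variants, {len(prom.genes)} with unique promoter variants"
        )
        for s, kind in ((fa, "function_altering"), (prom, "promoter")):
            for gene in sorted(s.genes):
                rows.append({"breed": target, "set": kind, "gene": gene})
        if term_map is not None and fa.genes:
            enr = enrichment_test(fa.genes, term_map, p_cutoff=config.enrichment_p_cutoff)
            enr.to_csv(out_dir / f"enrichment_{target}.tsv", sep="\t", index=False)
    pd.DataFrame(rows, columns=["breed", "set", "gene"]).to_csv(
        out_dir / "gene_sets.tsv", sep="\t", index=False
    )
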