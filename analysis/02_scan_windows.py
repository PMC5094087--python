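"""Scan the simulated cohort: filter, windowed Hp/FST, Z-scores, regions.

Consumes the VCF/GFF3 written by 01_simulate_cohort.py, runs the full scan
(200-kb windows sliding 100 kb; Z cut-offs -4/+4 on autosomes, -3/+3 on
chrX), and copies the per-window statistics, per-breed sweep-region BEDs and
the run summary under results/scan/.

Run from the repository root, after 01:  python analysis/02_scan_windows.py
"""

from pathlib import Path

from poolscan.experiments import default_recovery_design
from poolscan.pipeline import RunConfig, run_scan

SEED = 20160101
SCRATCH = Path("scratch/cohort")
OUT = Path("results/scan")


def main() -> None:
    design = default_recovery_design(SEED)
    config = RunConfig(
        vcf=str(SCRATCH / "cohort.vcf"),
        gff3=str(SCRATCH / "genes.gff3"),
        chrom_lengths=dict(design.chrom_lengths),
        pool_names=list(design.pool_names),
        out_dir=str(OUT),
    )
    result = run_scan(config)
    print(f"{result.n_variants_kept}/{result.n_variants_raw} variants retained")
    for row in result.summary.itertuples(index=False):
        print(f"{row.breed}: {row.n_regions} sweep regions, "
              f"{row.total_mb:.2f} Mb ({row.genome_pct:.2f} % of genome)")
    print(f"tables under {OUT}")


if __name__ == "__main__":
    main()
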