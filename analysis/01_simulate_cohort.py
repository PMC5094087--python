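"""Generate the synthetic Pool-seq cohort the downstream analyses scan.

Design: 3 breed pools of 15 diploids at 14.4x mean depth over a 30 Mb toy
genome (two 12-Mb autosomes plus a 6-Mb chrX), with five planted 400-kb
sweeps at full intensity, private to different breed subsets.  Large outputs
(VCF) land under scratch/; the ground truth and a short tally go to results/.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

import shutil
from pathlib import Path

from poolscan.experiments import default_cohort_design
from poolscan.simulate import simulate_cohort, write_simulated_cohort

SEED = 20160101
SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    config = default_cohort_design(SEED)
    cohort = simulate_cohort(config)
    paths = write_simulated_cohort(config, SCRATCH, cohort=cohort)

    RESULTS.mkdir(exist_ok=True)
    shutil.copy(paths.truth_bed, RESULTS / "truth_sweeps.bed")
    shutil.copy(paths.private_genes_tsv, RESULTS / "truth_private_genes.tsv")
    with open(RESULTS / "cohort_tally.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_breeds\t{config.n_breeds}\n")
        fh.write(f"pool_size\t{config.pool_size}\n")
        fh.write(f"mean_depth\t{config.mean_depth}\n")
        fh.write(f"genome_bp\t{sum(config.chrom_lengths.values())}\n")
        fh.write(f"n_sites\t{cohort.n_sites}\n")
        fh.write(f"n_planted_sweeps\t{len(config.sweeps)}\n")

    print(f"simulated {cohort.n_sites} SNPs over "
          f"{sum(config.chrom_lengths.values()) / 1e6:.0f} Mb; "
          f"VCF at {paths.vcf}, truth at {RESULTS / 'truth_sweeps.bed'}")


if __name__ == "__main__":
    main()
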