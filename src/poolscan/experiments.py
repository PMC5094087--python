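"""Standard validation experiments run on the synthetic cohort.

These are the package's own calibration/validation runs: they plant sweeps
under the study design the scan assumes (3 pools of 15 diploids at 14.4x) and
score how well the Hp outlier regions recover the planted truth.  Both the
test suite and the reproducibility script drive them.
"""

from __future__ import annotations

from dataclasses import dataclass

from poolscan.simulate import SimulationConfig, SweepSpec, simulate_cohort
from poolscan.vcfio import table_from_cohort
from poolscan.windows import compute_window_stats
from poolscan.sweeps import (
    ThresholdConfig,
    extract_outlier_windows,
    merge_windows_to_regions,
)

__all__ = [
    "RecoveryResult",
    "default_recovery_design",
    "default_cohort_design",
    "planted_sweep_recovery",
]

#: 30 Mb toy genome with 5 planted 400-kb sweeps at full intensity
RECOVERY_CHROM_LENGTHS = {"chr1": 12_000_000, "chr2": 12_000_000, "chrX": 6_000_000}
RECOVERY_SWEEPS = [
    SweepSpec("chr1", 2_000_000, 2_400_000, (0,), 1.0),
    SweepSpec("chr1", 7_000_000, 7_400_000, (1,), 1.0),
    SweepSpec("chr2", 1_500_000, 1_900_000, (2,), 1.0),
    SweepSpec("chr2", 6_000_000, 6_400_000, (0, 1), 1.0),
    SweepSpec("chr2", 9_500_000, 9_900_000, (1, 2), 1.0),
]


def default_recovery_design(seed: int) -> SimulationConfig:
    """The planted-sweep recovery scenario at the default study conditions."""
    return SimulationConfig(
        chrom_lengths=dict(RECOVERY_CHROM_LENGTHS),
        sweeps=list(RECOVERY_SWEEPS),
        seed=seed,
    )


def default_cohort_design(seed: int) -> SimulationConfig:
    """Recovery scenario plus 25 planted breed-private missense genes per
    breed, so variant-set analyses over the same cohort have a known answer."""
    config = default_recovery_design(seed)
    config.private_missense_per_breed = 25
    return config


@dataclass
class RecoveryResult:
    """Recovery scores of one or more seeds of the planted-sweep experiment."""

    seeds: list[int]
    #: per seed: fraction of planted sweeps overlapped by an Hp region of a swept breed
    recovered_fraction: list[float]
    #: pooled over seeds: fraction of detected Hp-region bp overlapping truth
    precision_bp: float
    #: pooled over seeds: fraction of truth bp covered by detected regions
    sensitivity_bp: float

    @property
    def seeds_fully_recovered(self) -> int:
        return sum(1 for f in self.recovered_fraction if f == 1.0)


def planted_sweep_recovery(
    seeds: list[int],
    thresholds: ThresholdConfig | None = None,
) -> RecoveryResult:
    """Run the recovery experiment for several seeds and score against truth."""
    if thresholds is None:
        thresholds = ThresholdConfig()
    recovered_fraction = []
    detected_bp = 0
    overlap_bp = 0
    truth_bp = 0
    truth_covered_bp = 0
    for seed in seeds:
        config = default_recovery_design(seed)
        cohort = simulate_cohort(config)
        table = table_from_cohort(cohort)
        stats = compute_window_stats(table, config.chrom_lengths)
        outliers = extract_outlier_windows(stats, thresholds)
        hp_regions = {
            pool: merge_windows_to_regions(outliers[f"hp_{pool}"], source=f"hp_{pool}")
            for pool in config.pool_names
        }
        n_hit = 0
        for sweep in config.sweeps:
            hit = False
            for b in sweep.swept_breeds:
                pool = config.pool_names[b]
                for r in hp_regions[pool]:
                    if r.chrom == sweep.chrom and r.start < sweep.end and r.end > sweep.start:
                        hit = True
            n_hit += hit
        recovered_fraction.append(n_hit / len(config.sweeps))

        for pool in config.pool_names:
            for r in hp_regions[pool]:
                detected_bp += r.width
                for sweep in config.sweeps:
                    if sweep.chrom == r.chrom:
                        overlap_bp += max(
                            0, min(r.end, sweep.end) - max(r.start, sweep.start)
                        )
        for sweep in config.sweeps:
            for b in sweep.swept_breeds:
                truth_bp += sweep.end - sweep.start
                pool = config.pool_names[b]
                for r in hp_regions[pool]:
                    if r.chrom == sweep.chrom:
                        truth_covered_bp += max(
                            0, min(r.end, sweep.end) - max(r.start, sweep.start)
                        )
    return RecoveryResult(
        seeds=list(seeds),
        recovered_fraction=recovered_fraction,
        precision_bp=overlap_bp / detected_bp if detected_bp else float("nan"),
        sensitivity_bp=truth_covered_bp / truth_bp if truth_bp else float("nan"),
    )
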