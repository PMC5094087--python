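"""Outlier-window extraction, sweep-region construction and gene assignment.

Candidate sweep windows are extracted from the extreme tails of the
Z-transformed genome-wide distributions — reduced pooled heterozygosity
(Z(Hp) below a negative cut-off) or elevated differentiation (Z(FST) above a
positive cut-off).  Autosomes use |Z| > 4; chromosome X, whose distributions
are wider, uses |Z| > 3.  Inequalities are strict.  Overlapping or book-ended
outlier windows merge into sweep regions; a breed's region set is the union
over its Hp outliers and the FST outliers of every pair involving it.
Protein-coding genes are assigned to a region when the gene extended by a
100-kb flank overlaps it by at least 1 bp.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from poolscan.vcfio import GeneModel

__all__ = [
    "ThresholdConfig",
    "SweepRegion",
    "extract_outlier_windows",
    "merge_windows_to_regions",
    "combine_region_sets",
    "intersect_region_sets",
    "assign_genes",
    "genome_fraction",
    "regions_for_breed",
]

DEFAULT_GENE_FLANK = 100_000


@dataclass(frozen=True)
class ThresholdConfig:
    """Z-score cut-offs for outlier windows (strict inequalities)."""

    z_hp_auto: float = -4.0
    z_fst_auto: float = 4.0
    z_hp_x: float = -3.0
    z_fst_x: float = 3.0

    def __post_init__(self) -> None:
        if not (self.z_hp_auto < 0 and self.z_hp_x < 0):
            raise ValueError("Hp thresholds must be negative")
        if not (self.z_fst_auto > 0 and self.z_fst_x > 0):
            raise ValueError("FST thresholds must be positive")
        if self.z_hp_x < self.z_hp_auto or self.z_fst_x > self.z_fst_auto:
            raise ValueError("chrX thresholds must be less extreme than autosomal")


@dataclass(frozen=True)
class SweepRegion:
    """A merged run of outlier windows (0-based half-open).

    ``source`` records which statistic/breed (e.g. ``hp_breed1`` or
    ``fst_breed1_breed2``) triggered the constituent windows; ``peak_z`` is
    the most extreme Z-score inside (largest |Z|).
    """

    chrom: str
    start: int
    end: int
    source: frozenset[str] = frozenset()
    peak_z: float = float("nan")
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region end must exceed start: {self}")

    @property
    def width(self) -> int:
        return self.end - self.start


def extract_outlier_windows(
    stats: pd.DataFrame,
    thresholds: ThresholdConfig | None = None,
    chrx_name: str = "chrX",
) -> dict[str, pd.DataFrame]:
    """Outlier windows per statistic column.

    Returns a dict keyed by statistic name (``hp_<pool>`` for each ``z_hp_*``
    column, ``fst_<a>_<b>`` for each ``z_fst_*``) of window rows passing the
    cut-off: Z(Hp) below, Z(FST) above, with chrX using its own thresholds.
    Windows with a missing statistic never qualify.
    """
    if thresholds is None:
        thresholds = ThresholdConfig()
    is_x = stats["chrom"].to_numpy() == chrx_name
    out: dict[str, pd.DataFrame] = {}
    for col in stats.columns:
        if col.startswith("z_hp_"):
            z = stats[col].to_numpy()
            cut = np.where(is_x, thresholds.z_hp_x, thresholds.z_hp_auto)
            sel = ~np.isnan(z) & (z < cut)
        elif col.startswith("z_fst_"):
            z = stats[col].to_numpy()
            cut = np.where(is_x, thresholds.z_fst_x, thresholds.z_fst_auto)
            sel = ~np.isnan(z) & (z > cut)
        else:
            continue
        key = col[2:]  # strip the z_ prefix: the underlying statistic
        out[key] = stats.loc[sel, ["chrom", "start", "end", col]].rename(
            columns={col: "z"}
        )
    return out


def merge_windows_to_regions(
    windows: pd.DataFrame | Sequence[tuple[str, int, int, float]],
    source: str | None = None,
) -> list[SweepRegion]:
    """Merge overlapping or book-ended outlier windows into regions.

    Half-step sliding windows make adjacency the signature of one contiguous
    signal, so windows sharing only a boundary also merge.
    """
    if isinstance(windows, pd.DataFrame):
        items = [
            (r.chrom, int(r.start), int(r.end), float(getattr(r, "z", np.nan)))
            for r in windows.itertuples(index=False)
        ]
    else:
        items = [(c, int(s), int(e), float(z)) for c, s, e, z in windows]
    items.sort(key=lambda t: (t[0], t[1], t[2]))
    src = frozenset([source]) if source else frozenset()

    regions: list[SweepRegion] = []
    for chrom, start, end, z in items:
        if regions and regions[-1].chrom == chrom and start <= regions[-1].end:
            prev = regions[-1]
            peak = _more_extreme(prev.peak_z, z)
            regions[-1] = replace(prev, end=max(prev.end, end), peak_z=peak)
        else:
            regions.append(SweepRegion(chrom, start, end, source=src, peak_z=z))
    _assert_disjoint(regions)
    return regions


def _more_extreme(a: float, b: float) -> float:
    if np.isnan(a):
        return b
    if np.isnan(b):
        return a
    return a if abs(a) >= abs(b) else b


def _assert_disjoint(regions: Sequence[SweepRegion]) -> None:
    by_chrom: dict[str, list[SweepRegion]] = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append(r)
    for rs in by_chrom.values():
        rs.sort(key=lambda r: r.start)
        for prev, nxt in zip(rs, rs[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"overlapping regions: {prev} / {nxt}")


def combine_region_sets(*region_sets: Iterable[SweepRegion]) -> list[SweepRegion]:
    """Interval union of several region sets, concatenating source provenance."""
    items = [r for rs in region_sets for r in rs]
    items.sort(key=lambda r: (r.chrom, r.start, r.end))
    out: list[SweepRegion] = []
    for r in items:
        if out and out[-1].chrom == r.chrom and r.start <= out[-1].end:
            prev = out[-1]
            out[-1] = replace(
                prev,
                end=max(prev.end, r.end),
                source=prev.source | r.source,
                peak_z=_more_extreme(prev.peak_z, r.peak_z),
            )
        else:
            out.append(r)
    _assert_disjoint(out)
    return out


def intersect_region_sets(
    set_a: Sequence[SweepRegion], set_b: Sequence[SweepRegion]
) -> tuple[list[SweepRegion], int]:
    """Maximal intervals present in both sets, and the total overlap in bp."""
    by_chrom_b: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in set_b:
        by_chrom_b[r.chrom][r.start:r.end] = r
    out: list[SweepRegion] = []
    total = 0
    for a in sorted(set_a, key=lambda r: (r.chrom, r.start)):
        for hit in sorted(by_chrom_b[a.chrom][a.start:a.end]):
            start = max(a.start, hit.begin)
            end = min(a.end, hit.end)
            if end > start:
                out.append(
                    SweepRegion(a.chrom, start, end, source=a.source | hit.data.source)
                )
                total += end - start
    return out, total


def regions_for_breed(
    outliers: Mapping[str, pd.DataFrame], pool: str
) -> list[SweepRegion]:
    """A breed's sweep regions: union of its Hp outliers and every FST pair
    involving it, merged."""
    parts = []
    for key, wins in outliers.items():
        if key == f"hp_{pool}" or (key.startswith("fst_") and pool in key.split("_")[1:]):
            parts.append(merge_windows_to_regions(wins, source=key))
    return combine_region_sets(*parts)


def assign_genes(
    regions: Sequence[SweepRegion],
    gene_models: Sequence[GeneModel],
    flank: int = DEFAULT_GENE_FLANK,
) -> list[SweepRegion]:
    """Attach genes whose flank-extended span overlaps each region by >= 1 bp."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in gene_models:
        trees[g.chrom][max(0, g.start - flank):g.end + flank] = g.gene_id
    out = []
    for r in regions:
        hits = sorted({iv.data for iv in trees[r.chrom][r.start:r.end]})
        out.append(replace(r, genes=tuple(hits)))
    return out


def genome_fraction(
    regions: Sequence[SweepRegion], chrom_lengths: Mapping[str, int]
) -> tuple[int, float]:
    """Total bp covered by (non-overlapping) regions and percent of genome."""
    _assert_disjoint(regions)
    total = sum(r.width for r in regions)
    genome = sum(chrom_lengths.values())
    if genome <= 0:
        raise ValueError("genome size must be positive")
    return total, 100.0 * total / genome
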