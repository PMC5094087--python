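"""Windowed Pool-seq scan statistics: pooled heterozygosity, FST, Z-scores.

Pooled heterozygosity follows the read-count formulation of Rubin et al.:

    Hp = 2 * S_maj * S_min / (S_maj + S_min)^2

where ``S_maj`` / ``S_min`` are the window sums of reads supporting each SNP's
most and least frequent allele in that pool.  Hp is bounded in [0, 0.5] and
drops toward 0 where one allele dominates across the window — the signature of
a selective sweep.

Per-SNP FST between two pools defaults to the Weir–Cockerham (1984) estimator
for allele-frequency samples, with pool allele frequencies taken as read
proportions and sample sizes fixed at the number of chromosomes in each pool
(2 x pool size).  With mean squares between (MSP) and within (MSG) populations
and effective sample size n_c,

    theta_hat = (MSP - MSG) / (MSP + (n_c - 1) * MSG)

which is 1 at a fixed difference and <= 0 for identical pools.  Negative
values are retained (not clamped) when averaging over windows, since clamping
biases the window mean upward.  Hudson's estimator is available as an
alternative behind ``estimator="hudson"``.

Z-transformation standardises each statistic genome-wide, ``z = (x - mu) /
sigma``, with autosomal windows pooled into one group and chromosome X its
own group (its diversity and differentiation distributions differ), using the
sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeWindow",
    "make_windows",
    "pooled_heterozygosity",
    "fst_snp",
    "window_fst",
    "z_transform",
    "compute_window_stats",
    "DEFAULT_WINDOW_SIZE",
    "DEFAULT_WINDOW_STEP",
    "DEFAULT_MIN_SNPS",
]

DEFAULT_WINDOW_SIZE = 200_000
DEFAULT_WINDOW_STEP = 100_000
#: windows with fewer informative SNPs than this get a missing value, not 0
DEFAULT_MIN_SNPS = 10


@dataclass(frozen=True)
class GenomeWindow:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end must exceed start: {self}")

    @property
    def width(self) -> int:
        return self.end - self.start


def make_windows(
    chrom_lengths: Mapping[str, int],
    size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_WINDOW_STEP,
) -> list[GenomeWindow]:
    """Sliding windows of ``size`` bp advancing by ``step`` bp per chromosome.

    Full windows start at 0, step, 2*step, ...; if any sequence remains beyond
    the last full window, one truncated window is appended starting one step
    after the last full start.  A chromosome shorter than one window yields a
    single window covering it.
    """
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if step > size:
        raise ValueError("step must not exceed size")
    windows: list[GenomeWindow] = []
    for chrom in chrom_lengths:
        length = int(chrom_lengths[chrom])
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        if length < size:
            windows.append(GenomeWindow(chrom, 0, length))
            continue
        start = 0
        while start + size <= length:
            windows.append(GenomeWindow(chrom, start, start + size))
            start += step
        last_full_end = windows[-1].end
        if length > last_full_end:
            windows.append(GenomeWindow(chrom, start, length))
    return windows


def pooled_heterozygosity(
    maj_reads: Sequence[int] | np.ndarray,
    min_reads: Sequence[int] | np.ndarray,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> float:
    """Windowed pooled heterozygosity from per-SNP major/minor read counts.

    ``maj_reads[i]`` / ``min_reads[i]`` are the reads supporting SNP ``i``'s
    most / least frequent allele in the pool.  Returns NaN when fewer than
    ``min_snps`` SNPs have nonzero depth.
    """
    maj = np.asarray(maj_reads, dtype=np.int64)
    mn = np.asarray(min_reads, dtype=np.int64)
    if np.any(maj < 0) or np.any(mn < 0):
        raise ValueError("negative read counts")
    informative = (maj + mn) > 0
    if informative.sum() < min_snps or not informative.any():
        return float("nan")
    s_maj = int(maj[informative].sum())
    s_min = int(mn[informative].sum())
    return 2.0 * s_maj * s_min / float(s_maj + s_min) ** 2


def fst_snp(
    counts1: tuple[int, int],
    counts2: tuple[int, int],
    n_chrom1: int = 30,
    n_chrom2: int = 30,
    estimator: str = "weir-cockerham",
) -> float:
    """Per-SNP FST between two pools from (ref_reads, alt_reads) counts.

    Allele frequencies are the alternate-read proportions; sample sizes are
    the pools' chromosome counts.  NaN if either pool has zero depth.
    """
    d1 = counts1[0] + counts1[1]
    d2 = counts2[0] + counts2[1]
    if d1 == 0 or d2 == 0:
        return float("nan")
    p1 = counts1[1] / d1
    p2 = counts2[1] / d2
    return float(
        fst_from_freqs(
            np.array([p1]), np.array([p2]), n_chrom1, n_chrom2, estimator=estimator
        )[0]
    )


def fst_from_freqs(
    p1: np.ndarray,
    p2: np.ndarray,
    n1: int,
    n2: int,
    estimator: str = "weir-cockerham",
) -> np.ndarray:
    """Vectorised two-population FST from allele frequencies and sample sizes."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if estimator == "weir-cockerham":
        return _fst_weir_cockerham(p1, p2, n1, n2)
    if estimator == "hudson":
        return _fst_hudson(p1, p2, n1, n2)
    raise ValueError(f"unknown FST estimator {estimator!r}")


def _fst_weir_cockerham(p1, p2, n1, n2):
    """Weir–Cockerham (1984) theta-hat for two allele-frequency samples."""
    n_tot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n_tot
    # mean squares between and within populations (r = 2 populations)
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 - 1 + n2 - 1)
    n_c = n_tot - (n1 * n1 + n2 * n2) / n_tot
    denom = msp + (n_c - 1) * msg
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom > 0, (msp - msg) / denom, np.nan)
    return theta


def _fst_hudson(p1, p2, n1, n2):
    """Hudson's estimator (mean pairwise difference form)."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def window_fst(per_snp_fst: Sequence[float] | np.ndarray, min_snps: int = DEFAULT_MIN_SNPS) -> float:
    """Unweighted mean of per-SNP FST over eligible (non-NaN) sites in a window."""
    vals = np.asarray(per_snp_fst, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < min_snps:
        return float("nan")
    return float(vals.mean())


def z_transform(
    values: Sequence[float] | np.ndarray,
    groups: Sequence | np.ndarray | None = None,
) -> np.ndarray:
    """Standardise values within groups: z = (x - mu) / sigma, sample sigma.

    NaN values stay NaN and are excluded from each group's mu and sigma.
    A degenerate group (sigma == 0 or fewer than 2 non-missing values) raises.
    """
    x = np.asarray(values, dtype=float)
    z = np.full(x.shape, np.nan)
    if groups is None:
        groups = np.zeros(x.shape, dtype=int)
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        sel = groups == g
        vals = x[sel]
        ok = ~np.isnan(vals)
        if ok.sum() < 2:
            raise ValueError(f"group {g!r}: need >= 2 non-missing values")
        mu = vals[ok].mean()
        sigma = vals[ok].std(ddof=1)
        if sigma == 0:
            raise ValueError(f"group {g!r}: degenerate (constant) distribution")
        z[sel] = (x[sel] - mu) / sigma
    return z


def _window_site_slices(pos: np.ndarray, windows: list[GenomeWindow]) -> list[slice]:
    """Index ranges of (sorted) positions falling in each window."""
    slices = []
    for w in windows:
        lo, hi = np.searchsorted(pos, [w.start, w.end])
        slices.append(slice(lo, hi))
    return slices


def compute_window_stats(
    table,
    chrom_lengths: Mapping[str, int],
    size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_WINDOW_STEP,
    min_snps: int = DEFAULT_MIN_SNPS,
    n_chrom_per_pool: int = 30,
    estimator: str = "weir-cockerham",
    chrx_name: str = "chrX",
) -> pd.DataFrame:
    """Full per-window statistics table for a VariantTable.

    One row per sliding window with columns: chrom, start, end, n_snps,
    ``hp_<pool>``, ``fst_<poolA>_<poolB>``, and Z-scores ``z_hp_*`` /
    ``z_fst_*`` standardised with autosomes pooled and ``chrx_name``
    standardised separately (when enough chrX windows exist).
    """
    pools = table.pool_names
    pairs = list(combinations(range(len(pools)), 2))
    windows = make_windows(chrom_lengths, size, step)

    rows: list[dict] = []
    for chrom in chrom_lengths:
        w_chr = [w for w in windows if w.chrom == chrom]
        idx = table.chrom_slice(chrom)
        pos = table.pos[idx]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        ref = table.ref_reads[idx][order]
        alt = table.alt_reads[idx][order]
        depth = ref + alt
        maj = np.maximum(ref, alt)
        mn = np.minimum(ref, alt)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
        # per-SNP FST for every pool pair, computed once per chromosome
        snp_fst = {}
        for a, b in pairs:
            f = fst_from_freqs(
                freqs[:, a], freqs[:, b], n_chrom_per_pool, n_chrom_per_pool, estimator
            )
            f[np.isnan(freqs[:, a]) | np.isnan(freqs[:, b])] = np.nan
            snp_fst[(a, b)] = f

        for w, sl in zip(w_chr, _window_site_slices(pos, w_chr)):
            row: dict = {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": sl.stop - sl.start,
            }
            for j, pool in enumerate(pools):
                row[f"hp_{pool}"] = pooled_heterozygosity(
                    maj[sl, j], mn[sl, j], min_snps=min_snps
                )
            for a, b in pairs:
                row[f"fst_{pools[a]}_{pools[b]}"] = window_fst(
                    snp_fst[(a, b)][sl], min_snps=min_snps
                )
            rows.append(row)

    stats = pd.DataFrame(rows)
    if stats.empty:
        return stats
    group = np.where(stats["chrom"].to_numpy() == chrx_name, "chrX", "autosome")
    # chrX falls back into the autosomal group if it has too few windows
    if (group == "chrX").sum() < 2:
        group = np.full(len(stats), "autosome")
    for j, pool in enumerate(pools):
        stats[f"z_hp_{pool}"] = z_transform(stats[f"hp_{pool}"].to_numpy(), group)
    for a, b in pairs:
        col = f"fst_{pools[a]}_{pools[b]}"
        stats[f"z_{col}"] = z_transform(stats[col].to_numpy(), group)
    return stats
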