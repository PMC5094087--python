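"""Reading and filtering multi-pool VCFs, gene models, and tabular output.

All internal coordinates are 0-based half-open; VCF (1-based) and GFF3
(1-based inclusive) are converted at the boundary.  A "pool" is one VCF sample
column holding the pooled reads of a breed, with FORMAT fields DP (depth) and
AD (ref,alt allelic depths).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from poolscan.variant_sets import parse_effects

logger = logging.getLogger(__name__)

__all__ = [
    "PoolVariant",
    "FilterConfig",
    "GeneModel",
    "VariantTable",
    "table_from_cohort",
    "read_pool_vcf",
    "filter_variants",
    "read_gene_models",
    "write_window_stats_tsv",
    "read_window_stats_tsv",
    "write_regions_bed",
    "read_regions_bed",
]


@dataclass(frozen=True)
class PoolVariant:
    """One biallelic SNP with per-pool read counts.

    ``per_pool`` holds one ``(depth, ref_reads, alt_reads)`` triple per pool,
    in the order of the pool names the VCF was read with.  ``effects`` is the
    parsed ANN content: ``(effect_class, gene_id)`` pairs, possibly empty.
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    qual: float
    per_pool: tuple[tuple[int, int, int], ...]
    effects: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.qual < 0:
            raise ValueError(f"negative quality at {self.chrom}:{self.pos + 1}")
        for depth, ref_reads, alt_reads in self.per_pool:
            if ref_reads < 0 or alt_reads < 0 or depth < 0:
                raise ValueError(f"negative read count at {self.chrom}:{self.pos + 1}")
            if ref_reads + alt_reads > depth:
                raise ValueError(
                    f"allelic depths exceed DP at {self.chrom}:{self.pos + 1}"
                )


@dataclass(frozen=True)
class FilterConfig:
    """Per-pool SNP filter thresholds.

    A variant is *present* in a pool iff that pool's depth >= ``min_depth``,
    its alternate-supporting reads >= ``min_alt_reads``, and the site quality
    >= ``min_qual``.  A variant is retained iff present in at least one pool.
    """

    min_depth: int = 5
    min_alt_reads: int = 2
    min_qual: float = 30.0

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_alt_reads < 0 or self.min_qual < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene interval, stored 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


def read_pool_vcf(
    path: str | Path,
    pool_names: Sequence[str],
    skip_multiallelic: bool = True,
) -> Iterator[PoolVariant]:
    """Stream PoolVariants from a VCF with per-sample DP and AD.

    Multi-allelic records are skipped (and counted in the log) by default;
    records are yielded in file order, which must be (chrom, pos) sorted.
    """
    vcf = VCF(str(path))
    sample_idx = []
    for name in pool_names:
        if name not in vcf.samples:
            raise ValueError(f"pool {name!r} not among VCF samples {vcf.samples}")
        sample_idx.append(vcf.samples.index(name))

    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if skip_multiallelic:
                n_multi += 1
                continue
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        try:
            ad = rec.format("AD")
            dp = rec.format("DP")
        except KeyError:
            ad = dp = None
        if ad is None or dp is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks AD/DP FORMAT fields")
        per_pool = []
        for i in sample_idx:
            ref_reads = max(int(ad[i][0]), 0)
            alt_reads = max(int(ad[i][1]), 0)
            depth = max(int(dp[i][0]) if np.ndim(dp[i]) else int(dp[i]), 0)
            per_pool.append((depth, ref_reads, alt_reads))
        ann = rec.INFO.get("ANN")
        effects = tuple(parse_effects(ann)) if ann else ()
        yield PoolVariant(
            chrom=rec.CHROM,
            pos=rec.POS - 1,
            ref=rec.REF,
            alt=rec.ALT[0],
            qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
            per_pool=tuple(per_pool),
            effects=effects,
        )
    if n_multi:
        logger.info("skipped %d multi-allelic records in %s", n_multi, path)


def presence_mask(
    variants: Sequence[PoolVariant], config: FilterConfig
) -> np.ndarray:
    """Boolean (n_variants, n_pools) matrix of the per-pool filter verdict."""
    if not variants:
        return np.zeros((0, 0), dtype=bool)
    n_pools = len(variants[0].per_pool)
    mask = np.zeros((len(variants), n_pools), dtype=bool)
    for i, v in enumerate(variants):
        if v.qual < config.min_qual:
            continue
        for j, (depth, _ref, alt) in enumerate(v.per_pool):
            mask[i, j] = depth >= config.min_depth and alt >= config.min_alt_reads
    return mask


def filter_variants(
    variants: Iterable[PoolVariant],
    config: FilterConfig | None = None,
) -> tuple[list[PoolVariant], np.ndarray]:
    """Apply the per-pool presence filter; keep variants present in >= 1 pool.

    Returns the retained variants and their per-pool presence mask
    (rows aligned with the returned list).
    """
    if config is None:
        config = FilterConfig()
    variants = list(variants)
    mask = presence_mask(variants, config)
    keep = mask.any(axis=1) if mask.size else np.zeros(len(variants), dtype=bool)
    kept = [v for v, k in zip(variants, keep) if k]
    return kept, mask[keep]


class VariantTable:
    """Columnar view of a variant set for fast windowed statistics.

    Arrays: ``chrom`` (object), ``pos`` (int64, 0-based), ``qual`` (float),
    ``ref_reads``/``alt_reads`` of shape ``(n_sites, n_pools)``.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        qual: np.ndarray,
        ref_reads: np.ndarray,
        alt_reads: np.ndarray,
        pool_names: Sequence[str],
    ):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.qual = np.asarray(qual, dtype=float)
        self.ref_reads = np.asarray(ref_reads, dtype=np.int64)
        self.alt_reads = np.asarray(alt_reads, dtype=np.int64)
        self.pool_names = list(pool_names)

    @classmethod
    def from_variants(
        cls, variants: Sequence[PoolVariant], pool_names: Sequence[str]
    ) -> "VariantTable":
        n = len(variants)
        p = len(pool_names)
        ref_reads = np.zeros((n, p), dtype=np.int64)
        alt_reads = np.zeros((n, p), dtype=np.int64)
        for i, v in enumerate(variants):
            for j, (_depth, ref, alt) in enumerate(v.per_pool):
                ref_reads[i, j] = ref
                alt_reads[i, j] = alt
        return cls(
            chrom=np.array([v.chrom for v in variants], dtype=object),
            pos=np.array([v.pos for v in variants], dtype=np.int64),
            qual=np.array([v.qual for v in variants], dtype=float),
            ref_reads=ref_reads,
            alt_reads=alt_reads,
            pool_names=pool_names,
        )

    def __len__(self) -> int:
        return self.pos.size

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)


def table_from_cohort(cohort, filter_config: FilterConfig | None = None) -> VariantTable:
    """Filtered VariantTable straight from an in-memory simulated cohort.

    Applies the same per-pool presence filter as :func:`filter_variants`
    (vectorised), keeping sites present in at least one pool.  Lets multi-seed
    experiments skip the VCF round trip, which unit tests cover separately.
    """
    if filter_config is None:
        filter_config = FilterConfig()
    chroms, poss, quals, refs, alts = [], [], [], [], []
    for chrom in sorted(cohort.chroms):
        data = cohort.chroms[chrom]
        depth = data.ref_reads + data.alt_reads
        present = (
            (depth >= filter_config.min_depth)
            & (data.alt_reads >= filter_config.min_alt_reads)
            & (data.qual >= filter_config.min_qual)[:, None]
        )
        keep = present.any(axis=1)
        chroms.append(np.full(keep.sum(), chrom, dtype=object))
        poss.append(data.pos[keep])
        quals.append(data.qual[keep])
        refs.append(data.ref_reads[keep])
        alts.append(data.alt_reads[keep])
    return VariantTable(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        qual=np.concatenate(quals),
        ref_reads=np.vstack(refs),
        alt_reads=np.vstack(alts),
        pool_names=cohort.config.pool_names,
    )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 into 0-based half-open GeneModels."""
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
            force=True,
        )
    except EmptyInputError:
        return []
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r} in {path}")
        seen.add(gene_id)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> half-open
                end=feat.end,
                strand=feat.strand or "+",
            )
        )
    return genes


# --- tabular output -------------------------------------------------------


def write_window_stats_tsv(stats: pd.DataFrame, path: str | Path) -> None:
    """Write the per-window statistics table (chrom, start, end, n_snps, ...)."""
    stats.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_window_stats_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_regions_bed(regions: Iterable, path: str | Path) -> None:
    """Write regions as sorted BED (0-based half-open); name column optional."""
    rows = []
    for r in regions:
        name = getattr(r, "source", None)
        if isinstance(name, (tuple, list, set, frozenset)):
            name = ",".join(sorted(map(str, name)))
        rows.append((r.chrom, int(r.start), int(r.end), name))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            if name:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
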