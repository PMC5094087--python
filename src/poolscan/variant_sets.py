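"""Breed-unique function-altering / promoter variant sets and term enrichment.

A variant is *breed-unique* when it passes the per-pool presence filter in the
target breed's pool and fails it in every background pool.  Function-altering
classes are missense and stop gained/lost; promoter variants are SNPs lying
within 1 kb outside either bound of a gene (but not inside its body).  Gene
sets derived this way are tested for term over-representation with the
hypergeometric upper tail and Benjamini–Hochberg FDR adjustment (adjusted
p < 0.1 flagged by default, following common GOstat settings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "BreedVariantSet",
    "TermMap",
    "parse_effects",
    "breed_unique_function_altering",
    "promoter_variants",
    "overlap_pvalue",
    "enrichment_test",
    "FUNCTION_ALTERING_CLASSES",
]

#: canonical effect-class names after normalising annotation strings
_EFFECT_ALIASES = {
    "missense_variant": "missense",
    "missense": "missense",
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "synonymous_variant": "synonymous",
    "synonymous": "synonymous",
}

FUNCTION_ALTERING_CLASSES = frozenset({"missense", "stop_gained", "stop_lost"})


def parse_effects(ann: str) -> list[tuple[str, str]]:
    """Parse an ANN-style INFO field into (effect_class, gene_id) pairs.

    Entries are comma-separated annotations of |-delimited fields with the
    effect first and the gene third (effect|impact|gene).  Unrecognised effect
    strings map to class ``"other"``; malformed entries are logged and skipped.
    """
    out: list[tuple[str, str]] = []
    if not ann:
        return out
    for entry in str(ann).split(","):
        parts = entry.split("|")
        if len(parts) < 3 or not parts[0] or not parts[2]:
            logger.warning("malformed ANN entry skipped: %r", entry)
            continue
        effect = _EFFECT_ALIASES.get(parts[0].strip(), "other")
        out.append((effect, parts[2].strip()))
    return out


@dataclass(frozen=True)
class BreedVariantSet:
    """Genes carrying variants unique to one breed versus the backgrounds."""

    target_breed: str
    background_breeds: tuple[str, ...]
    effect_classes: frozenset[str]
    genes: frozenset[str]
    variant_indices: tuple[int, ...] = ()


def _resolve_pools(pool_names: Sequence[str], target, backgrounds) -> tuple[int, list[int]]:
    names = list(pool_names)
    t = names.index(target) if isinstance(target, str) else int(target)
    bg = [names.index(b) if isinstance(b, str) else int(b) for b in backgrounds]
    if t in bg:
        raise ValueError("target breed cannot also be a background breed")
    return t, bg


def breed_unique_function_altering(
    variants: Sequence,
    presence: np.ndarray,
    pool_names: Sequence[str],
    target: str | int,
    backgrounds: Sequence[str | int],
    classes: frozenset[str] | set[str] = FUNCTION_ALTERING_CLASSES,
) -> BreedVariantSet:
    """Genes with function-altering variants present in ``target`` only.

    A variant qualifies iff one of its annotated effect classes is in
    ``classes`` AND it is present (per the filter mask) in the target pool AND
    absent in every background pool.
    """
    t, bg = _resolve_pools(pool_names, target, backgrounds)
    genes: set[str] = set()
    hits: list[int] = []
    for i, v in enumerate(variants):
        if not presence[i, t] or any(presence[i, b] for b in bg):
            continue
        v_genes = {g for eff, g in v.effects if eff in classes}
        if v_genes:
            genes |= v_genes
            hits.append(i)
    return BreedVariantSet(
        target_breed=str(pool_names[t]),
        background_breeds=tuple(str(pool_names[b]) for b in bg),
        effect_classes=frozenset(classes),
        genes=frozenset(genes),
        variant_indices=tuple(hits),
    )


def promoter_variants(
    variants: Sequence,
    presence: np.ndarray,
    gene_models: Sequence,
    pool_names: Sequence[str],
    target: str | int,
    backgrounds: Sequence[str | int],
    flank: int = 1000,
) -> BreedVariantSet:
    """Genes with promoter-region variants present in ``target`` only.

    Promoter region (as commonly defined for this scan): within ``flank`` bp
    outside either gene bound — upstream or downstream — excluding the gene
    body itself.
    """
    t, bg = _resolve_pools(pool_names, target, backgrounds)
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        tree = trees.setdefault(g.chrom, IntervalTree())
        if g.start > 0:
            tree[max(0, g.start - flank):g.start] = g.gene_id
        tree[g.end:g.end + flank] = g.gene_id
    bodies: dict[str, IntervalTree] = {}
    for g in gene_models:
        bodies.setdefault(g.chrom, IntervalTree())[g.start:g.end] = g.gene_id

    genes: set[str] = set()
    hits: list[int] = []
    for i, v in enumerate(variants):
        if not presence[i, t] or any(presence[i, b] for b in bg):
            continue
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        flanked = {iv.data for iv in tree[v.pos]}
        if not flanked:
            continue
        inside = {iv.data for iv in bodies[v.chrom][v.pos]}
        v_genes = flanked - inside  # a SNP inside gene A can still be promoter of gene B
        if v_genes:
            genes |= v_genes
            hits.append(i)
    return BreedVariantSet(
        target_breed=str(pool_names[t]),
        background_breeds=tuple(str(pool_names[b]) for b in bg),
        effect_classes=frozenset({"promoter"}),
        genes=frozenset(genes),
        variant_indices=tuple(hits),
    )


@dataclass
class TermMap:
    """term_id -> gene set mapping over a gene universe, for enrichment."""

    terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(*self.terms.values()) if self.terms else frozenset()
        for term, genes in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} has genes outside the universe")

    @classmethod
    def from_tsv(cls, path, universe=None, names_path=None) -> "TermMap":
        """Two-column TSV (term_id, gene_id); optional (term_id, name) table."""
        df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], comment="#")
        terms = {
            term: frozenset(sub["gene"]) for term, sub in df.groupby("term", sort=True)
        }
        names = {}
        if names_path is not None:
            ndf = pd.read_csv(names_path, sep="\t", header=None,
                              names=["term", "name"], comment="#")
            names = dict(zip(ndf["term"], ndf["name"]))
        return cls(terms=terms, names=names,
                   universe=frozenset(universe) if universe else frozenset())


def overlap_pvalue(overlap: int, universe: int, term_size: int, query_size: int) -> float:
    """Hypergeometric upper-tail P(X >= overlap) for one term/query overlap."""
    return float(hypergeom.sf(overlap - 1, universe, term_size, query_size))


def enrichment_test(
    query_genes: set[str] | frozenset[str],
    term_map: TermMap,
    p_cutoff: float = 0.1,
    correction: str = "benjamini-hochberg",
) -> pd.DataFrame:
    """Hypergeometric over-representation test with BH adjustment.

    For each term with k of its K genes in the query (size n, universe N), the
    p-value is the hypergeometric upper tail P(X >= k).  Rows with adjusted
    p < ``p_cutoff`` are flagged ``significant``.  Query genes outside the
    universe are dropped with a warning; empty terms are skipped.
    """
    if correction not in ("benjamini-hochberg", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    universe = term_map.universe
    query = set(query_genes)
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
        query &= universe
    columns = ["term", "name", "term_size", "query_size", "overlap", "p", "p_adj", "significant"]
    if not query:
        return pd.DataFrame(columns=columns)

    big_n = len(universe)
    n = len(query)
    rows = []
    for term, genes in sorted(term_map.terms.items()):
        big_k = len(genes)
        if big_k == 0:
            continue
        k = len(genes & query)
        p = overlap_pvalue(k, big_n, big_k, n)
        rows.append((term, term_map.names.get(term, ""), big_k, n, k, p))
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows, columns=columns[:6])
    if correction == "benjamini-hochberg":
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adj"] = df["p"]
    df["significant"] = df["p_adj"] < p_cutoff
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
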