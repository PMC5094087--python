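"""Breed-unique variant gene sets and a term-enrichment demonstration.

Reads the cohort VCF/GFF3 from 01, derives each breed's unique
function-altering (missense / stop gained / stop lost) and promoter (±1 kb)
gene sets, then runs the hypergeometric + Benjamini–Hochberg enrichment test
against a synthetic term map built by striping the toy genes into terms (so
one term is deliberately loaded with one breed's planted private genes).

Run from the repository root, after 01:
    python analysis/04_variant_sets_enrichment.py
"""

from pathlib import Path

import pandas as pd

from poolscan.experiments import default_cohort_design
from poolscan.simulate import simulate_cohort
from poolscan.variant_sets import (
    TermMap,
    breed_unique_function_altering,
    enrichment_test,
    promoter_variants,
)
from poolscan.vcfio import filter_variants, read_gene_models, read_pool_vcf

SEED = 20160101
SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")


def synthetic_term_map(genes, private_genes) -> TermMap:
    """One term per breed's planted private genes, plus striped filler terms."""
    universe = frozenset(g.gene_id for g in genes)
    terms: dict[str, set] = {}
    loaded: set = set()
    for b, gs in sorted(private_genes.items()):
        terms[f"T_private_breed{b + 1}"] = set(gs)
        loaded |= gs
    rest = sorted(universe - loaded)
    for i, gene in enumerate(rest):
        terms.setdefault(f"T{i % 9}", set()).add(gene)
    return TermMap(
        terms={t: frozenset(g) for t, g in terms.items() if g}, universe=universe
    )


def main() -> None:
    design = default_cohort_design(SEED)
    cohort = simulate_cohort(design)
    variants = list(read_pool_vcf(SCRATCH / "cohort.vcf", design.pool_names))
    kept, presence = filter_variants(variants)
    genes = read_gene_models(SCRATCH / "genes.gff3")
    term_map = synthetic_term_map(genes, cohort.private_genes)

    set_rows, enr_frames = [], []
    for target in design.pool_names:
        backgrounds = [p for p in design.pool_names if p != target]
        fa = breed_unique_function_altering(kept, presence, design.pool_names,
                                            target, backgrounds)
        prom = promoter_variants(kept, presence, genes, design.pool_names,
                                 target, backgrounds)
        set_rows.append({"breed": target,
                         "function_altering_genes": len(fa.genes),
                         "promoter_genes": len(prom.genes)})
        enr = enrichment_test(fa.genes, term_map)
        enr.insert(0, "breed", target)
        enr_frames.append(enr)
        top = enr.iloc[0]
        print(f"{target}: {len(fa.genes)} unique function-altering genes, "
              f"{len(prom.genes)} unique promoter genes; top term "
              f"{top['term']} (adj p = {top['p_adj']:.3g})")

    pd.DataFrame(set_rows).to_csv(RESULTS / "breed_unique_set_sizes.tsv",
                                  sep="\t", index=False)
    pd.concat(enr_frames).to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    print(f"tables at {RESULTS / 'breed_unique_set_sizes.tsv'} and "
          f"{RESULTS / 'enrichment.tsv'}")


if __name__ == "__main__":
    main()
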