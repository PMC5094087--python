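"""Region-haplotype carrier frequencies across populations.

Validation analysis for candidate sweep regions: given phased genotypes of a
SNP panel spanning a region, count how many chromosomes in each breed carry a
reference haplotype (by default the modal haplotype of the pooled panel) and
test pairwise frequency differences between breeds with Fisher's exact test
on carrier-chromosome counts (chi-square available as an alternative),
adjusting the pairwise matrix with Benjamini–Hochberg.

Missing genotype calls are wildcard by default: a missing site never counts
as a mismatch against the reference haplotype (strict handling is available
behind ``missing_is_mismatch``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhasedPanel",
    "HaplotypeFreqTable",
    "haplotype_frequencies",
    "compare_haplotype_frequencies",
    "all_pairwise",
    "modal_haplotype",
]

MISSING = "."


@dataclass(frozen=True)
class PhasedPanel:
    """Phased genotypes of a SNP panel: two allele strings per individual.

    Alleles are '0', '1' or '.' (missing); both haplotype strings of every
    individual must have one character per panel site.
    """

    individuals: tuple[tuple[str, str], ...]  # (individual_id, breed)
    sites: tuple[int, ...]  # ordered SNP positions
    haplotypes: tuple[tuple[str, str], ...]  # (hap1, hap2) per individual

    def __post_init__(self) -> None:
        if len(self.individuals) != len(self.haplotypes):
            raise ValueError("one haplotype pair required per individual")
        n = len(self.sites)
        for (ind, _breed), (h1, h2) in zip(self.individuals, self.haplotypes):
            if len(h1) != n or len(h2) != n:
                raise ValueError(f"individual {ind}: haplotype length != {n} sites")
            for h in (h1, h2):
                bad = set(h) - {"0", "1", MISSING}
                if bad:
                    raise ValueError(f"individual {ind}: invalid alleles {bad}")

    @property
    def breeds(self) -> list[str]:
        seen: list[str] = []
        for _ind, breed in self.individuals:
            if breed not in seen:
                seen.append(breed)
        return seen

    def chromosomes(self) -> list[tuple[str, str]]:
        """All (breed, haplotype string) chromosomes in panel order."""
        out = []
        for (_ind, breed), (h1, h2) in zip(self.individuals, self.haplotypes):
            out.append((breed, h1))
            out.append((breed, h2))
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhasedPanel":
        """Read a panel TSV: individual, breed, hap1, hap2 (header optional)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "individual":
                    continue
                if len(parts) < 4:
                    raise ValueError(f"panel line needs 4 columns: {line!r}")
                rows.append(parts[:4])
        if not rows:
            raise ValueError(f"empty panel file {path}")
        n_sites = len(rows[0][2])
        return cls(
            individuals=tuple((r[0], r[1]) for r in rows),
            sites=tuple(range(n_sites)),
            haplotypes=tuple((r[2], r[3]) for r in rows),
        )


@dataclass(frozen=True)
class HaplotypeFreqTable:
    """Carrier-chromosome counts and frequencies per breed."""

    reference: str
    counts: dict[str, tuple[int, int]]  # breed -> (carriers, total chromosomes)

    def frequency(self, breed: str) -> float:
        carriers, total = self.counts[breed]
        return carriers / total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"breed": b, "carrier_chromosomes": c, "total_chromosomes": t,
             "frequency": c / t}
            for b, (c, t) in self.counts.items()
        ]
        return pd.DataFrame(rows)


def modal_haplotype(panel: PhasedPanel) -> str:
    """Most frequent complete (no-missing) haplotype of the pooled panel."""
    counter = Counter(
        h for _breed, h in panel.chromosomes() if MISSING not in h
    )
    if not counter:
        raise ValueError("no complete haplotypes in panel")
    # deterministic tie-break: highest count, then lexicographic
    return min(counter, key=lambda h: (-counter[h], h))


def _matches(hap: str, ref: str, max_mismatch: int, missing_is_mismatch: bool) -> bool:
    mismatches = 0
    for a, r in zip(hap, ref):
        if a == MISSING:
            if missing_is_mismatch:
                mismatches += 1
        elif a != r:
            mismatches += 1
        if mismatches > max_mismatch:
            return False
    return True


def haplotype_frequencies(
    panel: PhasedPanel,
    reference_haplotype: str | None = None,
    max_mismatch: int = 0,
    missing_is_mismatch: bool = False,
) -> HaplotypeFreqTable:
    """Carrier frequency of a reference haplotype per breed.

    A chromosome is a carrier iff it matches the reference with at most
    ``max_mismatch`` mismatches; missing sites are wildcards by default.  The
    reference defaults to the modal haplotype of the pooled panel.
    """
    ref = reference_haplotype if reference_haplotype is not None else modal_haplotype(panel)
    if len(ref) != len(panel.sites):
        raise ValueError(
            f"reference length {len(ref)} != panel site count {len(panel.sites)}"
        )
    counts: dict[str, list[int]] = {}
    for breed, hap in panel.chromosomes():
        c = counts.setdefault(breed, [0, 0])
        c[1] += 1
        if _matches(hap, ref, max_mismatch, missing_is_mismatch):
            c[0] += 1
    return HaplotypeFreqTable(
        reference=ref, counts={b: (c[0], c[1]) for b, c in counts.items()}
    )


def compare_haplotype_frequencies(
    table: HaplotypeFreqTable,
    breed_a: str,
    breed_b: str,
    method: str = "fisher",
) -> float:
    """Two-sided p-value for a carrier-frequency difference between 2 breeds."""
    ca, ta = table.counts[breed_a]
    cb, tb = table.counts[breed_b]
    if ta == 0 or tb == 0:
        raise ValueError("both breeds need >= 1 chromosome")
    contingency = np.array([[ca, ta - ca], [cb, tb - cb]])
    if method == "fisher":
        return float(fisher_exact(contingency, alternative="two-sided")[1])
    if method == "chi2":
        return float(chi2_contingency(contingency, correction=False)[1])
    raise ValueError(f"unknown method {method!r}")


def all_pairwise(table: HaplotypeFreqTable, method: str = "fisher") -> pd.DataFrame:
    """Symmetric matrix of pairwise p-values, BH-adjusted across the pair set."""
    breeds = list(table.counts)
    mat = pd.DataFrame(np.ones((len(breeds), len(breeds))), index=breeds, columns=breeds)
    pairs = list(combinations(breeds, 2))
    if not pairs:
        return mat
    raw = [compare_haplotype_frequencies(table, a, b, method=method) for a, b in pairs]
    adj = multipletests(raw, method="fdr_bh")[1]
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = p
        mat.loc[b, a] = p
    return mat
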