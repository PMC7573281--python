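"""Enrichment and tumor-incidence statistics.

Covers the statistical layer of the strain comparison: one-sided
hypergeometric (Fisher exact) over-representation of gene sets with the
-log10(p) > 3 gate, backcross tumor incidence proportions, Pearson
goodness-of-fit against a Mendelian segregation ratio, 2x2 independence
chi-square (with and without the Yates correction), and the polygenic
expectation 0.5**n for n unlinked heterozygous modifier loci segregating in
a backcross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "IncidenceTable",
    "GeneSet",
    "fisher_overrepresentation",
    "incidence",
    "mendelian_gof",
    "contingency_chi2",
    "polygenic_expectation",
    "enrichment_table",
]

SCORE_GATE = 3.0  # -log10(p) threshold for keeping a gene set


@dataclass
class IncidenceTable:
    scheme: str
    n_tumor: int
    n_non_tumor: int

    def __post_init__(self) -> None:
        if self.n_tumor < 0 or self.n_non_tumor < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_tumor + self.n_non_tumor


@dataclass
class GeneSet:
    set_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} is empty")


def fisher_overrepresentation(
    query: Iterable[str], pathway: GeneSet, universe: Iterable[str]
) -> tuple[float, float, bool]:
    """One-sided hypergeometric over-representation test.

    Returns (p, -log10 p, keep) where keep means the score exceeds the
    -log10(p) > 3 gate (p < 0.001).  The pathway is intersected with the
    universe before testing; the query must be contained in it.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    members = pathway.members & universe
    overlap = len(query & members)
    m, n_path, n_query = len(universe), len(members), len(query)
    # P(overlap >= observed) under sampling n_query genes without replacement
    p = float(stats.hypergeom.sf(overlap - 1, m, n_path, n_query))
    p = min(max(p, 0.0), 1.0)
    score = -math.log10(p) if p > 0 else math.inf
    return p, score, score > SCORE_GATE


def incidence(table: IncidenceTable) -> float:
    """Tumor incidence as a percentage, one decimal."""
    if table.total == 0:
        raise ValueError("empty incidence table")
    return round(100.0 * table.n_tumor / table.total, 1)


def mendelian_gof(
    observed: tuple[int, int], expected_ratio: float = 0.5
) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) of an observed
    (tumor, non-tumor) split against an expected tumor proportion.

    For a single unlinked modifier segregating in a backcross the expected
    ratio is 1/2.
    """
    n_tumor, n_non = observed
    total = n_tumor + n_non
    if total <= 0:
        raise ValueError("observed counts sum to zero")
    if not 0 < expected_ratio < 1:
        raise ValueError("expected_ratio must be in (0,1)")
    expected = np.array([total * expected_ratio, total * (1 - expected_ratio)])
    if (expected == 0).any():
        raise ValueError("zero expected cell")
    obs = np.array([n_tumor, n_non], dtype=float)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, 1, p


def contingency_chi2(table: Sequence[Sequence[int]]) -> dict[str, float]:
    """Pearson chi-square of independence on a 2x2 table.

    Returns both the uncorrected statistic and the Yates-corrected one,
    each with its p-value (df = 1).  Expected counts are row*col/total.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal")
    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    chi2 = float(((t - expected) ** 2 / expected).sum())
    chi2_yates = float(((np.abs(t - expected) - 0.5).clip(min=0) ** 2 / expected).sum())
    return {
        "chi2": chi2,
        "p": float(stats.chi2.sf(chi2, df=1)),
        "chi2_yates": chi2_yates,
        "p_yates": float(stats.chi2.sf(chi2_yates, df=1)),
        "df": 1,
    }


def polygenic_expectation(n_unlinked_loci: int) -> float:
    """Expected fraction (percent) of backcross hybrids inheriting the
    permissive genotype at n unlinked heterozygous loci: 100 * 0.5**n."""
    if n_unlinked_loci < 1:
        raise ValueError("need at least one locus")
    return 100.0 * 0.5**n_unlinked_loci


def enrichment_table(
    query: Iterable[str],
    pathways: Mapping[str, GeneSet] | Sequence[GeneSet],
    universe: Iterable[str],
) -> "list[dict]":
    """Test every pathway and return one row per set (no cross-set multiple
    testing correction: the gate is on raw p < 0.001)."""
    if isinstance(pathways, Mapping):
        pathways = list(pathways.values())
    universe = set(universe)
    query = set(query)
    rows = []
    for ps in pathways:
        p, score, keep = fisher_overrepresentation(query, ps, universe)
        rows.append(
            {
                "set_id": ps.set_id,
                "n_set": len(ps.members & universe),
                "n_overlap": len(query & ps.members & universe),
                "p": p,
                "score": score,
                "keep": keep,
            }
        )
    return rows
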