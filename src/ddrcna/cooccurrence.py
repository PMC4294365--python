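"""Pairwise co-segregation / mutual-exclusivity screening of gene CNAs.

Every gene pair is cross-classified into a 2x2 table of altered/neutral
patients and tested with Fisher's exact test, one-sided in each direction:
``greater`` asks whether the genes are co-altered more often than chance
(co-segregation), ``less`` whether they avoid each other (mutual
exclusivity).  P-values are Bonferroni-corrected by the number of tested
pairs, separately per side.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import DataError


@dataclass
class PairwiseResult:
    gene_a: str
    gene_b: str
    both: int
    a_only: int
    b_only: int
    neither: int
    odds_direction: str  # "co-occurrence" | "exclusivity" | "none"
    p_cooccurrence: float
    p_exclusivity: float
    p_cooccurrence_bonf: float
    p_exclusivity_bonf: float
    significant: bool


def _altered_mask(matrix: pd.DataFrame, gene: str, altered_def: str) -> np.ndarray:
    if gene not in matrix.columns:
        raise DataError(f"gene {gene!r} not in CNA matrix")
    col = matrix[gene].to_numpy()
    return {"any": col != 0, "gain": col == 1, "loss": col == -1}[altered_def]


def build_pair_table(
    matrix: pd.DataFrame, gene_a: str, gene_b: str, altered_def: str = "any"
) -> tuple[int, int, int, int]:
    """Counts (both altered, a only, b only, neither); sums to cohort size."""
    a = _altered_mask(matrix, gene_a, altered_def)
    b = _altered_mask(matrix, gene_b, altered_def)
    return (
        int((a & b).sum()),
        int((a & ~b).sum()),
        int((~a & b).sum()),
        int((~a & ~b).sum()),
    )


def fisher_exact(table, side: str = "two") -> float:
    """Fisher's exact test on a 2x2 table with margins fixed.

    ``side='greater'`` is the co-occurrence tail (more double-altered
    patients than expected), ``'less'`` the exclusivity tail, ``'two'`` the
    usual two-sided test.
    """
    arr = np.asarray(table, dtype=float).reshape(2, 2)
    if (arr < 0).any():
        raise DataError("2x2 table has negative counts")
    alternative = {"greater": "greater", "less": "less", "two": "two-sided"}[side]
    return float(sps.fisher_exact(arr, alternative=alternative).pvalue)


def screen_all_pairs(
    matrix: pd.DataFrame,
    genes=None,
    alpha: float = 0.05,
    altered_def: str = "any",
) -> list[PairwiseResult]:
    """Fisher-test all gene pairs both ways with per-side Bonferroni.

    The Bonferroni multiplier is the number of tested pairs C(k, 2);
    ``alpha`` is the post-correction significance threshold.  Results come
    back sorted by the smaller corrected p-value.
    """
    if genes is None:
        genes = list(matrix.columns)
    if len(genes) < 2:
        raise DataError("need at least 2 genes to screen pairs")
    pairs = list(combinations(genes, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        both, a_only, b_only, neither = build_pair_table(matrix, a, b, altered_def)
        tab = [[both, a_only], [b_only, neither]]
        p_co = fisher_exact(tab, "greater")
        p_ex = fisher_exact(tab, "less")
        p_co_b = min(1.0, m * p_co)
        p_ex_b = min(1.0, m * p_ex)
        if p_co_b < p_ex_b:
            direction = "co-occurrence"
        elif p_ex_b < p_co_b:
            direction = "exclusivity"
        else:
            direction = "none"
        results.append(
            PairwiseResult(
                gene_a=a,
                gene_b=b,
                both=both,
                a_only=a_only,
                b_only=b_only,
                neither=neither,
                odds_direction=direction,
                p_cooccurrence=p_co,
                p_exclusivity=p_ex,
                p_cooccurrence_bonf=p_co_b,
                p_exclusivity_bonf=p_ex_b,
                significant=min(p_co_b, p_ex_b) < alpha,
            )
        )
    results.sort(key=lambda r: min(r.p_cooccurrence_bonf, r.p_exclusivity_bonf))
    return results


def results_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
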