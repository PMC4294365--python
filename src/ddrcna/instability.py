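"""Percent genome aberration (PGA) and its association with gene CNA status.

PGA is the cumulative length of a patient's aberrant regions divided by the
total genome size, x100.  Because a gene's own copy-number call can sit
inside a large aberration on its chromosome — mechanically coupling the call
to PGA — each gene also gets an *adjusted* PGA that excludes that gene's
chromosome from both numerator and denominator.  Associations are tested by
Mann-Whitney U and Welch t-tests, and by ordinary least squares adjusting
for the dichotomized clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .errors import ConfigurationError, DataError

CLINICAL_COVARIATES = ["psa_ge10", "t2_t3", "gs_ge7"]


def _aberrant_bp(regions: pd.DataFrame, chrom_sizes: dict[str, int], patients):
    """Per-(patient, chromosome) aberrant base pairs as a pivoted frame."""
    for chrom, grp in regions.groupby("chrom", observed=True):
        if chrom not in chrom_sizes:
            raise DataError(f"region chromosome {chrom!r} not in chrom sizes")
        if (grp["end"].to_numpy() > chrom_sizes[chrom]).any():
            raise DataError(f"region beyond end of {chrom}")
    lengths = regions["end"] - regions["start"]
    table = (
        pd.DataFrame(
            {
                "patient_id": regions["patient_id"],
                "chrom": regions["chrom"],
                "bp": lengths,
            }
        )
        .groupby(["patient_id", "chrom"], observed=True)["bp"]
        .sum()
        .unstack(fill_value=0)
    )
    return table.reindex(index=patients, columns=list(chrom_sizes), fill_value=0)


def compute_pga(
    regions: pd.DataFrame, chrom_sizes: dict[str, int], patients
) -> pd.DataFrame:
    """Raw PGA per patient: 100 x aberrant bp / total genome bp.

    ``patients`` fixes the row universe so region-free patients score 0.
    Assumes regions of one patient do not overlap (guaranteed upstream).
    """
    bp = _aberrant_bp(regions, chrom_sizes, patients)
    total = sum(chrom_sizes.values())
    out = pd.DataFrame(index=bp.index)
    out["raw_pga"] = 100.0 * bp.sum(axis=1) / total
    return out


def compute_adjusted_pga(
    regions: pd.DataFrame,
    chrom_sizes: dict[str, int],
    gene_chroms: dict[str, str],
    patients,
) -> pd.DataFrame:
    """Per-gene chromosome-excluded PGA.

    For a gene on chromosome c the adjusted PGA is
    100 x (aberrant bp off c) / (genome size minus c), so an association of
    the gene with instability must show up genome-wide, not just through its
    own chromosome.  Returns a frame with ``raw_pga`` plus one ``adj_<GENE>``
    column per gene.
    """
    if len(chrom_sizes) < 2:
        raise ConfigurationError("adjusted PGA needs >= 2 chromosomes")
    bp = _aberrant_bp(regions, chrom_sizes, patients)
    total = sum(chrom_sizes.values())
    out = pd.DataFrame(index=bp.index)
    out["raw_pga"] = 100.0 * bp.sum(axis=1) / total
    for gene, chrom in gene_chroms.items():
        if chrom not in chrom_sizes:
            raise DataError(f"gene {gene} on unknown chromosome {chrom!r}")
        denom = total - chrom_sizes[chrom]
        numer = bp.sum(axis=1) - (bp[chrom] if chrom in bp.columns else 0)
        out[f"adj_{gene}"] = 100.0 * numer / denom
    return out


@dataclass
class PgaAssociation:
    """Result of a two-group or regression PGA association test."""

    gene: str
    method: str
    n_altered: int
    n_neutral: int
    statistic: float
    p_value: float
    table: pd.DataFrame | None = None  # regression coefficient table


def _split_groups(profiles, matrix, gene, pga_column, altered="any"):
    if gene not in matrix.columns:
        raise DataError(f"gene {gene!r} not in CNA matrix")
    col = matrix[gene].reindex(profiles.index)
    if altered == "any":
        mask = col != 0
    elif altered == "gain":
        mask = col == 1
    elif altered == "loss":
        mask = col == -1
    else:
        raise ConfigurationError(f"unknown altered definition {altered!r}")
    values = profiles[pga_column]
    a, b = values[mask], values[col == 0]
    if len(a) < 2 or len(b) < 2:
        raise DataError(
            f"gene {gene}: need >=2 patients per group "
            f"(altered {len(a)}, neutral {len(b)})"
        )
    return a.to_numpy(float), b.to_numpy(float)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration for pooled n <= 20 without ties, otherwise the normal
    approximation with tie correction and continuity correction.  A fully
    degenerate comparison (all pooled values identical) returns p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def associate_pga(
    profiles: pd.DataFrame,
    matrix: pd.DataFrame,
    gene: str,
    method: str = "mann_whitney",
    pga_column: str | None = None,
    altered: str = "any",
) -> PgaAssociation:
    """Test PGA against a gene's CNA status (altered vs neutral).

    ``altered`` defaults to gain-or-loss; ``pga_column`` defaults to the
    gene's chromosome-adjusted PGA when present, else raw PGA.
    """
    if pga_column is None:
        pga_column = f"adj_{gene}" if f"adj_{gene}" in profiles.columns else "raw_pga"
    a, b = _split_groups(profiles, matrix, gene, pga_column, altered)
    if method == "mann_whitney":
        stat, p = mann_whitney(a, b)
    elif method == "t_test":
        res = sps.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    return PgaAssociation(
        gene=gene,
        method=method,
        n_altered=len(a),
        n_neutral=len(b),
        statistic=stat,
        p_value=p,
    )


def pga_regression(
    profiles: pd.DataFrame,
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    gene: str,
    pga_column: str | None = None,
    altered: str = "any",
) -> PgaAssociation:
    """OLS of (adjusted) PGA on gene status plus clinical covariates.

    Model: pga ~ altered + PSA>=10 + T2-T3 + GS>=7, all indicators.
    Raises if any design column is constant (degenerate design).
    """
    if pga_column is None:
        pga_column = f"adj_{gene}" if f"adj_{gene}" in profiles.columns else "raw_pga"
    if gene not in matrix.columns:
        raise DataError(f"gene {gene!r} not in CNA matrix")
    col = matrix[gene].reindex(profiles.index)
    ind = {"any": col != 0, "gain": col == 1, "loss": col == -1}[altered]
    X = pd.DataFrame({"altered": ind.astype(float)}, index=profiles.index)
    for c in CLINICAL_COVARIATES:
        if c not in clinical.columns:
            raise DataError(f"clinical table lacks covariate {c!r}")
        X[c] = clinical.set_index("patient_id").loc[profiles.index, c].astype(float)
    for c in X.columns:
        if X[c].nunique() < 2:
            raise DataError(f"design column {c!r} is constant")
    fit = sm.OLS(profiles[pga_column].to_numpy(float), sm.add_constant(X)).fit()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return PgaAssociation(
        gene=gene,
        method="ols",
        n_altered=int(ind.sum()),
        n_neutral=int((col == 0).sum()),
        statistic=float(fit.tvalues["altered"]),
        p_value=float(fit.pvalues["altered"]),
        table=table,
    )
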