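"""NanoString-style normalization and expression/radioresistance analyses.

Normalization follows the vendor-conventional three-step scheme: lane
scaling to the positive-control geometric mean, background subtraction of
the negative-control mean (floored at zero), then content scaling to the
housekeeping geometric mean.  Downstream: Welch t-test of abundance by
copy-number group, median-stratified Kaplan-Meier survival, and ordinary
least squares of clonogenic surviving fraction (SF3Gy) on normalized
abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import ConfigurationError, DataError
from . import survival as surv


def _geomean(values: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.exp(np.log(values).mean(axis=0))


def nanostring_normalize(
    counts: pd.DataFrame,
    probe_classes: pd.Series,
    background: str = "mean",
) -> pd.DataFrame:
    """Normalize a lane x probe count table; returns endogenous abundances.

    Steps, per lane: (1) scale all counts by (grand geometric mean of the
    per-lane positive-control geometric means) / (this lane's
    positive-control geometric mean); (2) subtract the lane's
    negative-control background (``mean`` or ``mean_2sd``), floor at 0;
    (3) scale endogenous counts by the analogous housekeeping
    geometric-mean factor.

    Parameters
    ----------
    counts : DataFrame probes x lanes (non-negative)
    probe_classes : Series probe -> {endogenous, positive, negative,
        housekeeping}
    """
    if counts.shape[1] < 2:
        raise DataError("need at least 2 lanes to normalize")
    cls = probe_classes.reindex(counts.index)
    if cls.isna().any():
        raise DataError("every probe needs a class annotation")
    pos = counts[cls == "positive"].to_numpy(float)
    neg = counts[cls == "negative"].to_numpy(float)
    hk = counts[cls == "housekeeping"].to_numpy(float)
    endo = counts[cls == "endogenous"].astype(float)
    if pos.shape[0] != 6 or neg.shape[0] != 8 or hk.shape[0] != 3:
        raise DataError(
            f"expected 6 positive / 8 negative / 3 housekeeping probes, got "
            f"{pos.shape[0]}/{neg.shape[0]}/{hk.shape[0]}"
        )

    pos_gm = _geomean(pos)
    if (pos_gm <= 0).any() or not np.isfinite(pos_gm).all():
        bad = list(counts.columns[(pos_gm <= 0) | ~np.isfinite(pos_gm)])
        raise DataError(f"zero positive-control geometric mean in lane(s) {bad}")
    lane_factor = float(np.exp(np.log(pos_gm).mean())) / pos_gm
    endo = endo * lane_factor
    neg = neg * lane_factor
    hk = hk * lane_factor

    if background == "mean":
        bg = neg.mean(axis=0)
    elif background == "mean_2sd":
        bg = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    else:
        raise ConfigurationError(f"unknown background mode {background!r}")
    endo = (endo - bg).clip(lower=0.0)
    hk_sub = np.clip(hk - bg, 0.0, None)

    hk_gm = _geomean(hk_sub)
    if (hk_gm <= 0).any() or not np.isfinite(hk_gm).all():
        bad = list(counts.columns[(hk_gm <= 0) | ~np.isfinite(hk_gm)])
        raise DataError(f"zero housekeeping geometric mean in lane(s) {bad}")
    content_factor = float(np.exp(np.log(hk_gm).mean())) / hk_gm
    return endo * content_factor


def cna_mrna_association(
    matrix: pd.DataFrame, abundance: pd.Series, gene: str
) -> tuple[float, float]:
    """Welch two-sample t-test of abundance: gain vs neutral carriers.

    Returns (t statistic, two-sided p).  Identical groups give t = 0, p = 1.
    """
    if gene not in matrix.columns:
        raise DataError(f"gene {gene!r} not in CNA matrix")
    status = matrix[gene].reindex(abundance.index)
    a = abundance[status == 1].to_numpy(float)
    b = abundance[status == 0].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise DataError(f"gene {gene}: need >=2 samples per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def median_stratified_km(
    abundance: pd.Series,
    records: pd.DataFrame,
    horizon: float | None = 5.0,
):
    """Kaplan-Meier curves for low vs high expression split at the median.

    Samples at or below the median go to the low stratum (ties low).
    Returns (curves dict, log-rank chi-square, log-rank p).
    """
    if len(abundance) < 4:
        raise DataError("median stratification needs >=4 samples")
    if abundance.nunique() < 2:
        raise DataError("constant abundance cannot be median-stratified")
    med = float(abundance.median())
    strata = pd.Series(
        np.where(abundance <= med, "low", "high"), index=abundance.index
    )
    rec = records.set_index("patient_id").loc[abundance.index].reset_index()
    rec["expr_stratum"] = strata.to_numpy()
    if horizon is not None:
        rec = surv.censor_at_horizon(rec, horizon)
    curves = surv.km_estimate(rec, strata="expr_stratum")
    chi2, p = surv.logrank_test(rec, "expr_stratum")
    return curves, chi2, p


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided t-test on the slope
    n: int


def sf_regression(
    abundance: pd.Series,
    sf3gy: pd.Series,
    exclude: tuple[str, ...] = ("PrEC",),
) -> RegressionResult:
    """OLS of surviving fraction at 3 Gy on normalized mRNA abundance.

    ``exclude`` drops named cell lines before fitting (the default drops
    PrEC, whose clonogenic value is an SF2Gy surrogate).
    """
    keep = [s for s in abundance.index if s not in set(exclude or ())]
    x = abundance.loc[keep].to_numpy(float)
    y = sf3gy.loc[keep].to_numpy(float)
    if len(x) < 3:
        raise DataError(f"need >=3 cell lines after exclusions, got {len(x)}")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )
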