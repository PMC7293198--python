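"""Sensitivity and biomarker statistics for virtual cohorts.

Partial rank correlation coefficients (PRCC) for global sensitivity over
LHS samples, Wilcoxon rank-sum comparisons between responders and
non-responders, and a biomarker summary table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["prcc", "wilcoxon_rank_sum", "biomarker_report", "BIOMARKER_COLUMNS"]


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def prcc(param_matrix, output, names=None) -> pd.Series:
    """Partial rank correlation coefficient of each parameter with an output.

    All columns and the output are rank-transformed (average ranks for
    ties); each parameter's PRCC is the Pearson correlation between the
    residuals of (its ranks ~ other parameters' ranks) and the residuals of
    (output ranks ~ other parameters' ranks), both fitted by OLS with an
    intercept.  Values lie in [-1, 1] and are invariant under strictly
    monotone transforms of any column.
    """
    if isinstance(param_matrix, pd.DataFrame):
        names = list(param_matrix.columns) if names is None else list(names)
        X = param_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(param_matrix, dtype=float)
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(output, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("output length must match the number of samples")
    if n <= k + 2:
        raise ValueError(f"need n > k+2 samples (n={n}, k={k})")
    for j in range(k):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"parameter {names[j]!r} is constant")
    if np.all(y == y[0]):
        raise ValueError("output is constant")

    R = np.column_stack([_rank(X[:, j]) for j in range(k)])
    ry = _rank(y)
    out = {}
    ones = np.ones((n, 1))
    for j in range(k):
        others = np.hstack([ones, np.delete(R, j, axis=1)])
        beta_x, *_ = np.linalg.lstsq(others, R[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, ry, rcond=None)
        ex = R[:, j] - others @ beta_x
        ey = ry - others @ beta_y
        denom = np.sqrt(ex @ ex) * np.sqrt(ey @ ey)
        out[names[j]] = float(ex @ ey / denom) if denom > 0 else 0.0
    return pd.Series(out, name="prcc")


def wilcoxon_rank_sum(group_a, group_b, exact_threshold: int = 20):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with tie correction.

    Uses exact enumeration for small samples (both groups at most
    ``exact_threshold`` and no ties) and the normal approximation otherwise.
    Returns ``(statistic, p_value)`` where the statistic is the Mann-Whitney
    U of the first group.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if max(a.size, b.size) <= exact_threshold and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


#: Biomarker columns reported by default: the parameters and tumor
#: microenvironment endpoints compared between responders and non-responders.
BIOMARKER_COLUMNS = (
    "tmb", "mhc_affinity", "cea_sites", "lambda_crossarm",
    "cd3_sites_treg", "cd3_sites_teff", "teff_density", "treg_density",
    "teff_treg_ratio", "koff_cd3tce",
)


def biomarker_report(cohort, parameters=BIOMARKER_COLUMNS,
                     adjust: bool = False) -> pd.DataFrame:
    """Responder vs non-responder comparison for each candidate biomarker.

    ``cohort`` is a CohortResult or a patient DataFrame with a ``recist``
    column.  Reports group medians, the direction of the difference and the
    two-sided Wilcoxon rank-sum p-value (optionally Benjamini-Hochberg
    adjusted when ``adjust=True``; the raw comparisons are the default).
    """
    df = cohort.patients if hasattr(cohort, "patients") else cohort
    resp = df[df["recist"].isin(["CR", "PR"])]
    nonresp = df[df["recist"].isin(["SD", "PD"])]
    if len(resp) == 0 or len(nonresp) == 0:
        raise ValueError("both responders and non-responders must be present")
    rows = []
    for p in parameters:
        if p not in df.columns:
            continue
        a = resp[p].to_numpy(dtype=float)
        b = nonresp[p].to_numpy(dtype=float)
        stat, pval = wilcoxon_rank_sum(a, b)
        med_r, med_n = float(np.median(a)), float(np.median(b))
        rows.append({"parameter": p, "median_responder": med_r,
                     "median_nonresponder": med_n,
                     "direction": "higher" if med_r > med_n else
                                  ("lower" if med_r < med_n else "equal"),
                     "statistic": stat, "p_value": pval})
    out = pd.DataFrame(rows)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
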