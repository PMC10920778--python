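"""Pre-to-post surgical cognitive change and its association with tumour habitats.

Change is tracked as delta = pre - post z-score per domain, so positive
values mean deterioration. The association battery mirrors a two-arm
design: occupancy regressions with a tumour-volume covariate for the fixed
four-quadrant habitats, presence (Mann-Whitney) comparisons for the
data-driven classes, chi-squared tests against IDH mutation status, a
Pearson covariate screen, and Benjamini-Hochberg FDR correction within
each declared test family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DOMAINS",
    "CognitiveChange",
    "RegressionReport",
    "PresenceComparisonReport",
    "compute_change",
    "occupancy_regression",
    "domain_followup_regressions",
    "presence_comparison",
    "idh_tests",
    "covariate_screen",
    "bh_fdr",
    "f_from_r2",
]

DOMAINS = ("memory", "verbal_skills", "nonverbal_skills", "attention", "executive_function")


@dataclass
class CognitiveChange:
    """Per-domain and mean-overall decline for one participant."""

    delta: dict[str, float]          # NaN where a domain is missing
    mean_overall: float
    excluded: bool                   # True when no post-operative scores exist


def compute_change(
    pre: dict[str, float], post: dict[str, float]
) -> CognitiveChange:
    """Delta = pre - post per domain; mean over domains with both scores."""
    delta = {}
    for d in pre:
        a, b = pre.get(d, np.nan), post.get(d, np.nan)
        delta[d] = a - b if np.isfinite(a) and np.isfinite(b) else np.nan
    avail = [v for v in delta.values() if np.isfinite(v)]
    if not avail:
        return CognitiveChange(delta=delta, mean_overall=np.nan, excluded=True)
    return CognitiveChange(delta=delta, mean_overall=float(np.mean(avail)), excluded=False)


@dataclass
class RegressionReport:
    """OLS of cognitive change on one habitat's occupancy plus tumour volume."""

    r_squared: float
    f_stat: float
    df1: int
    df2: int
    slope: float            # change per % occupancy
    se_slope: float
    p_slope: float
    p_model: float
    eta_squared: float
    n: int
    p_fdr: float = np.nan

    def __post_init__(self) -> None:
        # F and R^2 must agree: F = (R^2/df1) / ((1-R^2)/df2)
        expect = f_from_r2(self.r_squared, self.df1, self.df2)
        both_huge = expect > 1e12 and self.f_stat > 1e12
        if not both_huge and not math.isclose(
            expect, self.f_stat, rel_tol=1e-6, abs_tol=1e-9
        ):
            raise AssertionError("F statistic inconsistent with R^2")


def f_from_r2(r2: float, df1: int, df2: int) -> float:
    """Model F statistic implied by R^2 with (df1, df2) degrees of freedom."""
    if r2 >= 1.0 - 1e-14:       # perfect fit: F diverges
        return math.inf
    return (r2 / df1) / ((1.0 - r2) / df2)


def occupancy_regression(
    change: np.ndarray, occupancy: np.ndarray, volume: np.ndarray
) -> RegressionReport:
    """Regress mean overall decline on (% occupancy, tumour volume) + intercept."""
    change = np.asarray(change, dtype=float)
    occupancy = np.asarray(occupancy, dtype=float)
    volume = np.asarray(volume, dtype=float)
    ok = np.isfinite(change) & np.isfinite(occupancy) & np.isfinite(volume)
    change, occupancy, volume = change[ok], occupancy[ok], volume[ok]
    n = len(change)
    if n < 5:
        raise ValueError(f"need >= 5 complete cases, got {n}")
    if np.ptp(occupancy) == 0:
        raise ValueError("occupancy is constant: rank-deficient design")
    X = sm.add_constant(np.column_stack([occupancy, volume]))
    res = sm.OLS(change, X).fit()
    return RegressionReport(
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue),
        df1=int(res.df_model),
        df2=int(res.df_resid),
        slope=float(res.params[1]),
        se_slope=float(res.bse[1]),
        p_slope=float(res.pvalues[1]),
        p_model=float(res.f_pvalue),
        eta_squared=float(res.rsquared),
        n=n,
    )


def domain_followup_regressions(
    domain_changes: pd.DataFrame, occupancy: np.ndarray, volume: np.ndarray
) -> dict[str, RegressionReport]:
    """Per-domain regressions, run when an overall model survives FDR.

    The returned reports carry ``p_fdr`` adjusted across the domain family.
    """
    reports = {
        d: occupancy_regression(domain_changes[d].to_numpy(), occupancy, volume)
        for d in domain_changes.columns
    }
    adj = bh_fdr([reports[d].p_model for d in domain_changes.columns])
    for d, p in zip(domain_changes.columns, adj):
        reports[d].p_fdr = p
    return reports


@dataclass
class PresenceComparisonReport:
    """Mann-Whitney comparison of decline with/without one habitat class."""

    z: float
    eta_squared: float       # z^2 / N
    p: float
    n_present: int
    n_absent: int
    p_fdr: float = np.nan


def _mannwhitney_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U via the tie-corrected normal approximation.

    Returns (z, p); z is signed so positive means x tends larger than y.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    u = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    if sigma == 0:
        return 0.0, 1.0
    z = (u - mu) / sigma
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def presence_comparison(
    change: np.ndarray, presence: np.ndarray
) -> PresenceComparisonReport:
    """Compare decline between participants with and without a habitat class."""
    change = np.asarray(change, float)
    presence = np.asarray(presence, bool)
    ok = np.isfinite(change)
    change, presence = change[ok], presence[ok]
    x, y = change[presence], change[~presence]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("one presence group is empty")
    z, p = _mannwhitney_z(x, y)
    n = len(change)
    return PresenceComparisonReport(
        z=z, eta_squared=z * z / n, p=p, n_present=len(x), n_absent=len(y)
    )


@dataclass
class IDHTestReport:
    mw_z: float
    mw_p: float
    chi2: float
    chi2_p: float


def idh_tests(
    occupancy: np.ndarray, presence: np.ndarray, idh_mutated: np.ndarray
) -> IDHTestReport:
    """Occupancy-by-IDH Mann-Whitney and presence-by-IDH Pearson chi-squared.

    The chi-squared uses 1 df without continuity correction.
    """
    idh_mutated = np.asarray(idh_mutated, bool)
    presence = np.asarray(presence, bool)
    z, p = _mannwhitney_z(
        np.asarray(occupancy, float)[idh_mutated],
        np.asarray(occupancy, float)[~idh_mutated],
    )
    table = pd.crosstab(presence, idh_mutated)
    if table.shape != (2, 2) or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        raise ValueError("degenerate 2x2 table for chi-squared test")
    chi2, chi2_p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return IDHTestReport(mw_z=z, mw_p=p, chi2=float(chi2), chi2_p=float(chi2_p))


def covariate_screen(
    characteristics: pd.DataFrame, change: np.ndarray
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each characteristic with mean decline.

    Ordinal characteristics (e.g. tumour grade I-IV) must already be
    numerically encoded. Rows: characteristics; columns: r, p, n.
    """
    change = np.asarray(change, float)
    rows = []
    for col in characteristics.columns:
        vals = characteristics[col].to_numpy(dtype=float)
        ok = np.isfinite(vals) & np.isfinite(change)
        if ok.sum() < 3:
            raise ValueError(f"{col}: fewer than 3 complete pairs")
        if np.ptp(vals[ok]) == 0:
            raise ValueError(f"{col}: zero variance")
        r, p = stats.pearsonr(vals[ok], change[ok])
        rows.append({"characteristic": col, "r": float(r), "p": float(p), "n": int(ok.sum())})
    return pd.DataFrame(rows).set_index("characteristic")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
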