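"""Cohort-level statistics: correlations, z-scores and group comparisons.

Associations between per-ROI myelin heterogeneity (MHI) and cognitive test
scores are assessed with Pearson correlation, two-sided p-values from the
t distribution on n−2 degrees of freedom, and confidence intervals from the
Fisher z transform (a seeded percentile bootstrap is available for
comparison).  Significance thresholds use a Bonferroni correction across
the brain regions tested within each cognitive domain.  Group comparability
(age, education, sex) is checked with Welch's t, the chi-square test, and
Shapiro-Wilk / Levene assumption tests, falling back to Mann-Whitney when
parametric assumptions fail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "pearson_with_ci",
    "bonferroni_alpha",
    "cognitive_z_scores",
    "group_comparisons",
    "run_correlation_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Pearson correlation with confidence interval and adjusted threshold."""

    r: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    n: int
    alpha_adjusted: float = 0.05
    significant: bool = False


def _drop_missing_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson_with_ci(
    x,
    y,
    conf: float = 0.95,
    alpha_adjusted: float = 0.05,
    ci_method: str = "fisher",
    n_boot: int = 2000,
    seed: int | None = None,
) -> CorrelationResult:
    """Pearson product-moment correlation with CI and two-sided p-value.

    Missing pairs are dropped listwise.  The p-value comes from
    t = r·sqrt((n−2)/(1−r²)) on n−2 df; the default CI is the Fisher
    z-transform interval, r being back-transformed from
    atanh(r) ± z_(1−(1−conf)/2)/sqrt(n−3).  ``ci_method='bootstrap'``
    substitutes a seeded percentile bootstrap.

    Degenerate cases: zero variance in either variable gives NaN r with a
    log flag; |r| = 1 collapses the CI onto r; n = 3 has no Fisher CI.
    """
    x, y = _drop_missing_pairs(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance in x or y: correlation undefined")
        return CorrelationResult(
            float("nan"), float("nan"), float("nan"), float("nan"), n, alpha_adjusted
        )
    r, p = sps.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))
        ci_low = ci_high = r
        p = 0.0
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = np.empty(n_boot)
        for b in range(n_boot):
            xb, yb = x[idx[b]], y[idx[b]]
            if np.ptp(xb) == 0 or np.ptp(yb) == 0:
                boots[b] = np.nan
            else:
                boots[b] = np.corrcoef(xb, yb)[0, 1]
        lo, hi = np.nanpercentile(boots, [100 * (1 - conf) / 2, 100 * (1 + conf) / 2])
        ci_low, ci_high = float(lo), float(hi)
    elif n < 4:
        ci_low = ci_high = float("nan")
    else:
        z = math.atanh(r)
        half = sps.norm.ppf(0.5 + conf / 2) / math.sqrt(n - 3)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    p = float(p)
    return CorrelationResult(
        r, ci_low, ci_high, p, n, alpha_adjusted, bool(p < alpha_adjusted)
    )


def bonferroni_alpha(family_alpha: float, m: int) -> tuple[float, float]:
    """Bonferroni-adjusted per-test threshold for ``m`` comparisons.

    Returns ``(alpha, alpha_display)`` where the display value is truncated
    to 3 decimals, matching the convention of quoting e.g. 0.05/3 as .016.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    alpha = family_alpha / m
    return alpha, math.floor(alpha * 1000) / 1000


def cognitive_z_scores(scores, control_scores) -> np.ndarray:
    """Standardize scores against the control sample (mean / sample SD).

    NaN scores propagate; requires at least 2 finite control values and a
    positive control SD.
    """
    scores = np.asarray(scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    controls = controls[np.isfinite(controls)]
    if controls.size < 2:
        raise ValueError("need at least 2 finite control scores")
    sd = controls.std(ddof=1)
    if sd == 0:
        raise ValueError("control scores have zero SD; z-scores undefined")
    return (scores - controls.mean()) / sd


def _assumption_checks(a: np.ndarray, b: np.ndarray) -> dict:
    """Shapiro-Wilk per group and Levene across groups; flags violations."""
    sw_a = sps.shapiro(a) if 3 <= a.size <= 5000 else None
    sw_b = sps.shapiro(b) if 3 <= b.size <= 5000 else None
    lev = sps.levene(a, b)
    out = {
        "shapiro_p": (
            float(sw_a.pvalue) if sw_a else float("nan"),
            float(sw_b.pvalue) if sw_b else float("nan"),
        ),
        "levene_p": float(lev.pvalue),
    }
    out["parametric_ok"] = bool(
        all(p >= 0.05 or math.isnan(p) for p in out["shapiro_p"])
        and out["levene_p"] >= 0.05
    )
    return out


def group_comparisons(
    table: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("MS", "control"),
    continuous: tuple[str, ...] = ("age", "education"),
    categorical: tuple[str, ...] = ("sex",),
) -> dict:
    """Between-group comparability report.

    Continuous variables: Welch's t (Satterthwaite df) with Shapiro-Wilk and
    Levene assumption p-values; a Mann-Whitney U fallback is reported
    whenever an assumption fails.  Categorical variables: Pearson chi-square
    on the contingency table (no continuity correction).
    """
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError(f"both groups {groups} must be non-empty")
    report: dict = {"groups": groups, "n": (len(g1), len(g2))}
    for var in continuous:
        a = g1[var].dropna().to_numpy(dtype=float)
        b = g2[var].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"variable '{var}': each group needs >= 2 values")
        t_res = sps.ttest_ind(a, b, equal_var=False)
        entry = {
            "welch_t": float(t_res.statistic),
            "welch_p": float(t_res.pvalue),
            "df": float(t_res.df),
            "mean": (float(a.mean()), float(b.mean())),
        }
        entry.update(_assumption_checks(a, b))
        if not entry["parametric_ok"]:
            mw = sps.mannwhitneyu(a, b, alternative="two-sided")
            entry["mannwhitney_u"] = float(mw.statistic)
            entry["mannwhitney_p"] = float(mw.pvalue)
        report[var] = entry
    for var in categorical:
        contingency = pd.crosstab(table[group_col], table[var])
        chi2, p, dof, _ = sps.chi2_contingency(contingency, correction=False)
        report[var] = {
            "chi2": float(chi2),
            "p": float(p),
            "dof": int(dof),
            "table": contingency.to_dict(),
        }
    return report


def run_correlation_matrix(
    table: pd.DataFrame,
    rois: list[str],
    tests: list[str],
    family_alpha: float = 0.05,
    group_col: str = "group",
    ci_method: str = "fisher",
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-group, per-test, per-ROI MHI-cognition correlations.

    The Bonferroni threshold divides ``family_alpha`` by the number of ROIs
    (each cognitive domain is its own family); incomplete subjects are
    dropped listwise per test.  ROI MHI columns are named ``mhi_<roi>``.
    Returns a tidy frame with one row per (group, test, roi).
    """
    alpha_adj, _ = bonferroni_alpha(family_alpha, len(rois))
    rows = []
    for group, sub in table.groupby(group_col, sort=False):
        for test in tests:
            if test not in sub.columns:
                raise KeyError(f"cognitive test column '{test}' not in table")
            for roi in rois:
                col = f"mhi_{roi}"
                if col not in sub.columns:
                    raise KeyError(f"ROI column '{col}' not in table")
                x, y = _drop_missing_pairs(sub[col], sub[test])
                if x.size < 3:
                    logger.info(
                        "skipping %s/%s/%s: only %d complete pairs",
                        group, test, roi, x.size,
                    )
                    continue
                res = pearson_with_ci(
                    x, y, alpha_adjusted=alpha_adj, ci_method=ci_method, seed=seed
                )
                rows.append(
                    {
                        "group": group,
                        "test": test,
                        "roi": roi,
                        "n": res.n,
                        "r": res.r,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p": res.p_two_sided,
                        "alpha_adjusted": res.alpha_adjusted,
                        "significant": res.significant,
                    }
                )
    return pd.DataFrame(rows)
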