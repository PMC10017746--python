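"""Group-comparison and association statistics for network measures.

The battery mirrors a cross-sectional imaging study design:

* ANCOVA with a categorical group term plus covariates (age, sex), effect
  size as Cohen's f for the group term from its partial eta squared (type-II
  sums of squares), with a 95% CI obtained by inverting the noncentral-F
  distribution on the noncentrality parameter.
* Spearman rank correlations (average ranks for ties, asymptotic t p-value).
* Steiger's z for comparing two dependent correlations that share one
  variable (e.g. corr(tau measure A, memory) vs corr(tau measure B, memory)).
* Pearson chi-square for contingency tables (no continuity correction).
* ROC AUC via the Mann-Whitney identity with a DeLong 95% CI and the
  Youden-J operating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

__all__ = [
    "EffectSize",
    "ancova_cohens_f",
    "spearman",
    "steiger_test",
    "chi_square_independence",
    "roc_auc",
]


@dataclass
class EffectSize:
    cohens_f: float
    ci_low: float
    ci_high: float
    n: int
    covariates: tuple[str, ...]
    partial_eta_sq: float
    p_value: float


def _ncp_to_f(ncp: float, df1: float, df2: float) -> float:
    # effectsize-style conversion: eta^2 = ncp/(ncp + df1 + df2 + 1)
    return float(np.sqrt(ncp / (df1 + df2 + 1)))


def _ncp_ci(f_stat: float, df1: float, df2: float, level: float = 0.95):
    """Invert the noncentral-F CDF for a two-sided CI on the noncentrality."""
    lo_q = (1 + level) / 2  # cdf at lower bound
    hi_q = (1 - level) / 2

    def cdf(ncp: float) -> float:
        return sps.ncf.cdf(f_stat, df1, df2, ncp)

    upper_probe = max(4 * (f_stat * df1 + df1 + df2), 100.0)
    while cdf(upper_probe) > hi_q and upper_probe < 1e8:
        upper_probe *= 4
    lo = 0.0 if cdf(0.0) < lo_q else brentq(lambda t: cdf(t) - lo_q, 0.0, upper_probe)
    hi = 0.0 if cdf(0.0) < hi_q else brentq(lambda t: cdf(t) - hi_q, 0.0, upper_probe)
    return lo, hi


def ancova_cohens_f(
    y: Sequence[float],
    group: Sequence,
    covariates: pd.DataFrame | np.ndarray | None = None,
    level: float = 0.95,
) -> EffectSize:
    """Cohen's f (with CI) for the group effect in an ANCOVA.

    Fits ``y ~ C(group) + covariates`` by least squares, takes the type-II
    sum of squares for the group term, converts its partial eta squared to
    f = sqrt(eta2/(1-eta2)), and builds the CI by noncentral-F inversion.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if len(np.unique(group)) < 2:
        raise ValueError("need at least 2 groups")
    data = pd.DataFrame({"y": y, "group": group})
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        cov.columns = [str(c) for c in cov.columns]
        cov_names = tuple(cov.columns)
        data = pd.concat([data, cov], axis=1)
    mask = np.isfinite(data.select_dtypes(include=[np.number])).all(axis=1)
    data = data.loc[mask].reset_index(drop=True)
    n = len(data)
    terms = ["C(group)"] + [f"Q('{c}')" for c in cov_names]
    formula = "y ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data).fit()
    if fit.df_resid <= 0:
        raise ValueError("more model parameters than observations")
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError(f"rank-deficient design; check covariates {cov_names}")
    table = anova_lm(fit, typ=2)
    ss_group = float(table.loc["C(group)", "sum_sq"])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    df1 = float(table.loc["C(group)", "df"])
    df2 = float(table.loc["Residual", "df"])
    eta2 = ss_group / (ss_group + ss_resid)
    f_effect = float(np.sqrt(eta2 / (1 - eta2))) if eta2 < 1 else np.inf
    f_stat = (ss_group / df1) / (ss_resid / df2)
    p = float(sps.f.sf(f_stat, df1, df2))
    ncp_lo, ncp_hi = _ncp_ci(f_stat, df1, df2, level)
    return EffectSize(
        cohens_f=f_effect,
        ci_low=_ncp_to_f(ncp_lo, df1, df2),
        ci_high=_ncp_to_f(ncp_hi, df1, df2),
        n=n,
        covariates=cov_names,
        partial_eta_sq=eta2,
        p_value=p,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with asymptotic two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def steiger_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Compare two dependent correlations sharing variable j (Steiger 1980).

    ``r_jk`` and ``r_jh`` are the two correlations being compared; ``r_kh``
    is the correlation between the two non-shared variables. Uses Fisher
    z-transforms and the back-transformed mean correlation in the
    covariance term. Returns (z, two-sided p).
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n <= 3:
        raise ValueError("need n > 3")
    z1 = np.arctanh(r_jk)
    z2 = np.arctanh(r_jh)
    r_bar = np.tanh((z1 + z2) / 2)  # back-transformed mean correlation
    det = (
        r_kh * (1 - 2 * r_bar**2)
        - 0.5 * r_bar**2 * (1 - 2 * r_bar**2 - r_kh**2)
    )
    cov = det / (1 - r_bar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2 - 2 * cov))
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


def chi_square_independence(table: Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold nonnegative integer counts")
    expected = sps.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError("zero expected count in contingency table")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong variance of the AUC from structural components."""
    m, n = pos.size, neg.size
    # V10[i]: placement of positive i among negatives; V01[j]: vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    scores: Sequence[float], labels: Sequence[int], level: float = 0.95
) -> dict:
    """AUC (Mann-Whitney), DeLong CI, and the Youden-J operating point.

    Returns a dict with keys ``auc``, ``ci_low``, ``ci_high``,
    ``sensitivity``, ``specificity``, ``threshold``.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # Mann-Whitney identity: AUC = P(pos > neg) + 0.5 P(pos == neg)
    greater = np.sum(pos[:, None] > neg[None, :])
    equal = np.sum(pos[:, None] == neg[None, :])
    auc = (greater + 0.5 * equal) / (pos.size * neg.size)
    var = _delong_variance(pos, neg, auc)
    zq = sps.norm.ppf((1 + level) / 2)
    half = zq * np.sqrt(var)
    fpr, tpr, thresh = roc_curve(labels, scores)
    j = tpr - fpr
    k = int(np.argmax(j))
    return {
        "auc": float(auc),
        "ci_low": float(max(0.0, auc - half)),
        "ci_high": float(min(1.0, auc + half)),
        "sensitivity": float(tpr[k]),
        "specificity": float(1 - fpr[k]),
        "threshold": float(thresh[k]),
    }
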