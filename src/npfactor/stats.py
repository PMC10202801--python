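"""Effect sizes and inference for phenotype-connectome associations.

Covers the comparisons the pipeline reports: covariate-adjusted partial
correlations with one- or two-sided confidence intervals, pooled-SD
Cohen's d recovered from t statistics, two-sample t tests, Steiger's Z
for two dependent overlapping correlations, Fisher's z comparison of two
independent correlations, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_TAILS = {"two": "two-sided", "two-sided": "two-sided",
          "one": "greater", "greater": "greater", "less": "less"}


def _tail(tail: str) -> str:
    try:
        return _TAILS[tail]
    except KeyError:
        raise ValueError(f"unknown tail {tail!r}") from None


@dataclass
class AssociationResult:
    r: float
    t: float
    df: int
    ci: tuple[float, float]  # one-sided CIs use -inf / inf on the open side
    p: float
    tail: str
    covariates: tuple[str, ...] = ()


@dataclass
class GroupComparison:
    n1: int
    n2: int
    t: float
    cohens_d: float
    ci: tuple[float, float]  # CI for d
    p: float
    tail: str


def partial_corr(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    tail: str = "two-sided",
    ci_level: float = 0.95,
    covariate_names: tuple[str, ...] = (),
) -> AssociationResult:
    """Partial Pearson correlation of x and y controlling covariates.

    Both variables are residualized on the covariates plus an intercept;
    the residual correlation is tested with ``t = r sqrt(df/(1-r^2))``,
    ``df = n - 2 - q``.  The CI comes from the Fisher transform with
    standard error ``1/sqrt(n - 3 - q)``; with a directional tail the
    interval is one-sided (``[lo, inf)`` for "greater").
    """
    tail = _tail(tail)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        C1 = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C1 = np.column_stack([np.ones(n), C])
    q = C1.shape[1] - 1
    if n <= q + 3:
        raise ValueError("need n > q + 3 observations")
    beta_x, *_ = np.linalg.lstsq(C1, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(C1, y, rcond=None)
    rx, ry = x - C1 @ beta_x, y - C1 @ beta_y
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if sx < 1e-12 or sy < 1e-12:
        raise ValueError("constant residuals: partial correlation undefined")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))

    df = n - 2 - q
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    if tail == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif tail == "greater":
        p = sps.t.sf(t, df)
    else:
        p = sps.t.cdf(t, df)

    se = 1.0 / np.sqrt(n - 3 - q)
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    if tail == "two-sided":
        zc = sps.norm.isf((1 - ci_level) / 2)
        ci = (float(np.tanh(zr - zc * se)), float(np.tanh(zr + zc * se)))
    else:
        zc = sps.norm.isf(1 - ci_level)
        if tail == "greater":
            ci = (float(np.tanh(zr - zc * se)), np.inf)
        else:
            ci = (-np.inf, float(np.tanh(zr + zc * se)))
    return AssociationResult(
        r=r, t=float(t), df=df, ci=ci, p=float(min(p, 1.0)), tail=tail,
        covariates=covariate_names,
    )


def cohens_d_from_t(t: float, n1: int, n2: int | None = None) -> float:
    """Pooled-SD Cohen's d implied by a t statistic.

    Two-sample: ``d = t sqrt(1/n1 + 1/n2)``; one-sample (``n2`` omitted):
    ``d = t / sqrt(n1)``.
    """
    if n1 < 2 or (n2 is not None and n2 < 2):
        raise ValueError("group sizes must be at least 2")
    if n2 is None:
        return float(t / np.sqrt(n1))
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))


def two_sample_t(
    values1: np.ndarray,
    values2: np.ndarray,
    tail: str = "two-sided",
    pooled: bool = True,
    ci_level: float = 0.95,
) -> GroupComparison:
    """Two-sample t test with pooled-SD Cohen's d.

    The CI for d uses the normal approximation
    ``se_d = sqrt((n1+n2)/(n1 n2) + d^2 / (2 (n1+n2)))``; a directional
    tail gives a one-sided interval.
    """
    tail = _tail(tail)
    x1 = np.asarray(values1, dtype=float)
    x2 = np.asarray(values2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 values")
    res = sps.ttest_ind(x1, x2, equal_var=pooled, alternative=tail)
    t = float(res.statistic)
    if not np.isfinite(t):
        raise ValueError("zero pooled variance: t undefined")
    d = cohens_d_from_t(t, n1, n2)
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    if tail == "two-sided":
        zc = sps.norm.isf((1 - ci_level) / 2)
        ci = (float(d - zc * se_d), float(d + zc * se_d))
    elif tail == "greater":
        zc = sps.norm.isf(1 - ci_level)
        ci = (float(d - zc * se_d), np.inf)
    else:
        zc = sps.norm.isf(1 - ci_level)
        ci = (-np.inf, float(d + zc * se_d))
    return GroupComparison(
        n1=n1, n2=n2, t=t, cohens_d=d, ci=ci, p=float(res.pvalue), tail=tail
    )


def steiger_z(
    r_jk: float, r_jh: float, r_kh: float, n: int, tail: str = "two-sided"
) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable j.

    Compares ``corr(j,k)`` with ``corr(j,h)`` measured on the same ``n``
    subjects, given ``corr(k,h)``.  Uses the Fisher-z difference with the
    mean-r pooled covariance term (Steiger 1980, Z1*-bar):

        psi  = r_kh (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r_kh^2) / 2
        sbar = psi / (1 - rbar^2)^2
        Z    = (z_jk - z_jh) sqrt((n - 3) / (2 - 2 sbar))
    """
    tail = _tail(tail)
    for r in (r_jk, r_jh, r_kh):
        if abs(r) >= 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 10:
        raise ValueError("need n > 10")
    rbar = (r_jk + r_jh) / 2.0
    psi = r_kh * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_kh**2)
    sbar = psi / (1 - rbar**2) ** 2
    z = (np.arctanh(r_jk) - np.arctanh(r_jh)) * np.sqrt((n - 3) / (2.0 - 2.0 * sbar))
    if tail == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif tail == "greater":
        p = sps.norm.sf(z)
    else:
        p = sps.norm.cdf(z)
    return float(z), float(p)


def fisher_independent_z(
    r1: float, n1: int, r2: float, n2: int, tail: str = "two-sided"
) -> tuple[float, float, float]:
    """Fisher's z comparison of two correlations from independent samples.

    ``Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``.  Returns
    ``(Z, p, r_difference)`` with ``r_difference = r1 - r2``.
    """
    tail = _tail(tail)
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    if tail == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif tail == "greater":
        p = sps.norm.sf(z)
    else:
        p = sps.norm.cdf(z)
    return float(z), float(p), float(r1 - r2)


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(rejected, p_adjusted)``; adjusted p-values are monotone
    (cumulative-minimum enforced).  Empty input gives empty output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    rejected, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected, p_adj
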