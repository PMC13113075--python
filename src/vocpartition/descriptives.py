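"""Descriptive summaries, Cohen's d effect sizes, and the pitch-missingness model.

Effect sizes use the pooled-SD Cohen's d (no small-sample correction),
computed over observed values only, so pitch contrasts use the observed-n
per condition.  The missingness model is a logistic regression of
"pitch missing" on growth phase and distress condition; because some
design cells have zero missingness (complete separation), the default
estimator is Firth's penalized likelihood, with ordinary ML as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .io_schema import CONDITION_LEVELS, PHASE_LEVELS, FeatureTable


@dataclass(frozen=True)
class EffectSize:
    trait: str
    condition_a: str
    condition_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    d: float


def summarize_traits(table: FeatureTable, by: str) -> pd.DataFrame:
    """Per-level mean, SD, n, observed n, and missing % for every trait.

    ``missing_pct`` is reported to 1 decimal; for complete traits it is 0.
    """
    df = table.data
    if by not in df.columns:
        raise KeyError(f"unknown factor {by!r}")
    rows = []
    for level, sub in df.groupby(by, observed=True):
        n = len(sub)
        for trait in table.trait_names:
            obs = sub[trait].dropna()
            rows.append({
                by: level,
                "trait": trait,
                "n": n,
                "n_observed": len(obs),
                "missing_pct": round(100.0 * (n - len(obs)) / n, 1) if n else 0.0,
                "mean": obs.mean() if len(obs) else np.nan,
                "sd": obs.std(ddof=1) if len(obs) > 1 else (0.0 if len(obs) == 1 else np.nan),
            })
    return pd.DataFrame(rows)


def cohens_d_from_summary(
    trait: str, condition_a: str, condition_b: str,
    n_a: int, mean_a: float, sd_a: float,
    n_b: int, mean_b: float, sd_b: float,
) -> EffectSize:
    """Pooled-SD Cohen's d from group summary statistics.

    d = (mean_a - mean_b) / s_pooled with
    s_pooled = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)).
    Positive d means the first condition has the higher mean.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 observed values")
    s_pooled = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    diff = mean_a - mean_b
    if s_pooled == 0:
        if diff != 0:
            raise ValueError("pooled SD is 0 with unequal means; d undefined")
        d = 0.0
    else:
        d = diff / s_pooled
    return EffectSize(trait, condition_a, condition_b, n_a, n_b,
                      mean_a, mean_b, sd_a, sd_b, float(d))


def cohens_d(table: FeatureTable, trait: str,
             condition_a: str, condition_b: str) -> EffectSize:
    """Cohen's d between two conditions, over observed values of ``trait``."""
    df = table.data
    a = df.loc[df["condition"] == condition_a, trait].dropna()
    b = df.loc[df["condition"] == condition_b, trait].dropna()
    for cond, vals in ((condition_a, a), (condition_b, b)):
        if len(vals) < 2:
            raise ValueError(f"condition {cond!r} has < 2 observed {trait} values")
    return cohens_d_from_summary(
        trait, condition_a, condition_b,
        len(a), float(a.mean()), float(a.std(ddof=1)),
        len(b), float(b.mean()), float(b.std(ddof=1)),
    )


# ---- pitch-missingness logistic model ----------------------------------


def _firth_logit(X: np.ndarray, y: np.ndarray,
                 max_iter: int = 100, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Firth-penalized logistic regression (Jeffreys-prior score correction).

    Returns (beta, covariance).  The penalized score is
    U*(b) = X' (y - p + h (1/2 - p)) with h the leverages of the weighted
    hat matrix; estimates stay finite under complete separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        XtW = X.T * w
        info = XtW @ X
        # leverages of W^{1/2} X (X'WX)^{-1} X' W^{1/2}
        sol = np.linalg.solve(info, X.T)
        h = w * np.einsum("ij,ji->i", X, sol)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = np.linalg.solve(info, score)
        # damped step for stability far from the optimum
        while np.max(np.abs(step)) > 5.0:
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(score)) < tol:
            break
    eta = X @ beta
    w = expit(eta) * (1 - expit(eta))
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov


@dataclass
class MissingnessFit:
    """Odds ratios for pitch missingness vs (farrowing, normal) reference."""

    table: pd.DataFrame            # term, level, or, ci_low, ci_high, coef, se
    method: str                    # "firth" or "mle"
    separation: bool               # any factor level with all-0/all-1 outcome
    separated_levels: list[str]


def fit_missingness_model(table: FeatureTable, method: str = "firth") -> MissingnessFit:
    """Logistic regression of pitch-missing on growth phase + condition.

    Default estimator is Firth-penalized likelihood, which yields finite
    odds ratios under the complete separation created by phases or
    conditions with zero missingness; ``method="mle"`` uses ordinary ML via
    statsmodels.  95% CIs are Wald intervals on the (penalized) fit.
    """
    df = table.data
    y = df["pitch"].isna().to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("degenerate outcome: pitch is all-observed or all-missing")

    cols: list[str] = []
    parts = [np.ones((len(df), 1))]
    for factor, levels in (("phase", PHASE_LEVELS), ("condition", CONDITION_LEVELS)):
        present = [lv for lv in levels if (df[factor] == lv).any()]
        for lv in present[1:]:
            parts.append((df[factor] == lv).to_numpy(dtype=float)[:, None])
            cols.append(f"{factor}[{lv}]")
    X = np.hstack(parts)

    separated = []
    for factor in ("phase", "condition"):
        rates = df.assign(_m=y).groupby(factor, observed=True)["_m"].mean()
        for lv, r in rates.items():
            if r in (0.0, 1.0):
                separated.append(f"{factor}={lv}")

    if method == "firth":
        beta, cov = _firth_logit(X, y)
        se = np.sqrt(np.diag(cov))
    elif method == "mle":
        import statsmodels.api as sm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta, se = res.params, res.bse
    else:
        raise ValueError(f"unknown method {method!r}")

    z = norm.ppf(0.975)
    out = pd.DataFrame({
        "term": ["intercept"] + cols,
        "coef": beta,
        "se": se,
        "or": np.exp(beta),
        "ci_low": np.exp(beta - z * se),
        "ci_high": np.exp(beta + z * se),
    })
    return MissingnessFit(table=out, method=method,
                          separation=bool(separated), separated_levels=separated)
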