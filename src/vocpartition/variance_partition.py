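"""Hierarchical variance partitioning of acoustic traits.

For each trait y the core model is a Gaussian linear mixed model with
categorical fixed effects for sex, growth phase and distress condition and
a random intercept per animal,

    y = Xb + u_animal + eps,    u ~ N(0, s2_animal), eps ~ N(0, s2),

optionally extended with a recording-level random intercept nested in
animal (the three 20 s samples cut from one 60 s recording share it).
Estimation is REML via statsmodels MixedLM; model comparisons (likelihood
ratio tests, AIC) refit by ML.

Derived summaries:

* ICC_animal = s2_animal / (s2_animal + s2), adding s2_recording to the
  denominator when the recording effect is present;
* Nakagawa marginal/conditional R2, with the fixed-effect variance taken as
  the population variance of the fitted fixed-effect predictor;
* drop-one delta-R2 per fixed-effect block (sex / phase / distress), each
  reduced model refitted by the same procedure, negative deltas clamped to
  zero and flagged;
* distress x phase interaction selection by ML likelihood-ratio test at
  alpha = 0.05 *and* an AIC decrease;
* Benjamini-Hochberg FDR across the family of all trait x block tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io_schema import CONDITION_LEVELS, PHASE_LEVELS, SEX_LEVELS, FeatureTable

#: Traits treated as positively skewed and log-transformed before modeling
#: when the log switch is on.
LOG_TRAITS: tuple[str, ...] = ("duration", "energy", "pitch")

_FACTOR_LEVELS = {"sex": SEX_LEVELS, "phase": PHASE_LEVELS, "condition": CONDITION_LEVELS}
#: Block names for drop-one decomposition -> factor column.
BLOCKS = {"sex": "sex", "phase": "phase", "distress": "condition"}


class SingularDesignError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


class ConvergenceError(RuntimeError):
    """The (RE)ML optimizer failed to converge."""


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_animal: float
    sigma2_recording: float | None
    sigma2_resid: float

    def total_random(self) -> float:
        extra = self.sigma2_recording or 0.0
        return self.sigma2_animal + extra + self.sigma2_resid


@dataclass
class LMMFit:
    trait: str
    fixed: tuple[str, ...]
    random: tuple[str, ...]
    reml: bool
    components: VarianceComponents
    fe_params: pd.Series
    fitted_fixed: np.ndarray
    llf: float
    n_params: int            # fixed + variance parameters (for AIC)
    nobs: int
    converged: bool
    result: object = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params


@dataclass
class InteractionSelection:
    kept: bool
    lrt_stat: float
    df: int
    p_value: float
    aic_base: float
    aic_full: float
    n_interaction_cols: int
    design_warning: str | None = None

    @property
    def delta_aic(self) -> float:
        return self.aic_full - self.aic_base


@dataclass
class PartitionResult:
    trait: str
    components: VarianceComponents
    icc: float
    r2_marginal: float
    r2_conditional: float
    delta_r2: dict[str, float]
    delta_r2_clamped: dict[str, bool]
    animal_partial_r2: float
    interaction: InteractionSelection | None
    block_p: dict[str, float]
    fdr_q: dict[str, float] = field(default_factory=dict)
    log_transformed: bool = False


# ---- design matrices ---------------------------------------------------


def _dummy_design(df: pd.DataFrame, fixed: Sequence[str],
                  interaction: bool = False) -> tuple[pd.DataFrame, list[str], str | None]:
    """Treatment-coded dummy columns for the requested factors.

    Interaction columns are products of the non-reference phase and
    condition dummies; columns that are identically zero (design cells the
    study never ran, e.g. heat stress before growing) are dropped with a
    note, giving the estimable subset.
    """
    cols = {}
    for factor in fixed:
        levels = _FACTOR_LEVELS[factor]
        present = [lv for lv in levels if (df[factor] == lv).any()]
        if len(present) < 2:
            raise SingularDesignError(
                f"factor {factor!r} is constant in the analysis rows")
        for lv in present[1:]:
            cols[f"{factor}_{lv}"] = (df[factor] == lv).astype(float)
    note = None
    X = pd.DataFrame(cols, index=df.index)
    X.insert(0, "Intercept", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise SingularDesignError(
            f"fixed-effect design is rank deficient ({rank} < {X.shape[1]}); "
            f"check collinear factors among {list(fixed)}")
    if interaction:
        # Estimable subset: empty design cells (conditions the study never
        # ran in a phase) make some interaction columns zero or linearly
        # dependent on main effects; those are dropped greedily.
        dropped = []
        base = X.to_numpy()
        rank = np.linalg.matrix_rank(base)
        for pl in PHASE_LEVELS[1:]:
            for cl in CONDITION_LEVELS[1:]:
                v = ((df["phase"] == pl) & (df["condition"] == cl)).astype(float)
                if v.sum() == 0:
                    dropped.append(f"{pl}:{cl}")
                    continue
                cand = np.column_stack([base, v.to_numpy()])
                r = np.linalg.matrix_rank(cand)
                if r > rank:
                    X[f"ix_{pl}_{cl}"] = v
                    base, rank = cand, r
                else:
                    dropped.append(f"{pl}:{cl}")
        if dropped:
            note = ("interaction columns dropped (empty or inestimable design "
                    "cells): " + ", ".join(dropped))
    return X, [c for c in X.columns if c != "Intercept"], note


def _fit_mixedlm(df: pd.DataFrame, y: pd.Series, X: pd.DataFrame,
                 random: Sequence[str], reml: bool) -> "object":
    data = X.drop(columns=["Intercept"]).copy()
    data["y"] = y.to_numpy()
    data["animal_id"] = df["animal_id"].to_numpy()
    data["recording_id"] = df["recording_id"].to_numpy()
    terms = " + ".join(c for c in data.columns if c not in ("y", "animal_id", "recording_id"))
    formula = f"y ~ {terms}" if terms else "y ~ 1"
    vc = {"recording": "0 + C(recording_id)"} if "recording" in random else None
    model = smf.mixedlm(formula, data, groups=data["animal_id"],
                        re_formula="1", vc_formula=vc)
    last_exc = None
    # bfgs with a tight gradient tolerance matches the closed-form oracle on
    # balanced data; cg reproduces its optimum when bfgs's line search stops
    # early.  lbfgs is last: it reports convergence at visibly sub-optimal
    # likelihoods, which would corrupt likelihood-ratio statistics.
    attempts = (
        {"method": "bfgs", "gtol": 1e-10},
        {"method": "cg", "gtol": 1e-8},
        {"method": "powell"},
        {"method": "lbfgs"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for kwargs in attempts:
            try:
                res = model.fit(reml=reml, maxiter=200, **kwargs)
            except Exception as exc:      # singular fits raise LinAlgError etc.
                last_exc = exc
                continue
            if res.converged:
                return res
    if last_exc is not None:
        raise ConvergenceError(
            f"mixed model did not converge (last optimizer error: {last_exc})")
    raise ConvergenceError(
        "mixed model did not converge after lbfgs/powell/cg (maxiter=200)")


def fit_lmm(
    table: FeatureTable | pd.DataFrame,
    trait: str,
    fixed: Sequence[str] = ("sex", "phase", "condition"),
    random: Sequence[str] = ("animal",),
    reml: bool = True,
    log_transform: bool = False,
) -> LMMFit:
    """Fit the mixed model for one trait (observed rows only).

    ``random`` is ``("animal",)`` or ``("animal", "recording")`` — the
    recording intercept is nested within animal.  ``log_transform`` models
    log(y) (used for skewed traits).
    """
    df = table.data if isinstance(table, FeatureTable) else table
    if "animal" not in random:
        raise ValueError("random spec must include 'animal'")
    sub = df.dropna(subset=[trait])
    if sub["animal_id"].nunique() < 2:
        raise ValueError(f"trait {trait!r} observed in fewer than 2 animals")
    y = np.log(sub[trait]) if log_transform else sub[trait]
    X, names, _ = _dummy_design(sub, fixed)
    res = _fit_mixedlm(sub, y, X, random, reml)

    sigma2_animal = float(np.asarray(res.cov_re)[0, 0])
    sigma2_recording = float(res.vcomp[0]) if "recording" in random else None
    components = VarianceComponents(sigma2_animal, sigma2_recording, float(res.scale))
    fe = res.fe_params
    fitted_fixed = X.to_numpy() @ fe.reindex(X.columns).to_numpy()
    n_var = 2 if sigma2_recording is None else 3   # animal (+recording) + resid
    return LMMFit(
        trait=trait, fixed=tuple(fixed), random=tuple(random), reml=reml,
        components=components, fe_params=fe, fitted_fixed=fitted_fixed,
        llf=float(res.llf), n_params=len(fe) + n_var, nobs=len(sub),
        converged=bool(res.converged), result=res,
    )


# ---- derived quantities ------------------------------------------------


def icc(components: VarianceComponents) -> float:
    """Animal-identity intraclass correlation.

    s2_animal / (s2_animal + s2) with a single random intercept, or
    s2_animal / (s2_animal + s2_recording + s2) under recording nesting.
    """
    denom = components.total_random()
    if denom <= 0:
        raise ValueError("all variance components are zero; ICC undefined")
    return components.sigma2_animal / denom


def nakagawa_r2(fit: LMMFit) -> tuple[float, float]:
    """Marginal and conditional R2 for a Gaussian mixed model.

    var_fixed is the population (n-denominator) variance of the fitted
    fixed-effect predictor; random variances and the residual complete the
    denominator.
    """
    var_fixed = float(np.var(fit.fitted_fixed))
    denom = var_fixed + fit.components.total_random()
    if denom <= 0:
        raise ValueError("zero total variance; R2 undefined")
    var_random = fit.components.total_random() - fit.components.sigma2_resid
    r2m = var_fixed / denom
    r2c = (var_fixed + var_random) / denom
    return r2m, r2c


def drop_one_delta_r2(
    table: FeatureTable | pd.DataFrame,
    trait: str,
    blocks: Sequence[str] = ("sex", "phase", "distress"),
    random: Sequence[str] = ("animal",),
    log_transform: bool = False,
    full_fit: LMMFit | None = None,
) -> tuple[dict[str, float], dict[str, bool]]:
    """Drop-one-block decrease in marginal R2, clamped at zero.

    Each reduced model is refitted by the same (REML) procedure; because
    full and reduced fits are separate optimizations the raw difference can
    be slightly negative, in which case it is clamped and flagged.
    """
    unknown = [b for b in blocks if b not in BLOCKS]
    if unknown:
        raise ValueError(f"unknown block(s): {unknown}; choose from {list(BLOCKS)}")
    fixed_all = ("sex", "phase", "condition")
    if full_fit is None:
        full_fit = fit_lmm(table, trait, fixed=fixed_all, random=random,
                           log_transform=log_transform)
    r2m_full, _ = nakagawa_r2(full_fit)
    deltas: dict[str, float] = {}
    clamped: dict[str, bool] = {}
    for block in blocks:
        reduced_fixed = tuple(f for f in fixed_all if f != BLOCKS[block])
        red = fit_lmm(table, trait, fixed=reduced_fixed, random=random,
                      log_transform=log_transform)
        r2m_red, _ = nakagawa_r2(red)
        raw = r2m_full - r2m_red
        clamped[block] = raw < 0
        deltas[block] = max(0.0, raw)
    return deltas, clamped


def block_lrt_pvalues(
    table: FeatureTable | pd.DataFrame,
    trait: str,
    blocks: Sequence[str] = ("sex", "phase", "distress"),
    random: Sequence[str] = ("animal",),
    log_transform: bool = False,
) -> dict[str, float]:
    """ML likelihood-ratio p-value for dropping each fixed-effect block."""
    fixed_all = ("sex", "phase", "condition")
    full = fit_lmm(table, trait, fixed=fixed_all, random=random, reml=False,
                   log_transform=log_transform)
    out: dict[str, float] = {}
    for block in blocks:
        reduced_fixed = tuple(f for f in fixed_all if f != BLOCKS[block])
        red = fit_lmm(table, trait, fixed=reduced_fixed, random=random,
                      reml=False, log_transform=log_transform)
        df_diff = full.n_params - red.n_params
        stat = max(0.0, 2.0 * (full.llf - red.llf))
        out[block] = float(stats.chi2.sf(stat, df_diff)) if df_diff > 0 else 1.0
    return out


def select_interaction(
    table: FeatureTable | pd.DataFrame,
    trait: str,
    fixed: Sequence[str] = ("sex", "phase", "condition"),
    random: Sequence[str] = ("animal",),
    alpha: float = 0.05,
    log_transform: bool = False,
) -> InteractionSelection:
    """Decide whether the distress x phase interaction earns its keep.

    Base and base+interaction models are fitted by ML; the interaction is
    retained iff the likelihood-ratio p < alpha AND the AIC decreases.
    Interaction columns for design cells with no data are dropped
    (estimable subset) and noted.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    sub = df.dropna(subset=[trait])
    y = np.log(sub[trait]) if log_transform else sub[trait]

    X_base, _, _ = _dummy_design(sub, fixed)
    X_full, _, note = _dummy_design(sub, fixed, interaction=True)
    res_base = _fit_mixedlm(sub, y, X_base, random, reml=False)
    res_full = _fit_mixedlm(sub, y, X_full, random, reml=False)

    n_var = 3 if "recording" in random else 2
    k_base = len(res_base.fe_params) + n_var
    k_full = len(res_full.fe_params) + n_var
    df_diff = k_full - k_base
    stat = max(0.0, 2.0 * (float(res_full.llf) - float(res_base.llf)))
    p = float(stats.chi2.sf(stat, df_diff)) if df_diff > 0 else 1.0
    aic_base = -2.0 * float(res_base.llf) + 2.0 * k_base
    aic_full = -2.0 * float(res_full.llf) + 2.0 * k_full
    kept = (p < alpha) and (aic_full < aic_base)
    return InteractionSelection(
        kept=kept, lrt_stat=stat, df=df_diff, p_value=p,
        aic_base=aic_base, aic_full=aic_full,
        n_interaction_cols=df_diff, design_warning=note,
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---- oracles and variants ----------------------------------------------


def mom_variance_oracle(table: FeatureTable | pd.DataFrame, trait: str) -> VarianceComponents:
    """One-way ANOVA method-of-moments estimator (balanced designs only).

    sigma2_animal = (MS_between - MS_within) / n0 clamped at 0,
    sigma2_resid = MS_within; serves as an independent closed-form check of
    the REML fit on balanced intercept-only layouts.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    sub = df.dropna(subset=[trait])
    groups = sub.groupby("animal_id", observed=True)[trait]
    sizes = groups.size()
    if sizes.nunique() != 1:
        raise ValueError("oracle requires a balanced layout (equal n per animal)")
    n0 = int(sizes.iloc[0])
    k = len(sizes)
    if k < 2 or n0 < 2:
        raise ValueError("need >= 2 animals and >= 2 observations per animal")
    grand = sub[trait].mean()
    means = groups.mean()
    msb = n0 * ((means - grand) ** 2).sum() / (k - 1)
    msw = groups.apply(lambda x: ((x - x.mean()) ** 2).sum()).sum() / (k * (n0 - 1))
    return VarianceComponents(max(0.0, (msb - msw) / n0), None, float(msw))


def residual_icc(
    table: FeatureTable | pd.DataFrame,
    trait: str,
    fixed: Sequence[str] = ("sex", "phase", "condition"),
    log_transform: bool = False,
) -> float:
    """ICC of OLS fixed-effect residuals, grouped by animal.

    A model-free variant: regress the trait on the fixed factors by OLS,
    then estimate the animal variance share of the residuals with the
    unbalanced one-way method of moments.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    sub = df.dropna(subset=[trait])
    y = np.log(sub[trait]).to_numpy() if log_transform else sub[trait].to_numpy()
    X, _, _ = _dummy_design(sub, fixed)
    beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    resid = y - X.to_numpy() @ beta
    g = pd.Series(resid).groupby(sub["animal_id"].to_numpy())
    sizes = g.size().to_numpy(dtype=float)
    k, n = len(sizes), sizes.sum()
    if k < 2:
        raise ValueError("need >= 2 animals")
    grand = resid.mean()
    means = g.mean().to_numpy()
    ssb = (sizes * (means - grand) ** 2).sum()
    ssw = g.apply(lambda x: ((x - x.mean()) ** 2).sum()).sum()
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - (sizes**2).sum() / n) / (k - 1)
    s2a = max(0.0, (msb - msw) / n0)
    return s2a / (s2a + msw) if (s2a + msw) > 0 else 0.0


# ---- high-level per-trait partition ------------------------------------


def partition_traits(
    table: FeatureTable,
    traits: Sequence[str],
    random: Sequence[str] = ("animal", "recording"),
    log_skewed: bool = True,
    with_interaction: bool = True,
) -> list[PartitionResult]:
    """Full variance partition for several traits with family-wise BH-FDR.

    Skewed traits (duration, energy, pitch) are log-transformed before
    modeling when ``log_skewed`` is on.  The BH family is the set of all
    trait x block likelihood-ratio tests.
    """
    results: list[PartitionResult] = []
    family: list[tuple[str, str, float]] = []
    for trait in traits:
        logt = log_skewed and trait in LOG_TRAITS
        full = fit_lmm(table, trait, random=random, log_transform=logt)
        r2m, r2c = nakagawa_r2(full)
        deltas, clamped = drop_one_delta_r2(
            table, trait, random=random, log_transform=logt, full_fit=full)
        pvals = block_lrt_pvalues(table, trait, random=random, log_transform=logt)
        inter = select_interaction(table, trait, random=random,
                                   log_transform=logt) if with_interaction else None
        results.append(PartitionResult(
            trait=trait, components=full.components, icc=icc(full.components),
            r2_marginal=r2m, r2_conditional=r2c, delta_r2=deltas,
            delta_r2_clamped=clamped, animal_partial_r2=r2c - r2m,
            interaction=inter, block_p=pvals, log_transformed=logt,
        ))
        for block, p in pvals.items():
            family.append((trait, block, p))
    q = bh_fdr([p for _, _, p in family])
    for (trait, block, _), qv in zip(family, q):
        for r in results:
            if r.trait == trait:
                r.fdr_q[block] = float(qv)
    return results


def partition_to_frame(results: Sequence[PartitionResult]) -> pd.DataFrame:
    """Flatten partition results to a tidy table (one row per trait)."""
    rows = []
    for r in results:
        row = {
            "trait": r.trait,
            "log_transformed": r.log_transformed,
            "sigma2_animal": r.components.sigma2_animal,
            "sigma2_recording": r.components.sigma2_recording,
            "sigma2_resid": r.components.sigma2_resid,
            "icc": r.icc,
            "r2_marginal": r.r2_marginal,
            "r2_conditional": r.r2_conditional,
            "animal_partial_r2": r.animal_partial_r2,
        }
        for block in r.delta_r2:
            row[f"delta_r2_{block}"] = r.delta_r2[block]
            row[f"q_{block}"] = r.fdr_q.get(block, np.nan)
        if r.interaction is not None:
            row["interaction_kept"] = r.interaction.kept
            row["interaction_p"] = r.interaction.p_value
            row["interaction_delta_aic"] = r.interaction.delta_aic
        rows.append(row)
    return pd.DataFrame(rows)
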