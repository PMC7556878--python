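"""Mixed-effects treatment comparison and auxiliary tests.

Repeated vessel measurements within an animal are correlated, so
vehicle-vs-treatment diameter comparisons use a linear mixed-effects
model on the per-vessel diameter change:

    dD[n, a] = gamma + beta[a] (+ alpha * D[n])

where ``gamma`` is the fixed treatment effect, ``beta[a]`` a per-animal
random intercept, and (in the baseline-covariate variant) ``alpha`` a
shared slope on the vehicle-condition diameter ``D[n]``.  The treatment
is called significant when ``gamma`` differs from zero after Bonferroni
correction over the number of experimental groups.

By default ``dD`` is the normalized change (treatment / vehicle basal
minus 1), matching the percent-change reporting convention; raw
micrometer differences are available with ``normalized=False``.
Inference on ``gamma`` uses a t reference distribution with
``n_animals - 1`` degrees of freedom (the between-within convention for
a between-animal fixed effect): a plain normal approximation is
anti-conservative for cohorts of half a dozen animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDesignError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "COHORT_COLUMNS",
    "MixedModelResult",
    "RegressionResult",
    "PairedTestResult",
    "validate_cohort",
    "delta_diameter",
    "fit_lme_delta",
    "fit_lme_with_baseline",
    "bonferroni",
    "paired_ttest",
    "cross_condition_regression",
]

COHORT_COLUMNS = ("animal_id", "vessel_id", "vessel_class", "d_vehicle_um", "d_treatment_um")


@dataclass(frozen=True)
class MixedModelResult:
    """Fitted mixed-effects treatment comparison."""

    gamma: float
    gamma_se: float
    p_raw: float
    ci_low: float
    ci_high: float
    n_animals: int
    n_vessels: int
    beta_a: dict[str, float]
    alpha: float | None = None
    alpha_se: float | None = None
    p_corrected: float | None = None
    model: str = "dD ~ gamma + beta_a"

    def with_correction(self, n_groups: int) -> "MixedModelResult":
        from dataclasses import replace

        return replace(self, p_corrected=bonferroni(self.p_raw, n_groups))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    degenerate: bool = False


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    n: int
    degenerate: bool = False


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table for required columns and one row per vessel."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidParameterError(f"cohort table missing columns: {missing}")
    if table.duplicated(subset=["animal_id", "vessel_id"]).any():
        raise InvalidParameterError("each vessel may appear once per condition pair")
    if not np.isfinite(table[["d_vehicle_um", "d_treatment_um"]].to_numpy()).all():
        raise InvalidParameterError("diameters must be finite")
    if (table["d_vehicle_um"] <= 0).any():
        raise InvalidParameterError("vehicle diameters must be > 0")
    return table


def delta_diameter(table: pd.DataFrame, normalized: bool = True) -> np.ndarray:
    """Per-vessel diameter change: fractional (default) or raw um."""
    if normalized:
        return (table["d_treatment_um"] / table["d_vehicle_um"] - 1.0).to_numpy()
    return (table["d_treatment_um"] - table["d_vehicle_um"]).to_numpy()


def _t_inference(est: float, se: float, df: int) -> tuple[float, float, float]:
    if se == 0:
        return (1.0 if est == 0 else 0.0), est, est
    tval = est / se
    p = 2.0 * float(sps.t.sf(abs(tval), df))
    half = float(sps.t.ppf(0.975, df)) * se
    return p, est - half, est + half


def _fit_quietly(model):
    """REML fit with boundary-MLE convergence warnings silenced.

    Cohorts with a small or zero between-animal variance legitimately put
    the REML estimate on the boundary; statsmodels warns on every such
    fit, which would flood simulation loops.
    """
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        return model.fit(reml=True)


def fit_lme_delta(table: pd.DataFrame, normalized: bool = True) -> MixedModelResult:
    """Random-intercept mixed model for the treatment effect on diameter.

    Fits ``dD ~ 1`` with a per-animal random intercept by REML and tests
    whether the fixed effect ``gamma`` differs from zero.

    Raises
    ------
    DegenerateDesignError
        With a single animal the random effect is unidentifiable; use a
        one-sample (or paired) t-test instead.
    """
    import statsmodels.api as sm

    table = validate_cohort(table)
    groups = table["animal_id"].to_numpy()
    n_animals = len(np.unique(groups))
    if n_animals < 2:
        raise DegenerateDesignError(
            "mixed model needs >= 2 animals; use a one-sample t-test for a single animal"
        )
    if len(table) < 2:
        raise DegenerateDesignError("mixed model needs >= 2 vessels")
    dd = delta_diameter(table, normalized)

    if np.ptp(dd) == 0:
        # zero-variance cohorts (e.g. the all-zero null) have no model to fit
        gamma = float(dd[0])
        p = 1.0 if gamma == 0 else 0.0
        return MixedModelResult(
            gamma=gamma, gamma_se=0.0, p_raw=p, ci_low=gamma, ci_high=gamma,
            n_animals=n_animals, n_vessels=len(table),
            beta_a={str(a): 0.0 for a in np.unique(groups)},
        )

    model = sm.MixedLM(dd, np.ones((len(dd), 1)), groups=groups)
    fit = _fit_quietly(model)
    gamma = float(fit.fe_params[0])
    se = float(fit.bse_fe[0])
    p, lo, hi = _t_inference(gamma, se, n_animals - 1)
    beta = {str(k): float(v.iloc[0]) for k, v in fit.random_effects.items()}
    return MixedModelResult(
        gamma=gamma, gamma_se=se, p_raw=p, ci_low=lo, ci_high=hi,
        n_animals=n_animals, n_vessels=len(table), beta_a=beta,
    )


def fit_lme_with_baseline(table: pd.DataFrame, normalized: bool = True) -> MixedModelResult:
    """Mixed model with the vehicle-condition diameter as a covariate.

    Fits ``dD ~ 1 + D_vehicle`` with a per-animal random intercept; the
    shared slope ``alpha`` is what the diameter-scatter regression lines
    show.  (A per-vessel coefficient would be unidentifiable with one
    observation per vessel, so a single shared slope is used.)
    """
    import statsmodels.api as sm

    table = validate_cohort(table)
    groups = table["animal_id"].to_numpy()
    n_animals = len(np.unique(groups))
    if n_animals < 2:
        raise DegenerateDesignError("mixed model needs >= 2 animals")
    d_vehicle = table["d_vehicle_um"].to_numpy(dtype=float)
    if np.ptp(d_vehicle) == 0:
        raise InvalidParameterError("baseline covariate has no variation")
    dd = delta_diameter(table, normalized)

    exog = np.column_stack([np.ones(len(dd)), d_vehicle])
    coef, residual, *_ = np.linalg.lstsq(exog, dd, rcond=None)
    ss_total = float(np.sum((dd - dd.mean()) ** 2))
    if residual.size and float(residual[0]) <= 1e-12 * max(ss_total, 1.0):
        # noiseless data lie exactly on the line; REML has nothing to fit
        gamma, alpha = float(coef[0]), float(coef[1])
        p, lo, hi = _t_inference(gamma, 0.0, n_animals - 1)
        return MixedModelResult(
            gamma=gamma, gamma_se=0.0, p_raw=p, ci_low=lo, ci_high=hi,
            n_animals=n_animals, n_vessels=len(table),
            beta_a={str(a): 0.0 for a in np.unique(groups)},
            alpha=alpha, alpha_se=0.0,
            model="dD ~ gamma + alpha*D_vehicle + beta_a",
        )
    model = sm.MixedLM(dd, exog, groups=groups)
    fit = _fit_quietly(model)
    gamma = float(fit.fe_params[0])
    se = float(fit.bse_fe[0])
    p, lo, hi = _t_inference(gamma, se, n_animals - 1)
    beta = {str(k): float(v.iloc[0]) for k, v in fit.random_effects.items()}
    return MixedModelResult(
        gamma=gamma, gamma_se=se, p_raw=p, ci_low=lo, ci_high=hi,
        n_animals=n_animals, n_vessels=len(table), beta_a=beta,
        alpha=float(fit.fe_params[1]), alpha_se=float(fit.bse_fe[1]),
        model="dD ~ gamma + alpha*D_vehicle + beta_a",
    )


def bonferroni(p_raw: float, n_groups: int) -> float:
    """Bonferroni correction: ``min(1, p * n_groups)``.

    Corrected values above 1 are rounded down to 1.
    """
    if not 0 <= p_raw <= 1:
        raise InvalidParameterError("p_raw must be in [0, 1]")
    if n_groups < 1:
        raise InvalidParameterError("n_groups must be >= 1")
    return min(1.0, p_raw * n_groups)


def paired_ttest(x_vehicle: np.ndarray, x_treatment: np.ndarray) -> PairedTestResult:
    """Two-sided paired t-test (e.g. per-animal gamma-band power)."""
    x = np.asarray(x_vehicle, dtype=float)
    y = np.asarray(x_treatment, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidParameterError("paired test needs two equal-length vectors, n >= 2")
    diffs = y - x
    if np.std(diffs, ddof=1) == 0:
        if np.all(diffs == 0):
            return PairedTestResult(t=0.0, p=1.0, n=x.size)
        logger.warning("paired differences have zero variance; t statistic undefined")
        return PairedTestResult(t=float("inf") * np.sign(diffs[0]), p=0.0,
                                n=x.size, degenerate=True)
    t, p = sps.ttest_rel(y, x)
    return PairedTestResult(t=float(t), p=float(p), n=x.size)


def cross_condition_regression(
    diameter_changes: np.ndarray,
    gamma_changes: np.ndarray,
) -> RegressionResult:
    """OLS of diameter change on gamma-band power change across conditions."""
    x = np.asarray(gamma_changes, dtype=float)
    y = np.asarray(diameter_changes, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise InvalidParameterError("need two equal-length vectors with n >= 2")
    if x.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        logger.warning("two points determine the line exactly; p undefined")
        return RegressionResult(slope=float(slope), intercept=float(y[0] - slope * x[0]),
                                p_value=float("nan"), r_squared=1.0, degenerate=True)
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        p_value=float(res.pvalue), r_squared=float(res.rvalue**2),
    )
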