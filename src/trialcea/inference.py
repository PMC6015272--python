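"""Incremental estimation and uncertainty analysis.

The adjusted incremental cost and effects come from linear mixed models:
the 12-month outcome (total cost, QALY, or 12-month PAID) regressed on arm
plus baseline covariates (age, sex, cardiovascular history, smoking,
diabetes duration) and the corresponding baseline outcome, with a random
intercept per recruitment centre. Estimates from the m imputed copies are
pooled with Rubin's rules. Uncertainty around the cost-effect pair is
quantified by a nonparametric bootstrap (participants resampled with
replacement, stratified by arm), giving the cost-effectiveness plane and
the cost-effectiveness acceptability curve (probability that net monetary
benefit lambda x dE - dC is positive as willingness-to-pay lambda varies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import schema

#: default willingness-to-pay grid, pounds per QALY; the NICE range
#: endpoints 20,000 and 30,000 are always on the grid
DEFAULT_WTP_GRID = tuple(range(0, 50_001, 500))


@dataclass
class ModelSpec:
    """One adjusted-difference regression."""

    outcome: str
    baseline: str
    covariates: Sequence[str] = field(
        default_factory=lambda: ["age", "male", "cvd_history", "smoking",
                                 "diabetes_duration"]
    )
    arm_col: str = "arm"
    center_col: str = "center"


def fit_adjusted_difference(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[float, float]:
    """Arm coefficient and its variance from a random-intercept model.

    Fits outcome ~ arm + covariates + baseline outcome with a random
    centre intercept on one completed (no-missing) copy. Falls back to an
    ordinary fixed-intercept regression, with a warning, if the mixed fit
    is singular or fails to converge. Requires at least two centres.
    """
    import statsmodels.api as sm

    if df[spec.center_col].nunique() < 2:
        raise ValueError("need at least 2 centres for a random-centre model")
    work = df[
        [spec.outcome, spec.baseline, *spec.covariates, spec.arm_col,
         spec.center_col]
    ].copy()
    if work.drop(columns=spec.center_col).isna().any().any():
        raise ValueError("model input must be a completed (no-missing) copy")
    y = work[spec.outcome].to_numpy(dtype=float)
    X = work[[spec.baseline, *spec.covariates]].to_numpy(dtype=float)
    arm = (work[spec.arm_col] == "intervention").to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(y)), arm, X])
    groups = work[spec.center_col].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, exog, groups=groups).fit(reml=True, method="lbfgs")
        cov_re = float(np.asarray(res.cov_re).ravel()[0])
        if cov_re < 1e-6 * np.var(y):
            # REML on the boundary: the random-intercept model collapses to
            # ordinary least squares, so return the exact boundary solution
            ols = sm.OLS(y, exog).fit()
            return float(ols.params[1]), float(ols.bse[1]) ** 2
        est, var = float(res.params[1]), float(res.bse[1]) ** 2
        if not np.isfinite(est) or not np.isfinite(var) or var <= 0:
            raise np.linalg.LinAlgError("degenerate mixed fit")
        return est, var
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn(
            "mixed model singular; falling back to fixed-intercept OLS",
            stacklevel=2,
        )
        res = sm.OLS(y, exog).fit()
        return float(res.params[1]), float(res.bse[1]) ** 2


def fit_ols_difference(df: pd.DataFrame, spec: ModelSpec) -> tuple[float, float]:
    """Plain OLS arm coefficient (no centre effect); bootstrap workhorse."""
    import statsmodels.api as sm

    y = df[spec.outcome].to_numpy(dtype=float)
    X = df[[spec.baseline, *spec.covariates]].to_numpy(dtype=float)
    arm = (df[spec.arm_col] == "intervention").to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(y)), arm, X])
    res = sm.OLS(y, exog).fit()
    return float(res.params[1]), float(res.bse[1]) ** 2


@dataclass
class IncrementalEstimate:
    """Pooled adjusted difference with its 95% CI."""

    point: float
    se: float
    ci: tuple[float, float]
    df: float
    m: int


def pool_rubin(
    estimates: Sequence[float], variances: Sequence[float], alpha: float = 0.05
) -> IncrementalEstimate:
    """Pool per-imputation estimates with Rubin's rules.

    Point = mean of estimates; total variance = mean within-variance +
    (1 + 1/m) x between-imputation variance; the CI uses the t reference
    with the standard MI degrees of freedom (normal when the between
    component vanishes).
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    m = len(q)
    if m == 0:
        raise ValueError("no estimates to pool")
    point = q.mean()
    wbar = w.mean()
    b = q.var(ddof=1) if m > 1 else 0.0
    total = wbar + (1 + 1 / m) * b if m > 1 else wbar
    se = float(np.sqrt(total))
    if m > 1 and b > 0:
        nu = (m - 1) * (1 + wbar / ((1 + 1 / m) * b)) ** 2
        tcrit = stats.t.ppf(1 - alpha / 2, nu)
    else:
        nu = np.inf
        tcrit = stats.norm.ppf(1 - alpha / 2)
    return IncrementalEstimate(
        point=float(point),
        se=se,
        ci=(float(point - tcrit * se), float(point + tcrit * se)),
        df=float(nu),
        m=m,
    )


@dataclass
class ICERResult:
    """Cost per unit of effect, with the quadrant that disambiguates it."""

    ratio: float
    delta_cost: float
    delta_effect: float
    quadrant: str
    defined: bool = True


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Incremental cost-effectiveness ratio dC/dE with its CE-plane quadrant.

    A bare negative ratio is ambiguous (dominant vs dominated), so the
    quadrant (NE costlier/more effective, SE dominant, NW dominated,
    SW cheaper/less effective) is always reported. dE = 0 leaves the
    ratio undefined rather than infinite.
    """
    ns = "N" if delta_cost > 0 else ("S" if delta_cost < 0 else "axis")
    ew = "E" if delta_effect > 0 else ("W" if delta_effect < 0 else "axis")
    quadrant = ns + ew if "axis" not in (ns, ew) else "boundary"
    if delta_effect == 0:
        return ICERResult(np.nan, delta_cost, delta_effect, quadrant, defined=False)
    return ICERResult(
        float(delta_cost / delta_effect), delta_cost, delta_effect, quadrant
    )


@dataclass
class BootstrapCloud:
    """Paired (dCost, dEffect) bootstrap replicates."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    B: int
    seed: int
    effect_label: str = "qaly"

    def __post_init__(self):
        if len(self.delta_cost) != len(self.delta_effect):
            raise ValueError("cost and effect replicates must be paired")

    def percentile_ci(self, which: str = "cost", alpha: float = 0.05):
        arr = self.delta_cost if which == "cost" else self.delta_effect
        return tuple(np.quantile(arr, [alpha / 2, 1 - alpha / 2]))


def bootstrap_cloud(
    df: pd.DataFrame,
    pipeline: Callable[[pd.DataFrame, np.random.Generator], tuple[float, float]],
    B: int,
    seed: int,
    arm_col: str = "arm",
    effect_label: str = "qaly",
) -> BootstrapCloud:
    """Nonparametric bootstrap of the (dCost, dEffect) pair.

    Each replicate resamples participants with replacement within each arm
    (keeping arm sizes fixed) and feeds the resample through ``pipeline``,
    which returns one paired (dCost, dEffect). Deterministic in ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    groups = {arm: g.index.to_numpy() for arm, g in df.groupby(arm_col, sort=True)}
    dc = np.empty(B)
    de = np.empty(B)
    for b in range(B):
        idx = np.concatenate(
            [rng.choice(ix, size=len(ix), replace=True) for ix in groups.values()]
        )
        resample = df.loc[idx].reset_index(drop=True)
        dc[b], de[b] = pipeline(resample, rng)
    return BootstrapCloud(dc, de, B=B, seed=seed, effect_label=effect_label)


def ce_plane_summary(cloud: BootstrapCloud) -> dict[str, float]:
    """Proportion of replicates in each cost-effectiveness plane quadrant.

    Points exactly on the effect axis (dE = 0) count to the west (not
    cost-effective), points on the cost axis to the south; both are
    measure-zero for continuous data.
    """
    dc, de = cloud.delta_cost, cloud.delta_effect
    if len(dc) == 0:
        raise ValueError("empty cloud")
    east = de > 0
    north = dc > 0
    out = {
        "NE": float((north & east).mean()),
        "SE": float((~north & east).mean()),
        "NW": float((north & ~east).mean()),
        "SW": float((~north & ~east).mean()),
    }
    return out


def ceac(
    cloud: BootstrapCloud, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay lambda, the probability cost-effective is
    the fraction of replicates with positive net monetary benefit
    lambda x dE - dC > 0.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if (grid < 0).any():
        raise ValueError("WTP values must be nonnegative")
    nmb = grid[:, None] * cloud.delta_effect[None, :] - cloud.delta_cost[None, :]
    return pd.DataFrame({"wtp": grid, "probability": (nmb > 0).mean(axis=1)})


def ceac_at(curve: pd.DataFrame, wtp: float) -> float:
    row = curve.loc[curve["wtp"] == wtp, "probability"]
    if row.empty:
        raise KeyError(f"WTP {wtp} not on the grid")
    return float(row.iloc[0])
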