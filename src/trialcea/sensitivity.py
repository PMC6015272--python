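"""One-way sensitivity of the ICER to the number of users.

The intervention's fixed annual operating cost is spread over n active
users (up to the server capacity of 10,000), while per-user training and
facilitation costs and the incremental health-service cost are held fixed:

    ICER(n) = (fixed/n + per_user_variable + delta_healthcare_cost) / dQALY

With health-service savings exceeding the per-user variable cost, the
incremental total cost crosses zero at n* = fixed / -(variable + savings):
beyond that many users the intervention dominates usual care.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .costing import InterventionCostModel


def _components(
    model: InterventionCostModel, delta_healthcare_cost: float, rounding: str
) -> tuple[float, float]:
    """(per-user variable cost, healthcare cost difference), optionally
    rounded to whole pounds — the convention behind the published figures
    (variable 21 + 16 = 37, healthcare 111 - 263 = -152)."""
    variable = model.per_user_variable
    if rounding == "components":
        variable = round(model.per_user_training) + round(model.per_user_facilitation)
        delta_healthcare_cost = round(delta_healthcare_cost)
    elif rounding != "none":
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return float(variable), float(delta_healthcare_cost)


@dataclass
class ScalingResult:
    """ICER-vs-users curve plus the break-even user count (if any)."""

    table: pd.DataFrame  # n_users, per_user_cost, delta_total_cost, icer
    breakeven_n: int | None
    breakeven_exact: float | None


def default_n_grid(capacity: int = 10_000) -> np.ndarray:
    """1 to capacity log-spaced, densified over 50-500 users where the
    curve crosses the decision thresholds."""
    grid = np.unique(
        np.concatenate(
            [
                np.unique(np.round(np.logspace(0, np.log10(capacity), 200))),
                np.arange(50, 501),
            ]
        )
    ).astype(int)
    return grid[(grid >= 1) & (grid <= capacity)]


def icer_vs_users(
    model: InterventionCostModel,
    delta_healthcare_cost: float,
    delta_qaly: float,
    n_grid=None,
    rounding: str = "components",
) -> ScalingResult:
    """ICER as a function of the number of users sharing the fixed cost.

    ``delta_healthcare_cost`` is the adjusted incremental total cost minus
    the per-participant intervention cost — the part of the cost difference
    assumed to generalize as the user base grows. The fixed-cost share
    fixed/n stays continuous so the curve is smooth; in the default
    rounded-component mode the per-user variable cost and the healthcare
    difference are first rounded to whole pounds.
    """
    if delta_qaly == 0:
        raise ValueError("delta_qaly must be nonzero")
    grid = np.asarray(
        default_n_grid(model.capacity) if n_grid is None else list(n_grid)
    )
    if (grid < 1).any() or (grid > model.capacity).any():
        raise ValueError(f"n_grid outside [1, capacity={model.capacity}]")
    variable, dhc = _components(model, delta_healthcare_cost, rounding)
    per_user = model.fixed_annual / grid + variable
    delta_total = per_user + dhc
    table = pd.DataFrame(
        {
            "n_users": grid,
            "per_user_cost": per_user,
            "delta_total_cost": delta_total,
            "icer": delta_total / delta_qaly,
        }
    )
    exact = _breakeven_root(model.fixed_annual, variable, dhc, model.capacity)
    return ScalingResult(
        table=table,
        breakeven_n=None if exact is None else int(round(exact)),
        breakeven_exact=exact,
    )


def _breakeven_root(
    fixed: float, variable: float, dhc: float, capacity: int
) -> float | None:
    drain = -(variable + dhc)  # net saving per user excluding fixed share
    if drain <= 0:
        return None  # no savings: incremental cost never crosses zero
    if fixed == 0:
        return 1.0  # cost-saving from the first user
    root = fixed / drain
    return root if 1 <= root <= capacity else None


def breakeven_users(
    model: InterventionCostModel,
    delta_healthcare_cost: float,
    rounding: str = "components",
) -> tuple[int | None, float | None]:
    """User count at which the incremental total cost reaches zero.

    Solves fixed/n + variable + delta_healthcare = 0 exactly (the
    left-hand side is monotone in n, so the root is unique). Returns
    (nearest whole user, exact root); (None, None) when health-service
    savings never offset the per-user variable cost within capacity.
    """
    variable, dhc = _components(model, delta_healthcare_cost, rounding)
    exact = _breakeven_root(model.fixed_annual, variable, dhc, model.capacity)
    if exact is None:
        return None, None
    return int(round(exact)), exact


def run_cca_analysis(table, config=None, run_bootstrap: bool = True):
    """Complete-case re-analysis (filter + same model/bootstrap machinery).

    Convenience re-export so the scaling and complete-case sensitivity
    analyses live behind one module; see
    :func:`trialcea.pipeline.analyze_complete_cases`.
    """
    from .pipeline import analyze_complete_cases

    return analyze_complete_cases(table, config, run_bootstrap=run_bootstrap)
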