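"""Micro-costing of the intervention and costing of health-service use.

All costs are pounds sterling at 2014 prices, undiscounted (12-month
horizon). Two kinds of cost are produced:

* per-participant health-service costs, built by multiplying resource-use
  counts by national average unit costs and by extrapolating current
  prescriptions month-by-month over each costing window; and
* the intervention's operating cost, built bottom-up from a staff-activity
  schedule (time x hourly rate x frequency) plus invoiced infrastructure,
  split into a fixed annual component and per-user training/facilitation
  components with a server capacity bound.

Costs are aggregated into three sections per window (nurse-recorded
services, nurse-recorded medications, self-reported services); a missing
count for any individual item makes the whole section missing.
"""

from __future__ import annotations

import importlib.resources as _resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import schema


def _data_path(name: str):
    return _resources.files("trialcea.data").joinpath(name)


def load_reference_summary() -> dict:
    """Published trial summary statistics (replication-mode inputs)."""
    with _data_path("reference_summary.yaml").open() as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# unit costs and service-use costing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitCostTable:
    """Service type -> unit cost (pounds per consultation or episode)."""

    entries: Mapping[str, float]
    sources: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = {k: v for k, v in self.entries.items() if v < 0}
        if bad:
            raise ValueError(f"negative unit costs: {bad}")

    def __getitem__(self, service_type: str) -> float:
        try:
            return self.entries[service_type]
        except KeyError:
            raise KeyError(
                f"no unit cost for service type {service_type!r}"
            ) from None


def load_unit_costs(path=None) -> UnitCostTable:
    """Load the national-average unit-cost table (packaged default)."""
    df = pd.read_csv(path if path is not None else _data_path("unit_costs.csv"))
    return UnitCostTable(
        entries=dict(zip(df["service_type"], df["unit_cost"].astype(float))),
        sources=dict(zip(df["service_type"], df.get("source", ""))),
    )


def cost_service_use(counts: Mapping[str, float], unit_costs: UnitCostTable) -> float:
    """Cost one section's service-use counts: sum(count x unit cost).

    ``counts`` maps service type to a nonnegative count; NaN marks a missing
    count. If any count is missing the section cost is missing (NaN) — a
    single unrecorded item invalidates the whole section.
    """
    total = 0.0
    for service, count in counts.items():
        unit = unit_costs[service]  # unknown type -> KeyError naming it
        if count is None or (isinstance(count, float) and np.isnan(count)):
            return float("nan")
        if count < 0:
            raise ValueError(f"negative count {count} for {service!r}")
        total += float(count) * unit
    return total


def cost_prescriptions(
    items: Sequence[tuple[str, float]] | None,
    window: str,
    no_medication: bool = False,
) -> float:
    """Cost current prescriptions over ``window``.

    Prescriptions are assumed chronic and issued monthly, so the summed
    monthly item cost is multiplied by the months the window covers
    (12, 3 or 9). A blank prescription record is missing data unless an
    explicit no-medication flag was recorded, in which case the cost is 0.
    """
    if window not in schema.WINDOW_MONTHS:
        raise ValueError(f"unknown window {window!r}")
    months = schema.WINDOW_MONTHS[window]
    if no_medication:
        return 0.0
    if items is None:
        return float("nan")
    monthly = 0.0
    for name, cost in items:
        if cost < 0:
            raise ValueError(f"negative monthly cost for {name!r}")
        monthly += float(cost)
    return monthly * months


def cost_dataset(df: pd.DataFrame, unit_costs: UnitCostTable) -> pd.DataFrame:
    """Add aggregated section-cost columns to a participant-level table.

    For each window, produces ``cost_<window>__nurse_services``,
    ``cost_<window>__nurse_medications`` and
    ``cost_<window>__selfreport_services``. The missing-section rule is
    applied columnwise: any NaN count inside a section makes that
    participant's section cost NaN.
    """
    out = df.copy()
    for window in schema.WINDOWS:
        for section, services in schema.SECTION_SERVICES.items():
            cols = [schema.svc_col(window, s) for s in services]
            present = [c for c in cols if c in out.columns]
            if not present:
                continue
            counts = out[present]
            if (counts < 0).any().any():
                raise ValueError(f"negative counts in section {section}/{window}")
            unit = np.array(
                [unit_costs[c.split("__", 1)[1]] for c in present], dtype=float
            )
            value = counts.to_numpy(dtype=float) @ unit
            value[counts.isna().any(axis=1).to_numpy()] = np.nan
            out[schema.cost_col(window, section)] = value
        mcol = schema.rx_monthly_col(window)
        if mcol in out.columns:
            months = schema.WINDOW_MONTHS[window]
            monthly = out[mcol].to_numpy(dtype=float)
            value = monthly * months
            nonecol = schema.rx_none_col(window)
            if nonecol in out.columns:
                value = np.where(out[nonecol].fillna(False).astype(bool), 0.0, value)
            out[schema.cost_col(window, "nurse_medications")] = value
    return out


# ---------------------------------------------------------------------------
# intervention operating costs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StaffActivity:
    """One maintenance/delivery activity costed as time x rate x frequency."""

    name: str
    hours_per_period: float
    periods_per_year: float
    rate: float  # pounds per hour
    printed_cost: float | None = None  # audited published figure, if any

    def formula_cost(self) -> float:
        if self.rate < 0:
            raise ValueError(f"negative rate for {self.name!r}")
        return round(self.hours_per_period * self.periods_per_year * self.rate)


def load_staff_activities(path=None) -> list[StaffActivity]:
    df = pd.read_csv(
        path if path is not None else _data_path("staff_activities.csv")
    )
    return [
        StaffActivity(
            name=r.activity,
            hours_per_period=float(r.hours_per_period),
            periods_per_year=float(r.periods_per_year),
            rate=float(r.rate),
            printed_cost=float(r.printed_cost),
        )
        for r in df.itertuples()
    ]


def staff_activity_costs(
    activities: Iterable[StaffActivity], use_printed: bool = True
) -> pd.DataFrame:
    """Per-activity and total annual staff cost, with a formula audit.

    ``use_printed=True`` (default) takes each activity's published cost as
    authoritative where available; the ``formula_cost`` column and the
    relative discrepancy are always reported so annualisation conventions
    can be audited. The ``total`` is the sum of the chosen column.
    """
    rows = []
    for a in activities:
        formula = a.formula_cost()
        cost = a.printed_cost if (use_printed and a.printed_cost is not None) else formula
        rel = (
            abs(formula - a.printed_cost) / a.printed_cost
            if a.printed_cost
            else np.nan
        )
        rows.append(
            {
                "activity": a.name,
                "formula_cost": formula,
                "printed_cost": a.printed_cost,
                "cost": cost,
                "rel_discrepancy": rel,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["total"] = float(out["cost"].sum())
    return out


def load_infrastructure(path=None) -> pd.DataFrame:
    df = pd.read_csv(path if path is not None else _data_path("infrastructure.csv"))
    df.attrs["total"] = float(df["annual_cost"].sum())
    return df


@dataclass(frozen=True)
class InterventionCostModel:
    """Fixed annual operating cost plus per-user components.

    ``fixed_annual`` covers staff maintenance/delivery and infrastructure;
    it is spread over however many users the service carries, up to the
    server ``capacity``. Training and facilitation are incurred per user
    and held constant as the user base grows.
    """

    fixed_annual: float
    per_user_training: float
    per_user_facilitation: float
    capacity: int = 10_000
    trial_n: int = 185

    def __post_init__(self):
        for name in ("fixed_annual", "per_user_training", "per_user_facilitation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.capacity < self.trial_n:
            raise ValueError("capacity below the trial's own user count")

    @property
    def per_user_variable(self) -> float:
        return self.per_user_training + self.per_user_facilitation


def default_cost_model(
    staff_path=None, infrastructure_path=None, use_printed: bool = True
) -> InterventionCostModel:
    """Build the intervention cost model from the packaged schedules.

    Fixed annual cost = staff activities total + infrastructure total.
    Per-user training spreads the one-off nurse-training cost over the
    trial's intervention arm; per-user facilitation is 20 minutes of a
    practice nurse's time plus one booklet.
    """
    staff = staff_activity_costs(load_staff_activities(staff_path), use_printed)
    infra = load_infrastructure(infrastructure_path)
    ref = load_reference_summary()["intervention_cost"]
    trial_n = load_reference_summary()["trial"]["n_intervention"]
    facilitation = (
        ref["facilitation_nurse_hourly"] * ref["facilitation_minutes"] / 60.0
        + ref["booklet_unit_cost"]
    )
    return InterventionCostModel(
        fixed_annual=staff.attrs["total"] + infra.attrs["total"],
        per_user_training=ref["training_total"] / trial_n,
        per_user_facilitation=facilitation,
        capacity=ref["capacity"],
        trial_n=trial_n,
    )


def intervention_cost_per_user(
    model: InterventionCostModel, n_users: int, rounding: str = "components"
) -> float:
    """Intervention cost per user when ``n_users`` share the fixed cost.

    ``rounding='components'`` rounds each of the three components (fixed
    share, training, facilitation) to the nearest pound before summing —
    the convention that yields the published 226 + 21 + 16 = 263 per trial
    participant. ``rounding='none'`` sums the exact components.
    """
    if not 1 <= n_users <= model.capacity:
        raise ValueError(
            f"n_users={n_users} outside [1, capacity={model.capacity}]"
        )
    parts = (
        model.fixed_annual / n_users,
        model.per_user_training,
        model.per_user_facilitation,
    )
    if rounding == "components":
        return float(sum(round(p) for p in parts))
    if rounding == "none":
        return float(sum(parts))
    raise ValueError(f"unknown rounding mode {rounding!r}")
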