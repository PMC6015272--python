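"""End-to-end analysis pipeline.

Chains the stages on a participant-level table: cost the resource use,
score the outcomes, reduce to the aggregated analysis variables, impute,
fit the adjusted mixed models per imputed copy, pool with Rubin's rules,
and run the bootstrap for the CE plane and CEAC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import costing, imputation, inference, outcomes, schema

#: aggregated analysis variables (imputation operates on these)
COST_VARS = [schema.cost_col(w, s) for w in schema.WINDOWS for s in schema.SECTIONS]
TRIAL_COST_VARS = [
    schema.cost_col(w, s) for w in ("m0_3", "m3_12") for s in schema.SECTIONS
]
BASE_COST_VARS = [schema.cost_col("pre12m", s) for s in schema.SECTIONS]
OUTCOME_VARS = (
    [schema.utility_col(t) for t in schema.TIMEPOINTS]
    + [schema.paid_total_col(t) for t in schema.TIMEPOINTS]
)
AUX_VARS = ["u_12_raw", "paid_12_raw"]


@dataclass
class AnalysisConfig:
    m: int = 30
    k_donors: int = 5
    n_cycles: int = 10
    B: int = 5000
    seed: int = 0
    wtp_grid: tuple = inference.DEFAULT_WTP_GRID
    rounding: str = "components"
    intervention_cost: float | None = None  # per participant; default from model


def prepare_analysis_table(
    df: pd.DataFrame,
    unit_costs: costing.UnitCostTable | None = None,
    value_set: outcomes.EQ5DValueSet | None = None,
) -> pd.DataFrame:
    """Reduce raw participant data to the aggregated analysis variables.

    Costs each section per window, scores utilities and PAID, applies the
    10-14 month validity window to the 12-month outcomes (out-of-window
    measurements move to auxiliary ``*_raw`` columns and the outcome is
    set missing), and keeps ids, centre, arm and baseline covariates.
    """
    unit_costs = unit_costs or costing.load_unit_costs()
    value_set = value_set or outcomes.load_value_set()
    work = costing.cost_dataset(df, unit_costs)
    work = outcomes.score_outcomes(work, value_set)
    work = outcomes.apply_validity_window(work)

    u12, p12 = schema.utility_col(12), schema.paid_total_col(12)
    work["u_12_raw"] = work[u12]
    work["paid_12_raw"] = work[p12]
    invalid = ~work["valid_12"].to_numpy()
    work.loc[invalid, [u12, p12]] = np.nan

    keep = (
        ["id", "center", "arm", *schema.BASELINE_COVARIATES]
        + COST_VARS
        + OUTCOME_VARS
        + AUX_VARS
        + ["valid_12"]
    )
    return work[[c for c in keep if c in work.columns]].copy()


def _complete_copy_estimates(
    copy: pd.DataFrame,
    intervention_cost: float,
    mixed: bool = True,
) -> dict[str, tuple[float, float]]:
    """Fit the three adjusted models on one completed copy."""
    work = copy.copy()
    work["healthcare_cost"] = work[TRIAL_COST_VARS].sum(axis=1)
    work["baseline_cost"] = work[BASE_COST_VARS].sum(axis=1)
    work["total_cost"] = work["healthcare_cost"] + np.where(
        work["arm"] == "intervention", intervention_cost, 0.0
    )
    work["qaly"] = (
        0.125 * work[schema.utility_col(0)]
        + 0.5 * work[schema.utility_col(3)]
        + 0.375 * work[schema.utility_col(12)]
    )
    fit = inference.fit_adjusted_difference if mixed else inference.fit_ols_difference
    specs = {
        "cost": inference.ModelSpec("total_cost", "baseline_cost"),
        "qaly": inference.ModelSpec("qaly", schema.utility_col(0)),
        "paid": inference.ModelSpec(
            schema.paid_total_col(12), schema.paid_total_col(0)
        ),
    }
    return {k: fit(work, s) for k, s in specs.items()}


@dataclass
class AnalysisReport:
    estimates: dict[str, inference.IncrementalEstimate]
    icers: dict[str, inference.ICERResult]
    cloud: inference.BootstrapCloud | None
    ceac: pd.DataFrame | None
    plane: dict[str, float] | None
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        out = {
            "estimates": {
                k: {
                    "point": e.point,
                    "se": e.se,
                    "ci": list(e.ci),
                    "df": e.df,
                    "m": e.m,
                }
                for k, e in self.estimates.items()
            },
            "icers": {
                k: {
                    "ratio": None if not r.defined else r.ratio,
                    "quadrant": r.quadrant,
                    "defined": r.defined,
                }
                for k, r in self.icers.items()
            },
        }
        if self.plane is not None:
            out["ce_plane"] = self.plane
        if self.ceac is not None:
            out["ceac"] = {
                "wtp_20000": inference.ceac_at(self.ceac, 20_000),
                "wtp_30000": inference.ceac_at(self.ceac, 30_000),
            }
        return out


def _imputation_spec(config: AnalysisConfig, m: int | None = None) -> imputation.ImputationSpec:
    return imputation.ImputationSpec(
        variables=COST_VARS + OUTCOME_VARS + AUX_VARS,
        m=m if m is not None else config.m,
        k_donors=config.k_donors,
        n_cycles=config.n_cycles,
        seed=config.seed,
    )


def analyze(
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    run_bootstrap: bool = True,
) -> AnalysisReport:
    """Primary analysis on an aggregated analysis table.

    Multiple imputation (m copies) gives the pooled point estimates and
    Rubin CIs; the bootstrap (participants resampled within arm, one
    stochastic imputation per replicate, then the model fit) supplies the
    CE plane and CEAC. ``run_bootstrap=False`` skips the replicates and
    returns only pooled estimates and ICERs.
    """
    config = config or AnalysisConfig()
    cost_model = costing.default_cost_model()
    iv_cost = (
        config.intervention_cost
        if config.intervention_cost is not None
        else costing.intervention_cost_per_user(
            cost_model, cost_model.trial_n, rounding=config.rounding
        )
    )

    imputed = imputation.mice_pmm(table, _imputation_spec(config))
    per_copy = [
        _complete_copy_estimates(c, iv_cost) for c in imputed.copies
    ]
    estimates = {
        k: inference.pool_rubin(
            [pc[k][0] for pc in per_copy], [pc[k][1] for pc in per_copy]
        )
        for k in ("cost", "qaly", "paid")
    }
    icers = {
        "per_qaly": inference.icer(estimates["cost"].point, estimates["qaly"].point),
        "per_paid_improvement": inference.icer(
            estimates["cost"].point, -estimates["paid"].point
        ),
    }

    cloud = curve = plane = None
    if run_bootstrap:
        counter = {"b": 0}

        def one_replicate(resample: pd.DataFrame, rng: np.random.Generator):
            counter["b"] += 1
            spec = _imputation_spec(config, m=1)
            spec.seed = int(rng.integers(2**31 - 1))
            copy = imputation.mice_pmm(resample, spec).copies[0]
            est = _complete_copy_estimates(copy, iv_cost, mixed=False)
            return est["cost"][0], est["qaly"][0]

        cloud = inference.bootstrap_cloud(
            table, one_replicate, B=config.B, seed=config.seed
        )
        curve = inference.ceac(cloud, config.wtp_grid)
        plane = inference.ce_plane_summary(cloud)

    return AnalysisReport(
        estimates=estimates, icers=icers, cloud=cloud, ceac=curve, plane=plane,
        config=config,
    )


def cca_required_variables() -> list[str]:
    """Variables that must be complete for the complete-case analysis:
    baseline adjustment covariates, all section costs, and both health
    outcomes at every timepoint (12-month outcomes valid-in-window)."""
    return list(schema.BASELINE_COVARIATES) + COST_VARS + OUTCOME_VARS


def analyze_complete_cases(
    table: pd.DataFrame, config: AnalysisConfig | None = None,
    run_bootstrap: bool = True,
) -> tuple[AnalysisReport, pd.DataFrame]:
    """Complete-case re-analysis: filter, then the same model machinery.

    Uses no imputation (the filtered table is complete by construction).
    Returns the report and the per-arm retention summary.
    """
    config = config or AnalysisConfig()
    subset, retention = imputation.cca_filter(table, cca_required_variables())
    if subset["center"].nunique() < 2:
        raise ValueError("fewer than 2 centres survive the complete-case filter")
    cost_model = costing.default_cost_model()
    iv_cost = (
        config.intervention_cost
        if config.intervention_cost is not None
        else costing.intervention_cost_per_user(
            cost_model, cost_model.trial_n, rounding=config.rounding
        )
    )
    per = _complete_copy_estimates(subset, iv_cost)
    estimates = {
        k: inference.pool_rubin([per[k][0]], [per[k][1]]) for k in per
    }
    icers = {
        "per_qaly": inference.icer(estimates["cost"].point, estimates["qaly"].point),
        "per_paid_improvement": inference.icer(
            estimates["cost"].point, -estimates["paid"].point
        ),
    }
    cloud = curve = plane = None
    if run_bootstrap:
        def one_replicate(resample, rng):
            est = _complete_copy_estimates(resample, iv_cost, mixed=False)
            return est["cost"][0], est["qaly"][0]

        cloud = inference.bootstrap_cloud(
            subset.reset_index(drop=True), one_replicate, B=config.B,
            seed=config.seed,
        )
        curve = inference.ceac(cloud, config.wtp_grid)
        plane = inference.ce_plane_summary(cloud)
    report = AnalysisReport(
        estimates=estimates, icers=icers, cloud=cloud, ceac=curve, plane=plane,
        config=config,
    )
    return report, retention
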