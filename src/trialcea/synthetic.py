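"""Synthetic two-arm trial generator.

Emulates the data structure of a 374-participant, 21-centre randomized
trial of a web-based diabetes self-management programme: stratified
permuted-block randomization, baseline covariates, health-service use
counts over three costing windows, current prescriptions, EQ-5D-3L
profiles and PAID items at 0/3/12 months, jittered assessment dates, and
questionnaire-level nonresponse.

Default parameters are calibrated to the published arm-level summary
statistics (means/SEs of utilities, PAID and section costs; completion
rates), so the downstream pipeline can be exercised, and its estimators
validated, without any participant-level data ever having been deposited.

Utilities are generated *on the 243-state EQ-5D-3L grid*: a latent normal
per timepoint (sharing a within-participant factor) is snapped to the
nearest tariff value and a concrete profile with that value is emitted, so
the tariff scorer is exercised end to end. The latent location is
calibrated by root-finding so the post-snapping mean equals the target
exactly. Costs are Poisson counts with a gamma participant frailty
(right-skewed, SD of section costs on the order of their means); PAID
items are correlated ordinal 0-4 draws through a beta-binomial construction
whose rescaled total matches the target mean and SD.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import schema
from .costing import UnitCostTable, load_reference_summary, load_unit_costs
from .outcomes import EQ5DValueSet, load_value_set

GENERATOR_VERSION = "1.0"

EQ5D_MIN, EQ5D_MAX = -0.594, 1.0

#: relative weights of service types within each generated section
_SERVICE_WEIGHTS = {
    "nurse_services": {
        "gp_surgery": 0.30,
        "gp_telephone": 0.05,
        "nurse_surgery": 0.20,
        "outpatient": 0.20,
        "inpatient": 0.10,
        "day_case": 0.05,
        "a_and_e": 0.05,
        "clinical_test": 0.05,
    },
    "selfreport_services": {
        "podiatrist": 0.20,
        "optometry": 0.15,
        "physiotherapy": 0.20,
        "counselling_primary": 0.15,
        "occupational_therapy": 0.15,
        "dietician": 0.15,
    },
}


@dataclass
class ArmParams:
    """Outcome-generating parameters for one arm."""

    utility_means: tuple[float, float, float]
    utility_sd: float
    paid_means: tuple[float, float, float]
    paid_sd: float
    #: window -> section -> mean cost (pounds); dispersion shared
    cost_means: Mapping[str, Mapping[str, float]]
    cost_dispersion: float = 1.0

    def validate(self):
        for u in self.utility_means:
            if not EQ5D_MIN <= u <= EQ5D_MAX:
                raise ValueError(f"utility mean {u} outside tariff range")
        for p in self.paid_means:
            if not 0 <= p <= 100:
                raise ValueError(f"PAID mean {p} outside [0, 100]")
        if self.utility_sd < 0 or self.paid_sd < 0 or self.cost_dispersion <= 0:
            raise ValueError("dispersions must be positive, SDs nonnegative")
        for w, sections in self.cost_means.items():
            for s, m in sections.items():
                if m < 0:
                    raise ValueError(f"negative cost mean for {w}/{s}")


@dataclass
class MissingnessParams:
    """Questionnaire- and section-level nonresponse probabilities."""

    #: arm -> timepoint -> probability the self-report questionnaire
    #: (EQ-5D, PAID, self-reported services) is not returned
    nonresponse: Mapping[str, Mapping[int, float]]
    #: per-section-per-window probability a nurse-extracted section is blank
    nurse_section_rate: float = 0.005
    #: probability diabetes duration is unrecorded
    duration_rate: float = 0.011
    #: MAR slope: added (per SD of baseline PAID) to the nonresponse logit.
    #: Zero gives MCAR; any value keeps the mechanism MAR by construction,
    #: since it conditions only on the always-observed baseline.
    mar_paid_slope: float = 0.0

    def validate(self):
        for arm, by_tp in self.nonresponse.items():
            for tp, p in by_tp.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"nonresponse[{arm}][{tp}]={p} outside [0,1]")
        if not 0 <= self.nurse_section_rate <= 1 or not 0 <= self.duration_rate <= 1:
            raise ValueError("rates must be in [0,1]")


@dataclass
class TrialConfig:
    """Full specification of a synthetic trial."""

    n_per_arm: tuple[int, int] = (185, 189)
    n_centers: int = 21
    block_sizes: tuple[int, ...] = (2, 4, 6)
    # baseline covariates (shared across arms: randomization guarantees
    # identical distributions in the generative truth)
    age_mean: float = 64.8
    age_sd: float = 9.3
    male_prop: float = 0.69
    cvd_prop: float = 0.30
    smoking_prop: float = 0.15
    duration_mean: float = 8.0
    duration_sd: float = 5.9
    arm_params: Mapping[str, ArmParams] = field(default_factory=dict)
    #: optional (incremental total cost, incremental QALY) to embed: rebuilds
    #: the intervention arm from the control arm with equal baselines and
    #: follow-up means shifted so the adjusted contrasts equal the targets
    effect_targets: tuple[float, float] | None = None
    #: per-participant intervention cost added on top of health-service cost
    intervention_unit_cost: float = 263.0
    #: sample EQ-5D profiles on the 243-state grid (exercises the scorer);
    #: if False, emit utilities directly from a clipped normal
    utilities_on_grid: bool = True
    within_person_corr: float = 0.6
    #: centre heterogeneity: share of latent utility SD carried by a centre
    #: intercept, and the SD of the centre's log cost multiplier. Both are
    #: mean-zero constructions, so arm-level calibration targets are kept.
    center_utility_share: float = 0.15
    center_logcost_sd: float = 0.10
    #: timepoint -> (mean, sd) of the actual assessment month
    assess_month_params: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {0: (0.0, 0.0), 3: (3.0, 0.3), 12: (12.0, 1.0)}
    )
    missingness: MissingnessParams | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.arm_params:
            self.arm_params = _default_arm_params()
        if self.missingness is None:
            self.missingness = _default_missingness()
        if self.effect_targets is not None:
            self.arm_params = dict(self.arm_params)
            self.arm_params["intervention"] = _embed_effects(
                self.arm_params["control"],
                *self.effect_targets,
                self.intervention_unit_cost,
            )
        self.validate()

    def validate(self):
        if any(n < 1 for n in self.n_per_arm):
            raise ValueError("n_per_arm must be positive")
        if any(b < 2 or b % 2 for b in self.block_sizes):
            raise ValueError("block sizes must be even and >= 2")
        for p in (self.male_prop, self.cvd_prop, self.smoking_prop):
            if not 0 <= p <= 1:
                raise ValueError("proportions must be in [0,1]")
        if self.age_sd < 0 or self.duration_sd < 0:
            raise ValueError("SDs must be nonnegative")
        for arm in schema.ARMS:
            self.arm_params[arm].validate()
        self.missingness.validate()


def _split_cost_total(total: float, windows: Sequence[str]) -> dict:
    """Partition a window total over sections (55/30/15 services/meds/self)."""
    shares = {
        "nurse_services": 0.55,
        "nurse_medications": 0.30,
        "selfreport_services": 0.15,
    }
    out = {}
    for w, wshare in windows:
        out[w] = {s: total * wshare * sshare for s, sshare in shares.items()}
    return out


def _default_arm_params() -> dict[str, ArmParams]:
    ref = load_reference_summary()
    params = {}
    for arm in schema.ARMS:
        base = ref["costs"]["baseline_12m"][arm][0]
        trial = ref["costs"]["trial_12m"][arm][0]
        cost_means = _split_cost_total(base, [("pre12m", 1.0)])
        # 0-3 months carries ~25% of trial-period cost, 3-12 the rest
        cost_means.update(
            _split_cost_total(trial, [("m0_3", 0.25), ("m3_12", 0.75)])
        )
        params[arm] = ArmParams(
            utility_means=tuple(
                ref["utility"][k][arm][0] for k in ("m0", "m3", "m12")
            ),
            utility_sd=0.23,  # complete-case SDs span 0.19-0.25
            paid_means=tuple(ref["paid"][k][arm][0] for k in ("m0", "m3", "m12")),
            paid_sd=16.0,
            cost_means=cost_means,
            cost_dispersion=1.0,
        )
    return params


def _default_missingness() -> MissingnessParams:
    ref = load_reference_summary()["completion"]
    return MissingnessParams(
        nonresponse={
            arm: {0: 0.0, 3: 1 - ref["m3"][arm], 12: 1 - ref["m12"][arm]}
            for arm in schema.ARMS
        }
    )


def _embed_effects(
    control: ArmParams, delta_cost: float, delta_qaly: float, unit_cost: float
) -> ArmParams:
    """Intervention-arm parameters embedding known incremental effects.

    Baselines equal the control arm's, so the baseline-adjusted contrasts
    coincide with the raw follow-up contrasts in expectation. The QALY
    increment is spread equally over the 3- and 12-month utilities
    (AUC = 0.125 u0 + 0.5 u3 + 0.375 u12, so a common shift d gives
    0.875 d QALYs). The health-service cost shift is the cost target minus
    the per-participant intervention cost, spread over the trial windows.
    """
    du = delta_qaly / 0.875
    u0, u3, u12 = control.utility_means
    dhc = delta_cost - unit_cost
    cost_means = {w: dict(s) for w, s in control.cost_means.items()}
    trial_total = sum(sum(s.values()) for w, s in cost_means.items() if w != "pre12m")
    for w in ("m0_3", "m3_12"):
        for s in cost_means[w]:
            cost_means[w][s] *= 1 + dhc / trial_total
    return dataclasses.replace(
        control,
        utility_means=(u0, u3 + du, u12 + du),
        cost_means=cost_means,
    )


# ---------------------------------------------------------------------------
# randomization
# ---------------------------------------------------------------------------


def block_randomize(
    centers: Sequence, config: TrialConfig, rng: np.random.Generator
) -> np.ndarray:
    """Permuted-block randomization, 1:1, stratified by centre.

    Within each centre, blocks of (even) sizes drawn from
    ``config.block_sizes`` are filled half-and-half and shuffled; the final
    partial block bounds the within-centre imbalance by half the largest
    block. Returns an array of arm labels aligned with ``centers``.
    """
    centers = np.asarray(centers)
    if pd.isna(centers).any():
        raise ValueError("every participant must have a known centre")
    arms = np.empty(len(centers), dtype=object)
    for c in np.unique(centers):
        idx = np.flatnonzero(centers == c)
        assigned = []
        while len(assigned) < len(idx):
            b = int(rng.choice(config.block_sizes))
            block = ["intervention"] * (b // 2) + ["control"] * (b // 2)
            rng.shuffle(block)
            assigned.extend(block)
        arms[idx] = assigned[: len(idx)]
    return arms


# ---------------------------------------------------------------------------
# utility sampling on the tariff grid
# ---------------------------------------------------------------------------


class GridUtilitySampler:
    """Sample EQ-5D-3L profiles whose tariff values match a target mean.

    A latent normal is snapped to the nearest of the distinct tariff values;
    the latent location is calibrated (1-d root finding on the exact
    post-snapping expectation) so the sampled utilities are unbiased for
    the target mean. Among profiles sharing a tariff value, one is chosen
    uniformly.
    """

    def __init__(self, value_set: EQ5DValueSet):
        table = value_set.all_profiles()
        self.grid = np.sort(table["utility"].unique())
        self.profiles_by_u = {
            u: [
                tuple(int(c) for c in p)
                for p in table.loc[table["utility"] == u, "profile"]
            ]
            for u in self.grid
        }
        # snapping-cell boundaries: midpoints between adjacent grid values
        self.cuts = (self.grid[1:] + self.grid[:-1]) / 2

    def snapped_mean(self, mu: float, sd: float) -> float:
        upper = np.append(special.ndtr((self.cuts - mu) / sd), 1.0)
        probs = np.diff(np.insert(upper, 0, 0.0))
        return float(probs @ self.grid)

    def calibrate(self, target_mean: float, sd: float) -> float:
        if sd <= 0:
            raise ValueError("grid sampling needs sd > 0; use direct mode")
        lo, hi = EQ5D_MIN - 5 * sd, EQ5D_MAX + 5 * sd
        return optimize.brentq(
            lambda mu: self.snapped_mean(mu, sd) - target_mean, lo, hi, xtol=1e-10
        )

    def snap(self, z: np.ndarray) -> np.ndarray:
        return self.grid[np.searchsorted(self.cuts, z)]

    def profiles_for(self, utilities: np.ndarray, rng: np.random.Generator):
        out = np.empty((len(utilities), 5), dtype=int)
        for i, u in enumerate(utilities):
            cands = self.profiles_by_u[u]
            out[i] = cands[rng.integers(len(cands))] if len(cands) > 1 else cands[0]
        return out


# ---------------------------------------------------------------------------
# PAID sampling
# ---------------------------------------------------------------------------


def _beta_params(mean100: float, sd100: float) -> tuple[float, float]:
    """Beta(a, b) for the per-person response tendency p.

    The PAID total is 1.25 x Binomial(80, p); decomposing its variance into
    the between-person part (100^2 Var p) and the within-binomial part
    (125 E[p(1-p)]) and solving for Var p matches the target total SD.
    """
    pbar = mean100 / 100.0
    v = (sd100**2 - 125.0 * pbar * (1 - pbar)) / (10_000.0 - 125.0)
    v = float(np.clip(v, 1e-8, 0.98 * pbar * (1 - pbar)))
    k = pbar * (1 - pbar) / v - 1.0
    return pbar * k, (1 - pbar) * k


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = (
        "centers",
        "randomize",
        "covariates",
        "costs",
        "utilities",
        "paid",
        "assess",
        "missingness",
    )
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_trial(
    config: TrialConfig,
    unit_costs: UnitCostTable | None = None,
    value_set: EQ5DValueSet | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a complete (pre-missingness) participant-level dataset.

    Returns the wide participant table and a metadata dict (config echo,
    per-operation seed trail, generator version). Arm labels come from
    stratified permuted-block randomization, so realized arm sizes vary
    around n/2 within half the largest block per centre.
    """
    unit_costs = unit_costs or load_unit_costs()
    value_set = value_set or load_value_set()
    rngs = _spawn_rngs(config.seed)
    n = int(sum(config.n_per_arm))

    # centres: uneven recruitment, every centre nonempty
    weights = rngs["centers"].dirichlet(np.full(config.n_centers, 5.0))
    centers = rngs["centers"].choice(config.n_centers, size=n, p=weights)
    k = min(n, config.n_centers)
    centers[:k] = np.arange(k)  # no empty centre (when enough participants)
    rngs["centers"].shuffle(centers)

    arms = block_randomize(centers, config, rngs["randomize"])

    rng = rngs["covariates"]
    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "center": centers,
            "arm": arms,
            "age": rng.normal(config.age_mean, config.age_sd, n).round(1),
            "male": rng.random(n) < config.male_prop,
            "cvd_history": rng.random(n) < config.cvd_prop,
            "smoking": rng.random(n) < config.smoking_prop,
        }
    )
    shape = (config.duration_mean / config.duration_sd) ** 2
    scale = config.duration_sd**2 / config.duration_mean
    df["diabetes_duration"] = rng.gamma(shape, scale, n).round(1)
    for c in ("male", "cvd_history", "smoking"):
        df[c] = df[c].astype(int)

    cols: dict[str, np.ndarray] = {}
    _generate_costs(df, cols, config, unit_costs, rngs["costs"])
    _generate_utilities(df, cols, config, value_set, rngs["utilities"])
    _generate_paid(df, cols, config, rngs["paid"])

    rng = rngs["assess"]
    for tp in schema.TIMEPOINTS:
        m, s = config.assess_month_params[tp]
        cols[schema.assess_col(tp)] = (
            np.zeros(n) if s == 0 and m == 0 else rng.normal(m, s, n).round(2)
        )
    df = pd.concat([df, pd.DataFrame(cols, index=df.index)], axis=1)

    meta = {
        "generator_version": GENERATOR_VERSION,
        "seed": config.seed,
        "seed_trail": {k: "spawned from root seed" for k in rngs},
        "n": n,
        "config": _config_echo(config),
    }
    return df, meta


def _generate_costs(df, cols, config, unit_costs, rng):
    n = len(df)
    s = config.center_logcost_sd
    center_mult = np.exp(
        rng.normal(-s**2 / 2, s, config.n_centers) if s > 0 else np.zeros(config.n_centers)
    )[df["center"].to_numpy()]
    for arm in schema.ARMS:
        mask = (df["arm"] == arm).to_numpy()
        p = config.arm_params[arm]
        k = 1.0 / p.cost_dispersion
        for window in schema.WINDOWS:
            for section, weights in _SERVICE_WEIGHTS.items():
                m = p.cost_means[window][section]
                frailty = center_mult[mask] * rng.gamma(k, 1.0 / k, mask.sum())
                for service, w in weights.items():
                    lam = m * w / unit_costs[service]
                    col = schema.svc_col(window, service)
                    if col not in cols:
                        cols[col] = np.zeros(n)
                    cols[col][mask] = rng.poisson(frailty * lam).astype(float)
            # prescriptions: Poisson item count, gamma monthly item costs
            m_rx = p.cost_means[window]["nurse_medications"]
            months = schema.WINDOW_MONTHS[window]
            n_items = rng.poisson(4.0, mask.sum())
            mean_item = m_rx / months / 4.0
            totals = np.array(
                [
                    rng.gamma(1.5, mean_item / 1.5, ni).sum() if ni else 0.0
                    for ni in n_items
                ]
            )
            mcol, ncol = schema.rx_monthly_col(window), schema.rx_none_col(window)
            if mcol not in cols:
                cols[mcol] = np.zeros(n)
                cols[ncol] = np.zeros(n, dtype=bool)
            cols[mcol][mask] = totals.round(2)
            cols[ncol][mask] = n_items == 0
    # unused service types stay at count 0 so the sections are complete
    for window in schema.WINDOWS:
        for services in schema.SECTION_SERVICES.values():
            for s in services:
                cols.setdefault(schema.svc_col(window, s), np.zeros(n))


def _generate_utilities(df, cols, config, value_set, rng):
    n = len(df)
    rho = config.within_person_corr
    gc = config.center_utility_share
    resid = np.sqrt(max(1 - rho**2 - gc**2, 0.0))
    center_z = rng.normal(size=config.n_centers)[df["center"].to_numpy()]
    if not config.utilities_on_grid:
        common = rng.normal(size=n)
        for j, tp in enumerate(schema.TIMEPOINTS):
            vals = np.empty(n)
            for arm in schema.ARMS:
                mask = (df["arm"] == arm).to_numpy()
                p = config.arm_params[arm]
                z = (
                    gc * center_z[mask]
                    + rho * common[mask]
                    + resid * rng.normal(size=mask.sum())
                )
                vals[mask] = p.utility_means[j] + p.utility_sd * z
            cols[schema.utility_col(tp)] = np.clip(
                vals, EQ5D_MIN, EQ5D_MAX
            ).round(3)
        return
    sampler = GridUtilitySampler(value_set)
    common = rng.normal(size=n)
    for j, tp in enumerate(schema.TIMEPOINTS):
        utilities = np.empty(n)
        for arm in schema.ARMS:
            mask = (df["arm"] == arm).to_numpy()
            p = config.arm_params[arm]
            mu = sampler.calibrate(p.utility_means[j], p.utility_sd)
            z = mu + p.utility_sd * (
                gc * center_z[mask]
                + rho * common[mask]
                + resid * rng.normal(size=mask.sum())
            )
            utilities[mask] = sampler.snap(z)
        profiles = sampler.profiles_for(utilities, rng)
        for d, dim in enumerate(schema.EQ5D_DIMENSIONS):
            cols[schema.eq5d_col(tp, dim)] = profiles[:, d].astype(float)


def _generate_paid(df, cols, config, rng):
    n = len(df)
    rho = config.within_person_corr
    common = rng.normal(size=n)
    for j, tp in enumerate(schema.TIMEPOINTS):
        p_resp = np.empty(n)
        for arm in schema.ARMS:
            mask = (df["arm"] == arm).to_numpy()
            p = config.arm_params[arm]
            a, b = _beta_params(p.paid_means[j], p.paid_sd)
            z = rho * common[mask] + np.sqrt(1 - rho**2) * rng.normal(
                size=mask.sum()
            )
            p_resp[mask] = stats.beta.ppf(special.ndtr(z), a, b)
        items = rng.binomial(4, p_resp[:, None], size=(n, schema.N_PAID_ITEMS))
        for i in range(schema.N_PAID_ITEMS):
            cols[schema.paid_col(tp, i + 1)] = items[:, i].astype(float)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------


def impose_missingness(
    df: pd.DataFrame, config: TrialConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Apply questionnaire- and section-level nonresponse.

    Self-report nonresponse at a timepoint blanks the EQ-5D profile, the
    PAID items and the self-reported service counts for the corresponding
    window, per arm at the configured rates (optionally tilted by baseline
    PAID — a missing-at-random mechanism by construction, since it
    conditions only on observed baseline data, never on the removed
    values). Nurse-extracted sections and diabetes duration go missing
    independently at their own small rates.
    """
    miss = config.missingness
    miss.validate()
    if rng is None:
        rng = _spawn_rngs(config.seed)["missingness"]
    out = df.copy()
    n = len(out)

    paid0_cols = [schema.paid_col(0, i + 1) for i in range(schema.N_PAID_ITEMS)]
    if miss.mar_paid_slope and all(c in out.columns for c in paid0_cols):
        paid0 = out[paid0_cols].sum(axis=1).to_numpy() * 1.25
        zpaid = (paid0 - paid0.mean()) / (paid0.std() or 1.0)
    else:
        zpaid = np.zeros(n)

    for arm in schema.ARMS:
        mask = (out["arm"] == arm).to_numpy()
        for tp in schema.TIMEPOINTS:
            base = miss.nonresponse.get(arm, {}).get(tp, 0.0)
            if base <= 0:
                continue
            logit = np.log(base / (1 - base)) if base < 1 else np.inf
            prob = special.expit(logit + miss.mar_paid_slope * zpaid)
            prob = np.where(np.isinf(logit), 1.0, prob)
            hit = mask & (rng.random(n) < prob)
            cols = [schema.eq5d_col(tp, d) for d in schema.EQ5D_DIMENSIONS]
            cols += [schema.paid_col(tp, i + 1) for i in range(schema.N_PAID_ITEMS)]
            cols.append(schema.utility_col(tp))
            w = schema.TIMEPOINT_WINDOW[tp]
            cols += [schema.svc_col(w, s) for s in schema.SELFREPORT_SERVICES]
            for c in cols:
                if c in out.columns:
                    out.loc[hit, c] = np.nan

    if miss.nurse_section_rate > 0:
        for window in schema.WINDOWS:
            hit = rng.random(n) < miss.nurse_section_rate
            for s in schema.NURSE_SERVICES:
                c = schema.svc_col(window, s)
                if c in out.columns:
                    out.loc[hit, c] = np.nan
            hit = rng.random(n) < miss.nurse_section_rate
            mcol = schema.rx_monthly_col(window)
            if mcol in out.columns:
                out.loc[hit, mcol] = np.nan
                out.loc[hit, schema.rx_none_col(window)] = False
    if miss.duration_rate > 0:
        hit = rng.random(n) < miss.duration_rate
        out.loc[hit, "diabetes_duration"] = np.nan
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _config_echo(config: TrialConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)


def write_dataset(df: pd.DataFrame, meta: dict, csv_path, meta_path=None) -> None:
    """Write the wide participant CSV (missing as empty cells) + JSON sidecar."""
    df.to_csv(csv_path, index=False)
    if meta_path is None:
        meta_path = str(csv_path).rsplit(".", 1)[0] + ".meta.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def read_dataset(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)
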