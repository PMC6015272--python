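"""Health-outcome scoring: EQ-5D-3L utilities, PAID, and QALYs.

Utilities come from the UK general-population time-trade-off tariff in its
additive-decrement form: full health (11111) is anchored at 1; any
dysfunction subtracts a constant, each dimension/level its decrement, and
any level-3 response a further shared term. The resulting utilities span
[-0.594, 1]. QALYs over the 12-month trial are the trapezoidal area under
the utility curve through the 0-, 3- and 12-month assessments (0.25- and
0.75-year segments), undiscounted.

PAID (Problem Areas in Diabetes) is 20 items scored 0-4; the raw 0-80 sum
is rescaled to 0-100, with 40+ flagging significant diabetes distress.

Twelve-month assessments are only valid as outcomes if taken within the
pre-specified 10-14 month window; out-of-window measurements are retained
as auxiliary predictors for imputation.
"""

from __future__ import annotations

import hashlib
import importlib.resources as _resources
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import schema

PAID_DISTRESS_THRESHOLD = 40.0
VALIDITY_WINDOW = (10.0, 14.0)  # months, inclusive


@dataclass(frozen=True)
class EQ5DValueSet:
    """Additive-decrement tariff: constant + per-dimension + any-level-3."""

    constant: float
    n3: float
    decrements: Mapping[tuple[str, int], float]

    def utility(self, profile: Sequence[int]) -> float:
        if len(profile) != len(schema.EQ5D_DIMENSIONS):
            raise ValueError("profile must have exactly five dimension levels")
        levels = [int(l) for l in profile]
        if any(l not in (1, 2, 3) for l in levels):
            raise ValueError(f"levels must be in {{1,2,3}}, got {profile}")
        if all(l == 1 for l in levels):
            return 1.0
        u = 1.0 - self.constant
        for dim, level in zip(schema.EQ5D_DIMENSIONS, levels):
            if level > 1:
                u -= self.decrements[(dim, level)]
        if any(l == 3 for l in levels):
            u -= self.n3
        return round(u, 6)

    def all_profiles(self) -> pd.DataFrame:
        """All 243 profiles with their tariff values."""
        rows = [
            {"profile": "".join(map(str, p)), "utility": self.utility(p)}
            for p in product((1, 2, 3), repeat=5)
        ]
        return pd.DataFrame(rows)


def _verify_checksum(path) -> list[str]:
    raw = path.read_text().splitlines()
    stated = None
    for line in raw:
        if line.startswith("# md5:"):
            stated = line.split(":", 1)[1].strip()
    data_lines = [l.strip() for l in raw if l.strip() and not l.startswith("#")]
    if stated is None:
        raise ValueError(
            f"value set {path} has no provenance checksum header; refusing to score"
        )
    actual = hashlib.md5("\n".join(data_lines).encode()).hexdigest()
    if actual != stated:
        raise ValueError(
            f"value set {path} failed checksum verification "
            f"(stated {stated}, computed {actual})"
        )
    return data_lines


def load_value_set(path=None) -> EQ5DValueSet:
    """Load and checksum-verify the UK TTO tariff (packaged default)."""
    if path is None:
        path = _resources.files("trialcea.data").joinpath("eq5d3l_uk_tto.csv")
    data_lines = _verify_checksum(path)
    header, *rows = data_lines
    cols = header.split(",")
    constant = n3 = None
    decrements: dict[tuple[str, int], float] = {}
    for row in rows:
        rec = dict(zip(cols, row.split(",")))
        if rec["term"] == "constant":
            constant = float(rec["decrement"])
        elif rec["term"] == "n3":
            n3 = float(rec["decrement"])
        else:
            decrements[(rec["dimension"], int(rec["level"]))] = float(
                rec["decrement"]
            )
    if constant is None or n3 is None or len(decrements) != 10:
        raise ValueError("malformed value-set file")
    return EQ5DValueSet(constant=constant, n3=n3, decrements=decrements)


def eq5d_utility(profile: Sequence[int], value_set: EQ5DValueSet) -> float:
    """Tariff utility of one five-level profile."""
    return value_set.utility(profile)


def paid_score(items: Sequence[float]) -> float:
    """PAID total on the 0-100 scale: 1.25 x the 0-80 raw item sum."""
    arr = np.asarray(items, dtype=float)
    if arr.shape != (schema.N_PAID_ITEMS,):
        raise ValueError(f"expected {schema.N_PAID_ITEMS} items, got {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError("missing PAID items; score the questionnaire only when complete")
    if ((arr < 0) | (arr > 4)).any():
        raise ValueError("PAID items must be in [0, 4]")
    return float(arr.sum() * 1.25)


def paid_distress(total: float) -> bool:
    """Significant diabetes distress: PAID total of 40 or more."""
    return bool(total >= PAID_DISTRESS_THRESHOLD)


def qaly_auc(u0: float, u3: float, u12: float) -> float:
    """QALYs over 12 months: trapezoidal area under the utility curve.

    Segments are 0-3 months (0.25 years) and 3-12 months (0.75 years);
    no discounting over the one-year horizon. All three utilities must be
    present — imputation happens before QALY computation.
    """
    us = np.asarray([u0, u3, u12], dtype=float)
    if np.isnan(us).any():
        raise ValueError("missing utility; impute before computing QALYs")
    return float(0.25 * (us[0] + us[1]) / 2 + 0.75 * (us[1] + us[2]) / 2)


def apply_validity_window(
    df: pd.DataFrame, window: tuple[float, float] = VALIDITY_WINDOW
) -> pd.DataFrame:
    """Flag whether each 12-month assessment is valid as an outcome.

    Adds a boolean ``valid_12`` column: True when the assessment month lies
    in the closed interval ``window`` (default [10, 14]). Out-of-window
    measurements keep their values — they serve as imputation predictors —
    but must not enter the analysis as observed outcomes. Participants with
    no recorded assessment month are flagged invalid.
    """
    lo, hi = window
    out = df.copy()
    month = out[schema.assess_col(12)].to_numpy(dtype=float)
    out["valid_12"] = (month >= lo) & (month <= hi)
    return out


def score_outcomes(df: pd.DataFrame, value_set: EQ5DValueSet) -> pd.DataFrame:
    """Score utilities and PAID totals at every timepoint.

    For each timepoint with EQ-5D item columns, adds ``u_<t>`` (NaN when
    the questionnaire was not returned); likewise ``paid_<t>`` from the 20
    PAID items. Pre-scored ``u_<t>``/``paid_<t>`` columns, if already
    present, are left untouched (direct-utility generator mode).
    """
    out = df.copy()
    lookup = {
        tuple(int(c) for c in row.profile): row.utility
        for row in value_set.all_profiles().itertuples()
    }
    for tp in schema.TIMEPOINTS:
        ucol = schema.utility_col(tp)
        eq_cols = [schema.eq5d_col(tp, d) for d in schema.EQ5D_DIMENSIONS]
        if ucol not in out.columns and all(c in out.columns for c in eq_cols):
            levels = out[eq_cols].to_numpy(dtype=float)
            vals = np.full(len(out), np.nan)
            complete = ~np.isnan(levels).any(axis=1)
            for i in np.flatnonzero(complete):
                vals[i] = lookup[tuple(int(l) for l in levels[i])]
            out[ucol] = vals
        pcol = schema.paid_total_col(tp)
        paid_cols = [
            schema.paid_col(tp, i) for i in range(1, schema.N_PAID_ITEMS + 1)
        ]
        if pcol not in out.columns and all(c in out.columns for c in paid_cols):
            items = out[paid_cols].to_numpy(dtype=float)
            totals = np.full(len(out), np.nan)
            complete = ~np.isnan(items).any(axis=1)
            totals[complete] = items[complete].sum(axis=1) * 1.25
            out[pcol] = totals
    return out
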