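"""Column vocabulary shared across the pipeline.

Participant-level data travel as one wide :class:`pandas.DataFrame`, one row
per participant. Resource-use counts, prescription summaries, EQ-5D-3L item
levels and PAID item scores live in systematically named columns; this module
owns those names so that the generator, the costing stage and the outcome
scorers never disagree about them.
"""

from __future__ import annotations

#: Costing windows: 12 months pre-baseline, 0-3 months, 3-12 months.
WINDOWS = ("pre12m", "m0_3", "m3_12")

#: Months covered by each window (prescriptions are costed monthly).
WINDOW_MONTHS = {"pre12m": 12, "m0_3": 3, "m3_12": 9}

#: Questionnaire / assessment timepoints, months since randomisation.
TIMEPOINTS = (0, 3, 12)

#: Window whose self-reported service use is collected at each timepoint,
#: and whose current prescriptions are extrapolated over it.
TIMEPOINT_WINDOW = {0: "pre12m", 3: "m0_3", 12: "m3_12"}

#: Aggregated cost sections, mirroring how the data were summarised:
#: services from nurse-extracted records, medications from nurse-extracted
#: records, and services from participant self-report.
SECTIONS = ("nurse_services", "nurse_medications", "selfreport_services")

#: Service types extracted from medical records by practice/research nurses.
NURSE_SERVICES = (
    "gp_surgery",
    "gp_home_visit",
    "gp_telephone",
    "nurse_surgery",
    "nurse_home_visit",
    "walk_in_clinic",
    "ooh_telephone",
    "ooh_home_visit",
    "ooh_surgery",
    "a_and_e",
    "clinical_test",
    "outpatient",
    "day_case",
    "inpatient",
    "district_nurse_home",
    "district_nurse_clinic",
)

#: Service types collected by participant self-report questionnaire.
SELFREPORT_SERVICES = (
    "podiatrist",
    "optometry",
    "physiotherapy",
    "counselling_primary",
    "counselling_community",
    "social_worker",
    "occupational_therapy",
    "dietician",
)

SECTION_SERVICES = {
    "nurse_services": NURSE_SERVICES,
    "selfreport_services": SELFREPORT_SERVICES,
}

#: EQ-5D-3L dimensions in conventional order.
EQ5D_DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

N_PAID_ITEMS = 20

ARMS = ("intervention", "control")

BASELINE_COVARIATES = ("age", "male", "cvd_history", "smoking", "diabetes_duration")


def svc_col(window: str, service: str) -> str:
    """Count of ``service`` consultations/episodes in ``window``."""
    return f"svc_{window}__{service}"


def rx_monthly_col(window: str) -> str:
    """Summed monthly cost of current prescriptions applied to ``window``."""
    return f"rx_{window}__monthly"


def rx_none_col(window: str) -> str:
    """Explicit no-medication flag for ``window`` (blank != none)."""
    return f"rx_{window}__none"


def eq5d_col(timepoint: int, dimension: str) -> str:
    return f"eq5d_{timepoint}__{dimension}"


def paid_col(timepoint: int, item: int) -> str:
    return f"paid_{timepoint}__i{item:02d}"


def assess_col(timepoint: int) -> str:
    """Actual assessment month for the nominal ``timepoint`` visit."""
    return f"assess_month_{timepoint}"


def cost_col(window: str, section: str) -> str:
    """Aggregated section cost in pounds for ``window``."""
    return f"cost_{window}__{section}"


def utility_col(timepoint: int) -> str:
    return f"u_{timepoint}"


def paid_total_col(timepoint: int) -> str:
    return f"paid_{timepoint}"
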