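"""Canned synthetic scenarios emulating the study conditions.

These factories define, once, the default configurations used throughout
the test-suite and the worked examples: a hospital-style extract with the
April-2012 myocardial-infarction coding step, its no-effect null
counterpart, a gradual code-drift scenario, a financial-year clustering
scenario, and primary-care scenarios with rising cardiovascular prevalence
and selective practice dropout.

The hospital code set is the ten 3-character groups the cardiovascular
results discuss (angina I20, acute and subsequent myocardial infarction
I21/I22, chronic coronary heart disease I25, atrial fibrillation I48,
heart failure I50, cerebral infarction I63, unspecified stroke I64 and
transient ischaemic attack G45) plus the remainder pseudo-code ``IXX``
absorbing all other included cardiovascular codes.  Baseline shares follow
the published January-2001 values where printed (I20 18.8%, I21 8.0%,
I22 1.4%) and realistic magnitudes otherwise.  The default monthly volume
of included cardiovascular codes is 50 000; the drift and clustering
scenarios use 200 000, the realistic scale of national monthly
cardiovascular code volumes.
"""

from __future__ import annotations

import pandas as pd

from .slicing import Codelist
from .synthetic import ConditionSpec, MixShiftSpec, ScenarioConfig
from .synthetic import REMAINDER_CODE

__all__ = [
    "hes_codelist",
    "hospital_step_scenario",
    "hospital_null_scenario",
    "hospital_drift_scenario",
    "hospital_cluster_scenario",
    "primary_care_scenario",
    "practice_dropout_scenario",
]

#: baseline share of the monthly cardiovascular-code denominator per code
HES_BASE_SHARES = {
    "I20": 0.188,
    "I21": 0.080,
    "I22": 0.014,
    "I25": 0.180,
    "I48": 0.120,
    "I50": 0.100,
    "I63": 0.080,
    "I64": 0.070,
    "G45": 0.050,
}

HES_AGE_MARGINAL = {
    "40-44": 0.06, "45-49": 0.07, "50-54": 0.09, "55-59": 0.10,
    "60-64": 0.11, "65-69": 0.12, "70-74": 0.14, "75+": 0.31,
}
HES_DEMOGRAPHICS = {
    "age_band": HES_AGE_MARGINAL,
    "gender": {"F": 0.45, "M": 0.55},
    "imd_quintile": {1: 0.22, 2: 0.21, 3: 0.20, 4: 0.19, 5: 0.18},
}

PRIMARY_CARE_DEMOGRAPHICS = {
    "age_band": {"20-39": 0.36, "40-59": 0.33, "60-79": 0.24, "80+": 0.07},
    "gender": {"F": 0.51, "M": 0.49},
    "imd_quintile": {1: 0.20, 2: 0.20, 3: 0.20, 4: 0.20, 5: 0.20},
}

#: Read-code-style fixture codelists for the four primary-care conditions
PRIMARY_CARE_CODES = {
    "chd": ("G30..", "G33.."),
    "heart_failure": ("G58..",),
    "pad": ("G73..",),
    "stroke": ("G66..",),
}


def hes_codelist() -> Codelist:
    """Fixture codelist of included cardiovascular 3-character codes."""
    return Codelist(
        "cardiovascular",
        frozenset(HES_BASE_SHARES) | {REMAINDER_CODE},
        terminology="icd10-3char",
    )


def _flat_conditions(start, shares=HES_BASE_SHARES) -> list[ConditionSpec]:
    return [
        ConditionSpec(code, (code,), ((start, share),))
        for code, share in shares.items()
    ]


def hospital_step_scenario(
    seed: int = 0,
    start: str = "2001-01",
    n_months: int = 180,
    monthly_volume: int = 50_000,
    step_month_index: int = 135,
    step_factor: float = 0.109 / 0.080,
) -> ScenarioConfig:
    """Flat code shares with one planted step on I21.

    With the defaults the step lands on April 2012 (month index 135 of a
    180-month window starting January 2001) and raises the I21 share from
    8.0% to 10.9% of included codes, the remainder absorbing the balance.
    """
    start_p = pd.Period(start, freq="M")
    end_p = start_p + n_months - 1
    step_month = start_p + step_month_index
    conditions = []
    for code, share in HES_BASE_SHARES.items():
        steps = ((step_month, step_factor),) if code == "I21" else ()
        conditions.append(ConditionSpec(code, (code,), ((start_p, share),), steps))
    return ScenarioConfig(
        start_month=start_p,
        end_month=end_p,
        demographics=HES_DEMOGRAPHICS,
        conditions=tuple(conditions),
        monthly_volume=monthly_volume,
        seed=seed,
    )


def hospital_null_scenario(
    seed: int = 0,
    start: str = "2001-01",
    n_months: int = 180,
    monthly_volume: int = 50_000,
) -> ScenarioConfig:
    """Flat shares, stable demographics, no planted effects."""
    start_p = pd.Period(start, freq="M")
    return ScenarioConfig(
        start_month=start_p,
        end_month=start_p + n_months - 1,
        demographics=HES_DEMOGRAPHICS,
        conditions=tuple(_flat_conditions(start_p)),
        monthly_volume=monthly_volume,
        seed=seed,
    )


def hospital_drift_scenario(
    seed: int = 0,
    start: str = "2001-01",
    n_months: int = 96,
    monthly_volume: int = 200_000,
) -> ScenarioConfig:
    """Gradual multi-year code-share drift (no steps).

    Emulates the pre-2009 pattern: angina and unspecified stroke declining,
    chronic coronary heart disease and cerebral infarction rising.
    """
    start_p = pd.Period(start, freq="M")
    end_p = start_p + n_months - 1
    drift_ends = {
        "I20": 0.120, "I21": 0.070, "I25": 0.206, "I63": 0.100, "I64": 0.045,
        "I48": 0.135,
    }
    conditions = []
    for code, share in HES_BASE_SHARES.items():
        if code in drift_ends:
            traj = ((start_p, share), (end_p, drift_ends[code]))
        else:
            traj = ((start_p, share),)
        conditions.append(ConditionSpec(code, (code,), traj))
    return ScenarioConfig(
        start_month=start_p,
        end_month=end_p,
        demographics=HES_DEMOGRAPHICS,
        conditions=tuple(conditions),
        monthly_volume=monthly_volume,
        seed=seed,
    )


def hospital_cluster_scenario(
    seed: int = 0,
    start: str = "2009-04",
    n_months: int = 72,
    monthly_volume: int = 200_000,
) -> ScenarioConfig:
    """Biennial April coding steps producing financial-year-pair clusters.

    Shares are flat within each two-financial-year block and jump at the
    April boundaries (2011 and 2013 with the defaults), emulating coding
    guidance taking effect at the start of NHS financial years.
    """
    start_p = pd.Period(start, freq="M")
    end_p = start_p + n_months - 1
    step_months = [start_p + 24, start_p + 48]
    step_factors = {"I21": 1.3625, "I22": 0.5, "I20": 0.85, "I63": 1.2}
    conditions = []
    for code, share in HES_BASE_SHARES.items():
        steps = tuple((m, step_factors[code]) for m in step_months if code in step_factors)
        conditions.append(ConditionSpec(code, (code,), ((start_p, share),), steps))
    return ScenarioConfig(
        start_month=start_p,
        end_month=end_p,
        demographics=HES_DEMOGRAPHICS,
        conditions=tuple(conditions),
        monthly_volume=monthly_volume,
        seed=seed,
    )


def primary_care_scenario(
    seed: int = 0,
    start: str = "2001-01",
    n_months: int = 84,
    n_patients: int = 200_000,
) -> ScenarioConfig:
    """Rising recorded cardiovascular prevalence in a closed cohort.

    The four conditions drift linearly from their January-2001 recorded
    prevalences to their end-2007 values (per 1000 patients: coronary heart
    disease 44.7 to 48.2, heart failure 6.7 to 10.8, peripheral arterial
    disease 7.0 to 10.3, stroke 14.4 to 23.4).
    """
    start_p = pd.Period(start, freq="M")
    end_p = start_p + n_months - 1
    drift = {
        "chd": (0.0447, 0.0482),
        "heart_failure": (0.0067, 0.0108),
        "pad": (0.0070, 0.0103),
        "stroke": (0.0144, 0.0234),
    }
    conditions = tuple(
        ConditionSpec(name, PRIMARY_CARE_CODES[name], ((start_p, a), (end_p, b)))
        for name, (a, b) in drift.items()
    )
    return ScenarioConfig(
        start_month=start_p,
        end_month=end_p,
        demographics=PRIMARY_CARE_DEMOGRAPHICS,
        conditions=conditions,
        n_patients=n_patients,
        seed=seed,
    )


def practice_dropout_scenario(
    seed: int = 0,
    start: str = "2010-01",
    n_months: int = 36,
    n_patients: int = 50_000,
    retained: float = 0.6,
) -> ScenarioConfig:
    """Flat prevalence with dropout concentrated in two deprivation quintiles.

    Midway through the window the cohort shrinks to ``retained`` of its
    initial size, with leavers drawn preferentially from quintiles 1 and 2,
    shifting the deprivation mix of the remaining population.
    """
    start_p = pd.Period(start, freq="M")
    end_p = start_p + n_months - 1
    mid = start_p + n_months // 2
    conditions = tuple(
        ConditionSpec(name, codes, ((start_p, 0.02),))
        for name, codes in list(PRIMARY_CARE_CODES.items())[:2]
    )
    return ScenarioConfig(
        start_month=start_p,
        end_month=end_p,
        demographics=PRIMARY_CARE_DEMOGRAPHICS,
        conditions=conditions,
        mix_shifts=(MixShiftSpec(mid, end_p, "imd_quintile", {1: 8.0, 2: 8.0}),),
        dropout_schedule={mid: retained},
        n_patients=n_patients,
        seed=seed,
    )
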