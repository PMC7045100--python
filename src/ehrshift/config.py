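"""YAML run-configuration parsing for the command-line interface.

A single structured file describes a whole run: the synthetic scenario (or
the file schemas of real extracts), the codelists, the slicing settings,
the analysis variables, the dissimilarity scale and the detection
thresholds.  Every key has a default matching the package defaults, so a
minimal config only needs ``mode`` and a ``scenario``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .slicing import Codelist, HOSPITAL_AGE_BANDS, PRIMARY_CARE_AGE_BANDS
from .synthetic import ConditionSpec, MixShiftSpec, ScenarioConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Parsed run configuration."""

    mode: str  # "hospital" | "primary_care"
    scenario: ScenarioConfig | None
    codelists: list[Codelist]
    variables: list[str] | None
    age_bands: tuple[int, ...]
    age_range: tuple[int, int] = (20, 110)
    min_registration_days: int = 365
    jsd_scale: str = "distance"
    jsd_log_base: float = 2
    detection: dict = field(default_factory=dict)
    seed: int | None = None


def _parse_conditions(raw) -> tuple[ConditionSpec, ...]:
    out = []
    for c in raw:
        out.append(
            ConditionSpec(
                name=c["name"],
                codes=tuple(c.get("codes", (c["name"],))),
                trajectory=tuple((m, v) for m, v in c["trajectory"]),
                step_changes=tuple((m, f) for m, f in c.get("steps", ())),
            )
        )
    return tuple(out)


def _parse_scenario(raw: Mapping[str, Any] | None) -> ScenarioConfig | None:
    if raw is None:
        return None
    demo = {k: dict(v) for k, v in raw["demographics"].items()}
    mix = tuple(
        MixShiftSpec(m["start"], m["end"], m["variable"], m["weights"])
        for m in raw.get("mix_shifts", ())
    )
    return ScenarioConfig(
        start_month=raw["start_month"],
        end_month=raw["end_month"],
        demographics=demo,
        conditions=_parse_conditions(raw["conditions"]),
        mix_shifts=mix,
        dropout_schedule=raw.get("dropout", {}),
        n_patients=int(raw.get("n_patients", 200_000)),
        monthly_turnover=float(raw.get("monthly_turnover", 0.0)),
        monthly_volume=int(raw.get("monthly_volume", 50_000)),
        seed=int(raw.get("seed", 0)),
    )


def load_config(path, seed: int | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``seed`` overrides both the top-level and the scenario seed, so one
    config can drive many replicates.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    mode = raw.get("mode", "hospital")
    if mode not in ("hospital", "primary_care"):
        raise ValueError(f"unknown mode {mode!r}")
    scenario = _parse_scenario(raw.get("scenario"))
    eff_seed = seed if seed is not None else raw.get("seed")
    if scenario is not None and eff_seed is not None:
        scenario = ScenarioConfig(
            start_month=scenario.start_month,
            end_month=scenario.end_month,
            demographics=scenario.demographics,
            conditions=scenario.conditions,
            mix_shifts=scenario.mix_shifts,
            dropout_schedule=scenario.dropout_schedule,
            n_patients=scenario.n_patients,
            monthly_turnover=scenario.monthly_turnover,
            monthly_volume=scenario.monthly_volume,
            seed=int(eff_seed),
        )
    codelists = [
        Codelist(c["condition"], frozenset(c["codes"]), c.get("terminology", "read"))
        for c in raw.get("codelists", ())
    ]
    slicing_cfg = raw.get("slicing", {})
    default_bands = HOSPITAL_AGE_BANDS if mode == "hospital" else PRIMARY_CARE_AGE_BANDS
    jsd = raw.get("jsd", {})
    return RunConfig(
        mode=mode,
        scenario=scenario,
        codelists=codelists,
        variables=raw.get("variables"),
        age_bands=tuple(slicing_cfg.get("age_bands", default_bands)),
        age_range=tuple(slicing_cfg.get("age_range", (20, 110))),
        min_registration_days=int(slicing_cfg.get("min_registration_days", 365)),
        jsd_scale=jsd.get("scale", "distance"),
        jsd_log_base=jsd.get("log_base", 2),
        detection=dict(raw.get("detection", {})),
        seed=eff_seed,
    )
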