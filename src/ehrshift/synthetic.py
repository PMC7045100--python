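"""Synthetic EHR generators with known, configurable temporal structure.

Two generators emulate the shapes of UK routine-data extracts:

``generate_primary_care``
    a patient table (year of birth, gender, deprivation quintile,
    registration interval) plus a dated event table of first-ever diagnosis
    codes, emulating a primary-care database with ever-recorded condition
    phenotypes;
``generate_hospital_counts``
    a table of monthly admission-code counts preaggregated by age band,
    gender, deprivation quintile and 3-character ICD-10 code, emulating a
    hospital activity extract.

Every planted temporal effect -- gradual prevalence or code-share drifts,
step changes at month boundaries, demographic mix shifts and practice
dropout -- is returned in a :class:`GroundTruthManifest` so downstream
detectors can be scored against known truth.

Randomness
----------
All randomness flows from the single integer ``seed`` of the scenario
through a fixed ``numpy.random.SeedSequence`` splitting scheme: the root
sequence is spawned into (in order) a demographics stream, a churn stream,
one stream per condition, an event-day stream, and -- for the hospital
generator -- one stream per month.  Outputs are byte-identical across runs
for a fixed configuration.

Declining recorded prevalence
-----------------------------
An ever-recorded phenotype is monotone within a patient, so in a closed
cohort recorded prevalence cannot fall.  Declining trajectories are
therefore only feasible when registration churn is enabled
(``monthly_turnover > 0``): leavers are replaced by new registrants whose
recorded prevalence reflects the current, lower target, so the
cross-sectional prevalence falls gradually.  A declining trajectory without
churn is rejected with an explanatory error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._months import month_range, to_month

__all__ = [
    "ConditionSpec",
    "MixShiftSpec",
    "ScenarioConfig",
    "GroundTruthManifest",
    "generate_primary_care",
    "generate_hospital_counts",
]

_PROB_ATOL = 1e-9


def _check_marginal(name: str, marginal: Mapping) -> dict:
    marginal = dict(marginal)
    total = sum(marginal.values())
    if abs(total - 1.0) > _PROB_ATOL:
        raise ValueError(f"{name} marginal sums to {total}, not 1")
    if any(v < 0 for v in marginal.values()):
        raise ValueError(f"{name} marginal has negative entries")
    return marginal


@dataclass(frozen=True)
class ConditionSpec:
    """One condition (or hospital code) with its planted temporal behaviour.

    Parameters
    ----------
    name
        Condition label (primary care) or 3-character code (hospital mode).
    codes
        Clinical codes emitted for this condition's events.
    trajectory
        Piecewise-linear breakpoints ``(month, target)``; the target is the
        recorded prevalence (primary-care mode) or the code share of the
        monthly denominator (hospital mode).  Values are interpolated
        linearly between breakpoints and held flat outside them.
    step_changes
        ``(month, multiplicative_factor)`` pairs; each factor applies to the
        target from the first day of its month onward (factors compound).
    """

    name: str
    codes: tuple[str, ...]
    trajectory: tuple[tuple, ...]
    step_changes: tuple[tuple, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "codes", tuple(self.codes))
        traj = tuple(sorted(((to_month(m), float(v)) for m, v in self.trajectory)))
        if not traj:
            raise ValueError(f"condition {self.name!r} has an empty trajectory")
        for _, v in traj:
            if not 0 < v < 1:
                raise ValueError(f"trajectory value {v} for {self.name!r} outside (0, 1)")
        object.__setattr__(self, "trajectory", traj)
        steps = tuple(sorted(((to_month(m), float(f)) for m, f in self.step_changes)))
        if any(f <= 0 for _, f in steps):
            raise ValueError("step factors must be positive")
        object.__setattr__(self, "step_changes", steps)

    def targets(self, months: Sequence[pd.Period]) -> np.ndarray:
        """Monthly targets: interpolated trajectory with step factors applied."""
        origin = months[0]
        x = np.array([(m - origin).n for m in months], dtype=float)
        xp = np.array([(m - origin).n for m, _ in self.trajectory], dtype=float)
        fp = np.array([v for _, v in self.trajectory], dtype=float)
        t = np.interp(x, xp, fp)
        for sm, f in self.step_changes:
            i = (sm - origin).n
            if not 0 <= i < len(months):
                raise ValueError(f"step month {sm} outside scenario range for {self.name!r}")
            t[i:] *= f
        if np.any((t <= 0) | (t >= 1)):
            raise ValueError(
                f"monthly targets for {self.name!r} leave (0, 1) after applying steps"
            )
        return t


@dataclass(frozen=True)
class MixShiftSpec:
    """A planted demographic mix shift over a period.

    During ``[start, end]`` the marginal of ``variable`` is reweighted by
    ``weights`` (hospital mode), or dropout within the period is
    concentrated on categories in proportion to ``weights`` (primary-care
    mode).  Unmentioned categories get weight 1.
    """

    start: pd.Period
    end: pd.Period
    variable: str
    weights: Mapping

    def __post_init__(self):
        object.__setattr__(self, "start", to_month(self.start))
        object.__setattr__(self, "end", to_month(self.end))
        if self.end < self.start:
            raise ValueError("mix shift end precedes start")
        w = dict(self.weights)
        if any(v < 0 for v in w.values()):
            raise ValueError("mix shift weights must be non-negative")
        object.__setattr__(self, "weights", w)

    def covers(self, month: pd.Period) -> bool:
        return self.start <= month <= self.end


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic scenario.

    The same config type drives both generators; ``n_patients``,
    ``monthly_turnover`` and ``dropout_schedule`` matter in primary-care
    mode, ``monthly_volume`` in hospital mode.
    """

    start_month: pd.Period
    end_month: pd.Period
    demographics: Mapping[str, Mapping]
    conditions: tuple[ConditionSpec, ...]
    mix_shifts: tuple[MixShiftSpec, ...] = ()
    dropout_schedule: Mapping = field(default_factory=dict)
    n_patients: int = 200_000
    monthly_turnover: float = 0.0
    monthly_volume: int = 50_000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "start_month", to_month(self.start_month))
        object.__setattr__(self, "end_month", to_month(self.end_month))
        if not self.start_month < self.end_month:
            raise ValueError("start_month must be strictly before end_month")
        demo = {k: _check_marginal(k, v) for k, v in self.demographics.items()}
        object.__setattr__(self, "demographics", demo)
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.n_patients <= 0 or self.monthly_volume <= 0:
            raise ValueError("n_patients and monthly_volume must be positive")
        if not 0 <= self.monthly_turnover < 1:
            raise ValueError("monthly_turnover must be in [0, 1)")
        sched = {to_month(m): float(f) for m, f in dict(self.dropout_schedule).items()}
        sched = dict(sorted(sched.items()))
        fracs = list(sched.values())
        if any(not 0 < f <= 1 for f in fracs):
            raise ValueError("dropout fractions must be in (0, 1]")
        if any(b > a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("dropout fractions must be non-increasing over time")
        for m in sched:
            if not self.start_month <= m <= self.end_month:
                raise ValueError(f"dropout month {m} outside scenario range")
        object.__setattr__(self, "dropout_schedule", sched)
        object.__setattr__(self, "mix_shifts", tuple(self.mix_shifts))
        for ms in self.mix_shifts:
            if ms.variable not in demo:
                raise ValueError(f"mix shift variable {ms.variable!r} not in demographics")
        # validate trajectories/steps eagerly
        for c in self.conditions:
            c.targets(self.months)

    @property
    def months(self) -> list[pd.Period]:
        return month_range(self.start_month, self.end_month)


@dataclass(frozen=True)
class GroundTruthManifest:
    """Planted temporal effects, for scoring detectors against known truth.

    ``planted_steps``: ``(month, target, direction, magnitude)`` tuples,
    where magnitude is the multiplicative factor applied to the target.
    ``planted_trend_periods``: ``(start, end, target, slope_sign)``.
    ``planted_mix_shifts``: ``(start, end, variable)``.
    """

    planted_steps: tuple[tuple, ...] = ()
    planted_trend_periods: tuple[tuple, ...] = ()
    planted_mix_shifts: tuple[tuple, ...] = ()

    def to_dict(self) -> dict:
        return {
            "planted_steps": [
                [str(m), t, d, float(f)] for m, t, d, f in self.planted_steps
            ],
            "planted_trend_periods": [
                [str(a), str(b), t, int(s)] for a, b, t, s in self.planted_trend_periods
            ],
            "planted_mix_shifts": [
                [str(a), str(b), v] for a, b, v in self.planted_mix_shifts
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruthManifest":
        return cls(
            planted_steps=tuple(
                (to_month(m), t, dr, float(f)) for m, t, dr, f in d.get("planted_steps", [])
            ),
            planted_trend_periods=tuple(
                (to_month(a), to_month(b), t, int(s))
                for a, b, t, s in d.get("planted_trend_periods", [])
            ),
            planted_mix_shifts=tuple(
                (to_month(a), to_month(b), v) for a, b, v in d.get("planted_mix_shifts", [])
            ),
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _build_manifest(config: ScenarioConfig, extra_mix: Sequence[tuple] = ()) -> GroundTruthManifest:
    steps, trends = [], []
    for c in config.conditions:
        for m, f in c.step_changes:
            steps.append((m, c.name, "up" if f > 1 else "down", f))
        traj = c.trajectory
        for (m0, v0), (m1, v1) in zip(traj, traj[1:]):
            if v1 != v0:
                trends.append((max(m0, config.start_month), min(m1, config.end_month),
                               c.name, 1 if v1 > v0 else -1))
    mixes = [(ms.start, ms.end, ms.variable) for ms in config.mix_shifts]
    mixes.extend(extra_mix)
    return GroundTruthManifest(tuple(steps), tuple(trends), tuple(mixes))


def _marginal_arrays(marginal: Mapping) -> tuple[list, np.ndarray]:
    cats = list(marginal.keys())
    probs = np.array([marginal[c] for c in cats], dtype=float)
    return cats, probs / probs.sum()


def _shifted_marginal(marginal: Mapping, shifts: Sequence[MixShiftSpec],
                      variable: str, month: pd.Period) -> tuple[list, np.ndarray]:
    cats, probs = _marginal_arrays(marginal)
    for ms in shifts:
        if ms.variable == variable and ms.covers(month):
            w = np.array([ms.weights.get(c, 1.0) for c in cats], dtype=float)
            probs = probs * w
            probs = probs / probs.sum()
    return cats, probs


# --------------------------------------------------------------------------
# hospital mode
# --------------------------------------------------------------------------

#: pseudo-code absorbing the share not allocated to any named code, so the
#: monthly code shares always normalise to 1
REMAINDER_CODE = "IXX"


def generate_hospital_counts(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Generate a preaggregated monthly hospital count table.

    For each month the configured total volume is drawn from a multinomial
    over code x age-band x gender x deprivation cells, where the code
    marginal follows the configured share trajectories (with a remainder
    pseudo-code absorbing unallocated share) and the demographic marginals
    are independent of code, optionally reweighted by active mix shifts.

    Returns
    -------
    (counts, manifest)
        ``counts`` has columns ``month, age_band, gender, imd_quintile,
        code, count`` (zero cells omitted); ``manifest`` lists every
        planted effect.
    """
    months = config.months
    n_months = len(months)
    share_rows = np.array([c.targets(months) for c in config.conditions])  # C x M
    totals = share_rows.sum(axis=0)
    if np.any(totals >= 1):
        bad = months[int(np.argmax(totals >= 1))]
        raise ValueError(f"code shares sum to >= 1 in {bad}; no room for the remainder")
    codes = [c.name for c in config.conditions] + [REMAINDER_CODE]
    shares = np.vstack([share_rows, 1.0 - totals])  # (C+1) x M

    root = np.random.SeedSequence(config.seed)
    month_streams = root.spawn(n_months)

    rows = []
    for t, m in enumerate(months):
        ab_cats, ab_p = _shifted_marginal(
            config.demographics["age_band"], config.mix_shifts, "age_band", m
        )
        g_cats, g_p = _shifted_marginal(
            config.demographics["gender"], config.mix_shifts, "gender", m
        )
        q_cats, q_p = _shifted_marginal(
            config.demographics["imd_quintile"], config.mix_shifts, "imd_quintile", m
        )
        demo_p = np.einsum("a,g,q->agq", ab_p, g_p, q_p).ravel()
        joint = np.outer(shares[:, t], demo_p).ravel()
        rng = np.random.default_rng(month_streams[t])
        counts = rng.multinomial(config.monthly_volume, joint / joint.sum())
        nz = np.flatnonzero(counts)
        n_demo = len(demo_p)
        n_g, n_q = len(g_cats), len(q_cats)
        for flat in nz:
            ci, di = divmod(flat, n_demo)
            ai, rest = divmod(di, n_g * n_q)
            gi, qi = divmod(rest, n_q)
            rows.append(
                (str(m), ab_cats[ai], g_cats[gi], int(q_cats[qi]), codes[ci], int(counts[flat]))
            )
    counts_df = pd.DataFrame(
        rows, columns=["month", "age_band", "gender", "imd_quintile", "code", "count"]
    )
    return counts_df, _build_manifest(config)


# --------------------------------------------------------------------------
# primary-care mode
# --------------------------------------------------------------------------


def _sample_demographics(rng: np.random.Generator, config: ScenarioConfig, n: int,
                         at_month: pd.Period) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (year_of_birth, gender, imd) for n patients entering at a month."""
    ab_cats, ab_p = _marginal_arrays(config.demographics["age_band"])
    g_cats, g_p = _marginal_arrays(config.demographics["gender"])
    q_cats, q_p = _marginal_arrays(config.demographics["imd_quintile"])
    band_idx = rng.choice(len(ab_cats), size=n, p=ab_p)
    ages = np.empty(n, dtype=int)
    for i, cat in enumerate(ab_cats):
        sel = band_idx == i
        if not sel.any():
            continue
        label = str(cat)
        if label.endswith("+"):
            lo, hi = int(label[:-1]), int(label[:-1]) + 15
        else:
            lo, hi = (int(x) for x in label.split("-"))
        ages[sel] = rng.integers(lo, hi + 1, size=int(sel.sum()))
    yob = at_month.year - ages
    gender = np.asarray(g_cats, dtype=object)[rng.choice(len(g_cats), size=n, p=g_p)]
    imd = np.asarray(q_cats)[rng.choice(len(q_cats), size=n, p=q_p)].astype(int)
    return yob, gender, imd


def _random_day_in_month(rng: np.random.Generator, month: pd.Period, n: int) -> np.ndarray:
    start = np.datetime64(month.start_time.date(), "D")
    return start + rng.integers(0, month.days_in_month, size=n).astype("timedelta64[D]")


def generate_primary_care(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthManifest]:
    """Generate a synthetic primary-care patient and event table.

    Patients carry year of birth, gender, deprivation quintile and a
    registration interval; the initial cohort is registered well before the
    scenario start (so everyone passes the 1-year registration rule from
    month one).  Optional monthly turnover replaces a fraction of active
    patients each month; a dropout schedule removes patients without
    replacement, optionally concentrated on demographic categories via mix
    shifts (emulating selective practice attrition).

    Condition events are first-ever diagnosis codes placed so that, after
    ever-recorded ascertainment on the first of each month, the expected
    cross-sectional recorded prevalence of each condition tracks its
    configured trajectory (exactly, in a closed cohort).

    Raises
    ------
    ValueError
        If a trajectory declines anywhere while ``monthly_turnover`` is 0:
        ever-recorded prevalence is monotone within a patient, so declines
        require registration churn.
    """
    months = config.months
    n_months = len(months)
    targets = {c.name: c.targets(months) for c in config.conditions}
    for name, t in targets.items():
        if np.any(np.diff(t) < -1e-12) and config.monthly_turnover == 0:
            raise ValueError(
                f"trajectory for {name!r} declines but monthly_turnover is 0: recorded "
                "prevalence of an ever-recorded phenotype cannot fall in a closed "
                "cohort; enable registration churn to allow declines"
            )

    root = np.random.SeedSequence(config.seed)
    demo_ss, churn_ss, cond_root, days_ss = root.spawn(4)
    rng_demo = np.random.default_rng(demo_ss)
    rng_churn = np.random.default_rng(churn_ss)
    rng_days = np.random.default_rng(days_ss)
    cond_streams = cond_root.spawn(max(len(config.conditions), 1))

    start = months[0]
    n0 = config.n_patients
    yob, gender, imd = _sample_demographics(rng_demo, config, n0, start)
    first_day = np.datetime64(start.start_time.date(), "D")
    reg_start = first_day - np.timedelta64(366, "D") - rng_demo.integers(
        0, 5475, size=n0
    ).astype("timedelta64[D]")
    reg_end = np.full(n0, np.datetime64("NaT"), dtype="datetime64[D]")
    entry_idx = np.zeros(n0, dtype=int)  # first month index the patient exists in

    yob_l, gender_l, imd_l = [yob], [gender], [imd]
    reg_start_l, reg_end_l, entry_l = [reg_start], [reg_end], [entry_idx]
    n_total = n0

    def active_mask() -> np.ndarray:
        re = np.concatenate(reg_end_l)
        return np.isnat(re)

    extra_mix: list[tuple] = []
    prev_frac = 1.0
    for t, m in enumerate(months):
        if t > 0 and config.monthly_turnover > 0:
            act = np.flatnonzero(active_mask())
            n_leave = int(round(config.monthly_turnover * len(act)))
            if n_leave > 0:
                leavers = rng_churn.choice(act, size=n_leave, replace=False)
                ends = _random_day_in_month(rng_churn, m, n_leave)
                _set_end(reg_end_l, leavers, ends)
                n_new = n_leave
                ny, ng, nq = _sample_demographics(rng_demo, config, n_new, m)
                yob_l.append(ny); gender_l.append(ng); imd_l.append(nq)
                reg_start_l.append(np.full(n_new, np.datetime64(m.start_time.date(), "D")))
                reg_end_l.append(np.full(n_new, np.datetime64("NaT"), dtype="datetime64[D]"))
                entry_l.append(np.full(n_new, t, dtype=int))
                n_total += n_new
        if m in config.dropout_schedule:
            frac = config.dropout_schedule[m]
            if frac < prev_frac:
                act = np.flatnonzero(active_mask())
                target_n = int(round(frac * config.n_patients))
                n_drop = len(act) - target_n
                if n_drop > 0:
                    weights = np.ones(len(act))
                    imd_all = np.concatenate(imd_l)
                    gender_all = np.concatenate(gender_l)
                    for ms in config.mix_shifts:
                        if not ms.covers(m):
                            continue
                        if ms.variable == "imd_quintile":
                            vals = imd_all[act]
                        elif ms.variable == "gender":
                            vals = gender_all[act]
                        else:
                            continue
                        w = np.array([ms.weights.get(v, ms.weights.get(int(v), 1.0))
                                      if not isinstance(v, str) else ms.weights.get(v, 1.0)
                                      for v in vals], dtype=float)
                        weights *= w
                        extra_mix.append((ms.start, ms.end, ms.variable))
                    p = weights / weights.sum()
                    dropped = rng_churn.choice(act, size=n_drop, replace=False, p=p)
                    ends = _random_day_in_month(rng_churn, m, n_drop)
                    _set_end(reg_end_l, dropped, ends)
            prev_frac = frac

    yob = np.concatenate(yob_l)
    gender = np.concatenate(gender_l)
    imd = np.concatenate(imd_l)
    reg_start = np.concatenate(reg_start_l)
    reg_end = np.concatenate(reg_end_l)
    entry_idx = np.concatenate(entry_l)

    patient_ids = np.array([f"P{i + 1:07d}" for i in range(n_total)])

    # condition events: one first-ever code per patient per condition
    ev_pid, ev_date, ev_code = [], [], []
    for ci, cond in enumerate(config.conditions):
        rng_c = np.random.default_rng(cond_streams[ci])
        tgt = targets[cond.name]
        u = rng_c.uniform(size=n_total)
        for e in np.unique(entry_idx):
            sel = np.flatnonzero(entry_idx == e)
            runmax = np.maximum.accumulate(tgt[e:])
            # prevalent at entry: recorded historically (on/before registration)
            at_entry = u[sel] <= tgt[e]
            idx_entry = sel[at_entry]
            if len(idx_entry):
                ev_pid.append(patient_ids[idx_entry])
                ev_date.append(reg_start[idx_entry])
                ev_code.append(rng_c.choice(cond.codes, size=len(idx_entry)))
            # incident later: first month index (relative to entry) where the
            # running-max target reaches u; event dated in the preceding month
            rest = sel[~at_entry]
            if len(rest):
                pos = np.searchsorted(runmax, u[rest], side="left")
                hit = pos < len(runmax)
                onset = rest[hit]
                onset_t = pos[hit] + e  # absolute month index of first flagged month
                for tt in np.unique(onset_t):
                    grp = onset[onset_t == tt]
                    ev_pid.append(patient_ids[grp])
                    ev_date.append(_random_day_in_month(rng_days, months[tt - 1], len(grp)))
                    ev_code.append(rng_c.choice(cond.codes, size=len(grp)))

    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "year_of_birth": yob,
            "gender": gender,
            "imd_quintile": imd,
            "registration_start": pd.to_datetime(reg_start),
            "registration_end": pd.to_datetime(reg_end),
        }
    )
    if ev_pid:
        events = pd.DataFrame(
            {
                "patient_id": np.concatenate(ev_pid),
                "event_date": pd.to_datetime(np.concatenate(ev_date)),
                "code": np.concatenate(ev_code),
            }
        ).sort_values(["patient_id", "event_date"], kind="stable").reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=["patient_id", "event_date", "code"])

    seen = set()
    dedup_mix = tuple(m for m in extra_mix if not (m in seen or seen.add(m)))
    return patients, events, _build_manifest(config, dedup_mix)


def _set_end(reg_end_l: list[np.ndarray], indices: np.ndarray, ends: np.ndarray) -> None:
    """Assign registration ends to global patient indices across chunks."""
    offsets = np.cumsum([0] + [len(a) for a in reg_end_l])
    for j, idx in enumerate(indices):
        chunk = np.searchsorted(offsets, idx, side="right") - 1
        reg_end_l[chunk][idx - offsets[chunk]] = ends[j]
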