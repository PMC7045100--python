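"""Synthetic generators: determinism, planted effects, feasibility rules."""

import numpy as np
import pandas as pd
import pytest

from ehrshift import (
    Codelist,
    ConditionSpec,
    MixShiftSpec,
    ScenarioConfig,
    build_hospital_slices,
    build_primary_care_slices,
    estimate_dtm,
    generate_hospital_counts,
    generate_primary_care,
    js_divergence,
    marginalize,
)
from ehrshift.scenarios import (
    HES_DEMOGRAPHICS,
    PRIMARY_CARE_CODES,
    PRIMARY_CARE_DEMOGRAPHICS,
    hes_codelist,
    hospital_step_scenario,
    practice_dropout_scenario,
    primary_care_scenario,
)


class TestConfigValidation:
    def test_marginals_must_sum_to_one(self):
        bad = dict(PRIMARY_CARE_DEMOGRAPHICS, gender={"F": 0.6, "M": 0.5})
        with pytest.raises(ValueError, match="sums to"):
            ScenarioConfig("2001-01", "2001-12", bad, ())

    def test_start_before_end(self):
        with pytest.raises(ValueError, match="strictly before"):
            ScenarioConfig("2001-12", "2001-01", PRIMARY_CARE_DEMOGRAPHICS, ())

    def test_dropout_fractions_non_increasing(self):
        with pytest.raises(ValueError, match="non-increasing"):
            ScenarioConfig(
                "2001-01", "2002-12", PRIMARY_CARE_DEMOGRAPHICS, (),
                dropout_schedule={"2001-06": 0.5, "2002-06": 0.8},
            )

    def test_trajectory_values_must_be_probabilities(self):
        with pytest.raises(ValueError, match=r"outside \(0, 1\)"):
            ConditionSpec("x", ("X",), (("2001-01", 1.2),))

    def test_step_outside_range_rejected(self):
        cond = ConditionSpec("x", ("X",), (("2001-01", 0.1),), (("2005-01", 2.0),))
        with pytest.raises(ValueError, match="outside scenario range"):
            ScenarioConfig("2001-01", "2001-12", HES_DEMOGRAPHICS, (cond,))

    def test_post_step_targets_must_stay_in_unit_interval(self):
        cond = ConditionSpec("x", ("X",), (("2001-01", 0.6),), (("2001-06", 2.0),))
        with pytest.raises(ValueError, match=r"leave \(0, 1\)"):
            ScenarioConfig("2001-01", "2001-12", HES_DEMOGRAPHICS, (cond,))


class TestHospitalGenerator:
    def test_fixed_seed_is_byte_identical(self):
        cfg = hospital_step_scenario(seed=9, n_months=24, monthly_volume=5000,
                                     step_month_index=12)
        a, _ = generate_hospital_counts(cfg)
        b, _ = generate_hospital_counts(cfg)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_monthly_totals_equal_configured_volume(self):
        cfg = hospital_step_scenario(seed=9, n_months=12, monthly_volume=7000,
                                     step_month_index=6)
        counts, _ = generate_hospital_counts(cfg)
        assert (counts.groupby("month")["count"].sum() == 7000).all()

    def test_single_code_single_cell_takes_everything(self):
        cfg = ScenarioConfig(
            "2001-01", "2001-03",
            {"age_band": {"40-44": 1.0}, "gender": {"F": 1.0}, "imd_quintile": {1: 1.0}},
            (ConditionSpec("I21", ("I21",), (("2001-01", 0.999),)),),
            monthly_volume=1000,
        )
        counts, _ = generate_hospital_counts(cfg)
        i21 = counts[counts["code"] == "I21"]
        # share 0.999 with one demographic cell: essentially all mass there
        assert (i21.groupby("month")["count"].sum() > 980).all()
        assert set(counts["age_band"]) == {"40-44"}

    def test_shares_exceeding_one_rejected(self):
        cfg_kwargs = dict(
            demographics=HES_DEMOGRAPHICS,
            conditions=(
                ConditionSpec("A", ("A",), (("2001-01", 0.6),)),
                ConditionSpec("B", ("B",), (("2001-01", 0.5),)),
            ),
        )
        cfg = ScenarioConfig("2001-01", "2001-12", **cfg_kwargs)
        with pytest.raises(ValueError, match="shares sum to >= 1"):
            generate_hospital_counts(cfg)

    def test_planted_step_magnitude_matches_published_example(self):
        """8.0% -> 10.9% step: realized relative change ~ +36%."""
        cfg = hospital_step_scenario(seed=17)
        counts, manifest = generate_hospital_counts(cfg)
        dtm = marginalize(
            estimate_dtm(build_hospital_slices(counts, hes_codelist(), cfg.months)), "code"
        )
        j = dtm.support.index(("I21",))
        p = dtm.probabilities[:, j]
        before = p[123:135].mean()  # 12 months up to and incl. March 2012
        after = p[135:147].mean()
        rel = 100 * (after - before) / before
        assert rel == pytest.approx(36.25, abs=4)
        (step,) = manifest.planted_steps
        assert str(step[0]) == "2012-04" and step[1] == "I21"

    def test_share_swap_moves_code_marginal_not_demographics(self):
        """A swap-like step leaves the demographic mix untouched."""
        start = pd.Period("2001-01", freq="M")
        step = pd.Period("2001-07", freq="M")
        cfg = ScenarioConfig(
            "2001-01", "2001-12", HES_DEMOGRAPHICS,
            (
                ConditionSpec("A", ("A",), ((start, 0.30),), ((step, 1 / 3),)),
                ConditionSpec("B", ("B",), ((start, 0.10),), ((step, 3.0),)),
            ),
            monthly_volume=200_000,
        )
        counts, _ = generate_hospital_counts(cfg)
        cl = Codelist("ab", {"A", "B", "IXX"}, terminology="icd10-3char")
        dtm = estimate_dtm(build_hospital_slices(counts, cl, cfg.months))
        code = marginalize(dtm, "code")
        demo = marginalize(dtm, "imd_quintile")
        i, j = 5, 6  # June vs July rows
        d_code = js_divergence(code.probabilities[i], code.probabilities[j])
        d_demo = js_divergence(demo.probabilities[i], demo.probabilities[j])
        assert d_code > 100 * d_demo
        assert d_demo < 1e-4


class TestPrimaryCareGenerator:
    def test_fixed_seed_is_byte_identical(self):
        cfg = primary_care_scenario(seed=4, n_months=12, n_patients=2000)
        a_p, a_e, _ = generate_primary_care(cfg)
        b_p, b_e, _ = generate_primary_care(cfg)
        assert a_p.to_csv(index=False) == b_p.to_csv(index=False)
        assert a_e.to_csv(index=False) == b_e.to_csv(index=False)

    def test_constant_trajectories_give_flat_prevalence(self):
        cfg = ScenarioConfig(
            "2001-01", "2002-12", PRIMARY_CARE_DEMOGRAPHICS,
            (ConditionSpec("chd", PRIMARY_CARE_CODES["chd"], (("2001-01", 0.05),)),),
            n_patients=50_000, seed=8,
        )
        pats, evs, _ = generate_primary_care(cfg)
        slices = build_primary_care_slices(
            pats, evs, [Codelist("chd", frozenset(PRIMARY_CARE_CODES["chd"]))], cfg.months
        )
        marg = marginalize(estimate_dtm(slices), "chd")
        j = marg.support.index((1,))
        p = marg.probabilities[:, j]
        # flat up to binomial noise: 4 sigma band around the target
        assert np.all(np.abs(p - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 50_000))

    def test_stroke_drift_reproduces_published_relative_change(self):
        """14.4 -> 23.4 per 1000 over 84 months: +62% within +-5 points."""
        cfg = primary_care_scenario(seed=31)
        pats, evs, _ = generate_primary_care(cfg)
        cl = Codelist("stroke", frozenset(PRIMARY_CARE_CODES["stroke"]))
        slices = build_primary_care_slices(pats, evs, [cl], cfg.months)
        marg = marginalize(estimate_dtm(slices), "stroke")
        j = marg.support.index((1,))
        p = marg.probabilities[:, j]
        rel = 100 * (p[-1] - p[0]) / p[0]
        assert rel == pytest.approx(62.5, abs=5)

    def test_decline_without_churn_rejected(self):
        cfg = ScenarioConfig(
            "2001-01", "2002-12", PRIMARY_CARE_DEMOGRAPHICS,
            (ConditionSpec("chd", PRIMARY_CARE_CODES["chd"],
                           (("2001-01", 0.05), ("2002-12", 0.03)),),),
            n_patients=1000,
        )
        with pytest.raises(ValueError, match="churn"):
            generate_primary_care(cfg)

    def test_decline_feasible_with_churn(self):
        cfg = ScenarioConfig(
            "2001-01", "2004-12", PRIMARY_CARE_DEMOGRAPHICS,
            (ConditionSpec("chd", PRIMARY_CARE_CODES["chd"],
                           (("2001-01", 0.08), ("2004-12", 0.04)),),),
            n_patients=40_000, monthly_turnover=0.03, seed=12,
        )
        pats, evs, _ = generate_primary_care(cfg)
        cl = Codelist("chd", frozenset(PRIMARY_CARE_CODES["chd"]))
        slices = build_primary_care_slices(pats, evs, [cl], cfg.months)
        marg = marginalize(estimate_dtm(slices), "chd")
        j = marg.support.index((1,))
        p = marg.probabilities[:, j]
        assert p[:6].mean() > p[-6:].mean()  # prevalence genuinely fell

    def test_concentrated_dropout_shifts_deprivation_mix(self):
        """Post-dropout quintile JSD exceeds the month-to-month baseline."""
        from ehrshift import consecutive_series, pairwise_matrix

        cfg = practice_dropout_scenario(seed=14)
        pats, evs, manifest = generate_primary_care(cfg)
        cl = Codelist("chd", frozenset(PRIMARY_CARE_CODES["chd"]))
        slices = build_primary_care_slices(pats, evs, [cl], cfg.months)
        marg = marginalize(estimate_dtm(slices), "imd_quintile")
        mat = pairwise_matrix(marg, scale="divergence")
        series = consecutive_series(mat)
        mid = cfg.months[len(cfg.months) // 2]
        jump = series[series.index == mid + 1].iloc[0]
        baseline = series[series.index != mid + 1]
        assert jump > 10 * baseline.median()
        assert any(v == "imd_quintile" for *_, v in manifest.planted_mix_shifts)

    def test_monthly_denominator_tracks_cohort_size(self):
        cfg = primary_care_scenario(seed=2, n_months=12, n_patients=5000)
        pats, evs, _ = generate_primary_care(cfg)
        cl = Codelist("chd", frozenset(PRIMARY_CARE_CODES["chd"]))
        slices = build_primary_care_slices(pats, evs, [cl], cfg.months)
        # closed cohort: all patients registered >=1y before start, none leave;
        # only under-20s (July-convention) are excluded
        denoms = [s.denominator for s in slices]
        assert max(denoms) <= 5000
        assert min(denoms) > 4500


class TestManifest:
    def test_round_trips_through_json(self, tmp_path):
        cfg = hospital_step_scenario(seed=1, n_months=24, monthly_volume=1000,
                                     step_month_index=12)
        _, manifest = generate_hospital_counts(cfg)
        path = tmp_path / "manifest.json"
        manifest.to_json(path)
        from ehrshift import GroundTruthManifest
        assert GroundTruthManifest.from_json(path) == manifest
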