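"""Monthly slicing: eligibility, ascertainment boundary, age convention."""

import numpy as np
import pandas as pd
import pytest

from ehrshift import Codelist, build_hospital_slices, build_primary_care_slices, compute_age_band
from ehrshift.slicing import HOSPITAL_AGE_BANDS, age_band_labels
from ehrshift._months import month_range


def patients_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "year_of_birth", "gender", "imd_quintile",
            "registration_start", "registration_end",
        ],
    )


def events_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "event_date", "code"])


CHD = Codelist("chd", {"G30.."})


class TestAgeConvention:
    @pytest.mark.parametrize(
        "yob,month,expected",
        [
            (1941, "2001-06", "40-59"),  # age 59 before the July increment
            (1941, "2001-07", "60-79"),  # turns 60 in July
            (1980, "2001-06", "20-39"),  # age 20 through June
        ],
    )
    def test_july_increment_band_boundaries(self, yob, month, expected):
        assert compute_age_band(yob, month, (20, 40, 60, 80)) == expected

    def test_exhaustive_sweep_against_two_branch_reference(self):
        """Full 1880-2015 year-of-birth sweep x 12 months vs brute force."""
        edges = (20, 40, 60, 80)
        labels = age_band_labels(edges)
        for yob in range(1880, 2016):
            for mo in range(1, 13):
                month = pd.Period(f"2015-{mo:02d}", freq="M")
                age = (month.year - yob) if mo >= 7 else (month.year - yob - 1)
                if age < edges[0]:
                    with pytest.raises(ValueError):
                        compute_age_band(yob, month, edges)
                    continue
                expected = labels[sum(age >= e for e in edges) - 1]
                assert compute_age_band(yob, month, edges) == expected

    def test_implausible_year_of_birth_rejected(self):
        with pytest.raises(ValueError):
            compute_age_band(1850, "2001-01", (20, 40))


class TestPrimaryCareSlices:
    def test_ever_recorded_boundary_is_strictly_before_month(self):
        """A code on 2003-05-10 flags from the 2003-06 slice onward."""
        pats = patients_frame([("p1", 1950, "M", 3, "2000-01-15", None)])
        evs = events_frame([("p1", "2003-05-10", "G30..")])
        slices = build_primary_care_slices(pats, evs, [CHD], ["2003-05", "2003-06"])
        def flag(s):
            (cell,) = s.counts
            return cell[3]
        assert flag(slices[0]) == 0
        assert flag(slices[1]) == 1

    def test_one_year_registration_rule(self):
        pats = patients_frame([("p1", 1950, "F", 1, "2002-06-15", None)])
        slices = build_primary_care_slices(pats, events_frame([]), [CHD],
                                           ["2003-06", "2003-07"])
        assert slices[0].denominator == 0  # registered 365 days only on 2003-06-15
        assert slices[1].denominator == 1

    def test_mid_month_leaver_still_contributes(self):
        pats = patients_frame([("p1", 1950, "F", 1, "2000-01-01", "2003-06-20")])
        slices = build_primary_care_slices(pats, events_frame([]), [CHD],
                                           ["2003-06", "2003-07"])
        assert slices[0].denominator == 1
        assert slices[1].denominator == 0

    def test_incomplete_records_excluded(self):
        pats = patients_frame(
            [("p1", 1950, "F", 1, "2000-01-01", None),
             ("p2", 1950, None, 1, "2000-01-01", None),
             ("p3", 1950, "M", np.nan, "2000-01-01", None)]
        )
        slices = build_primary_care_slices(pats, events_frame([]), [CHD], ["2003-06"])
        assert slices[0].denominator == 1

    def test_denominators_match_brute_force_interval_scan(self):
        """Generator output vs an independent per-patient interval scan."""
        from ehrshift import generate_primary_care
        from ehrshift.scenarios import primary_care_scenario

        cfg = primary_care_scenario(seed=21, n_months=18, n_patients=3000)
        pats, evs, _ = generate_primary_care(cfg)
        slices = build_primary_care_slices(
            pats, evs, [CHD], cfg.months
        )
        reg_start = pd.to_datetime(pats["registration_start"])
        reg_end = pd.to_datetime(pats["registration_end"])
        for s in slices:
            first = pd.Timestamp(s.month.start_time)
            n = 0
            for i in range(len(pats)):
                age = first.year - pats["year_of_birth"].iloc[i] - (0 if first.month >= 7 else 1)
                if not 20 <= age <= 110:
                    continue
                if reg_start.iloc[i] > first - pd.Timedelta(days=365):
                    continue
                if pd.notna(reg_end.iloc[i]) and reg_end.iloc[i] < first:
                    continue
                n += 1
            assert s.denominator == n

    def test_conservation_and_flag_monotonicity(self):
        from ehrshift import estimate_dtm, generate_primary_care, marginalize
        from ehrshift.scenarios import primary_care_scenario, PRIMARY_CARE_CODES

        cfg = primary_care_scenario(seed=22, n_months=24, n_patients=5000)
        pats, evs, _ = generate_primary_care(cfg)
        codelists = [Codelist(n, frozenset(c)) for n, c in PRIMARY_CARE_CODES.items()]
        slices = build_primary_care_slices(pats, evs, codelists, cfg.months)
        for s in slices:
            assert sum(s.counts.values()) == s.denominator
        # closed cohort: per-condition prevalence counts never decrease
        dtm = estimate_dtm(slices)
        for cond in PRIMARY_CARE_CODES:
            marg = marginalize(dtm, cond)
            j = marg.support.index((1,))
            flagged = marg.counts[:, j]
            assert np.all(np.diff(flagged) >= 0)


class TestHospitalSlices:
    @staticmethod
    def counts_frame(rows):
        return pd.DataFrame(
            rows, columns=["month", "age_band", "gender", "imd_quintile", "code", "count"]
        )

    def test_excluded_codes_dropped_before_denominator(self):
        df = self.counts_frame(
            [("2001-01", "40-44", "F", 1, "I21", 10),
             ("2001-01", "40-44", "F", 1, "Z99", 5)]
        )
        cl = Codelist("cvd", {"I21"}, terminology="icd10-3char")
        (s,) = build_hospital_slices(df, cl, ["2001-01"])
        assert s.denominator == 10

    def test_code_share_normalization(self):
        df = self.counts_frame(
            [("2001-01", "40-44", "F", 1, "I20", 188),
             ("2001-01", "40-44", "F", 1, "I21", 812)]
        )
        cl = Codelist("cvd", {"I20", "I21"}, terminology="icd10-3char")
        from ehrshift import estimate_dtm, marginalize
        (s,) = build_hospital_slices(df, cl, ["2001-01"])
        marg = marginalize(estimate_dtm([s]), "code")
        assert dict(zip([c[0] for c in marg.support], marg.probabilities[0])) == pytest.approx(
            {"I20": 0.188, "I21": 0.812}
        )

    def test_four_character_codes_truncated(self):
        df = self.counts_frame([("2001-01", "40-44", "F", 1, "I219", 7)])
        cl = Codelist("cvd", {"I21"}, terminology="icd10-3char")
        (s,) = build_hospital_slices(df, cl, ["2001-01"])
        assert s.denominator == 7

    def test_negative_counts_rejected(self):
        df = self.counts_frame([("2001-01", "40-44", "F", 1, "I21", -1)])
        cl = Codelist("cvd", {"I21"}, terminology="icd10-3char")
        with pytest.raises(ValueError, match="negative"):
            build_hospital_slices(df, cl, ["2001-01"])

    def test_unknown_age_band_rejected(self):
        df = self.counts_frame([("2001-01", "18-25", "F", 1, "I21", 3)])
        cl = Codelist("cvd", {"I21"}, terminology="icd10-3char")
        with pytest.raises(ValueError, match="age band"):
            build_hospital_slices(df, cl, ["2001-01"])

    def test_generator_shares_within_multinomial_bounds(self):
        """Slice shares track generator targets within a 99% binomial band."""
        from ehrshift import estimate_dtm, generate_hospital_counts, marginalize
        from ehrshift.scenarios import hes_codelist, hospital_null_scenario, HES_BASE_SHARES

        cfg = hospital_null_scenario(seed=5, n_months=12)
        counts, _ = generate_hospital_counts(cfg)
        slices = build_hospital_slices(counts, hes_codelist(), cfg.months)
        marg = marginalize(estimate_dtm(slices), "code")
        n = cfg.monthly_volume
        for code, share in HES_BASE_SHARES.items():
            j = marg.support.index((code,))
            bound = 2.576 * np.sqrt(share * (1 - share) / n)
            # 12 months x 9 codes at the 1% level: allow one excursion
            excess = np.abs(marg.probabilities[:, j] - share) > bound
            assert excess.sum() <= 2


class TestCodelistValidation:
    def test_duplicate_code_across_conditions_rejected(self):
        from ehrshift.slicing import validate_codelists
        with pytest.raises(ValueError, match="appears in both"):
            validate_codelists([Codelist("a", {"X1"}), Codelist("b", {"X1"})])

    def test_unknown_terminology_rejected(self):
        with pytest.raises(ValueError, match="terminology"):
            Codelist("a", {"X1"}, terminology="snomed")

    def test_empty_codelist_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Codelist("a", set())
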