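import numpy as np
import pandas as pd
import pytest

from octtrend import (
    apply_eligibility,
    exclude_session,
    read_cohort,
    to_series,
    write_cohort,
)
from octtrend.exceptions import (
    CohortValidationError,
    EmptyCohortError,
    LookupError_,
    SchemaError,
)

from conftest import make_cohort_frame


def _write_csv(tmp_path, text, name="cohort.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCohort:
    def test_minimal_well_formed(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "eye_id,t_years,measure,sector,thickness_um\n"
            "e1,0,RNFL,G,60\n"
            "e1,0.5,RNFL,G,59\n"
            "e1,1.0,RNFL,G,58\n",
        )
        df = read_cohort(p)
        assert len(df) == 3
        assert df["eye_id"].nunique() == 1
        assert list(df["session_index"]) == [0, 1, 2]
        assert not df["session_excluded"].any()

    def test_duplicate_row_rejected(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "eye_id,t_years,measure,sector,thickness_um\n"
            "e1,0,RNFL,G,60\n"
            "e1,0,RNFL,G,61\n",
        )
        with pytest.raises(CohortValidationError, match="duplicate"):
            read_cohort(p)

    def test_nonpositive_thickness_rejected(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "eye_id,t_years,measure,sector,thickness_um\n"
            "e1,0,RNFL,G,60\ne1,0.5,RNFL,G,-5\n",
        )
        with pytest.raises(CohortValidationError, match="thickness"):
            read_cohort(p)

    def test_missing_column_names_it(self, tmp_path):
        p = _write_csv(tmp_path, "eye_id,t_years,measure,thickness_um\ne1,0,RNFL,60\n")
        with pytest.raises(SchemaError, match="sector"):
            read_cohort(p)

    def test_unknown_sector_token(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "eye_id,t_years,measure,sector,thickness_um\ne1,0,RNFL,Q,60\n",
        )
        with pytest.raises(CohortValidationError, match="sector"):
            read_cohort(p)

    def test_iso_dates_become_years_from_baseline(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "eye_id,session_date,measure,sector,thickness_um\n"
            "e1,2020-01-01,RNFL,G,60\n"
            "e1,2021-01-01,RNFL,G,59\n"
            "e1,2021-12-31,RNFL,G,58\n",
        )
        df = read_cohort(p)
        t = np.sort(df["t_years"].to_numpy())
        assert t[0] == 0.0
        assert t[1] == pytest.approx(366 / 365.25)  # 2020 is a leap year

    def test_schema_remap(self, tmp_path):
        p = _write_csv(
            tmp_path,
            "id,years,metric,region,um\nE,0,RNFL,G,60\nE,0.5,RNFL,G,59\nE,1,RNFL,G,58\n",
        )
        df = read_cohort(
            p,
            schema={
                "eye_id": "id",
                "t_years": "years",
                "measure": "metric",
                "sector": "region",
                "thickness_um": "um",
            },
        )
        assert len(df) == 3

    def test_write_read_round_trip(self, tmp_path, one_eye_cohort):
        p = tmp_path / "out.csv"
        write_cohort(one_eye_cohort, p)
        back = read_cohort(p)
        a = one_eye_cohort.sort_values(["eye_id", "session_index", "measure", "sector"]).reset_index(drop=True)
        b = back.sort_values(["eye_id", "session_index", "measure", "sector"]).reset_index(drop=True)
        assert np.allclose(a["thickness_um"], b["thickness_um"])
        assert np.allclose(a["t_years"], b["t_years"])
        assert (a["measure"] == b["measure"]).all()
        assert (a["session_excluded"] == b["session_excluded"]).all()


class TestExcludeSession:
    def test_flags_whole_session_across_measures_and_sectors(self, one_eye_cohort):
        out = exclude_session(one_eye_cohort, "eye1", 2)
        flagged = out.loc[out["session_excluded"]]
        assert len(flagged) == 14  # 2 measures x 7 sectors
        assert set(flagged["session_index"]) == {2}

    def test_idempotent(self, one_eye_cohort):
        once = exclude_session(one_eye_cohort, "eye1", 2)
        twice = exclude_session(once, "eye1", 2)
        pd.testing.assert_frame_equal(once, twice)

    def test_unknown_session_is_lookup_error(self, one_eye_cohort):
        with pytest.raises(LookupError_):
            exclude_session(one_eye_cohort, "eye1", 99)
        with pytest.raises(LookupError_):
            exclude_session(one_eye_cohort, "nope", 0)

    def test_series_shrink_by_one_per_measure_sector(self, one_eye_cohort):
        before = {s.key: len(s) for s in to_series(one_eye_cohort)}
        after = {s.key: len(s) for s in to_series(exclude_session(one_eye_cohort, "eye1", 3))}
        assert set(before) == set(after)
        assert all(after[k] == before[k] - 1 for k in before)


class TestEligibility:
    @staticmethod
    def _eye(eye_id, times):
        return [(eye_id, j, t, "RNFL", "G", 60.0) for j, t in enumerate(times)]

    def test_too_few_sessions_removed(self):
        df = make_cohort_frame(self._eye("a", [0, 3.0]) + self._eye("b", [0, 0.5, 2.0]))
        kept, summary, report = apply_eligibility(df)
        assert set(kept["eye_id"]) == {"b"}
        assert report.loc[report["eye_id"] == "a", "reason"].str.contains("sessions").all()

    def test_short_followup_removed(self):
        df = make_cohort_frame(
            self._eye("a", [0, 0.25, 0.5, 0.75, 1.0]) + self._eye("b", [0, 0.8, 1.6])
        )
        kept, summary, report = apply_eligibility(df)
        assert set(kept["eye_id"]) == {"b"}
        assert "follow-up" in report["reason"].iloc[0]

    def test_three_sessions_spanning_1p6_years_retained(self):
        df = make_cohort_frame(self._eye("a", [0, 0.8, 1.6]))
        kept, summary, _ = apply_eligibility(df)
        assert summary.n_eyes == 1
        assert summary.min_sessions == 3

    def test_excluded_sessions_do_not_count(self):
        df = make_cohort_frame(self._eye("a", [0, 0.8, 1.6]))
        df = exclude_session(df, "a", 2)
        with pytest.raises(EmptyCohortError):
            apply_eligibility(df)

    def test_monotone_in_thresholds(self, small_cohort):
        cohort, _ = small_cohort
        counts = []
        for ms, mf in [(3, 1.5), (5, 2.5), (8, 4.0), (12, 5.5)]:
            try:
                _, summary, _ = apply_eligibility(cohort, ms, mf)
                counts.append(summary.n_eyes)
            except EmptyCohortError:
                counts.append(0)
        assert counts == sorted(counts, reverse=True)

    def test_empty_cohort_is_explicit_error(self, one_eye_cohort):
        with pytest.raises(EmptyCohortError):
            apply_eligibility(one_eye_cohort, min_sessions=99)


class TestToSeries:
    def test_cardinality(self, one_eye_cohort):
        series = to_series(one_eye_cohort)
        assert len(series) == 14
        assert all(len(s) == 10 for s in series)

    def test_reanchored_after_baseline_exclusion(self, one_eye_cohort):
        out = exclude_session(one_eye_cohort, "eye1", 0)
        for s in to_series(out):
            assert s.t[0] == 0.0
            assert len(s) == 9

    def test_invariant_under_row_order(self, one_eye_cohort):
        shuffled = one_eye_cohort.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = to_series(one_eye_cohort)
        b = to_series(shuffled)
        assert [s.key for s in a] == [s.key for s in b]
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.t, sb.t)
            assert np.array_equal(sa.y, sb.y)

    def test_short_series_dropped_with_warning(self):
        rows = [("a", j, 0.5 * j, "RNFL", "G", 60.0) for j in range(3)]
        df = make_cohort_frame(rows)
        df = exclude_session(df, "a", 1)
        with pytest.warns(UserWarning, match="dropping series"):
            assert to_series(df) == []
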