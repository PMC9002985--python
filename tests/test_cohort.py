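"""Variable coding, file round-trips, validation drops and summaries."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungmediation.cohort import (CohortError, CohortTable, SchemaConfig,
                                  SilhouetteReport,
                                  code_overweight_from_silhouette,
                                  derive_exposure_category, read_cohort,
                                  summarize_cohort, write_cohort)


def report(sex, score):
    return SilhouetteReport(sex=sex, score_age8=score, score_puberty=score,
                            score_age30=score)


class TestSilhouetteCoding:
    @pytest.mark.parametrize("sex,score,expected", [
        ("male", 5, True),       # male cut-off is five
        ("female", 4, True),     # female cut-off is four
        ("male", 4, False),
        ("female", 3, False),
        ("male", 9, True),
        ("female", 1, False),
    ])
    def test_cutoffs(self, sex, score, expected):
        assert code_overweight_from_silhouette(report(sex, score), "age8") is expected

    @pytest.mark.parametrize("score", [0, 10, -3])
    def test_out_of_range_score(self, score):
        with pytest.raises(CohortError):
            code_overweight_from_silhouette(report("male", score), "puberty")

    def test_unknown_stage(self):
        with pytest.raises(CohortError):
            code_overweight_from_silhouette(report("male", 5), "age40")

    @settings(max_examples=60, deadline=None)
    @given(sex=st.sampled_from(["male", "female"]),
           lo=st.integers(1, 9), hi=st.integers(1, 9))
    def test_monotone_in_score(self, sex, lo, hi):
        """A heavier silhouette can never flip overweight back to False."""
        lo, hi = sorted((lo, hi))
        if code_overweight_from_silhouette(report(sex, lo), "age30"):
            assert code_overweight_from_silhouette(report(sex, hi), "age30")


class TestExposureCategory:
    @pytest.mark.parametrize("flags,expected", [
        ((True, False, True), "before_puberty"),   # age-8 overweight dominates
        ((False, True, False), "before_puberty"),
        ((False, False, True), "at30_not_before"),
        ((False, False, False), "never"),
    ])
    def test_cases(self, flags, expected):
        assert derive_exposure_category(*flags) == expected

    def test_exhaustive_and_exclusive(self):
        seen = set()
        for a in (False, True):
            for b in (False, True):
                for c in (False, True):
                    seen.add(derive_exposure_category(a, b, c))
        assert seen == {"before_puberty", "at30_not_before", "never"}

    @pytest.mark.parametrize("flags", [(None, False, True), (True, np.nan, False)])
    def test_missing_flag(self, flags):
        with pytest.raises(CohortError):
            derive_exposure_category(*flags)


class TestRoundTrip:
    def test_write_read_identity(self, small_cohort, tmp_path):
        table, _ = small_cohort
        path = tmp_path / "cohort.csv"
        write_cohort(table, path)
        back = read_cohort(path)
        a, b = table.df.reset_index(drop=True), back.df
        assert list(a.columns) == list(b.columns)
        for col in a.columns:
            if a[col].dtype.kind == "f":
                np.testing.assert_allclose(a[col], b[col], rtol=0, atol=1e-9)
            else:
                assert (a[col] == b[col]).all()

    def test_booleans_and_enums_on_disk(self, small_cohort, tmp_path):
        table, _ = small_cohort
        path = tmp_path / "cohort.csv"
        write_cohort(table, path)
        header, first = open(path).read().splitlines()[:2]
        assert header.startswith("offspring_id,parent_id,line,sex")
        fields = dict(zip(header.split(","), first.split(",")))
        assert fields["ever_smoker"] in ("0", "1")
        assert fields["parent_exposure"] in ("before_puberty", "at30_not_before", "never")

    def test_column_order_follows_schema(self, small_cohort, tmp_path):
        table, _ = small_cohort
        schema = SchemaConfig(columns={"fev1_ml": "FEV1"})
        path = tmp_path / "renamed.csv"
        write_cohort(table, path, schema)
        header = open(path).readline().strip().split(",")
        assert "FEV1" in header and "fev1_ml" not in header
        back = read_cohort(path, schema)
        np.testing.assert_allclose(back.df.fev1_ml, table.df.fev1_ml)


def _rows(n, **overrides):
    base = {
        "offspring_id": [f"o{i}" for i in range(n)],
        "parent_id": [f"p{i}" for i in range(n)],
        "line": "paternal", "sex": "son", "age": 30, "ever_smoker": 0,
        "m1_overweight_prepuberty": 0, "height_cm": 180.0,
        "fev1_ml": 4000.0, "fvc_ml": 5000.0,
        "fev1_post_ml": np.nan, "fvc_post_ml": np.nan,
        "parent_edu_low": 0, "parent_exposure": "never",
    }
    df = pd.DataFrame({k: [v] * n if not isinstance(v, list) else v
                       for k, v in base.items()})
    for col, vals in overrides.items():
        df[col] = vals
    return df


class TestValidation:
    def test_incomplete_rows_dropped_with_log(self, tmp_path, caplog):
        df = _rows(7, height_cm=[180.0] * 6 + [""])
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with caplog.at_level(logging.INFO):
            table = read_cohort(path)
        assert len(table) == 6
        assert any("DROPPED 1 rows" in r.getMessage() for r in caplog.records)

    def test_duplicate_offspring_id(self, tmp_path):
        df = _rows(3, offspring_id=["o1", "o1", "o2"])
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortError, match="duplicate"):
            read_cohort(path)

    def test_missing_column_and_empty_file(self, tmp_path):
        df = _rows(3).drop(columns=["height_cm"])
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortError, match="height_cm"):
            read_cohort(path)
        empty = tmp_path / "empty.csv"
        empty.write_text("offspring_id,parent_id\n")
        with pytest.raises(CohortError, match="empty"):
            read_cohort(empty)

    def test_half_post_pair_blanked(self, tmp_path):
        df = _rows(2, fev1_post_ml=["4100", ""], fvc_post_ml=["", ""])
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        table = read_cohort(path)
        assert table.df.fev1_post_ml.isna().all()

    def test_parent_in_both_lines_rejected(self, tmp_path):
        df = _rows(2, parent_id=["p1", "p1"], line=["paternal", "maternal"])
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortError, match="more than one line"):
            read_cohort(path)

    def test_silhouette_scores_coded_on_read(self, tmp_path):
        df = _rows(2).drop(columns=["parent_exposure"])
        df["parent_score_age8"] = [6, 2]   # paternal line: male cut-off 5
        df["parent_score_puberty"] = [2, 2]
        df["parent_score_age30"] = [2, 6]
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        table = read_cohort(path)
        assert list(table.df.parent_exposure) == ["before_puberty", "at30_not_before"]


class TestSummaries:
    def test_hand_computed_means(self):
        heights = [170.0, 172, 174, 176, 178, 180, 182, 184, 186, 188]
        df = _rows(10, height_cm=heights,
                   sex=["son"] * 5 + ["daughter"] * 5,
                   m1_overweight_prepuberty=[1, 0, 0, 0, 0, 1, 1, 0, 0, 0])
        summary = summarize_cohort(CohortTable(df), "paternal")
        assert summary.get("offspring", "height_mean") == pytest.approx(179.0)
        assert summary.get("offspring", "height_mean", "son") == pytest.approx(174.0)
        assert summary.get("offspring", "height_sd", "son") == pytest.approx(
            np.std(heights[:5], ddof=1))
        assert summary.get("offspring", "overweight_prepuberty_pct") == 30.0
        assert summary.get("offspring", "overweight_prepuberty_pct", "daughter") == 40.0

    def test_identical_heights_zero_sd(self):
        df = _rows(4, sex=["son", "son", "daughter", "daughter"])
        summary = summarize_cohort(CohortTable(df), "paternal")
        assert summary.get("offspring", "height_sd") == 0.0

    def test_exposure_counts_sum_to_parents(self, small_cohort):
        table, _ = small_cohort
        summary = summarize_cohort(table, "paternal")
        df = summary.df
        counts = df[(df.generation == "parent") & (df.group == "total")
                    & df.statistic.str.startswith("exposure_")]["count"]
        assert counts.sum() == summary.get("parent", "n")

    def test_missing_line_errors(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(CohortError, match="maternal"):
            summarize_cohort(table, "maternal")

    def test_prevalence_rounding_half_away(self):
        # 25/184 = 13.5869... -> 13.6 ; construct a group with that ratio
        df = _rows(184, m1_overweight_prepuberty=[1] * 25 + [0] * 159,
                   sex=["son"] * 92 + ["daughter"] * 92)
        summary = summarize_cohort(CohortTable(df), "paternal")
        assert summary.get("offspring", "overweight_prepuberty_pct") == 13.6
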