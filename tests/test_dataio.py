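"""Survey I/O, total scores, and the IQR careless-response screen."""

import math

import numpy as np
import pandas as pd
import pytest

from depclust import (
    FilterReport,
    ResponseMatrix,
    SchemaError,
    SurveySchema,
    SurveyTable,
    iqr_filter,
    read_survey,
    total_scores,
    write_survey,
)
from tests.conftest import make_matrix


def _table_from_totals(totals, ids=None):
    """One wide-range item per respondent, so totals are arbitrary."""
    totals = np.asarray(totals).reshape(-1, 1)
    return SurveyTable(
        ids=np.asarray(ids) if ids is not None else np.arange(len(totals)),
        responses=ResponseMatrix(totals, np.array([max(200, totals.max())])),
    )


class TestTotalScores:
    def test_zero_row_scores_zero(self):
        assert total_scores(make_matrix([[0] * 13]))[0] == 0

    def test_all_max_bdi13_row_scores_39(self):
        assert total_scores(make_matrix([[3] * 13], item_max=[3] * 13))[0] == 39

    def test_partial_row(self):
        row = [1, 1, 1] + [0] * 10
        assert total_scores(make_matrix([row]))[0] == 3


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path, tiny_table):
        schema = SurveySchema(correlate_cols=("sas",))
        path = tmp_path / "survey.csv"
        write_survey(tiny_table, path, schema)
        back = read_survey(path, schema)
        np.testing.assert_array_equal(back.ids, tiny_table.ids)
        np.testing.assert_array_equal(back.responses.values,
                                      tiny_table.responses.values)
        pd.testing.assert_frame_equal(back.correlates, tiny_table.correlates)

    def test_out_of_range_score_names_row_and_column(self, tmp_path):
        df = pd.DataFrame({"id": [1, 2]})
        for j in range(1, 14):
            df[f"item_{j}"] = [0, 1]
        df.loc[1, "item_5"] = 4
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match=r"row 1.*item_5"):
            read_survey(path)

    def test_missing_column_is_reported(self, tmp_path):
        df = pd.DataFrame({"id": [1], "item_1": [0]})
        path = tmp_path / "short.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="missing required columns"):
            read_survey(path)

    def test_missing_item_value_rejected(self, tmp_path):
        df = pd.DataFrame({"id": [1, 2]})
        for j in range(1, 14):
            df[f"item_{j}"] = [0, 1]
        df.loc[0, "item_2"] = np.nan
        path = tmp_path / "nan.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="missing item response"):
            read_survey(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SchemaError, match="duplicate"):
            SurveyTable(ids=np.array([1, 1]),
                        responses=make_matrix([[0] * 13, [1] * 13]))


class TestIQRFilter:
    def test_hand_computed_example_removes_the_outlier(self):
        # totals {2,3,3,4,3,100}: Q1=3, Q3=3.75 (linear interpolation),
        # fences [1.875, 4.875] -> only the 100 falls outside
        table = _table_from_totals([2, 3, 3, 4, 3, 100],
                                   ids=[10, 11, 12, 13, 14, 15])
        kept, report = iqr_filter(table, multiplier=1.5)
        assert report.n_removed == 1
        assert report.removed_ids == [15]
        assert kept.n == 5
        assert report.n_input == report.n_removed + report.n_retained

    def test_identical_totals_remove_nothing(self):
        _, report = iqr_filter(_table_from_totals([7, 7, 7, 7, 7]))
        assert report.n_removed == 0

    def test_infinite_multiplier_disables_the_screen(self):
        _, report = iqr_filter(_table_from_totals([0, 1, 2, 1000]),
                               multiplier=math.inf)
        assert report.n_removed == 0

    def test_too_few_respondents_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            iqr_filter(_table_from_totals([1, 2, 3]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_raising_multiplier_never_removes_more(self, seed):
        rng = np.random.default_rng(seed)
        table = _table_from_totals(rng.integers(0, 40, size=60))
        removed = [
            iqr_filter(table, multiplier=m)[1].n_removed
            for m in (0.5, 1.0, 1.5, 3.0, math.inf)
        ]
        assert removed == sorted(removed, reverse=True)

    def test_covariates_are_subset_together(self, tiny_table):
        table = _table_from_totals([5, 5, 5, 5, 500])
        table = SurveyTable(
            ids=table.ids,
            responses=table.responses,
            correlates=pd.DataFrame({"sas": [1.0, 2.0, 3.0, 4.0, 5.0]}),
        )
        kept, report = iqr_filter(table)
        assert report.n_removed == 1
        assert kept.correlates["sas"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_inconsistent_report_counts_rejected(self):
        with pytest.raises(ValueError, match="reconcile"):
            FilterReport(n_input=10, n_removed=2, n_retained=7,
                         lower_fence=0.0, upper_fence=1.0)
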