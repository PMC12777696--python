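"""Panel container: reading, validation, eligibility, listwise deletion, reshaping."""

import numpy as np
import pandas as pd
import pytest

from panelgvar.panel import (
    AGE_COL,
    SUBJECT_COL,
    WAVE_COL,
    CohortFilterSpec,
    PanelValidationError,
    SchemaError,
    apply_eligibility,
    from_wide,
    listwise_delete,
    read_long_csv,
    to_wide,
    write_long_csv,
)
from panelgvar.synthetic import make_ground_truth, simulate_panel

from conftest import make_toy_panel


def _write_csv(tmp_path, rows, name="panel.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


class TestReadLongCsv:
    def test_toy_roundtrip_shapes(self, tmp_path):
        rows = [
            {SUBJECT_COL: "a", WAVE_COL: w, AGE_COL: 65, "item1": v1, "item2": v2}
            for w, v1, v2 in [("2013", 0, 1), ("2015", 2, 3), ("2018", 1, 1)]
        ]
        ds = read_long_csv(_write_csv(tmp_path, rows), items=["item1", "item2"])
        assert ds.n_waves == 3 and ds.n_items == 2 and ds.n_subjects == 1
        assert float(ds.baseline_age.loc["a"]) == 65.0

    def test_out_of_range_value_names_row(self, tmp_path):
        rows = [
            {SUBJECT_COL: "a", WAVE_COL: "2013", AGE_COL: 65, "item1": 0, "item2": 1},
            {SUBJECT_COL: "a", WAVE_COL: "2015", AGE_COL: 65, "item1": 7, "item2": 1},
        ]
        with pytest.raises(PanelValidationError, match=r"\[1\]"):
            read_long_csv(_write_csv(tmp_path, rows), items=["item1", "item2"])

    def test_missing_mapped_column_is_schema_error(self, tmp_path):
        rows = [{SUBJECT_COL: "a", WAVE_COL: "2013", "item1": 0, "item2": 1}]
        with pytest.raises(SchemaError):
            read_long_csv(_write_csv(tmp_path, rows), items=["item1", "item2"])

    def test_na_and_empty_cells_read_as_missing(self, tmp_path):
        path = tmp_path / "na.csv"
        path.write_text(f"{SUBJECT_COL},{WAVE_COL},{AGE_COL},item1,item2\na,2013,65,NA,1\na,2015,65,,2\n")
        ds = read_long_csv(path, items=["item1", "item2"])
        assert ds.data["item1"].isna().all()

    def test_write_read_roundtrip(self, tmp_path):
        ds = make_toy_panel(n_subjects=7, seed=3)
        path = tmp_path / "rt.csv"
        write_long_csv(ds, path)
        back = read_long_csv(path, items=ds.items)
        a = ds.data.sort_values([SUBJECT_COL, WAVE_COL]).reset_index(drop=True)
        b = back.data.sort_values([SUBJECT_COL, WAVE_COL]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)
        # byte-stable: writing again reproduces the same file
        path2 = tmp_path / "rt2.csv"
        write_long_csv(back, path2)
        assert path.read_text() == path2.read_text()


class TestEligibility:
    def _cohort(self):
        ds = make_toy_panel(n_subjects=100, seed=1, ages=np.full(100, 70.0))
        # 10 forced-incomplete, then 5 distinct under-age subjects
        incomplete = [f"s{i:03d}" for i in range(10)]
        underage = [f"s{i:03d}" for i in range(10, 15)]
        df = ds.data.copy()
        for s in incomplete:
            idx = df[(df[SUBJECT_COL] == s) & (df[WAVE_COL] == "2015")].index[0]
            df.loc[idx, "item1"] = np.nan
        ds.data = df
        ds.baseline_age.loc[underage] = 59.0
        return ds, incomplete, underage

    def test_exclusion_counts_and_retention(self):
        ds, incomplete, underage = self._cohort()
        out, ledger = apply_eligibility(ds, CohortFilterSpec())
        assert out.n_subjects == 85
        assert ledger.counts == {"missing_wave": 0, "incomplete_scale": 10, "age": 5}
        assert ledger.n_input - ledger.n_retained == ledger.n_excluded

    def test_age_is_inclusive_at_60_and_strict_below(self):
        ds = make_toy_panel(n_subjects=3, ages=[60.0, 59.9, 75.0])
        out, ledger = apply_eligibility(ds, CohortFilterSpec())
        assert out.n_subjects == 2
        assert ledger.counts["age"] == 1

    def test_attribution_order_missing_wave_first(self):
        ds = make_toy_panel(n_subjects=2, ages=[59.0, 70.0])
        # subject s000 both under-age AND missing a wave -> attributed to missing_wave
        ds.data = ds.data[~((ds.data[SUBJECT_COL] == "s000") & (ds.data[WAVE_COL] == "2018"))].reset_index(drop=True)
        _, ledger = apply_eligibility(ds)
        assert ledger.counts == {"missing_wave": 1, "incomplete_scale": 0, "age": 0}

    def test_idempotent(self):
        ds, _, _ = self._cohort()
        once, _ = apply_eligibility(ds)
        twice, ledger2 = apply_eligibility(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert ledger2.n_excluded == 0

    def test_empty_result_warns_not_raises(self):
        ds = make_toy_panel(n_subjects=2, ages=[50.0, 55.0])
        with pytest.warns(UserWarning):
            out, _ = apply_eligibility(ds)
        assert out.n_subjects == 0


class TestListwiseDelete:
    def test_complete_data_unchanged(self):
        ds = make_toy_panel(n_subjects=6)
        out = listwise_delete(ds)
        pd.testing.assert_frame_equal(out.data, ds.data)

    def test_single_missing_cell_drops_whole_subject(self):
        ds = make_toy_panel(n_subjects=10)
        ds.data.loc[3, "item2"] = np.nan
        out = listwise_delete(ds)
        assert out.n_subjects == 9
        assert ds.data.loc[3, SUBJECT_COL] not in set(out.data[SUBJECT_COL])

    def test_mcar_fixture_matches_brute_force_scan(self):
        truth = make_ground_truth(p=10, seed=11, n_subjects=500, n_waves=4, missing_rate=0.02)
        ds = simulate_panel(truth).dataset
        out = listwise_delete(ds)
        # independent scan: count subjects with zero missing cells
        ok = ds.data.groupby(SUBJECT_COL).apply(lambda g: g[ds.items].notna().all().all(), include_groups=False)
        assert out.n_subjects == int(ok.sum())

    def test_retained_values_unaltered(self):
        ds = make_toy_panel(n_subjects=10, seed=5)
        ds.data.loc[0, "item1"] = np.nan
        out = listwise_delete(ds)
        kept = out.subjects
        orig = ds.data[ds.data[SUBJECT_COL].isin(kept)].reset_index(drop=True)
        pd.testing.assert_frame_equal(out.data, orig)


class TestToWide:
    def test_hand_case_wave_major(self):
        ds = make_toy_panel(n_subjects=1, waves=("w1", "w2"), items=("a", "b"))
        ds.data.loc[:, ["a", "b"]] = [[1, 2], [3, 0]]
        wide, labels = to_wide(ds)
        assert wide.tolist() == [[1.0, 2.0, 3.0, 0.0]]
        assert labels == ["a@w1", "b@w1", "a@w2", "b@w2"]

    def test_column_count_is_p_times_t(self):
        ds = make_toy_panel(n_subjects=4, waves=("w1", "w2", "w3"), items=("a", "b"))
        wide, labels = to_wide(ds)
        assert wide.shape == (4, 6) and len(labels) == 6

    def test_missing_cells_direct_to_listwise(self):
        ds = make_toy_panel(n_subjects=3)
        ds.data.loc[1, "item1"] = np.nan
        with pytest.raises(ValueError, match="listwise"):
            to_wide(ds)

    def test_wide_long_wide_roundtrip(self):
        ds = make_toy_panel(n_subjects=8, seed=9)
        wide, _ = to_wide(ds)
        back = from_wide(wide, ds.waves, ds.items, subjects=ds.subjects, baseline_age=ds.baseline_age)
        wide2, _ = to_wide(back)
        np.testing.assert_array_equal(wide, wide2)
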