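"""Stand panel I/O, validation, and the self-thinning filter."""

import numpy as np
import pandas as pd
import pytest

import selfthinning as st
from selfthinning.stand_data import CANONICAL_COLUMNS


def _write_csv(path, rows, columns=CANONICAL_COLUMNS):
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
    return path


WELL_FORMED = [
    ("A", 3000, 10, 2950, 40.0),
    ("A", 3000, 12, 2800, 55.0),
    ("A", 3000, 14, 2600, 75.0),
]


class TestReadStandTable:
    def test_round_trip_well_formed(self, tmp_path):
        p = _write_csv(tmp_path / "panel.csv", WELL_FORMED)
        panel = st.read_stand_table(p)
        assert panel.n_plots == 1
        assert panel.n_records == 3
        rec = panel.records[0]
        assert rec.plot_id == "A"
        assert rec.mean_volume_V == 40.0

    def test_missing_volume_column_is_format_error(self, tmp_path):
        p = _write_csv(tmp_path / "bad.csv",
                       [("A", 3000, 10, 2950)], columns=CANONICAL_COLUMNS[:-1])
        with pytest.raises(st.FormatError, match="mean_volume"):
            st.read_stand_table(p)

    def test_zero_density_is_validation_error(self, tmp_path):
        rows = list(WELL_FORMED) + [("A", 3000, 16, 0, 80.0)]
        p = _write_csv(tmp_path / "bad.csv", rows)
        with pytest.raises(st.ValidationError, match="positive"):
            st.read_stand_table(p)

    def test_dialect_maps_foreign_headers(self, tmp_path):
        cols = ["Plot", "Planted", "AGE", "N", "V"]
        p = _write_csv(tmp_path / "dialect.csv", WELL_FORMED, columns=cols)
        panel = st.read_stand_table(p, dialect={
            "plot_id": "Plot", "planting_density": "Planted", "age": "AGE",
            "density": "N", "mean_volume": "V"})
        assert panel.n_records == 3

    def test_write_read_round_trip_with_retained_flag(self, tmp_path):
        panel = st.StandPanel(pd.DataFrame(WELL_FORMED, columns=list(CANONICAL_COLUMNS)))
        out = tmp_path / "out.csv"
        st.write_stand_table(panel, out, retained={"A": True})
        df = pd.read_csv(out)
        assert df["retained"].all()
        assert st.read_stand_table(out).n_records == 3


class TestPanelInvariants:
    def test_density_above_planting_rejected(self):
        rows = [("A", 3000, 10, 3100, 40.0)]
        with pytest.raises(st.ValidationError, match="planting"):
            st.StandPanel(pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)))

    def test_ingrowth_rejected(self):
        rows = [("A", 3000, 10, 2500, 40.0), ("A", 3000, 12, 2600, 55.0)]
        with pytest.raises(st.ValidationError, match="non-increasing"):
            st.StandPanel(pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)))

    def test_duplicate_age_rejected(self):
        rows = [("A", 3000, 10, 2500, 40.0), ("A", 3000, 10, 2500, 41.0)]
        with pytest.raises(st.ValidationError, match="strictly increasing"):
            st.StandPanel(pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)))

    def test_rows_sorted_by_plot_then_age(self):
        rows = [("B", 3000, 12, 2800, 55.0), ("A", 2000, 14, 1500, 75.0),
                ("B", 3000, 10, 2950, 40.0)]
        panel = st.StandPanel(pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)))
        ages = panel.frame["age"].tolist()
        assert panel.frame["plot_id"].tolist() == ["B", "B", "A"]  # first appearance
        assert ages == [10, 12, 14]


def _two_plot_panel(mortality_a=13.3, mortality_b=0.0):
    def rows(pid, planted, frac):
        final = planted * (1 - frac / 100.0)
        return [(pid, planted, 10, planted, 40.0), (pid, planted, 14, round(final), 70.0)]

    data = rows("A", 3000, mortality_a) + rows("B", 3000, mortality_b)
    return st.StandPanel(pd.DataFrame(data, columns=list(CANONICAL_COLUMNS)))


class TestFilterSelfThinning:
    def test_mortality_above_threshold_retained_zero_excluded(self):
        panel = _two_plot_panel(13.3, 0.0)
        kept = st.filter_self_thinning(panel)
        assert kept.plot_ids == ["A"]

    def test_exact_threshold_is_excluded(self):
        panel = _two_plot_panel(13.3, 10.0)
        kept = st.filter_self_thinning(panel, 0.10)
        assert kept.plot_ids == ["A"]

    def test_fifteen_plot_panel_reduces_to_ten(self, table1_panel):
        kept = st.filter_self_thinning(table1_panel)
        assert table1_panel.n_plots == 15
        assert kept.n_plots == 10

    def test_idempotent(self, table1_panel):
        once = st.filter_self_thinning(table1_panel)
        twice = st.filter_self_thinning(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_all_filtered_out_is_error(self):
        panel = _two_plot_panel(2.0, 1.0)
        with pytest.raises(st.ValidationError, match="no self-thinning"):
            st.filter_self_thinning(panel)

    def test_threshold_zero_keeps_any_mortality(self):
        panel = _two_plot_panel(1.0, 5.0)
        assert st.filter_self_thinning(panel, 0.0).n_plots == 2

    def test_threshold_near_one_keeps_none(self, table1_panel):
        with pytest.raises(st.ValidationError):
            st.filter_self_thinning(table1_panel, 0.999)

    def test_first_density_reference(self):
        # plot measured from 2950 with min 2600: 11.9% vs planting-based 13.3%
        panel = st.StandPanel(pd.DataFrame(
            [("A", 3000, 10, 2950, 40.0), ("A", 3000, 14, 2600, 70.0)],
            columns=list(CANONICAL_COLUMNS)))
        kept = st.filter_self_thinning(panel, 0.118, reference="first")
        assert kept.n_plots == 1
        with pytest.raises(st.ValidationError):
            st.filter_self_thinning(panel, 0.120, reference="first")


class TestToLogPairs:
    def test_unit_volume_gives_zero_log(self):
        panel = st.StandPanel(pd.DataFrame(
            [("A", 3000, 10, 2500, 1.0), ("A", 3000, 12, 2400, 2.0)],
            columns=list(CANONICAL_COLUMNS)))
        ds = st.to_log_pairs(panel)
        assert ds.lnV[0] == 0.0

    def test_table1_mean_values(self):
        panel = st.StandPanel(pd.DataFrame(
            [("A", 6000, 10, 4877, 120.3), ("A", 6000, 12, 4800, 130.0)],
            columns=list(CANONICAL_COLUMNS)))
        ds = st.to_log_pairs(panel)
        assert ds.lnV[0] == pytest.approx(np.log(120.3), abs=1e-12)
        assert ds.lnV[0] == pytest.approx(4.7900, abs=1e-4)
        assert ds.lnN[0] == pytest.approx(8.4923, abs=1e-4)

    def test_plot_indices_contiguous_first_appearance(self, table1_panel):
        kept = st.filter_self_thinning(table1_panel)
        ds = st.to_log_pairs(kept)
        assert sorted(set(ds.plot_index.tolist())) == list(range(1, 11))
        assert ds.n_obs == kept.n_records
        # first appearance order preserved
        first_rows = kept.frame.groupby("plot_id", sort=False).head(1)
        assert list(ds.plot_ids) == first_rows["plot_id"].tolist()

    def test_record_count_preserved(self, table1_panel):
        ds = st.to_log_pairs(table1_panel)
        assert ds.n_obs == table1_panel.n_records

    def test_mortality_against_planting_density(self, table1_panel):
        m = table1_panel.mortality()
        assert (m >= 0).all() and (m < 1).all()
        assert (m > 0.10).sum() == 10
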