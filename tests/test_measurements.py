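import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tracheidzones as tz
from tracheidzones.measurements import COLUMNS

from conftest import make_cells


# ---------------------------------------------------------------------------
# validation and I/O

class TestCellValidation:
    def test_zero_lumen_rejected(self):
        # D = 10, CWT = 5 puts CWT/D exactly at the 1/2 geometric boundary
        with pytest.raises(tz.ValidationError, match="lumen"):
            tz.CellMeasurement("t1", 2000, 1, 1, D=10.0, CWT=5.0)

    @pytest.mark.parametrize("d,cwt", [(-1.0, 1.0), (10.0, 0.0), (0.0, 1.0)])
    def test_nonpositive_traits_rejected(self, d, cwt):
        with pytest.raises(tz.ValidationError):
            tz.CellMeasurement("t1", 2000, 1, 1, D=d, CWT=cwt)

    def test_lumen_and_ratio(self):
        c = tz.CellMeasurement("t1", 2000, 1, 1, D=30.0, CWT=3.0)
        assert c.lumen == pytest.approx(24.0)
        assert c.ratio == pytest.approx(0.1)


class TestIO:
    def test_round_trip_identity(self, tmp_path, small_ring):
        path = tmp_path / "cells.csv"
        tz.write_measurements(small_ring, path)
        back = tz.read_measurements(path)
        assert back == small_ring

    def test_tab_delimiter_round_trip(self, tmp_path, small_ring):
        path = tmp_path / "cells.tsv"
        tz.write_measurements(small_ring, path, delimiter="\t")
        assert tz.read_measurements(path, delimiter="\t") == small_ring

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("tree_id,year,row_id,rank,D_um\nt1,2000,1,1,30\n")
        with pytest.raises(tz.SchemaError, match="CWT_um"):
            tz.read_measurements(path)

    def test_invalid_record_names_offender(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(",".join(COLUMNS) + "\nt7,1999,2,1,10,5\n")
        with pytest.raises(tz.ValidationError, match="tree=t7"):
            tz.read_measurements(path)

    def test_non_consecutive_ranks_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(",".join(COLUMNS) + "\nt1,2000,1,1,30,3\nt1,2000,1,3,30,3\n")
        with pytest.raises(tz.ValidationError, match="consecutive"):
            tz.read_measurements(path)


# ---------------------------------------------------------------------------
# tracheidogram normalization

def brute_force_resample(values, target_n, grid=200_000):
    """Oracle: sample the piecewise-constant trait profile on a fine grid
    of intra-ring positions and average each output cell's slice."""
    values = np.asarray(values, dtype=float)
    pos = (np.arange(grid) + 0.5) / grid
    profile = values[np.minimum((pos * len(values)).astype(int), len(values) - 1)]
    return np.array([profile[(pos >= j / target_n) & (pos < (j + 1) / target_n)].mean()
                     for j in range(target_n)])


class TestResample:
    def test_identity_when_lengths_match(self):
        assert np.array_equal(tz.resample_profile([10, 20, 30], 3), [10, 20, 30])

    def test_constant_rows_preserved(self):
        assert np.allclose(tz.resample_profile([25.0] * 7, 4), 25.0)

    def test_compression_matches_brute_force_oracle(self):
        out = tz.resample_profile([10, 20, 30, 40], 2)
        assert np.allclose(out, [15.0, 35.0])
        assert np.allclose(out, brute_force_resample([10, 20, 30, 40], 2), atol=1e-3)

    @pytest.mark.parametrize("n,m", [(3, 7), (7, 3), (5, 8), (11, 4)])
    def test_general_resampling_matches_oracle(self, n, m):
        rng = np.random.default_rng(n * 100 + m)
        v = rng.uniform(10, 50, n)
        assert np.allclose(tz.resample_profile(v, m), brute_force_resample(v, m), atol=1e-3)

    @given(
        values=st.lists(st.floats(5, 60), min_size=1, max_size=30),
        target=st.integers(1, 40),
    )
    @settings(max_examples=100, deadline=None)
    def test_resampled_values_stay_in_input_range(self, values, target):
        out = tz.resample_profile(values, target)
        assert len(out) == target
        assert out.min() >= min(values) - 1e-9
        assert out.max() <= max(values) + 1e-9

    def test_empty_row_errors(self):
        with pytest.raises(ValueError):
            tz.resample_profile([], 3)


class TestAverageRows:
    def test_mean_of_one_row_is_identity(self):
        tg = tz.Tracheidogram("t", 2000, [10.0, 20.0], [1.0, 2.0])
        out = tz.average_rows([tg])
        assert np.array_equal(out.D_seq, [10, 20])

    def test_positionwise_mean(self):
        a = tz.Tracheidogram("t", 2000, [10.0, 20.0], [1.0, 2.0])
        b = tz.Tracheidogram("t", 2000, [30.0, 40.0], [3.0, 4.0])
        out = tz.average_rows([a, b])
        assert np.allclose(out.D_seq, [20, 30])
        assert np.allclose(out.CWT_seq, [2, 3])

    def test_five_random_rows(self):
        rng = np.random.default_rng(0)
        rows = [
            tz.Tracheidogram("t", 2000, d, d * 0.1)
            for d in rng.uniform(20, 50, size=(5, 6))
        ]
        out = tz.average_rows(rows)
        assert np.allclose(out.D_seq, np.mean([r.D_seq for r in rows], axis=0), atol=1e-12)

    def test_mismatched_lengths_error(self):
        a = tz.Tracheidogram("t", 2000, [10.0, 20.0], [1.0, 2.0])
        b = tz.Tracheidogram("t", 2000, [10.0], [1.0])
        with pytest.raises(ValueError, match="lengths"):
            tz.average_rows([a, b])


def test_build_tracheidograms_normalizes_to_mean_row_length():
    # two rows of lengths 4 and 5 -> mean 4.5 rounds half-up to 5
    cells = make_cells(row=1, d_seq=(40, 35, 30, 25)) + make_cells(
        row=2, d_seq=(42, 38, 33, 27, 22)
    )
    (tg,) = tz.build_tracheidograms(cells)
    assert tg.n_cells == 5


# ---------------------------------------------------------------------------
# standardization and slope angles

class TestStandardize:
    def test_index_means_are_one(self, small_ring):
        df, summary = tz.standardize(small_ring)
        assert df["D_i"].mean() == pytest.approx(1.0, abs=1e-9)
        assert df["CWT_i"].mean() == pytest.approx(1.0, abs=1e-9)
        assert summary.n_cells_raw == len(small_ring)

    def test_cell_at_both_means_has_phi_45(self):
        cells = make_cells(d_seq=(20, 30, 40), cwt_seq=(2, 3, 4))
        df, _ = tz.standardize(cells)
        assert df.loc[df["D"] == 30, "phi_i"].iloc[0] == pytest.approx(45.0)

    def test_scale_equivariance(self, small_ring):
        df1, _ = tz.standardize(small_ring)
        scaled = [
            tz.CellMeasurement(c.tree_id, c.year, c.row_id, c.rank, c.D * 3.7, c.CWT)
            for c in small_ring
        ]
        df2, _ = tz.standardize(scaled)
        assert np.allclose(df1["D_i"], df2["D_i"])

    def test_summary_min_le_mean_le_max(self, small_ring):
        _, summary = tz.standardize(small_ring)
        t = summary.traits
        assert (t["min"] <= t["mean"] + 1e-12).all()
        assert (t["mean"] <= t["max"] + 1e-12).all()


class TestSlopeAngle:
    def test_unit_ratio_is_45_degrees(self):
        assert tz.compute_slope_angle(1.0) == pytest.approx(45.0)

    def test_mork_ratio_angle(self):
        # arctan(0.167) from an independent tables value
        assert tz.compute_slope_angle(0.167) == pytest.approx(9.48, abs=0.01)

    def test_strictly_increasing(self):
        rng = np.random.default_rng(1)
        r = np.sort(rng.uniform(0.01, 5.0, 1000))
        phi = tz.compute_slope_angle(r)
        assert np.all(np.diff(phi) > 0)

    def test_nonpositive_ratio_errors(self):
        with pytest.raises(ValueError):
            tz.compute_slope_angle(0.0)


# ---------------------------------------------------------------------------
# histograms

class TestBinHistogram:
    def test_left_closed_right_open_labels(self):
        h = tz.bin_histogram([0.05, 0.059], width=0.01)
        assert h.counts.sum() == 2
        assert h.lower_edges[np.argmax(h.counts)] == pytest.approx(0.05)
        assert len(h.lower_edges) == 1

    def test_counts_conserved_and_densities_sum_to_one(self):
        rng = np.random.default_rng(2)
        v = rng.normal(45, 10, 977)
        h = tz.bin_histogram(v, width=1.5)
        assert h.n == 977
        assert h.densities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_exact_edge_falls_in_own_bin(self):
        h = tz.bin_histogram([1.5], width=1.5)
        assert h.lower_edges[0] == pytest.approx(1.5)
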