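"""Time-series assembly, readout selection, calibration and titer math."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titervision import (
    CalibrationFit,
    FrameAreas,
    build_timeseries,
    cells_from_confluence,
    fit_confluence_calibration,
    infectious_titer,
    normalized_positive_area,
    plate_titer,
    select_readout,
    viable_positive_percent,
)
from titervision.plate_io import PlateLayout, WellInfo

from oracles import normal_equation_ols


def areas(a_c, a_g=None, a_d=None, a_pd=None, field=1.0e5):
    return FrameAreas(a_c_um2=a_c, a_ff488_um2=a_g, a_d_um2=a_d, a_pd_um2=a_pd,
                      field_area_um2=field)


class TestPositivePercentages:
    def test_normalized_positive_area_forced_arithmetic(self):
        assert normalized_positive_area(0.0, 120.0) == 0.0
        assert normalized_positive_area(120.0, 120.0) == 100.0
        assert normalized_positive_area(6.0e4, 1.2e5) == pytest.approx(50.0)

    def test_viable_positive_forced_arithmetic(self):
        assert viable_positive_percent(30, 10, 100, 20) == pytest.approx(25.0)
        assert viable_positive_percent(30, 30, 100, 20) == 0.0

    def test_error_conditions(self):
        with pytest.raises(ValueError):
            normalized_positive_area(1.0, 0.0)
        with pytest.raises(ValueError):
            viable_positive_percent(10, 20, 100, 0)   # A_PD > A_FF488
        with pytest.raises(ValueError):
            viable_positive_percent(10, 0, 50, 50)    # no viable area

    @settings(max_examples=200, derandomize=True)
    @given(
        a_g=st.floats(0, 1e5),
        a_c=st.floats(1e-3, 1e6),
    )
    def test_viable_equals_all_cells_without_death(self, a_g, a_c):
        """With no dead area the viable-cell form reduces to the all-cell form."""
        assert viable_positive_percent(a_g, 0.0, a_c, 0.0) == pytest.approx(
            normalized_positive_area(a_g, a_c)
        )


class TestSelectReadout:
    def test_strictly_increasing_curve_selects_the_last_timepoint(self):
        t, v = select_readout([0, 2, 4, 6], [1, 2, 3, 4])
        assert (t, v) == (6.0, 4.0)

    def test_peak_before_decline(self):
        t, v = select_readout([26, 40, 66, 90, 98], [0, 10, 40, 38, 30])
        assert (t, v) == (66.0, 40.0)

    def test_ties_break_to_the_earliest_time(self):
        t, _ = select_readout([10, 20, 30], [5, 7, 7])
        assert t == 20.0

    def test_window_restricts_the_search_and_may_be_empty(self):
        t, v = select_readout([10, 20, 30], [9, 1, 2], window=(15, None))
        assert (t, v) == (30.0, 2.0)
        with pytest.raises(ValueError):
            select_readout([10, 20], [1, 2], window=(50, None))

    def test_constant_shift_does_not_move_the_readout_time(self, rng):
        times = np.arange(10.0)
        vals = rng.random(10)
        t1, _ = select_readout(times, vals)
        t2, _ = select_readout(times, vals + 123.4)
        assert t1 == t2


class TestCalibration:
    def test_noiseless_line_recovered_exactly(self):
        counts = np.array([2200, 10000, 20000, 40000, 53400], dtype=float)
        conf = 0.002 * counts + 1.0
        fit = fit_confluence_calibration(counts, conf)
        assert fit.m == pytest.approx(0.002)
        assert fit.b == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_points_match_the_normal_equations_oracle(self):
        counts = [1000.0, 2000.0, 3000.0]
        conf = [3.0, 5.0, 7.6]
        fit = fit_confluence_calibration(counts, conf)
        slope, intercept, r2 = normal_equation_ols(counts, conf)
        assert fit.m == pytest.approx(slope)
        assert fit.b == pytest.approx(intercept)
        assert fit.r_squared == pytest.approx(r2)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            fit_confluence_calibration([1000, 2000], [2, 3])
        with pytest.raises(ValueError):
            fit_confluence_calibration([1000, 1000, 1000], [2, 3, 4])
        with pytest.raises(ValueError):
            fit_confluence_calibration([1000, 2000, 3000], [5, 5, 5])

    def test_inversion_identity_and_clipping(self):
        fit = CalibrationFit(m=1.0, b=0.0, r_squared=1.0, n_points=5)
        assert cells_from_confluence(37.5, fit) == pytest.approx(37.5)
        fit2 = CalibrationFit(m=0.002, b=1.0, r_squared=1.0, n_points=5)
        assert cells_from_confluence(1.0, fit2) == 0.0
        with pytest.warns(UserWarning):
            assert cells_from_confluence(0.5, fit2) == 0.0
        with pytest.raises(ValueError):
            cells_from_confluence(10.0, CalibrationFit(m=-1, b=0, r_squared=1, n_points=3))

    @settings(max_examples=200, derandomize=True)
    @given(
        n=st.floats(0, 1e6),
        m=st.floats(1e-6, 1e2),
        b=st.floats(-50, 50),
    )
    def test_calibration_round_trip(self, n, m, b):
        """cells_from_confluence(m*N + b) recovers N for any N >= 0."""
        fit = CalibrationFit(m=m, b=b, r_squared=1.0, n_points=3)
        assert cells_from_confluence(m * n + b, fit) == pytest.approx(n, rel=1e-9, abs=1e-6)


class TestInfectiousTiter:
    def test_forced_arithmetic(self):
        assert infectious_titer(0, 1e4, 2, 0.1) == 0.0
        assert infectious_titer(100, 1e4, 1, 0.1) == pytest.approx(1e5)
        assert infectious_titer(50, 6000, 625, 0.05) == pytest.approx(3.75e7)

    def test_invalid_arguments(self):
        for bad in [(-1, 1, 1, 1), (1, -1, 1, 1), (1, 1, 0.5, 1), (1, 1, 1, 0)]:
            with pytest.raises(ValueError):
                infectious_titer(*bad)

    @settings(max_examples=200, derandomize=True)
    @given(
        p=st.floats(0.01, 200), n=st.floats(1, 1e6), d=st.floats(1, 2048),
        v=st.floats(1e-3, 1.0), c=st.floats(0.1, 10),
    )
    def test_homogeneity_in_each_argument(self, p, n, d, v, c):
        """Titer is degree-1 homogeneous in P, N, D and degree -1 in V."""
        base = infectious_titer(p, n, d, v)
        assert infectious_titer(c * p, n, d, v) == pytest.approx(c * base, rel=1e-9)
        assert infectious_titer(p, c * n, d, v) == pytest.approx(c * base, rel=1e-9)
        if c * d >= 1:
            assert infectious_titer(p, n, c * d, v) == pytest.approx(c * base, rel=1e-9)
        assert infectious_titer(p, n, d, c * v) == pytest.approx(base / c, rel=1e-9)


class TestBuildTimeseries:
    def test_no_death_means_full_viability(self):
        by_t = {t: areas(100, a_g=20, a_d=0.0, a_pd=0.0) for t in (48.0, 50.0)}
        s = build_timeseries(by_t, "B2")
        assert np.allclose(s.viability, 100.0)
        assert np.allclose(s.p2, s.p3)

    def test_single_timepoint_series(self):
        s = build_timeseries({48.0: areas(100, a_g=50)}, "B2")
        assert len(s.times_h) == 1 and s.p2[0] == pytest.approx(50.0)

    def test_zero_confluence_timepoint_is_flagged_not_dropped(self):
        s = build_timeseries({48.0: areas(0.0), 50.0: areas(100, a_g=10)}, "B2")
        assert s.flags[48.0] == "zero_confluence"
        assert len(s.times_h) == 2 and np.isnan(s.p2[0])

    def test_missing_red_channel_gives_nan_viability_not_zero(self):
        s = build_timeseries({48.0: areas(100, a_g=10)}, "B2")
        assert np.isnan(s.viability[0]) and np.isnan(s.p3[0])


def _layout_three_replicates():
    layout = PlateLayout()
    layout.add(WellInfo(well="A1", role="matrix_control", sample_id="matrix",
                        dilution_factor=1.0, volume_ml=0.05))
    for w in ("B2", "C2", "D2"):
        layout.add(WellInfo(well=w, role="sample", sample_id="LV",
                            dilution_factor=64.0, volume_ml=0.05))
    return layout


class TestPlateTiter:
    def _series(self, peak_pct=40.0, a_d=None):
        # 1e5 um^2 field; 10% confluence at transduction, 50% at readout
        pd = 0.0 if a_d is not None else None
        return {
            24.0: areas(1.0e4, a_g=None, a_d=a_d, a_pd=pd),
            66.0: areas(5.0e4, a_g=5.0e4 * peak_pct / 100, a_d=a_d, a_pd=pd),
            90.0: areas(5.0e4, a_g=5.0e4 * peak_pct / 200, a_d=a_d, a_pd=pd),
        }

    def test_identical_replicates_have_zero_sd(self):
        layout = _layout_three_replicates()
        fit = CalibrationFit(m=0.001, b=0.0, r_squared=1.0, n_points=5)
        series = {w: build_timeseries(self._series(), w) for w in ("B2", "C2", "D2")}
        _, samples = plate_titer(series, layout, fit, window=(48, None))
        (s,) = samples
        assert s.n_wells_used == 3 and s.sd == 0.0
        # P=40, N=(10-0)/0.001=1e4, D=64, V=0.05 -> 40*1e4*64/(0.05*100)
        assert s.titer_tu_per_ml == pytest.approx(40 * 1e4 * 64 / (0.05 * 100))

    def test_viable_mode_equals_all_cells_mode_without_death(self):
        layout = _layout_three_replicates()
        fit = CalibrationFit(m=0.001, b=0.0, r_squared=1.0, n_points=5)
        series = {w: build_timeseries(self._series(a_d=0.0), w) for w in ("B2", "C2", "D2")}
        _, all_cells = plate_titer(series, layout, fit, mode="all_cells", window=(48, None))
        _, viable = plate_titer(series, layout, fit, mode="viable_cells", window=(48, None))
        assert all_cells[0].titer_tu_per_ml == pytest.approx(viable[0].titer_tu_per_ml)

    def test_out_of_range_wells_are_flagged_not_averaged(self):
        from titervision import LinearRangeResult

        layout = _layout_three_replicates()
        fit = CalibrationFit(m=0.001, b=0.0, r_squared=1.0, n_points=5)
        series = {w: build_timeseries(self._series(), w) for w in ("B2", "C2", "D2")}
        lr = LinearRangeResult(
            dilution_lo=2, dilution_hi=8, r_squared_linear=1.0, r_squared_log=1.0,
            llod_percent=50.0, ulod_percent=90.0,
        )
        wells, samples = plate_titer(series, layout, fit, window=(48, None), linear_range=lr)
        assert all(not w.in_range and w.flag == "below_llod" for w in wells)
        assert samples[0].flag == "out_of_range" and samples[0].n_wells_used == 0
        assert np.isnan(samples[0].titer_tu_per_ml)
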