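"""Analysis windows and AUC-based closure/death metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woundscore import (
    AnalysisConfig,
    closure_death_metrics,
    endpoint_time,
    time_to_rwd,
    trapezoid_auc,
)
from woundscore.errors import DegenerateControlError, StratumError, WindowError

from conftest import GRID_72H, make_well


class TestTrapezoidAuc:
    @pytest.mark.parametrize(
        "times,values,t_end,expected",
        [
            ([0, 1, 2], [0, 1, 2], 2.0, 2.0),  # triangle
            (GRID_72H, np.ones(37), 72.0, 72.0),  # rectangle
            ([0, 2, 4], [0, 1, 0], 3.0, 1.75),  # interpolated endpoint
        ],
    )
    def test_known_integrals(self, times, values, t_end, expected):
        assert trapezoid_auc(np.asarray(times, float), np.asarray(values, float), t_end) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("t_end", [0.0, -1.0, 4.5])
    def test_window_outside_range(self, t_end):
        with pytest.raises(WindowError):
            trapezoid_auc(np.array([0.0, 2.0, 4.0]), np.zeros(3), t_end)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=3, max_size=12),
        st.floats(0.01, 0.99),
    )
    def test_exact_on_piecewise_linear(self, values, frac):
        """Trapezoid equals the closed-form integral of the sampled polyline."""
        times = np.arange(len(values), dtype=float)
        t_end = times[0] + frac * (times[-1] - times[0])
        dense = np.linspace(times[0], t_end, 40001)
        oracle = np.trapezoid(np.interp(dense, times, values), dense)
        assert trapezoid_auc(times, np.asarray(values), t_end) == pytest.approx(oracle, abs=1e-6)


class TestTimeToRwd:
    def test_exact_sample_hit(self):
        w = make_well([0, 0.25, 0.5, 0.75], times=[0.0, 2.0, 4.0, 6.0])
        assert time_to_rwd(w, 0.5) == 4.0

    def test_interpolated_crossing(self):
        w = make_well([0, 0.4, 0.8], times=[0.0, 2.0, 4.0])
        assert time_to_rwd(w, 0.5) == pytest.approx(2.5)

    def test_unreachable_plateau(self):
        w = make_well([0, 0.2, 0.3, 0.3, 0.3])
        assert time_to_rwd(w, 0.5) is None


class TestEndpointTime:
    def test_method_a_is_fixed_endpoint(self, simple_stratum, config):
        cfg = AnalysisConfig(endpoint_method="A")
        t = endpoint_time(simple_stratum, cfg, simple_stratum[1].condition)
        assert t == 72.0

    def test_method_b_linear_ramp(self):
        """Control closing at 1/24 per hour: the smoothed slope first dips
        below 0.02/h one sample after full closure at 24 h."""
        rwd = np.minimum(GRID_72H / 24.0, 1.0)
        ctrl = make_well(rwd, times=GRID_72H)
        cfg = AnalysisConfig(endpoint_method="B")
        assert endpoint_time([ctrl], cfg, ctrl.condition) == 26.0

    def test_method_b_requires_control(self):
        treated = make_well(np.minimum(GRID_72H / 24.0, 1.0), times=GRID_72H, drug="DRUG-X", conc=1.0)
        cfg = AnalysisConfig(endpoint_method="B")
        with pytest.raises(StratumError):
            endpoint_time([treated], cfg, treated.condition)

    def test_method_b_shared_across_stratum(self, simple_stratum):
        cfg = AnalysisConfig(endpoint_method="B")
        times = {endpoint_time(simple_stratum, cfg, w.condition) for w in simple_stratum}
        assert len(times) == 1

    def test_method_c_exponential_half_closure(self):
        rwd = 1.0 - np.exp(-0.1 * GRID_72H)
        w = make_well(rwd, times=GRID_72H)
        cfg = AnalysisConfig(endpoint_method="C")
        t = endpoint_time([w], cfg, w.condition)
        assert t == pytest.approx(np.log(2) / 0.1, abs=0.1)  # 2-h grid interpolation

    def test_method_c_falls_back_to_last_time(self):
        rwd = np.full(37, 0.3)
        rwd[0] = 0.0
        w = make_well(rwd, times=GRID_72H)
        cfg = AnalysisConfig(endpoint_method="C")
        assert endpoint_time([w], cfg, w.condition) == 72.0


class TestClosureDeathMetrics:
    def test_no_effect_gives_zero_wc(self, config):
        ctrl = make_well(np.minimum(GRID_72H / 36.0, 1.0), times=GRID_72H)
        same = make_well(
            np.minimum(GRID_72H / 36.0, 1.0), times=GRID_72H, drug="DRUG-X", conc=1.0
        )
        mets = closure_death_metrics([ctrl, same], AnalysisConfig(endpoint_method="A"))
        treated = next(m for m in mets if not m.condition.is_control)
        assert treated.wc == pytest.approx(0.0, abs=1e-12)
        assert treated.wc_ind == pytest.approx(1.0, abs=1e-12)

    def test_full_block_gives_wc_one(self):
        ctrl = make_well(np.minimum(GRID_72H / 36.0, 1.0), times=GRID_72H)
        blocked = make_well(np.zeros(37), times=GRID_72H, drug="DRUG-X", conc=1.0)
        mets = closure_death_metrics([ctrl, blocked], AnalysisConfig(endpoint_method="A"))
        treated = next(m for m in mets if not m.condition.is_control)
        assert treated.wc == pytest.approx(1.0)
        assert treated.wc_ind == pytest.approx(0.0)

    def test_death_change_formula(self):
        """AUC(D): control 10, treated 30, stratum max 40 -> DC = 0.5."""
        ramp = np.minimum(GRID_72H / 36.0, 1.0)
        ctrl = make_well(ramp, times=GRID_72H, caspase=np.full(37, 10.0 / 72.0))
        t1 = make_well(ramp * 0.9, times=GRID_72H, caspase=np.full(37, 30.0 / 72.0), drug="D", conc=1.0)
        t2 = make_well(ramp * 0.8, times=GRID_72H, caspase=np.full(37, 40.0 / 72.0), drug="D", conc=2.0)
        mets = closure_death_metrics([ctrl, t1, t2], AnalysisConfig(endpoint_method="A"))
        assert mets[1].dc == pytest.approx((30.0 - 10.0) / 40.0)

    def test_control_scores_zero(self, simple_stratum, config):
        mets = closure_death_metrics(simple_stratum, config)
        ctrl = next(m for m in mets if m.condition.is_control)
        assert ctrl.wc == 0.0 and ctrl.dc == 0.0 and ctrl.wc_ind == 1.0

    def test_wc_and_wc_ind_complementary(self, mixed_screen, config):
        from woundscore import aggregate_replicates

        for wells in aggregate_replicates(mixed_screen).strata().values():
            for m in closure_death_metrics(wells, config):
                assert m.wc + m.wc_ind == pytest.approx(1.0, abs=1e-12)

    def test_negative_dc_clamped_raw_kept(self):
        ramp = np.minimum(GRID_72H / 36.0, 1.0)
        ctrl = make_well(ramp, times=GRID_72H, caspase=np.full(37, 2.0))
        quieter = make_well(ramp, times=GRID_72H, caspase=np.full(37, 1.0), drug="D", conc=1.0)
        mets = closure_death_metrics([ctrl, quieter], AnalysisConfig(endpoint_method="A"))
        treated = next(m for m in mets if not m.condition.is_control)
        assert treated.dc == 0.0
        assert treated.dc_raw < 0.0

    def test_degenerate_control_raises(self):
        ctrl = make_well(np.zeros(37), times=GRID_72H)
        treated = make_well(np.zeros(37), times=GRID_72H, drug="D", conc=1.0)
        with pytest.raises(DegenerateControlError):
            closure_death_metrics([ctrl, treated], AnalysisConfig(endpoint_method="A"))

    def test_zero_death_normalizer_warns(self):
        ramp = np.minimum(GRID_72H / 36.0, 1.0)
        ctrl = make_well(ramp, times=GRID_72H, caspase=np.zeros(37))
        treated = make_well(ramp * 0.5, times=GRID_72H, caspase=np.zeros(37), drug="D", conc=1.0)
        with pytest.warns(UserWarning, match="normalizer"):
            mets = closure_death_metrics([ctrl, treated], AnalysisConfig(endpoint_method="A"))
        assert all(m.dc == 0.0 for m in mets)

    def test_method_c_time_averages_unequal_windows(self):
        """Two conditions with identical per-hour mean RWD but different
        50%-closure times score wc = 0 under method C."""
        fast = 1.0 - np.exp(-0.1 * GRID_72H)
        slow = 1.0 - np.exp(-0.05 * GRID_72H)
        ctrl = make_well(fast, times=GRID_72H)
        treated = make_well(slow, times=GRID_72H, drug="D", conc=1.0)
        mets = closure_death_metrics([ctrl, treated], AnalysisConfig(endpoint_method="C"))
        treated_m = next(m for m in mets if not m.condition.is_control)
        ctrl_m = next(m for m in mets if m.condition.is_control)
        # windows differ roughly two-fold, but time-averaged closure over
        # [0, t50] is similar for self-similar exponentials
        assert treated_m.window_end > 1.5 * ctrl_m.window_end
        assert abs(treated_m.wc) < 0.1

    def test_wc_antitone_in_treated_auc(self):
        ramp = np.minimum(GRID_72H / 36.0, 1.0)
        ctrl = make_well(ramp, times=GRID_72H)
        wells = [ctrl] + [
            make_well(ramp * s, times=GRID_72H, drug="D", conc=c)
            for s, c in [(0.9, 1.0), (0.6, 2.0), (0.3, 4.0)]
        ]
        mets = closure_death_metrics(wells, AnalysisConfig(endpoint_method="A"))
        wc = [m.wc for m in mets if not m.condition.is_control]
        assert wc == sorted(wc)
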