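"""Healthy-interval, occupancy, ratio and fold-change tests against oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ibdsim import (
    ImmuneState,
    Trajectory,
    fold_change,
    healthy_interval,
    intervals_from_states,
    occupancy,
    ratio_report,
)


def make_traj(times, **columns) -> Trajectory:
    names = tuple(columns)
    states = np.column_stack([np.asarray(columns[n], dtype=float) for n in names])
    return Trajectory(np.asarray(times, dtype=float), states, names)


class TestHealthyInterval:
    @pytest.mark.parametrize(
        "patient, healthy, lower, upper",
        [
            (4.0, 2.0, 1.0, 3.0),
            (1.0, 3.0, 2.0, 4.0),
            (2.0, 2.0, 2.0, 2.0),
        ],
    )
    def test_worked_examples(self, patient, healthy, lower, upper):
        iv = healthy_interval(patient, healthy)
        assert iv.lower == pytest.approx(lower)
        assert iv.upper == pytest.approx(upper)

    def test_negative_levels_rejected(self):
        with pytest.raises(ValueError):
            healthy_interval(-1.0, 2.0)

    @given(healthy=st.floats(0.1, 100), gap=st.floats(0, 50))
    def test_symmetric_in_patient_side(self, healthy, gap):
        """Swapping which side of healthy the patient sits on moves the
        interval but preserves its width and centre."""
        above = healthy_interval(healthy + gap, healthy)
        below = healthy_interval(max(healthy - gap, 0.0), healthy)
        if healthy - gap >= 0:
            assert above.width == pytest.approx(below.width, abs=1e-9)
        assert above.lower + above.upper == pytest.approx(2 * healthy, rel=1e-12)


class TestOccupancy:
    times = np.linspace(0.0, 50.0, 5001)

    def interval(self, patient=4.0, healthy=2.0):
        return {"X": healthy_interval(patient, healthy, "X")}

    def test_always_inside_is_100(self):
        traj = make_traj(self.times, X=np.full_like(self.times, 2.5))
        rep = occupancy(traj, self.interval(), (14.0, 50.0))
        assert rep.occupancy["X"] == 100.0

    def test_always_outside_is_0(self):
        traj = make_traj(self.times, X=np.full_like(self.times, 5.0))
        rep = occupancy(traj, self.interval(), (14.0, 50.0))
        assert rep.occupancy["X"] == 0.0

    def test_zero_width_interval_at_healthy_level_scores_100(self):
        traj = make_traj(self.times, X=np.full_like(self.times, 2.0))
        rep = occupancy(traj, self.interval(patient=2.0), (14.0, 50.0))
        assert rep.occupancy["X"] == 100.0

    def test_square_wave_matches_grid_count_oracle(self):
        # in-band on [14, 32), out on [32, 50]: half the window up to grid quantization
        x = np.where(self.times < 32.0, 2.5, 10.0)
        traj = make_traj(self.times, X=x)
        rep = occupancy(traj, self.interval(), (14.0, 50.0))
        mask = (self.times >= 14.0) & (self.times <= 50.0)
        oracle = 100.0 * np.mean((x[mask] >= 1.0) & (x[mask] <= 3.0))
        assert rep.occupancy["X"] == pytest.approx(oracle, abs=1e-12)
        grid_step_pct = 100.0 * 0.01 / 36.0
        assert abs(rep.occupancy["X"] - 50.0) <= grid_step_pct

    def test_window_outside_span_rejected(self):
        traj = make_traj(self.times, X=np.full_like(self.times, 2.0))
        with pytest.raises(ValueError, match="window"):
            occupancy(traj, self.interval(), (14.0, 60.0))

    def test_bounds_are_closed(self):
        x = np.full_like(self.times, 3.0)  # exactly on the upper bound
        traj = make_traj(self.times, X=x)
        rep = occupancy(traj, self.interval(), (14.0, 50.0))
        assert rep.occupancy["X"] == 100.0


class TestRatioReport:
    times = np.linspace(0.0, 50.0, 5001)

    def healthy(self, **kw):
        d = {"P": 2.0, "A": 1.0}
        d.update(kw)
        return ImmuneState.from_dict(tuple(d), d)

    def test_identity_percent_change_is_zero(self):
        traj = make_traj(self.times, P=np.full_like(self.times, 2.0),
                         A=np.full_like(self.times, 1.0))
        rep = ratio_report(traj, self.healthy(), [("P", "A")], (14.0, 50.0))
        p = rep.pair("P", "A")
        assert p.pct_change_min == pytest.approx(0.0, abs=1e-9)
        assert p.pct_change_max == pytest.approx(0.0, abs=1e-9)

    def test_doubled_pro_is_plus_100_percent(self):
        traj = make_traj(self.times, P=np.full_like(self.times, 4.0),
                         A=np.full_like(self.times, 1.0))
        rep = ratio_report(traj, self.healthy(), [("P", "A")], (14.0, 50.0))
        assert rep.pair("P", "A").pct_change_max == pytest.approx(100.0)

    def test_min_max_match_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        P = 1.0 + rng.random(self.times.size)
        A = 0.5 + rng.random(self.times.size)
        traj = make_traj(self.times, P=P, A=A)
        rep = ratio_report(traj, self.healthy(), [("P", "A")], (14.0, 50.0))
        mask = (self.times >= 14.0) & (self.times <= 50.0)
        r = P[mask] / A[mask]
        assert rep.pair("P", "A").ratio_min == pytest.approx(r.min())
        assert rep.pair("P", "A").ratio_max == pytest.approx(r.max())

    def test_zero_anti_is_flagged_gap_not_infinity(self):
        A = np.full_like(self.times, 1.0)
        A[self.times > 30.0] = 0.0
        traj = make_traj(self.times, P=np.full_like(self.times, 2.0), A=A)
        rep = ratio_report(traj, self.healthy(), [("P", "A")], (14.0, 50.0))
        p = rep.pair("P", "A")
        assert p.flagged
        assert np.isfinite(p.ratio_max)


class TestFoldChange:
    def test_identity(self, healthy_ss):
        fc = fold_change(healthy_ss, healthy_ss)
        assert np.allclose(fc["fold_change"], 1.0)
        assert set(fc["group"]) == {"pro_inflammatory", "anti_inflammatory",
                                    "immune_cells"}

    def test_single_component_tripled(self, healthy_ss):
        case = healthy_ss.replace(Th1=3.0 * healthy_ss["Th1"])
        fc = fold_change(case, healthy_ss).set_index("compartment")["fold_change"]
        assert fc["Th1"] == pytest.approx(3.0)
        assert np.allclose(fc.drop("Th1"), 1.0)

    def test_zero_healthy_component_rejected(self):
        a = ImmuneState(("X",), [1.0])
        z = ImmuneState(("X",), [0.0])
        with pytest.raises(ValueError):
            fold_change(a, z, groups={"g": ("X",)})


def test_intervals_from_states_skip_drug_compartments(healthy_ss, case_sss):
    ivs = intervals_from_states(case_sss["case1"], healthy_ss)
    assert "D_alpha" not in ivs
    assert ivs["I_alpha"].patient_level == pytest.approx(case_sss["case1"]["I_alpha"])
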