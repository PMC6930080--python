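"""Hysteresis state machine, event extraction and residence statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from lipsite import (
    BindingEvent,
    BindingSite,
    bootstrap_ci,
    extract_events,
    mann_whitney_u,
    residence_summary,
    state_series,
    states_from_distances,
)
from lipsite.kinetics import StateSeries
from conftest import brute_force_hysteresis, exact_mw_pvalue, make_trapping_ensemble


class TestStateMachine:
    def test_hand_simulated_hysteresis(self):
        d = [4.0, 1.5, 2.0, 3.0, 3.6, 1.0, 4.0]
        # frames at 2.0 and 3.0 stay bound: they are inside the 3.5 nm buffer
        assert states_from_distances(d, 1.8, 3.5).tolist() == [0, 1, 1, 1, 0, 1, 0]

    def test_never_entering_lipid_is_all_outside(self):
        d = np.full(20, 2.5)
        assert states_from_distances(d, 1.8, 3.5).sum() == 0

    def test_degenerate_hysteresis_is_single_threshold(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 4, size=200)
        states = states_from_distances(d, 1.8, 1.8)
        np.testing.assert_array_equal(states, (d <= 1.8).astype(int))

    def test_initial_state_uses_entry_radius(self):
        # 2.0 nm is inside the buffer but outside the entry radius: start outside
        assert states_from_distances([2.0, 2.0], 1.8, 3.5).tolist() == [0, 0]
        assert states_from_distances([1.0, 2.0], 1.8, 3.5).tolist() == [1, 1]

    @given(
        d=st.lists(st.floats(0.0, 5.0), min_size=1, max_size=50),
        radii=st.tuples(st.floats(0.5, 2.5), st.floats(0.0, 2.0)),
    )
    def test_matches_brute_force_labeller(self, d, radii):
        r_on, extra = radii
        r_off = r_on + extra
        got = states_from_distances(np.array(d), r_on, r_off)
        assert got.tolist() == brute_force_hysteresis(d, r_on, r_off)

    @given(
        d=st.lists(st.floats(0.0, 5.0), min_size=2, max_size=40),
        r_on=st.floats(0.5, 2.0),
        extra=st.tuples(st.floats(0.0, 1.0), st.floats(0.0, 1.0)),
    )
    def test_enlarging_buffer_merges_events(self, d, r_on, extra):
        """Larger r_off: never more events, never fewer bound frames."""
        lo, hi = sorted([r_on + extra[0], r_on + extra[1]])
        d = np.array(d)
        s_lo = states_from_distances(d, r_on, lo)
        s_hi = states_from_distances(d, r_on, hi)
        ev_lo = extract_events(StateSeries([s_lo[None, :]], 1.0))
        ev_hi = extract_events(StateSeries([s_hi[None, :]], 1.0))
        assert len(ev_hi) <= len(ev_lo)
        assert s_hi.sum() >= s_lo.sum()

    def test_empty_cavity_selection_errors(self):
        _, _, traj = make_trapping_ensemble(n_lipids=5, n_frames=5)
        site = BindingSite(center=np.array([], dtype=int), r_on=1.8, r_off=3.5)
        with pytest.raises(ValueError, match="empty cavity"):
            state_series(traj, site)

    def test_dynamic_center_follows_selected_beads(self):
        """Cavity centre = per-frame centre of mass of the selected beads."""
        _, _, traj = make_trapping_ensemble(n_lipids=10, n_frames=20, seed=3)
        site = BindingSite(center=[0, 1], r_on=1.8, r_off=3.5)
        centers = site.center_per_frame(traj.replicas[0].positions)
        expected = traj.replicas[0].positions[:, [0, 1], :].mean(axis=1)
        np.testing.assert_allclose(centers, expected)


class TestExtractEvents:
    def test_all_outside_yields_no_events(self):
        ss = StateSeries([np.zeros((3, 10), dtype=int)], 1.0)
        assert extract_events(ss) == []

    def test_two_events_from_worked_series(self):
        ss = StateSeries([np.array([[0, 1, 1, 1, 0, 1, 0]])], 1.0)
        ev = extract_events(ss)
        assert [(e.start_frame, e.end_frame, e.duration) for e in ev] == [
            (1, 3, 3.0),
            (5, 5, 1.0),
        ]
        assert not any(e.truncated_start or e.truncated_end for e in ev)

    def test_boundary_runs_are_flagged_truncated(self):
        ss = StateSeries([np.array([[1, 1, 0], [0, 1, 1]])], 2.0)
        ev = extract_events(ss)
        assert ev[0].truncated_start and not ev[0].truncated_end
        assert ev[1].truncated_end and not ev[1].truncated_start
        assert ev[0].duration == 4.0  # 2 frames x 2 ns

    @given(rows=st.lists(st.lists(st.integers(0, 1), min_size=1, max_size=40),
                         min_size=1, max_size=5))
    def test_events_partition_bound_frames(self, rows):
        width = max(len(r) for r in rows)
        mat = np.zeros((len(rows), width), dtype=int)
        for i, r in enumerate(rows):
            mat[i, : len(r)] = r
        ss = StateSeries([mat], 1.0)
        ev = extract_events(ss)
        # disjoint per lipid, and total bound frames equals summed event length
        assert sum(e.end_frame - e.start_frame + 1 for e in ev) == int(mat.sum())
        by_lipid: dict[int, list[BindingEvent]] = {}
        for e in ev:
            by_lipid.setdefault(e.lipid_id, []).append(e)
        for evs in by_lipid.values():
            evs.sort(key=lambda e: e.start_frame)
            for a, b in zip(evs, evs[1:]):
                assert b.start_frame > a.end_frame + 1  # >=1 separating o frame


class TestBootstrap:
    def test_degenerate_sample_gives_point_interval(self):
        lo, hi = bootstrap_ci([7.0] * 25, seed=1)
        assert lo == hi == 7.0

    def test_intervals_nest_with_level(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(100, size=80)
        lo90, hi90 = bootstrap_ci(x, level=0.90, n_boot=4000, seed=9)
        lo99, hi99 = bootstrap_ci(x, level=0.99, n_boot=4000, seed=9)
        assert lo99 <= lo90 <= hi90 <= hi99

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(3).exponential(10, size=50)
        assert bootstrap_ci(x, seed=42) == bootstrap_ci(x, seed=42)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([])


class TestMannWhitney:
    def test_small_sample_exact_enumeration(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)
        assert p == pytest.approx(exact_mw_pvalue([1, 2], [3, 4]))

    def test_identical_samples_with_ties(self):
        x = [1.0, 1.0, 2.0, 3.0, 5.0] * 4
        u, p = mann_whitney_u(x, list(x))
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p > 0.95

    @given(
        x=st.lists(st.integers(0, 100), min_size=1, max_size=10),
        y=st.lists(st.integers(0, 100), min_size=1, max_size=10),
    )
    def test_u_statistics_sum_to_nx_ny(self, x, y):
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestResidenceSummary:
    def _events(self, spec):
        ev = []
        for i, (label, dur) in enumerate(spec):
            ev.append(
                BindingEvent(0, i, label, 0, int(dur) - 1, float(dur), False, False)
            )
        return ev

    def test_ratio_of_means(self):
        ev = self._events([("CDL", 10), ("CDL", 20), ("POPC", 4), ("POPE", 8)])
        s = residence_summary(ev, ["CDL", "POPC", "POPE"], n_boot=200)
        assert s.per_type["CDL"].mean_residence == 15.0
        assert s.ratio_CDL_vs_others == pytest.approx(15.0 / 6.0)  # 2.5
        assert s.per_type_ratio["POPC"] == pytest.approx(15.0 / 4.0)

    def test_single_type_ratio_undefined(self):
        ev = self._events([("CDL", 5), ("CDL", 7)])
        s = residence_summary(ev, ["CDL"], n_boot=200)
        assert np.isnan(s.ratio_CDL_vs_others)
        assert s.per_type["CDL"].n_events == 2

    def test_truncated_events_can_be_censored(self):
        ev = self._events([("CDL", 10), ("POPC", 4)])
        ev.append(BindingEvent(0, 9, "CDL", 0, 99, 100.0, True, False))
        full = residence_summary(ev, ["CDL", "POPC"], n_boot=200)
        cens = residence_summary(ev, ["CDL", "POPC"], include_truncated=False, n_boot=200)
        assert full.per_type["CDL"].n_events == 2
        assert cens.per_type["CDL"].n_events == 1
        assert cens.per_type["CDL"].mean_residence == 10.0

    def test_no_events_is_error(self):
        with pytest.raises(ValueError):
            residence_summary([], ["CDL"])

    def test_mw_p_small_when_distributions_differ(self):
        rng = np.random.default_rng(0)
        ev = self._events(
            [("CDL", d) for d in rng.exponential(100, 150)]
            + [("POPC", d) for d in rng.exponential(20, 150)]
        )
        s = residence_summary(ev, ["CDL", "POPC"], n_boot=500)
        assert s.per_type["POPC"].p_vs_CDL < 1e-6
        ci = s.per_type["CDL"].ci90
        assert ci[0] < s.per_type["CDL"].mean_residence < ci[1]
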