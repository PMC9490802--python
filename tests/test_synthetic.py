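"""Generators: Markov gating traces, NB flux counts, toy trajectories."""

import dataclasses
import math

import numpy as np
import pytest

from aquagate.intervals import IntervalScheme
from aquagate.permeation import CylinderSpec, assign_compartments, detect_permeation_events, filter_spurious_events
from aquagate.structures import Trajectory
from aquagate.synthetic import (
    ResidueProcess,
    SyntheticSpec,
    ToyTrajectorySpec,
    default_spec,
    recovery_spec,
    simulate_flux_counts,
    simulate_state_traces,
    simulate_toy_trajectory,
    truth_report,
)


def one_pore_spec(residues, duration_ns=2000.0, **kw):
    return SyntheticSpec(
        variants=("wt",),
        replicas=1,
        chains=("A",),
        duration_ns=duration_ns,
        residues=residues,
        **kw,
    )


class TestStateTraces:
    def test_two_state_stationary_half(self):
        proc = ResidueProcess(
            definition_id="g",
            state_labels=("a", "b"),
            reference_state="b",
            mean_dwell_ns={"a": 10.0, "b": 10.0},
            beta={"a": 0.0, "b": 0.0},
        )
        spec = one_pore_spec({"g": proc}, duration_ns=4000.0)
        traces = simulate_state_traces(spec, seed=0)
        tr = traces[("wt", 1, "A")]["g"]
        frac_a = float(np.mean(tr.states == 0))
        # ~400 alternations; occupancy SE ~ sqrt(p q * 2*tau/T) ~ 0.035
        assert abs(frac_a - 0.5) < 0.105

    def test_absorbing_limit_constant_trace(self):
        proc = ResidueProcess(
            definition_id="g",
            state_labels=("a", "b"),
            reference_state="b",
            mean_dwell_ns={"a": 1e12, "b": 1e12},
            beta={"a": 0.0, "b": 0.0},
        )
        spec = one_pore_spec({"g": proc}, duration_ns=100.0)
        tr = simulate_state_traces(spec, seed=3)[("wt", 1, "A")]["g"]
        assert np.all(tr.states == tr.states[0])

    def test_seed_determinism(self):
        spec = dataclasses.replace(recovery_spec(), duration_ns=100.0)
        a = simulate_state_traces(spec, seed=9)
        b = simulate_state_traces(spec, seed=9)
        for pore in a:
            np.testing.assert_array_equal(a[pore]["gate"].states, b[pore]["gate"].states)

    def test_different_seeds_differ(self):
        spec = dataclasses.replace(recovery_spec(), duration_ns=200.0)
        a = simulate_state_traces(spec, seed=1)
        b = simulate_state_traces(spec, seed=2)
        assert any(
            not np.array_equal(a[p]["gate"].states, b[p]["gate"].states) for p in a
        )


class TestFluxCounts:
    def test_poisson_intercept_limit(self):
        # beta = 0, sigma_u = 0, phi huge: mean y ~ exp(alpha*) within 3 SE
        proc = ResidueProcess(
            definition_id="g",
            state_labels=("a", "b"),
            reference_state="b",
            mean_dwell_ns={"a": 10.0, "b": 10.0},
            beta={"a": 0.0, "b": 0.0},
        )
        spec = one_pore_spec(
            {"g": proc}, duration_ns=2000.0, sigma_u_star=0.0, phi_star=1e6
        )
        scheme = IntervalScheme(analysis_start=1000, analysis_end=3000)
        traces = simulate_state_traces(spec, seed=5)
        df, _ = simulate_flux_counts(traces, scheme, spec, seed=5)
        mean_true = math.exp(spec.alpha_star)
        se = math.sqrt(mean_true / len(df))
        assert abs(df["flux_count"].mean() - mean_true) < 3 * se

    def test_poisson_limit_variance_matches_mean(self):
        proc = ResidueProcess(
            definition_id="g",
            state_labels=("a", "b"),
            reference_state="b",
            mean_dwell_ns={"a": 1e12, "b": 1e12},
            beta={"a": 0.0, "b": 0.0},
        )
        spec = one_pore_spec(
            {"g": proc}, duration_ns=2000.0, sigma_u_star=0.0, phi_star=1e6
        )
        scheme = IntervalScheme(analysis_start=1000, analysis_end=3000)
        traces = simulate_state_traces(spec, seed=6)
        df, _ = simulate_flux_counts(traces, scheme, spec, seed=6)
        y = df["flux_count"].to_numpy()
        mu = y.mean()
        # variance of the sample variance of Poisson ~ (mu + 2 mu^2)... use
        # 3 SE of the variance estimator
        se_var = math.sqrt((mu + 2 * mu**2) / y.size)
        assert abs(y.var() - mu) < 3 * se_var

    def test_blocking_state_rate(self):
        # windows fully blocked average ~1.0 counts (Fig-2-inset scale truth)
        proc = ResidueProcess(
            definition_id="g",
            state_labels=("blocked", "open"),
            reference_state="open",
            mean_dwell_ns={"blocked": 100.0, "open": 100.0},
            beta={"blocked": math.log(1.0 / 4.6), "open": 0.0},
        )
        spec = one_pore_spec({"g": proc}, sigma_u_star=0.0, phi_star=1e6)
        scheme = IntervalScheme(analysis_start=1000, analysis_end=3000)
        traces = simulate_state_traces(spec, seed=8)
        df, _ = simulate_flux_counts(traces, scheme, spec, seed=8)
        blocked = df[df["g.blocked"] == 1.0]["flux_count"]
        assert len(blocked) > 30
        se = math.sqrt(1.0 / len(blocked))
        assert abs(blocked.mean() - 1.0) < 3 * se

    def test_sigma_u_increases_between_pore_variance(self):
        base = recovery_spec()
        scheme = IntervalScheme()
        lo = dataclasses.replace(base, sigma_u_star=0.05)
        hi = dataclasses.replace(base, sigma_u_star=0.4)
        traces = simulate_state_traces(base, seed=4)
        df_lo, _ = simulate_flux_counts(traces, scheme, lo, seed=4)
        df_hi, _ = simulate_flux_counts(traces, scheme, hi, seed=4)
        v_lo = df_lo.groupby("pore_id")["flux_count"].mean().var()
        v_hi = df_hi.groupby("pore_id")["flux_count"].mean().var()
        assert v_hi > v_lo

    def test_determinism(self):
        spec = dataclasses.replace(recovery_spec(), duration_ns=100.0)
        scheme = IntervalScheme(analysis_start=1000, analysis_end=1100)
        traces = simulate_state_traces(spec, seed=2)
        a, ua = simulate_flux_counts(traces, scheme, spec, seed=2)
        b, ub = simulate_flux_counts(traces, scheme, spec, seed=2)
        assert a.equals(b)
        assert ua == ub


class TestTruthReport:
    def test_open_blocked_algebra(self):
        spec = recovery_spec()
        tr = truth_report(spec)
        open_row = tr[(tr.residue == "gate") & (tr.state == "open")].iloc[0]
        blocked_row = tr[(tr.residue == "gate") & (tr.state == "blocked")].iloc[0]
        assert open_row.expected_per_5ns == pytest.approx(4.6)
        assert blocked_row.expected_per_5ns == pytest.approx(1.0)
        assert bool(open_row.is_reference)

    def test_all_positive(self):
        tr = truth_report(default_spec())
        assert (tr.expected_per_5ns > 0).all()


class TestToyTrajectory:
    def _count(self, traj):
        ct = assign_compartments(
            traj, CylinderSpec(center_mode="fixed"), water_atom_ids=traj.atom_ids
        )
        events = detect_permeation_events(ct)
        kept, removed = filter_spurious_events(events)
        return events, kept, removed

    def test_clean_case_exact(self):
        toy = ToyTrajectorySpec(n_half_crossers=0, n_radial_escapees=0, n_bulk_decoys=0)
        traj, truth = simulate_toy_trajectory(toy, seed=1)
        _, kept, _ = self._count(traj)
        assert len(kept) == len(truth) == 10

    def test_confounders_filtered(self):
        traj, truth = simulate_toy_trajectory(seed=3)
        events, kept, removed = self._count(traj)
        assert len(truth) == 10
        assert len(kept) == 10
        assert len(removed) == 3  # the radial escapees

    def test_event_times_match_ground_truth(self):
        traj, truth = simulate_toy_trajectory(seed=5)
        _, kept, _ = self._count(traj)
        det = sorted((e.water_id, e.direction, e.entry_time_ns, e.exit_time_ns) for e in kept)
        tru = sorted((e.water_id, e.direction, e.entry_time_ns, e.exit_time_ns) for e in truth)
        assert det == pytest.approx(tru)

    def test_time_reversal_flips_directions(self):
        traj, truth = simulate_toy_trajectory(seed=9)
        _, kept, _ = self._count(traj)
        rev = Trajectory(
            atom_ids=traj.atom_ids,
            coords=traj.coords[::-1],
            frame_period_ps=traj.frame_period_ps,
        )
        _, kept_rev, _ = self._count(rev)
        assert len(kept_rev) == len(kept)
        fwd = sorted(e.direction for e in kept)
        bwd = sorted(-e.direction for e in kept_rev)
        assert fwd == bwd

    def test_determinism(self):
        t1, e1 = simulate_toy_trajectory(seed=11)
        t2, e2 = simulate_toy_trajectory(seed=11)
        np.testing.assert_array_equal(t1.coords, t2.coords)
        assert [(e.water_id, e.exit_time_ns) for e in e1] == [
            (e.water_id, e.exit_time_ns) for e in e2
        ]
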