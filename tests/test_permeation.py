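"""Cylinder compartment assignment, the crossing state machine, and flux
windowing."""

import numpy as np
import pytest

from aquagate.errors import (
    ConfigurationError,
    EmptySelectionError,
    UndefinedStatisticError,
)
from aquagate.permeation import (
    ABOVE,
    BELOW,
    INSIDE,
    OUTSIDE_RADIUS,
    CompartmentTrace,
    CylinderSpec,
    FluxSeries,
    PermeationEvent,
    SpuriousFilterCriteria,
    assign_compartments,
    detect_permeation_events,
    filter_spurious_events,
    flux_in_windows,
    transit_time_stats,
)

from conftest import single_water_trajectory

FIXED_CYL = CylinderSpec(center_mode="fixed")  # 2.2 nm x 1.5 nm at origin


class TestAssignCompartments:
    @pytest.mark.parametrize(
        "xyz,expected",
        [
            ((0.0, 0.0, 0.0), INSIDE),  # cylinder center
            ((1.6, 0.0, 0.0), OUTSIDE_RADIUS),  # in slab, beyond radius
            ((0.0, 0.0, 1.2), ABOVE),  # beyond the axial cap
            ((0.0, 0.0, -1.2), BELOW),
            ((1.5, 0.0, 0.0), INSIDE),  # radial boundary inclusive
            ((0.0, 0.0, 1.1), INSIDE),  # axial boundary inclusive
        ],
    )
    def test_single_point_labels(self, xyz, expected):
        traj = single_water_trajectory([xyz[2]], xs=[xyz[0]], ys=[xyz[1]])
        ct = assign_compartments(traj, FIXED_CYL, water_atom_ids=[1])
        assert ct.labels[0, 0] == expected

    def test_no_waters_is_error(self):
        traj = single_water_trajectory([0.0])
        with pytest.raises(EmptySelectionError):
            assign_compartments(traj, FIXED_CYL, water_atom_ids=[])


def labels_to_trace(labels, radial=None):
    labels = np.asarray([labels], dtype=np.int8)
    n = labels.shape[1]
    radial = np.asarray([radial if radial is not None else [0.1] * n], float)
    z = np.zeros_like(radial)
    return CompartmentTrace(
        water_ids=np.array([1]),
        labels=labels,
        z=z,
        radial=radial,
        times_ns=np.arange(n) * 0.01,
    )


class TestDetectEvents:
    def test_minimal_crossing(self):
        ct = labels_to_trace([BELOW, INSIDE, INSIDE, ABOVE])
        events = detect_permeation_events(ct)
        assert len(events) == 1
        e = events[0]
        assert e.direction == 1
        assert e.entry_time_ns == pytest.approx(0.01)
        assert e.exit_time_ns == pytest.approx(0.03)
        assert e.transit_time_ns == pytest.approx(0.02)

    def test_reentry_resets_transit_start(self):
        # below, inside, below, inside, above -> entry at the SECOND inside
        ct = labels_to_trace([BELOW, INSIDE, BELOW, INSIDE, ABOVE])
        events = detect_permeation_events(ct)
        assert len(events) == 1
        assert events[0].entry_time_ns == pytest.approx(0.03)

    def test_radial_escape_voids_crossing(self):
        ct = labels_to_trace([BELOW, INSIDE, OUTSIDE_RADIUS, ABOVE])
        assert detect_permeation_events(ct) == []

    def test_reverse_direction(self):
        ct = labels_to_trace([ABOVE, INSIDE, BELOW])
        events = detect_permeation_events(ct)
        assert len(events) == 1
        assert events[0].direction == -1

    def test_no_event_without_inside_frames(self):
        ct = labels_to_trace([BELOW, ABOVE, BELOW])
        assert detect_permeation_events(ct) == []


class TestSpuriousFilter:
    def _event(self, max_r):
        return PermeationEvent(
            water_id=1,
            direction=1,
            entry_time_ns=0.0,
            exit_time_ns=1.0,
            max_radial_excursion_nm=max_r,
            max_radial_slab_nm=max_r,
        )

    def test_contained_event_kept(self):
        kept, removed = filter_spurious_events([self._event(0.2)])
        assert len(kept) == 1 and not removed

    def test_around_protein_path_removed(self):
        kept, removed = filter_spurious_events([self._event(1.4)])
        assert not kept and len(removed) == 1

    def test_r_sf_larger_than_radius_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_spurious_events(
                [self._event(0.2)],
                SpuriousFilterCriteria(r_sf=2.0),
                cylinder=FIXED_CYL,
            )

    def test_loose_criterion_keeps_axial_set(self):
        events = [self._event(r) for r in (0.1, 0.2, 0.3)]
        kept, removed = filter_spurious_events(
            events, SpuriousFilterCriteria(r_sf=1.5 - 1e-9)
        )
        assert len(kept) == 3 and not removed


class TestFluxWindows:
    def _series(self, times, directions):
        events = [
            PermeationEvent(i, d, t - 0.5, t, 0.1) for i, (t, d) in enumerate(zip(times, directions))
        ]
        return FluxSeries(pore_id=("wt", 1, "A"), events=events)

    def test_total_and_net_all_forward(self):
        s = self._series(np.linspace(1, 9, 10), [1] * 10)
        assert flux_in_windows(s, [(0.0, 10.0)], "total")[0] == 10
        assert flux_in_windows(s, [(0.0, 10.0)], "net")[0] == 10

    def test_balanced_net_zero(self):
        s = self._series(np.linspace(1, 9, 10), [1] * 5 + [-1] * 5)
        assert flux_in_windows(s, [(0.0, 10.0)], "total")[0] == 10
        assert flux_in_windows(s, [(0.0, 10.0)], "net")[0] == 0

    def test_half_open_window_assignment(self):
        s = self._series([1.0, 2.0, 3.0], [1, 1, 1])
        counts = flux_in_windows(s, [(0.0, 2.0), (2.0, 4.0)], "total")
        assert counts.tolist() == [1, 2]

    def test_overlap_requires_flag(self):
        s = self._series([1.0], [1])
        with pytest.raises(ConfigurationError):
            flux_in_windows(s, [(0.0, 2.0), (1.0, 3.0)], "total")
        counts = flux_in_windows(s, [(0.0, 2.0), (1.0, 3.0)], "total", allow_overlap=True)
        assert counts.tolist() == [1, 1]


class TestTransitStats:
    def test_arithmetic(self):
        events = [PermeationEvent(i, 1, 0.0, t, 0.1) for i, t in enumerate([1.0, 2.0, 3.0])]
        mean, f1, f3 = transit_time_stats(events)
        assert mean == pytest.approx(2.0)
        assert f1 == pytest.approx(0.0)
        assert f3 == pytest.approx(2 / 3)

    def test_single_event(self):
        mean, _, _ = transit_time_stats([PermeationEvent(1, 1, 0.0, 2.8, 0.1)])
        assert mean == pytest.approx(2.8)

    def test_empty_is_error(self):
        with pytest.raises(UndefinedStatisticError):
            transit_time_stats([])

    def test_seeded_distribution_moments(self):
        # transits drawn from a fixed exponential; sample mean within 3 SE
        rng = np.random.default_rng(42)
        scale = 2.8
        transits = rng.exponential(scale, size=1000)
        events = [PermeationEvent(i, 1, 0.0, t, 0.1) for i, t in enumerate(transits)]
        mean, _, _ = transit_time_stats(events)
        se = scale / np.sqrt(1000)
        assert abs(mean - scale) < 3 * se
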