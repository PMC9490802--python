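"""Single-file water permeation counting through a per-protomer cylinder.

A water molecule is counted as having permeated when its compartment
sequence visits one axial cap, then the cylinder interior, then the
opposite cap, without ever leaving the cylinder radially in between.
Events are timestamped at the frame where the opposite cap is first
reached, so each event falls into exactly one half-open flux window.

Waters that traverse the generous counting cylinder at large radial
distance (slipping around the protein rather than through the single-file
pore) are removed afterwards by a configurable radial-containment filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptySelectionError, UndefinedStatisticError
from .structures import Trajectory

# compartment codes
BELOW = 0
INSIDE = 1
ABOVE = 2
OUTSIDE_RADIUS = 3

COMPARTMENT_NAMES = {BELOW: "below", INSIDE: "inside", ABOVE: "above", OUTSIDE_RADIUS: "outside_radius"}
COMPARTMENT_CODES = {v: k for k, v in COMPARTMENT_NAMES.items()}


@dataclass
class CylinderSpec:
    """Axial counting cylinder along the membrane normal (z).

    Defaults follow the generous counting geometry used for GlpF: a 2.2 nm
    long, 1.5 nm radius cylinder centered on the protomer's center of mass
    after superposition onto the reference structure.
    """

    length: float = 2.2  # nm
    radius: float = 1.5  # nm
    center_mode: str = "chain_com"  # or "fixed"
    center_point: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.radius <= 0:
            raise ConfigurationError("cylinder length and radius must be positive")
        if self.center_mode not in {"chain_com", "fixed"}:
            raise ConfigurationError(f"unknown center_mode {self.center_mode!r}")


@dataclass
class PermeationEvent:
    """One directed, complete pore crossing by a single water."""

    water_id: int
    direction: int  # +1 below->above (periplasm->cytoplasm convention), -1 reverse
    entry_time_ns: float
    exit_time_ns: float
    max_radial_excursion_nm: float  # max radial distance while inside, within |z| <= z of slab
    max_radial_slab_nm: float = np.nan  # max radial distance within the single-file slab

    @property
    def transit_time_ns(self) -> float:
        return self.exit_time_ns - self.entry_time_ns


@dataclass
class FluxSeries:
    """Time-ordered permeation events for one pore."""

    pore_id: tuple  # (variant, replica, chain)
    events: list[PermeationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.exit_time_ns)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pore_id": ["/".join(map(str, self.pore_id))] * len(self.events),
                "water_id": [e.water_id for e in self.events],
                "direction": [e.direction for e in self.events],
                "entry_ns": [e.entry_time_ns for e in self.events],
                "exit_ns": [e.exit_time_ns for e in self.events],
                "transit_ns": [e.transit_time_ns for e in self.events],
                "max_radial_nm": [e.max_radial_excursion_nm for e in self.events],
            }
        )


@dataclass
class CompartmentTrace:
    """Per-water, per-frame compartment labels plus cylinder-frame geometry."""

    water_ids: np.ndarray  # (n_waters,)
    labels: np.ndarray  # (n_waters, n_frames) int8
    z: np.ndarray  # (n_waters, n_frames) axial coordinate relative to center
    radial: np.ndarray  # (n_waters, n_frames)
    times_ns: np.ndarray  # (n_frames,)
    cylinder: CylinderSpec = field(default_factory=CylinderSpec)


def assign_compartments(
    traj: Trajectory,
    cylinder: CylinderSpec,
    water_atom_ids: Sequence[int],
    protein_atom_ids: Sequence[int] | None = None,
) -> CompartmentTrace:
    """Label every water in every frame as below/inside/above/outside_radius.

    ``below``/``above`` apply whenever the water is axially beyond the
    respective cap (|z - z_center| > length/2); within the axial slab the
    label is ``inside`` when the radial distance is <= radius and
    ``outside_radius`` otherwise.  Frames are assumed already superposed
    onto the reference.  The cylinder center is the per-frame center of
    mass of ``protein_atom_ids`` (mode ``chain_com``) or a fixed point.
    """
    water_atom_ids = np.asarray(list(water_atom_ids), dtype=int)
    if water_atom_ids.size == 0:
        raise EmptySelectionError("no water atoms selected")
    widx = traj.atom_index(water_atom_ids)
    pos = traj.coords[:, widx, :]  # (F, n_w, 3)

    if cylinder.center_mode == "chain_com":
        if protein_atom_ids is None:
            raise ConfigurationError("center_mode='chain_com' requires protein_atom_ids")
        pidx = traj.atom_index(protein_atom_ids)
        center = traj.coords[:, pidx, :].mean(axis=1)  # (F, 3)
    else:
        center = np.broadcast_to(
            np.asarray(cylinder.center_point, float), (traj.n_frames, 3)
        )

    rel = pos - center[:, None, :]
    z = rel[..., 2].T  # (n_w, F)
    radial = np.hypot(rel[..., 0], rel[..., 1]).T

    half = cylinder.length / 2.0
    labels = np.full(z.shape, INSIDE, dtype=np.int8)
    labels[z < -half] = BELOW
    labels[z > half] = ABOVE
    slab = np.abs(z) <= half
    labels[slab & (radial > cylinder.radius)] = OUTSIDE_RADIUS
    return CompartmentTrace(
        water_ids=water_atom_ids,
        labels=labels,
        z=z,
        radial=radial,
        times_ns=traj.times_ns,
        cylinder=cylinder,
    )


def detect_permeation_events(
    trace: CompartmentTrace,
    z_sf: float = 0.8,
) -> list[PermeationEvent]:
    """Run the cap-to-cap crossing state machine on each water's labels.

    An event is recorded when a water visits one cap, then the interior
    (one or more frames), then the opposite cap, with no ``outside_radius``
    frame in between.  Touching ``outside_radius`` resets the machine to
    the last cap visited; re-entering the entry cap restarts the transit
    clock.  ``entry_time`` is the first interior frame of the final
    approach; ``exit_time`` the first frame beyond the opposite cap.

    ``z_sf`` only controls the slab within which the per-event maximal
    radial excursion is additionally recorded (for the spurious-path
    filter); it does not affect which events are found.
    """
    events: list[PermeationEvent] = []
    times = trace.times_ns
    caps = (BELOW, ABOVE)
    for w in range(trace.water_ids.size):
        labels = trace.labels[w]
        radial = trace.radial[w]
        z = trace.z[w]
        last_cap: int | None = None
        entry_idx: int | None = None
        max_r = 0.0
        max_r_slab = 0.0
        for i, lab in enumerate(labels):
            if lab == OUTSIDE_RADIUS:
                entry_idx = None
            elif lab in caps:
                if last_cap is not None and lab != last_cap and entry_idx is not None:
                    direction = 1 if lab == ABOVE else -1
                    events.append(
                        PermeationEvent(
                            water_id=int(trace.water_ids[w]),
                            direction=direction,
                            entry_time_ns=float(times[entry_idx]),
                            exit_time_ns=float(times[i]),
                            max_radial_excursion_nm=float(max_r),
                            max_radial_slab_nm=float(max_r_slab),
                        )
                    )
                last_cap = lab
                entry_idx = None
            else:  # INSIDE
                if last_cap is not None and entry_idx is None:
                    entry_idx = i
                    max_r = 0.0
                    max_r_slab = 0.0
                if entry_idx is not None:
                    max_r = max(max_r, float(radial[i]))
                    if abs(z[i]) <= z_sf:
                        max_r_slab = max(max_r_slab, float(radial[i]))
    events.sort(key=lambda e: e.exit_time_ns)
    return events


@dataclass
class SpuriousFilterCriteria:
    """Radial single-file containment criterion.

    An event is spurious when its path exceeds ``r_sf`` radially anywhere
    inside the single-file slab ``|z - z_center| <= z_sf`` — such a water
    slipped around the protein inside the generous counting cylinder.
    """

    r_sf: float = 0.4  # nm
    z_sf: float = 0.8  # nm


def filter_spurious_events(
    events: Sequence[PermeationEvent],
    criteria: SpuriousFilterCriteria | None = None,
    cylinder: CylinderSpec | None = None,
) -> tuple[list[PermeationEvent], list[PermeationEvent]]:
    """Split events into (kept, removed) under the containment criterion."""
    criteria = criteria or SpuriousFilterCriteria()
    if cylinder is not None and criteria.r_sf > cylinder.radius:
        raise ConfigurationError("r_sf cannot exceed the cylinder radius")
    kept, removed = [], []
    for e in events:
        r = e.max_radial_slab_nm
        if np.isnan(r):
            r = e.max_radial_excursion_nm
        (removed if r > criteria.r_sf else kept).append(e)
    return kept, removed


def flux_in_windows(
    series: FluxSeries | Sequence[PermeationEvent],
    windows: Sequence[tuple[float, float]],
    mode: str = "total",
    allow_overlap: bool = False,
) -> np.ndarray:
    """Count events per half-open window [start, end) by exit time.

    ``total`` counts all events; ``net`` is (+1 events) - (-1 events).
    Overlapping windows are rejected unless ``allow_overlap`` is set.
    """
    events = series.events if isinstance(series, FluxSeries) else list(series)
    if mode not in {"total", "net"}:
        raise ConfigurationError(f"unknown mode {mode!r}")
    wins = [(float(a), float(b)) for a, b in windows]
    if not allow_overlap:
        for (a1, b1), (a2, b2) in zip(sorted(wins), sorted(wins)[1:]):
            if a2 < b1:
                raise ConfigurationError(
                    "overlapping windows; pass allow_overlap=True if intended"
                )
    exits = np.array([e.exit_time_ns for e in events])
    dirs = np.array([e.direction for e in events])
    counts = np.zeros(len(wins), dtype=int)
    for k, (a, b) in enumerate(wins):
        m = (exits >= a) & (exits < b)
        counts[k] = int(dirs[m].sum()) if mode == "net" else int(m.sum())
    return counts


def transit_time_stats(
    events: Sequence[PermeationEvent],
) -> tuple[float, float, float]:
    """(mean transit ns, fraction < 1 ns, fraction < 3 ns)."""
    transits = np.array([e.transit_time_ns for e in events])
    if transits.size == 0:
        raise UndefinedStatisticError("transit statistics undefined for zero events")
    return (
        float(transits.mean()),
        float(np.mean(transits < 1.0)),
        float(np.mean(transits < 3.0)),
    )


def events_to_dataframe(series_list: Sequence[FluxSeries]) -> pd.DataFrame:
    """Concatenate the event tables of several pores."""
    frames = [s.to_dataframe() for s in series_list]
    if not frames:
        return pd.DataFrame(
            columns=["pore_id", "water_id", "direction", "entry_ns", "exit_ns", "transit_ns", "max_radial_nm"]
        )
    return pd.concat(frames, ignore_index=True)
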