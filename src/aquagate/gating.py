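"""Gating-state descriptors and classification for pore-lining residues.

Each gating residue of GlpF is described either by a side-chain torsion
(W48: Calpha-Cbeta-Cgamma-Cdelta1; R206: the four-point torsion
Calpha-Cbeta-Cgamma-Czeta, skipping the intermediate side-chain atoms) or
by the minimum heavy-atom distance between two side chains.  The
descriptor domain is partitioned into half-open, named state bins; "less
than threshold" is strict, so a value exactly at a threshold falls into
the upper bin.  The registry below carries the published thresholds for
the nine modulating residues; it is data driven and extensible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    SelectionError,
    UndefinedTorsionError,
)
from .structures import StructureModel, Trajectory

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3", "HN"}


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------


def dihedral_angle(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    p4: np.ndarray,
    domain: tuple[float, float] = (-180.0, 180.0),
) -> float | np.ndarray:
    """Signed torsion of four points in degrees, IUPAC sign convention
    (positive clockwise looking from point 2 toward point 3), wrapped into
    ``domain`` ([-180, 180) or [0, 360)).

    Accepts single points or arrays of shape (n, 3) for a whole series.
    The four atoms need not be covalently bonded.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    if np.any(norm1 < 1e-10) or np.any(norm2 < 1e-10):
        raise UndefinedTorsionError("colinear atom triple: torsion undefined")
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    lo, hi = domain
    if not np.isclose(hi - lo, 360.0):
        raise ConfigurationError("angle domain must span 360 degrees")
    wrapped = (ang - lo) % 360.0 + lo
    return float(wrapped) if wrapped.ndim == 0 else wrapped


def sidechain_atom_ids(
    structure: StructureModel,
    chain_id: str | None,
    residue_number: int,
    policy: str = "heavy",
) -> np.ndarray:
    """Atom ids of a residue's side chain (Cbeta outward).

    ``policy='heavy'`` excludes hydrogens (the crystal structure carries
    none, so thresholds calibrated on it must be hydrogen free);
    ``policy='all'`` keeps them.
    """
    if policy not in {"heavy", "all"}:
        raise ConfigurationError(f"unknown atom policy {policy!r}")
    sub = structure.select(chain_id=chain_id, residue_numbers=[residue_number])
    if sub.empty:
        raise SelectionError(f"residue {residue_number} (chain {chain_id!r}) not found")
    mask = ~sub["atom_name"].isin(BACKBONE_ATOMS)
    if policy == "heavy":
        is_h = sub["element"].str.upper().eq("H") | sub["atom_name"].str.startswith("H")
        mask &= ~is_h
    ids = sub.loc[mask, "atom_id"].to_numpy(int)
    if ids.size == 0:
        raise SelectionError(
            f"residue {residue_number} has no side-chain atoms under policy {policy!r}"
        )
    return ids


def _pairwise_min(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> float:
    diff = a[:, None, :] - b[None, :, :]
    if box is not None:
        box = np.asarray(box, float)
        diff -= box * np.round(diff / box)
    return float(np.sqrt((diff**2).sum(-1)).min())


def min_sidechain_distance(
    structure: StructureModel,
    res_a: tuple[str | None, int],
    res_b: tuple[str | None, int],
    policy: str = "heavy",
    coords: np.ndarray | None = None,
    coord_atom_ids: Sequence[int] | None = None,
    box: np.ndarray | None = None,
) -> float:
    """Minimum distance (nm) between the side-chain atom sets of two
    residues, under the minimum-image convention when ``box`` is given.

    By default the structure's own coordinates are used; pass ``coords``
    (with the matching ``coord_atom_ids``) to evaluate a trajectory frame.
    """
    ids_a = sidechain_atom_ids(structure, res_a[0], res_a[1], policy)
    ids_b = sidechain_atom_ids(structure, res_b[0], res_b[1], policy)
    if coords is None:
        pa = structure.positions_for(ids_a)
        pb = structure.positions_for(ids_b)
    else:
        coords = np.asarray(coords, float)
        lookup = pd.Index(np.asarray(list(coord_atom_ids), dtype=int))
        ia = lookup.get_indexer(ids_a)
        ib = lookup.get_indexer(ids_b)
        if np.any(ia < 0) or np.any(ib < 0):
            raise SelectionError("side-chain atoms missing from coordinate frame")
        pa = coords[ia]
        pb = coords[ib]
    return _pairwise_min(pa, pb, box)


# ---------------------------------------------------------------------------
# state definitions and classification
# ---------------------------------------------------------------------------


@dataclass
class StateDefinition:
    """Partition of one residue's geometric descriptor into named states."""

    id: str
    residue_number: int
    residue_name: str
    metric: str  # "dihedral" or "min_distance"
    state_labels: tuple[str, ...]
    reference_state: str
    edges: tuple[float, ...] = ()  # bin edges tiling the domain, half-open [lo, hi)
    # dihedral specifics
    atoms: tuple[str, ...] = ()
    domain: tuple[float, float] = (-180.0, 180.0)
    # min-distance specifics
    partner_residue_number: int | None = None
    partner_residue_name: str | None = None

    def __post_init__(self) -> None:
        if self.metric not in {"dihedral", "min_distance"}:
            raise ConfigurationError(f"unknown metric {self.metric!r}")
        if self.metric == "dihedral":
            if len(self.atoms) != 4:
                raise ConfigurationError("dihedral metric needs 4 atom names")
            if not self.edges:
                raise ConfigurationError("dihedral metric needs bin edges")
            if not (
                np.isclose(self.edges[0], self.domain[0])
                and np.isclose(self.edges[-1], self.domain[1])
            ):
                raise ConfigurationError("bin edges must tile the angle domain")
        else:
            if self.partner_residue_number is None:
                raise ConfigurationError("min_distance metric needs a partner residue")
            if not self.edges:
                raise ConfigurationError("min_distance metric needs a threshold edge")
        n_bins = len(self.edges) - 1 if self.metric == "dihedral" else len(self.edges) + 1
        if len(self.state_labels) != n_bins:
            raise ConfigurationError("labels must match bins")
        if self.reference_state not in self.state_labels:
            raise ConfigurationError("reference_state must be one of state_labels")
        if len(set(self.state_labels)) != len(self.state_labels):
            raise ConfigurationError("state labels must be unique")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def nonreference_states(self) -> tuple[str, ...]:
        return tuple(s for s in self.state_labels if s != self.reference_state)

    def full_edges(self) -> np.ndarray:
        if self.metric == "dihedral":
            return np.asarray(self.edges, float)
        # distance partition: (0, thr_1, ..., thr_k, inf)
        return np.concatenate([[0.0], np.asarray(self.edges, float), [np.inf]])

    def classify_values(self, values: np.ndarray) -> np.ndarray:
        """Map metric values to state indices (into state_labels)."""
        values = np.asarray(values, float)
        if self.metric == "dihedral":
            lo, hi = self.domain
            values = (values - lo) % 360.0 + lo
            # float rounding can land a tiny negative remainder on hi exactly
            values = np.where(values >= hi, lo, values)
        edges = self.full_edges()
        idx = np.searchsorted(edges, values, side="right") - 1
        # a value exactly at the domain's upper edge wraps to the first bin
        idx = np.clip(idx, 0, self.n_states - 1)
        out_of_domain = (values < edges[0]) | (values >= edges[-1])
        if self.metric == "dihedral" and np.any(out_of_domain):
            raise ConfigurationError("angle outside domain after wrapping")
        if self.metric == "min_distance" and np.any(values < 0):
            raise ConfigurationError("negative distance")
        return idx.astype(np.int8)


@dataclass
class StateTrace:
    """Per-frame gating-state labels for one residue of one pore."""

    pore_id: tuple
    definition_id: str
    state_labels: tuple[str, ...]
    states: np.ndarray  # (n_frames,) int8 indices into state_labels
    frame_period_ps: float = 10.0
    time_origin_ns: float = 0.0
    reference_state: str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)

    @property
    def n_frames(self) -> int:
        return self.states.size

    @property
    def times_ns(self) -> np.ndarray:
        return self.time_origin_ns + np.arange(self.n_frames) * (self.frame_period_ps / 1000.0)

    @property
    def end_time_ns(self) -> float:
        return self.time_origin_ns + self.n_frames * self.frame_period_ps / 1000.0

    def frame_slice(self, start_ns: float, end_ns: float) -> slice:
        """Frames with time in the half-open interval [start_ns, end_ns)."""
        dt = self.frame_period_ps / 1000.0
        i0 = int(np.ceil((start_ns - self.time_origin_ns) / dt - 1e-9))
        i1 = int(np.ceil((end_ns - self.time_origin_ns) / dt - 1e-9))
        return slice(max(i0, 0), min(max(i1, 0), self.n_frames))


def classify(
    values: np.ndarray,
    definition: StateDefinition,
    pore_id: tuple = ("", 0, ""),
    frame_period_ps: float = 10.0,
    time_origin_ns: float = 0.0,
) -> StateTrace:
    """Classify a metric time series into a :class:`StateTrace`."""
    return StateTrace(
        pore_id=pore_id,
        definition_id=definition.id,
        state_labels=definition.state_labels,
        states=definition.classify_values(values),
        frame_period_ps=frame_period_ps,
        time_origin_ns=time_origin_ns,
        reference_state=definition.reference_state,
    )


def state_populations(
    trace: StateTrace, time_range: tuple[float, float] | None = None
) -> dict[str, float]:
    """Fraction of frames per state over a half-open time range."""
    if time_range is None:
        sl = slice(None)
    else:
        sl = trace.frame_slice(*time_range)
    states = trace.states[sl]
    if states.size == 0:
        raise ConfigurationError("empty time range for state populations")
    counts = np.bincount(states, minlength=len(trace.state_labels))
    fracs = counts / counts.sum()
    return {lab: float(f) for lab, f in zip(trace.state_labels, fracs)}


# ---------------------------------------------------------------------------
# metric evaluation on structures and trajectories
# ---------------------------------------------------------------------------


def evaluate_metric_structure(
    structure: StructureModel,
    definition: StateDefinition,
    chain_id: str | None = None,
    policy: str = "heavy",
) -> float:
    """Evaluate a definition's descriptor on a static structure."""
    if definition.metric == "dihedral":
        sub = structure.select(
            chain_id=chain_id, residue_numbers=[definition.residue_number]
        )
        pts = []
        for name in definition.atoms:
            row = sub[sub["atom_name"] == name]
            if row.empty:
                raise SelectionError(
                    f"atom {name} of residue {definition.residue_number} not found"
                )
            pts.append(row[["x", "y", "z"]].to_numpy(float)[0])
        return float(dihedral_angle(*pts, domain=definition.domain))
    return min_sidechain_distance(
        structure,
        (chain_id, definition.residue_number),
        (chain_id, definition.partner_residue_number),
        policy=policy,
    )


def evaluate_metric_trajectory(
    traj: Trajectory,
    structure: StructureModel,
    definition: StateDefinition,
    chain_id: str | None = None,
    policy: str = "heavy",
) -> np.ndarray:
    """Evaluate a definition's descriptor on every trajectory frame."""
    if definition.metric == "dihedral":
        sub = structure.select(
            chain_id=chain_id, residue_numbers=[definition.residue_number]
        )
        ids = []
        for name in definition.atoms:
            row = sub[sub["atom_name"] == name]
            if row.empty:
                raise SelectionError(
                    f"atom {name} of residue {definition.residue_number} not found"
                )
            ids.append(int(row["atom_id"].iloc[0]))
        idx = traj.atom_index(ids)
        p = traj.coords[:, idx, :]
        return np.asarray(
            dihedral_angle(p[:, 0], p[:, 1], p[:, 2], p[:, 3], domain=definition.domain)
        )
    ids_a = sidechain_atom_ids(structure, chain_id, definition.residue_number, policy)
    ids_b = sidechain_atom_ids(
        structure, chain_id, definition.partner_residue_number, policy
    )
    ia = traj.atom_index(ids_a)
    ib = traj.atom_index(ids_b)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        box = traj.box[f] if traj.box is not None else None
        out[f] = _pairwise_min(traj.coords[f, ia], traj.coords[f, ib], box)
    return out


# ---------------------------------------------------------------------------
# built-in registry
# ---------------------------------------------------------------------------


def _dist_def(
    id_: str,
    resnum: int,
    resname: str,
    partner_num: int,
    partner_name: str,
    threshold: float,
    labels: tuple[str, str],
    reference: str,
) -> StateDefinition:
    return StateDefinition(
        id=id_,
        residue_number=resnum,
        residue_name=resname,
        metric="min_distance",
        state_labels=labels,
        reference_state=reference,
        edges=(threshold,),
        partner_residue_number=partner_num,
        partner_residue_name=partner_name,
    )


def default_registry() -> dict[str, StateDefinition]:
    """The nine built-in gating-state definitions for GlpF.

    Thresholds and bins follow the published per-residue descriptors; the
    reference state of every residue is the crystal-like open state.
    """
    registry: dict[str, StateDefinition] = {}
    registry["w48"] = StateDefinition(
        id="w48",
        residue_number=48,
        residue_name="TRP",
        metric="dihedral",
        atoms=("CA", "CB", "CG", "CD1"),
        domain=(-180.0, 180.0),
        edges=(-180.0, 0.0, 70.0, 180.0),
        state_labels=("blocked", "partial", "open"),
        reference_state="open",
    )
    registry["r206"] = StateDefinition(
        id="r206",
        residue_number=206,
        residue_name="ARG",
        metric="dihedral",
        atoms=("CA", "CB", "CG", "CZ"),
        domain=(0.0, 360.0),
        edges=(0.0, 50.0, 115.0, 160.0, 210.0, 240.0, 290.0, 360.0),
        state_labels=(
            "s0_50",
            "s50_115",
            "s115_160",
            "s160_210",
            "s210_240",
            "s240_290",
            "s290_360",
        ),
        reference_state="s290_360",
    )
    registry["f200"] = _dist_def("f200", 200, "PHE", 196, "PRO", 0.37, ("near", "far"), "far")
    registry["a201"] = _dist_def("a201", 201, "ALA", 48, "TRP", 0.35, ("blocking", "open"), "open")
    registry["m202"] = _dist_def("m202", 202, "MET", 21, "LEU", 0.40, ("in_pore", "out"), "out")
    registry["n203"] = _dist_def("n203", 203, "ASN", 187, "ILE", 0.30, ("in_pore", "out"), "out")
    registry["n68"] = _dist_def("n68", 68, "ASN", 52, "VAL", 0.45, ("in_pore", "out"), "out")
    registry["h66"] = _dist_def("h66", 66, "HIS", 183, "ILE", 0.35, ("in_pore", "out"), "out")
    registry["v173"] = _dist_def("v173", 173, "VAL", 75, "LEU", 0.40, ("in_pore", "out"), "out")
    return registry


def registry_to_yaml(registry: Mapping[str, StateDefinition], path) -> None:
    payload = {}
    for key, d in registry.items():
        payload[key] = {
            "residue_number": d.residue_number,
            "residue_name": d.residue_name,
            "metric": d.metric,
            "state_labels": list(d.state_labels),
            "reference_state": d.reference_state,
            "edges": [float(e) for e in d.edges],
            "atoms": list(d.atoms),
            "domain": [float(x) for x in d.domain],
            "partner_residue_number": d.partner_residue_number,
            "partner_residue_name": d.partner_residue_name,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def registry_from_yaml(path) -> dict[str, StateDefinition]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    registry = {}
    for key, d in payload.items():
        registry[key] = StateDefinition(
            id=key,
            residue_number=int(d["residue_number"]),
            residue_name=str(d["residue_name"]),
            metric=str(d["metric"]),
            state_labels=tuple(d["state_labels"]),
            reference_state=str(d["reference_state"]),
            edges=tuple(float(e) for e in d["edges"]),
            atoms=tuple(d.get("atoms") or ()),
            domain=tuple(d.get("domain") or (-180.0, 180.0)),
            partner_residue_number=d.get("partner_residue_number"),
            partner_residue_name=d.get("partner_residue_name"),
        )
    return registry
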