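"""Secondary structural observables: per-segment RMSD, water dipole tilt
along the pore axis, and water-residue hydrogen-bond counts.

The hydrogen-bond criterion is the de facto standard geometric one
(donor-acceptor distance <= 0.35 nm and donor-hydrogen...acceptor angle
within 30 degrees of linear); it is recorded in the output metadata since
different conventions shift absolute counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapabilityError, SelectionError
from .structures import StructureModel, Trajectory, superpose

#: Default named segments of one protomer: six transmembrane helices, the
#: two half-helices and the two intra-pore loops.
DEFAULT_SEGMENTS: dict[str, tuple[tuple[int, int], ...]] = {
    "H1": ((7, 35),),
    "H2": ((41, 63),),
    "L2": ((64, 68),),
    "HH1": ((69, 79),),
    "H3": ((83, 119),),
    "H4": ((145, 167),),
    "H5": ((178, 196),),
    "L6": ((197, 203),),
    "HH2": ((204, 217),),
    "H6": ((232, 255),),
}


@dataclass
class SegmentSet:
    """Named, non-overlapping residue ranges (inclusive)."""

    segments: dict[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS)
    )

    def __post_init__(self) -> None:
        for name, ranges in self.segments.items():
            seen: set[int] = set()
            for lo, hi in ranges:
                span = set(range(lo, hi + 1))
                if seen & span:
                    raise ValueError(f"segment {name}: overlapping ranges")
                seen |= span


@dataclass
class ProfileSeries:
    """Binned profile along z: centers, mean, dispersion and counts."""

    z_centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z_nm": self.z_centers, "mean": self.mean, "sd": self.sd, "n": self.n}
        )


def _segment_calpha_ids(
    reference: StructureModel, chain_id: str | None, ranges
) -> np.ndarray:
    numbers = [n for lo, hi in ranges for n in range(lo, hi + 1)]
    sub = reference.select(chain_id=chain_id, residue_numbers=numbers, atom_names=["CA"])
    if sub.empty:
        raise SelectionError(f"no Calpha atoms for residue ranges {ranges}")
    return sub["atom_id"].to_numpy(int)


def segment_rmsd(
    trajectories: Sequence[Trajectory],
    reference: StructureModel,
    segments: SegmentSet | None = None,
    fit_selection: Sequence[int] | None = None,
    chain_id: str | None = None,
    time_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Mean Calpha RMSD per named segment, averaged over frames, with SEM
    across the supplied protomer trajectories.

    Every frame is first superposed onto the reference using
    ``fit_selection`` (default: the TM-bundle Calpha atoms), then each
    segment's RMSD is measured without further fitting.
    """
    segments = segments or SegmentSet()
    if fit_selection is None:
        fit_selection = reference.calpha_ids(chain_id=chain_id)
    seg_ids = {
        name: _segment_calpha_ids(reference, chain_id, ranges)
        for name, ranges in segments.segments.items()
    }
    per_traj: dict[str, list[float]] = {name: [] for name in seg_ids}
    for traj in trajectories:
        if time_range is None:
            frame_idx = range(traj.n_frames)
        else:
            t = traj.times_ns
            frame_idx = np.nonzero((t >= time_range[0]) & (t < time_range[1]))[0]
        sums = {name: 0.0 for name in seg_ids}
        count = 0
        for i in frame_idx:
            res = superpose(traj.coords[i], traj.atom_ids, reference, fit_selection)
            fitted = res.apply(traj.coords[i])
            for name, ids in seg_ids.items():
                idx = traj.atom_index(ids)
                ref = reference.positions_for(ids)
                d = fitted[idx] - ref
                sums[name] += float(np.sqrt((d**2).sum(axis=1).mean()))
            count += 1
        if count == 0:
            raise SelectionError("trajectory has no frames in the analysis range")
        for name in seg_ids:
            per_traj[name].append(sums[name] / count)
    rows = []
    for name, vals in per_traj.items():
        vals = np.asarray(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows.append({"segment": name, "mean_rmsd_nm": float(vals.mean()), "sem_nm": sem, "n": vals.size})
    return pd.DataFrame(rows)


def dipole_tilt_profile(
    traj: Trajectory,
    water_triplets: Sequence[tuple[int, int, int]],
    z_edges: np.ndarray,
    charges: Mapping[int, float] | None = None,
    z_reference: float = 0.0,
) -> ProfileSeries:
    """Tilt of the water dipole to the membrane normal, binned along z.

    ``water_triplets`` lists (O, H1, H2) atom ids per water.  The dipole is
    the charge-weighted sum when ``charges`` gives per-atom partial
    charges, otherwise the O -> (H,H midpoint) bisector.  Tilt is the angle
    to +z in degrees [0, 180]; the water's z is the oxygen position
    relative to ``z_reference``.
    """
    z_edges = np.asarray(z_edges, float)
    nbin = z_edges.size - 1
    acc = np.zeros(nbin)
    acc2 = np.zeros(nbin)
    cnt = np.zeros(nbin, dtype=int)
    for (o_id, h1_id, h2_id) in water_triplets:
        idx = traj.atom_index([o_id, h1_id, h2_id])
        o = traj.coords[:, idx[0], :]
        h1 = traj.coords[:, idx[1], :]
        h2 = traj.coords[:, idx[2], :]
        if charges is not None:
            q_o = charges[o_id]
            q1 = charges[h1_id]
            q2 = charges[h2_id]
            dip = q_o * o + q1 * h1 + q2 * h2 - (q_o + q1 + q2) * o
        else:
            dip = 0.5 * (h1 + h2) - o
        norm = np.linalg.norm(dip, axis=1)
        ok = norm > 1e-12
        cos = np.clip(dip[:, 2] / np.where(ok, norm, 1.0), -1.0, 1.0)
        tilt = np.degrees(np.arccos(cos))
        zw = o[:, 2] - z_reference
        which = np.searchsorted(z_edges, zw, side="right") - 1
        valid = ok & (which >= 0) & (which < nbin)
        np.add.at(acc, which[valid], tilt[valid])
        np.add.at(acc2, which[valid], tilt[valid] ** 2)
        np.add.at(cnt, which[valid], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        var = np.where(cnt > 1, acc2 / np.maximum(cnt, 1) - mean**2, np.nan)
    sd = np.sqrt(np.clip(var, 0.0, None))
    centers = 0.5 * (z_edges[:-1] + z_edges[1:])
    return ProfileSeries(z_centers=centers, mean=mean, sd=sd, n=cnt)


# -- hydrogen bonds ---------------------------------------------------------

_ACCEPTOR_ELEMENTS = {"O", "N"}
_H_COVALENT_CUTOFF = 0.12  # nm, to attach hydrogens to their donor heavy atom


def _residue_frame(structure: StructureModel, chain_id, residue_number):
    sub = structure.select(chain_id=chain_id, residue_numbers=[residue_number])
    if sub.empty:
        raise SelectionError(f"residue {residue_number} not found")
    return sub


def water_hbond_counts(
    traj: Trajectory,
    structure: StructureModel,
    residues: Sequence[tuple[str | None, int]],
    water_triplets: Sequence[tuple[int, int, int]],
    d_da_max: float = 0.35,
    angle_dha_min: float = 150.0,
) -> pd.DataFrame:
    """Mean number of water-residue hydrogen bonds per residue per frame.

    A bond requires donor-acceptor distance <= ``d_da_max`` and a
    D-H...A angle >= ``angle_dha_min`` (both water and residue can donate
    or accept; residue donors are N/O heavy atoms with a covalently
    attached hydrogen, acceptors are all N/O heavy atoms).  Raises
    :class:`CapabilityError` when the residues carry no hydrogens at all
    while donor geometry is required.
    """
    if not water_triplets:
        raise SelectionError("no waters supplied")
    wat = np.asarray(water_triplets, dtype=int)

    rows = []
    for chain_id, resnum in residues:
        sub = _residue_frame(structure, chain_id, resnum)
        heavies = sub[sub["element"].str.upper().isin(_ACCEPTOR_ELEMENTS)]
        hydros = sub[sub["element"].str.upper().eq("H") | sub["atom_name"].str.startswith("H")]
        res_has_h = not hydros.empty
        res_all_h = structure.atoms["element"].str.upper().eq("H").any()
        if not res_all_h:
            raise CapabilityError(
                "topology carries no hydrogens; use distance-only descriptors instead"
            )
        acceptors = heavies["atom_id"].to_numpy(int)
        # donors: heavy N/O with an attached hydrogen (checked per frame 0)
        donor_pairs = []
        if res_has_h:
            hidx = traj.atom_index(hydros["atom_id"].to_numpy(int))
            didx = traj.atom_index(acceptors) if acceptors.size else np.empty(0, int)
            if acceptors.size and hydros.shape[0]:
                d0 = traj.coords[0]
                dmat = np.linalg.norm(
                    d0[didx][:, None, :] - d0[hidx][None, :, :], axis=-1
                )
                for a_i, h_i in zip(*np.nonzero(dmat < _H_COVALENT_CUTOFF)):
                    donor_pairs.append((acceptors[a_i], hydros["atom_id"].to_numpy(int)[h_i]))

        total = np.zeros(traj.n_frames)
        for f in range(traj.n_frames):
            c = traj.coords[f]
            ow = c[traj.atom_index(wat[:, 0])]
            h1 = c[traj.atom_index(wat[:, 1])]
            h2 = c[traj.atom_index(wat[:, 2])]
            # water as donor -> residue acceptor
            for acc_id in acceptors:
                a = c[traj.atom_index([acc_id])[0]]
                d = np.linalg.norm(ow - a, axis=1)
                close = np.nonzero(d <= d_da_max)[0]
                for wi in close:
                    for h in (h1[wi], h2[wi]):
                        if _dha_angle(ow[wi], h, a) >= angle_dha_min:
                            total[f] += 1
                            break
            # residue as donor -> water oxygen acceptor
            for d_id, h_id in donor_pairs:
                dpos = c[traj.atom_index([d_id])[0]]
                hpos = c[traj.atom_index([h_id])[0]]
                d = np.linalg.norm(ow - dpos, axis=1)
                for wi in np.nonzero(d <= d_da_max)[0]:
                    if _dha_angle(dpos, hpos, ow[wi]) >= angle_dha_min:
                        total[f] += 1
        mean = float(total.mean())
        sem = float(total.std(ddof=1) / np.sqrt(total.size)) if total.size > 1 else 0.0
        rows.append(
            {
                "residue_number": resnum,
                "chain_id": chain_id,
                "mean_hbonds": mean,
                "sem": sem,
                "criterion": f"d_DA<={d_da_max}nm, D-H...A>={angle_dha_min}deg",
            }
        )
    return pd.DataFrame(rows)


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1 = d - h
    v2 = a - h
    cos = float(
        np.dot(v1, v2) / max(np.linalg.norm(v1) * np.linalg.norm(v2), 1e-12)
    )
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
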