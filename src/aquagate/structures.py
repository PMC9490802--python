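"""Structure/trajectory data model, readers, and rigid-body superposition.

Internal length unit is nm throughout the package; PDB/GRO coordinates
(handled through MDAnalysis, which reports angstrom) are converted on read.
A portable plain-text trajectory format (CSV with columns
``frame,time_ps,atom_id,x_nm,y_nm,z_nm``) is first class so that synthetic
fixtures never need a binary MD format; XTC/DCD/TRR are supported through
MDAnalysis when a binary trajectory is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    OrderingError,
    ParseError,
    StructuralError,
    UnderdeterminedFitError,
)

#: Calpha transmembrane-bundle residue ranges (inclusive) used for the
#: default superposition selection of one protomer.
TM_BUNDLE_RANGES: tuple[tuple[int, int], ...] = (
    (7, 35),
    (41, 63),
    (69, 79),
    (83, 119),
    (145, 167),
    (178, 196),
    (204, 217),
    (232, 255),
)

ANGSTROM_PER_NM = 10.0

_ATOM_COLUMNS = [
    "atom_id",
    "atom_name",
    "residue_name",
    "residue_number",
    "chain_id",
    "element",
    "x",
    "y",
    "z",
]


@dataclass
class StructureModel:
    """A static set of atoms with coordinates in nm.

    ``atoms`` is a DataFrame with columns atom_id, atom_name, residue_name,
    residue_number, chain_id, element, x, y, z.  The key
    (chain_id, residue_number, atom_name) is unique.
    """

    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns {missing}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates in structure")
        key = self.atoms[["chain_id", "residue_number", "atom_name"]]
        if key.duplicated().any():
            raise ValueError("(chain_id, residue_number, atom_name) not unique")
        self.atoms = self.atoms.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinates in nm."""
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    @property
    def atom_ids(self) -> np.ndarray:
        return self.atoms["atom_id"].to_numpy(int)

    def positions_for(self, atom_ids: Sequence[int]) -> np.ndarray:
        idx = self._indices_for(atom_ids)
        return self.positions[idx]

    def _indices_for(self, atom_ids: Sequence[int]) -> np.ndarray:
        lookup = pd.Index(self.atoms["atom_id"])
        idx = lookup.get_indexer(np.asarray(list(atom_ids), dtype=int))
        if np.any(idx < 0):
            bad = np.asarray(list(atom_ids))[idx < 0]
            raise StructuralError(f"atom ids not in structure: {bad.tolist()}")
        return idx

    def select(
        self,
        chain_id: str | None = None,
        residue_numbers: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
    ) -> pd.DataFrame:
        """Subset of the atom table by chain, residue number and atom name."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain_id is not None:
            mask &= (self.atoms["chain_id"] == chain_id).to_numpy()
        if residue_numbers is not None:
            mask &= self.atoms["residue_number"].isin(list(residue_numbers)).to_numpy()
        if atom_names is not None:
            mask &= self.atoms["atom_name"].isin(list(atom_names)).to_numpy()
        return self.atoms[mask]

    def calpha_ids(
        self,
        chain_id: str | None = None,
        residue_ranges: Iterable[tuple[int, int]] = TM_BUNDLE_RANGES,
    ) -> np.ndarray:
        """Atom ids of Calpha atoms within the given residue ranges."""
        numbers: list[int] = []
        for lo, hi in residue_ranges:
            numbers.extend(range(lo, hi + 1))
        sub = self.select(chain_id=chain_id, residue_numbers=numbers, atom_names=["CA"])
        return sub["atom_id"].to_numpy(int)


@dataclass
class Trajectory:
    """Time-ordered coordinate frames (nm) for a declared atom subset."""

    atom_ids: np.ndarray  # (n_atoms,)
    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    frame_period_ps: float = 10.0
    time_origin_ns: float = 0.0
    box: np.ndarray | None = None  # (n_frames, 3) nm or None

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] != self.atom_ids.size:
            raise StructuralError(
                f"frame atom count {self.coords.shape[1]} != declared "
                f"{self.atom_ids.size}"
            )
        if self.frame_period_ps <= 0:
            raise ValueError("frame_period_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atom_ids.size

    @property
    def times_ns(self) -> np.ndarray:
        return self.time_origin_ns + np.arange(self.n_frames) * (
            self.frame_period_ps / 1000.0
        )

    def atom_index(self, atom_ids: Sequence[int]) -> np.ndarray:
        lookup = pd.Index(self.atom_ids)
        idx = lookup.get_indexer(np.asarray(list(atom_ids), dtype=int))
        if np.any(idx < 0):
            bad = np.asarray(list(atom_ids))[idx < 0]
            raise StructuralError(f"atom ids not in trajectory: {bad.tolist()}")
        return idx


@dataclass
class SuperpositionResult:
    """Rigid transform (rotation then translation) fitting a frame onto a
    reference; ``transform(x) = x @ rotation.T + translation``."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    fit_rmsd: float  # nm over the selection
    selection: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _mda_universe(path: Path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path))


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or GRO file into a :class:`StructureModel` (nm units).

    ``format`` is inferred from the suffix when omitted.  Raises
    :class:`ParseError` on empty or malformed files and ``FileNotFoundError``
    when the path does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"pdb", "gro"}:
        raise ParseError(f"unsupported structure format {fmt!r}")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    try:
        u = _mda_universe(path)
    except Exception as exc:  # MDAnalysis raises many concrete types
        raise ParseError(f"{path}: {exc}") from exc
    ag = u.atoms
    if len(ag) == 0:
        raise ParseError(f"{path}: no atoms parsed")

    def _attr(name: str, default):
        try:
            return getattr(ag, name)
        except Exception:
            return [default] * len(ag)

    names = [str(n) for n in _attr("names", "")]
    elements = [str(e) for e in _attr("elements", "")]
    if not any(elements):
        # fall back to the leading letter(s) of the atom name
        elements = ["".join(c for c in n if c.isalpha())[:1] for n in names]
    chains = [str(c) for c in _attr("chainIDs", "")]
    if not any(chains):
        chains = [str(s).strip() if str(s) != "SYSTEM" else "" for s in _attr("segids", "")]
    table = pd.DataFrame(
        {
            "atom_id": np.asarray(_attr("ids", 0), dtype=int),
            "atom_name": names,
            "residue_name": [str(r) for r in ag.resnames],
            "residue_number": np.asarray(ag.resids, dtype=int),
            "chain_id": chains,
            "element": elements,
            "x": ag.positions[:, 0] / ANGSTROM_PER_NM,
            "y": ag.positions[:, 1] / ANGSTROM_PER_NM,
            "z": ag.positions[:, 2] / ANGSTROM_PER_NM,
        }
    )
    # drop alternate locations beyond the first
    table = table.drop_duplicates(
        subset=["chain_id", "residue_number", "atom_name"], keep="first"
    )
    try:
        return StructureModel(table)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_trajectory_csv(traj: Trajectory, path: str | Path, decimals: int = 6) -> None:
    """Write the portable CSV trajectory format.

    Coordinates are rounded to ``decimals`` places; reading the file back
    reproduces the written decimals exactly.
    """
    path = Path(path)
    n_f, n_a = traj.n_frames, traj.n_atoms
    frame_col = np.repeat(np.arange(n_f), n_a)
    time_col = np.repeat(
        traj.time_origin_ns * 1000.0 + np.arange(n_f) * traj.frame_period_ps, n_a
    )
    atom_col = np.tile(traj.atom_ids, n_f)
    xyz = traj.coords.reshape(-1, 3)
    df = pd.DataFrame(
        {
            "frame": frame_col,
            "time_ps": time_col,
            "atom_id": atom_col,
            "x_nm": xyz[:, 0],
            "y_nm": xyz[:, 1],
            "z_nm": xyz[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")


def _read_portable_csv(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (times_ps, atom_ids, coords) from one portable CSV file."""
    df = pd.read_csv(path)
    required = {"frame", "time_ps", "atom_id", "x_nm", "y_nm", "z_nm"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    frames = np.unique(df["frame"].to_numpy())
    first = df[df["frame"] == frames[0]].sort_values("atom_id")
    atom_ids = first["atom_id"].to_numpy(int)
    n_a = atom_ids.size
    times = np.empty(frames.size)
    coords = np.empty((frames.size, n_a, 3))
    for k, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values("atom_id")
        if sub.shape[0] != n_a or not np.array_equal(sub["atom_id"].to_numpy(int), atom_ids):
            raise StructuralError(f"{path}: frame {f} atom set differs from frame {frames[0]}")
        t = sub["time_ps"].to_numpy(float)
        if not np.allclose(t, t[0]):
            raise ParseError(f"{path}: inconsistent time within frame {f}")
        times[k] = t[0]
        coords[k] = sub[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
    return times, atom_ids, coords


def read_trajectory(
    paths: str | Path | Sequence[str | Path],
    topology: StructureModel | None = None,
    format: str | None = None,
    frame_period_ps: float | None = None,
) -> Trajectory:
    """Read one or more trajectory segments into a single :class:`Trajectory`.

    The portable CSV format needs no topology; binary formats (XTC/DCD/TRR)
    are read through MDAnalysis using the topology's atom count.  Multiple
    segments are concatenated and must have continuous, strictly increasing
    times.  ``frame_period_ps`` overrides the period inferred from the file.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no trajectory paths given")

    all_times: list[np.ndarray] = []
    all_coords: list[np.ndarray] = []
    atom_ids: np.ndarray | None = None
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
        fmt = (format or p.suffix.lstrip(".")).lower()
        if fmt == "csv":
            times, ids, coords = _read_portable_csv(p)
        elif fmt in {"xtc", "trr", "dcd"}:
            if topology is None:
                raise StructuralError("binary trajectory formats require a topology")
            import MDAnalysis as mda

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe.empty(topology.n_atoms, trajectory=True)
                u.load_new(str(p))
            ids = topology.atom_ids
            times = np.array([ts.time for ts in u.trajectory], float)
            coords = np.array(
                [u.trajectory[i].positions / ANGSTROM_PER_NM for i in range(len(u.trajectory))]
            )
        else:
            raise ParseError(f"unsupported trajectory format {fmt!r}")
        if atom_ids is None:
            atom_ids = ids
        elif not np.array_equal(atom_ids, ids):
            raise StructuralError("trajectory segments declare different atom sets")
        all_times.append(times)
        all_coords.append(coords)

    times = np.concatenate(all_times)
    coords = np.concatenate(all_coords)
    if times.size > 1:
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise OrderingError("trajectory times are not strictly increasing")
        period = float(np.median(dt))
        if not np.allclose(dt, period, rtol=1e-6, atol=1e-9):
            raise OrderingError("trajectory times are not uniformly spaced")
    else:
        period = frame_period_ps if frame_period_ps is not None else 10.0
    if frame_period_ps is not None:
        period = frame_period_ps
    if topology is not None and atom_ids is not None:
        topology._indices_for(atom_ids)  # validates membership
    return Trajectory(
        atom_ids=atom_ids,
        coords=coords,
        frame_period_ps=period,
        time_origin_ns=float(times[0]) / 1000.0,
    )


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def superpose(
    frame_coords: np.ndarray,
    frame_atom_ids: Sequence[int],
    reference: StructureModel,
    selection: Sequence[int],
) -> SuperpositionResult:
    """Least-squares (Kabsch) fit of a frame onto the reference.

    The transform minimizes the mass-unweighted RMSD over ``selection``
    (atom ids present in both the frame and the reference); applying the
    returned transform to the frame coordinates realizes ``fit_rmsd``.
    """
    selection = np.asarray(list(selection), dtype=int)
    if selection.size < 3:
        raise UnderdeterminedFitError(
            f"superposition needs >= 3 atoms, got {selection.size}"
        )
    frame_coords = np.asarray(frame_coords, float)
    lookup = pd.Index(np.asarray(list(frame_atom_ids), dtype=int))
    idx = lookup.get_indexer(selection)
    if np.any(idx < 0):
        raise StructuralError("selection atoms missing from frame")
    mobile = frame_coords[idx]
    ref = reference.positions_for(selection)

    mob_c = mobile.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_c, mobile - mob_c)
    rmat = rot.as_matrix()
    translation = ref_c - rmat @ mob_c
    rmsd = float(rssd) / np.sqrt(selection.size)
    return SuperpositionResult(
        rotation=rmat,
        translation=translation,
        fit_rmsd=rmsd,
        selection=selection,
    )


def fit_trajectory(
    traj: Trajectory, reference: StructureModel, selection: Sequence[int]
) -> tuple[Trajectory, list[SuperpositionResult]]:
    """Superpose every frame onto the reference; returns the fitted
    trajectory and the per-frame transforms."""
    results = []
    fitted = np.empty_like(traj.coords)
    for i in range(traj.n_frames):
        res = superpose(traj.coords[i], traj.atom_ids, reference, selection)
        fitted[i] = res.apply(traj.coords[i])
        results.append(res)
    return (
        Trajectory(
            atom_ids=traj.atom_ids,
            coords=fitted,
            frame_period_ps=traj.frame_period_ps,
            time_origin_ns=traj.time_origin_ns,
            box=traj.box,
        ),
        results,
    )
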