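"""Paired property/flux interval scheme and model-input assembly.

The statistical model relates the conformational state of the pore in a
5-ns *property* window to the number of waters crossing in a 5-ns *flux*
window that starts 3 ns later (2 ns overlap) — encoding that conformation
precedes transport.  Consecutive paired windows advance by a configurable
stride whose default, 10/3 ns, lays 599 paired windows over 2,000 ns of
analyzed time per pore.

A paired window is emitted whenever its property window lies fully inside
the analysis range; the trailing flux windows may overhang the nominal
analysis end by up to ``lag`` ns, so the event series must extend that far
(with a 3-mus trajectory analyzed from 1 mus this is the last ~1.3 ns).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AssemblyError, ConfigurationError
from .gating import StateTrace
from .permeation import FluxSeries, flux_in_windows

DEFAULT_STRIDE_NS = 10.0 / 3.0


@dataclass
class IntervalScheme:
    """Timing of the paired property/flux windows (all units ns)."""

    property_len: float = 5.0
    flux_len: float = 5.0
    lag: float = 3.0
    stride: float = DEFAULT_STRIDE_NS
    analysis_start: float = 1000.0
    analysis_end: float = 3000.0

    def __post_init__(self) -> None:
        if self.stride <= 0:
            raise ConfigurationError("stride must be positive")
        if not 0 < self.lag < self.property_len:
            raise ConfigurationError("lag must satisfy 0 < lag < property_len")
        if self.property_len <= 0 or self.flux_len <= 0:
            raise ConfigurationError("window lengths must be positive")
        if self.analysis_end <= self.analysis_start:
            raise ConfigurationError("empty analysis range")

    @property
    def overlap(self) -> float:
        return self.property_len - self.lag

    @property
    def block_len(self) -> float:
        """Span of one paired block (3 ns property alone, 2 ns overlap,
        3 ns flux alone with the defaults: 8 ns)."""
        return max(self.property_len, self.lag + self.flux_len)


def build_windows(
    scheme: IntervalScheme,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Paired (property, flux) half-open windows for the scheme.

    Returns an empty list when the analysis range is shorter than one
    paired block (property + lag + flux - overlap).
    """
    span = scheme.analysis_end - scheme.analysis_start
    if span < scheme.block_len - 1e-9:
        return []
    pairs = []
    k = 0
    while True:
        t = scheme.analysis_start + k * scheme.stride
        if t + scheme.property_len > scheme.analysis_end + 1e-9:
            break
        prop = (t, t + scheme.property_len)
        flux = (t + scheme.lag, t + scheme.lag + scheme.flux_len)
        pairs.append((prop, flux))
        k += 1
    return pairs


def phase_fractions(
    trace: StateTrace, window: tuple[float, float]
) -> dict[str, float]:
    """Fraction of frames per state within the half-open window (ns)."""
    sl = trace.frame_slice(*window)
    states = trace.states[sl]
    if states.size == 0:
        raise ConfigurationError(f"window {window} contains no frames")
    counts = np.bincount(states, minlength=len(trace.state_labels))
    fracs = counts / counts.sum()
    return {lab: float(f) for lab, f in zip(trace.state_labels, fracs)}


def predictor_column(definition_id: str, state: str) -> str:
    return f"{definition_id}.{state}"


def _fractions_matrix(trace: StateTrace, windows: Sequence[tuple[float, float]]) -> np.ndarray:
    """(n_windows, n_states) phase-fraction matrix, computed via cumulative
    state counts so long traces stay cheap."""
    n_states = len(trace.state_labels)
    onehot_cum = np.zeros((trace.n_frames + 1, n_states), dtype=np.int64)
    eye = np.eye(n_states, dtype=np.int64)
    onehot_cum[1:] = np.cumsum(eye[trace.states], axis=0)
    out = np.empty((len(windows), n_states))
    for k, win in enumerate(windows):
        sl = trace.frame_slice(*win)
        n = sl.stop - sl.start
        if n <= 0:
            raise ConfigurationError(f"window {win} contains no frames")
        out[k] = (onehot_cum[sl.stop] - onehot_cum[sl.start]) / n
    return out


def assemble(
    traces: Mapping[tuple, Mapping[str, StateTrace]],
    flux: Mapping[tuple, FluxSeries] | Mapping[tuple, Sequence[int]],
    scheme: IntervalScheme,
    drop_reference: bool = True,
) -> pd.DataFrame:
    """Assemble the model's interval dataset.

    ``traces`` maps pore_id -> {definition_id -> StateTrace}; ``flux`` maps
    pore_id -> FluxSeries (events are counted per flux window, total mode)
    or directly to precomputed per-window counts.  One row is produced per
    pore per paired window.  With ``drop_reference`` (the default, k-1
    encoding) each residue contributes one predictor column per
    non-reference state, named like ``r206.s290_360``; the diagnostic mode
    keeps all states, whose fractions then sum to 1 per residue and row.
    """
    windows = build_windows(scheme)
    if not windows:
        raise ConfigurationError("scheme produces no paired windows")
    prop_windows = [p for p, _ in windows]
    flux_windows = [f for _, f in windows]

    pores = list(traces.keys())
    if not pores:
        raise AssemblyError("no pores in traces")
    first = traces[pores[0]]
    residue_ids = list(first.keys())
    rows = []
    for pore in pores:
        per_res = traces[pore]
        missing = [r for r in residue_ids if r not in per_res]
        if missing:
            raise AssemblyError(f"pore {pore}: missing traces for {missing}")
        if pore not in flux:
            raise AssemblyError(f"pore {pore}: missing flux series")
        fl = flux[pore]
        if isinstance(fl, FluxSeries):
            counts = flux_in_windows(fl, flux_windows, mode="total", allow_overlap=True)
        else:
            counts = np.asarray(fl, dtype=int)
            if counts.size != len(windows):
                raise AssemblyError(
                    f"pore {pore}: {counts.size} flux counts for {len(windows)} windows"
                )
        block: dict[str, np.ndarray] = {}
        for rid in residue_ids:
            tr = per_res[rid]
            mat = _fractions_matrix(tr, prop_windows)
            labels = tr.state_labels
            for j, lab in enumerate(labels):
                block[predictor_column(rid, lab)] = mat[:, j]
        df = pd.DataFrame(block)
        df.insert(0, "variant", pore[0])
        df.insert(1, "replica", pore[1])
        df.insert(2, "chain", pore[2])
        df.insert(3, "interval", np.arange(len(windows)))
        df.insert(4, "t_start_ns", [p[0] for p in prop_windows])
        df["flux_count"] = counts
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out["pore_id"] = (
        out["variant"].astype(str)
        + "/"
        + out["replica"].astype(str)
        + "/"
        + out["chain"].astype(str)
    )
    if drop_reference:
        drop_cols = []
        for rid in residue_ids:
            tr = traces[pores[0]][rid]
            ref = _reference_state_of(tr, rid)
            drop_cols.append(predictor_column(rid, ref))
        out = out.drop(columns=drop_cols)
    return out


# reference states are attached to definitions, not traces; assemble accepts
# traces from classify() which carry labels only, so the convention is that
# the reference label is recorded on the trace via attribute when available,
# falling back to the last label (the registry places the open/reference
# state last for distances and dihedral bins alike).
def _reference_state_of(trace: StateTrace, rid: str) -> str:
    ref = getattr(trace, "reference_state", None)
    return ref if ref is not None else trace.state_labels[-1]


def predictor_columns(df: pd.DataFrame) -> list[str]:
    """Phase-percentage predictor columns of an assembled dataset."""
    meta = {"variant", "replica", "chain", "interval", "t_start_ns", "flux_count", "pore_id"}
    return [c for c in df.columns if c not in meta]
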