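"""Terminal base-pair unwrapping counter.

A terminal base pair is *unwrapped* when its minimum heavy-atom distance to
the histone core exceeds the contact cutoff (6.0 A by default).  Per DNA
end, the count N is the maximal run of consecutive terminal base pairs all
beyond the cutoff, ending at the first base pair at or below it — an
interior base pair beyond the cutoff (a bulge) is never counted.  A base
pair at exactly the cutoff stops the run (counted as wrapped): the
defining two-sided condition (> cutoff for the N outer pairs, < cutoff for
pair N+1) leaves equality open, and stopping is the conservative reading.
The total is the sum of the entry- and exit-side counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import SelectionError, TopologyError
from .geometry import SeriesStat
from .model import NucleoAssembly, RegionAnnotation, Selection, Trajectory, resolve_selection

DEFAULT_CUTOFF = 6.0


@dataclass
class UnwrapRecord:
    """Unwrapped base-pair counts for one conformation."""

    frame_index: int
    n_entry: int
    n_exit: int
    n_total: int
    full_detachment: bool = False
    bp_min_distances: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.n_total != self.n_entry + self.n_exit:
            raise ValueError("inconsistent UnwrapRecord: n_total != n_entry + n_exit")


def default_core_selection(assembly: NucleoAssembly,
                           exclude_regions: Optional[Sequence[RegionAnnotation]] = None
                           ) -> np.ndarray:
    """Heavy atoms of all histone chains, minus any excluded (tail) regions.

    The histone core is taken as every histone-role chain by default; pass
    annotated tail regions in ``exclude_regions`` to strip them, since
    flexible tails materially change minimum distances.
    """
    idx = Selection.histone_core().resolve(assembly)
    if exclude_regions:
        drop = np.zeros(assembly.n_atoms, dtype=bool)
        for region in exclude_regions:
            try:
                drop[Selection.region(region).resolve(assembly)] = True
            except SelectionError:
                continue  # region absent from this assembly
        idx = idx[~drop[idx]]
        if idx.size == 0:
            raise SelectionError("core selection empty after region exclusion")
    return idx


def bp_min_distance(assembly: NucleoAssembly, bp_index: int,
                    core_sel=None, _tree: Optional[cKDTree] = None) -> float:
    """Minimum heavy-atom distance (A) from base pair ``bp_index`` to the core."""
    bp_idx = assembly.bp_atom_indices(bp_index, heavy=True)
    if bp_idx.size == 0:
        raise TopologyError(f"base pair {bp_index} has no heavy atoms")
    tree = _tree
    if tree is None:
        core_idx = (default_core_selection(assembly) if core_sel is None
                    else resolve_selection(assembly, core_sel))
        tree = cKDTree(assembly.coord[core_idx])
    d, _ = tree.query(assembly.coord[bp_idx], k=1)
    return float(np.min(d))


def count_unwrapped(assembly: NucleoAssembly, core_sel=None,
                    cutoff: float = DEFAULT_CUTOFF,
                    diagnostics: bool = False,
                    frame_index: int = 0,
                    _core_tree: Optional[cKDTree] = None) -> UnwrapRecord:
    """Count unwrapped base pairs at the entry and exit ends of one conformation."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n_bp = assembly.n_bp
    if n_bp == 0:
        raise TopologyError("assembly has no base-pair ordering")
    if _core_tree is not None:
        tree = _core_tree
    else:
        core_idx = (default_core_selection(assembly) if core_sel is None
                    else resolve_selection(assembly, core_sel))
        tree = cKDTree(assembly.coord[core_idx])

    cache: dict = {}

    def dist(bp: int) -> float:
        if bp not in cache:
            cache[bp] = bp_min_distance(assembly, bp, _tree=tree)
        return cache[bp]

    n_entry = 0
    while n_entry < n_bp and dist(n_entry + 1) > cutoff:
        n_entry += 1
    if n_entry == n_bp:
        record = UnwrapRecord(frame_index, n_bp, 0, n_bp, full_detachment=True)
    else:
        n_exit = 0
        while n_exit < n_bp - n_entry and dist(n_bp - n_exit) > cutoff:
            n_exit += 1
        record = UnwrapRecord(frame_index, n_entry, n_exit, n_entry + n_exit)
    if diagnostics:
        record.bp_min_distances = np.array([dist(i) for i in range(1, n_bp + 1)])
    return record


def unwrap_series(traj: Trajectory, core_sel=None,
                  cutoff: float = DEFAULT_CUTOFF,
                  diagnostics: bool = False) -> Tuple[List[UnwrapRecord], SeriesStat]:
    """Per-frame unwrapped counts plus the n_total summary series.

    When the core atoms do not move over the trajectory (synthetic breathing,
    restrained cores) their KD-tree is built once and shared across frames.
    """
    core_idx = (default_core_selection(traj.topology) if core_sel is None
                else resolve_selection(traj.topology, core_sel))
    core_coords = traj.coords[:, core_idx]
    shared_tree = None
    if traj.n_frames > 1 and (core_coords == core_coords[0]).all():
        shared_tree = cKDTree(core_coords[0])
    records = [count_unwrapped(traj.frame(t), core_sel=core_idx, cutoff=cutoff,
                               diagnostics=diagnostics, frame_index=t,
                               _core_tree=shared_tree)
               for t in range(traj.n_frames)]
    stat = SeriesStat.from_values([r.n_total for r in records],
                                  metric="n_unwrapped_total", cutoff=cutoff)
    return records, stat


def aggregate_unwrap_replicas(series: Sequence[SeriesStat]) -> SeriesStat:
    """Cross-replica mean +/- population SD of the per-frame total counts."""
    return SeriesStat.from_replicas(series, metric="n_unwrapped_total")


def records_to_frame(records: Sequence[UnwrapRecord]) -> pd.DataFrame:
    """Tabular per-frame view: (frame, n_entry, n_exit, n_total)."""
    return pd.DataFrame({
        "frame": [r.frame_index for r in records],
        "n_entry": [r.n_entry for r in records],
        "n_exit": [r.n_exit for r in records],
        "n_total": [r.n_total for r in records],
    })
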