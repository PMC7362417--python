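"""Geometric observables: RMSD, end-to-end distance, Rg, RMSF, angles.

All distances are in Angstrom and angles in degrees.  Rigid-body
superposition is the standard least-squares fit (proper rotations only,
via :func:`scipy.spatial.transform.Rotation.align_vectors`).  Replica
aggregation uses the population standard deviation across replicas, the
convention for error shading over a small fixed set of independent runs;
the choice is recorded in the metadata of every SeriesStat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import GeometryError, SelectionError, TopologyError
from .model import NucleoAssembly, Selection, Trajectory, resolve_selection

ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
               "P": 30.974, "S": 32.06}


@dataclass
class SeriesStat:
    """A per-frame series with its summary statistics.

    For multi-replica results, ``replica_values`` holds the per-replica
    series (R, n_frames), and ``frame_mean`` / ``frame_sd`` the per-frame
    cross-replica mean and population SD.
    """

    values: np.ndarray
    mean: float
    sd: float
    replica_values: Optional[np.ndarray] = None
    frame_mean: Optional[np.ndarray] = None
    frame_sd: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_values(cls, values, **metadata) -> "SeriesStat":
        v = np.asarray(values, dtype=float)
        return cls(values=v, mean=float(v.mean()), sd=float(v.std(ddof=0)),
                   metadata={"sd_convention": "population", **metadata})

    @classmethod
    def from_replicas(cls, replicas: Sequence, **metadata) -> "SeriesStat":
        """Cross-replica aggregation: per-frame mean and population SD."""
        arrs = [np.asarray(getattr(r, "values", r), dtype=float) for r in replicas]
        n = {a.shape for a in arrs}
        if len(n) != 1:
            raise TopologyError("replica series have unequal lengths")
        mat = np.stack(arrs)
        fmean = mat.mean(axis=0)
        fsd = mat.std(axis=0, ddof=0)
        return cls(values=fmean, mean=float(fmean.mean()), sd=float(fmean.std(ddof=0)),
                   replica_values=mat, frame_mean=fmean, frame_sd=fsd,
                   metadata={"sd_convention": "population",
                             "n_replicas": mat.shape[0], **metadata})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"frame": np.arange(len(self.values)),
                           "value": self.values})
        if self.frame_sd is not None:
            df["sd_across_replicas"] = self.frame_sd
        return df


# ---------------------------------------------------------------------------
# superposition


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed copy of ``mobile``; reflections are never
    produced.  Requires >= 3 non-degenerate points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise SelectionError("superposition point sets differ in shape")
    if mobile.shape[0] < 3:
        raise SelectionError("underdetermined fit: need >= 3 atoms in fit selection")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    return rot.apply(mobile - mob_c) + ref_c


def _superpose_frame(frame_coords, ref_coords, fit_idx):
    """Fit on fit_idx, apply the transform to the whole frame."""
    mob = frame_coords[fit_idx]
    ref = ref_coords[fit_idx]
    if len(fit_idx) < 3:
        raise SelectionError("underdetermined fit: need >= 3 atoms in fit selection")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    return rot.apply(frame_coords - mob_c) + ref_c


# ---------------------------------------------------------------------------
# metrics


def rmsd_series(traj: Trajectory, sel=None,
                ref: Union[int, NucleoAssembly] = 0,
                fit_sel=None, superpose_fit: bool = True) -> SeriesStat:
    """Per-frame RMSD (A) over ``sel`` after least-squares fitting on ``fit_sel``.

    ``ref`` is a frame index or an assembly sharing the topology.
    ``fit_sel`` defaults to ``sel`` (e.g. fit and measure on all P atoms);
    pass ``superpose_fit=False`` for an identity fit (raw deviation).
    """
    topo = traj.topology
    sel_idx = resolve_selection(topo, sel)
    fit_idx = resolve_selection(topo, fit_sel) if fit_sel is not None else sel_idx
    ref_coords = traj.coords[ref] if isinstance(ref, (int, np.integer)) else ref.coord
    if ref_coords.shape != traj.coords[0].shape:
        raise SelectionError("reference does not match trajectory topology")
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        frame = traj.coords[t]
        if superpose_fit:
            frame = _superpose_frame(frame, ref_coords, fit_idx)
        d = frame[sel_idx] - ref_coords[sel_idx]
        out[t] = np.sqrt((d * d).sum(axis=1).mean())
    return SeriesStat.from_values(out, metric="rmsd", unit="A",
                                  fitted=bool(superpose_fit))


def end_to_end_series(traj: Trajectory) -> SeriesStat:
    """Distance (A) between the first P atom at the entry and at the exit."""
    i = traj.topology.entry_p_index
    j = traj.topology.exit_p_index
    d = np.linalg.norm(traj.coords[:, i] - traj.coords[:, j], axis=1)
    return SeriesStat.from_values(d, metric="end_to_end", unit="A")


def radius_of_gyration(frame: NucleoAssembly, sel=None,
                       mass_weighted: bool = False) -> float:
    """Rg (A) of the selected atoms: sqrt(sum w|r - rbar|^2 / sum w)."""
    idx = resolve_selection(frame, sel)
    coords = frame.coord[idx]
    if mass_weighted:
        elems = np.char.upper(np.asarray(frame.element[idx], dtype=str))
        w = np.array([ATOMIC_MASS.get(e, 12.011) for e in elems])
    else:
        w = np.ones(len(idx))
    center = (coords * w[:, None]).sum(axis=0) / w.sum()
    d2 = ((coords - center) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def rg_series(traj: Trajectory, sel=None, mass_weighted: bool = False) -> SeriesStat:
    vals = [radius_of_gyration(traj.frame(t), sel, mass_weighted)
            for t in range(traj.n_frames)]
    return SeriesStat.from_values(vals, metric="rg", unit="A")


def rmsf_per_residue(traj: Trajectory, sel=None, fit_sel=None,
                     superpose_fit: bool = True) -> pd.DataFrame:
    """Per-residue RMSF (A) about the mean structure.

    Frames are superposed on ``fit_sel`` in two passes (first onto frame 0,
    then onto the resulting mean structure) before fluctuations are taken;
    the per-residue value is the mean over that residue's selected atoms.
    Returns a DataFrame with columns (chain_id, res_id, res_name, rmsf).
    """
    if traj.n_frames < 2:
        raise TopologyError("RMSF needs >= 2 frames (degenerate trajectory)")
    topo = traj.topology
    sel_idx = resolve_selection(topo, sel)
    fit_idx = resolve_selection(topo, fit_sel) if fit_sel is not None else sel_idx

    coords = traj.coords
    if superpose_fit:
        aligned = np.stack([_superpose_frame(coords[t], coords[0], fit_idx)
                            for t in range(traj.n_frames)])
        mean1 = aligned.mean(axis=0)
        aligned = np.stack([_superpose_frame(aligned[t], mean1, fit_idx)
                            for t in range(traj.n_frames)])
    else:
        aligned = coords
    mean = aligned.mean(axis=0)
    fluct2 = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom
    atom_rmsf = np.sqrt(fluct2)

    rows = []
    keys = list(zip(topo.chain_id[sel_idx], topo.res_id[sel_idx]))
    seen = {}
    for pos, key in zip(sel_idx, keys):
        seen.setdefault(key, []).append(pos)
    for (cid, rid), atom_pos in seen.items():
        rows.append({"chain_id": cid, "res_id": int(rid),
                     "res_name": topo.res_name[atom_pos[0]],
                     "rmsf": float(atom_rmsf[atom_pos].mean())})
    return pd.DataFrame(rows)


def angle(p_a, p_b, p_c) -> float:
    """Angle (degrees, in [0, 180]) at vertex b between rays b->a and b->c."""
    a = np.asarray(p_a, dtype=float)
    b = np.asarray(p_b, dtype=float)
    c = np.asarray(p_c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("zero-length ray in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angle_series(traj: Trajectory, idx_a: int, idx_b: int, idx_c: int) -> SeriesStat:
    """Per-frame three-point angle over atom indices (e.g. named P1/P2/P4)."""
    vals = [angle(traj.coords[t, idx_a], traj.coords[t, idx_b], traj.coords[t, idx_c])
            for t in range(traj.n_frames)]
    return SeriesStat.from_values(vals, metric="angle", unit="deg")
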