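"""Heavy-atom contact statistics, per-residue profiles and the q factor.

A *contact* exists between two components when any pair of their heavy
atoms is closer than the cutoff (6.0 A by default, strict inequality).
Per-residue profiles are averaged over frames, then over the two copies of
the same histone, then reported as mean +/- population SD across replicas.
The q factor of a conformation is the fraction of a reference structure's
native contacts that are formed in that conformation; with the default
formation tolerance of 1.2 x cutoff it follows common native-contact
(Go-analysis) practice, and a tolerance factor of 1.0 recovers the strict
reference rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    DefinitionError,
    RangeError,
    SelectionError,
    TopologyError,
)
from .model import (
    NucleoAssembly,
    RegionAnnotation,
    Selection,
    Trajectory,
    resolve_selection,
)

DEFAULT_CUTOFF = 6.0

#: Region presets read off the H2A/H2A.B sequence comparison.  The L2
#: ranges are stated directly (H2A 74-KKTRII, H2A.B 78-GERNII); the H2A
#: C-terminal tail (107-129) and docking domain (80-106), and the H2A.B
#: docking (84-108) / C-terminal stub (109-114) / N-tail (1-8), follow the
#: domain-swap construct boundaries; the H3 alphaN helix (44-56) and the
#: H2A N-tail (1-12) are reconstructions anchored on the residues named in
#: the text (R49/R52/K56).  All are editable configuration, not fixed truth.
REGION_PRESETS = {
    "H2A": {"Nt": (1, 12), "L2": (74, 79), "docking": (80, 106), "Ct": (107, 129)},
    "H2A.B": {"Nt": (1, 8), "L2": (78, 83), "docking": (84, 108), "Ct": (109, 114)},
    "H3": {"alphaN": (44, 56)},
}


def preset_regions(histone_class: str) -> List[RegionAnnotation]:
    """RegionAnnotation list for one histone class from the shipped presets."""
    if histone_class not in REGION_PRESETS:
        raise ConfigurationError(f"no region presets for {histone_class!r}")
    return [RegionAnnotation(name=name, start=lo, end=hi, histone_class=histone_class)
            for name, (lo, hi) in REGION_PRESETS[histone_class].items()]


# ---------------------------------------------------------------------------
# pair counting


def _strict_pairs(coords_a: np.ndarray, coords_b: np.ndarray,
                  cutoff: float) -> Tuple[np.ndarray, np.ndarray]:
    """Index pairs (into a, into b) with distance strictly below cutoff.

    KD-tree ball queries are inclusive (<=), so candidates at exactly the
    cutoff are re-checked with exact distances and dropped.
    """
    tree_b = cKDTree(coords_b)
    neighbors = cKDTree(coords_a).query_ball_tree(tree_b, r=cutoff)
    ia, ib = [], []
    for i, lst in enumerate(neighbors):
        for j in lst:
            ia.append(i)
            ib.append(j)
    if not ia:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    ia = np.asarray(ia)
    ib = np.asarray(ib)
    d = np.linalg.norm(coords_a[ia] - coords_b[ib], axis=1)
    keep = d < cutoff
    return ia[keep], ib[keep]


def count_contacts(frame: NucleoAssembly, sel_a, sel_b,
                   cutoff: float = DEFAULT_CUTOFF) -> int:
    """Number of heavy-atom pairs between two disjoint selections within cutoff."""
    idx_a = resolve_selection(frame, sel_a)
    idx_b = resolve_selection(frame, sel_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise SelectionError("contact selections overlap")
    ia, _ = _strict_pairs(frame.coord[idx_a], frame.coord[idx_b], cutoff)
    return int(ia.size)


def contact_atom_pairs(frame: NucleoAssembly, sel_a, sel_b,
                       cutoff: float = DEFAULT_CUTOFF) -> List[Tuple[int, int]]:
    """Global atom-index pairs in contact between two disjoint selections."""
    idx_a = resolve_selection(frame, sel_a)
    idx_b = resolve_selection(frame, sel_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise SelectionError("contact selections overlap")
    ia, ib = _strict_pairs(frame.coord[idx_a], frame.coord[idx_b], cutoff)
    return [(int(idx_a[i]), int(idx_b[j])) for i, j in zip(ia, ib)]


# ---------------------------------------------------------------------------
# per-residue profiles


@dataclass
class ContactProfile:
    """Per-residue contact counts of component A against component B.

    ``per_replica`` is (n_replicas, n_residues) after frame- and
    copy-averaging; ``mean`` / ``sd`` are the cross-replica mean and
    population SD per residue.
    """

    component_a: str
    component_b: str
    res_ids: np.ndarray
    res_names: np.ndarray
    per_replica: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def total_per_replica(self) -> np.ndarray:
        return self.per_replica.sum(axis=1)

    @property
    def total(self) -> Tuple[float, float]:
        """(mean, population SD) of the summed profile across replicas."""
        t = self.total_per_replica
        return float(t.mean()), float(t.std(ddof=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": self.component_a,
            "partner": self.component_b,
            "res_id": self.res_ids,
            "res_name": self.res_names,
            "mean_contacts": self.mean,
            "sd_contacts": self.sd,
        })


def _component_chains(assembly: NucleoAssembly, comp: str) -> List[List[str]]:
    """Resolve a component name to chain-id groups, one group per copy.

    ``comp`` may be a histone class ("H3", "H2A.B", ...), the keyword "DNA"
    (all DNA chains as one group), or a chain id.  Histone copies are paired
    by copy_index / chain-id order.
    """
    if comp.upper() == "DNA":
        cids = [c.chain_id for c in assembly.chains_of_kind("dna")]
        if not cids:
            raise ConfigurationError("assembly has no DNA chains")
        return [cids]
    by_class = assembly.chains_of_class(comp)
    if by_class:
        return [[c.chain_id] for c in by_class]
    if any(c.chain_id == comp for c in assembly.chains):
        return [[comp]]
    raise ConfigurationError(f"component {comp!r} matches no chain or histone class")


def _per_residue_counts(frame: NucleoAssembly, chain_ids_a: Sequence[str],
                        partner_idx: np.ndarray, res_axis: np.ndarray,
                        cutoff: float) -> np.ndarray:
    """Counts per residue of one A copy against fixed partner atoms."""
    idx_a = resolve_selection(frame, Selection(chain_ids=tuple(chain_ids_a)))
    overlap = np.intersect1d(idx_a, partner_idx)
    if overlap.size:
        raise SelectionError("component and partner selections overlap")
    ia, _ = _strict_pairs(frame.coord[idx_a], frame.coord[partner_idx], cutoff)
    counts = np.zeros(len(res_axis), dtype=float)
    rid_of_atom = frame.res_id[idx_a]
    pos = {rid: k for k, rid in enumerate(res_axis)}
    for i in ia:
        counts[pos[rid_of_atom[i]]] += 1
    return counts


def residue_profile(replicas: Union[Trajectory, Sequence[Trajectory]],
                    component_a: str, component_b: str,
                    cutoff: float = DEFAULT_CUTOFF) -> ContactProfile:
    """Average per-residue contacts of A with B over frames, copies, replicas.

    Each copy of A is counted against its paired copy of B (copies paired
    by order) when B has the same number of copies, otherwise against all
    of B (the DNA case).  Frame averages come first, then the copy average,
    then the cross-replica mean +/- population SD.
    """
    if isinstance(replicas, Trajectory):
        replicas = [replicas]
    if not replicas:
        raise ConfigurationError("no replicas given")
    topo = replicas[0].topology
    groups_a = _component_chains(topo, component_a)
    groups_b = _component_chains(topo, component_b)
    if len(groups_b) not in (1, len(groups_a)):
        raise ConfigurationError(
            f"cannot pair {len(groups_a)} copies of {component_a} with "
            f"{len(groups_b)} copies of {component_b}")

    # residue axis from the first copy of A; copies must be congruent
    axes = []
    for g in groups_a:
        sel = Selection(chain_ids=tuple(g))
        idx = sel.resolve(topo)
        axes.append(np.unique(topo.res_id[idx]))
    for ax in axes[1:]:
        if not np.array_equal(ax, axes[0]):
            raise ConfigurationError(f"copies of {component_a} are not congruent")
    res_axis = axes[0]
    first_idx = Selection(chain_ids=tuple(groups_a[0])).resolve(topo)
    res_names = np.array([topo.res_name[first_idx[topo.res_id[first_idx] == rid][0]]
                          for rid in res_axis])

    per_replica = np.zeros((len(replicas), len(res_axis)))
    for r, traj in enumerate(replicas):
        copy_profiles = []
        for c, group_a in enumerate(groups_a):
            group_b = groups_b[c] if len(groups_b) == len(groups_a) else groups_b[0]
            partner_idx = Selection(chain_ids=tuple(group_b)).resolve(traj.topology)
            frames = np.zeros((traj.n_frames, len(res_axis)))
            for t in range(traj.n_frames):
                frames[t] = _per_residue_counts(traj.frame(t), group_a,
                                                partner_idx, res_axis, cutoff)
            copy_profiles.append(frames.mean(axis=0))
        per_replica[r] = np.mean(copy_profiles, axis=0)

    return ContactProfile(
        component_a=component_a, component_b=component_b,
        res_ids=res_axis, res_names=res_names,
        per_replica=per_replica,
        mean=per_replica.mean(axis=0),
        sd=per_replica.std(axis=0, ddof=0),
        metadata={"cutoff": cutoff, "n_replicas": len(replicas),
                  "n_copies": len(groups_a),
                  "averaging_order": "frames, then copies, then replicas",
                  "sd_convention": "population"},
    )


def region_total(profile: ContactProfile,
                 region: RegionAnnotation) -> Tuple[float, float]:
    """Summed contacts over a region of the profile axis: mean +/- SD.

    The sum is taken per replica, then aggregated across replicas.  A
    region that does not intersect the axis is an error, not zero.
    """
    mask = (profile.res_ids >= region.start) & (profile.res_ids <= region.end)
    if not mask.any():
        raise RangeError(
            f"region {region.name!r} [{region.start}, {region.end}] does not "
            f"intersect the profile axis")
    sums = profile.per_replica[:, mask].sum(axis=1)
    return float(sums.mean()), float(sums.std(ddof=0))


# ---------------------------------------------------------------------------
# native contacts / q factor


@dataclass
class NativeContactSet:
    """Contacts present in a reference conformation under the contact rule.

    Pairs are canonically sorted and unique.  Residue granularity excludes
    sequence neighbors (|i - j| < 3 on the same chain); atom granularity
    excludes only same-residue pairs.
    """

    granularity: str
    cutoff: float
    pairs: list
    reference_id: str = "reference"

    @property
    def n(self) -> int:
        return len(self.pairs)


def build_native_contacts(ref: NucleoAssembly, granularity: str = "residue",
                          cutoff: float = DEFAULT_CUTOFF,
                          sel=None) -> NativeContactSet:
    """Enumerate the reference conformation's contacts.

    ``sel`` restricts the atom universe (default: all heavy atoms).
    """
    if granularity not in ("atom", "residue"):
        raise ConfigurationError("granularity must be 'atom' or 'residue'")
    idx = resolve_selection(ref, sel)
    coords = ref.coord[idx]
    tree = cKDTree(coords)
    cand = tree.query_pairs(r=cutoff, output_type="ndarray")
    if cand.size:
        d = np.linalg.norm(coords[cand[:, 0]] - coords[cand[:, 1]], axis=1)
        cand = cand[d < cutoff]

    chain = ref.chain_id[idx]
    rid = ref.res_id[idx]
    pairs = set()
    for i, j in cand:
        same_res = chain[i] == chain[j] and rid[i] == rid[j]
        if same_res:
            continue
        if granularity == "atom":
            gi, gj = int(idx[i]), int(idx[j])
            pairs.add((gi, gj) if gi < gj else (gj, gi))
        else:
            if chain[i] == chain[j] and abs(int(rid[i]) - int(rid[j])) < 3:
                continue
            a = (str(chain[i]), int(rid[i]))
            b = (str(chain[j]), int(rid[j]))
            pairs.add((a, b) if a < b else (b, a))
    return NativeContactSet(granularity=granularity, cutoff=cutoff,
                            pairs=sorted(pairs))


def q_factor(frame: NucleoAssembly, native: NativeContactSet,
             tolerance_factor: float = 1.2) -> float:
    """Fraction of native contacts formed in ``frame``.

    A native pair is *formed* when its distance (atom distance, or minimum
    heavy-atom distance for residue pairs) is below
    ``tolerance_factor * cutoff``.  Always in [0, 1]; equals 1 at the
    reference for any tolerance_factor >= 1.
    """
    if native.n == 0:
        raise DefinitionError("q factor undefined for an empty native-contact set")
    thr = tolerance_factor * native.cutoff
    formed = 0
    if native.granularity == "atom":
        ii = np.array([p[0] for p in native.pairs])
        jj = np.array([p[1] for p in native.pairs])
        d = np.linalg.norm(frame.coord[ii] - frame.coord[jj], axis=1)
        formed = int((d < thr).sum())
    else:
        res_cache = {}

        def atoms_of(ref):
            if ref not in res_cache:
                res_cache[ref] = frame.residue_atom_indices(ref, heavy=True)
            return res_cache[ref]

        for a, b in native.pairs:
            ca = frame.coord[atoms_of(a)]
            cb = frame.coord[atoms_of(b)]
            dmin = np.min(np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2))
            if dmin < thr:
                formed += 1
    return formed / native.n


def q_series(traj: Trajectory, native: NativeContactSet,
             tolerance_factor: float = 1.2):
    """Per-frame q factor over a trajectory."""
    from .geometry import SeriesStat
    vals = [q_factor(traj.frame(t), native, tolerance_factor)
            for t in range(traj.n_frames)]
    return SeriesStat.from_values(vals, metric="q_factor",
                                  tolerance_factor=tolerance_factor)
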