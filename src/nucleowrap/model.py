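"""Core containers for nucleosome-like assemblies.

A :class:`NucleoAssembly` is a columnar, heavy-atom-aware description of one
conformation of a nucleosome core particle (NCP), chromatosome or toy
complex: chains annotated with a molecular role (histone / DNA / linker
histone), per-atom arrays, and an ordered base-pair list that fixes which
DNA terminus is the *entry* side.  A :class:`Trajectory` is an ordered stack
of coordinate sets sharing one topology.

Coordinates are in Angstrom throughout.  Residue indices are 1-based within
each chain; base pairs are indexed 1..n_bp from the entry terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    ConfigurationError,
    SelectionError,
    TopologyError,
    ValidationError,
)

#: (chain_id, residue_index) reference to one residue.
ResidueRef = Tuple[str, int]

MOLECULE_KINDS = ("histone", "dna", "linker_histone")
HISTONE_CLASSES = ("H2A", "H2A.B", "H2B", "H3", "H4", "H1")


@dataclass(frozen=True)
class ChainInfo:
    """Role annotation for one chain.

    Parameters
    ----------
    chain_id : str
        PDB-style chain identifier.
    kind : {"histone", "dna", "linker_histone"}
        Molecular role of the chain.
    histone_class : str or None
        One of H2A, H2A.B, H2B, H3, H4, H1 for protein chains; None for DNA
        or for synthetic bead cores that model no particular histone.
    copy_index : int or None
        1 or 2 for the two copies of a core histone in an octamer; None when
        the distinction does not apply.
    """

    chain_id: str
    kind: str
    histone_class: Optional[str] = None
    copy_index: Optional[int] = None

    def __post_init__(self):
        if self.kind not in MOLECULE_KINDS:
            raise ConfigurationError(f"unknown molecule kind {self.kind!r}")
        if self.histone_class is not None and self.histone_class not in HISTONE_CLASSES:
            raise ConfigurationError(f"unknown histone class {self.histone_class!r}")
        if self.copy_index is not None and self.copy_index not in (1, 2):
            raise ConfigurationError("copy_index must be 1, 2 or None")


@dataclass
class NucleoAssembly:
    """One conformation of a nucleosome-like assembly.

    Attributes
    ----------
    chains : list of ChainInfo
        Ordered chain annotations; order matches first appearance in the
        atom arrays.
    chain_id, res_id, res_name, atom_name, element : ndarray
        Per-atom annotation arrays of equal length.  ``res_id`` is 1-based
        within its chain.
    coord : (n_atoms, 3) float ndarray
        Cartesian coordinates in Angstrom.
    dna_pairing : list of (ResidueRef, ResidueRef or None)
        Ordered base pairs, pair 1 at the entry terminus.  The second
        reference is None for single-strand (bead) DNA representations
        where one residue stands for a whole base pair.
    metadata : dict
        Free-form provenance: generator specs, planted ground truth,
        named point selections (e.g. P1..P4 atom indices), seeds.
    """

    chains: list
    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    dna_pairing: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        n = len(self.chain_id)
        for name in ("res_id", "res_name", "atom_name", "element"):
            if len(getattr(self, name)) != n:
                raise TopologyError(f"annotation array {name!r} length mismatch")
        if self.coord.shape != (n, 3):
            raise TopologyError("coord must have shape (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.chain_id)

    @property
    def n_bp(self) -> int:
        return len(self.dna_pairing)

    def chain_info(self, chain_id: str) -> ChainInfo:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ConfigurationError(f"chain {chain_id!r} has no role annotation")

    @property
    def heavy_mask(self) -> np.ndarray:
        """Boolean mask of heavy atoms (element != H).

        The element column is authoritative; empty elements fall back to an
        atom-name heuristic (names whose first alphabetic character is H are
        treated as hydrogen).  Coarse-grained beads carry non-H elements and
        are therefore all heavy.
        """
        elem = np.char.upper(np.asarray(self.element, dtype=str))
        mask = (elem != "H") & (elem != "D")
        blank = elem == ""
        if blank.any():
            for i in np.nonzero(blank)[0]:
                name = str(self.atom_name[i]).strip()
                alpha = next((ch for ch in name if ch.isalpha()), "")
                mask[i] = alpha.upper() != "H"
        return mask

    def validate(self) -> None:
        """Check the container invariants, raising ValidationError on failure."""
        if not np.all(np.isfinite(self.coord)):
            raise ValidationError("non-finite coordinates")
        seen = set()
        for ref1, ref2 in self.dna_pairing:
            for ref in (ref1, ref2):
                if ref is None:
                    continue
                if ref in seen:
                    raise ValidationError(f"residue {ref} appears in two base pairs")
                seen.add(ref)
        annotated = {c.chain_id for c in self.chains}
        present = set(np.unique(self.chain_id))
        if not present <= annotated:
            raise ConfigurationError(
                f"chains without role annotation: {sorted(present - annotated)}"
            )

    def copy(self) -> "NucleoAssembly":
        return NucleoAssembly(
            chains=list(self.chains),
            chain_id=self.chain_id.copy(),
            res_id=self.res_id.copy(),
            res_name=self.res_name.copy(),
            atom_name=self.atom_name.copy(),
            element=self.element.copy(),
            coord=self.coord.copy(),
            dna_pairing=list(self.dna_pairing),
            metadata=dict(self.metadata),
        )

    def with_coord(self, coord: np.ndarray) -> "NucleoAssembly":
        """Same topology, different coordinates (shares annotation arrays)."""
        coord = np.asarray(coord, dtype=float)
        if coord.shape != self.coord.shape:
            raise TopologyError("coordinate shape mismatch")
        out = NucleoAssembly(
            chains=self.chains,
            chain_id=self.chain_id,
            res_id=self.res_id,
            res_name=self.res_name,
            atom_name=self.atom_name,
            element=self.element,
            coord=coord,
            dna_pairing=self.dna_pairing,
            metadata=self.metadata,
        )
        return out

    # -- indexing -------------------------------------------------------------

    def residue_atom_indices(self, ref: ResidueRef, heavy: bool = True) -> np.ndarray:
        cid, rid = ref
        mask = (self.chain_id == cid) & (self.res_id == rid)
        if heavy:
            mask &= self.heavy_mask
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise TopologyError(f"residue {ref} has no atoms")
        return idx

    def bp_atom_indices(self, bp_index: int, heavy: bool = True) -> np.ndarray:
        """Heavy-atom indices of base pair ``bp_index`` (1-based from entry)."""
        if not 1 <= bp_index <= self.n_bp:
            raise TopologyError(f"base pair index {bp_index} outside 1..{self.n_bp}")
        ref1, ref2 = self.dna_pairing[bp_index - 1]
        idx = [self.residue_atom_indices(ref1, heavy=heavy)]
        if ref2 is not None:
            idx.append(self.residue_atom_indices(ref2, heavy=heavy))
        return np.concatenate(idx)

    def _terminal_p_index(self, which: str) -> int:
        if self.n_bp == 0:
            raise TopologyError("assembly has no base pairs")
        if which == "entry":
            ref1, _ = self.dna_pairing[0]
            ref = ref1
        else:
            ref1, ref2 = self.dna_pairing[-1]
            # the 5' end at the exit lies on the complementary strand when a
            # duplex is present; bead DNA has only one residue per pair
            ref = ref2 if ref2 is not None else ref1
        idx = self.residue_atom_indices(ref, heavy=True)
        names = np.char.strip(np.asarray(self.atom_name[idx], dtype=str))
        p = idx[names == "P"]
        if p.size == 0:
            raise SelectionError(f"no P atom in the {which} terminal base pair")
        return int(p[0])

    @property
    def entry_p_index(self) -> int:
        """Atom index of the first P atom at the DNA entry terminus."""
        return self._terminal_p_index("entry")

    @property
    def exit_p_index(self) -> int:
        """Atom index of the first P atom at the DNA exit terminus."""
        return self._terminal_p_index("exit")

    def chains_of_kind(self, kind: str) -> list:
        return [c for c in self.chains if c.kind == kind]

    def chains_of_class(self, histone_class: str) -> list:
        out = [c for c in self.chains if c.histone_class == histone_class]
        return sorted(out, key=lambda c: (c.copy_index or 0, c.chain_id))


@dataclass
class Trajectory:
    """Ordered coordinate frames over one shared topology.

    ``coords`` has shape (n_frames, n_atoms, 3); frame indices are 0-based
    and preserved on round-trip through multi-model PDB (model numbers are
    frame_index + 1).
    """

    topology: NucleoAssembly
    coords: np.ndarray
    time_per_frame: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise TopologyError(
                "trajectory coords must have shape (n_frames, n_atoms, 3) "
                "matching the topology atom count"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> NucleoAssembly:
        """Assembly view of frame ``i`` (0-based)."""
        return self.topology.with_coord(self.coords[i])

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass(frozen=True)
class RegionAnnotation:
    """A named inclusive residue range on a chain or on a histone class.

    Exactly one of ``chain_id`` / ``histone_class`` should be given; a
    class-level region (e.g. the H2A L2 loop) applies to both copies.
    """

    name: str
    start: int
    end: int
    chain_id: Optional[str] = None
    histone_class: Optional[str] = None

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"region {self.name!r}: invalid range [{self.start}, {self.end}]"
            )
        if (self.chain_id is None) == (self.histone_class is None):
            raise ValidationError(
                f"region {self.name!r}: give exactly one of chain_id/histone_class"
            )

    def residue_ids(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


@dataclass
class Selection:
    """Declarative atom selection resolved against an assembly.

    All criteria are conjunctive; unset criteria match everything.
    Resolution is deterministic: indices come back in atom-array order.
    """

    chain_ids: Optional[Sequence[str]] = None
    kinds: Optional[Sequence[str]] = None
    histone_classes: Optional[Sequence[str]] = None
    copy_index: Optional[int] = None
    res_range: Optional[Tuple[int, int]] = None
    atom_names: Optional[Sequence[str]] = None
    heavy_only: bool = True

    def resolve(self, assembly: NucleoAssembly) -> np.ndarray:
        mask = np.ones(assembly.n_atoms, dtype=bool)
        chain_ids = set(self.chain_ids) if self.chain_ids is not None else None
        if self.kinds is not None or self.histone_classes is not None or self.copy_index is not None:
            allowed = set()
            for c in assembly.chains:
                if self.kinds is not None and c.kind not in self.kinds:
                    continue
                if self.histone_classes is not None and c.histone_class not in self.histone_classes:
                    continue
                if self.copy_index is not None and c.copy_index != self.copy_index:
                    continue
                allowed.add(c.chain_id)
            chain_ids = allowed if chain_ids is None else chain_ids & allowed
        if chain_ids is not None:
            mask &= np.isin(assembly.chain_id, sorted(chain_ids))
        if self.res_range is not None:
            lo, hi = self.res_range
            mask &= (assembly.res_id >= lo) & (assembly.res_id <= hi)
        if self.atom_names is not None:
            names = np.char.strip(np.asarray(assembly.atom_name, dtype=str))
            mask &= np.isin(names, list(self.atom_names))
        if self.heavy_only:
            mask &= assembly.heavy_mask
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise SelectionError(f"selection {self} resolved to zero atoms")
        return idx

    @staticmethod
    def p_atoms() -> "Selection":
        """All DNA phosphorus atoms (linker DNA included)."""
        return Selection(kinds=("dna",), atom_names=("P",))

    @staticmethod
    def histone_core() -> "Selection":
        """All heavy atoms of histone chains (the default 'histone core')."""
        return Selection(kinds=("histone",))

    @staticmethod
    def region(assembly_region: RegionAnnotation, heavy_only: bool = True) -> "Selection":
        r = assembly_region
        return Selection(
            chain_ids=(r.chain_id,) if r.chain_id else None,
            histone_classes=(r.histone_class,) if r.histone_class else None,
            res_range=(r.start, r.end),
            heavy_only=heavy_only,
        )


def resolve_selection(assembly: NucleoAssembly, sel) -> np.ndarray:
    """Accept a Selection, an index array, or None (= all heavy atoms)."""
    if sel is None:
        idx = np.nonzero(assembly.heavy_mask)[0]
        if idx.size == 0:
            raise SelectionError("assembly has no heavy atoms")
        return idx
    if isinstance(sel, Selection):
        return sel.resolve(assembly)
    idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise SelectionError("empty index selection")
    return idx
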