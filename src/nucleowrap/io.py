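"""Structure, trajectory and table I/O.

PDB reading/writing is delegated to biotite; this module binds parsed atoms
to the package's :class:`~nucleowrap.model.NucleoAssembly` topology (chain
roles, base-pair ordering, entry/exit designation).  A JSON *sidecar* file
written next to each structure preserves everything PDB cannot carry:
chain roles, the base-pair table, named point selections and generator
ground truth.  A simple per-frame XYZ series is supported as an alternative
trajectory dialect.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ConfigurationError, FormatError, PairingError, TopologyError
from .model import ChainInfo, NucleoAssembly, Trajectory

_DNA_RES_NAMES = {
    "DA", "DT", "DG", "DC", "DU", "A", "T", "G", "C", "U",
    "ADE", "THY", "GUA", "CYT", "URA",
}

#: chain ids of the canonical NCP layout (3AFA/1KX5 convention), used as the
#: fallback histone-class inference when no role map is supplied.
CANONICAL_NCP_CHAINS = {
    "A": ("histone", "H3", 1), "B": ("histone", "H4", 1),
    "C": ("histone", "H2A", 1), "D": ("histone", "H2B", 1),
    "E": ("histone", "H3", 2), "F": ("histone", "H4", 2),
    "G": ("histone", "H2A", 2), "H": ("histone", "H2B", 2),
    "I": ("dna", None, None), "J": ("dna", None, None),
}


# ---------------------------------------------------------------------------
# chain roles and pairing


def _infer_chains(atoms: "struc.AtomArray", chain_roles: Optional[dict]) -> list:
    """Build ChainInfo list from an explicit role map or by inference.

    ``chain_roles`` maps chain_id -> {kind, histone_class, copy_index}.
    Without it, chains whose residues are nucleotides become DNA; protein
    chains fall back to the canonical NCP chain-id convention, else get
    histone_class None.
    """
    infos = []
    seen = []
    for cid in atoms.chain_id:
        if cid not in seen:
            seen.append(cid)
    for cid in seen:
        if chain_roles and cid in chain_roles:
            r = chain_roles[cid]
            if "kind" not in r:
                raise ConfigurationError(f"chain {cid!r}: role map entry lacks 'kind'")
            infos.append(ChainInfo(cid, r["kind"], r.get("histone_class"),
                                   r.get("copy_index")))
            continue
        res_names = set(np.char.strip(atoms.res_name[atoms.chain_id == cid]))
        if res_names <= _DNA_RES_NAMES:
            infos.append(ChainInfo(cid, "dna"))
        elif cid in CANONICAL_NCP_CHAINS:
            kind, cls, copy = CANONICAL_NCP_CHAINS[cid]
            infos.append(ChainInfo(cid, kind, cls, copy))
        else:
            infos.append(ChainInfo(cid, "histone"))
    return infos


def _positional_pairing(assembly_chains, chain_id, res_id, explicit=None):
    """Default base-pair table: residue i of strand 1 with n+1-i of strand 2.

    One DNA strand yields bead pairing (second reference None); two strands
    of unequal length without an explicit table raise PairingError.
    """
    if explicit is not None:
        return [(tuple(p[0]), tuple(p[1]) if p[1] is not None else None)
                for p in explicit]
    dna = [c.chain_id for c in assembly_chains if c.kind == "dna"]
    if not dna:
        return []
    if len(dna) == 1:
        cid = dna[0]
        rids = np.unique(res_id[chain_id == cid])
        return [((cid, int(r)), None) for r in np.sort(rids)]
    if len(dna) == 2:
        c1, c2 = dna
        r1 = np.sort(np.unique(res_id[chain_id == c1]))
        r2 = np.sort(np.unique(res_id[chain_id == c2]))
        if len(r1) != len(r2):
            raise PairingError(
                f"strands {c1}/{c2} have {len(r1)} vs {len(r2)} residues; "
                "supply an explicit pairing table"
            )
        n = len(r1)
        return [((c1, int(r1[i])), (c2, int(r2[n - 1 - i]))) for i in range(n)]
    raise PairingError(
        f"{len(dna)} DNA strands present; supply an explicit pairing table "
        "or mark linker strands via chain_roles"
    )


# ---------------------------------------------------------------------------
# biotite conversion


def _from_atom_array(atoms, chains, pairing, metadata) -> NucleoAssembly:
    return NucleoAssembly(
        chains=chains,
        chain_id=np.asarray(atoms.chain_id, dtype=str),
        res_id=np.asarray(atoms.res_id, dtype=int),
        res_name=np.char.strip(np.asarray(atoms.res_name, dtype=str)),
        atom_name=np.char.strip(np.asarray(atoms.atom_name, dtype=str)),
        element=np.char.strip(np.asarray(atoms.element, dtype=str)),
        coord=np.asarray(atoms.coord, dtype=float),
        dna_pairing=pairing,
        metadata=metadata or {},
    )


def _to_atom_array(assembly: NucleoAssembly) -> "struc.AtomArray":
    n = assembly.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = assembly.coord.astype(np.float32)
    arr.chain_id = assembly.chain_id.astype("U4")
    arr.res_id = assembly.res_id.astype(int)
    arr.res_name = assembly.res_name.astype("U5")
    arr.atom_name = assembly.atom_name.astype("U6")
    arr.element = assembly.element.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


# ---------------------------------------------------------------------------
# sidecar


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def _pairing_to_json(pairing):
    return [[list(a), list(b) if b is not None else None] for a, b in pairing]


def _chains_to_json(chains):
    return [
        {"chain_id": c.chain_id, "kind": c.kind,
         "histone_class": c.histone_class, "copy_index": c.copy_index}
        for c in chains
    ]


def write_sidecar(assembly: NucleoAssembly, path) -> None:
    doc = {
        "chains": _chains_to_json(assembly.chains),
        "dna_pairing": _pairing_to_json(assembly.dna_pairing),
        "metadata": assembly.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(doc, indent=1, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _load_sidecar(path):
    sc = _sidecar_path(path)
    if not sc.exists():
        return None
    doc = json.loads(sc.read_text())
    chains = [ChainInfo(d["chain_id"], d["kind"], d.get("histone_class"),
                        d.get("copy_index")) for d in doc["chains"]]
    pairing = [((a[0], a[1]), (b[0], b[1]) if b is not None else None)
               for a, b in doc["dna_pairing"]]
    return chains, pairing, doc.get("metadata", {})


# ---------------------------------------------------------------------------
# public API


def read_structure(path, format: str = "pdb", chain_roles: Optional[dict] = None,
                   pairing: Optional[list] = None,
                   use_sidecar: bool = True) -> NucleoAssembly:
    """Read a single-conformation structure into a NucleoAssembly.

    Hydrogens are kept in the atom records; every distance-based analysis
    masks them out through ``heavy_mask``.  A ``<path>.json`` sidecar, when
    present and ``use_sidecar`` is True, restores chain roles, pairing and
    metadata exactly; explicit ``chain_roles`` / ``pairing`` arguments
    override it.
    """
    if format != "pdb":
        raise FormatError(f"unsupported structure format {format!r}")
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse {path} as PDB: {exc}") from exc
    side = _load_sidecar(path) if use_sidecar else None
    if side is not None and chain_roles is None and pairing is None:
        chains, pair, meta = side
        return _from_atom_array(atoms, chains, pair, meta)
    chains = _infer_chains(atoms, chain_roles)
    pair = _positional_pairing(chains, np.asarray(atoms.chain_id, dtype=str),
                               np.asarray(atoms.res_id, dtype=int), pairing)
    return _from_atom_array(atoms, chains, pair, {})


def read_trajectory(path, format: str = "pdb", chain_roles: Optional[dict] = None,
                    pairing: Optional[list] = None,
                    use_sidecar: bool = True,
                    topology: Optional[NucleoAssembly] = None) -> Trajectory:
    """Read a multi-model PDB or XYZ series as a Trajectory.

    XYZ input carries no topology, so ``topology`` is required for it.
    Model order defines frame order; all models must share the atom count.
    """
    if format == "pdb":
        try:
            pdb = PDBFile.read(str(path))
            stack = pdb.get_structure()  # AtomArrayStack
        except Exception as exc:
            raise FormatError(f"cannot parse {path} as multi-model PDB: {exc}") from exc
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        first = stack[0]
        if topology is not None:
            if topology.n_atoms != first.array_length():
                raise TopologyError("supplied topology does not match model atom count")
            topo = topology
        else:
            side = _load_sidecar(path) if use_sidecar else None
            if side is not None and chain_roles is None and pairing is None:
                chains, pair, meta = side
            else:
                chains = _infer_chains(first, chain_roles)
                pair = _positional_pairing(
                    chains, np.asarray(first.chain_id, dtype=str),
                    np.asarray(first.res_id, dtype=int), pairing)
                meta = {}
            topo = _from_atom_array(first, chains, pair, meta)
        coords = np.asarray(stack.coord, dtype=float)
        return Trajectory(topology=topo, coords=coords)
    if format == "xyz":
        if topology is None:
            raise ConfigurationError("XYZ trajectories need an explicit topology")
        coords = _read_xyz(path, topology.n_atoms)
        return Trajectory(topology=topology, coords=coords)
    raise FormatError(f"unsupported trajectory format {format!r}")


def write_structure(assembly: NucleoAssembly, path, sidecar: bool = True) -> None:
    """Write one conformation as PDB (plus JSON sidecar by default)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(assembly))
    pdb.write(str(path))
    if sidecar:
        write_sidecar(assembly, path)


def write_trajectory(traj: Trajectory, path, format: str = "pdb",
                     sidecar: bool = True) -> None:
    """Write a trajectory as multi-model PDB or XYZ series."""
    if format == "pdb":
        base = _to_atom_array(traj.topology)
        stack = struc.AtomArrayStack(traj.n_frames, traj.topology.n_atoms)
        stack.coord = traj.coords.astype(np.float32)
        for field in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
            setattr(stack, field, getattr(base, field))
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
        if sidecar:
            doc_assembly = traj.topology.copy()
            doc_assembly.metadata = {**traj.topology.metadata, **traj.metadata}
            write_sidecar(doc_assembly, path)
        return
    if format == "xyz":
        _write_xyz(traj, path)
        return
    raise FormatError(f"unsupported trajectory format {format!r}")


def _write_xyz(traj: Trajectory, path) -> None:
    names = traj.topology.atom_name
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.topology.n_atoms}\n")
            fh.write(f"frame {f}\n")
            for name, (x, y, z) in zip(names, traj.coords[f]):
                fh.write(f"{name} {x:.3f} {y:.3f} {z:.3f}\n")


def _read_xyz(path, n_atoms: int) -> np.ndarray:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"bad XYZ atom-count line: {lines[i]!r}") from exc
        if n != n_atoms:
            raise TopologyError(f"XYZ frame has {n} atoms, topology has {n_atoms}")
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise FormatError("truncated XYZ frame")
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return np.asarray(frames, dtype=float)


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a tabular result as delimited text with a header row."""
    df.to_csv(path, sep=sep, index=False)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    # '#'-prefixed lines carry run metadata (version, config hash)
    return pd.read_csv(path, sep=sep, comment="#")
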