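"""Synthetic nucleosome / chromatosome conformation generator.

These builders provide ground-truth-labeled stand-ins for simulation
trajectories of nucleosome core particles: a DNA superhelix wrapped around
an idealized bead core, controllable terminal unwrapping ("peeling"),
stochastic two-state breathing trajectories per DNA end, and a chromatosome
with two articulated linker-DNA arms at prescribed angles.

The geometry is deliberately idealized: the DNA is one bead chain with one
residue per base pair (first atom named P, on the superhelical path) and
the histone core is a cylinder of beads — the analyses downstream depend
only on distances and labels, not on a physical histone fold.  Every
generated object records its spec, seed and planted ground truth in
``metadata``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, ValidationError
from .model import ChainInfo, NucleoAssembly, Trajectory

DNA_CHAIN = "I"
CORE_CHAIN = "O"
LINKER_CHAINS = ("J", "K")
H1_CHAIN = "L"

#: heavy-atom contact cutoff (Angstrom) shared with the analysis modules
DEFAULT_CUTOFF = 6.0


@dataclass(frozen=True)
class SuperhelixSpec:
    """Geometry of the wrapped DNA superhelix and its bead core.

    Defaults follow the canonical nucleosome: ~146 bp of DNA in about 1.65
    left-handed superhelical turns of radius 41.8 A and pitch 25.9 A.  The
    core is a bead cylinder whose surface sits ``core_gap`` inside the DNA
    path, so every wrapped base pair is within the 6.0 A contact cutoff of
    the core by construction (verified by tests, not assumed).
    """

    n_bp: int = 146
    superhelix_radius: float = 41.8
    pitch: float = 25.9
    turns: float = 1.65
    rise_per_bp: Optional[float] = None   # overrides turns when given
    core_gap: float = 4.0                 # radial DNA-to-core-surface gap, A
    core_bead_spacing: float = 2.0
    atoms_per_bp: int = 3

    @property
    def core_radius(self) -> float:
        return self.superhelix_radius - self.core_gap

    @property
    def effective_turns(self) -> float:
        if self.rise_per_bp is None:
            return self.turns
        arc_per_turn = math.hypot(2 * math.pi * self.superhelix_radius, self.pitch)
        return self.n_bp * self.rise_per_bp / arc_per_turn

    def validate(self) -> None:
        if self.n_bp < 2:
            raise ValidationError("n_bp must be >= 2")
        if self.superhelix_radius <= 0 or self.pitch <= 0 or self.core_radius <= 0:
            raise ValidationError("radii and pitch must be positive")
        if self.effective_turns <= 0:
            raise ValidationError("turns must be positive")
        if self.atoms_per_bp < 1:
            raise ValidationError("atoms_per_bp must be >= 1")
        if self.core_bead_spacing <= 0:
            raise ValidationError("core_bead_spacing must be positive")


@dataclass(frozen=True)
class BreathingSpec:
    """Two-state (closed/open) breathing model applied independently per end.

    ``k_open`` / ``k_close`` are per-frame transition probabilities of the
    closed->open and open->closed moves; the stationary open occupancy is
    k_open / (k_open + k_close).  Open frames peel ``n_unwrap_open`` base
    pairs off that end.
    """

    k_open: float = 0.1
    k_close: float = 0.3
    n_unwrap_open: int = 15
    n_frames: int = 1000
    seed: int = 0
    lift: float = 4.0

    def validate(self, n_bp: int) -> None:
        for name, k in (("k_open", self.k_open), ("k_close", self.k_close)):
            if not 0.0 <= k <= 1.0:
                raise ValidationError(f"{name} must be a probability in [0, 1]")
        if not 0 < self.n_unwrap_open < n_bp / 2:
            raise ValidationError("n_unwrap_open must be in (0, n_bp/2)")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.lift <= 0:
            raise ValidationError("lift must be positive")


@dataclass(frozen=True)
class ChromatosomeSpec:
    """NCP core plus two straight linker-DNA arms at prescribed angles.

    The two reported angles are P1-P2-P4 and P3-P4-P2, where P1/P2 are the
    terminal/proximal P atoms of the entry-side arm and P3/P4 of the
    exit-side arm.  ``angle_noise_sd`` perturbs the target angles (degrees,
    normal) before the exact construction.
    """

    core: SuperhelixSpec = field(default_factory=SuperhelixSpec)
    linker_length_bp: int = 20
    linker_angles: Tuple[float, float] = (90.0, 90.0)
    angle_noise_sd: float = 0.0
    seed: int = 0
    include_h1: bool = False

    def validate(self) -> None:
        self.core.validate()
        if self.linker_length_bp < 2:
            raise ValidationError("linker_length_bp must be >= 2")
        for a in self.linker_angles:
            if not 0.0 < a < 180.0:
                raise ValidationError("linker angles must lie in (0, 180) degrees")
        if self.angle_noise_sd < 0:
            raise ValidationError("angle_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# wrapped NCP


def _helix_points(spec: SuperhelixSpec) -> np.ndarray:
    n = spec.n_bp
    turns = spec.effective_turns
    s = np.arange(n) / (n - 1)
    theta = 2 * math.pi * turns * s
    x = spec.superhelix_radius * np.cos(theta)
    y = spec.superhelix_radius * np.sin(theta)
    z = spec.pitch * turns * s
    return np.column_stack([x, y, z])


def _core_beads(spec: SuperhelixSpec, z_min: float, z_max: float) -> np.ndarray:
    rc = spec.core_radius
    dz = spec.core_bead_spacing
    n_rings = max(2, int(math.ceil((z_max - z_min) / dz)) + 1)
    zs = np.linspace(z_min, z_max, n_rings)
    n_phi = max(3, int(math.ceil(2 * math.pi * rc / dz)))
    phis = np.arange(n_phi) * (2 * math.pi / n_phi)
    pts = []
    for z in zs:
        pts.append(np.column_stack([rc * np.cos(phis), rc * np.sin(phis),
                                    np.full(n_phi, z)]))
    return np.vstack(pts)


def make_wrapped_ncp(spec: SuperhelixSpec = SuperhelixSpec()) -> NucleoAssembly:
    """Build a fully wrapped synthetic NCP (deterministic for a given spec).

    DNA: one bead chain, one residue per base pair; the first atom of each
    residue is named P and sits exactly on the superhelical path; any extra
    atoms per bp are placed within 2 A of the P atom.  Core: a histone-role
    bead cylinder spanning the DNA's axial extent.
    """
    spec.validate()
    p = _helix_points(spec)

    # deterministic small offsets for extra per-bp atoms (within 2 A of P)
    offsets = []
    for k in range(1, spec.atoms_per_bp):
        ang = 2 * math.pi * (k - 1) / max(1, spec.atoms_per_bp - 1)
        offsets.append(np.array([1.2 * math.cos(ang), 1.2 * math.sin(ang),
                                 0.8 if k % 2 else -0.8]))

    chain_id, res_id, res_name, atom_name, element, coord = [], [], [], [], [], []
    for i in range(spec.n_bp):
        chain_id.append(DNA_CHAIN); res_id.append(i + 1); res_name.append("DA")
        atom_name.append("P"); element.append("P"); coord.append(p[i])
        for k, off in enumerate(offsets, start=1):
            chain_id.append(DNA_CHAIN); res_id.append(i + 1); res_name.append("DA")
            atom_name.append(f"B{k}"); element.append("C"); coord.append(p[i] + off)

    core = _core_beads(spec, p[:, 2].min(), p[:, 2].max())
    for j, c in enumerate(core):
        chain_id.append(CORE_CHAIN); res_id.append(j + 1); res_name.append("COR")
        atom_name.append("CA"); element.append("C"); coord.append(c)

    assembly = NucleoAssembly(
        chains=[ChainInfo(DNA_CHAIN, "dna"), ChainInfo(CORE_CHAIN, "histone")],
        chain_id=np.array(chain_id), res_id=np.array(res_id),
        res_name=np.array(res_name), atom_name=np.array(atom_name),
        element=np.array(element), coord=np.array(coord),
        dna_pairing=[((DNA_CHAIN, i + 1), None) for i in range(spec.n_bp)],
        metadata={"generator": "make_wrapped_ncp", "superhelix_spec": asdict(spec),
                  "axis": {"origin_xy": [0.0, 0.0]}},
    )
    assembly.validate()
    return assembly


# ---------------------------------------------------------------------------
# peeling


def peel_ends(ncp: NucleoAssembly, n_entry: int, n_exit: int, lift: float = 4.0,
              cutoff: float = DEFAULT_CUTOFF) -> NucleoAssembly:
    """Displace the first ``n_entry`` and last ``n_exit`` base pairs off the core.

    Peeled base pairs are laid out as a straight extension along the local
    wrapping tangent and then pushed radially outward (relative to the core
    axis) by ``cutoff + lift``, which guarantees each peeled bp's minimum
    heavy-atom distance to every core bead exceeds the cutoff for any
    lift > 0.  All other base pairs are untouched.  The planted counts are
    recorded as ground truth in ``metadata['planted_unwrap']``.
    """
    n_bp = ncp.n_bp
    if n_entry < 0 or n_exit < 0:
        raise ValidationError("peel counts must be non-negative")
    if n_entry + n_exit >= n_bp:
        raise ValidationError("peel ranges overlap: n_entry + n_exit must be < n_bp")
    if lift <= 0:
        raise ValidationError("lift must be positive")

    out = ncp.copy()
    axis_xy = np.asarray(
        ncp.metadata.get("axis", {}).get("origin_xy",
                                         _core_centroid_xy(ncp)), dtype=float)

    def _p_coord(bp_index: int) -> np.ndarray:
        idx = ncp.bp_atom_indices(bp_index, heavy=True)
        names = ncp.atom_name[idx]
        return ncp.coord[idx[names == "P"][0]]

    def _peel_side(side: str, n_peel: int) -> None:
        if n_peel == 0:
            return
        if side == "entry":
            boundary, nxt = n_peel + 1, n_peel + 2
            peeled = range(n_peel, 0, -1)          # outward from the boundary
        else:
            boundary, nxt = n_bp - n_peel, n_bp - n_peel - 1
            peeled = range(n_bp - n_peel + 1, n_bp + 1)
        anchor = _p_coord(boundary)
        inner = _p_coord(nxt)
        tangent = anchor - inner
        step = float(np.linalg.norm(tangent))
        if step == 0:
            raise GeometryError("degenerate base-pair spacing at the peel boundary")
        t_hat = tangent / step
        for j, bp in enumerate(peeled, start=1):
            target_p = anchor + j * step * t_hat
            radial = target_p[:2] - axis_xy
            r_norm = np.linalg.norm(radial)
            if r_norm == 0:
                radial, r_norm = np.array([1.0, 0.0]), 1.0
            push = (cutoff + lift) * radial / r_norm
            target_p = target_p + np.array([push[0], push[1], 0.0])
            old_p = _p_coord(bp)
            shift = target_p - old_p
            for ref in ncp.dna_pairing[bp - 1]:
                if ref is None:
                    continue
                idx = ncp.residue_atom_indices(ref, heavy=False)
                out.coord[idx] = ncp.coord[idx] + shift

    _peel_side("entry", n_entry)
    _peel_side("exit", n_exit)
    out.metadata = dict(out.metadata)
    out.metadata["planted_unwrap"] = {"entry": int(n_entry), "exit": int(n_exit),
                                      "total": int(n_entry + n_exit),
                                      "lift": float(lift), "cutoff": float(cutoff)}
    return out


def _core_centroid_xy(assembly: NucleoAssembly) -> np.ndarray:
    core_chains = [c.chain_id for c in assembly.chains
                   if c.kind in ("histone", "linker_histone")]
    mask = np.isin(assembly.chain_id, core_chains)
    if not mask.any():
        return np.zeros(2)
    return assembly.coord[mask, :2].mean(axis=0)


# ---------------------------------------------------------------------------
# breathing trajectories


def _two_state_chain(rng: np.random.Generator, k_open: float, k_close: float,
                     n_frames: int) -> np.ndarray:
    """Sample a closed(0)/open(1) Markov chain, initialized from stationarity."""
    states = np.empty(n_frames, dtype=np.int8)
    p_open = k_open / (k_open + k_close) if (k_open + k_close) > 0 else 0.0
    states[0] = rng.random() < p_open
    u = rng.random(n_frames - 1) if n_frames > 1 else np.empty(0)
    for t in range(1, n_frames):
        if states[t - 1] == 0:
            states[t] = u[t - 1] < k_open
        else:
            states[t] = 0 if u[t - 1] < k_close else 1
    return states


def make_breathing_trajectory(spec: SuperhelixSpec = SuperhelixSpec(),
                              breath: BreathingSpec = BreathingSpec()) -> Trajectory:
    """Stochastic breathing trajectory: each DNA end opens/closes independently.

    Ground-truth per-frame state sequences are stored in
    ``metadata['states_entry']`` / ``['states_exit']`` (0 = closed, 1 = open).
    Fixed seed gives a bit-identical trajectory.
    """
    spec.validate()
    breath.validate(spec.n_bp)
    base = make_wrapped_ncp(spec)
    rng = np.random.default_rng(breath.seed)
    states_entry = _two_state_chain(rng, breath.k_open, breath.k_close, breath.n_frames)
    states_exit = _two_state_chain(rng, breath.k_open, breath.k_close, breath.n_frames)

    n = breath.n_unwrap_open
    variants = {}
    for se in (0, 1):
        for sx in (0, 1):
            variants[(se, sx)] = peel_ends(base, n * se, n * sx,
                                           lift=breath.lift).coord

    coords = np.empty((breath.n_frames, base.n_atoms, 3))
    for t in range(breath.n_frames):
        coords[t] = variants[(int(states_entry[t]), int(states_exit[t]))]

    return Trajectory(
        topology=base, coords=coords,
        metadata={"generator": "make_breathing_trajectory",
                  "superhelix_spec": asdict(spec), "breathing_spec": asdict(breath),
                  "states_entry": states_entry.tolist(),
                  "states_exit": states_exit.tolist(),
                  "stationary_open": (breath.k_open / (breath.k_open + breath.k_close)
                                      if breath.k_open + breath.k_close > 0 else 0.0)},
    )


# ---------------------------------------------------------------------------
# chromatosome


def _plane_basis(a1: np.ndarray, a2: np.ndarray, axis_xy: np.ndarray):
    """Working plane for the arms: spanned by the a1->a2 axis and an outward
    radial direction at their midpoint."""
    v = a2 - a1
    v_hat = v / np.linalg.norm(v)
    mid = 0.5 * (a1 + a2)
    radial = np.array([mid[0] - axis_xy[0], mid[1] - axis_xy[1], 0.0])
    m = radial - np.dot(radial, v_hat) * v_hat
    if np.linalg.norm(m) < 1e-9:
        ref = np.array([0.0, 0.0, 1.0])
        m = ref - np.dot(ref, v_hat) * v_hat
    return v_hat, m / np.linalg.norm(m)


def make_chromatosome(spec: ChromatosomeSpec = ChromatosomeSpec()) -> NucleoAssembly:
    """Wrapped NCP with two straight linker-DNA arms at prescribed angles.

    The arms are placed in the plane spanned by the entry->exit axis and the
    outward radial direction, on the outward side.  The two defined angles
    (P1-P2-P4 at the entry arm, P3-P4-P2 at the exit arm) are solved to the
    (noise-perturbed) targets by a fixed-point iteration on the P2->P4 axis;
    for zero noise they match the targets to ~1e-9 degrees.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alpha, beta = spec.linker_angles
    if spec.angle_noise_sd > 0:
        alpha = alpha + rng.normal(0.0, spec.angle_noise_sd)
        beta = beta + rng.normal(0.0, spec.angle_noise_sd)
        alpha = float(np.clip(alpha, 1.0, 179.0))
        beta = float(np.clip(beta, 1.0, 179.0))

    ncp = make_wrapped_ncp(spec.core)
    axis_xy = np.asarray(ncp.metadata["axis"]["origin_xy"])
    a1 = ncp.coord[ncp.entry_p_index].copy()
    a2 = ncp.coord[ncp.exit_p_index].copy()
    # local inter-bp step of the wrap, reused as the linker rise
    step = float(np.linalg.norm(
        ncp.coord[ncp.entry_p_index]
        - ncp.coord[ncp.bp_atom_indices(2)[0]]))

    v_hat, m_hat = _plane_basis(a1, a2, axis_xy)
    ar, br = math.radians(alpha), math.radians(beta)
    L = spec.linker_length_bp

    def arm_dirs(u_hat):
        d1 = math.cos(ar) * u_hat + math.sin(ar) * m_hat
        d2 = -math.cos(br) * u_hat + math.sin(br) * m_hat
        return d1, d2

    # fixed point on the P2->P4 direction: P2/P4 are the proximal linker bps,
    # which themselves move as the arm directions rotate
    u_hat = v_hat
    for _ in range(200):
        d1, d2 = arm_dirs(u_hat)
        p2 = a1 + step * d1
        p4 = a2 + step * d2
        new_u = p4 - p2
        nrm = np.linalg.norm(new_u)
        if nrm < 1e-9:
            raise GeometryError("degenerate linker geometry (P2 and P4 coincide)")
        new_u = new_u / nrm
        if np.linalg.norm(new_u - u_hat) < 1e-14:
            u_hat = new_u
            break
        u_hat = new_u
    else:
        raise GeometryError("linker angle construction did not converge")
    d1, d2 = arm_dirs(u_hat)

    arm1 = np.array([a1 + j * step * d1 for j in range(1, L + 1)])
    arm2 = np.array([a2 + j * step * d2 for j in range(1, L + 1)])

    # reject arms that interpenetrate the core cylinder (grazing its bead
    # shell is tolerated; > 2 A inside the shell radius is a collision)
    core_mask = ncp.chain_id == CORE_CHAIN
    core_z = ncp.coord[core_mask][:, 2]
    z_lo, z_hi = core_z.min() - 2.0, core_z.max() + 2.0
    for arm in (arm1, arm2):
        r_xy = np.linalg.norm(arm[:, :2] - axis_xy, axis=1)
        inside = (r_xy < spec.core.core_radius - 2.0) & \
                 (arm[:, 2] > z_lo) & (arm[:, 2] < z_hi)
        if inside.any():
            raise GeometryError("infeasible angle targets: linker arm collides "
                                "with the histone core")

    out = ncp.copy()
    chain_id = list(out.chain_id); res_id = list(out.res_id)
    res_name = list(out.res_name); atom_name = list(out.atom_name)
    element = list(out.element); coord = list(out.coord)
    named = {}
    for cid, arm, term, prox in ((LINKER_CHAINS[0], arm1, "P1", "P2"),
                                 (LINKER_CHAINS[1], arm2, "P3", "P4")):
        for j, pos in enumerate(arm, start=1):
            chain_id.append(cid); res_id.append(j); res_name.append("DA")
            atom_name.append("P"); element.append("P"); coord.append(pos)
            if j == 1:
                named[prox] = len(coord) - 1
            if j == len(arm):
                named[term] = len(coord) - 1

    chains = list(out.chains) + [ChainInfo(LINKER_CHAINS[0], "dna"),
                                 ChainInfo(LINKER_CHAINS[1], "dna")]
    if spec.include_h1:
        h1_center = 0.5 * (arm1[0] + arm2[0])
        for j in range(1, 4):
            chain_id.append(H1_CHAIN); res_id.append(j); res_name.append("COR")
            atom_name.append("CA"); element.append("C")
            coord.append(h1_center + np.array([0.0, 0.0, 2.0 * (j - 2)]))
        chains.append(ChainInfo(H1_CHAIN, "linker_histone", "H1"))

    result = NucleoAssembly(
        chains=chains,
        chain_id=np.array(chain_id), res_id=np.array(res_id),
        res_name=np.array(res_name), atom_name=np.array(atom_name),
        element=np.array(element), coord=np.array(coord),
        dna_pairing=list(out.dna_pairing),
        metadata={**out.metadata,
                  "generator": "make_chromatosome",
                  "chromatosome_spec": {**asdict(spec)},
                  "realized_angles": {"P1-P2-P4": alpha, "P3-P4-P2": beta},
                  "named_points": named, "seed": spec.seed},
    )
    result.validate()
    return result


def measured_linker_angles(assembly: NucleoAssembly) -> Tuple[float, float]:
    """Measure the two linker angles from the named P1..P4 points."""
    from .geometry import angle
    pts = assembly.metadata.get("named_points")
    if not pts or any(k not in pts for k in ("P1", "P2", "P3", "P4")):
        raise GeometryError("assembly has no P1..P4 named points")
    c = assembly.coord
    a1 = angle(c[pts["P1"]], c[pts["P2"]], c[pts["P4"]])
    a2 = angle(c[pts["P3"]], c[pts["P4"]], c[pts["P2"]])
    return a1, a2
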