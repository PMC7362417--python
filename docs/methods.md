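# Methods

## Scope and data model

`nucleowrap` analyzes conformations and trajectories of nucleosome-like
assemblies: nucleosome core particles (NCPs), chromatosomes (NCP + two
linker-DNA arms ± linker histone H1), and toy complexes. A
`NucleoAssembly` holds per-atom annotation arrays (chain, residue, atom
name, element, coordinates in Å), chain roles (histone / DNA / linker
histone, histone class, copy index), and an ordered base-pair list indexed
1..n_bp from the designated *entry* terminus. A `Trajectory` is a frame
stack over one topology. PDB I/O goes through biotite; a JSON sidecar
written next to each PDB preserves what the format cannot carry (roles,
pairing, named points, generator ground truth). Coarse-grained bead models
are accepted as PDBs whose "atoms" are beads; beads are all heavy atoms.

Which 5′ terminus is the entry is configuration (default: strand 1,
residue 1, i.e. base pair 1). For duplex DNA read from PDB, strands are
paired positionally (residue *i* of strand 1 with *n*+1−*i* of strand 2)
unless an explicit pairing table is given; unequal strand lengths without
a table are an error, and the table is the escape hatch for overhangs.
Synthetic DNA uses one bead residue per base pair (second pairing
reference absent), which keeps closed-form geometry oracles exact.

Heavy atom means element ≠ H (element column authoritative, atom-name
heuristic as fallback). Hydrogens are retained in records but masked from
every distance computation.

## Unwrapping counter

Per DNA end, the unwrapped count *N* is the maximal run of consecutive
terminal base pairs whose minimum heavy-atom distance to the histone core
exceeds the cutoff (default 6.0 Å), scanning inward and stopping at the
first base pair at or below the cutoff. Consequences of this "maximal
terminal run" reading:

- an interior base pair beyond the cutoff (a bulge) is never counted;
- a base pair at exactly the cutoff stops the scan (counted as wrapped) —
  the two-sided defining condition (> cutoff to count, < cutoff to stop)
  leaves equality open, and stopping is the conservative choice;
- if the entry scan consumes all base pairs the record is flagged
  `full_detachment` with n_entry = n_bp, n_exit = 0, preserving
  n_total = n_entry + n_exit ≤ n_bp.

The *histone core* defaults to all heavy atoms of histone-role chains;
annotated tail regions can be excluded via `default_core_selection`,
since flexible tails materially change minimum distances. Both behaviors
are exposed; the default is recorded in run manifests. The same 6.0 Å
default applies to bead (CG) inputs and is configurable.

Distance searches use a k-d tree (SciPy `cKDTree`); the test suite holds
them to exact agreement with exhaustive O(n²) enumeration. Over a
trajectory whose core atoms do not move, the core tree is built once and
shared across frames.

## Contacts, profiles, q factor

A contact between two disjoint components is a heavy-atom pair strictly
closer than the cutoff (6.0 Å default). Tree-based candidate pairs within
the (inclusive) ball radius are re-checked with exact distances so the
boundary is strict.

Per-residue profiles are computed per frame, averaged over frames, then
over the two copies of the same histone (copies paired by copy index /
chain-id order; a partner without matching copies — DNA — is taken whole),
then reported as mean ± population SD across replicas. This ordering is
recorded in the profile metadata. Region totals sum the per-replica
profile over an inclusive residue range and aggregate across replicas; an
empty region/axis intersection is an error rather than a silent zero, and
totals are additive over any partition of the axis.

Region presets ship for H2A (Nt 1–12, L2 74–79 "KKTRII", docking 80–106,
Ct 107–129), H2A.B (Nt 1–8, L2 78–83 "GERNII", docking 84–108, Ct stub
109–114) and H3 (αN 44–56). The L2 ranges follow the stated sequences;
the others are reconstructions from domain boundaries and named residues
(R49/R52/K56 in the αN) and are deliberately editable configuration.

Native contacts of a reference conformation are all pairs satisfying the
contact rule, excluding pairs within one residue and, at residue
granularity, sequence neighbors |i−j| < 3 on the same chain (which would
otherwise be trivially permanent). The q factor of a conformation is the
fraction of native pairs *formed*, i.e. with distance (atom distance, or
minimum heavy-atom distance for residue pairs) below
`tolerance_factor × cutoff`. The default tolerance factor 1.2 follows
common native-contact practice for deciding formation away from the
reference; factor 1.0 recovers the strict rule. q(reference) = 1 for any
factor ≥ 1, and q ∈ [0, 1] always. Note that a native set built over all
heavy atoms includes intra-chain pairs, so separating two chains drives q
to the intra-chain fraction, not to 0; build the set over a cross-chain
selection when 0 is the intended floor.

## Geometry metrics

Rigid superposition is the standard least-squares fit via
`scipy.spatial.transform.Rotation.align_vectors` (proper rotations only;
reflections never produced; ≥ 3 fit atoms required). RMSD is measured over
a selection after fitting on a fit selection, which defaults to the
measured selection (e.g. fit and measure on all DNA P atoms); a flag
disables fitting, and fitting on the histone core instead is a one-line
selection change — both are exposed because the fit group convention
varies between studies. The end-to-end distance is between the first P
atom of the entry base pair and the first P atom of the exit base pair
(the 5′ residue of the complementary strand when a duplex is present).
Rg is √(Σwᵢ|rᵢ−r̄|²/Σwᵢ), unweighted by default with optional atomic-mass
weighting. RMSF superposes frames in two passes (onto frame 0, then onto
the resulting mean structure), takes per-atom root-mean-square
fluctuations about the final mean, and averages atoms within each
residue; a single-frame trajectory is rejected. Three-point angles are
arccos of the normalized dot product, in [0, 180]°, with zero-length rays
rejected.

Replica aggregation reports per-frame cross-replica mean and *population*
SD (ddof = 0), the convention for error shading over a small fixed set of
independent runs; the convention is recorded in output metadata.

## Synthetic generator

The generator emulates the study conditions the analyses are meant for,
with known ground truth; it is idealized geometry, not physics.

- **Wrapped NCP.** DNA P atoms on a superhelix — defaults 146 bp, 1.65
  turns, radius 41.8 Å, pitch 25.9 Å (canonical NCP dimensions) — with
  `atoms_per_bp − 1` extra bead atoms within 2 Å of each P. The core is a
  bead cylinder whose surface sits `core_gap` (4 Å) inside the DNA path
  with bead spacing 2 Å, so every wrapped base pair clears the 6.0 Å
  contact rule; tests verify this rather than assume it. Construction is
  deterministic per spec.
- **Peeling.** The first/last *n* base pairs are laid out as a straight
  extension along the local wrapping tangent and pushed radially outward
  by (cutoff + lift). A pure tangential extension would leave the first
  peeled base pair only ~4–5 Å from the core cylinder, inside the 6.0 Å
  rule; the radial push guarantees the planted count for every lift > 0,
  which is the generator's contract. Untouched base pairs are bit-equal
  to the input; planted counts ride along as metadata.
- **Breathing.** Each DNA end is an independent two-state (closed/open)
  Markov chain with per-frame transition probabilities k_open, k_close,
  initialized from the stationary law p_open = k_open/(k_open + k_close);
  open frames peel `n_unwrap_open` base pairs (default 15, the scale of
  terminal unwrapping this models). One seeded generator per call; fixed
  seed ⇒ bit-identical trajectories, with the hidden state sequences
  stored as ground truth. Occupancy estimates are compared against the
  stationary value with the autocorrelation-corrected standard error
  √(p(1−p)/n)·√((1+ρ)/(1−ρ)), ρ = 1 − k_open − k_close.
- **Chromatosome.** Two straight linker arms (default 20 bp, the common
  linker construct length) attach at the entry/exit termini in the plane
  spanned by the entry→exit axis and the outward radial direction. The
  two defined angles (P1–P2–P4 at the entry arm's proximal phosphate,
  P3–P4–P2 at the exit arm's) are solved exactly by a fixed-point
  iteration on the P2→P4 axis (the proximal phosphates move as the arm
  directions rotate); zero-noise targets are met to ~1e−9 degrees. Angle
  noise is applied to the targets before the exact construction — and an
  azimuthal rotation alone cannot change the defined angles — so the
  realized angle SD equals the specified SD. Arms that would penetrate
  more than 2 Å inside the core cylinder are rejected as infeasible;
  grazing the bead shell is tolerated. An optional three-bead H1
  placeholder sits between the proximal linker ends.

What the generator does **not** emulate: sequence-dependent DNA mechanics,
bending of peeled segments, electrostatics, a real histone fold, or the
conformational populations of force-field simulations. Passing tests
therefore demonstrate that the *analyses* are correct against planted
truth and closed forms — not that any particular real system unwraps by a
given amount.

## Pipeline, determinism, problem sizes

`run_pipeline` executes configured stages (unwrap, end-to-end, RMSD, Rg,
distribution) over synthetic replicas (replica *r* seeded with
seed + *r*) or input trajectories, writing per-replica tables, aggregate
tables with mean ± SD columns, and a `manifest.json` with the config, a
hash of its scientific content (output location excluded), every default
in effect, and per-stage wall time. Identical config and seed reproduce
all numeric outputs byte-for-byte.

Histogram summaries use 2 Å bins, 3-bin moving-average smoothing and a
peak-prominence floor of 5 % of the maximum smoothed density — enough to
separate modes ~20 Å apart with ~5 Å component spread while ignoring bin
noise; all three are configurable and echoed in outputs. A constant
series yields a single bin with its peak at the value; densities
integrate to 1.

Default problem sizes in the test suite and acceptance script — 146 bp
full-scale nucleosomes for exactness grids, 30–60 bp assemblies for
contact/q demonstrations, 10,000-frame breathing runs at 40 bp with a
coarser (4 Å) core bead spacing — were chosen so the whole validation
suite completes in a couple of minutes on one CPU while every statistical
check retains comfortable power; the coarser core still keeps each
wrapped base pair within ~5.4 Å of a bead, inside the 6.0 Å rule.

## Known limitations

- Positional pairing assumes blunt duplexes; three or more DNA chains
  need explicit pairing or sidecar metadata (linker arms are excluded
  from the base-pair order by construction).
- `peel_ends` requires the core-axis information that generated
  assemblies carry (falling back to the histone-bead centroid); applying
  it to arbitrary experimental structures is not its purpose.
- Residue-granularity q on large frames recomputes per-pair minimum
  distances without caching across frames beyond residue atom indices;
  for very long trajectories atom granularity is markedly faster.
- The RMSD fit-group convention (P atoms vs whole complex) changes
  absolute values on real trajectories; both options are exposed and the
  choice is recorded, but no claim is made about which convention any
  particular published number used.
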