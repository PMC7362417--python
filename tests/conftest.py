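"""Shared fixtures: toy assemblies built in memory and tiny PDB files."""

import numpy as np
import pytest

from nucleowrap.model import ChainInfo, NucleoAssembly
from nucleowrap.synth import SuperhelixSpec, make_wrapped_ncp

# 3-bp toy DNA duplex, two 3-residue strands, one P atom per residue
TOY_DUPLEX_PDB = """\
ATOM      1  P    DA I   1       0.000   0.000   0.000  1.00  0.00           P
ATOM      2  P    DT I   2       3.400   0.000   0.000  1.00  0.00           P
ATOM      3  P    DG I   3       6.800   0.000   0.000  1.00  0.00           P
ATOM      4  P    DC J   1       6.800   2.000   0.000  1.00  0.00           P
ATOM      5  P    DA J   2       3.400   2.000   0.000  1.00  0.00           P
ATOM      6  P    DT J   3       0.000   2.000   0.000  1.00  0.00           P
END
"""


@pytest.fixture
def toy_duplex_path(tmp_path):
    p = tmp_path / "duplex.pdb"
    p.write_text(TOY_DUPLEX_PDB)
    return p


@pytest.fixture(scope="session")
def small_spec():
    """A fast, small superhelix used where full 146-bp scale is unnecessary."""
    return SuperhelixSpec(n_bp=30, atoms_per_bp=2, core_bead_spacing=3.0)


@pytest.fixture(scope="session")
def small_ncp(small_spec):
    return make_wrapped_ncp(small_spec)


@pytest.fixture(scope="session")
def full_ncp():
    """The default 146-bp wrapped synthetic nucleosome."""
    return make_wrapped_ncp(SuperhelixSpec())


def make_two_component_toy(coords_a, coords_b, class_a="H3", class_b="H2A"):
    """Two single-copy protein chains A/B with one CA atom per residue."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    na, nb = len(coords_a), len(coords_b)
    return NucleoAssembly(
        chains=[ChainInfo("A", "histone", class_a, 1),
                ChainInfo("B", "histone", class_b, 1)],
        chain_id=np.array(["A"] * na + ["B"] * nb),
        res_id=np.array(list(range(1, na + 1)) + list(range(1, nb + 1))),
        res_name=np.array(["ALA"] * (na + nb)),
        atom_name=np.array(["CA"] * (na + nb)),
        element=np.array(["C"] * (na + nb)),
        coord=np.vstack([coords_a, coords_b]),
    )


@pytest.fixture
def two_component_toy():
    return make_two_component_toy
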