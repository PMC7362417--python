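"""Contact statistic, per-residue profiles, region totals and q factor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from nucleowrap.contacts import (
    ContactProfile,
    build_native_contacts,
    count_contacts,
    preset_regions,
    q_factor,
    region_total,
    residue_profile,
)
from nucleowrap.errors import DefinitionError, RangeError, SelectionError
from nucleowrap.model import ChainInfo, NucleoAssembly, RegionAnnotation, Selection, Trajectory

SEL_A = Selection(chain_ids=("A",))
SEL_B = Selection(chain_ids=("B",))


class TestCountContacts:
    @pytest.mark.parametrize("d,expected", [(5.99, 1), (6.00, 0), (6.01, 0)])
    def test_strict_inequality_boundary(self, two_component_toy, d, expected):
        toy = two_component_toy([[0, 0, 0]], [[d, 0, 0]])
        assert count_contacts(toy, SEL_A, SEL_B) == expected

    def test_complete_bipartite(self, two_component_toy):
        toy = two_component_toy([[0, 0, 0], [1, 0, 0], [0, 1, 0]],
                                [[0, 0, 1], [1, 1, 1]])
        assert count_contacts(toy, SEL_A, SEL_B) == 6

    def test_symmetric_in_selections(self, two_component_toy):
        rng = np.random.default_rng(4)
        toy = two_component_toy(rng.uniform(0, 20, (40, 3)),
                                rng.uniform(0, 20, (60, 3)))
        assert count_contacts(toy, SEL_A, SEL_B) == count_contacts(toy, SEL_B, SEL_A)

    def test_overlapping_selections_rejected(self, two_component_toy):
        toy = two_component_toy([[0, 0, 0]], [[1, 0, 0]])
        with pytest.raises(SelectionError):
            count_contacts(toy, SEL_A, Selection(chain_ids=("A", "B")))

    def test_matches_exhaustive_double_loop(self, two_component_toy):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.uniform(0, 40, (300, 3))
            b = rng.uniform(0, 40, (400, 3))
            toy = two_component_toy(a, b)
            brute = int((cdist(a, b) < 6.0).sum())
            assert count_contacts(toy, SEL_A, SEL_B) == brute


# ---------------------------------------------------------------------------
# per-residue profiles with copy averaging


def profile_toy(counts1, counts2):
    """Two-copy toy: copy pair (A,B) and (C,D); residue i of each A-copy has
    exactly counts[i] heavy-atom contacts with its partner chain."""
    counts1, counts2 = list(counts1), list(counts2)
    n = len(counts1)
    chain_id, res_id, coord = [], [], []

    def place(copy_chain, partner_chain, counts, y0):
        # distant sentinel keeps the partner chain non-empty at zero contacts
        chain_id.append(partner_chain)
        res_id.append(999)
        coord.append([-5000.0, y0, 0.0])
        for i, c in enumerate(counts):
            chain_id.append(copy_chain)
            res_id.append(i + 1)
            coord.append([100.0 * i, y0, 0.0])
            for k in range(c):
                chain_id.append(partner_chain)
                res_id.append(1)
                coord.append([100.0 * i, y0 + 1.0 + 0.1 * k, 0.0])

    place("A", "B", counts1, 0.0)
    place("C", "D", counts2, 1000.0)
    m = len(chain_id)
    return NucleoAssembly(
        chains=[ChainInfo("A", "histone", "H3", 1), ChainInfo("B", "histone", "H2A", 1),
                ChainInfo("C", "histone", "H3", 2), ChainInfo("D", "histone", "H2A", 2)],
        chain_id=np.array(chain_id), res_id=np.array(res_id),
        res_name=np.array(["ALA"] * m), atom_name=np.array(["CA"] * m),
        element=np.array(["C"] * m), coord=np.array(coord, dtype=float),
    )


def _traj(assembly, n_frames=1):
    return Trajectory(assembly, np.stack([assembly.coord] * n_frames))


class TestResidueProfile:
    def test_identical_copies_average_to_either(self):
        toy = profile_toy([2, 1, 3], [2, 1, 3])
        prof = residue_profile(_traj(toy), "H3", "H2A")
        assert np.allclose(prof.mean, [2, 1, 3])

    def test_copy_average_of_10_and_20_is_15(self):
        toy = profile_toy([10], [20])
        prof = residue_profile(_traj(toy), "H3", "H2A")
        assert prof.mean[0] == pytest.approx(15.0)

    def test_frame_average_before_copy_average(self):
        toy = profile_toy([4, 2], [0, 2])
        far = toy.copy()
        far.coord[np.isin(far.chain_id, ["B", "D"])] += 10_000.0
        traj = Trajectory(toy, np.stack([toy.coord, far.coord]))
        prof = residue_profile(traj, "H3", "H2A")
        # frame mean halves each copy's counts, then copies average
        assert np.allclose(prof.mean, [(4 / 2 + 0 / 2) / 2, (2 / 2 + 2 / 2) / 2])

    def test_three_replica_mean_and_sd_hand_computed(self):
        planted = [([1, 2, 0], [3, 0, 1]),
                   ([1, 0, 0], [1, 0, 1]),
                   ([0, 0, 0], [0, 0, 0])]
        replicas = [_traj(profile_toy(c1, c2)) for c1, c2 in planted]
        prof = residue_profile(replicas, "H3", "H2A")
        expected = np.array([(np.array(c1) + np.array(c2)) / 2
                             for c1, c2 in planted])
        assert np.allclose(prof.per_replica, expected)
        assert np.allclose(prof.mean, expected.mean(axis=0))
        assert np.allclose(prof.sd, expected.std(axis=0, ddof=0))
        total_mean, total_sd = prof.total
        sums = expected.sum(axis=1)
        assert total_mean == pytest.approx(sums.mean())
        assert total_sd == pytest.approx(sums.std(ddof=0))

    def test_dna_partner_uses_all_strands(self, small_ncp):
        traj = Trajectory(small_ncp, small_ncp.coord[None])
        # synthetic core chain has histone role but no class; address by chain id
        prof = residue_profile(traj, "O", "DNA")
        assert prof.mean.sum() > 0


class TestRegionTotal:
    def _profile(self):
        per = np.arange(1.0, 11.0)[None, :]
        return ContactProfile(
            component_a="H2A", component_b="DNA",
            res_ids=np.arange(1, 11), res_names=np.array(["ALA"] * 10),
            per_replica=per, mean=per[0], sd=np.zeros(10),
        )

    def test_full_axis_equals_profile_total(self):
        prof = self._profile()
        m, s = region_total(prof, RegionAnnotation("all", 1, 10, histone_class="H2A"))
        assert m == pytest.approx(prof.total[0]) == 55.0

    def test_interior_region_arithmetic(self):
        m, _ = region_total(self._profile(),
                            RegionAnnotation("L2", 4, 6, histone_class="H2A"))
        assert m == 15.0

    def test_empty_intersection_is_an_error_not_zero(self):
        with pytest.raises(RangeError):
            region_total(self._profile(),
                         RegionAnnotation("Ct", 11, 20, histone_class="H2A"))

    def test_additive_over_axis_partition(self):
        prof = self._profile()
        parts = [(1, 3), (4, 6), (7, 10)]
        total = sum(region_total(prof, RegionAnnotation("p", lo, hi,
                                                        histone_class="H2A"))[0]
                    for lo, hi in parts)
        assert total == pytest.approx(prof.total[0])

    def test_shipped_presets_cover_stated_loops(self):
        h2a = {r.name: (r.start, r.end) for r in preset_regions("H2A")}
        h2ab = {r.name: (r.start, r.end) for r in preset_regions("H2A.B")}
        assert h2a["L2"] == (74, 79)      # KKTRII
        assert h2ab["L2"] == (78, 83)     # GERNII


# ---------------------------------------------------------------------------
# native contacts / q factor


class TestNativeContacts:
    def test_single_cross_chain_pair(self, two_component_toy):
        toy = two_component_toy([[0, 0, 0]], [[3, 0, 0]])
        nat = build_native_contacts(toy, granularity="residue")
        assert nat.pairs == [(("A", 1), ("B", 1))]

    def test_exact_cutoff_pair_excluded(self, two_component_toy):
        toy = two_component_toy([[0, 0, 0]], [[6.0, 0, 0]])
        nat = build_native_contacts(toy, granularity="residue")
        assert nat.n == 0

    def test_sequence_neighbors_excluded_at_residue_granularity(self, two_component_toy):
        toy = two_component_toy([[0, 0, 0], [3, 0, 0], [0, 3, 0], [20, 0, 0]],
                                [[100, 0, 0]])
        nat = build_native_contacts(toy, granularity="residue")
        assert nat.n == 0  # residues 1..3 of chain A are all within |i-j| < 3

    def test_atom_granularity_matches_brute_force(self, two_component_toy):
        rng = np.random.default_rng(21)
        a = rng.uniform(0, 25, (60, 3))
        b = rng.uniform(0, 25, (80, 3))
        toy = two_component_toy(a, b)
        nat = build_native_contacts(toy, granularity="atom")
        coords = toy.coord
        expected = set()
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                same_res = (toy.chain_id[i] == toy.chain_id[j]
                            and toy.res_id[i] == toy.res_id[j])
                if not same_res and np.linalg.norm(coords[i] - coords[j]) < 6.0:
                    expected.add((i, j))
        assert set(nat.pairs) == expected


class TestQFactor:
    def _ref(self, two_component_toy, n=10):
        a = np.column_stack([np.arange(n) * 50.0, np.zeros(n), np.zeros(n)])
        b = a + np.array([3.0, 0.0, 0.0])
        return two_component_toy(a, b)

    def test_reference_scores_one(self, two_component_toy):
        ref = self._ref(two_component_toy)
        nat = build_native_contacts(ref, granularity="atom")
        assert nat.n == 10
        assert q_factor(ref, nat) == 1.0
        assert q_factor(ref, nat, tolerance_factor=1.0) == 1.0

    def test_full_separation_scores_zero(self, two_component_toy):
        ref = self._ref(two_component_toy)
        nat = build_native_contacts(ref, granularity="atom")
        apart = ref.copy()
        apart.coord[ref.chain_id == "B"] += np.array([0.0, 100.0, 0.0])
        assert q_factor(apart, nat) == 0.0

    def test_half_stretched_scores_half(self, two_component_toy):
        ref = self._ref(two_component_toy)
        nat = build_native_contacts(ref, granularity="atom")
        half = ref.copy()
        b_idx = np.nonzero(ref.chain_id == "B")[0][:5]
        half.coord[b_idx] += np.array([0.0, 30.0, 0.0])
        assert q_factor(half, nat) == 0.5

    def test_monotone_under_growing_separation(self, two_component_toy):
        rng = np.random.default_rng(6)
        ref = two_component_toy(rng.uniform(0, 15, (30, 3)),
                                rng.uniform(0, 15, (30, 3)))
        nat = build_native_contacts(ref, granularity="residue")
        qs = []
        for shift in (0.0, 2.0, 5.0, 20.0, 100.0):
            frame = ref.copy()
            frame.coord[ref.chain_id == "B"] += np.array([shift, 0.0, 0.0])
            qs.append(q_factor(frame, nat))
        assert qs[0] == 1.0
        assert all(x >= y for x, y in zip(qs, qs[1:]))
        # after full separation only intra-chain native pairs remain formed
        intra = sum(1 for a, b in nat.pairs if a[0] == b[0])
        assert qs[-1] == pytest.approx(intra / nat.n)

    def test_empty_native_set_rejected(self, two_component_toy):
        toy = two_component_toy([[0, 0, 0]], [[50, 0, 0]])
        nat = build_native_contacts(toy, granularity="residue")
        with pytest.raises(DefinitionError):
            q_factor(toy, nat)


@settings(max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_accelerated_count_equals_brute_force(seed):
    """Neighbor-search contact counting is exactly the O(n^2) count."""
    from conftest import make_two_component_toy

    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 30, (80, 3))
    b = rng.uniform(0, 30, (90, 3))
    toy = make_two_component_toy(a, b)
    assert count_contacts(toy, SEL_A, SEL_B) == int((cdist(a, b) < 6.0).sum())
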