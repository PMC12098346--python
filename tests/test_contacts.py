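"""Interface/environment detection against an all-pairs brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from structscope import (
    ContactCriteria,
    StructureError,
    environment_delta,
    interface,
    make_complex,
    residue_environment,
)
from conftest import brute_force_pairs


class TestInterface:
    def test_separated_chains_have_empty_interface(self):
        # background residues only: nearest cross-chain atoms far beyond cutoff
        m = make_complex(seed=3, n_contacts=0, n_res_b=4)
        report = interface(m.model, ["A"], ["B"])
        assert report.contacts == []
        assert report.interface_residues_a == [] and report.interface_residues_b == []

    @pytest.mark.parametrize("seed,k", [(0, 3), (1, 7), (2, 5)])
    def test_planted_contacts_match_brute_force(self, seed, k):
        m = make_complex(seed=seed, n_contacts=k, n_retained_on_mutation=min(3, k))
        report = interface(m.model, ["A"], ["B"])
        oracle = brute_force_pairs(m.model, ["A"], ["B"], 5.5)
        got = {(c.residue_a, c.residue_b): c.min_distance for c in report.contacts}
        assert set(got) == set(oracle)
        for pair in got:
            assert got[pair] == pytest.approx(oracle[pair], abs=1e-9)
        assert len(report.contacts) == k
        planted = {
            (p["residue_a"], p["residue_b"]) for p in m.truth["contacts"]
        }
        assert {(str(a), str(b)) for a, b in got} == planted

    def test_symmetry_of_partners(self, complex_fixture):
        model = complex_fixture.model
        ab = interface(model, ["A"], ["B"])
        ba = interface(model, ["B"], ["A"])
        pairs_ab = {frozenset((c.residue_a, c.residue_b)) for c in ab.contacts}
        pairs_ba = {frozenset((c.residue_a, c.residue_b)) for c in ba.contacts}
        assert pairs_ab == pairs_ba
        assert ab.interface_residues_a == ba.interface_residues_b

    def test_overlapping_or_empty_groups_rejected(self, complex_fixture):
        with pytest.raises(ValueError, match="overlap"):
            interface(complex_fixture.model, ["A"], ["A", "B"])
        with pytest.raises(ValueError, match="non-empty"):
            interface(complex_fixture.model, [], ["B"])

    @given(cutoff_lo=st.floats(1.0, 5.4), extra=st.floats(0.1, 2.0))
    @settings(max_examples=20, deadline=None)
    def test_enlarging_cutoff_never_removes_contacts(self, cutoff_lo, extra):
        m = make_complex(seed=17)
        small = interface(m.model, ["A"], ["B"], ContactCriteria(cutoff=cutoff_lo))
        large = interface(m.model, ["A"], ["B"], ContactCriteria(cutoff=cutoff_lo + extra))
        small_pairs = {(c.residue_a, c.residue_b) for c in small.contacts}
        large_pairs = {(c.residue_a, c.residue_b) for c in large.contacts}
        assert small_pairs <= large_pairs


class TestResidueEnvironment:
    def test_isolated_residue_has_empty_environment(self):
        m = make_complex(seed=5, n_contacts=0, n_res_a=1, n_res_b=3)
        focal = m.truth["focal"]
        assert residue_environment(m.model, focal) == []

    def test_environment_equals_brute_force_and_is_sorted(self, complex_fixture):
        model = complex_fixture.model
        focal = complex_fixture.truth["focal"]
        env = residue_environment(model, focal)
        oracle = brute_force_pairs(model, ["A"], ["B"], 5.5)
        inter = [c for c in env if not c.same_chain]
        assert {(c.residue_a, c.residue_b) for c in inter} == set(oracle)
        dists = [c.min_distance for c in env]
        assert dists == sorted(dists)

    def test_partner_scope_partitions_environment(self, complex_fixture):
        model = complex_fixture.model
        focal = complex_fixture.truth["focal"]
        env_all = residue_environment(model, focal, partner_scope="all")
        env_inter = residue_environment(model, focal, partner_scope="inter_chain")
        env_intra = residue_environment(model, focal, partner_scope="intra_chain")
        assert len(env_all) == len(env_inter) + len(env_intra)
        assert all(not c.same_chain for c in env_inter)
        assert all(c.same_chain for c in env_intra)

    def test_environment_subset_of_interface_contacts(self, complex_fixture):
        model = complex_fixture.model
        focal = complex_fixture.truth["focal"]
        env_inter = residue_environment(model, focal, partner_scope="inter_chain")
        iface = interface(model, ["A"], ["B"])
        touching_focal = {
            c.residue_b for c in iface.contacts if str(c.residue_a) == focal
        }
        assert {c.residue_b for c in env_inter} == touching_focal

    def test_missing_focal_names_nearest_keys(self, complex_fixture):
        with pytest.raises(StructureError, match="nearest"):
            residue_environment(complex_fixture.model, "A:999")


class TestGridOracleEquivalence:
    """Neighbour search equals brute force on many seeded fixtures."""

    @pytest.mark.parametrize("seed", range(12))
    def test_fixture_sweep(self, seed):
        rng = np.random.default_rng(seed + 1000)
        k = int(rng.integers(1, 8))
        m = make_complex(
            seed=seed,
            n_contacts=k,
            n_retained_on_mutation=int(rng.integers(0, k + 1)),
            contact_distance=float(rng.uniform(4.2, 5.2)),
        )
        assert m.model.atom_count <= 500
        report = interface(m.model, ["A"], ["B"])
        oracle = brute_force_pairs(m.model, ["A"], ["B"], 5.5)
        got = {(c.residue_a, c.residue_b): c.min_distance for c in report.contacts}
        assert set(got) == set(oracle)
        np.testing.assert_allclose(
            [got[p] for p in sorted(got)], [oracle[p] for p in sorted(oracle)], atol=1e-9
        )


class TestEnvironmentDelta:
    def test_identical_lists_no_changes(self, complex_fixture):
        env = residue_environment(complex_fixture.model, complex_fixture.truth["focal"])
        delta = environment_delta(env, env)
        assert (delta.n_lost, delta.n_gained) == (0, 0)
        assert delta.n_retained == len(env)

    def test_subset_arithmetic(self, complex_fixture):
        env = residue_environment(complex_fixture.model, complex_fixture.truth["focal"])
        sub = env[:3]
        delta = environment_delta(env, sub)
        assert delta.n_lost == len(env) - 3
        assert delta.n_gained == 0
        assert delta.n_retained == 3
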