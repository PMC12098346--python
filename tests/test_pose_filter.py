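"""Membrane triage: superposition, exclusion rules, centroid selection."""

import numpy as np
import pytest

from structscope import (
    FilterCriteria,
    MembraneFrame,
    PoseRecord,
    StructureError,
    filter_pose,
    gamma_cterm,
    make_pose_ensemble,
    read_pose_table,
    read_structure,
    select_models,
    superpose,
    triage_ensemble,
)
from structscope.geometry import random_rotation
from structscope.model import Atom, Residue, StructureModel
from structscope.synthetic import _make_residue, _residue_unit, _transform_unit


def _simple_pose(lig_z_shift=0.0, cterm_depth=10.0, frame=None):
    """Receptor spanning the membrane plus a two-chain ligand below it."""
    frame = frame or MembraneFrame(15.0, -15.0)
    from structscope.geometry import rotation_about_axis

    ala = _residue_unit("ALA")
    chains = {"R": [], "B": [], "G": []}
    for i in range(4):
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 90.0 * i)
        shift = rot @ np.array([2.5, 0.0, 0.0]) + np.array([0.0, 0.0, -15.0 + 10.0 * i])
        unit = _transform_unit(ala, rot, shift)
        chains["R"].append(_make_residue("R", i + 1, "ALA", unit))
    for i in range(2):
        z = frame.z_lower - 5.0 - 3.0 * i + lig_z_shift
        unit = _transform_unit(ala, np.eye(3), np.array([6.0, 0.0, z]))
        chains["B"].append(_make_residue("B", i + 1, "ALA", unit))
    for i in range(2):
        z = frame.z_lower - (cterm_depth - 2.0 if i == 0 else cterm_depth)
        unit = _transform_unit(ala, np.eye(3), np.array([-6.0, 2.0 * i, z]))
        chains["G"].append(_make_residue("G", i + 1, "ALA", unit))
    # pin the terminal CA exactly at the requested depth
    ca = chains["G"][-1].atom("CA")
    ca.coords = np.array([-6.0, 2.0, frame.z_lower - cterm_depth])
    return StructureModel(id="pose", chains=chains), frame


CRIT = FilterCriteria(gamma_chain="G", receptor_chains=("R",), ligand_chains=("B", "G"))


class TestSuperpose:
    def test_identity_alignment_is_zero_rmsd(self):
        model, _ = _simple_pose()
        sp = superpose(model, model, ("R",))
        assert sp.rmsd <= 1e-9

    def test_random_rigid_transform_recovered(self):
        model, _ = _simple_pose()
        rng = np.random.default_rng(7)
        rot = random_rotation(rng)
        t = rng.uniform(-40, 40, 3)
        moved = model.copy()
        for res in moved.residues():
            for a in res.atoms:
                a.coords = rot @ a.coords + t
        sp = superpose(moved, model, ("R",))
        assert sp.rmsd <= 1e-6
        np.testing.assert_allclose(sp.rotation @ rot, np.eye(3), atol=1e-9)

    def test_too_few_or_collinear_selections_rejected(self):
        model, _ = _simple_pose()
        two = model.copy()
        two.chains["R"] = two.chains["R"][:2]
        with pytest.raises(StructureError, match="at least 3"):
            superpose(two, two, ("R",))
        collinear = model.copy()
        for i, res in enumerate(collinear.chains["R"]):
            res.atom("CA").coords = np.array([0.0, 0.0, float(i)])
        with pytest.raises(StructureError, match="collinear"):
            superpose(collinear, collinear, ("R",))


class TestGammaCterm:
    def test_highest_numbered_residue_wins(self):
        model, _ = _simple_pose(cterm_depth=12.0)
        ca = gamma_cterm(model, "G")
        assert ca.coords[2] == pytest.approx(-27.0)

    def test_icode_ordering(self):
        ala = _residue_unit("ALA")
        r1 = _make_residue("G", 5, "ALA", ala)
        r2 = _make_residue("G", 5, "ALA", _transform_unit(ala, np.eye(3), np.array([5.0, 0, 0])))
        r2.icode = "A"
        model = StructureModel(chains={"G": [r1, r2]})
        assert gamma_cterm(model, "G").coords[0] == pytest.approx(5.0)

    def test_missing_chain_raises(self):
        model, _ = _simple_pose()
        with pytest.raises(StructureError, match="absent"):
            gamma_cterm(model, "Z")


class TestFilterPose:
    def test_compliant_pose_retained(self):
        model, frame = _simple_pose()
        v = filter_pose(model, frame, CRIT)
        assert v.retained and v.reason == "none"

    def test_single_atom_above_lower_leaflet_excludes(self):
        model, frame = _simple_pose()
        # push one ligand atom just past the plane
        atom = model.chains["B"][0].atoms[0]
        atom.coords = np.array([6.0, 0.0, frame.z_lower + 0.1])
        v = filter_pose(model, frame, CRIT)
        assert not v.retained and v.reason == "atom_above_lower_leaflet"
        assert v.worst_z == pytest.approx(frame.z_lower + 0.1)

    def test_cterm_exactly_30_retained_strictly_more_excluded(self):
        model, frame = _simple_pose(cterm_depth=30.0)
        v = filter_pose(model, frame, CRIT)
        assert v.retained, "boundary 30.0 Å is not 'more than 30'"
        model2, frame2 = _simple_pose(cterm_depth=30.01)
        v2 = filter_pose(model2, frame2, CRIT)
        assert not v2.retained and v2.reason == "gamma_cterm_too_far"

    def test_missing_ligand_chain_raises(self):
        model, frame = _simple_pose()
        del model.chains["B"]
        with pytest.raises(StructureError, match="absent"):
            filter_pose(model, frame, CRIT)


class TestTriageEnsemble:
    def test_planted_verdicts_recovered_exactly(self, pose_ensemble):
        records = read_pose_table(pose_ensemble.paths["pose_table"])
        ref = read_structure(pose_ensemble.paths["reference"])
        frame = MembraneFrame.from_dum_atoms(ref)
        assert frame.z_lower == pytest.approx(-15.0)
        retained, verdicts = triage_ensemble(
            records, frame, ref, CRIT, base_dir=str(
                __import__("pathlib").Path(pose_ensemble.paths["pose_table"]).parent
            )
        )
        truth = {t["model_id"]: (t["retained"], t["reason"]) for t in pose_ensemble.truth["poses"]}
        for v in verdicts:
            assert (v.retained, v.reason) == truth[v.model_id]
        assert [p.model_id for p in retained] == pose_ensemble.truth["retained"]
        # conservation: every pose gets exactly one verdict
        assert len(verdicts) == len(records)

    def test_selection_matches_planted_argmax_argmin(self, pose_ensemble):
        records = read_pose_table(pose_ensemble.paths["pose_table"])
        by_id = {r.model_id: r for r in records}
        retained = [by_id[m] for m in pose_ensemble.truth["retained"]]
        picks = select_models(retained)
        assert [p.model_id for p in picks] == pose_ensemble.truth["selected"]

    def test_all_excluded_ensemble_retains_nothing(self, tmp_path):
        m = make_pose_ensemble(seed=9, n_poses=6, frac_above_leaflet=1.0,
                               frac_cterm_far=0.0, out_dir=tmp_path / "allfail")
        records = read_pose_table(m.paths["pose_table"])
        ref = read_structure(m.paths["reference"])
        frame = MembraneFrame.from_dum_atoms(ref)
        retained, verdicts = triage_ensemble(records, frame, ref, CRIT, tmp_path / "allfail")
        assert retained == []
        assert all(v.reason == "atom_above_lower_leaflet" for v in verdicts)

    def test_relaxing_cterm_limit_is_monotone(self, pose_ensemble):
        import pathlib

        records = read_pose_table(pose_ensemble.paths["pose_table"])
        ref = read_structure(pose_ensemble.paths["reference"])
        frame = MembraneFrame.from_dum_atoms(ref)
        base = pathlib.Path(pose_ensemble.paths["pose_table"]).parent
        strict, _ = triage_ensemble(records, frame, ref, CRIT, base)
        loose_crit = FilterCriteria(gamma_chain="G", receptor_chains=("R",),
                                    ligand_chains=("B", "G"), max_gamma_cterm_distance=60.0)
        loose, _ = triage_ensemble(records, frame, ref, loose_crit, base)
        assert {p.model_id for p in strict} <= {p.model_id for p in loose}

    def test_unreadable_pose_logged_and_run_continues(self, pose_ensemble, tmp_path):
        import pathlib

        records = read_pose_table(pose_ensemble.paths["pose_table"])
        records[0].path = "missing_file.pdb"
        ref = read_structure(pose_ensemble.paths["reference"])
        frame = MembraneFrame.from_dum_atoms(ref)
        base = pathlib.Path(pose_ensemble.paths["pose_table"]).parent
        retained, verdicts = triage_ensemble(records, frame, ref, CRIT, base)
        assert verdicts[0].reason.startswith("error:")
        assert len(verdicts) == len(records)


class TestSelectModels:
    def _rec(self, mid, cid, size, score):
        return PoseRecord(model_id=mid, path=f"{mid}.pdb", cluster_id=cid,
                          cluster_size=size, score=score)

    def test_single_cluster_double_role(self):
        picks = select_models([self._rec("a", 1, 5, -10.0)])
        assert [p.model_id for p in picks] == ["a"]

    def test_largest_and_best_score_roles(self):
        a = self._rec("a", 1, 10, -50.0)
        b = self._rec("b", 2, 3, -80.0)
        picks = select_models([a, b])
        assert [p.model_id for p in picks] == ["a", "b"]

    def test_matches_brute_force_scan_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(1, 12))
            recs = [
                self._rec(f"m{i}", i, int(rng.integers(1, 30)),
                          float(np.round(rng.uniform(-100, -10), 2)))
                for i in range(n)
            ]
            picks = select_models(recs)
            largest = min(recs, key=lambda p: (-p.cluster_size, p.score, p.cluster_id))
            best = min(recs, key=lambda p: (p.score, p.cluster_id))
            expected = [largest.model_id]
            if best.model_id != largest.model_id:
                expected.append(best.model_id)
            assert [p.model_id for p in picks] == expected

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        recs = [self._rec(f"m{i}", i, int(rng.integers(1, 20)),
                          float(rng.uniform(-90, -10))) for i in range(8)]
        baseline = [p.model_id for p in select_models(recs)]
        for _ in range(5):
            rng.shuffle(recs)
            assert [p.model_id for p in select_models(recs)] == baseline

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no retained"):
            select_models([])


def test_filtering_invariant_under_joint_rigid_shift_along_xy():
    """Moving pose and frame together in the membrane plane changes nothing."""
    model, frame = _simple_pose()
    v0 = filter_pose(model, frame, CRIT)
    shifted = model.copy()
    for res in shifted.residues():
        for a in res.atoms:
            a.coords = a.coords + np.array([25.0, -13.0, 0.0])
    v1 = filter_pose(shifted, frame, CRIT)
    assert (v0.retained, v0.reason) == (v1.retained, v1.reason)
    assert v0.gamma_cterm_distance == pytest.approx(v1.gamma_cterm_distance)
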