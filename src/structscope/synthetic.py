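"""Deterministic synthetic fixtures with planted ground truth.

Every pipeline stage can be exercised without downloading real structures:
this module builds small poly-ALA chains (plus one fully built focal LEU)
whose cross-chain contact distances, membrane-geometry verdicts and ΔΔG
classes are *planted by construction* and emitted alongside the files as a
truth record.  Fixtures are tiny (≤ a few hundred atoms) so brute-force
oracles over all atom pairs run in milliseconds, and generation is seeded
and text-only, so the same seed reproduces byte-identical files.

The complex fixture emulates the shape of a channel–Gβγ interface study: a
focal leucine with a planted number of cross-chain contacts, a subset of
which are anchored on side-chain tip atoms and therefore disappear under a
rigid Leu→Pro substitution, while backbone-anchored contacts survive.  The
generator verifies all planted margins and raises on infeasible geometry
rather than emitting a fixture whose truth could be wrong.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import canonical_backbone, random_rotation, rotation_about_axis
from .model import Atom, Residue, ResidueKey, StructureModel, write_structure
from .mutate import build_side_chain
from .poses import MembraneFrame, PoseRecord, write_pose_table

__all__ = [
    "FixtureManifest",
    "GeometryError",
    "make_complex",
    "make_pose_ensemble",
    "make_ddg_table",
    "make_interaction_cluster",
]

CONTACT_CUTOFF = 5.5  # the downstream interface criterion the truths assume
_MARGIN = 0.05


class GeometryError(ValueError):
    """Planted geometry is infeasible or a verification margin failed."""


@dataclass
class FixtureManifest:
    seed: int
    fixture_kind: str  # complex | pose_ensemble | ddg_table | interaction_cluster
    truth: dict
    paths: dict[str, str] = field(default_factory=dict)
    model: StructureModel | None = None  # in-memory convenience copy

    def write_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------- units

def _residue_unit(aa_name: str) -> dict[str, np.ndarray]:
    """Canonical residue (backbone + ideal side chain), CA at the origin."""
    frame = canonical_backbone()
    coords = dict(frame)
    coords.update(build_side_chain(frame, aa_name))
    return coords


def _make_residue(
    chain_id: str, number: int, aa_name: str, coords: dict[str, np.ndarray]
) -> Residue:
    atoms = [
        Atom(name=n, element=("S" if n in ("SG", "SD") else n[0]), coords=c)
        for n, c in coords.items()
    ]
    return Residue(chain_id, number, "", aa_name, atoms)


def _transform_unit(
    unit: dict[str, np.ndarray], rotation: np.ndarray, translation: np.ndarray
) -> dict[str, np.ndarray]:
    return {n: rotation @ c + translation for n, c in unit.items()}


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 deg about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        return rotation_about_axis(axis, 180.0)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _min_dist(unit_a: dict[str, np.ndarray], unit_b: dict[str, np.ndarray]):
    """(min distance, name_a, name_b) over all atom pairs of two units."""
    names_a = list(unit_a)
    names_b = list(unit_b)
    ca = np.array([unit_a[n] for n in names_a])
    cb = np.array([unit_b[n] for n in names_b])
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    ij = np.unravel_index(np.argmin(d), d.shape)
    return float(d[ij]), names_a[ij[0]], names_b[ij[1]]


def _place_at_min_distance(
    unit: dict[str, np.ndarray],
    target: dict[str, np.ndarray],
    direction: np.ndarray,
    distance: float,
    point_atom: str = "CB",
) -> dict[str, np.ndarray]:
    """Rigidly place ``unit`` along ``direction`` from ``target`` so the
    minimal atom-pair distance equals ``distance`` exactly.

    The unit is oriented with its ``point_atom`` facing the target, pushed
    out along the direction, then slid until the minimum distance matches.
    """
    u = direction / np.linalg.norm(direction)
    # orient: unit's CA->point_atom axis opposing the approach direction
    axis = unit[point_atom] - unit["CA"]
    rot = _rotation_between(axis, -u)
    oriented = _transform_unit(unit, rot, np.zeros(3))
    # start far out along u from the extreme target atom
    target_coords = np.array(list(target.values()))
    start = target_coords[np.argmax(target_coords @ u)] + (distance + 6.0) * u
    placed = _transform_unit(oriented, np.eye(3), start - oriented[point_atom])
    for _ in range(200):
        m, _, _ = _min_dist(target, placed)
        err = m - distance
        if abs(err) < 1e-9:
            break
        placed = {n: c - err * u for n, c in placed.items()}
    m, _, _ = _min_dist(target, placed)
    if abs(m - distance) > 1e-6:
        raise GeometryError(f"could not plant contact at {distance} Å (got {m:.4f})")
    return placed


def _cone_directions(base: np.ndarray, n: int, half_angle_deg: float, phase: float):
    """n unit vectors on a cone around ``base``."""
    base = base / np.linalg.norm(base)
    if n == 1:
        return [base]
    ref = np.array([0.0, 0.0, 1.0]) if abs(base[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(base, ref)
    v /= np.linalg.norm(v)
    w = np.cross(base, v)
    a = np.radians(half_angle_deg)
    out = []
    for j in range(n):
        phi = phase + 2 * np.pi * j / n
        d = base * np.cos(a) + (v * np.cos(phi) + w * np.sin(phi)) * np.sin(a)
        out.append(d / np.linalg.norm(d))
    return out


# ---------------------------------------------------------------- complex

def make_complex(
    seed: int,
    n_res_a: int = 9,
    n_res_b: int = 9,
    n_contacts: int = 7,
    contact_distance: float = 5.0,
    background_min_distance: float = 8.0,
    n_retained_on_mutation: int | None = None,
    out_dir: str | Path | None = None,
) -> FixtureManifest:
    """Two-chain complex with ``n_contacts`` planted focal contacts.

    Chain A carries a focal LEU in the middle of a widely spaced poly-ALA
    arc; chain B residues are planted so that exactly ``n_contacts`` of them
    touch the focal residue at ``contact_distance`` (±0.01 Å) while every
    other cross-chain residue pair stays beyond ``background_min_distance``.
    ``n_retained_on_mutation`` of the planted contacts anchor on backbone/CB
    atoms (surviving a rigid Leu→Pro substitution); the rest anchor on the
    leucine side-chain tip and are planted far enough from all persisting
    atoms to vanish from the 5.5 Å environment of the mutant.
    """
    if not contact_distance < CONTACT_CUTOFF < background_min_distance:
        raise GeometryError(
            "need contact_distance < 5.5 < background_min_distance, got "
            f"{contact_distance} / {background_min_distance}"
        )
    if n_contacts > n_res_b:
        raise GeometryError(
            f"cannot plant {n_contacts} contacts with only {n_res_b} chain-B residues"
        )
    if n_retained_on_mutation is None:
        n_retained_on_mutation = min(3, n_contacts)
    if not 0 <= n_retained_on_mutation <= n_contacts:
        raise GeometryError("n_retained_on_mutation must be within [0, n_contacts]")
    if n_contacts > 12:
        raise GeometryError("at most 12 planted contacts fit around one focal residue")
    if n_res_a < 1:
        raise GeometryError("chain A needs at least one residue")
    rng = np.random.default_rng(seed)

    rise = 18.0
    focal_index = n_res_a // 2
    ala = _residue_unit("ALA")
    leu = _residue_unit("LEU")
    chain_a: list[Residue] = []
    focal_unit: dict[str, np.ndarray] = {}
    for i in range(n_res_a):
        z = (i - focal_index) * rise
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 137.0 * i)
        shift = rot @ np.array([2.3, 0.0, 0.0]) + np.array([0.0, 0.0, z])
        if i == focal_index:
            unit = _transform_unit(leu, np.eye(3), np.zeros(3))
            focal_unit = unit
            chain_a.append(_make_residue("A", i + 1, "LEU", unit))
        else:
            chain_a.append(_make_residue("A", i + 1, "ALA", _transform_unit(ala, rot, shift)))
    focal_key = ResidueKey("A", focal_index + 1, "")

    persisting = {n: focal_unit[n] for n in ("N", "CA", "C", "O", "CB")}
    removed = {n: focal_unit[n] for n in ("CG", "CD1", "CD2")}
    # the rigid-template mutant is deterministic, so the exact post-mutation
    # atom set (backbone + CB + ideal proline ring) is known in advance
    mutant_atoms = dict(persisting)
    mutant_atoms.update(build_side_chain(dict(persisting), "PRO", skip=set(persisting)))
    # kept contacts approach from the backbone side (opposite the side chain);
    # lost contacts extend past the side-chain tip, directly away from CB so
    # the rebuilt proline ring cannot reach them
    u_side = focal_unit["CB"] - focal_unit["CA"]
    u_side /= np.linalg.norm(u_side)
    u_tip = focal_unit["CD1"] - focal_unit["CB"]
    u_tip /= np.linalg.norm(u_tip)

    n_lost = n_contacts - n_retained_on_mutation
    phase_kept = rng.uniform(0, 2 * np.pi)
    phase_lost = rng.uniform(0, 2 * np.pi)
    kept_dirs = _cone_directions(-u_side, n_retained_on_mutation, 30.0, phase_kept)
    lost_dirs = _cone_directions(u_tip, n_lost, 10.0, phase_lost)

    chain_b: list[Residue] = []
    planted = []
    b_number = 0
    for dirs, is_kept in ((kept_dirs, True), (lost_dirs, False)):
        for u in dirs:
            placed = _place_at_min_distance(ala, focal_unit, u, contact_distance)
            m, name_f, _ = _min_dist(focal_unit, placed)
            if is_kept and name_f not in persisting:
                raise GeometryError(
                    f"kept contact realized at non-persisting atom {name_f}"
                )
            if not is_kept:
                if name_f not in removed:
                    raise GeometryError(
                        f"lost contact realized at persisting atom {name_f}"
                    )
                # after the rigid Leu->Pro every surviving atom (backbone,
                # CB and the ideal proline ring) must stay outside the 5.5 Å
                # environment, so the contact disappears in the mutant
                m_mut, _, _ = _min_dist(mutant_atoms, placed)
                if m_mut <= CONTACT_CUTOFF + _MARGIN:
                    raise GeometryError(
                        f"lost contact within {m_mut:.2f} Å of the mutant residue"
                    )
            b_number += 1
            chain_b.append(_make_residue("B", b_number, "ALA", placed))
            planted.append(
                {
                    "residue_a": str(focal_key),
                    "residue_b": f"B:{b_number}",
                    "distance": round(m, 4),
                    "retained_on_mutation": is_kept,
                }
            )
    # background chain-B residues, far from everything
    n_far = n_res_b - n_contacts
    for j in range(n_far):
        theta = 360.0 * j / max(n_far, 1)
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), theta)
        shift = rot @ np.array([32.0, 0.0, 0.0]) + np.array(
            [0.0, 0.0, -(focal_index + 1) * rise - 15.0 - 7.0 * j]
        )
        b_number += 1
        chain_b.append(_make_residue("B", b_number, "ALA", _transform_unit(ala, rot, shift)))

    model = StructureModel(id=f"complex_seed{seed}", chains={"A": chain_a, "B": chain_b})

    # full cross-chain verification against the planted truth
    planted_pairs = {(p["residue_a"], p["residue_b"]): p["distance"] for p in planted}
    for ra in chain_a:
        ua = {a.name: a.coords for a in ra.atoms}
        for rb in chain_b:
            ub = {a.name: a.coords for a in rb.atoms}
            m, _, _ = _min_dist(ua, ub)
            key = (str(ra.key), str(rb.key))
            if key in planted_pairs:
                if abs(m - contact_distance) > 0.01:
                    raise GeometryError(f"planted pair {key} at {m:.3f} Å, wanted {contact_distance}")
            elif m <= background_min_distance:
                raise GeometryError(
                    f"background pair {key} at {m:.2f} Å, within {background_min_distance}"
                )

    truth = {
        "focal": str(focal_key),
        "focal_aa": "LEU",
        "mutation": f"A:{focal_key.number}:LEU>PRO",
        "chain_a": "A",
        "chain_b": "B",
        "contact_distance": contact_distance,
        "contacts": planted,
        "n_contacts": n_contacts,
        "n_retained_on_mutation": n_retained_on_mutation,
        "n_lost_on_mutation": n_lost,
    }
    manifest = FixtureManifest(seed=seed, fixture_kind="complex", truth=truth, model=model)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pdb = out / "complex.pdb"
        write_structure(model, pdb)
        manifest.paths["structure"] = str(pdb)
        tj = out / "truth.json"
        manifest.write_truth(tj)
        manifest.paths["truth"] = str(tj)
    return manifest


# ---------------------------------------------------------------- poses

def _ligand_units() -> tuple[list[tuple[str, int, str, dict]], float, float]:
    """Gβγ-like rigid ligand in local coordinates.

    Returns (units, top_z, cterm_z): chain B is a compact poly-ALA blob,
    chain G a short descending chain whose last CA is the C-terminal anchor.
    """
    ala = _residue_unit("ALA")
    units = []
    for i in range(6):
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 75.0 * i)
        shift = rot @ np.array([4.5, 0.0, 0.0]) + np.array([0.0, 0.0, 5.0 + 2.0 * (i % 3)])
        units.append(("B", i + 1, "ALA", _transform_unit(ala, rot, shift)))
    g_positions = [(-2.0, 3.5, 2.0), (-3.5, 1.0, 0.0), (-2.5, -2.0, -1.0), (0.0, -3.0, -2.0)]
    for i, (x, y, z) in enumerate(g_positions):
        rot = rotation_about_axis(np.array([0.0, 1.0, 0.0]), 40.0 * i)
        units.append(("G", i + 1, "ALA", _transform_unit(ala, rot, np.array([x, y, z]))))
    top_z = max(c[2] for _, _, _, unit in units for c in unit.values())
    cterm_z = units[-1][3]["CA"][2]
    return units, top_z, cterm_z


def _receptor_units() -> list[tuple[str, int, str, dict]]:
    ala = _residue_unit("ALA")
    units = []
    for i in range(11):
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 100.0 * i)
        shift = rot @ np.array([2.0, 0.0, 0.0]) + np.array([0.0, 0.0, -20.0 + 4.0 * i])
        units.append(("R", i + 1, "ALA", _transform_unit(ala, rot, shift)))
    return units


def _units_to_model(model_id: str, units) -> StructureModel:
    chains: dict[str, list[Residue]] = {}
    for chain_id, number, aa, unit in units:
        chains.setdefault(chain_id, []).append(_make_residue(chain_id, number, aa, unit))
    return StructureModel(id=model_id, chains=chains)


def _dum_residues(frame: MembraneFrame) -> list[Residue]:
    out = []
    num = 9000
    for z in (frame.z_upper, frame.z_lower):
        for x, y in ((-25.0, -25.0), (25.0, -25.0), (-25.0, 25.0), (25.0, 25.0)):
            num += 1
            atom = Atom(name="DUM", element="N", coords=np.array([x, y, z]), is_hetero=True)
            out.append(Residue("M", num, "", "DUM", [atom]))
    return out


def make_pose_ensemble(
    seed: int,
    n_poses: int = 40,
    frac_above_leaflet: float = 0.3,
    frac_cterm_far: float = 0.2,
    frame: MembraneFrame | None = None,
    out_dir: str | Path | None = None,
    max_gamma_cterm_distance: float = 30.0,
) -> FixtureManifest:
    """Docked-pose ensemble with planted membrane-triage verdicts.

    Each pose holds a membrane-spanning receptor (chain R) plus a rigid
    Gβγ-like ligand (chains B and G) placed so the pose passes both
    exclusion rules, pokes an atom above the lower leaflet, or parks the
    γ C-terminal Cα more than 30 Å below it.  Whole poses are scrambled by
    a random rigid transform, so triage must first superpose the receptor
    onto the in-frame reference.  One cluster-score row per pose (every
    pose a centroid) with distinct sizes and scores; the truth records the
    per-pose verdict and the expected largest-cluster / best-score picks.
    """
    if not (0 <= frac_above_leaflet <= 1 and 0 <= frac_cterm_far <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if frac_above_leaflet + frac_cterm_far > 1:
        raise ValueError("fractions must sum to at most 1")
    frame = frame or MembraneFrame(z_upper=15.0, z_lower=-15.0)
    rng = np.random.default_rng(seed)

    receptor = _receptor_units()
    ligand, top_z, cterm_z = _ligand_units()
    delta = top_z - cterm_z  # vertical extent from anchor to highest atom

    n_above = int(round(n_poses * frac_above_leaflet))
    n_far = int(round(n_poses * frac_cterm_far))
    n_far = min(n_far, n_poses - n_above)
    labels = ["above"] * n_above + ["far"] * n_far + ["pass"] * (n_poses - n_above - n_far)
    rng.shuffle(labels)

    score_types = ("balanced", "electrostatic", "hydrophobic", "vdw")
    sizes = rng.choice(np.arange(1, max(3 * n_poses, 10)), size=n_poses, replace=False)
    scores = rng.choice(np.arange(2000, 12001), size=n_poses, replace=False) / -100.0

    reference = _units_to_model("reference", receptor)
    reference.chains["M"] = _dum_residues(frame)

    records: list[PoseRecord] = []
    pose_models: list[StructureModel] = []
    truth_poses = []
    for i, label in enumerate(labels):
        if label == "pass":
            top_target = frame.z_lower - rng.uniform(1.0, 6.0)
        elif label == "above":
            top_target = frame.z_lower + rng.uniform(0.5, 4.0)
        else:  # far
            ct = rng.uniform(33.0, 45.0)
            top_target = frame.z_lower + delta - ct
        dz = top_target - top_z
        dxy = rng.uniform(-8.0, 8.0, size=2)
        shift = np.array([dxy[0], dxy[1], dz])
        lig = [(c, n, aa, _transform_unit(u, np.eye(3), shift)) for c, n, aa, u in ligand]

        # verify the planted verdict in frame coordinates
        atoms_z = [c[2] for _, _, _, u in lig for c in u.values()]
        ct_dist = frame.z_lower - lig[-1][3]["CA"][2]
        worst = max(atoms_z)
        if label == "pass":
            assert worst <= frame.z_lower - 0.5 and ct_dist <= max_gamma_cterm_distance - 0.5
        elif label == "above":
            assert worst >= frame.z_lower + 0.3
        else:
            assert ct_dist >= max_gamma_cterm_distance + 2.0 and worst < frame.z_lower - 0.5

        rot = random_rotation(rng)
        trans = rng.uniform(-30.0, 30.0, size=3)
        scrambled = [
            (c, n, aa, _transform_unit(u, rot, trans)) for c, n, aa, u in receptor + lig
        ]
        model_id = f"pose_{i:03d}"
        pose_models.append(_units_to_model(model_id, scrambled))
        records.append(
            PoseRecord(
                model_id=model_id,
                path=f"{model_id}.pdb",
                cluster_id=i + 1,
                cluster_size=int(sizes[i]),
                score=float(scores[i]),
                score_type=score_types[i % 4],
            )
        )
        reason = {"pass": "none", "above": "atom_above_lower_leaflet", "far": "gamma_cterm_too_far"}[label]
        truth_poses.append(
            {
                "model_id": model_id,
                "retained": label == "pass",
                "reason": reason,
                "cluster_size": int(sizes[i]),
                "score": float(scores[i]),
            }
        )

    retained_truth = [t for t in truth_poses if t["retained"]]
    selection = []
    if retained_truth:
        largest = min(retained_truth, key=lambda t: (-t["cluster_size"], t["score"]))
        best = min(retained_truth, key=lambda t: t["score"])
        selection = [largest["model_id"]]
        if best["model_id"] != largest["model_id"]:
            selection.append(best["model_id"])
    truth = {
        "n_poses": n_poses,
        "frame": {"z_upper": frame.z_upper, "z_lower": frame.z_lower},
        "gamma_chain": "G",
        "receptor_chains": ["R"],
        "ligand_chains": ["B", "G"],
        "max_gamma_cterm_distance": max_gamma_cterm_distance,
        "poses": truth_poses,
        "retained": [t["model_id"] for t in retained_truth],
        "selected": selection,
    }
    manifest = FixtureManifest(seed=seed, fixture_kind="pose_ensemble", truth=truth)
    manifest.reference = reference  # type: ignore[attr-defined]
    manifest.pose_models = pose_models  # type: ignore[attr-defined]
    manifest.records = records  # type: ignore[attr-defined]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ref_path = out / "reference.pdb"
        write_structure(reference, ref_path)
        manifest.paths["reference"] = str(ref_path)
        for rec, pm in zip(records, pose_models):
            write_structure(pm, out / rec.path)
        table = out / "poses.tsv"
        write_pose_table(records, table)
        manifest.paths["pose_table"] = str(table)
        tj = out / "truth.json"
        manifest.write_truth(tj)
        manifest.paths["truth"] = str(tj)
    return manifest


# ---------------------------------------------------------------- ddg

CLASS_INTERVALS = {
    "significant": (1.05, 3.0),
    "above_noise": (0.65, 0.95),
    "within_noise": (0.0, 0.55),
}


def make_ddg_table(
    seed: int,
    n_rows: int = 12,
    class_mix: dict[str, float] | None = None,
    out_dir: str | Path | None = None,
) -> FixtureManifest:
    """ΔΔG table sampled inside each class's magnitude interval.

    ``class_mix`` gives the fraction of rows per class (must sum to 1);
    stability and affinity columns are labelled independently.  Signs are
    random (classification is magnitude-based).
    """
    mix = class_mix or {"significant": 1 / 3, "above_noise": 1 / 3, "within_noise": 1 / 3}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix fractions must sum to 1")
    rng = np.random.default_rng(seed)

    def assign(counts_seed: int) -> list[str]:
        # largest-remainder apportionment, then shuffle
        quotas = {k: n_rows * v for k, v in mix.items()}
        counts = {k: int(np.floor(q)) for k, q in quotas.items()}
        left = n_rows - sum(counts.values())
        for k in sorted(mix, key=lambda k: -(quotas[k] - counts[k]))[:left]:
            counts[k] += 1
        labels = [k for k, c in counts.items() for _ in range(c)]
        rng.shuffle(labels)
        return labels

    stab_labels = assign(0)
    aff_labels = assign(1)
    rows = []
    for i in range(n_rows):
        entry = {"complex_id": f"cpx_{i:02d}", "mutation": "L95P"}
        for col, label in (("ddg_stability", stab_labels[i]), ("ddg_affinity", aff_labels[i])):
            lo, hi = CLASS_INTERVALS[label]
            mag = rng.uniform(lo, hi)
            sign = 1.0 if rng.uniform() < 0.8 else -1.0
            entry[col] = round(sign * mag, 3)
        rows.append(entry)
    truth = {
        "n_rows": n_rows,
        "rows": [
            {
                "complex_id": rows[i]["complex_id"],
                "class_stability": stab_labels[i],
                "class_affinity": aff_labels[i],
            }
            for i in range(n_rows)
        ],
    }
    manifest = FixtureManifest(seed=seed, fixture_kind="ddg_table", truth=truth)
    manifest.rows = rows  # type: ignore[attr-defined]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = out / "ddg.tsv"
        with open(table, "w") as fh:
            fh.write("complex_id\tmutation\tddg_stability\tddg_affinity\tprovenance\n")
            for r in rows:
                fh.write(
                    f"{r['complex_id']}\t{r['mutation']}\t{r['ddg_stability']}\t"
                    f"{r['ddg_affinity']}\tsynthetic\n"
                )
        manifest.paths["table"] = str(table)
        tj = out / "truth.json"
        manifest.write_truth(tj)
        manifest.paths["truth"] = str(tj)
    return manifest


# ------------------------------------------------- interaction cluster

def make_interaction_cluster(seed: int = 0, out_dir: str | Path | None = None) -> FixtureManifest:
    """Single-chain cluster with planted interaction kinds around a focal LEU.

    Partners are placed in separate angular sectors so that only the planted
    pairs fall inside any rule window: a second leucine in side-chain carbon
    range (hydrophobic), a serine whose OG hydrogen-bonds the focal backbone
    O, and an alanine at generic fallback range.  All other residue pairs
    exceed the 5.5 Å contact cutoff.
    """
    leu = _residue_unit("LEU")
    ser = _residue_unit("SER")
    ala = _residue_unit("ALA")
    focal = dict(leu)
    u_tip = focal["CD1"] - focal["CA"]
    u_tip /= np.linalg.norm(u_tip)

    # hydrophobic partner: leucine tip-to-tip at 4.5 Å
    leu2 = _place_at_min_distance(leu, focal, u_tip, 4.5, point_atom="CD1")
    # hbond partner: serine OG at 3.2 Å from the focal backbone O
    u_o = focal["O"] - focal["CA"]
    u_o /= np.linalg.norm(u_o)
    ser1 = _place_at_min_distance(ser, focal, u_o, 3.2, point_atom="OG")
    # generic partner: alanine at 5.2 Å, perpendicular to both other sectors
    u_back = np.cross(u_tip, u_o)
    u_back /= np.linalg.norm(u_back)
    ala1 = _place_at_min_distance(ala, focal, u_back, 5.2, point_atom="CB")

    residues = [
        _make_residue("A", 1, "LEU", focal),
        _make_residue("A", 3, "LEU", leu2),
        _make_residue("A", 5, "SER", ser1),
        _make_residue("A", 7, "ALA", ala1),
    ]
    model = StructureModel(id=f"rin_cluster_seed{seed}", chains={"A": residues})

    # verify sector separation and rule windows
    units = {"A:1": focal, "A:3": leu2, "A:5": ser1, "A:7": ala1}
    for ka, kb in (("A:3", "A:5"), ("A:3", "A:7"), ("A:5", "A:7")):
        m, _, _ = _min_dist(units[ka], units[kb])
        if m <= CONTACT_CUTOFF + _MARGIN:
            raise GeometryError(f"partners {ka}/{kb} too close ({m:.2f} Å)")
    d_hb = float(np.linalg.norm(ser1["OG"] - focal["O"]))
    if abs(d_hb - 3.2) > 1e-6:
        raise GeometryError("hbond pair not at planted distance")

    truth = {
        "focal": "A:1",
        "nodes": ["A:1", "A:3", "A:5", "A:7"],
        "edges": [
            {"residue_a": "A:1", "residue_b": "A:3", "kind": "hydrophobic"},
            {"residue_a": "A:1", "residue_b": "A:5", "kind": "hbond"},
            {"residue_a": "A:1", "residue_b": "A:7", "kind": "generic"},
        ],
    }
    manifest = FixtureManifest(
        seed=seed, fixture_kind="interaction_cluster", truth=truth, model=model
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pdb = out / "cluster.pdb"
        write_structure(model, pdb)
        manifest.paths["structure"] = str(pdb)
        tj = out / "truth.json"
        manifest.write_truth(tj)
        manifest.paths["truth"] = str(tj)
    return manifest
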