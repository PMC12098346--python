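"""Membrane-geometry triage of docked poses and centroid selection.

The membrane is a pair of z-planes (OPM convention, +z toward the
extracellular side).  After rigid superposition of each pose's receptor onto
a membrane-embedded reference, two conjunctive exclusion rules apply:

1. any ligand (Gβγ) heavy atom strictly *above* the lower (cytoplasmic)
   leaflet plane (z > z_lower) excludes the pose;
2. a γ-chain C-terminal Cα strictly *more than* ``max_gamma_cterm_distance``
   (default 30 Å) below the lower leaflet excludes the pose — the physical
   rationale being the geranylgeranyl membrane anchor of the Gγ C-terminus.

Distances to leaflets are signed plane distances along z.  From the
retained poses, the centroids of the largest cluster and of the best
(lowest) energy-score cluster are selected.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .model import Atom, ResidueKey, StructureModel, StructureError, read_structure

__all__ = [
    "MembraneFrame",
    "PoseRecord",
    "FilterCriteria",
    "FilterVerdict",
    "Superposition",
    "superpose",
    "apply_superposition",
    "gamma_cterm",
    "filter_pose",
    "triage_ensemble",
    "select_models",
    "read_pose_table",
    "write_pose_table",
    "write_verdicts",
    "read_cluspro_scores",
]


@dataclass(frozen=True)
class MembraneFrame:
    """Leaflet z-planes; +z points to the extracellular side."""

    z_upper: float
    z_lower: float

    def __post_init__(self) -> None:
        if not self.z_upper > self.z_lower:
            raise ValueError(
                f"z_upper ({self.z_upper}) must exceed z_lower ({self.z_lower})"
            )

    def flipped(self) -> "MembraneFrame":
        """Mirror the membrane normal (for structures embedded -z out)."""
        return MembraneFrame(z_upper=-self.z_lower, z_lower=-self.z_upper)

    @classmethod
    def from_dum_atoms(cls, model: StructureModel) -> "MembraneFrame":
        """Infer leaflet planes from OPM DUM pseudo-atom layers.

        DUM atoms form two planar layers; each leaflet plane is the mean z
        of its layer (split at the overall midpoint).
        """
        zs = np.array(
            [a.coords[2] for res in model.residues() if res.aa_name == "DUM" for a in res.atoms]
        )
        if zs.size < 2:
            raise StructureError("no DUM pseudo-atom layers found in reference model")
        mid = (zs.min() + zs.max()) / 2.0
        upper = zs[zs > mid]
        lower = zs[zs <= mid]
        if upper.size == 0 or lower.size == 0:
            raise StructureError("DUM atoms do not form two layers")
        return cls(z_upper=float(upper.mean()), z_lower=float(lower.mean()))


@dataclass
class PoseRecord:
    model_id: str
    path: str
    cluster_id: int
    cluster_size: int
    score: float
    score_type: str = "balanced"
    is_centroid: bool = True

    def __post_init__(self) -> None:
        if self.cluster_size < 1:
            raise ValueError(f"pose {self.model_id}: cluster_size must be >= 1")
        if not np.isfinite(self.score):
            raise ValueError(f"pose {self.model_id}: score must be finite")


@dataclass(frozen=True)
class FilterCriteria:
    gamma_chain: str = "G"
    receptor_chains: tuple[str, ...] = ()
    ligand_chains: tuple[str, ...] = ()
    max_gamma_cterm_distance: float = 30.0
    exclude_above_lower_leaflet: bool = True

    def __post_init__(self) -> None:
        if self.max_gamma_cterm_distance <= 0:
            raise ValueError("max_gamma_cterm_distance must be positive")


@dataclass
class FilterVerdict:
    model_id: str
    retained: bool
    reason: str  # none | atom_above_lower_leaflet | gamma_cterm_too_far | error:<msg>
    worst_z: float = float("nan")
    gamma_cterm_distance: float = float("nan")
    rmsd: float = float("nan")


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int


def _ca_coords(model: StructureModel, chains: tuple[str, ...], keys=None):
    out: dict[ResidueKey, np.ndarray] = {}
    for cid in chains:
        for res in model.chains.get(cid, []):
            ca = res.atom("CA")
            if ca is not None:
                out[res.key] = ca.coords
    if keys is not None:
        out = {k: v for k, v in out.items() if k in keys}
    return out


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    chains: tuple[str, ...],
    residue_keys: list[ResidueKey] | None = None,
) -> Superposition:
    """Least-squares (Kabsch) rigid alignment of matched Cα atoms.

    Atom pairs are matched by residue key over ``chains``.  Raises on fewer
    than 3 pairs or a collinear selection, since the rotation would be
    underdetermined.
    """
    mob = _ca_coords(mobile, chains, residue_keys)
    ref = _ca_coords(reference, chains, residue_keys)
    common = sorted(set(mob) & set(ref))
    if residue_keys is not None:
        missing = [str(k) for k in residue_keys if k not in common]
        if missing:
            raise StructureError(f"selection keys missing from one structure: {missing}")
    if len(common) < 3:
        raise StructureError(
            f"need at least 3 matched Cα pairs for superposition, got {len(common)}"
        )
    x = np.array([mob[k] for k in common])
    y = np.array([ref[k] for k in common])
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    sv = np.linalg.svd(y0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise StructureError("selected Cα atoms are collinear; rotation underdetermined")
    rot, _ = Rotation.align_vectors(y0, x0)
    r = rot.as_matrix()
    t = yc - r @ xc
    # residual-based rmsd: the closed-form rssd cancels catastrophically
    # for near-perfect alignments of large coordinates
    residuals = x0 @ r.T - y0
    rmsd = float(np.sqrt((residuals**2).sum() / len(common)))
    return Superposition(rotation=r, translation=t, rmsd=rmsd, n_atoms=len(common))


def apply_superposition(model: StructureModel, sp: Superposition) -> StructureModel:
    out = model.copy()
    for res in out.residues():
        for a in res.atoms:
            a.coords = sp.rotation @ a.coords + sp.translation
    return out


def gamma_cterm(model: StructureModel, gamma_chain: str) -> Atom:
    """Cα of the C-terminal (highest (number, icode)) residue of the γ chain."""
    residues = model.chains.get(gamma_chain)
    if not residues:
        raise StructureError(
            f"gamma chain {gamma_chain!r} absent; available: {model.chain_ids()}"
        )
    amino = [r for r in residues if not r.is_water]
    if not amino:
        raise StructureError(f"gamma chain {gamma_chain!r} has no residues")
    last = max(amino, key=lambda r: (r.number, r.icode))
    ca = last.atom("CA")
    if ca is None:
        raise StructureError(f"terminal residue {last.key} of γ chain has no Cα atom")
    return ca


def filter_pose(
    model: StructureModel, frame: MembraneFrame, criteria: FilterCriteria
) -> FilterVerdict:
    """Apply the two membrane-geometry exclusion rules to one aligned pose."""
    lig_chains = tuple(criteria.ligand_chains) or (criteria.gamma_chain,)
    absent = [c for c in lig_chains if c not in model.chains]
    if absent:
        raise StructureError(f"ligand chain(s) {absent} absent from pose {model.id}")
    lig_z = [
        a.coords[2]
        for cid in lig_chains
        for res in model.chains[cid]
        if not res.is_water
        for a in res.heavy_atoms()
    ]
    if not lig_z:
        raise StructureError(f"ligand chains of pose {model.id} contain no heavy atoms")
    worst_z = float(max(lig_z))
    ct = gamma_cterm(model, criteria.gamma_chain)
    ct_dist = float(frame.z_lower - ct.coords[2])
    if criteria.exclude_above_lower_leaflet and worst_z > frame.z_lower:
        return FilterVerdict(model.id, False, "atom_above_lower_leaflet", worst_z, ct_dist)
    if ct_dist > criteria.max_gamma_cterm_distance:
        return FilterVerdict(model.id, False, "gamma_cterm_too_far", worst_z, ct_dist)
    return FilterVerdict(model.id, True, "none", worst_z, ct_dist)


def triage_ensemble(
    poses: list[PoseRecord],
    frame: MembraneFrame,
    reference: StructureModel,
    criteria: FilterCriteria,
    base_dir: str | Path | None = None,
) -> tuple[list[PoseRecord], list[FilterVerdict]]:
    """Superpose every pose onto the reference and filter it.

    Unreadable poses are logged as error verdicts and the run continues;
    the retained list preserves the input order.
    """
    retained: list[PoseRecord] = []
    verdicts: list[FilterVerdict] = []
    base = Path(base_dir) if base_dir is not None else None
    for pose in poses:
        path = Path(pose.path)
        if base is not None and not path.is_absolute():
            path = base / path
        try:
            model = read_structure(path)
            model.id = pose.model_id
            sp = superpose(model, reference, tuple(criteria.receptor_chains))
            aligned = apply_superposition(model, sp)
            verdict = filter_pose(aligned, frame, criteria)
            verdict.rmsd = sp.rmsd
        except StructureError as exc:
            verdicts.append(FilterVerdict(pose.model_id, False, f"error:{exc}"))
            continue
        verdicts.append(verdict)
        if verdict.retained:
            retained.append(pose)
    return retained, verdicts


def select_models(retained: list[PoseRecord]) -> list[PoseRecord]:
    """Centroids of the largest cluster and of the best-score cluster.

    Ties: largest-cluster tie -> lower score wins; score tie -> lower
    cluster id.  When both roles name the same model it is returned once.
    The result does not depend on input order.
    """
    if not retained:
        raise ValueError("no retained poses to select from")
    centroids = [p for p in retained if p.is_centroid] or list(retained)
    largest = min(centroids, key=lambda p: (-p.cluster_size, p.score, p.cluster_id))
    best = min(centroids, key=lambda p: (p.score, p.cluster_id))
    if largest.model_id == best.model_id:
        return [largest]
    return [largest, best]


POSE_TABLE_COLUMNS = [
    "model_id", "cluster_id", "cluster_size", "score", "score_type", "is_centroid", "path",
]


def read_pose_table(path: str | Path) -> list[PoseRecord]:
    """Read the documented TSV pose table."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(POSE_TABLE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"pose table {path} missing columns: {sorted(missing)}")
        for row in reader:
            records.append(
                PoseRecord(
                    model_id=row["model_id"],
                    path=row["path"],
                    cluster_id=int(row["cluster_id"]),
                    cluster_size=int(row["cluster_size"]),
                    score=float(row["score"]),
                    score_type=row["score_type"],
                    is_centroid=row["is_centroid"].strip().lower() in ("1", "true", "yes"),
                )
            )
    return records


def write_pose_table(records: list[PoseRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(POSE_TABLE_COLUMNS)
        for r in records:
            w.writerow(
                [r.model_id, r.cluster_id, r.cluster_size, f"{r.score:.2f}",
                 r.score_type, str(r.is_centroid).lower(), r.path]
            )


def write_verdicts(verdicts: list[FilterVerdict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["model_id", "retained", "reason", "worst_z", "gamma_cterm_distance", "rmsd"])
        for v in verdicts:
            w.writerow(
                [v.model_id, str(v.retained).lower(), v.reason,
                 f"{v.worst_z:.3f}", f"{v.gamma_cterm_distance:.3f}", f"{v.rmsd:.4f}"]
            )


def read_cluspro_scores(path: str | Path, score_type: str = "balanced") -> list[PoseRecord]:
    """Best-effort adapter for ClusPro-style ``cluster.scores`` exports.

    Expects whitespace- or tab-separated rows with at least cluster number,
    member count and a score column; pose paths default to
    ``model.<score_type>.<cluster>.pdb`` alongside the table.
    """
    records = []
    for line in Path(path).read_text().splitlines():
        parts = line.replace(",", " ").split()
        if not parts or not parts[0].lstrip("-").isdigit():
            continue
        nums = []
        for p in parts:
            try:
                nums.append(float(p))
            except ValueError:
                pass
        if len(nums) < 3:
            continue
        cluster = int(nums[0])
        members = int(nums[1])
        score = float(nums[-1])
        records.append(
            PoseRecord(
                model_id=f"{score_type}.{cluster:03d}",
                path=f"model.{score_type}.{cluster:03d}.pdb",
                cluster_id=cluster,
                cluster_size=max(members, 1),
                score=score,
                score_type=score_type,
            )
        )
    return records


def run_metadata(frame: MembraneFrame, criteria: FilterCriteria) -> dict:
    """JSON-serialisable record of the conventions a triage run used."""
    return {
        "membrane_convention": "+z extracellular; 'above the lower leaflet' means z > z_lower",
        "leaflet_distance": "signed plane distance along z",
        "boundary_strictness": {
            "atom_above_lower_leaflet": "strict (z > z_lower)",
            "gamma_cterm_too_far": "strict (distance > max)",
        },
        "frame": asdict(frame),
        "criteria": asdict(criteria),
    }
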