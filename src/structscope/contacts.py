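"""Inter-chain interface detection and focal-residue contact environments.

A residue pair is *in contact* when the minimum heavy-atom/heavy-atom
Euclidean distance is at or below the cutoff (default 5.5 Å, the
PRODIGY-style interface criterion; the comparison is <=, "5.5 Å and below").
An *interface residue* is any residue of one partner with at least one
contact to the other partner; a *residue environment* is the INTAA-style
contact list of every residue within the cutoff of a focal residue.

Neighbour search uses a k-d tree over atom coordinates; unit tests hold it
to an all-pairs brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.spatial import cKDTree

from .model import Residue, ResidueKey, StructureModel, StructureError

__all__ = [
    "ContactCriteria",
    "ContactRecord",
    "InterfaceReport",
    "EnvironmentDelta",
    "interface",
    "residue_environment",
    "environment_delta",
]


@dataclass(frozen=True)
class ContactCriteria:
    """Parameters of the distance criterion."""

    cutoff: float = 5.5
    heavy_atoms_only: bool = True
    exclude_waters: bool = True
    exclude_hetero: bool = True
    exclude_self_residue: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")


@dataclass(frozen=True)
class ContactRecord:
    """An unordered residue pair with its minimal atom-atom distance."""

    residue_a: ResidueKey
    residue_b: ResidueKey
    min_distance: float
    same_chain: bool
    aa_a: str = ""
    aa_b: str = ""

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError("contact endpoints must differ")

    def key_pair(self) -> tuple[ResidueKey, ResidueKey]:
        """Canonical (sorted) endpoint pair, so (a,b) == (b,a)."""
        return tuple(sorted((self.residue_a, self.residue_b)))  # type: ignore[return-value]


@dataclass
class InterfaceReport:
    partner_a: tuple[str, ...]
    partner_b: tuple[str, ...]
    interface_residues_a: list[ResidueKey]
    interface_residues_b: list[ResidueKey]
    contacts: list[ContactRecord]
    criteria: ContactCriteria = field(default_factory=ContactCriteria)

    def is_interface_residue(self, key: ResidueKey | str) -> bool:
        if isinstance(key, str):
            key = ResidueKey.parse(key)
        return key in self.interface_residues_a or key in self.interface_residues_b


@dataclass
class EnvironmentDelta:
    """Set-difference bookkeeping between two contact environments."""

    retained: list[ResidueKey]
    lost: list[ResidueKey]
    gained: list[ResidueKey]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_lost(self) -> int:
        return len(self.lost)

    @property
    def n_gained(self) -> int:
        return len(self.gained)


def _eligible_residues(model: StructureModel, criteria: ContactCriteria) -> list[Residue]:
    out = []
    for res in model.residues():
        if criteria.exclude_waters and res.is_water:
            continue
        if criteria.exclude_hetero and res.is_hetero and not res.is_water:
            continue
        out.append(res)
    return out


def _atom_table(residues: Iterable[Residue], criteria: ContactCriteria):
    """Flatten residues into (coords array, residue-index array, residue list)."""
    res_list: list[Residue] = []
    coords: list[np.ndarray] = []
    index: list[int] = []
    for res in residues:
        atoms = res.heavy_atoms() if criteria.heavy_atoms_only else res.atoms
        if not atoms:
            continue
        ri = len(res_list)
        res_list.append(res)
        for a in atoms:
            coords.append(a.coords)
            index.append(ri)
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int), res_list
    return np.asarray(coords), np.asarray(index, dtype=int), res_list


def _min_distances(
    coords_a: np.ndarray,
    index_a: np.ndarray,
    coords_b: np.ndarray,
    index_b: np.ndarray,
    cutoff: float,
) -> dict[tuple[int, int], float]:
    """Minimal distance per residue-index pair among atom pairs within cutoff."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return {}
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)
    best: dict[tuple[int, int], float] = {}
    for ia, neighbours in enumerate(pairs):
        if not neighbours:
            continue
        d = np.linalg.norm(coords_b[neighbours] - coords_a[ia], axis=1)
        ra = index_a[ia]
        for ib, dist in zip(neighbours, d):
            if dist > cutoff:
                continue
            pair = (ra, index_b[ib])
            if dist < best.get(pair, np.inf):
                best[pair] = float(dist)
    return best


def interface(
    model: StructureModel,
    group_a: Iterable[str],
    group_b: Iterable[str],
    criteria: ContactCriteria | None = None,
) -> InterfaceReport:
    """Interface residues and contacts between two disjoint chain groups."""
    criteria = criteria or ContactCriteria()
    ga = tuple(dict.fromkeys(group_a))
    gb = tuple(dict.fromkeys(group_b))
    if not ga or not gb:
        raise ValueError("both chain groups must be non-empty")
    overlap = set(ga) & set(gb)
    if overlap:
        raise ValueError(f"chain groups overlap: {sorted(overlap)}")
    for cid in (*ga, *gb):
        if cid not in model.chains:
            raise StructureError(
                f"unknown chain id {cid!r}; available chains: {model.chain_ids()}"
            )
    res_a = _eligible_residues_in_chains(model, ga, criteria)
    res_b = _eligible_residues_in_chains(model, gb, criteria)
    ca, ia, la = _atom_table(res_a, criteria)
    cb, ib, lb = _atom_table(res_b, criteria)
    best = _min_distances(ca, ia, cb, ib, criteria.cutoff)
    contacts = [
        ContactRecord(
            residue_a=la[ra].key,
            residue_b=lb[rb].key,
            min_distance=dist,
            same_chain=False,
            aa_a=la[ra].aa_name,
            aa_b=lb[rb].aa_name,
        )
        for (ra, rb), dist in best.items()
    ]
    contacts.sort(key=lambda c: (c.residue_a, c.residue_b))
    iface_a = sorted({c.residue_a for c in contacts})
    iface_b = sorted({c.residue_b for c in contacts})
    return InterfaceReport(ga, gb, iface_a, iface_b, contacts, criteria)


def _eligible_residues_in_chains(
    model: StructureModel, chains: tuple[str, ...], criteria: ContactCriteria
) -> list[Residue]:
    sub = StructureModel(model.id, {c: model.chains[c] for c in chains}, model.source_format)
    return _eligible_residues(sub, criteria)


def residue_environment(
    model: StructureModel,
    focal: ResidueKey | str,
    criteria: ContactCriteria | None = None,
    partner_scope: Literal["all", "intra_chain", "inter_chain"] = "all",
    exclude_backbone_neighbors: bool = False,
) -> list[ContactRecord]:
    """All residues with a heavy atom within the cutoff of the focal residue.

    Results are sorted by ascending minimal distance, ties broken by residue
    key.  ``partner_scope`` restricts partners to the focal residue's own
    chain or to other chains; sequence neighbours (i±1) are included unless
    ``exclude_backbone_neighbors`` is set.
    """
    criteria = criteria or ContactCriteria()
    if isinstance(focal, str):
        focal = ResidueKey.parse(focal)
    focal_res = model.get_residue(focal)
    partners = []
    for res in _eligible_residues(model, criteria):
        if res.key == focal:
            continue
        if partner_scope == "intra_chain" and res.chain_id != focal.chain_id:
            continue
        if partner_scope == "inter_chain" and res.chain_id == focal.chain_id:
            continue
        if (
            exclude_backbone_neighbors
            and res.chain_id == focal.chain_id
            and res.icode == focal.icode
            and abs(res.number - focal.number) == 1
        ):
            continue
        partners.append(res)
    cf, if_, lf = _atom_table([focal_res], criteria)
    cp, ip, lp = _atom_table(partners, criteria)
    best = _min_distances(cf, if_, cp, ip, criteria.cutoff)
    records = [
        ContactRecord(
            residue_a=focal,
            residue_b=lp[rb].key,
            min_distance=dist,
            same_chain=lp[rb].chain_id == focal.chain_id,
            aa_a=focal_res.aa_name,
            aa_b=lp[rb].aa_name,
        )
        for (_, rb), dist in best.items()
    ]
    records.sort(key=lambda c: (c.min_distance, c.residue_b))
    return records


def environment_delta(
    env_wt: list[ContactRecord], env_mut: list[ContactRecord]
) -> EnvironmentDelta:
    """Residues retained / lost / gained between two contact environments."""
    keys_wt = {c.residue_b for c in env_wt}
    keys_mut = {c.residue_b for c in env_mut}
    return EnvironmentDelta(
        retained=sorted(keys_wt & keys_mut),
        lost=sorted(keys_wt - keys_mut),
        gained=sorted(keys_mut - keys_wt),
    )
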