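"""Residue interaction network (RIN) around a focal residue.

Each residue pair in the focal environment is classified into at most one
non-covalent interaction kind by a fixed precedence:

    ionic > hbond > hydrophobic > vdw > generic

with purely geometric default rules (side-chain charged N/O pairs at
<= 4.0 Å, donor/acceptor N/O pairs at <= 3.5 Å, apolar side-chain carbons at
<= 5.0 Å, any heavy-atom pair within the sum of van der Waals radii + 0.5 Å,
and a <= 5.5 Å generic fallback).  The thresholds live in a user-editable
rule table (YAML-serialisable) so a pipeline run records exactly which
geometry produced its edges.  No angle terms are used by default because the
pipeline operates on heavy atoms only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .contacts import ContactCriteria, residue_environment
from .model import Residue, ResidueKey, StructureModel

__all__ = [
    "InteractionRules",
    "InteractionEdge",
    "InteractionNetwork",
    "classify_pair",
    "build_network",
    "network_summary",
]

KIND_PRECEDENCE = ("ionic", "hbond", "hydrophobic", "vdw", "generic")

POSITIVE_SIDE_CHAIN = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
NEGATIVE_SIDE_CHAIN = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
# donor/acceptor capability of N/O heavy atoms (no hydrogens required)
DONOR_ATOMS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
}
ACCEPTOR_ATOMS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
BACKBONE = {"N", "CA", "C", "O", "OXT"}
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90, "H": 1.20}
DEFAULT_VDW_RADIUS = 1.70


@dataclass(frozen=True)
class InteractionRules:
    """Geometric thresholds (Å) for each interaction kind."""

    ionic_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    hydrophobic_cutoff: float = 5.0
    vdw_slack: float = 0.5
    generic_cutoff: float = 5.5
    his_chargeable: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InteractionRules":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass(frozen=True)
class InteractionEdge:
    residue_a: ResidueKey
    residue_b: ResidueKey
    kind: str
    atom_a: str
    atom_b: str
    distance: float


@dataclass
class InteractionNetwork:
    focal: ResidueKey
    nodes: list[ResidueKey]
    edges: list[InteractionEdge]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.residue_a, e.residue_b, kind=e.kind, distance=e.distance)
        return g

    def focal_degree(self) -> int:
        return sum(1 for e in self.edges if self.focal in (e.residue_a, e.residue_b))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "focal": str(self.focal),
            "nodes": [str(k) for k in self.nodes],
            "edges": [
                {
                    "residue_a": str(e.residue_a),
                    "residue_b": str(e.residue_b),
                    "kind": e.kind,
                    "atom_a": e.atom_a,
                    "atom_b": e.atom_b,
                    "distance": round(e.distance, 4),
                }
                for e in self.edges
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _charged_atoms(res: Residue, rules: InteractionRules, sign: str) -> set[str]:
    table = POSITIVE_SIDE_CHAIN if sign == "+" else NEGATIVE_SIDE_CHAIN
    names = table.get(res.aa_name, set())
    if sign == "+" and res.aa_name == "HIS" and not rules.his_chargeable:
        return set()
    return names


def _pair_distances(res_a: Residue, res_b: Residue):
    atoms_a = res_a.heavy_atoms()
    atoms_b = res_b.heavy_atoms()
    if not atoms_a or not atoms_b:
        return atoms_a, atoms_b, np.empty((0, 0))
    ca = np.array([a.coords for a in atoms_a])
    cb = np.array([b.coords for b in atoms_b])
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    return atoms_a, atoms_b, d


def classify_pair(
    res_a: Residue, res_b: Residue, rules: InteractionRules | None = None
) -> InteractionEdge | None:
    """Classify one residue pair; returns None when no rule fires.

    Symmetric in its arguments: endpoints are reported in canonical
    (sorted-key) order and each rule is evaluated over both atom orderings.
    """
    rules = rules or InteractionRules()
    if res_a.key > res_b.key:
        res_a, res_b = res_b, res_a
    atoms_a, atoms_b, dist = _pair_distances(res_a, res_b)
    if dist.size == 0:
        return None

    def best_match(mask: np.ndarray, cutoff: float):
        masked = np.where(mask, dist, np.inf)
        ij = np.unravel_index(np.argmin(masked), masked.shape)
        d = masked[ij]
        if d <= cutoff:
            return atoms_a[ij[0]], atoms_b[ij[1]], float(d)
        return None

    names_a = [a.name for a in atoms_a]
    names_b = [b.name for b in atoms_b]

    # ionic: charged side-chain N/O of opposite signs
    pos_a = _charged_atoms(res_a, rules, "+")
    neg_a = _charged_atoms(res_a, rules, "-")
    pos_b = _charged_atoms(res_b, rules, "+")
    neg_b = _charged_atoms(res_b, rules, "-")
    mask_ionic = np.zeros_like(dist, dtype=bool)
    for ia, na in enumerate(names_a):
        for ib, nb in enumerate(names_b):
            if (na in pos_a and nb in neg_b) or (na in neg_a and nb in pos_b):
                mask_ionic[ia, ib] = True
    hit = best_match(mask_ionic, rules.ionic_cutoff)
    if hit:
        return _edge(res_a, res_b, "ionic", *hit)

    # hbond: donor-capable N/O vs acceptor-capable N/O
    def donors(res: Residue, names: list[str]) -> set[int]:
        side = DONOR_ATOMS.get(res.aa_name, set())
        return {i for i, n in enumerate(names) if n == "N" or n in side}

    def acceptors(res: Residue, names: list[str]) -> set[int]:
        side = ACCEPTOR_ATOMS.get(res.aa_name, set())
        return {i for i, n in enumerate(names) if n in ("O", "OXT") or n in side}

    don_a, acc_a = donors(res_a, names_a), acceptors(res_a, names_a)
    don_b, acc_b = donors(res_b, names_b), acceptors(res_b, names_b)
    mask_hb = np.zeros_like(dist, dtype=bool)
    for ia in don_a:
        for ib in acc_b:
            mask_hb[ia, ib] = True
    for ia in acc_a:
        for ib in don_b:
            mask_hb[ia, ib] = True
    hit = best_match(mask_hb, rules.hbond_cutoff)
    if hit:
        return _edge(res_a, res_b, "hbond", *hit)

    # hydrophobic: side-chain carbons of apolar residues
    if res_a.aa_name in APOLAR_RESIDUES and res_b.aa_name in APOLAR_RESIDUES:
        sc_a = [i for i, a in enumerate(atoms_a) if a.element == "C" and a.name not in BACKBONE]
        sc_b = [i for i, b in enumerate(atoms_b) if b.element == "C" and b.name not in BACKBONE]
        mask_ph = np.zeros_like(dist, dtype=bool)
        for ia in sc_a:
            mask_ph[ia, [ib for ib in sc_b]] = True
        if sc_a and sc_b:
            hit = best_match(mask_ph, rules.hydrophobic_cutoff)
            if hit:
                return _edge(res_a, res_b, "hydrophobic", *hit)

    # vdw: any heavy-atom pair within the radii sum + slack
    radii_a = np.array([VDW_RADII.get(a.element.upper(), DEFAULT_VDW_RADIUS) for a in atoms_a])
    radii_b = np.array([VDW_RADII.get(b.element.upper(), DEFAULT_VDW_RADIUS) for b in atoms_b])
    limit = radii_a[:, None] + radii_b[None, :] + rules.vdw_slack
    gap = dist - limit
    ij = np.unravel_index(np.argmin(gap), gap.shape)
    if gap[ij] <= 0:
        return _edge(res_a, res_b, "vdw", atoms_a[ij[0]], atoms_b[ij[1]], float(dist[ij]))

    # generic fallback
    hit = best_match(np.ones_like(dist, dtype=bool), rules.generic_cutoff)
    if hit:
        return _edge(res_a, res_b, "generic", *hit)
    return None


def _edge(res_a, res_b, kind, atom_a, atom_b, distance) -> InteractionEdge:
    return InteractionEdge(
        residue_a=res_a.key,
        residue_b=res_b.key,
        kind=kind,
        atom_a=atom_a.name,
        atom_b=atom_b.name,
        distance=distance,
    )


def build_network(
    model: StructureModel,
    focal: ResidueKey | str,
    criteria: ContactCriteria | None = None,
    rules: InteractionRules | None = None,
) -> InteractionNetwork:
    """Build the interaction network of a focal residue and its environment."""
    criteria = criteria or ContactCriteria()
    rules = rules or InteractionRules()
    if isinstance(focal, str):
        focal = ResidueKey.parse(focal)
    env = residue_environment(model, focal, criteria)
    node_keys = sorted({focal} | {c.residue_b for c in env})
    residues = {k: model.get_residue(k) for k in node_keys}
    edges: list[InteractionEdge] = []
    for i, ka in enumerate(node_keys):
        for kb in node_keys[i + 1 :]:
            edge = classify_pair(residues[ka], residues[kb], rules)
            if edge is not None:
                edges.append(edge)
    edges.sort(key=lambda e: (e.residue_a, e.residue_b))
    return InteractionNetwork(focal=focal, nodes=node_keys, edges=edges)


def network_summary(net: InteractionNetwork) -> dict:
    """Counts per interaction kind plus the focal residue's degree."""
    counts = {kind: 0 for kind in KIND_PRECEDENCE}
    for e in net.edges:
        counts[e.kind] += 1
    return {
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "focal_degree": net.focal_degree(),
        **{f"n_{kind}": counts[kind] for kind in KIND_PRECEDENCE},
    }
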