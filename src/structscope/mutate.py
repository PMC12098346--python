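"""In-place point mutagenesis with idealised side-chain templates.

This is a deliberately *rigid-template* builder: the backbone (N, CA, C, O,
and CB when shared) keeps its original coordinates bit-exactly, the old side
chain is removed, and the new side chain is grown from ideal internal
coordinates (bond lengths, angles, torsions) in the local backbone frame.
No rotamer search, repacking or energy minimisation is performed, so
downstream contact counts on mutants are geometric estimates of a rigid
substitution, not relaxed structures.  The proline ring uses fixed internal
coordinates whose two ring torsions were solved once for ring closure
(CD-N = 1.474 Å); the backbone φ is not adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import place_atom
from .model import Atom, Residue, ResidueKey, StructureModel, StructureError

__all__ = [
    "MutationSpec",
    "SIDE_CHAIN_TEMPLATES",
    "substitute_residue",
    "clash_report",
    "build_side_chain",
]

# CB from the backbone frame: refs (C, N, CA), L-configuration torsion.
_CB_ENTRY = ("CB", ("C", "N", "CA"), 1.530, 110.4, 122.686)

# Side-chain heavy atoms as internal-coordinate entries
# (name, (ref1, ref2, ref3), bond Å, angle deg, torsion deg); the new atom is
# bonded to ref3.  Torsions use extended (180°) chains with ±60° branches;
# rings use planar idealisations.  PRO ring torsions solved for closure.
SIDE_CHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB_ENTRY],
    "SER": [_CB_ENTRY, ("OG", ("N", "CA", "CB"), 1.417, 110.8, 180.0)],
    "CYS": [_CB_ENTRY, ("SG", ("N", "CA", "CB"), 1.808, 113.8, 180.0)],
    "THR": [
        _CB_ENTRY,
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, -60.0),
    ],
    "VAL": [
        _CB_ENTRY,
        ("CG1", ("N", "CA", "CB"), 1.527, 110.7, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.527, 110.4, -60.0),
    ],
    "LEU": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 180.0),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, -60.0),
    ],
    "ILE": [
        _CB_ENTRY,
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, -60.0),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.9, 180.0),
    ],
    "PRO": [
        _CB_ENTRY,
        # ring torsions solved so that CD closes onto N at 1.474 Å
        ("CG", ("N", "CA", "CB"), 1.495, 104.5, -0.894),
        ("CD", ("CA", "CB", "CG"), 1.507, 105.8, 15.552),
    ],
    "MET": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.9, 180.0),
    ],
    "ASP": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, 0.0),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, 180.0),
    ],
    "ASN": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, 0.0),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, 180.0),
    ],
    "GLU": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, 0.0),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, 180.0),
    ],
    "GLN": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, 180.0),
    ],
    "LYS": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, 180.0),
    ],
    "ARG": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
        ("NE", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
        ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, 180.0),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "PHE": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.391, 120.8, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.391, 120.8, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.391, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.391, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.391, 120.0, 0.0),
    ],
    "TYR": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.391, 120.8, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.391, 120.8, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.391, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.391, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.391, 120.0, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.377, 119.9, 180.0),
    ],
    "HIS": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.497, 113.8, 180.0),
        ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.356, 131.0, -90.0),
        ("CE1", ("CB", "CG", "ND1"), 1.323, 109.2, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0),
    ],
    "TRP": [
        _CB_ENTRY,
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, -90.0),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.8, 180.0),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.368, 121.1, 0.0),
    ],
}


def _element_for(name: str) -> str:
    if name.startswith(("S",)) and name in ("SG", "SD"):
        return "S"
    return name[0]


@dataclass(frozen=True)
class MutationSpec:
    """A single point substitution addressed by author numbering."""

    chain_id: str
    number: int
    icode: str = ""
    from_aa: str | None = None  # expected source residue name, or None/wildcard
    to_aa: str = "PRO"

    def __post_init__(self) -> None:
        if self.to_aa not in SIDE_CHAIN_TEMPLATES:
            raise ValueError(f"no side-chain template for {self.to_aa!r}")

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.number, self.icode)

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse ``"B:95:LEU>PRO"`` (from_aa may be ``*`` for wildcard)."""
        try:
            chain, number, rest = text.split(":", 2)
            frm, _, to = rest.partition(">")
        except ValueError as exc:
            raise ValueError(f"cannot parse mutation {text!r}; expected CHAIN:NUM:FROM>TO") from exc
        key = ResidueKey.parse(f"{chain}:{number}")
        from_aa = None if frm in ("", "*") else frm.upper()
        return cls(key.chain_id, key.number, key.icode, from_aa, to.upper())


def build_side_chain(
    backbone: dict[str, np.ndarray], aa_name: str, skip: set[str] = frozenset()
) -> dict[str, np.ndarray]:
    """Grow the side chain of ``aa_name`` from a backbone frame.

    ``backbone`` must map at least N, CA, C to coordinates; already-present
    names in ``skip`` (e.g. an inherited CB) are used as reference atoms but
    not rebuilt.
    """
    placed = dict(backbone)
    out: dict[str, np.ndarray] = {}
    for name, (r1, r2, r3), bond, angle, torsion in SIDE_CHAIN_TEMPLATES[aa_name]:
        if name in placed:
            continue
        missing = [r for r in (r1, r2, r3) if r not in placed]
        if missing:
            raise StructureError(f"cannot place {name}: missing reference atoms {missing}")
        pos = place_atom(placed[r1], placed[r2], placed[r3], bond, angle, torsion)
        placed[name] = pos
        if name not in skip:
            out[name] = pos
    return out


def substitute_residue(model: StructureModel, spec: MutationSpec) -> StructureModel:
    """Return a copy of the model with one residue substituted in place.

    Backbone atoms (N, CA, C, O, plus OXT and a shared CB) are copied
    bit-exactly; the remaining side chain comes from the ideal template.
    All other residues are untouched.
    """
    out = model.copy()
    res = out.get_residue(spec.key)
    if spec.from_aa is not None and res.aa_name != spec.from_aa:
        raise StructureError(
            f"residue {spec.key} is {res.aa_name}, expected {spec.from_aa}"
        )
    names = {a.name for a in res.atoms}
    missing_bb = [n for n in ("N", "CA", "C") if n not in names]
    if missing_bb:
        raise StructureError(f"residue {spec.key} is missing backbone atoms {missing_bb}")

    keep_names = {"N", "CA", "C", "O", "OXT"}
    target_has_cb = any(e[0] == "CB" for e in SIDE_CHAIN_TEMPLATES[spec.to_aa])
    if target_has_cb and "CB" in names:
        keep_names.add("CB")
    kept = [a for a in res.atoms if a.name in keep_names and not a.is_hydrogen]

    frame = {a.name: a.coords for a in kept}
    new_coords = build_side_chain(frame, spec.to_aa, skip=set(frame))
    new_atoms = [
        Atom(name=n, element=_element_for(n), coords=c, occupancy=1.0)
        for n, c in new_coords.items()
    ]
    res.aa_name = spec.to_aa
    res.atoms = kept + new_atoms
    return out


def clash_report(
    model: StructureModel, focus: ResidueKey | str, threshold: float = 2.5
) -> list[tuple[str, str, str, str, float]]:
    """Heavy-atom pairs between ``focus`` and other residues closer than
    ``threshold`` (strict), sorted by ascending distance.

    Peptide-bond partners (previous C / next N of sequence neighbours) are
    not reported since those are covalent, not clashes.  Each entry is
    ``(focus_atom, partner_key, partner_aa, partner_atom, distance)``.
    """
    if isinstance(focus, str):
        focus = ResidueKey.parse(focus)
    focal_res = model.get_residue(focus)
    results = []
    for res in model.residues():
        if res.key == focus:
            continue
        neighbour = (
            res.chain_id == focus.chain_id
            and res.icode == focus.icode
            and abs(res.number - focus.number) == 1
        )
        for fa in focal_res.heavy_atoms():
            for oa in res.heavy_atoms():
                if neighbour:
                    # skip the covalent peptide linkage
                    if res.number == focus.number - 1 and (fa.name, oa.name) == ("N", "C"):
                        continue
                    if res.number == focus.number + 1 and (fa.name, oa.name) == ("C", "N"):
                        continue
                d = float(np.linalg.norm(fa.coords - oa.coords))
                if d < threshold:
                    results.append((fa.name, str(res.key), res.aa_name, oa.name, d))
    results.sort(key=lambda t: (t[4], t[1], t[0], t[3]))
    return results
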