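"""Macromolecular structure container and PDB/mmCIF I/O.

The in-memory model is deliberately small: chains of residues of heavy/light
atoms, addressed by *author* numbering (chain id, residue number, insertion
code), which is how positions such as Gβ L95 are referred to in practice.
Parsing is delegated to :mod:`gemmi`; this module only normalises what the
geometric stages need (altloc resolution, water/hydrogen flags, first model
of multi-model files).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueKey",
    "StructureModel",
    "StructureError",
    "read_structure",
    "write_structure",
    "select",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structure input."""


class ResidueKey(NamedTuple):
    """Author-numbering residue address: (chain id, residue number, icode)."""

    chain_id: str
    number: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "B:95" or "B:95A"
        return f"{self.chain_id}:{self.number}{self.icode}"

    @classmethod
    def parse(cls, text: str) -> "ResidueKey":
        """Parse ``"B:95"`` / ``"B:95A"`` into a key."""
        chain, _, rest = text.partition(":")
        if not chain or not rest:
            raise ValueError(f"cannot parse residue key {text!r}; expected CHAIN:NUMBER[ICODE]")
        digits = rest
        icode = ""
        if digits and digits[-1].isalpha():
            icode = digits[-1]
            digits = digits[:-1]
        try:
            number = int(digits)
        except ValueError as exc:
            raise ValueError(f"cannot parse residue number in {text!r}") from exc
        return cls(chain, number, icode)


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: element must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    aa_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.number, self.icode)

    @property
    def is_water(self) -> bool:
        return self.aa_name in WATER_NAMES

    @property
    def is_hetero(self) -> bool:
        return bool(self.atoms) and all(a.is_hetero for a in self.atoms)

    @property
    def is_standard_aa(self) -> bool:
        return self.aa_name in STANDARD_AA

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id,
            self.number,
            self.icode,
            self.aa_name,
            [replace(a, coords=a.coords.copy()) for a in self.atoms],
        )


@dataclass
class StructureModel:
    """Ordered chains of residues; the substrate of every geometric stage."""

    id: str = "model"
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_format: str = "pdb"

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def get_residue(self, key: ResidueKey | str) -> Residue:
        if isinstance(key, str):
            key = ResidueKey.parse(key)
        for res in self.chains.get(key.chain_id, []):
            if res.key == key:
                return res
        raise StructureError(
            f"residue {key} not found; nearest keys in chain {key.chain_id!r}: "
            f"{self._nearest_keys(key)}"
        )

    def _nearest_keys(self, key: ResidueKey, n: int = 3) -> list[str]:
        residues = self.chains.get(key.chain_id, [])
        ranked = sorted(residues, key=lambda r: abs(r.number - key.number))
        return [str(r.key) for r in ranked[:n]]

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def validate(self) -> None:
        seen: set[ResidueKey] = set()
        for res in self.residues():
            if not res.atoms:
                raise StructureError(f"residue {res.key} has no atoms")
            if res.key in seen:
                raise StructureError(f"duplicate residue key {res.key}")
            seen.add(res.key)

    def copy(self) -> "StructureModel":
        return StructureModel(
            self.id,
            {cid: [r.copy() for r in residues] for cid, residues in self.chains.items()},
            self.source_format,
        )


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> smallest altloc."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    resolved = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        resolved.append(best)
    return resolved


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Altlocs are resolved to the highest-occupancy conformer (ties broken by
    the lexicographically smallest altloc letter).  Waters and hydrogens are
    retained but flagged so that downstream stages can exclude them.  Only
    the first model of a multi-model file is loaded (with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise StructureError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no atoms (file contains no model)")
    if len(st) > 1:
        warnings.warn(
            f"{path.name}: {len(st)} models present; using the first only",
            stacklevel=2,
        )
    source_format = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    model = StructureModel(id=path.stem, source_format=source_format)
    gmodel = st[0]
    for chain in gmodel:
        residues: list[Residue] = []
        for gres in chain:
            is_het = gres.het_flag == "H"
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name or "X",
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc=ga.altloc if ga.altloc != "\x00" else "",
                    is_hetero=is_het,
                )
                for ga in gres
            ]
            atoms = _resolve_altlocs(atoms)
            residues.append(
                Residue(
                    chain_id=chain.name,
                    number=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    aa_name=gres.name,
                    atoms=atoms,
                )
            )
        if residues:
            model.chains.setdefault(chain.name, []).extend(residues)
    if model.atom_count == 0:
        raise StructureError(f"{path}: no atoms")
    model.validate()
    return model


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model as fixed-column PDB text (3-decimal coordinates)."""
    if model.atom_count == 0:
        raise StructureError("cannot write an empty model")
    for res in model.residues():
        if not -999 <= res.number <= 9999:
            raise StructureError(
                f"residue number {res.number} in chain {res.chain_id} "
                "outside the PDB fixed-column range [-999, 9999]"
            )
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gchain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.aa_name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.b_iso = 0.0
                if atom.altloc:
                    ga.altloc = atom.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


def select(
    model: StructureModel,
    chain_ids: Iterable[str] | None = None,
    include_hetero: bool = False,
    include_waters: bool = False,
    include_hydrogens: bool = False,
) -> StructureModel:
    """Restrict a model to chains and atom classes.

    Defaults drop waters, hydrogens and non-water hetero groups, which is the
    atom set the 5.5 Å amino-acid contact criterion operates on.
    """
    if chain_ids is None:
        wanted = list(model.chains)
    else:
        wanted = list(chain_ids)
        missing = [c for c in wanted if c not in model.chains]
        if missing:
            raise StructureError(
                f"unknown chain id(s) {missing}; available chains: {model.chain_ids()}"
            )
    out = StructureModel(id=model.id, source_format=model.source_format)
    for cid in wanted:
        kept: list[Residue] = []
        for res in model.chains[cid]:
            if res.is_water and not include_waters:
                continue
            if res.is_hetero and not res.is_water and not include_hetero:
                continue
            atoms = res.atoms if include_hydrogens else res.heavy_atoms()
            if not atoms:
                continue
            new = res.copy()
            new.atoms = [replace(a, coords=a.coords.copy()) for a in atoms]
            kept.append(new)
        if kept:
            out.chains[cid] = kept
    return out
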