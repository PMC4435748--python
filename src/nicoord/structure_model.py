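"""Data model for macromolecular structures and PDB-format I/O.

The model is deliberately flat: a structure is a mapping from residue keys
``(chain_id, residue_seq, insertion_code)`` to lists of :class:`AtomRecord`.
Author numbering is used everywhere because all residue-position arithmetic
downstream (chelate spacing, probability tables) is done in author numbering.

Parsing and serialisation are delegated to ``gemmi``; this module only
normalises the result into the package's own records and applies the
alternate-location policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

import gemmi
import numpy as np

from .errors import EmptyInputError, FormatError, ValidationError

ResidueKey = tuple[str, int, str]

#: Two-letter element symbols that appear in PDB atom names and must not be
#: mistaken for a one-letter element plus remoteness indicator.
_TWO_LETTER_ELEMENTS = {
    "NI", "FE", "ZN", "MG", "MN", "CU", "CO", "NA", "CL", "BR", "SE", "CD",
    "HG", "PB", "AS", "BE", "CA", "LI", "AL", "SI",
}

AltlocPolicy = Literal["highest_occupancy", "all"]


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record.

    ``position`` is a length-3 tuple in Å (kept immutable so records are
    hashable); ``b_factor`` is the isotropic displacement parameter in Å².
    """

    serial: int
    atom_name: str
    element: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    position: tuple[float, float, float]
    occupancy: float
    b_factor: float
    is_het: bool

    def __post_init__(self):
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValidationError(
                f"occupancy {self.occupancy!r} outside [0, 1] "
                f"(atom {self.atom_name} {self.residue_name}{self.residue_seq})"
            )
        if self.b_factor < 0:
            raise ValidationError(f"negative B-factor {self.b_factor!r}")
        if not all(math.isfinite(c) for c in self.position):
            raise ValidationError(f"non-finite coordinates {self.position!r}")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class StructureModel:
    """A parsed structure: residues (keyed by chain/number/icode) → atoms."""

    structure_id: str
    resolution: float | None = None
    method: str = ""
    residues: dict[ResidueKey, list[AtomRecord]] = field(default_factory=dict)

    def atoms(self) -> Iterator[AtomRecord]:
        for atom_list in self.residues.values():
            yield from atom_list

    @property
    def n_atoms(self) -> int:
        return sum(len(v) for v in self.residues.values())

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def chain_ids(self) -> list[str]:
        return sorted({key[0] for key in self.residues})

    def chain_residues(self, chain_id: str) -> list[ResidueKey]:
        """Residue keys of one chain in (residue_seq, icode) order."""
        keys = [k for k in self.residues if k[0] == chain_id]
        return sorted(keys, key=lambda k: (k[1], k[2]))

    def add_atom(self, atom: AtomRecord) -> None:
        self.residues.setdefault(atom.residue_key, []).append(atom)

    def translated(self, shift: np.ndarray) -> "StructureModel":
        return self.transformed(np.eye(3), np.asarray(shift, dtype=float))

    def transformed(self, rotation: np.ndarray, shift: np.ndarray) -> "StructureModel":
        """Rigid-body (or general linear) transform of every atom."""
        out = StructureModel(self.structure_id, self.resolution, self.method)
        for atom in self.atoms():
            pos = rotation @ atom.xyz + shift
            out.add_atom(replace(atom, position=tuple(float(c) for c in pos)))
        return out


def infer_element(atom_name: str, residue_name: str, is_het: bool) -> str:
    """Derive the element symbol from a PDB atom name.

    Follows the usual convention: strip digits and primes, then check
    whether the leading two characters form a known two-letter element
    (metals, halogens, Se); otherwise the first letter is the element.
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS and (is_het or two == residue_name.strip().upper()):
        return two[0] + two[1].lower()
    return stripped[0].upper()


def _normalise_altloc(altloc: str) -> str:
    return "" if altloc in ("", "\x00", " ") else altloc


def _apply_altloc_policy(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one alternate location per (residue, atom name): the highest
    occupancy; ties broken by the alphabetically first altloc id."""
    groups: dict[tuple[ResidueKey, str], list[AtomRecord]] = {}
    order: list[tuple[ResidueKey, str]] = []
    for atom in atoms:
        key = (atom.residue_key, atom.atom_name)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(atom)
    kept: list[AtomRecord] = []
    for key in order:
        group = groups[key]
        best = min(group, key=lambda a: (-a.occupancy, a.alt_loc))
        kept.append(best)
    return kept


def read_structure(
    path: str | Path,
    altloc_policy: AltlocPolicy = "highest_occupancy",
) -> StructureModel:
    """Read a PDB file (optionally gzip-compressed) into a StructureModel.

    Only the first model of a multi-model file is read; NMR ensembles are
    outside the intended use. Hydrogens are parsed like any other atom —
    downstream donor analysis excludes them by default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports line context
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyInputError(f"{path}: no atomic model found")

    model = StructureModel(
        structure_id=st.name.strip() or path.stem,
        resolution=float(st.resolution) if st.resolution > 0 else None,
        method=getattr(st, "experimental_method", "") or "",
    )
    raw: list[AtomRecord] = []
    for chain in st[0]:
        for res in chain:
            icode = res.seqid.icode.strip()
            for atom in res:
                element = atom.element.name
                if element in ("X", ""):
                    element = infer_element(atom.name, res.name, res.het_flag == "H")
                raw.append(
                    AtomRecord(
                        serial=atom.serial,
                        atom_name=atom.name,
                        element=element,
                        alt_loc=_normalise_altloc(atom.altloc),
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_seq=res.seqid.num,
                        insertion_code=icode,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_factor=max(atom.b_iso, 0.0),
                        is_het=res.het_flag == "H",
                    )
                )
    if not raw:
        raise EmptyInputError(f"{path}: file contains no ATOM/HETATM records")
    if altloc_policy == "highest_occupancy":
        raw = _apply_altloc_policy(raw)
    elif altloc_policy != "all":
        raise ValidationError(f"unknown altloc policy {altloc_policy!r}")
    for atom in raw:
        model.add_atom(atom)
    return model


def read_structures(path: str | Path, **kwargs) -> list[StructureModel]:
    """Read one file, or every ``*.pdb`` / ``*.pdb.gz`` / ``*.ent`` in a directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix in (".pdb", ".ent") or p.name.endswith(".pdb.gz")
        )
        return [read_structure(p, **kwargs) for p in files]
    return [read_structure(path, **kwargs)]


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Serialise a StructureModel as a PDB file.

    The emitted file re-parses to an equivalent model within PDB column
    precision (coordinates to 3 decimals, B-factors/occupancies to 2).
    """
    path = Path(path)
    if model.n_atoms == 0:
        path.write_text("END\n")
        return
    st = gemmi.Structure()
    st.name = model.structure_id
    if model.resolution is not None:
        st.resolution = model.resolution
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current: dict[str, gemmi.Residue] = {}
    serial = 0
    for key in sorted(model.residues, key=lambda k: (k[0], k[1], k[2])):
        chain_id, seq, icode = key
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
        res = None
        for atom in model.residues[key]:
            if res is None:
                res = gemmi.Residue()
                res.name = atom.residue_name
                res.seqid = gemmi.SeqId(seq, icode or " ")
                res.het_flag = "H" if atom.is_het else "A"
            ga = gemmi.Atom()
            ga.name = atom.atom_name
            ga.element = gemmi.Element(atom.element)
            ga.altloc = atom.alt_loc or "\x00"
            ga.pos = gemmi.Position(*atom.position)
            ga.occ = atom.occupancy
            ga.b_iso = atom.b_factor
            serial += 1
            ga.serial = serial
            res.add_atom(ga)
        chains[chain_id].add_residue(res)
    for chain in chains.values():
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


ResolutionGroup = Literal["A", "B", "C", "unknown"]


def resolution_group(model: StructureModel) -> ResolutionGroup:
    """Resolution bin: A ≤ 2.0 Å < B ≤ 3.0 Å < C; ``unknown`` if absent."""
    res = model.resolution
    if res is None:
        return "unknown"
    if res < 0:
        raise ValidationError(f"negative resolution {res!r}")
    if res <= 2.0:
        return "A"
    if res <= 3.0:
        return "B"
    return "C"


def select_analysis_chain(model: StructureModel, site) -> str:
    """Chain contributing the most protein donor atoms to a metal site.

    Only a single polypeptide chain per structure enters the sequence-level
    analysis, so multi-chain sites need a deterministic choice: donor-atom
    majority, ties broken alphabetically.
    """
    counts: dict[str, int] = {}
    for contact in site.protein_donors:
        counts[contact.atom.chain_id] = counts.get(contact.atom.chain_id, 0) + 1
    if not counts:
        raise ValidationError(
            f"site in {model.structure_id} has no protein donors; no analysis chain"
        )
    return min(counts, key=lambda c: (-counts[c], c))
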