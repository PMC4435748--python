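"""Metal-site detection, first-shell partitioning, and chelate loops.

A *first shell* is every atom within a distance cutoff (3 Å by default) of
the metal ion. Shell atoms are partitioned into protein donors, non-water
hetero donors, solvent (water oxygens) and carbon contacts. Carbons are
recorded because they frequently sit just inside the cutoff (e.g. His CE1
dragged in by the coordinating NE2) but they are never counted as donors —
the electron-pair donors of interest are N, O, S and Se.

The *chelate loop* is the ordered set of protein residues whose atoms
coordinate the metal, written as a one-letter pattern string (``HDH``) with
positional spacing in ``n / n+k / m`` notation, where ``m`` flags a donor
more than 100 residues from the first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structure_model import (
    AtomRecord,
    ResidueKey,
    StructureModel,
    resolution_group,
    select_analysis_chain,
)

WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}
DONOR_ELEMENTS = {"N", "O", "S", "Se"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}


def one_letter(residue_name: str) -> str:
    return THREE_TO_ONE.get(residue_name.strip().upper(), "X")


@dataclass(frozen=True)
class Contact:
    """A first-shell atom together with its distance to the metal (Å)."""

    atom: AtomRecord
    distance: float


@dataclass
class MetalSite:
    """One metal ion plus its partitioned first shell."""

    structure_id: str
    metal: AtomRecord
    cutoff: float
    protein_donors: list[Contact] = field(default_factory=list)
    hetero_donors: list[Contact] = field(default_factory=list)
    solvent: list[Contact] = field(default_factory=list)
    carbon_contacts: list[Contact] = field(default_factory=list)
    hydrogen_contacts: list[Contact] = field(default_factory=list)

    def all_contacts(self) -> list[Contact]:
        return (
            self.protein_donors + self.hetero_donors + self.solvent
            + self.carbon_contacts + self.hydrogen_contacts
        )

    def donor_atoms(self) -> list[Contact]:
        """Non-carbon, non-hydrogen shell atoms: the coordination polyhedron."""
        return self.protein_donors + self.hetero_donors + self.solvent

    def protein_donor_residues(self) -> list[ResidueKey]:
        """Distinct residues contributing ≥ 1 protein donor atom, in
        (chain, seq, icode) order."""
        seen: dict[ResidueKey, None] = {}
        for c in self.protein_donors:
            seen.setdefault(c.atom.residue_key)
        return sorted(seen, key=lambda k: (k[0], k[1], k[2]))


def find_metal_sites(
    model: StructureModel,
    element: str = "Ni",
    cutoff: float = 3.0,
    include_hydrogens: bool = False,
) -> list[MetalSite]:
    """Locate every atom of ``element`` and extract its first shell.

    The cutoff comparison is inclusive (distance ≤ cutoff). Hydrogens are
    listed separately and never counted as donors unless
    ``include_hydrogens`` is set, in which case they join the protein or
    hetero lists (crystallographic H placement is model-dependent, so the
    default keeps them out of the census).
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff!r}")
    want = element.strip().capitalize()
    atoms = list(model.atoms())
    metals = [a for a in atoms if a.element.strip().capitalize() == want]
    if not metals:
        return []
    others = [a for a in atoms]
    coords = np.array([a.xyz for a in others])
    tree = cKDTree(coords)
    sites = []
    for metal in metals:
        idx = tree.query_ball_point(metal.xyz, cutoff)
        site = MetalSite(model.structure_id, metal, cutoff)
        for i in sorted(idx):
            atom = others[i]
            if atom is metal:
                continue
            dist = float(np.linalg.norm(atom.xyz - metal.xyz))
            contact = Contact(atom, dist)
            elem = atom.element.strip().capitalize()
            if elem in ("H", "D") and not include_hydrogens:
                site.hydrogen_contacts.append(contact)
            elif elem == "C":
                site.carbon_contacts.append(contact)
            elif atom.residue_name.strip().upper() in WATER_RESIDUES:
                site.solvent.append(contact)
            elif atom.is_het:
                site.hetero_donors.append(contact)
            else:
                site.protein_donors.append(contact)
        sites.append(site)
    return sites


def donor_census(site: MetalSite) -> tuple[int, int, int, int]:
    """(coordination number, n protein-donor residues, n hetero, n solvent).

    The coordination number counts non-carbon, non-hydrogen shell atoms
    across the protein, hetero and solvent lists.
    """
    def _nonh(contacts: Iterable[Contact]) -> list[Contact]:
        return [c for c in contacts if c.atom.element.strip().capitalize() not in ("H", "D")]

    protein = _nonh(site.protein_donors)
    hetero = _nonh(site.hetero_donors)
    solvent = _nonh(site.solvent)
    cn = len(protein) + len(hetero) + len(solvent)
    n_protein_res = len({c.atom.residue_key for c in protein})
    return cn, n_protein_res, len(hetero), len(solvent)


def metal_donor_distances(site: MetalSite) -> list[tuple[str, str, str, float]]:
    """(atom name, residue name, element, distance) for every shell atom,
    carbon contacts included."""
    return [
        (c.atom.atom_name, c.atom.residue_name, c.atom.element, c.distance)
        for c in site.all_contacts()
    ]


def spacing_notation(donor_positions: Sequence[int]) -> str:
    """Render donor positions relative to the first donor.

    ``[12, 14, 16]`` → ``"n, n+2, n+4"``; a donor more than 100 residues
    from the first is written ``m``.
    """
    positions = list(donor_positions)
    if not positions:
        raise ValidationError("spacing_notation requires at least one position")
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValidationError(f"positions must be strictly increasing: {positions!r}")
    first = positions[0]
    parts = ["n"]
    for p in positions[1:]:
        offset = p - first
        parts.append("m" if offset > 100 else f"n+{offset}")
    return ", ".join(parts)


def chelate_size(donor_positions: Sequence[int]) -> int:
    """Inclusive residue span from first to last donor; a single donor → 1.

    The inclusive convention makes the number of one-donor chelates equal
    the number of size-1 chelates, which is how the two censuses coincide.
    """
    positions = list(donor_positions)
    if not positions:
        raise ValidationError("chelate_size requires at least one position")
    return positions[-1] - positions[0] + 1


Denticity = str  # "mono" | "bi" | "tri"


@dataclass
class ChelateLoop:
    """Ordered protein-donor residues of one metal site (analysis chain)."""

    site: MetalSite | None
    chain_id: str
    donors: list[tuple[str, int, str, tuple[str, ...]]]
    # (one-letter code, residue_seq, chain_id, donor atom names)
    pattern: str
    spacing: str
    chelate_size: int
    n_protein_donors: int
    coordination_number: int
    n_heteroatom_donors: int
    denticity: list[Denticity]
    flags: list[str] = field(default_factory=list)

    @property
    def donor_positions(self) -> list[int]:
        return [seq for _, seq, _, _ in self.donors]


def toy_loop(donors: Sequence[tuple[str, int]], chain_id: str = "A") -> ChelateLoop:
    """Build a ChelateLoop directly from (one-letter code, position) pairs.

    Used by the synthetic-data generators and anywhere a loop is specified
    by its pattern rather than detected from coordinates.
    """
    ordered = sorted(donors, key=lambda d: d[1])
    positions = [p for _, p in ordered]
    if len(set(positions)) != len(positions):
        raise ValidationError(f"duplicate donor positions: {positions!r}")
    return ChelateLoop(
        site=None,
        chain_id=chain_id,
        donors=[(code, pos, chain_id, ("X",)) for code, pos in ordered],
        pattern="".join(code for code, _ in ordered),
        spacing=spacing_notation(positions),
        chelate_size=chelate_size(positions),
        n_protein_donors=len(ordered),
        coordination_number=len(ordered),
        n_heteroatom_donors=0,
        denticity=["mono"] * len(ordered),
    )


def build_chelate_loop(site: MetalSite) -> ChelateLoop:
    """Assemble the chelate loop of a site.

    Donors are the distinct residues on the analysis chain (the chain
    contributing the most protein donor atoms) that donate ≥ 1 non-carbon
    atom; residues on other chains stay in the site and count toward the
    coordination number but are excluded from the pattern and spacing —
    sequence arithmetic is only meaningful within one chain.

    A site with no protein donor at all yields an empty pattern flagged
    ``no-protein-donor``; for nickel such sites are asserted never to occur,
    and the flag makes the assertion testable.
    """
    cn, _, n_het, n_solv = donor_census(site)
    residue_keys = site.protein_donor_residues()
    if not residue_keys:
        return ChelateLoop(
            site=site, chain_id="", donors=[], pattern="", spacing="",
            chelate_size=0, n_protein_donors=0, coordination_number=cn,
            n_heteroatom_donors=n_het + n_solv, denticity=[],
            flags=["no-protein-donor"],
        )
    # pseudo-model carrying just enough for chain selection
    chain = select_analysis_chain(
        StructureModel(site.structure_id), site
    )
    by_residue: dict[ResidueKey, list[Contact]] = {}
    for c in site.protein_donors:
        if c.atom.element.strip().capitalize() in ("H", "D"):
            continue
        by_residue.setdefault(c.atom.residue_key, []).append(c)
    chain_keys = sorted(
        (k for k in by_residue if k[0] == chain), key=lambda k: (k[1], k[2])
    )
    donors = []
    denticity: list[Denticity] = []
    for key in chain_keys:
        contacts = by_residue[key]
        atom_names = tuple(c.atom.atom_name for c in contacts)
        code = one_letter(contacts[0].atom.residue_name)
        donors.append((code, key[1], key[0], atom_names))
        n = len(contacts)
        if n > 3:
            warnings.warn(
                f"{site.structure_id}: residue {key} contributes {n} donor atoms; "
                "reporting denticity 'tri'", stacklevel=2,
            )
        denticity.append("mono" if n == 1 else "bi" if n == 2 else "tri")
    positions = [seq for _, seq, _, _ in donors]
    flags = []
    if len(chain_keys) != len(by_residue):
        flags.append("cross-chain-donors")
    return ChelateLoop(
        site=site,
        chain_id=chain,
        donors=donors,
        pattern="".join(code for code, _, _, _ in donors),
        spacing=spacing_notation(positions),
        chelate_size=chelate_size(positions),
        n_protein_donors=len(donors),
        coordination_number=cn,
        n_heteroatom_donors=n_het + n_solv,
        denticity=denticity,
        flags=flags,
    )


def coordination_table(
    records: Iterable[tuple[StructureModel, MetalSite, ChelateLoop]],
    secondary_structure: dict[int, str] | None = None,
    fold_annotation: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate per-site coordination details (one row per metal site)."""
    rows = []
    for i, (model, site, loop) in enumerate(records):
        rows.append({
            "structure_id": model.structure_id,
            "resolution": model.resolution,
            "resolution_group": resolution_group(model),
            "chelate_loop": loop.pattern,
            "spacing": loop.spacing,
            "chelate_size": loop.chelate_size,
            "residue_length": loop.n_protein_donors,
            "n_heteroatoms": loop.n_heteroatom_donors,
            "coordination_number": loop.coordination_number,
            "denticity": ",".join(loop.denticity),
            "secondary_structure": (secondary_structure or {}).get(i, ""),
            "fold": (fold_annotation or {}).get(model.structure_id, ""),
            "flags": ";".join(loop.flags),
        })
    return pd.DataFrame(rows)


def write_coordination_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
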