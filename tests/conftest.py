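"""Shared fixtures: hand-built PDB text and random structure generators."""

from __future__ import annotations

import numpy as np
import pytest

from nicoord.structure_model import AtomRecord, StructureModel


def pdb_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.0,
    b: float = 15.0,
    element: str = "",
    altloc: str = " ",
) -> str:
    """Format one fixed-column ATOM/HETATM line."""
    atom_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {atom_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def write_pdb_text(tmp_path):
    def _write(lines, name="toy.pdb"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\nEND\n")
        return path

    return _write


def make_atom(
    serial: int,
    name: str,
    element: str,
    resname: str,
    chain: str,
    resseq: int,
    pos,
    occ: float = 1.0,
    b: float = 15.0,
    is_het: bool = False,
) -> AtomRecord:
    return AtomRecord(
        serial=serial, atom_name=name, element=element, alt_loc="",
        residue_name=resname, chain_id=chain, residue_seq=resseq,
        insertion_code="", position=tuple(float(c) for c in pos),
        occupancy=occ, b_factor=b, is_het=is_het,
    )


def random_metal_structure(rng: np.random.Generator, n_atoms: int = 50) -> StructureModel:
    """A Ni ion at the origin plus random atoms in a 10 Å box.

    Elements, residue types and het flags are drawn so that all four
    first-shell partitions (protein donor, hetero, solvent, carbon) can
    occur.
    """
    model = StructureModel("RND", resolution=1.9)
    model.add_atom(make_atom(1, "NI", "Ni", "NI", "A", 500, (0, 0, 0), is_het=True))
    kinds = [
        ("NE2", "N", "HIS", False),
        ("OD1", "O", "ASP", False),
        ("SG", "S", "CYS", False),
        ("CE1", "C", "HIS", False),
        ("O", "O", "HOH", True),
        ("O1", "O", "SO4", True),
        ("H", "H", "HIS", False),
    ]
    for i in range(n_atoms):
        name, element, resname, is_het = kinds[int(rng.integers(len(kinds)))]
        pos = rng.uniform(-5, 5, size=3)
        chain = "A" if rng.random() < 0.8 else "B"
        model.add_atom(
            make_atom(i + 2, name, element, resname, chain, 10 + i, pos, is_het=is_het)
        )
    return model
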