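"""Seed-deterministic generators for every fixture the pipeline consumes.

Three families of synthetic inputs:

* *ideal metal sites*: a Ni ion at the origin with donor atoms placed on
  the ideal directions of a named coordination template, optional Gaussian
  coordinate noise, and minimal residue stubs whose backbone stays outside
  the first shell. These exercise detection, validation and geometry
  classification with a known ground truth.
* *toy chelate tables*: chelate loops realising an exact requested census
  of (first residue, succeeding residue, spacing) counts — the exact
  pre-image of a probability table.
* *planted-motif alignments*: family alignments with a motif planted at a
  controllable per-column conservation level over a random background,
  with a truth record naming the planted columns.

All generators are pure functions of their specs (fixed seed → identical
output). Residue stubs use idealised internal geometry; no rotamer realism
is claimed — sufficient for donor analysis, not for modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .coordination import ChelateLoop, toy_loop
from .errors import ValidationError
from .geometry import TEMPLATE_DIRECTIONS
from .patterns import AMINO_ACIDS
from .structure_model import AtomRecord, StructureModel

#: Background preset reflecting the hydrophilic enrichment seen around
#: nickel sites (His/Asp/Glu/Cys and other polar residues up-weighted).
HYDROPHILIC_BACKGROUND: dict[str, float] = {
    **{aa: 0.03 for aa in AMINO_ACIDS},
    "H": 0.12, "D": 0.09, "E": 0.09, "C": 0.06, "S": 0.06,
    "N": 0.06, "Q": 0.06, "G": 0.04,
}

_ATOM_ELEMENT_OVERRIDES = {"SG": "S", "SD": "S", "SE": "Se"}


def _donor_element(atom_name: str) -> str:
    return _ATOM_ELEMENT_OVERRIDES.get(atom_name, atom_name[0].upper())


@dataclass
class SiteSpec:
    """Recipe for one ideal-geometry nickel site."""

    geometry_label: str
    donors: list[tuple[str, str]] | None = None  # (residue 3-letter, donor atom)
    bond_length: float = 2.1
    noise_sigma: float = 0.0
    seed: int = 0
    positions: list[int] | None = None  # author residue numbers of donors
    chain_id: str = "A"
    metal_b_factor: float = 20.0
    default_b_factor: float = 15.0
    donor_b_factors: list[float] | None = None
    donor_occupancies: list[float] | None = None
    structure_id: str = "SYNTH"
    resolution: float | None = 1.8


def make_ideal_site(spec: SiteSpec) -> StructureModel:
    """Build a structure realising the spec's coordination template.

    The Ni ion sits at the origin; donor atoms sit on the template's ideal
    directions scaled to ``bond_length``, with independent Gaussian noise
    of ``noise_sigma`` Å per coordinate. Each donor is embedded in a
    residue stub whose backbone N/CA/C lie further out along the donor
    direction (≥ 4 Å from the metal) so they stay outside the shell.
    """
    if spec.geometry_label not in TEMPLATE_DIRECTIONS:
        raise ValidationError(f"unknown geometry {spec.geometry_label!r}")
    directions = TEMPLATE_DIRECTIONS[spec.geometry_label]
    n = len(directions)
    donors = spec.donors or [("HIS", "NE2")] * n
    if len(donors) != n:
        raise ValidationError(
            f"{spec.geometry_label} needs {n} donors, got {len(donors)}"
        )
    if spec.bond_length <= 0:
        raise ValidationError("bond_length must be positive")
    if spec.noise_sigma < 0:
        raise ValidationError("noise_sigma must be non-negative")
    positions = spec.positions or [10 + 2 * i for i in range(n)]
    if len(positions) != n:
        raise ValidationError(f"need {n} residue positions, got {len(positions)}")
    rng = np.random.default_rng(spec.seed)

    model = StructureModel(
        structure_id=spec.structure_id, resolution=spec.resolution
    )
    serial = 1
    model.add_atom(
        AtomRecord(
            serial=serial, atom_name="NI", element="Ni", alt_loc="",
            residue_name="NI", chain_id=spec.chain_id, residue_seq=999,
            insertion_code="", position=(0.0, 0.0, 0.0), occupancy=1.0,
            b_factor=spec.metal_b_factor, is_het=True,
        )
    )
    for i, (direction, (res_name, atom_name)) in enumerate(zip(directions, donors)):
        unit = direction / np.linalg.norm(direction)
        # orthonormal frame for laterally offsetting the backbone stub
        helper = np.array([0.0, 0.0, 1.0]) if abs(unit[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        perp = np.cross(unit, helper)
        perp /= np.linalg.norm(perp)
        donor_pos = unit * spec.bond_length
        if spec.noise_sigma > 0:
            donor_pos = donor_pos + rng.normal(0.0, spec.noise_sigma, size=3)
        b = spec.donor_b_factors[i] if spec.donor_b_factors else spec.default_b_factor
        occ = spec.donor_occupancies[i] if spec.donor_occupancies else 1.0
        seq = positions[i]
        backbone = {
            "N": unit * (spec.bond_length + 2.5),
            "CA": unit * (spec.bond_length + 3.4) + perp * 0.8,
            "C": unit * (spec.bond_length + 4.3),
        }
        for name, pos in backbone.items():
            serial += 1
            model.add_atom(
                AtomRecord(
                    serial=serial, atom_name=name,
                    element="N" if name == "N" else "C",
                    alt_loc="", residue_name=res_name, chain_id=spec.chain_id,
                    residue_seq=seq, insertion_code="",
                    position=tuple(float(c) for c in pos),
                    occupancy=occ, b_factor=spec.default_b_factor, is_het=False,
                )
            )
        serial += 1
        model.add_atom(
            AtomRecord(
                serial=serial, atom_name=atom_name,
                element=_donor_element(atom_name), alt_loc="",
                residue_name=res_name, chain_id=spec.chain_id, residue_seq=seq,
                insertion_code="", position=tuple(float(c) for c in donor_pos),
                occupancy=occ, b_factor=b, is_het=False,
            )
        )
    return model


def perturb_site(model: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Displace every non-metal atom by independent Gaussian noise.

    Deterministic for a fixed seed; ``sigma = 0`` returns identical
    coordinates. The metal stays fixed so the perturbation changes the
    coordination polyhedron, not its centre.
    """
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    out = StructureModel(model.structure_id, model.resolution, model.method)
    for atom in model.atoms():
        if atom.element in ("Ni", "NI") or sigma == 0:
            out.add_atom(atom)
            continue
        shift = rng.normal(0.0, sigma, size=3)
        out.add_atom(
            replace(atom, position=tuple(float(c) for c in atom.xyz + shift))
        )
    return out


def make_toy_chelate_table(
    counts: Mapping[tuple[str, str, int], int], seed: int = 0
) -> list[ChelateLoop]:
    """Chelate loops realising an exact (first, succeeding, spacing) census.

    Each requested occurrence becomes one two-donor loop, so feeding the
    result to ``succeeding_probability_table`` reproduces the count map
    exactly (for spacings within the counting window).
    """
    rng = np.random.default_rng(seed)
    loops: list[ChelateLoop] = []
    for (a, b, k), count in sorted(counts.items()):
        if count < 0:
            raise ValidationError(f"negative count for {(a, b, k)!r}")
        if k < 1:
            raise ValidationError(f"spacing must be ≥ 1, got {k}")
        for _ in range(count):
            start = int(rng.integers(1, 200))
            loops.append(toy_loop([(a, start), (b, start + k)]))
    return loops


@dataclass
class FamilySpec:
    """Recipe for a planted-motif family alignment."""

    depth: int
    length: int
    motif: str
    motif_offset: int = 0
    conservation: float = 1.0
    background_frequencies: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1 or self.length < 1:
            raise ValidationError("depth and length must be ≥ 1")
        if not 0.0 <= self.conservation <= 1.0:
            raise ValidationError("conservation must be in [0, 1]")
        if self.motif_offset < 0 or self.motif_offset + len(self.motif) > self.length:
            raise ValidationError("motif does not fit within length at offset")


def make_toy_family_alignment(spec: FamilySpec) -> tuple[list[str], dict]:
    """Generate alignment rows plus a truth record of the planted columns.

    Every row is drawn from the background distribution; at each motif
    column the motif residue replaces the background draw with probability
    ``conservation`` (independently per row and column). A motif position
    written ``X`` stays background. The truth record lists the planted
    columns/residues and the rows that carry the complete motif.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = spec.background_frequencies or {aa: 1 / 20 for aa in AMINO_ACIDS}
    letters = sorted(freqs)
    probs = np.array([freqs[ch] for ch in letters], dtype=float)
    probs = probs / probs.sum()
    motif_cols = {
        spec.motif_offset + i: ch
        for i, ch in enumerate(spec.motif.upper())
        if ch != "X"
    }
    rows: list[str] = []
    for _ in range(spec.depth):
        draw = rng.choice(len(letters), size=spec.length, p=probs)
        chars = [letters[i] for i in draw]
        for col, residue in motif_cols.items():
            if rng.random() < spec.conservation:
                chars[col] = residue
        rows.append("".join(chars))
    carriers = [
        i for i, row in enumerate(rows)
        if all(row[col] == res for col, res in motif_cols.items())
    ]
    truth = {
        "motif": spec.motif.upper(),
        "offset": spec.motif_offset,
        "columns": sorted(motif_cols),
        "residues": motif_cols,
        "rows_with_motif": carriers,
    }
    return rows, truth


def make_random_sequences(
    n: int,
    length: int,
    seed: int = 0,
    background_frequencies: dict[str, float] | None = None,
) -> list[str]:
    """Random protein sequences for background/specificity checks."""
    rng = np.random.default_rng(seed)
    freqs = background_frequencies or {aa: 1 / 20 for aa in AMINO_ACIDS}
    letters = sorted(freqs)
    probs = np.array([freqs[ch] for ch in letters], dtype=float)
    probs = probs / probs.sum()
    out = []
    for _ in range(n):
        draw = rng.choice(len(letters), size=length, p=probs)
        out.append("".join(letters[i] for i in draw))
    return out
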