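"""Coordination geometry and backbone-dihedral analysis.

Geometry classification compares the multiset of metal-centred donor–donor
angles with ideal templates. For ``d`` donor atoms there are C(d, 2)
angles; the template minimising the RMSD between the sorted observed and
sorted ideal angle multisets wins. Ideal templates:

====================  ======  ==========================================
label                 donors  angle multiset (degrees)
====================  ======  ==========================================
linear                2       180
trigonal_planar       3       120 ×3
trigonal_pyramidal    3       109.47 ×3
tetrahedral           4       109.47 ×6
square_planar         4       90 ×4, 180 ×2
see_saw               4       90 ×4, 120, 180  (also the all-cis variant
                              90 ×5, 180; best RMSD wins)
square_pyramidal      5       90 ×8, 180 ×2
trigonal_bipyramidal  5       90 ×6, 120 ×3, 180
octahedral            6       90 ×12, 180 ×3
====================  ======  ==========================================

Backbone dihedrals use the standard convention
φ = C(i−1)–N–CA–C, ψ = N–CA–C–N(i+1), reported in (−180°, 180°].
Ramachandran windows: region A (right-handed helix) φ ∈ [−180, 0),
ψ ∈ [−120, 60); region B (sheet) φ ∈ [−180, 0) with ψ ≥ 60 or ψ < −120
(the sheet window wraps through ±180); region E (left-handed helix)
φ ∈ [90, 100], ψ ∈ [−20, 80]; region CD (partially allowed)
φ ∈ [−180, −40], ψ ∈ [−40, 0). Overlaps resolve in the order A, B, E, CD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coordination import ChelateLoop, Contact, MetalSite
from .errors import (
    DegenerateGeometryError,
    NotClassifiableError,
    ValidationError,
)
from .structure_model import ResidueKey, StructureModel

TETRAHEDRAL_ANGLE = math.degrees(math.acos(-1.0 / 3.0))  # 109.471...

#: Ideal donor direction sets (unit vectors); one entry per geometry label.
TEMPLATE_DIRECTIONS: dict[str, np.ndarray] = {
    "linear": np.array([[1, 0, 0], [-1, 0, 0]], dtype=float),
    "trigonal_planar": np.array(
        [[1, 0, 0], [-0.5, math.sqrt(3) / 2, 0], [-0.5, -math.sqrt(3) / 2, 0]]
    ),
    "trigonal_pyramidal": np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1]], dtype=float
    ) / math.sqrt(3),
    "tetrahedral": np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / math.sqrt(3),
    "square_planar": np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float
    ),
    "see_saw": np.array(
        [[0, 0, 1], [0, 0, -1], [1, 0, 0], [-0.5, math.sqrt(3) / 2, 0]]
    ),
    "square_pyramidal": np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]], dtype=float
    ),
    "trigonal_bipyramidal": np.array(
        [
            [0, 0, 1], [0, 0, -1],
            [1, 0, 0], [-0.5, math.sqrt(3) / 2, 0], [-0.5, -math.sqrt(3) / 2, 0],
        ]
    ),
    "octahedral": np.array(
        [
            [1, 0, 0], [-1, 0, 0], [0, 1, 0],
            [0, -1, 0], [0, 0, 1], [0, 0, -1],
        ],
        dtype=float,
    ),
}

GEOMETRY_LABELS = tuple(TEMPLATE_DIRECTIONS)


def _pairwise_angles(directions: np.ndarray) -> np.ndarray:
    unit = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    dots = np.clip(unit @ unit.T, -1.0, 1.0)
    iu = np.triu_indices(len(unit), k=1)
    return np.degrees(np.arccos(dots[iu]))


def _template_angle_sets() -> dict[str, list[np.ndarray]]:
    sets = {
        label: [np.sort(_pairwise_angles(dirs))]
        for label, dirs in TEMPLATE_DIRECTIONS.items()
    }
    # all-cis see-saw variant: trans pair retained, equatorial pair at 90°
    cis = np.array([[0, 0, 1], [0, 0, -1], [1, 0, 0], [0, 1, 0]], dtype=float)
    sets["see_saw"].append(np.sort(_pairwise_angles(cis)))
    return sets


TEMPLATE_ANGLES: dict[str, list[np.ndarray]] = _template_angle_sets()


@dataclass
class GeometryAssignment:
    site: MetalSite
    donor_atoms_used: list[Contact]
    angles: list[float]
    label: str
    angular_rmsd: float
    distorted: bool


def donor_angles(
    site: MetalSite, atoms: Sequence[Contact] | None = None
) -> list[float]:
    """All metal-centred donor–metal–donor angles, in degrees.

    ``atoms`` defaults to the site's coordination polyhedron (every
    non-carbon, non-hydrogen shell atom, so bidentate residues contribute
    each of their donor atoms).
    """
    contacts = list(atoms) if atoms is not None else site.donor_atoms()
    if len(contacts) < 2:
        raise ValidationError("need ≥ 2 donor atoms for angles")
    centre = site.metal.xyz
    vectors = np.array([c.atom.xyz - centre for c in contacts])
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms < 1e-9):
        raise DegenerateGeometryError("donor atom coincides with the metal")
    return [float(a) for a in _pairwise_angles(vectors)]


def classify_geometry(
    site: MetalSite,
    atoms: Sequence[Contact] | None = None,
    distortion_threshold: float = 15.0,
) -> GeometryAssignment:
    """Assign the best-fitting ideal coordination geometry.

    Scans every template compatible with the donor count and keeps the one
    with the smallest RMSD between sorted angle multisets. More than six
    donor atoms is labelled ``irregular``; fewer than two is not
    classifiable. ``distorted`` flags an RMSD above the threshold (15° by
    default — ideal-template noise studies put clean assignments well
    below it).
    """
    contacts = list(atoms) if atoms is not None else site.donor_atoms()
    d = len(contacts)
    if d < 2:
        raise NotClassifiableError(f"{d} donor atoms; need ≥ 2")
    if d > 6:
        return GeometryAssignment(
            site, contacts, donor_angles(site, contacts),
            label="irregular", angular_rmsd=float("nan"), distorted=True,
        )
    observed = np.sort(donor_angles(site, contacts))
    best_label, best_rmsd = "irregular", float("inf")
    for label, variants in TEMPLATE_ANGLES.items():
        if len(TEMPLATE_DIRECTIONS[label]) != d:
            continue
        for ideal in variants:
            rmsd = float(np.sqrt(np.mean((observed - ideal) ** 2)))
            if rmsd < best_rmsd:
                best_label, best_rmsd = label, rmsd
    return GeometryAssignment(
        site, contacts, [float(a) for a in observed],
        label=best_label, angular_rmsd=best_rmsd,
        distorted=best_rmsd > distortion_threshold,
    )


def residue_denticity(site: MetalSite, residue_key: ResidueKey) -> str:
    """mono/bi/tri by the residue's count of in-shell non-carbon donor atoms."""
    n = sum(
        1
        for c in site.protein_donors
        if c.atom.residue_key == residue_key
        and c.atom.element.strip().capitalize() not in ("C", "H", "D")
    )
    if n == 0:
        raise LookupError(f"residue {residue_key} contributes no donor atom")
    if n > 3:
        import warnings

        warnings.warn(
            f"residue {residue_key} contributes {n} donor atoms; reporting 'tri'",
            stacklevel=2,
        )
    return "mono" if n == 1 else "bi" if n == 2 else "tri"


def dihedral(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    """Torsion angle p1–p2–p3–p4 in degrees, range (−180, 180]."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear atoms: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    angle = math.degrees(math.atan2(y, x))
    return 180.0 if angle <= -180.0 else angle


@dataclass
class DihedralPair:
    residue_key: ResidueKey
    phi: float | None
    psi: float | None
    region: str = "undefined"  # "A" | "B" | "E" | "CD" | "other" | "undefined"


def _backbone(model: StructureModel, key: ResidueKey) -> dict[str, np.ndarray] | None:
    atoms = {a.atom_name: a.xyz for a in model.residues.get(key, [])}
    if all(n in atoms for n in ("N", "CA", "C")):
        return atoms
    return None


def backbone_dihedrals(model: StructureModel, residue_key: ResidueKey) -> DihedralPair:
    """φ/ψ of one residue; chain-terminal residues get None markers."""
    chain_id = residue_key[0]
    chain = model.chain_residues(chain_id)
    if residue_key not in chain:
        raise LookupError(f"residue {residue_key} not in model")
    idx = chain.index(residue_key)
    here = _backbone(model, residue_key)
    prev_atoms = _backbone(model, chain[idx - 1]) if idx > 0 else None
    next_atoms = _backbone(model, chain[idx + 1]) if idx + 1 < len(chain) else None
    if here is None:
        return DihedralPair(residue_key, None, None)
    phi = psi = None
    if prev_atoms is not None:
        phi = dihedral(prev_atoms["C"], here["N"], here["CA"], here["C"])
    if next_atoms is not None:
        psi = dihedral(here["N"], here["CA"], here["C"], next_atoms["N"])
    pair = DihedralPair(residue_key, phi, psi)
    if phi is not None and psi is not None:
        pair.region = ramachandran_region(pair)
    return pair


def ramachandran_region(pair: DihedralPair) -> str:
    """Assign the φ/ψ window; precedence A, B, E, CD on overlap."""
    phi, psi = pair.phi, pair.psi
    if phi is None or psi is None:
        return "undefined"
    if -180 <= phi < 0 and -120 <= psi < 60:
        return "A"
    if -180 <= phi < 0 and (psi >= 60 or psi < -120):
        return "B"
    if 90 <= phi <= 100 and -20 <= psi <= 80:
        return "E"
    if -180 <= phi <= -40 and -40 <= psi < 0:
        return "CD"
    return "other"


def secondary_structure_label(
    chelate: ChelateLoop, dihedrals: Sequence[DihedralPair]
) -> str:
    """Per-donor H (helix, region A) / S (sheet, region B) / T (other),
    aligned with the loop's pattern order."""
    if len(dihedrals) != len(chelate.donors):
        raise ValidationError(
            f"{len(dihedrals)} dihedral pairs for {len(chelate.donors)} donors"
        )
    out = []
    for pair in dihedrals:
        region = pair.region if pair.region != "undefined" else ramachandran_region(pair)
        out.append("H" if region == "A" else "S" if region == "B" else "T")
    return "".join(out)


def geometry_table(assignments: Iterable[GeometryAssignment]) -> pd.DataFrame:
    rows = [
        {
            "structure_id": a.site.structure_id,
            "n_donor_atoms": len(a.donor_atoms_used),
            "label": a.label,
            "angular_rmsd": a.angular_rmsd,
            "distorted": a.distorted,
            "angles": ",".join(f"{x:.2f}" for x in a.angles),
        }
        for a in assignments
    ]
    return pd.DataFrame(rows)


def write_geometry_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
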