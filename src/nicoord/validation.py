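"""Quality control of metal sites and the associated statistics.

Crystallographic sanity checks before any coordination statistics:

* a coordinating residue with a donor-atom B-factor ≤ 2.0 Å² or an
  occupancy outside [0.5, 1.0] marks the whole structure for exclusion
  (implausibly rigid atoms and partially occupied sites both make the
  modelled coordination unreliable);
* the metal's B-factor should track the B-factors of its environment, so
  structures where |B(metal) − mean B(coordinating residues)| ≥ 7.0 Å² are
  excluded as outliers;
* the surviving set is summarised by the Pearson correlation between metal
  and mean-residue B-factors.

Group comparisons (e.g. which residue dominates coordination) use the
Kruskal–Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coordination import MetalSite, metal_donor_distances
from .errors import InsufficientDataError, ValidationError
from .structure_model import ResidueKey, StructureModel

Reason = str  # "ok" | "low_b" | "bad_occupancy" | "deviation_outlier" | "not_applicable"


@dataclass
class ValidationReport:
    structure_id: str
    metal_b: float
    mean_residue_b: float
    excluded_residues: list[tuple[ResidueKey, Reason]] = field(default_factory=list)
    include_flag: bool = True
    reason: Reason = "ok"

    @property
    def deviation(self) -> float:
        return abs(self.metal_b - self.mean_residue_b)


def residue_quality_filter(
    site: MetalSite,
    model: StructureModel | None = None,
    b_min: float = 2.0,
    occ_range: tuple[float, float] = (0.5, 1.0),
    donor_atoms_only: bool = False,
) -> ValidationReport:
    """Flag a structure whose coordinating residues have suspect B/occupancy.

    A residue is flagged if *any of its donor atoms* has ``b_factor ≤ b_min``
    or an occupancy outside ``occ_range``; one flagged residue excludes the
    structure. ``mean_residue_b`` averages over all atoms of the
    coordinating residues when the full model is supplied (set
    ``donor_atoms_only`` to restrict to in-shell donor atoms; without a
    model only donor atoms are available anyway).
    """
    if not site.protein_donors:
        return ValidationReport(
            site.structure_id, metal_b=site.metal.b_factor, mean_residue_b=float("nan"),
            include_flag=False, reason="not_applicable",
        )
    lo, hi = occ_range
    excluded: list[tuple[ResidueKey, Reason]] = []
    seen: set[tuple[ResidueKey, Reason]] = set()
    for contact in site.protein_donors:
        atom = contact.atom
        if atom.b_factor <= b_min:
            entry = (atom.residue_key, "low_b")
        elif not (lo <= atom.occupancy <= hi):
            entry = (atom.residue_key, "bad_occupancy")
        else:
            continue
        if entry not in seen:
            seen.add(entry)
            excluded.append(entry)

    donor_keys = {c.atom.residue_key for c in site.protein_donors}
    if model is not None and not donor_atoms_only:
        b_values = [
            a.b_factor
            for key in donor_keys
            for a in model.residues.get(key, [])
        ]
    else:
        b_values = [c.atom.b_factor for c in site.protein_donors]
    mean_b = float(np.mean(b_values))

    include = not excluded
    # reason priority: low_b before bad_occupancy, mirroring the check order
    reason: Reason = "ok"
    if excluded:
        reasons = [r for _, r in excluded]
        reason = "low_b" if "low_b" in reasons else "bad_occupancy"
    return ValidationReport(
        structure_id=site.structure_id,
        metal_b=site.metal.b_factor,
        mean_residue_b=mean_b,
        excluded_residues=excluded,
        include_flag=include,
        reason=reason,
    )


def deviation_outlier_filter(
    reports: Sequence[ValidationReport], threshold: float = 7.0
) -> list[ValidationReport]:
    """Mark reports whose metal/residue B-factor deviation is ≥ threshold.

    Already-excluded reports pass through unchanged; the filter is
    idempotent.
    """
    out = []
    for rep in reports:
        if rep.include_flag and rep.deviation >= threshold:
            out.append(replace(rep, include_flag=False, reason="deviation_outlier"))
        else:
            out.append(rep)
    return out


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    n: int
    p_value: float


def bfactor_correlation(reports: Sequence[ValidationReport]) -> CorrelationResult:
    """Pearson correlation of metal vs mean-residue B-factor (included only)."""
    included = [r for r in reports if r.include_flag]
    if len(included) < 3:
        raise InsufficientDataError(
            f"need ≥ 3 included reports, have {len(included)}"
        )
    x = np.array([r.metal_b for r in included])
    y = np.array([r.mean_residue_b for r in included])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, n=len(included), p_value=float(res.pvalue))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (mid-ranks, tie-corrected) and chi-square p-value.

    Degenerate input where every pooled observation is identical returns
    (0, 1) rather than erroring: no evidence of any group difference.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("groups must be non-empty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def resolution_distance_consistency(
    group_a_sites: Sequence[MetalSite], group_b_sites: Sequence[MetalSite]
) -> CorrelationResult:
    """Correlate per-atom-type mean metal–donor distances across resolution
    groups.

    For every atom type (PDB atom name) seen in both groups, the mean
    metal–atom distance is computed per group and the paired means are
    correlated; a high r says the distance census is not a resolution
    artefact.
    """
    def _means(sites: Sequence[MetalSite]) -> dict[str, float]:
        acc: dict[str, list[float]] = {}
        for site in sites:
            for atom_name, _res, _elem, dist in metal_donor_distances(site):
                acc.setdefault(atom_name, []).append(dist)
        return {k: float(np.mean(v)) for k, v in acc.items()}

    means_a = _means(group_a_sites)
    means_b = _means(group_b_sites)
    shared = sorted(set(means_a) & set(means_b))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared atom types; need ≥ 3"
        )
    x = np.array([means_a[k] for k in shared])
    y = np.array([means_b[k] for k in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, n=len(shared), p_value=float(res.pvalue))


def validation_table(reports: Iterable[ValidationReport]) -> pd.DataFrame:
    rows = [
        {
            "structure_id": r.structure_id,
            "metal_b": r.metal_b,
            "mean_residue_b": r.mean_residue_b,
            "deviation": r.deviation,
            "included": r.include_flag,
            "reason": r.reason,
            "excluded_residues": ";".join(
                f"{c}:{s}{i}:{why}" for (c, s, i), why in r.excluded_residues
            ),
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def write_validation_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
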