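"""End-to-end orchestration: detect → validate → chelate → geometry →
patterns (→ signatures when alignments are supplied)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import coordination, geometry, patterns, signatures, validation
from .errors import NicoordError, ValidationError
from .structure_model import StructureModel, read_structure

logger = logging.getLogger("nicoord")


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline in one place.

    Defaults are the analysis constants: 3 Å first-shell cutoff, residue
    B-factor floor 2.0 Å², occupancy window [0.5, 1.0], metal/residue
    B-factor deviation limit 7.0 Å², geometry distortion threshold 15°,
    10-residue spacing window, majority (> 0.5) conservation, 90 %
    clustering identity.
    """

    cutoff: float = 3.0
    metal: str = "Ni"
    b_min: float = 2.0
    occ_min: float = 0.5
    occ_max: float = 1.0
    deviation_threshold: float = 7.0
    distortion_threshold: float = 15.0
    max_spacing_window: int = 10
    conservation_threshold: float = 0.5
    clustering_identity: float = 0.90
    seed: int = 0

    def __post_init__(self):
        for name in ("cutoff", "b_min", "deviation_threshold", "distortion_threshold"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("occ_min", "occ_max", "conservation_threshold", "clustering_identity"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")


class NoMetalSitesError(NicoordError):
    """No structure in the run contained a metal site."""


@dataclass
class ReportBundle:
    coordination: pd.DataFrame
    validation: pd.DataFrame
    geometry: pd.DataFrame
    probability_table: patterns.ProbabilityTable
    prosite_patterns: list[patterns.SequencePattern]
    signatures: pd.DataFrame | None
    no_site_structures: list[str]
    excluded_structures: list[str]
    out_dir: Path | None = None


def _analyse_structure(model: StructureModel, config: RunConfig):
    """Per-structure stage: sites, validation, loops, geometry, dihedrals."""
    sites = coordination.find_metal_sites(
        model, element=config.metal, cutoff=config.cutoff
    )
    results = []
    for site in sites:
        report = validation.residue_quality_filter(
            site, model=model, b_min=config.b_min,
            occ_range=(config.occ_min, config.occ_max),
        )
        results.append((site, report))
    return sites, results


def run_pipeline(
    structure_paths: Sequence[str | Path],
    config: RunConfig | None = None,
    alignments: dict[str, str | Path] | None = None,
    background_fasta: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Run the whole analysis over a set of PDB files.

    Every input structure ends up in exactly one of: the coordination
    table, the exclusion log, or the no-site log. Deterministic for fixed
    config and inputs. Raises :class:`NoMetalSitesError` when no structure
    contains any site of the requested metal.
    """
    config = config or RunConfig()
    coord_records: list[tuple] = []
    all_reports: list[validation.ValidationReport] = []
    report_meta: list[tuple[StructureModel, coordination.MetalSite]] = []
    no_site: list[str] = []

    for path in structure_paths:
        model = read_structure(path)
        sites, site_reports = _analyse_structure(model, config)
        if not sites:
            logger.info("no-site structure=%s", model.structure_id)
            no_site.append(model.structure_id)
            continue
        for site, report in site_reports:
            all_reports.append(report)
            report_meta.append((model, site))

    if not report_meta:
        raise NoMetalSitesError(
            f"no {config.metal} sites found in {len(list(structure_paths))} structures"
        )

    all_reports = validation.deviation_outlier_filter(
        all_reports, threshold=config.deviation_threshold
    )

    geometry_assignments: list[geometry.GeometryAssignment] = []
    secondary: dict[int, str] = {}
    kept_loops: list[coordination.ChelateLoop] = []
    excluded: list[str] = []
    kept_records = []
    for (model, site), report in zip(report_meta, all_reports):
        if not report.include_flag:
            logger.info(
                "excluded structure=%s reason=%s", model.structure_id, report.reason
            )
            excluded.append(model.structure_id)
            continue
        loop = coordination.build_chelate_loop(site)
        kept_loops.append(loop)
        idx = len(kept_records)
        kept_records.append((model, site, loop))
        if len(site.donor_atoms()) >= 2:
            geometry_assignments.append(
                geometry.classify_geometry(
                    site, distortion_threshold=config.distortion_threshold
                )
            )
        dihedrals = [
            geometry.backbone_dihedrals(model, (chain, seq, ""))
            for _, seq, chain, _ in loop.donors
        ]
        if dihedrals:
            secondary[idx] = geometry.secondary_structure_label(loop, dihedrals)

    coord_df = coordination.coordination_table(kept_records, secondary)
    valid_df = validation.validation_table(all_reports)
    geom_df = geometry.geometry_table(geometry_assignments)
    prob_table = patterns.succeeding_probability_table(
        kept_loops, max_spacing=config.max_spacing_window
    )
    pair_spacings: dict[tuple[str, str], set[int]] = {}
    for (a, b, k), count in prob_table.counts.items():
        if count > 0:
            pair_spacings.setdefault((a, b), set()).add(k)
    prosite_patterns = patterns.derive_prosite_patterns(pair_spacings)

    signature_df = None
    if alignments:
        background = (
            signatures.read_fasta(background_fasta) if background_fasta else []
        )
        sigs: list[signatures.Signature] = []
        for family, aln_path in sorted(alignments.items()):
            rows = signatures.read_alignment(aln_path)
            profile = signatures.conservation_profile(
                rows, threshold=config.conservation_threshold
            )
            candidates = signatures.extract_signatures(
                profile, table=prob_table,
                max_gap=config.max_spacing_window,
                threshold=config.conservation_threshold, family=family,
            )
            for sig in candidates:
                sigs.append(
                    signatures.validate_signature(sig, rows, background)
                    if background or rows else sig
                )
        signature_df = signatures.signature_table(sigs)

    bundle = ReportBundle(
        coordination=coord_df,
        validation=valid_df,
        geometry=geom_df,
        probability_table=prob_table,
        prosite_patterns=prosite_patterns,
        signatures=signature_df,
        no_site_structures=no_site,
        excluded_structures=excluded,
    )
    if out_dir is not None:
        bundle.out_dir = Path(out_dir)
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    coordination.write_coordination_table(bundle.coordination, out_dir / "coordination.tsv")
    validation.write_validation_table(bundle.validation, out_dir / "validation.tsv")
    geometry.write_geometry_table(bundle.geometry, out_dir / "geometry.tsv")
    patterns.write_probability_table(bundle.probability_table, out_dir / "probability_table.tsv")
    patterns.write_patterns(bundle.prosite_patterns, out_dir / "patterns.tsv")
    if bundle.signatures is not None:
        signatures.write_signature_table(bundle.signatures, out_dir / "signatures.tsv")
    (out_dir / "logs.tsv").write_text(
        "structure_id\tstatus\n"
        + "".join(f"{s}\tno-site\n" for s in bundle.no_site_structures)
        + "".join(f"{s}\texcluded\n" for s in bundle.excluded_structures)
    )
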