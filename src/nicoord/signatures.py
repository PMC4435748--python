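"""Mining metal-binding signatures from protein-family alignments.

Pipeline: cluster the family at 90 % identity to strip redundancy, profile
the alignment column-by-column, extract PROSITE candidates from conserved
runs (a column is conserved when its modal residue occurs in more than half
of the sequences; gaps never count as conserved), and validate each
candidate by scanning family members versus an unrelated background.

A candidate is additionally flagged *structure-supported* when it contains
a donor pair whose (first residue, succeeding residue, spacing) has nonzero
probability in the structural spacing table — the cross-check between
sequence conservation and coordination statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner

from .errors import ValidationError
from .patterns import (
    AMINO_ACIDS,
    ProbabilityTable,
    SequencePattern,
    parse_prosite,
    scan_prosite,
)

GAP_CHARS = "-."


# ---------------------------------------------------------------------------
# redundancy reduction


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Fraction of identical aligned positions: matches / max(len(a), len(b)).

    Matches are maximised by a global alignment scoring 1 per identity and
    nothing for mismatches or gaps, which makes the identity measure
    deterministic and symmetric.
    """
    if not a or not b:
        return 0.0
    if aligner is None:
        aligner = _make_aligner()
    matches = aligner.score(a, b)
    return float(matches) / max(len(a), len(b))


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


def greedy_identity_cluster(
    sequences: Sequence[str], threshold: float = 0.90
) -> list[str]:
    """Greedy longest-first clustering; returns one representative per cluster.

    Sequences are visited longest-first (ties lexicographic); each joins
    the first existing cluster whose representative it matches at
    ≥ threshold identity, else founds a new cluster.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold!r}")
    ordered = sorted(sequences, key=lambda s: (-len(s), s))
    aligner = _make_aligner()
    representatives: list[str] = []
    for seq in ordered:
        for rep in representatives:
            if pairwise_identity(seq, rep, aligner) >= threshold:
                break
        else:
            representatives.append(seq)
    return representatives


# ---------------------------------------------------------------------------
# conservation profiling


@dataclass
class AlignmentProfile:
    """Per-column residue frequencies of an alignment (gap tracked as '-')."""

    columns: list[dict[str, float]]
    depth: int
    conserved_flags: list[bool]

    @property
    def length(self) -> int:
        return len(self.columns)


def conservation_profile(
    alignment: Sequence[str], threshold: float = 0.5
) -> AlignmentProfile:
    """Column frequencies plus a conserved flag per column.

    A column is conserved when its modal *residue* frequency is strictly
    greater than ``threshold`` (default: majority, > 0.5). Gap characters
    are tallied under ``-`` and can never make a column conserved.
    """
    rows = [str(r).upper() for r in alignment]
    if not rows:
        raise ValidationError("empty alignment")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValidationError("alignment rows must have equal length")
    depth = len(rows)
    columns: list[dict[str, float]] = []
    flags: list[bool] = []
    for j in range(length):
        counts: dict[str, int] = {}
        for row in rows:
            ch = row[j]
            ch = "-" if ch in GAP_CHARS else ch
            counts[ch] = counts.get(ch, 0) + 1
        freqs = {ch: c / depth for ch, c in counts.items()}
        columns.append(freqs)
        residue_freqs = {ch: f for ch, f in freqs.items() if ch in AMINO_ACIDS}
        flags.append(bool(residue_freqs) and max(residue_freqs.values()) > threshold)
    return AlignmentProfile(columns=columns, depth=depth, conserved_flags=flags)


# ---------------------------------------------------------------------------
# signature extraction


@dataclass
class Signature:
    pattern: SequencePattern
    family: str = ""
    structure_supported: bool = False
    n_family_hits: int = 0
    n_family: int = 0
    n_background_hits: int = 0
    n_background: int = 0

    @property
    def sensitivity(self) -> float:
        return self.n_family_hits / self.n_family if self.n_family else float("nan")

    @property
    def specificity(self) -> float:
        if not self.n_background:
            return float("nan")
        return 1.0 - self.n_background_hits / self.n_background


#: A bracket-set member must itself be this frequent, and the set must
#: jointly cover more than SET_COVERAGE of the column — otherwise small
#: alignments sprout spurious sets from chance co-occurrence.
SET_MEMBER_MIN_FREQ = 0.2
SET_COVERAGE = 0.75


def _column_token(
    freqs: Mapping[str, float], threshold: float, max_set: int
) -> str | None:
    """PROSITE token for one column: literal, bracket set, or None (→ X)."""
    residue_freqs = sorted(
        ((f, ch) for ch, f in freqs.items() if ch in AMINO_ACIDS),
        key=lambda t: (-t[0], t[1]),
    )
    if not residue_freqs:
        return None
    if residue_freqs[0][0] > threshold:
        return residue_freqs[0][1]
    total = 0.0
    chosen: list[str] = []
    for f, ch in residue_freqs[:max_set]:
        if f < SET_MEMBER_MIN_FREQ:
            break
        total += f
        chosen.append(ch)
        if total > max(threshold, SET_COVERAGE) and len(chosen) >= 2:
            return "[" + "".join(sorted(chosen)) + "]"
    return None


def extract_signatures(
    profile: AlignmentProfile,
    table: ProbabilityTable | None = None,
    max_gap: int = 10,
    threshold: float = 0.5,
    max_set: int = 3,
    family: str = "",
) -> list[Signature]:
    """Extract PROSITE signature candidates from an alignment profile.

    The profile is split into maximal runs of columns without a gap
    majority. Within a run, a conserved column becomes its residue; a
    column where 2–``max_set`` individually frequent residues jointly
    cover most of the depth becomes a bracket set; anything else becomes
    ``X``, and consecutive ``X`` collapse to ``X(k)``. Leading/trailing wildcards are trimmed; runs with fewer than
    two resolved columns are dropped. When a structural spacing table is
    given, candidates containing a donor pair with nonzero probability are
    flagged structure-supported.
    """
    runs: list[list[int]] = [[]]
    for j, freqs in enumerate(profile.columns):
        if freqs.get("-", 0.0) > 0.5:
            if runs[-1]:
                runs.append([])
        else:
            runs[-1].append(j)
    signatures: list[Signature] = []
    for run in runs:
        tokens: list[str | None] = [
            _column_token(profile.columns[j], threshold, max_set) for j in run
        ]
        # trim unresolved edges
        while tokens and tokens[0] is None:
            tokens.pop(0)
        while tokens and tokens[-1] is None:
            tokens.pop()
        if sum(t is not None for t in tokens) < 2:
            continue
        parts: list[str] = []
        x_run = 0
        for tok in tokens:
            if tok is None:
                x_run += 1
                continue
            if x_run:
                parts.append("X" if x_run == 1 else f"X({x_run})")
                x_run = 0
            parts.append(tok)
        prosite = "-".join(parts)
        pattern = SequencePattern(prosite, provenance=family or "alignment run")
        sig = Signature(pattern=pattern, family=family)
        if table is not None:
            sig.structure_supported = _structure_supported(pattern, table)
        signatures.append(sig)
    return signatures


def _structure_supported(pattern: SequencePattern, table: ProbabilityTable) -> bool:
    """Does the pattern contain a donor pair (a, k, b) seen in structures?"""
    _, _, elements = parse_prosite(pattern.prosite)
    # enumerate resolved single-residue positions and their offsets
    placed: list[tuple[int, frozenset[str]]] = []
    offset = 0
    variable = False
    for elem in elements:
        if elem.kind in ("literal", "set"):
            placed.append((offset, elem.residues))
        offset += elem.min_count
        if elem.max_count != elem.min_count:
            variable = True
    pairs_seen = {(a, b, k) for (a, b, k), c in table.counts.items() if c > 0}
    for i, (pi, ri) in enumerate(placed):
        for pj, rj in placed[i + 1:]:
            for k_extra in range(0, 4 if variable else 1):
                k = pj - pi + k_extra
                if any((a, b, k) in pairs_seen for a in ri for b in rj):
                    return True
    return False


def validate_signature(
    sig: Signature,
    family: Sequence[str],
    background: Sequence[str],
) -> Signature:
    """Scan family and background sequences; fill in hit counts.

    A sequence is a hit when the pattern matches at least once. Sensitivity
    is hits/family; specificity is 1 − background hit rate.
    """
    if not family:
        raise ValidationError("empty family")
    fam_hits = sum(1 for seq in family if scan_prosite(sig.pattern, _degap(seq)))
    bg_hits = sum(1 for seq in background if scan_prosite(sig.pattern, _degap(seq)))
    return replace(
        sig,
        n_family_hits=fam_hits,
        n_family=len(family),
        n_background_hits=bg_hits,
        n_background=len(background),
    )


def _degap(seq: str) -> str:
    return "".join(ch for ch in str(seq) if ch not in GAP_CHARS)


# ---------------------------------------------------------------------------
# I/O helpers


def read_alignment(path: str | Path, fmt: str | None = None) -> list[str]:
    """Read a FASTA or Clustal alignment into a list of row strings."""
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in (".aln", ".clustal") else "fasta"
    alignment = AlignIO.read(str(path), fmt)
    return [str(rec.seq) for rec in alignment]


def read_fasta(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def signature_table(signatures: Iterable[Signature]) -> pd.DataFrame:
    rows = [
        {
            "family": s.family,
            "pattern": s.pattern.prosite,
            "structure_supported": s.structure_supported,
            "n_family_hits": s.n_family_hits,
            "n_family": s.n_family,
            "n_background_hits": s.n_background_hits,
            "n_background": s.n_background,
            "sensitivity": s.sensitivity,
            "specificity": s.specificity,
        }
        for s in signatures
    ]
    return pd.DataFrame(rows)


def write_signature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
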