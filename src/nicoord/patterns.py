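"""Spacing statistics over chelate loops and PROSITE pattern machinery.

The probability table answers: given a donor residue ``a``, how likely is a
donor residue ``b`` to follow it ``k`` positions later (1 ≤ k ≤ 10) within
a chelate loop? Counting runs over every ordered in-loop donor pair with
offset ≤ 10 — coordination numbers top out near 8, so a ten-residue window
covers any designable chelate — and probabilities share a single global
denominator: the total number of counted pair occurrences.

The PROSITE machinery is a full local reimplementation of pattern
scanning: literal residues, ``[ABC]`` alternative sets, ``{ABC}``
exclusions, ``X`` wildcards with ``(m)`` / ``(m,n)`` repeat counts, and
``<`` / ``>`` terminal anchors. All match spans are reported, overlapping
ones included, with every wildcard length tried.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coordination import ChelateLoop
from .errors import PatternSyntaxError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_SPACING = 10


# ---------------------------------------------------------------------------
# probability / position tables


@dataclass
class ProbabilityTable:
    """Counts and probabilities of (first residue, succeeding residue,
    position) triples; probability = count / total_occurrences."""

    counts: dict[tuple[str, str, int], int] = field(default_factory=dict)

    @property
    def total_occurrences(self) -> int:
        return sum(self.counts.values())

    def probability(self, first: str, succeeding: str, position: int) -> float:
        total = self.total_occurrences
        if total == 0:
            return 0.0
        return self.counts.get((first, succeeding, position), 0) / total

    def entries(self) -> dict[tuple[str, str, int], tuple[int, float]]:
        total = self.total_occurrences
        return {
            key: (count, count / total) for key, count in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "first_residue": a,
                "succeeding_residue": b,
                "position": k,
                "count": c,
                "probability": c / self.total_occurrences,
            }
            for (a, b, k), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["first_residue", "succeeding_residue", "position", "count", "probability"],
        )


def succeeding_probability_table(
    chelates: Iterable[ChelateLoop], max_spacing: int = MAX_SPACING
) -> ProbabilityTable:
    """Count ordered donor pairs (a at p, b at p+k), 1 ≤ k ≤ max_spacing.

    Loops wider than the window still contribute their qualifying
    sub-pairs; a loop with no pair inside the window contributes nothing.
    """
    counts: dict[tuple[str, str, int], int] = {}
    for loop in chelates:
        donors = [(code, pos) for code, pos, _, _ in loop.donors]
        for i, (a, p) in enumerate(donors):
            for b, q in donors[i + 1:]:
                k = q - p
                if 1 <= k <= max_spacing:
                    key = (a, b, k)
                    counts[key] = counts.get(key, 0) + 1
    return ProbabilityTable(counts)


def position_table(
    table: ProbabilityTable,
) -> dict[tuple[str, int], set[str]]:
    """(first residue, position) → set of observed succeeding residues."""
    cells: dict[tuple[str, int], set[str]] = {}
    for (a, b, k), count in table.counts.items():
        if count > 0:
            cells.setdefault((a, k), set()).add(b)
    return cells


# ---------------------------------------------------------------------------
# PROSITE patterns


@dataclass(frozen=True)
class PatternElement:
    kind: str  # "literal" | "set" | "exclude" | "any"
    residues: frozenset[str]
    min_count: int = 1
    max_count: int = 1

    def matches(self, ch: str) -> bool:
        if self.kind == "any":
            return True
        if ch == "X":  # unknown residue in the sequence matches only wildcards
            return False
        if self.kind == "literal" or self.kind == "set":
            return ch in self.residues
        return ch not in self.residues  # exclude


@dataclass(frozen=True)
class SequencePattern:
    """A PROSITE-syntax pattern with free-text provenance."""

    prosite: str
    provenance: str = ""

    def elements(self) -> tuple[bool, bool, list[PatternElement]]:
        return parse_prosite(self.prosite)


def parse_prosite(text: str) -> tuple[bool, bool, list[PatternElement]]:
    """Parse a PROSITE pattern into (anchored_start, anchored_end, elements).

    Raises :class:`PatternSyntaxError` with the character offset of the
    first offending character.
    """
    raw = text.strip()
    if raw.endswith("."):
        raw = raw[:-1]
    if not raw:
        raise PatternSyntaxError("empty pattern", 0)
    anchor_start = raw.startswith("<")
    if anchor_start:
        raw = raw[1:]
    anchor_end = raw.endswith(">")
    if anchor_end:
        raw = raw[:-1]
    elements: list[PatternElement] = []
    pos = 0
    tokens = raw.split("-")
    for token in tokens:
        token = token.strip()
        if not token:
            raise PatternSyntaxError("empty element", pos)
        base, counts = token, (1, 1)
        if "(" in token:
            if not token.endswith(")"):
                raise PatternSyntaxError(f"unclosed repeat in {token!r}", pos)
            base, _, rep = token.partition("(")
            rep = rep[:-1]
            parts = rep.split(",")
            try:
                nums = [int(p) for p in parts]
            except ValueError:
                raise PatternSyntaxError(f"bad repeat count {rep!r}", pos) from None
            if len(nums) == 1:
                counts = (nums[0], nums[0])
            elif len(nums) == 2:
                counts = (nums[0], nums[1])
            else:
                raise PatternSyntaxError(f"bad repeat count {rep!r}", pos)
            if counts[0] < 0 or counts[0] > counts[1]:
                raise PatternSyntaxError(f"bad repeat range {rep!r}", pos)
        base = base.strip()
        if base in ("X", "x"):
            elements.append(PatternElement("any", frozenset(), *counts))
        elif base.startswith("[") and base.endswith("]"):
            residues = base[1:-1].upper()
            if not residues or any(r not in AMINO_ACIDS for r in residues):
                raise PatternSyntaxError(f"bad residue set {base!r}", pos)
            elements.append(PatternElement("set", frozenset(residues), *counts))
        elif base.startswith("{") and base.endswith("}"):
            residues = base[1:-1].upper()
            if not residues or any(r not in AMINO_ACIDS for r in residues):
                raise PatternSyntaxError(f"bad exclusion set {base!r}", pos)
            elements.append(PatternElement("exclude", frozenset(residues), *counts))
        elif len(base) == 1 and base.upper() in AMINO_ACIDS:
            elements.append(PatternElement("literal", frozenset(base.upper()), *counts))
        else:
            raise PatternSyntaxError(f"unrecognised element {base!r}", pos)
        pos += len(token) + 1
    return anchor_start, anchor_end, elements


def scan_prosite(
    pattern: SequencePattern | str, sequence: str
) -> list[tuple[int, int]]:
    """All (start, end) matches of a PROSITE pattern, 1-based inclusive.

    Overlapping matches are reported and every wildcard length of an
    ``X(m,n)`` element is tried, so one start position can yield several
    spans. An ``X`` in the *sequence* matches nothing except a pattern
    wildcard.
    """
    if isinstance(pattern, str):
        pattern = SequencePattern(pattern)
    anchor_start, anchor_end, elements = pattern.elements()
    seq = sequence.upper()
    n = len(seq)
    spans: set[tuple[int, int]] = set()

    def extend(elem_idx: int, pos: int, start: int) -> None:
        if elem_idx == len(elements):
            if not anchor_end or pos == n:
                spans.add((start + 1, pos))
            return
        elem = elements[elem_idx]
        for count in range(elem.min_count, elem.max_count + 1):
            if pos + count > n:
                break
            if all(elem.matches(seq[pos + j]) for j in range(count)):
                extend(elem_idx + 1, pos + count, start)
            # a failed fixed-position match also fails every longer repeat
            # of the same element only for deterministic elements; with
            # per-position checks above we must keep trying longer counts
            # only if this count matched — otherwise a later position could
            # not match either (prefix property), so break.
            else:
                break

    starts = [0] if anchor_start else range(n)
    for start in starts:
        extend(0, start, start)
    return sorted(spans)


def derive_prosite_patterns(
    pairs: Mapping[tuple[str, str], set[int] | Sequence[int]],
) -> list[SequencePattern]:
    """Turn (first, succeeding) → spacing sets into PROSITE patterns.

    Spacing 1 → ``a-b``; a single spacing k → ``a-X(k−1)-b``; a run of
    consecutive spacings {k, …, k+j} collapses to ``a-X(k−1,k+j−1)-b``;
    non-contiguous sets emit one pattern per run.
    """
    out: list[SequencePattern] = []
    for (a, b), spacings in pairs.items():
        ordered = sorted(set(int(s) for s in spacings))
        if not ordered or ordered[0] < 1:
            raise ValidationError(f"spacings must be ≥ 1, got {ordered!r}")
        runs: list[list[int]] = [[ordered[0]]]
        for s in ordered[1:]:
            if s == runs[-1][-1] + 1:
                runs[-1].append(s)
            else:
                runs.append([s])
        for run in runs:
            lo, hi = run[0], run[-1]
            if lo == 1 and hi == 1:
                prosite = f"{a}-{b}"
            elif lo == hi:
                prosite = f"{a}-X({lo - 1})-{b}"
            elif lo == 1:
                # adjacent plus gapped: emit the adjacent form separately
                out.append(SequencePattern(f"{a}-{b}", provenance=f"pair {a}{b} spacing 1"))
                if hi == 2:
                    prosite = f"{a}-X(1)-{b}"
                else:
                    prosite = f"{a}-X(1,{hi - 1})-{b}"
            else:
                prosite = f"{a}-X({lo - 1},{hi - 1})-{b}"
            out.append(
                SequencePattern(
                    prosite, provenance=f"pair {a}{b} spacings {run}"
                )
            )
    return out


# ---------------------------------------------------------------------------
# mutual information


def mutual_information(columns: Sequence[str]) -> np.ndarray:
    """Pairwise mutual information (bits) between aligned residue columns.

    ``columns[i]`` is the string of symbols of column *i* down the
    alignment. Plug-in (maximum-likelihood) frequency estimates:
    MI(i,j) = Σ p(x,y) log2 p(x,y)/(p(x)p(y)) over observed symbol pairs.
    """
    if len(columns) < 2:
        raise ValidationError("need ≥ 2 columns")
    depth = len(columns[0])
    if depth < 2:
        raise ValidationError("column depth must be ≥ 2")
    if any(len(c) != depth for c in columns):
        raise ValidationError("columns must have equal depth")
    k = len(columns)
    mi = np.zeros((k, k))
    marginals = [Counter(c) for c in columns]
    for i in range(k):
        for j in range(i + 1, k):
            joint = Counter(zip(columns[i], columns[j]))
            total = 0.0
            for (x, y), nxy in joint.items():
                pxy = nxy / depth
                px = marginals[i][x] / depth
                py = marginals[j][y] / depth
                total += pxy * math.log2(pxy / (px * py))
            mi[i, j] = mi[j, i] = max(total, 0.0)
    return mi


# ---------------------------------------------------------------------------
# serialisation


def write_probability_table(table: ProbabilityTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_patterns(patterns: Iterable[SequencePattern], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pat in patterns:
            fh.write(f"{pat.prosite}\t{pat.provenance}\n")


def write_scan_results(
    results: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    pd.DataFrame(
        results, columns=["sequence_id", "start", "end", "matched"]
    ).to_csv(path, sep="\t", index=False)
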