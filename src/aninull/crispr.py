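"""CRISPR spacer-array equivalence between assemblies.

Spacer arrays are ordered lists of short sequences; identical arrays are
strong evidence of shared strain history.  Comparison must tolerate two
assembly artifacts: the array may sit on either strand (so one genome's
array can be the reverse-complemented, reversed spacer list of the
other's), and a single array may be split across contigs.  Equivalence
therefore searches concatenation orders and orientations of each genome's
arrays; matching is exact and spacer-wise (case-insensitive) by default,
with an optional per-spacer mismatch budget.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import permutations, product
from pathlib import Path

from ._encoding import revcomp
from .formats import ParseError, clean_sequence

logger = logging.getLogger(__name__)

MAX_EXHAUSTIVE_ARRAYS = 6


@dataclass
class SpacerArray:
    """One CRISPR array: ordered spacers on a contig."""

    genome_label: str
    contig_id: str
    spacers: list[str]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.spacers:
            raise ValueError("a spacer array needs at least one spacer")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.spacers = [s.upper() for s in self.spacers]
        for s in self.spacers:
            if not set(s) <= set("ACGTN"):
                raise ValueError(f"spacer {s!r} has characters outside ACGTN")

    def oriented(self, flip: bool) -> tuple[str, ...]:
        if flip:
            return tuple(revcomp(s) for s in reversed(self.spacers))
        return tuple(self.spacers)


@dataclass
class ArrayMatchReport:
    verdict: str  # "identical" | "different"
    shared_spacers: int
    only_a: int
    only_b: int
    orientation_used: str  # "forward" | "reverse-complement"
    split_resolved: bool
    no_crispr_system: bool = False

    def to_dict(self) -> dict:
        return dict(vars(self))


def parse_spacers(path) -> list[SpacerArray]:
    """Parse an exported spacer table (TSV: contig, start, spacer sequence).

    Rows are grouped by contig; spacers are ordered by coordinate.  An
    empty file yields an empty list (the "no CRISPR-Cas system" case).
    """
    path = Path(path)
    rows: list[tuple[str, int, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns "
                    f"(contig, start, spacer), found {len(parts)}")
            contig, start_s, spacer = parts[0], parts[1], parts[2]
            try:
                start = int(start_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer start {start_s!r}") from exc
            cleaned, _ = clean_sequence(spacer)
            rows.append((contig, start, cleaned))
    arrays: dict[str, list[tuple[int, str]]] = {}
    for contig, start, spacer in rows:
        arrays.setdefault(contig, []).append((start, spacer))
    out = []
    for contig in dict.fromkeys(c for c, _, _ in rows):  # first-seen order
        ordered = sorted(arrays[contig], key=lambda t: t[0])
        out.append(SpacerArray(genome_label=path.stem, contig_id=contig,
                               spacers=[s for _, s in ordered]))
    return out


def canonicalize(arrays: list[SpacerArray]) -> list[tuple[str, ...]]:
    """Strand-canonical form of each array: the lexicographically smaller of
    the spacer list and its reverse-complemented reversal."""
    out = []
    for arr in arrays:
        fwd = arr.oriented(flip=False)
        rev = arr.oriented(flip=True)
        out.append(min(fwd, rev))
    return out


def _achievable_concatenations(arrays: list[SpacerArray]) -> set[tuple[str, ...]]:
    """All full spacer sequences reachable by ordering the genome's arrays
    and flipping each independently, reduced to strand-canonical form."""
    forms: set[tuple[str, ...]] = set()
    n = len(arrays)
    for order in permutations(range(n)):
        for flips in product((False, True), repeat=n):
            concat: tuple[str, ...] = ()
            for idx, flip in zip(order, flips):
                concat = concat + arrays[idx].oriented(flip)
            rc = tuple(revcomp(s) for s in reversed(concat))
            forms.add(min(concat, rc))
    return forms


def _spacer_multiset(arrays: list[SpacerArray]) -> Counter:
    counter: Counter = Counter()
    for arr in arrays:
        for s in arr.spacers:
            counter[min(s, revcomp(s))] += 1
    return counter


def arrays_equivalent(a: list[SpacerArray], b: list[SpacerArray],
                      max_mismatch: int = 0) -> ArrayMatchReport:
    """Compare two genomes' spacer arrays, tolerant of strand flips and of
    arrays split across contigs.

    Verdict is "identical" iff some concatenation order/orientation of A's
    arrays equals one of B's (exact spacer-wise equality unless
    ``max_mismatch`` allows per-spacer mismatches).  Shared/only counts are
    computed over strand-canonicalized spacer multisets either way.  Two
    genomes with no arrays at all compare as identical with zero spacers,
    flagged ``no_crispr_system``.
    """
    ms_a, ms_b = _spacer_multiset(a), _spacer_multiset(b)
    shared = sum((ms_a & ms_b).values())
    only_a = sum((ms_a - ms_b).values())
    only_b = sum((ms_b - ms_a).values())

    if not a and not b:
        return ArrayMatchReport(verdict="identical", shared_spacers=0,
                                only_a=0, only_b=0, orientation_used="forward",
                                split_resolved=False, no_crispr_system=True)
    if not a or not b:
        return ArrayMatchReport(verdict="different", shared_spacers=0,
                                only_a=only_a, only_b=only_b,
                                orientation_used="forward", split_resolved=False)

    if len(a) > MAX_EXHAUSTIVE_ARRAYS or len(b) > MAX_EXHAUSTIVE_ARRAYS:
        logger.warning(
            "more than %d arrays per genome: falling back to multiset "
            "comparison (order not checked)", MAX_EXHAUSTIVE_ARRAYS)
        identical = ms_a == ms_b
        orientation = "forward"
    else:
        forms_a = _achievable_concatenations(a)
        forms_b = _achievable_concatenations(b)
        if max_mismatch == 0:
            common = forms_a & forms_b
            identical = bool(common)
        else:
            identical = any(_fuzzy_equal(fa, fb, max_mismatch)
                            for fa in forms_a for fb in forms_b)
        fwd_a = tuple(s for arr in a for s in arr.oriented(False))
        fwd_b = tuple(s for arr in b for s in arr.oriented(False))
        orientation = ("forward" if not identical or fwd_a == fwd_b
                       else "reverse-complement")

    split_resolved = identical and len(a) != len(b)
    return ArrayMatchReport(
        verdict="identical" if identical else "different",
        shared_spacers=shared, only_a=only_a, only_b=only_b,
        orientation_used=orientation, split_resolved=split_resolved)


def _fuzzy_equal(a: tuple[str, ...], b: tuple[str, ...],
                 max_mismatch: int) -> bool:
    if len(a) != len(b):
        return False
    for sa, sb in zip(a, b):
        if len(sa) != len(sb):
            return False
        if sum(x != y for x, y in zip(sa, sb)) > max_mismatch:
            return False
    return True
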