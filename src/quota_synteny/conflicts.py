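"""1D-overlap detection: which blocks compete for the same axis positions.

After chaining, blocks that are distinct on the 2D dot plot may still
overlap in their projections onto a single genome axis; the projection
depth at any position should not exceed that genome's expected number of
syntenic regions.  This module finds, per axis and chromosome, the maximal
sets of mutually overlapping block projections — these become the
inequality constraints of the screening program.

Chaining over-extends block boundaries by up to ``Dm``, so slight overlaps
are not real competition.  The tolerance ``Nm`` handles this: every block
interval is shrunk by ``Nm`` at both ends before overlap detection, so two
blocks conflict only when their original projections overlap by more than
``2*Nm``.  An interval too short to shrink collapses to a single point at
its midpoint and still participates there.

Overlap is computed on closed integer intervals (touching counts) with a
single sweep per chromosome; the sets emitted are exactly the maximal
cliques of the interval-overlap graph, so no retained set is a subset of
another.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .chaining import SyntenyBlock
from .errors import InvalidInputError

DEFAULT_NM = 10  # overlap tolerance, gene ranks


@dataclass(frozen=True)
class ConstraintSet:
    """A maximal set of blocks whose shrunken projections share a position."""

    axis: str  # 'x' or 'y'
    chrom: str
    blocks: frozenset[int]

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise InvalidInputError(f"axis must be 'x' or 'y', got {self.axis!r}")
        if len(self.blocks) < 2:
            raise InvalidInputError("a constraint set needs at least 2 blocks")


def shrink_interval(start: int, stop: int, nm: int) -> tuple[int, int]:
    """Shrink half-open ``[start, stop)`` by ``nm`` per side; return closed bounds.

    Returns the closed interval ``(lo, hi)`` remaining after contraction.
    When the interval is too short (length <= 2*nm) it collapses to the
    degenerate point ``floor((start + stop) / 2)``.
    """
    if nm < 0:
        raise InvalidInputError("nm must be >= 0")
    lo, hi = start + nm, stop - 1 - nm
    if lo > hi:
        mid = (start + stop) // 2
        return mid, mid
    return lo, hi


def shrink_intervals(
    blocks: Sequence[SyntenyBlock], nm: int
) -> dict[str, list[tuple[int, int, int]]]:
    """Shrunken projections per axis: ``{'x'|'y': [(lo, hi, block_id), ...]}``."""
    out: dict[str, list[tuple[int, int, int]]] = {"x": [], "y": []}
    for b in blocks:
        lo, hi = shrink_interval(b.x_start, b.x_stop, nm)
        out["x"].append((lo, hi, b.block_id))
        lo, hi = shrink_interval(b.y_start, b.y_stop, nm)
        out["y"].append((lo, hi, b.block_id))
    return out


def _maximal_overlap_sets(intervals: list[tuple[int, int, int]]) -> list[frozenset[int]]:
    """Maximal cliques of a closed-interval overlap graph via one sweep.

    Events are processed in coordinate order, starts before ends at equal
    coordinates so that touching intervals count as overlapping.  The
    active set just before an end event — provided some interval started
    since the last emission — is a maximal clique; every maximal clique
    arises this way exactly once (up to duplicates from identical sets,
    which are removed).
    """
    events: list[tuple[int, int, int]] = []
    for lo, hi, bid in intervals:
        events.append((lo, 0, bid))
        events.append((hi, 1, bid))
    events.sort()
    active: set[int] = set()
    fresh = False
    seen: set[frozenset[int]] = set()
    out: list[frozenset[int]] = []
    for _, kind, bid in events:
        if kind == 0:
            active.add(bid)
            fresh = True
        else:
            if fresh and len(active) >= 2:
                clique = frozenset(active)
                if clique not in seen:
                    seen.add(clique)
                    out.append(clique)
            fresh = False
            active.discard(bid)
    return out


def build_constraints(blocks: Sequence[SyntenyBlock], nm: int = DEFAULT_NM) -> list[ConstraintSet]:
    """Find all maximal sets of 1D-overlapping blocks on both axes.

    Blocks are grouped per chromosome on each axis (projections on
    different chromosomes never interact), their intervals shrunk by
    ``nm``, and maximal overlapping sets of size >= 2 are emitted.  The
    result is deterministic: sorted by (axis, chrom, member ids).
    """
    constraints: list[ConstraintSet] = []
    for axis in ("x", "y"):
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for b in blocks:
            if axis == "x":
                chrom, lo_hi = b.x_chrom, shrink_interval(b.x_start, b.x_stop, nm)
            else:
                chrom, lo_hi = b.y_chrom, shrink_interval(b.y_start, b.y_stop, nm)
            per_chrom.setdefault(chrom, []).append((lo_hi[0], lo_hi[1], b.block_id))
        for chrom in sorted(per_chrom):
            for clique in _maximal_overlap_sets(per_chrom[chrom]):
                constraints.append(ConstraintSet(axis=axis, chrom=chrom, blocks=clique))
    constraints.sort(key=lambda c: (c.axis, c.chrom, sorted(c.blocks)))
    return constraints


def write_constraints(constraints: Iterable[ConstraintSet], path: str | Path) -> None:
    """Dump constraint sets as text, one per line: ``axis:chrom: id id id``."""
    with open(path, "w") as handle:
        for c in constraints:
            ids = " ".join(str(i) for i in sorted(c.blocks))
            handle.write(f"{c.axis}:{c.chrom}: {ids}\n")
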