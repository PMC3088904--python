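"""Chaining anchors into synteny blocks by rectangle merging.

Anchors that are close on the dot plot belong to the same syntenic segment.
Rather than collinear chaining with gap penalties, closeness is resolved
geometrically: every anchor rectangle is expanded by the chaining distance
``Dm`` on all four sides, which turns "adjacent within Dm" into "overlapping",
and connected components of overlapping expanded rectangles — found with a
plane-sweep over x — become the synteny blocks.  A block's intervals bound
its member anchors at their *original* (unexpanded) extents and its weight
is the sum of member anchor weights.

Blocks deliberately ignore orientation at this stage: a component mixing
ascending and descending anchor runs stays one block.  Each block is then
given an orientation sign by comparing its first and last anchors along x
(:func:`assign_sign`), which is what downstream rearrangement export uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .anchors import Anchor
from .errors import InvalidInputError, ParseError

logger = logging.getLogger(__name__)

DEFAULT_DM = 20  # chaining distance, gene ranks


@dataclass
class SyntenyBlock:
    """A chained cluster of anchors with bounding intervals on both axes."""

    block_id: int
    x_chrom: str
    x_start: int
    x_stop: int
    y_chrom: str
    y_start: int
    y_stop: int
    weight: float
    sign: str = "?"
    anchors: tuple[Anchor, ...] = ()

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def assign_sign(block: SyntenyBlock) -> SyntenyBlock:
    """Set the block's orientation sign from its endpoint anchors (in place).

    The sign is '+' when the anchor with minimal x sits at or below (in y)
    the anchor with maximal x — i.e. the block ascends on the dot plot — and
    '-' otherwise.  Interior anchors are ignored, so a mostly-ascending
    block with local noise still reads '+'.  Single-anchor blocks are '+'.
    """
    if not block.anchors:
        raise InvalidInputError(f"block {block.block_id} has no anchors; cannot assign a sign")
    first = min(block.anchors, key=lambda a: (a.x_start, a.x_stop, a.y_start))
    last = max(block.anchors, key=lambda a: (a.x_start, a.x_stop, a.y_start))
    block.sign = "+" if first.y_start <= last.y_start else "-"
    return block


def _components_sweep(lo_x, hi_x, lo_y, hi_y) -> np.ndarray:
    """Connected components of rectangles under closed overlap-or-touch.

    Rectangles are given as closed coordinate bounds.  A sweep over x visits
    rectangles in lo_x order; each rectangle is tested against the ones
    whose x-range is still active (lo_x[j] <= hi_x[i] for j after i), and
    y-overlap produces an edge.  Component labels come from scipy's
    csgraph on the resulting edge list.
    """
    n = len(lo_x)
    order = np.lexsort((lo_y, lo_x))
    lo_x, hi_x = lo_x[order], hi_x[order]
    lo_y, hi_y = lo_y[order], hi_y[order]
    edges_i: list[np.ndarray] = []
    edges_j: list[np.ndarray] = []
    for i in range(n):
        j_hi = np.searchsorted(lo_x, hi_x[i], side="right")
        if j_hi <= i + 1:
            continue
        window = slice(i + 1, j_hi)
        hit = (lo_y[window] <= hi_y[i]) & (lo_y[i] <= hi_y[window])
        js = np.nonzero(hit)[0]
        if js.size:
            js = js + (i + 1)
            edges_i.append(np.full(js.size, i))
            edges_j.append(js)
    if edges_i:
        ii = np.concatenate(edges_i)
        jj = np.concatenate(edges_j)
        graph = coo_matrix((np.ones(ii.size), (ii, jj)), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    _, labels = connected_components(graph, directed=False)
    out = np.empty(n, dtype=labels.dtype)
    out[order] = labels
    return out


def chain_anchors(
    anchors: Iterable[Anchor], dm: int = DEFAULT_DM, min_anchors: int = 1
) -> list[SyntenyBlock]:
    """Merge anchors within distance ``dm`` into synteny blocks.

    Anchors are partitioned by chromosome pair; within each pair, anchor
    rectangles expanded by ``dm`` on all sides are grouped into connected
    components of (closed) overlap, and each component becomes one block.
    Every input anchor belongs to exactly one block.  Blocks with fewer
    than ``min_anchors`` members are dropped (default keeps all).  Block
    ids are assigned in sorted (x_chrom, x_start, y_chrom, y_start) order
    for determinism.
    """
    if dm < 0:
        raise InvalidInputError("dm must be >= 0")
    anchors = list(anchors)
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.x_chrom, a.y_chrom), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (x_chrom, y_chrom) in sorted(by_pair):
        group = by_pair[(x_chrom, y_chrom)]
        xs = np.array([a.x_start for a in group])
        xe = np.array([a.x_stop for a in group])
        ys = np.array([a.y_start for a in group])
        ye = np.array([a.y_stop for a in group])
        # closed bounds of the expanded rectangles; an empty interval
        # (start == stop) behaves as a point
        lo_x, hi_x = xs - dm, np.maximum(xe - 1, xs) + dm
        lo_y, hi_y = ys - dm, np.maximum(ye - 1, ys) + dm
        labels = _components_sweep(lo_x, hi_x, lo_y, hi_y)
        members: dict[int, list[Anchor]] = {}
        for a, lab in zip(group, labels):
            members.setdefault(int(lab), []).append(a)
        for comp in members.values():
            if len(comp) < min_anchors:
                continue
            block = SyntenyBlock(
                block_id=-1,
                x_chrom=x_chrom,
                x_start=min(a.x_start for a in comp),
                x_stop=max(a.x_stop for a in comp),
                y_chrom=y_chrom,
                y_start=min(a.y_start for a in comp),
                y_stop=max(a.y_stop for a in comp),
                weight=float(sum(a.weight for a in comp)),
                anchors=tuple(sorted(comp, key=lambda a: (a.x_start, a.x_stop, a.y_start, a.y_stop))),
            )
            blocks.append(assign_sign(block))

    blocks.sort(key=lambda b: (b.x_chrom, b.x_start, b.y_chrom, b.y_start, b.y_stop))
    for i, b in enumerate(blocks):
        b.block_id = i
    logger.info("chained %d anchors into %d blocks (dm=%d)", len(anchors), len(blocks), dm)
    return blocks


BLOCK_TSV_HEADER = (
    "#block_id\tx_chrom\tx_start\tx_stop\ty_chrom\ty_start\ty_stop\tweight\tsign\tn_anchors"
)


def write_blocks(
    blocks: Sequence[SyntenyBlock],
    path: str | Path,
    anchors_path: Optional[str | Path] = None,
) -> None:
    """Write blocks to TSV; optionally a companion anchors-with-block-id file."""
    with open(path, "w") as handle:
        handle.write(BLOCK_TSV_HEADER + "\n")
        for b in blocks:
            handle.write(
                f"{b.block_id}\t{b.x_chrom}\t{b.x_start}\t{b.x_stop}\t{b.y_chrom}\t"
                f"{b.y_start}\t{b.y_stop}\t{b.weight:g}\t{b.sign}\t{b.n_anchors}\n"
            )
    if anchors_path is not None:
        with open(anchors_path, "w") as handle:
            handle.write("#block_id\tx_chrom\tx_start\tx_stop\ty_chrom\ty_start\ty_stop\tweight\n")
            for b in blocks:
                for a in b.anchors:
                    handle.write(
                        f"{b.block_id}\t{a.x_chrom}\t{a.x_start}\t{a.x_stop}\t"
                        f"{a.y_chrom}\t{a.y_start}\t{a.y_stop}\t{a.weight:g}\n"
                    )


def read_blocks(
    path: str | Path, anchors_path: Optional[str | Path] = None
) -> list[SyntenyBlock]:
    """Read a blocks TSV (and optionally its companion anchors file)."""
    anchors_by_block: dict[int, list[Anchor]] = {}
    if anchors_path is not None:
        with open(anchors_path) as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 8:
                    raise ParseError(f"{anchors_path}: line {lineno}: expected 8 columns")
                anchors_by_block.setdefault(int(f[0]), []).append(
                    Anchor(f[1], int(f[2]), int(f[3]), f[4], int(f[5]), int(f[6]), float(f[7]))
                )
    blocks: list[SyntenyBlock] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ParseError(f"{path}: line {lineno}: expected 10 tab-separated columns")
            try:
                bid = int(f[0])
                blocks.append(
                    SyntenyBlock(
                        block_id=bid,
                        x_chrom=f[1], x_start=int(f[2]), x_stop=int(f[3]),
                        y_chrom=f[4], y_start=int(f[5]), y_stop=int(f[6]),
                        weight=float(f[7]), sign=f[8],
                        anchors=tuple(anchors_by_block.get(bid, ())),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return blocks
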