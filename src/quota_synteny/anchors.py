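"""Homology anchors: parsing, scoring and pre-filtering.

An *anchor* is one putative homologous gene/marker pair between the two
genomes under comparison: a (possibly degenerate) rectangle on the syntenic
dot plot, carrying a similarity-derived weight.  Anchors are the raw input
to chaining; before chaining they are de-duplicated (isoform hits collapsed
to genes, local tandem duplicates reduced to their best representative).

Coordinate conventions
----------------------
All intervals are 0-based, half-open ``[start, stop)`` and expressed either
in gene ranks (the default: each gene's index along its chromosome) or in
base pairs.  A point anchor at rank ``r`` is stored as ``[r, r + 1)``.
Input formats are converted on read and back on write.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import InvalidInputError, ParseError

logger = logging.getLogger(__name__)

#: Upper bound of the E-value derived anchor score.
MAX_ANCHOR_SCORE = 50.0


@dataclass(frozen=True)
class GenomeLayout:
    """Axis layout of one genome: ordered chromosomes with their lengths.

    Parameters
    ----------
    genome_id : str
        Label for the genome (used in reports and GRIMM headers).
    chromosomes : sequence of (str, int)
        Ordered ``(chrom_id, length)`` pairs; lengths are in
        ``coordinate_unit`` units and must be positive.
    coordinate_unit : {"gene_rank", "base_pair"}
        Unit of all coordinates on this axis.  Both genomes in a comparison
        must use the same unit.
    """

    genome_id: str
    chromosomes: tuple[tuple[str, int], ...]
    coordinate_unit: str = "gene_rank"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(tuple(c) for c in self.chromosomes))
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvalidInputError(f"duplicate chromosome ids in layout {self.genome_id!r}")
        for chrom, length in self.chromosomes:
            if length <= 0:
                raise InvalidInputError(
                    f"chromosome {chrom!r} in layout {self.genome_id!r} has non-positive length {length}"
                )
        if self.coordinate_unit not in ("gene_rank", "base_pair"):
            raise InvalidInputError(f"unknown coordinate unit {self.coordinate_unit!r}")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        for c, length in self.chromosomes:
            if c == chrom:
                return length
        raise KeyError(chrom)

    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def chrom_offset(self, chrom: str) -> int:
        """Cumulative start of ``chrom`` when chromosomes are laid end to end."""
        offset = 0
        for c, length in self.chromosomes:
            if c == chrom:
                return offset
            offset += length
        raise KeyError(chrom)


@dataclass(frozen=True)
class Anchor:
    """One homologous pair: a weighted rectangle on the dot plot."""

    x_chrom: str
    x_start: int
    x_stop: int
    y_chrom: str
    y_start: int
    y_stop: int
    weight: float
    x_gene: Optional[str] = None
    y_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.x_start > self.x_stop or self.y_start > self.y_stop:
            raise InvalidInputError(
                f"anchor has inverted interval: x=[{self.x_start},{self.x_stop}) "
                f"y=[{self.y_start},{self.y_stop})"
            )
        if self.weight < 0:
            raise InvalidInputError(f"anchor weight must be non-negative, got {self.weight}")


def point_anchor(x_chrom: str, x: int, y_chrom: str, y: int, weight: float = 1.0,
                 x_gene: Optional[str] = None, y_gene: Optional[str] = None) -> Anchor:
    """A degenerate single-position anchor, stored half-open as ``[p, p+1)``."""
    return Anchor(x_chrom, x, x + 1, y_chrom, y, y + 1, weight, x_gene, y_gene)


def score_from_evalue(evalue: float) -> float:
    """Transform a BLAST E-value into an anchor score in ``[0, 50]``.

    The score is ``min(50, -log10(E))``, clamped below at 0 so that
    E-values above 1 contribute nothing; an E-value of exactly 0 maps to
    the cap.  Base 10 makes ``E = 1e-50`` hit the cap exactly.
    """
    if evalue < 0:
        raise InvalidInputError(f"E-value must be non-negative, got {evalue}")
    if evalue == 0:
        return MAX_ANCHOR_SCORE
    return max(0.0, min(MAX_ANCHOR_SCORE, -math.log10(evalue)))


def read_gene_positions(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Read a BED-like gene position table (chrom, start, stop, gene_id).

    Coordinates are 0-based half-open, as in BED.  Returns a mapping
    ``gene_id -> (chrom, start, stop)``; later duplicates override earlier
    ones with a logged warning.
    """
    positions: dict[str, tuple[str, int, int]] = {}
    n_dup = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >= 4 tab-separated columns")
            chrom, start, stop, gene = fields[0], fields[1], fields[2], fields[3]
            try:
                start_i, stop_i = int(start), int(stop)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if gene in positions:
                n_dup += 1
            positions[gene] = (chrom, start_i, stop_i)
    if n_dup:
        logger.warning("%s: %d duplicate gene ids (last occurrence kept)", path, n_dup)
    return positions


def parse_blast_tab(
    path: str | Path,
    gene_positions: Mapping[str, tuple[str, int, int]],
    x_layout: Optional[GenomeLayout] = None,
    y_layout: Optional[GenomeLayout] = None,
) -> list[Anchor]:
    """Read 12-column tabular BLAST (``-m8`` / ``outfmt 6``) into anchors.

    The query is placed on the x axis and the subject on the y axis; anchor
    coordinates come from ``gene_positions`` (not from the HSP coordinates)
    and the weight is ``score_from_evalue`` of column 11.  Hits whose query
    or subject has no known position — or whose chromosome is absent from a
    supplied layout — are dropped, with the count logged.
    """
    anchors: list[Anchor] = []
    n_dropped = 0
    x_chroms = set(x_layout.chrom_names) if x_layout is not None else None
    y_chroms = set(y_layout.chrom_names) if y_layout is not None else None
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}: line {lineno}: expected 12 tab-separated BLAST columns")
            query, subject = fields[0], fields[1]
            try:
                evalue = float(fields[10])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad E-value {fields[10]!r}") from exc
            qpos = gene_positions.get(query)
            spos = gene_positions.get(subject)
            if qpos is None or spos is None:
                n_dropped += 1
                continue
            if (x_chroms is not None and qpos[0] not in x_chroms) or (
                y_chroms is not None and spos[0] not in y_chroms
            ):
                n_dropped += 1
                continue
            anchors.append(
                Anchor(
                    x_chrom=qpos[0], x_start=qpos[1], x_stop=qpos[2],
                    y_chrom=spos[0], y_start=spos[1], y_stop=spos[2],
                    weight=score_from_evalue(evalue),
                    x_gene=query, y_gene=subject,
                )
            )
    if n_dropped:
        logger.warning("%s: dropped %d hits without usable gene positions", path, n_dropped)
    return anchors


def _collapse_local(anchors: list[Anchor], side: str, window: int) -> list[Anchor]:
    """Keep the best anchor per cluster of near-identical partners.

    Groups anchors by the gene on ``side``; among each group's partners that
    lie on one chromosome, chains partners whose successive midpoints are
    within ``window`` of each other and keeps only the highest-weight anchor
    of each chain (ties: smallest partner coordinate).
    """
    by_gene: dict[tuple, list[Anchor]] = {}
    passthrough: list[Anchor] = []
    for a in anchors:
        gene = a.x_gene if side == "x" else a.y_gene
        if gene is None:
            passthrough.append(a)
            continue
        chrom = a.y_chrom if side == "x" else a.x_chrom
        by_gene.setdefault((gene, chrom), []).append(a)

    kept: list[Anchor] = list(passthrough)
    for group in by_gene.values():
        if side == "x":
            group.sort(key=lambda a: (a.y_start + a.y_stop, a.y_start))
            mid = lambda a: (a.y_start + a.y_stop) / 2  # noqa: E731
        else:
            group.sort(key=lambda a: (a.x_start + a.x_stop, a.x_start))
            mid = lambda a: (a.x_start + a.x_stop) / 2  # noqa: E731
        cluster: list[Anchor] = [group[0]]
        for a in group[1:]:
            if mid(a) - mid(cluster[-1]) <= window:
                cluster.append(a)
            else:
                kept.append(max(cluster, key=lambda c: c.weight))
                cluster = [a]
        kept.append(max(cluster, key=lambda c: c.weight))
    return kept


def filter_redundant(
    anchors: Iterable[Anchor],
    isoform_map: Optional[Mapping[str, str]] = None,
    local_dup_window: int = 10,
) -> list[Anchor]:
    """Remove isoform and local-duplicate redundancy before chaining.

    Two reductions are applied, in order:

    1. gene labels are mapped through ``isoform_map`` (transcript -> gene;
       identity when omitted) and anchors are collapsed to one per
       ``(x_gene, y_gene)`` pair, keeping the maximum weight;
    2. among anchors that share one endpoint gene and whose partners lie
       within ``local_dup_window`` of each other on the same chromosome
       (local/tandem duplicates), only the highest-weight representative
       is kept — first on the x side, then on the y side.

    Multi-isoform and tandem matches concentrate weight on a few genes and
    produce chaining artifacts, hence this pre-filter.  Anchors lacking gene
    labels skip both reductions.  The operation is idempotent.
    """
    if local_dup_window < 0:
        raise InvalidInputError("local_dup_window must be >= 0")
    anchors = list(anchors)
    if isoform_map:
        anchors = [
            replace(
                a,
                x_gene=isoform_map.get(a.x_gene, a.x_gene) if a.x_gene else None,
                y_gene=isoform_map.get(a.y_gene, a.y_gene) if a.y_gene else None,
            )
            for a in anchors
        ]
    # collapse to one anchor per gene pair, keeping max weight
    best: dict[tuple[str, str], Anchor] = {}
    unlabeled: list[Anchor] = []
    for a in anchors:
        if a.x_gene is None or a.y_gene is None:
            unlabeled.append(a)
            continue
        key = (a.x_gene, a.y_gene)
        cur = best.get(key)
        if cur is None or a.weight > cur.weight:
            best[key] = a
    deduped = unlabeled + list(best.values())
    deduped = _collapse_local(deduped, "x", local_dup_window)
    deduped = _collapse_local(deduped, "y", local_dup_window)
    deduped.sort(key=lambda a: (a.x_chrom, a.x_start, a.y_chrom, a.y_start, -a.weight))
    return deduped


ANCHOR_TSV_HEADER = "#x_chrom\tx_start\tx_stop\ty_chrom\ty_start\ty_stop\tweight"


def write_anchors(anchors: Sequence[Anchor], path: str | Path) -> None:
    """Write anchors to the native 7-column TSV (0-based, half-open)."""
    with open(path, "w") as handle:
        handle.write(ANCHOR_TSV_HEADER + "\n")
        for a in anchors:
            handle.write(
                f"{a.x_chrom}\t{a.x_start}\t{a.x_stop}\t{a.y_chrom}\t{a.y_start}\t{a.y_stop}\t{a.weight:g}\n"
            )


def read_anchors(path: str | Path) -> list[Anchor]:
    """Read the native anchor TSV; a leading '#' header line is optional.

    An optional 8th numeric column (e.g. a precomputed Ks value used for dot
    plot coloring) is tolerated and ignored here; see
    :func:`quota_synteny.plotting.read_anchor_colors`.
    """
    anchors: list[Anchor] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}: line {lineno}: expected >= 7 tab-separated columns")
            try:
                anchors.append(
                    Anchor(
                        x_chrom=fields[0], x_start=int(fields[1]), x_stop=int(fields[2]),
                        y_chrom=fields[3], y_start=int(fields[4]), y_stop=int(fields[5]),
                        weight=float(fields[6]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return anchors
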