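"""Dot-plot rendering of anchors and screened synteny blocks."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .anchors import Anchor, GenomeLayout
from .chaining import SyntenyBlock
from .errors import InvalidInputError, ParseError


def read_anchor_colors(path: str | Path) -> Optional[np.ndarray]:
    """Read the optional per-anchor color column (8th) of an anchor TSV.

    Returns one float per data line, or None when no line has an 8th
    column.  Typical use: precomputed Ks values for age-colored plots
    (never computed here).  Lines lacking the column yield NaN.
    """
    values: list[float] = []
    any_color = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 8 and fields[7] != "":
                try:
                    values.append(float(fields[7]))
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: bad color value {fields[7]!r}") from exc
                any_color = True
            else:
                values.append(float("nan"))
    return np.array(values) if any_color else None


def infer_layout(anchors: Sequence[Anchor], axis: str, genome_id: str) -> GenomeLayout:
    """Minimal axis layout covering the anchors (chrom length = max stop)."""
    if axis not in ("x", "y"):
        raise InvalidInputError("axis must be 'x' or 'y'")
    lengths: dict[str, int] = {}
    for a in anchors:
        chrom = a.x_chrom if axis == "x" else a.y_chrom
        stop = a.x_stop if axis == "x" else a.y_stop
        lengths[chrom] = max(lengths.get(chrom, 1), stop, 1)
    return GenomeLayout(genome_id, tuple(sorted(lengths.items())))


def _axis_position(layout: GenomeLayout, chrom: str, start: int, stop: int) -> float:
    try:
        offset = layout.chrom_offset(chrom)
    except KeyError:
        raise InvalidInputError(
            f"anchor chromosome {chrom!r} is not in layout {layout.genome_id!r}"
        ) from None
    return offset + (start + stop) / 2


def render_dotplot(
    anchors: Sequence[Anchor],
    blocks: Sequence[SyntenyBlock] = (),
    selected: Optional[frozenset[int] | set[int]] = None,
    x_layout: Optional[GenomeLayout] = None,
    y_layout: Optional[GenomeLayout] = None,
    out_path: str | Path = "dotplot.png",
    colors: Optional[np.ndarray] = None,
    title: Optional[str] = None,
) -> Path:
    """Render the syntenic dot plot to ``out_path`` (format by extension).

    All anchors are drawn in gray; anchors belonging to selected blocks are
    highlighted (colored by ``colors`` when given, with a colorbar).
    Chromosome boundaries are drawn as grid lines.  Layouts are inferred
    from the anchors when not supplied.
    """
    anchors = list(anchors)
    if x_layout is None:
        x_layout = infer_layout(anchors, "x", "genome_x")
    if y_layout is None:
        y_layout = infer_layout(anchors, "y", "genome_y")
    selected = set(selected) if selected is not None else {b.block_id for b in blocks}

    xs = np.array([_axis_position(x_layout, a.x_chrom, a.x_start, a.x_stop) for a in anchors])
    ys = np.array([_axis_position(y_layout, a.y_chrom, a.y_start, a.y_stop) for a in anchors])
    in_selected = np.zeros(len(anchors), dtype=bool)
    selected_points = {
        (a.x_chrom, a.x_start, a.y_chrom, a.y_start)
        for b in blocks
        if b.block_id in selected
        for a in b.anchors
    }
    for i, a in enumerate(anchors):
        if (a.x_chrom, a.x_start, a.y_chrom, a.y_start) in selected_points:
            in_selected[i] = True

    fig, ax = plt.subplots(figsize=(7, 7))
    if len(anchors):
        ax.scatter(xs[~in_selected], ys[~in_selected], s=2, c="0.75", linewidths=0, label="anchors")
        if colors is not None:
            sc = ax.scatter(
                xs[in_selected], ys[in_selected], s=4,
                c=np.asarray(colors)[in_selected], cmap="viridis", linewidths=0,
            )
            fig.colorbar(sc, ax=ax, label="anchor color value")
        else:
            ax.scatter(xs[in_selected], ys[in_selected], s=4, c="crimson", linewidths=0,
                       label="selected")
    offset = 0
    for _, length in x_layout.chromosomes:
        offset += length
        ax.axvline(offset, color="0.85", lw=0.5, zorder=0)
    offset = 0
    for _, length in y_layout.chromosomes:
        offset += length
        ax.axhline(offset, color="0.85", lw=0.5, zorder=0)
    ax.set_xlim(0, max(1, x_layout.total_length()))
    ax.set_ylim(0, max(1, y_layout.total_length()))
    ax.set_xlabel(f"{x_layout.genome_id} ({x_layout.coordinate_unit})")
    ax.set_ylabel(f"{y_layout.genome_id} ({y_layout.coordinate_unit})")
    if title:
        ax.set_title(title)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
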