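"""Signed-permutation encoding of 1:1-screened blocks for GRIMM.

After screening with quota 1:1 the retained blocks do not overlap in their
1D projections, so each genome can be written as an ordered sequence of
signed block identifiers — the input format of rearrangement tools in the
GRIMM/MGR family.  Blocks are numbered 1..K along the x genome; a block's
sign records whether its two regions lie in the same ('+') or opposite
('-') orientation, read off its endpoint anchors during chaining.

Only the encoding and the file format live here; computing rearrangement
scenarios is GRIMM's job.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .anchors import GenomeLayout
from .chaining import SyntenyBlock
from .errors import ParseError, UnsupportedOperationError


@dataclass(frozen=True)
class SignedPermutation:
    """Block order of one genome: signed integers per chromosome."""

    genome_id: str
    chromosomes: tuple[tuple[int, ...], ...]

    def flat(self) -> tuple[int, ...]:
        return tuple(v for chrom in self.chromosomes for v in chrom)


def _check_non_overlapping(blocks: Sequence[SyntenyBlock]) -> None:
    for axis in ("x", "y"):
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for b in blocks:
            if axis == "x":
                per_chrom.setdefault(b.x_chrom, []).append((b.x_start, b.x_stop, b.block_id))
            else:
                per_chrom.setdefault(b.y_chrom, []).append((b.y_start, b.y_stop, b.block_id))
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            for (s1, e1, i1), (s2, e2, i2) in zip(ivs, ivs[1:]):
                if s2 < e1:  # strict interior overlap; touching is fine
                    raise UnsupportedOperationError(
                        "rearrangement analysis for ratios different than 1:1 is currently "
                        f"not supported: blocks {i1} and {i2} overlap on {axis}:{chrom}"
                    )


def _chrom_order(chroms: set[str], layout: Optional[GenomeLayout]) -> list[str]:
    if layout is None:
        return sorted(chroms)
    ordered = [c for c in layout.chrom_names if c in chroms]
    ordered += sorted(chroms - set(ordered))
    return ordered


def encode_permutations(
    blocks: Sequence[SyntenyBlock],
    x_layout: Optional[GenomeLayout] = None,
    y_layout: Optional[GenomeLayout] = None,
) -> tuple[SignedPermutation, SignedPermutation]:
    """Encode 1:1-screened blocks as signed permutations of both genomes.

    Blocks are numbered 1..K by x-genome order (chromosome, then start),
    so the x permutation is the identity with all '+'; the y permutation
    lists the same identifiers in y-genome order, negated for blocks whose
    regions run in opposite orientation.  Raises
    :class:`UnsupportedOperationError` if any two blocks overlap in a 1D
    projection (i.e. the input was not screened at quota 1:1 with Nm=0).
    """
    blocks = list(blocks)
    for b in blocks:
        if b.sign not in ("+", "-"):
            raise UnsupportedOperationError(
                f"block {b.block_id} has undetermined sign; run sign assignment first"
            )
    _check_non_overlapping(blocks)
    x_id = x_layout.genome_id if x_layout else "genome_x"
    y_id = y_layout.genome_id if y_layout else "genome_y"
    if not blocks:
        return SignedPermutation(x_id, ()), SignedPermutation(y_id, ())

    x_chroms = _chrom_order({b.x_chrom for b in blocks}, x_layout)
    x_rank = {c: i for i, c in enumerate(x_chroms)}
    x_sorted = sorted(blocks, key=lambda b: (x_rank[b.x_chrom], b.x_start, b.x_stop))
    number = {b.block_id: k for k, b in enumerate(x_sorted, 1)}

    x_perm = tuple(
        tuple(number[b.block_id] for b in x_sorted if b.x_chrom == chrom) for chrom in x_chroms
    )
    y_chroms = _chrom_order({b.y_chrom for b in blocks}, y_layout)
    y_rank = {c: i for i, c in enumerate(y_chroms)}
    y_sorted = sorted(blocks, key=lambda b: (y_rank[b.y_chrom], b.y_start, b.y_stop))
    y_perm = tuple(
        tuple(
            number[b.block_id] if b.sign == "+" else -number[b.block_id]
            for b in y_sorted
            if b.y_chrom == chrom
        )
        for chrom in y_chroms
    )
    return SignedPermutation(x_id, x_perm), SignedPermutation(y_id, y_perm)


def write_grimm(perms: Sequence[SignedPermutation], path: str | Path) -> None:
    """Write permutations in GRIMM genome format.

    One block per genome: a ``>genome_id`` header line, then each
    chromosome as space-separated signed integers terminated by ``$``.
    """
    with open(path, "w") as handle:
        for perm in perms:
            handle.write(f">{perm.genome_id}\n")
            for chrom in perm.chromosomes:
                signed = " ".join(f"{v:+d}".replace("+", "") if v > 0 else str(v) for v in chrom)
                handle.write(f"{signed} $\n" if signed else "$\n")


def read_grimm(path: str | Path) -> list[SignedPermutation]:
    """Parse a GRIMM genome file back into signed permutations."""
    perms: list[SignedPermutation] = []
    genome_id: Optional[str] = None
    chroms: list[tuple[int, ...]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if genome_id is not None:
                    perms.append(SignedPermutation(genome_id, tuple(chroms)))
                genome_id = line[1:].strip()
                chroms = []
                continue
            if genome_id is None:
                raise ParseError(f"{path}: line {lineno}: sequence before any '>' header")
            tokens = line.split()
            if tokens and tokens[-1] in ("$", ";"):
                tokens = tokens[:-1]
            try:
                chroms.append(tuple(int(t) for t in tokens))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad integer token") from exc
    if genome_id is not None:
        perms.append(SignedPermutation(genome_id, tuple(chroms)))
    return perms
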