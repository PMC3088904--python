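"""Rectangle-merge chaining: examples, partition property, oracle equivalence."""

import numpy as np
import pytest

from quota_synteny.anchors import Anchor, point_anchor
from quota_synteny.chaining import (
    SyntenyBlock,
    assign_sign,
    chain_anchors,
    read_blocks,
    write_blocks,
)
from quota_synteny.errors import InvalidInputError


# --- independent oracle: quadratic pairwise overlap + union-find -------------


def _closed_expanded(a: Anchor, dm: int):
    return (
        a.x_start - dm, max(a.x_stop - 1, a.x_start) + dm,
        a.y_start - dm, max(a.y_stop - 1, a.y_start) + dm,
    )


def _rect_overlap(r1, r2) -> bool:
    return r1[0] <= r2[1] and r2[0] <= r1[1] and r1[2] <= r2[3] and r2[2] <= r1[3]


def brute_force_partition(anchors, dm):
    """Connected components via all-pairs overlap tests and union-find."""
    parent = list(range(len(anchors)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    rects = [_closed_expanded(a, dm) for a in anchors]
    for i in range(len(anchors)):
        for j in range(i + 1, len(anchors)):
            if (anchors[i].x_chrom, anchors[i].y_chrom) != (anchors[j].x_chrom, anchors[j].y_chrom):
                continue
            if _rect_overlap(rects[i], rects[j]):
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(len(anchors)):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def _partition_from_blocks(anchors, blocks):
    # anchors are generated distinct in these tests, so coordinate identity suffices
    coord = lambda a: (a.x_chrom, a.x_start, a.x_stop, a.y_chrom, a.y_start, a.y_stop)  # noqa: E731
    lookup = {coord(a): i for i, a in enumerate(anchors)}
    return {frozenset(lookup[coord(a)] for a in b.anchors) for b in blocks}


def _random_anchors(rng, n, span=150, max_len=8, n_chrom=1):
    seen = set()
    anchors = []
    while len(anchors) < n:
        xs = int(rng.integers(0, span))
        ys = int(rng.integers(0, span))
        xl = int(rng.integers(0, max_len))
        yl = int(rng.integers(0, max_len))
        cx = f"x{rng.integers(n_chrom)}"
        cy = f"y{rng.integers(n_chrom)}"
        key = (cx, xs, xs + xl, cy, ys, ys + yl)
        if key in seen:
            continue
        seen.add(key)
        anchors.append(Anchor(cx, xs, xs + xl, cy, ys, ys + yl, float(rng.integers(1, 10))))
    return anchors


class TestChainAnchors:
    def test_single_anchor_single_block(self):
        blocks = chain_anchors([point_anchor("c", 5, "d", 7, 3.0)], dm=10)
        assert len(blocks) == 1
        assert blocks[0].weight == 3.0
        assert (blocks[0].x_start, blocks[0].x_stop) == (5, 6)

    def test_two_points_merge_when_expansion_bridges_gap(self):
        anchors = [point_anchor("c", 0, "d", 0), point_anchor("c", 15, "d", 15)]
        blocks = chain_anchors(anchors, dm=10)
        assert len(blocks) == 1
        assert blocks[0].weight == 2.0

    def test_two_points_stay_apart_below_merge_distance(self):
        anchors = [point_anchor("c", 0, "d", 0), point_anchor("c", 15, "d", 15)]
        assert len(chain_anchors(anchors, dm=5)) == 2

    def test_partition_conserves_anchor_multiset(self):
        rng = np.random.default_rng(3)
        anchors = _random_anchors(rng, 120, n_chrom=2)
        blocks = chain_anchors(anchors, dm=12)
        chained = sorted(
            (a.x_chrom, a.x_start, a.y_chrom, a.y_start) for b in blocks for a in b.anchors
        )
        assert chained == sorted((a.x_chrom, a.x_start, a.y_chrom, a.y_start) for a in anchors)
        for b in blocks:
            assert b.x_start == min(a.x_start for a in b.anchors)
            assert b.x_stop == max(a.x_stop for a in b.anchors)
            assert b.weight == pytest.approx(sum(a.weight for a in b.anchors))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_union_find(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        dm = int(rng.integers(0, 15))
        anchors = _random_anchors(rng, n, n_chrom=2)
        blocks = chain_anchors(anchors, dm=dm)
        assert _partition_from_blocks(anchors, blocks) == brute_force_partition(anchors, dm)

    def test_block_count_non_increasing_in_dm(self):
        rng = np.random.default_rng(11)
        anchors = _random_anchors(rng, 100)
        counts = [len(chain_anchors(anchors, dm=dm)) for dm in (0, 2, 5, 10, 20, 40)]
        assert counts == sorted(counts, reverse=True)

    def test_dm_zero_merges_only_overlapping_rectangles(self):
        apart = [point_anchor("c", 0, "d", 0), point_anchor("c", 2, "d", 2)]
        assert len(chain_anchors(apart, dm=0)) == 2
        sharing = [Anchor("c", 0, 3, "d", 0, 3, 1.0), Anchor("c", 2, 5, "d", 2, 5, 1.0)]
        assert len(chain_anchors(sharing, dm=0)) == 1
        # adjacent rank runs (no shared rank) need dm >= 1 to merge
        adjacent = [Anchor("c", 0, 3, "d", 0, 3, 1.0), Anchor("c", 3, 5, "d", 3, 5, 1.0)]
        assert len(chain_anchors(adjacent, dm=0)) == 2
        assert len(chain_anchors(adjacent, dm=1)) == 1

    def test_expanded_rectangles_touching_exactly_do_merge(self):
        # points 14 apart: expansion by 7 makes the rectangles meet at one point
        anchors = [point_anchor("c", 0, "d", 0), point_anchor("c", 14, "d", 14)]
        assert len(chain_anchors(anchors, dm=7)) == 1
        assert len(chain_anchors(anchors, dm=6)) == 2

    def test_min_anchors_filter(self):
        anchors = [point_anchor("c", 0, "d", 0), point_anchor("c", 1, "d", 1),
                   point_anchor("c", 500, "d", 500)]
        blocks = chain_anchors(anchors, dm=5, min_anchors=2)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 2

    def test_empty_input(self):
        assert chain_anchors([], dm=10) == []


class TestAssignSign:
    def _block(self, points):
        anchors = tuple(point_anchor("c", x, "d", y) for x, y in points)
        return SyntenyBlock(0, "c", 0, 1, "d", 0, 1, 1.0, anchors=anchors)

    @pytest.mark.parametrize(
        "points,sign",
        [
            ([(0, 0), (10, 10)], "+"),
            ([(0, 10), (10, 0)], "-"),
            ([(0, 5), (3, 2), (10, 9)], "+"),  # endpoints ascend despite interior noise
            ([(4, 4)], "+"),  # single anchor
        ],
    )
    def test_endpoint_rule(self, points, sign):
        assert assign_sign(self._block(points)).sign == sign

    def test_empty_block_rejected(self):
        with pytest.raises(InvalidInputError):
            assign_sign(self._block([]))


class TestBlockIO:
    def test_round_trip_with_companion_anchors(self, tmp_path):
        rng = np.random.default_rng(5)
        blocks = chain_anchors(_random_anchors(rng, 40), dm=8)
        write_blocks(blocks, tmp_path / "b.tsv", tmp_path / "b.anchors.tsv")
        back = read_blocks(tmp_path / "b.tsv", tmp_path / "b.anchors.tsv")
        assert len(back) == len(blocks)
        for orig, rb in zip(blocks, back):
            assert (orig.block_id, orig.x_chrom, orig.x_start, orig.x_stop) == (
                rb.block_id, rb.x_chrom, rb.x_start, rb.x_stop)
            assert orig.sign == rb.sign
            assert orig.n_anchors == rb.n_anchors
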