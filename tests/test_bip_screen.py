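"""Screening program: construction, solver correctness, quota statistics."""

import numpy as np
import pytest

from quota_synteny.anchors import GenomeLayout
from quota_synteny.bip_screen import (
    BipInstance,
    QuotaRatio,
    build_instance,
    export_lp,
    quota_stats,
    screen_blocks,
    solve,
    verify_quota,
)
from quota_synteny.chaining import SyntenyBlock
from quota_synteny.conflicts import ConstraintSet, build_constraints
from quota_synteny.errors import ConsistencyError, InvalidInputError


def _block(bid, xs, xe, ys, ye, weight=1.0):
    return SyntenyBlock(bid, "c", xs, xe, "d", ys, ye, weight)


def brute_force_optimum(instance: BipInstance) -> float:
    """Exhaustive enumeration of all 2^n selections (vectorized bitmasks)."""
    n = instance.n
    ids = instance.block_ids
    w = np.array([instance.weights[i] for i in ids])
    bits = ((np.arange(2**n, dtype=np.uint32)[:, None] >> np.arange(n)) & 1).astype(np.int8)
    ok = np.ones(2**n, dtype=bool)
    pos = {bid: k for k, bid in enumerate(ids)}
    for members, bound in instance.iter_constraints():
        ok &= bits[:, [pos[b] for b in members]].sum(axis=1) <= bound
    vals = bits.astype(float) @ w
    return float(vals[ok].max())


def random_instance(rng) -> BipInstance:
    n = int(rng.integers(1, 16))
    weights = {i: float(np.round(rng.uniform(0.5, 20), 3)) for i in range(n)}
    xc, yc = [], []
    if n >= 2:
        for _ in range(int(rng.integers(0, 6))):
            size = int(rng.integers(2, min(n, 5) + 1))
            members = frozenset(int(v) for v in rng.choice(n, size=size, replace=False))
            (xc if rng.random() < 0.5 else yc).append(members)
    return BipInstance(sorted(weights), weights, xc, yc,
                       QuotaRatio(int(rng.integers(1, 4)), int(rng.integers(1, 4))))


class TestQuotaRatio:
    def test_parse_and_bounds(self):
        q = QuotaRatio.parse("4:2")
        # a region of the x genome may match up to qy = 2 regions of y,
        # so depth along the x axis is bounded by 2 (and y-axis depth by 4)
        assert (q.qx, q.qy) == (4, 2)
        assert q.x_axis_bound == 2
        assert q.y_axis_bound == 4

    @pytest.mark.parametrize("text", ["0:1", "1:0", "a:b", "1", "1:2:3"])
    def test_invalid_quotas_rejected(self, text):
        with pytest.raises(InvalidInputError):
            QuotaRatio.parse(text)


class TestBuildInstance:
    def test_no_conflicts_no_constraints(self):
        blocks = [_block(0, 0, 10, 0, 10, 2.0), _block(1, 50, 60, 50, 60, 3.0)]
        inst = build_instance(blocks, [], QuotaRatio(1, 1))
        assert (inst.n, inst.m) == (2, 0)

    def test_one_pairwise_conflict(self):
        blocks = [_block(0, 0, 10, 0, 10, 2.0), _block(1, 0, 10, 50, 60, 3.0)]
        cons = [ConstraintSet("x", "c", frozenset({0, 1}))]
        inst = build_instance(blocks, cons, QuotaRatio(1, 1))
        assert list(inst.iter_constraints()) == [(frozenset({0, 1}), 1)]

    def test_bound_follows_quota(self):
        blocks = [_block(i, 0, 10, i * 100, i * 100 + 10) for i in range(3)]
        cons = [ConstraintSet("x", "c", frozenset({0, 1, 2}))]
        inst = build_instance(blocks, cons, QuotaRatio(2, 2))
        assert list(inst.iter_constraints()) == [(frozenset({0, 1, 2}), 2)]

    def test_unknown_block_in_constraint_rejected(self):
        blocks = [_block(0, 0, 10, 0, 10)]
        with pytest.raises(ConsistencyError):
            build_instance(blocks, [ConstraintSet("x", "c", frozenset({0, 99}))], QuotaRatio(1, 1))


class TestSolve:
    @pytest.mark.parametrize("backend", ["milp", "exact_bb"])
    def test_two_conflicting_blocks_keep_heavier(self, backend):
        inst = BipInstance([0, 1], {0: 5.0, 1: 3.0}, [frozenset({0, 1})], [], QuotaRatio(1, 1))
        res = solve(inst, backend=backend)
        assert res.selected == frozenset({0})
        assert res.objective == 5.0
        assert res.solver_status == "optimal"

    @pytest.mark.parametrize("backend", ["milp", "exact_bb"])
    def test_three_mutual_conflicts_bound_two(self, backend):
        inst = BipInstance([0, 1, 2], {0: 4.0, 1: 4.0, 2: 3.0},
                           [frozenset({0, 1, 2})], [], QuotaRatio(2, 2))
        res = solve(inst, backend=backend)
        assert res.selected == frozenset({0, 1})
        assert res.objective == 8.0

    def test_unconstrained_instance_selects_everything(self):
        inst = BipInstance([0, 1], {0: 1.0, 1: 2.0}, [], [], QuotaRatio(1, 1))
        assert solve(inst).selected == frozenset({0, 1})

    def test_empty_instance(self):
        res = solve(BipInstance([], {}, [], [], QuotaRatio(1, 1)))
        assert res.selected == frozenset() and res.objective == 0.0

    @pytest.mark.parametrize("backend", ["milp", "exact_bb"])
    def test_matches_exhaustive_enumeration(self, backend):
        rng = np.random.default_rng(17)
        for _ in range(60):
            inst = random_instance(rng)
            res = solve(inst, backend=backend)
            assert res.objective == pytest.approx(brute_force_optimum(inst))
            # selection must itself be feasible and consistent with the objective
            assert res.objective == pytest.approx(
                sum(inst.weights[i] for i in res.selected))
            for members, bound in inst.iter_constraints():
                assert len(members & res.selected) <= bound

    def test_backends_agree_on_selection_with_tie_breaking(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            inst = random_instance(rng)
            assert solve(inst, backend="milp").selected == \
                solve(inst, backend="exact_bb").selected

    def test_objective_monotone_in_quota(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            inst = random_instance(rng)
            prev = -1.0
            for q in (1, 2, 3):
                relaxed = BipInstance(inst.block_ids, inst.weights,
                                      inst.x_constraints, inst.y_constraints, QuotaRatio(q, q))
                obj = solve(relaxed, backend="exact_bb").objective
                assert obj >= prev - 1e-9
                prev = obj

    def test_unknown_backend_rejected(self):
        with pytest.raises(InvalidInputError):
            solve(BipInstance([0], {0: 1.0}, [], [], QuotaRatio(1, 1)), backend="quantum")


class TestScreenBlocks:
    def _toy(self):
        # blocks 0 and 1 compete on x; 2 and 3 are free
        return [
            _block(0, 0, 100, 0, 100, 10.0),
            _block(1, 10, 90, 200, 300, 4.0),
            _block(2, 200, 300, 400, 500, 5.0),
            _block(3, 400, 500, 600, 700, 1.0),
        ]

    def test_conflict_resolved_by_weight(self):
        result, kept = screen_blocks(self._toy(), QuotaRatio(1, 1), nm=0)
        assert {b.block_id for b in kept} == {0, 2, 3}
        assert result.objective == pytest.approx(16.0)

    def test_screening_is_idempotent(self):
        _, kept = screen_blocks(self._toy(), QuotaRatio(1, 1), nm=0)
        result2, kept2 = screen_blocks(kept, QuotaRatio(1, 1), nm=0)
        assert kept2 == kept
        assert result2.objective == pytest.approx(sum(b.weight for b in kept))

    def test_objective_bounded_by_total_weight(self):
        blocks = self._toy()
        result, _ = screen_blocks(blocks, QuotaRatio(1, 1), nm=0)
        assert result.objective <= sum(b.weight for b in blocks)


class TestVerifyQuota:
    def test_empty_selection_is_compliant(self):
        ok, violations = verify_quota([_block(0, 0, 10, 0, 10)], set(), QuotaRatio(1, 1), 0)
        assert ok and violations == []

    def test_optimal_screens_are_always_compliant(self):
        rng = np.random.default_rng(71)
        for _ in range(15):
            blocks = []
            for bid in range(25):
                xs, ys = int(rng.integers(0, 200)), int(rng.integers(0, 200))
                blocks.append(_block(bid, xs, xs + int(rng.integers(1, 70)),
                                     ys, ys + int(rng.integers(1, 70)),
                                     float(rng.integers(1, 20))))
            quota = QuotaRatio(int(rng.integers(1, 3)), int(rng.integers(1, 3)))
            nm = int(rng.choice([0, 5, 10]))
            result, _ = screen_blocks(blocks, quota, nm=nm)
            ok, violations = verify_quota(blocks, result.selected, quota, nm)
            assert ok, violations

    def test_over_quota_selection_reports_the_position(self):
        blocks = [_block(0, 0, 100, 0, 10), _block(1, 0, 100, 200, 210)]
        ok, violations = verify_quota(blocks, {0, 1}, QuotaRatio(1, 1), 0)
        assert not ok
        axis, chrom, pos, depth = violations[0]
        assert (axis, chrom, depth) == ("x", "c", 2)
        assert 0 <= pos < 100


class TestQuotaStats:
    LAYOUT_X = GenomeLayout("gx", (("c", 100),))
    LAYOUT_Y = GenomeLayout("gy", (("d", 100),))

    def test_no_selection_zero_everything(self):
        cov, pct = quota_stats([_block(0, 0, 10, 0, 10)], set(), QuotaRatio(1, 1),
                               self.LAYOUT_X, self.LAYOUT_Y)
        assert cov == {"x": 0.0, "y": 0.0} and pct == 0.0

    def test_half_coverage_no_excess(self):
        cov, pct = quota_stats([_block(0, 0, 50, 0, 50)], {0}, QuotaRatio(1, 1),
                               self.LAYOUT_X, self.LAYOUT_Y)
        assert cov["x"] == pytest.approx(0.5)
        assert cov["y"] == pytest.approx(0.5)
        assert pct == 0.0

    def test_stacked_blocks_excess_equals_shared_span(self):
        blocks = [_block(0, 0, 50, 0, 50), _block(1, 0, 50, 0, 50)]
        cov, pct = quota_stats(blocks, {0, 1}, QuotaRatio(1, 1),
                               self.LAYOUT_X, self.LAYOUT_Y)
        # depth 2 > 1 on 50/100 of each axis -> pooled 50%
        assert pct == pytest.approx(50.0)
        assert cov["x"] == pytest.approx(0.5)


class TestExportLp:
    def test_lp_file_structure(self, tmp_path):
        inst = BipInstance([0, 1], {0: 5.0, 1: 3.0}, [frozenset({0, 1})], [], QuotaRatio(1, 1))
        path = tmp_path / "instance.lp"
        export_lp(inst, path)
        text = path.read_text()
        assert "Maximize" in text
        assert "x0 + x1 <= 1" in text
        assert text.count("\n x") == 2  # two binaries declared
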