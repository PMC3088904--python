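"""Quota-based screening of synteny blocks as a binary integer program.

Given blocks with weights and the maximal 1D-overlap sets from
:mod:`quota_synteny.conflicts`, select the subset of blocks maximizing
total weight subject to the quota: at any position of either genome, the
number of selected blocks covering it may not exceed that genome's
expected syntenic depth.

With quota ``Qx:Qy`` (the expected numbers of subgenomes of the x and y
genome respectively), a region of the x genome may match at most ``Qy``
regions of the y genome and vice versa.  Depth along the x axis therefore
has bound ``Qy`` and depth along the y axis bound ``Qx``: every maximal
set of blocks overlapping on the x axis yields an inequality
``sum(x_j) <= Qy``, and every y-axis set ``sum(x_k) <= Qx``, over binary
selection variables ``x_i`` maximizing ``sum(w_i * x_i)``.  For quota 1:1
this is exactly maximum-weight independent set on the 1D-conflict graph.

Two interchangeable solver backends are provided: ``milp`` (scipy's HiGHS
mixed-integer solver, the default) and ``exact_bb``, a self-contained
depth-first branch-and-bound that is guaranteed optimal and requires no
LP machinery (practical up to a few hundred blocks).  Both receive the
same epsilon-perturbed weights so that tie selections agree.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .anchors import GenomeLayout
from .chaining import SyntenyBlock
from .conflicts import ConstraintSet, shrink_interval
from .errors import ConsistencyError, InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_TIME_LIMIT = 60.0  # seconds; real instances solve in well under a second
WEIGHT_DECIMALS = 3
_BOUNDS_01 = Bounds(0, 1)


@dataclass(frozen=True)
class QuotaRatio:
    """Expected subgenome multiplicities ``Qx:Qy`` of the two genomes.

    ``qx`` is the multiplication level of the genome on the x axis and
    ``qy`` that of the y-axis genome (e.g. 1:1 for plain orthology, 4:2
    for a twice-doubled genome against a once-doubled one).  The depth
    bound *along* the x axis is ``qy`` and along the y axis ``qx``.
    """

    qx: int
    qy: int

    def __post_init__(self) -> None:
        if self.qx < 1 or self.qy < 1:
            raise InvalidInputError(f"quota values must be >= 1, got {self.qx}:{self.qy}")

    @classmethod
    def parse(cls, text: str) -> "QuotaRatio":
        try:
            qx, qy = text.split(":")
            return cls(int(qx), int(qy))
        except ValueError as exc:
            raise InvalidInputError(f"cannot parse quota {text!r}; expected 'Qx:Qy'") from exc

    @property
    def x_axis_bound(self) -> int:
        return self.qy

    @property
    def y_axis_bound(self) -> int:
        return self.qx

    def __str__(self) -> str:
        return f"{self.qx}:{self.qy}"


@dataclass
class BipInstance:
    """The screening program: weights, constraint sets and their bounds."""

    block_ids: list[int]
    weights: dict[int, float]
    x_constraints: list[frozenset[int]]
    y_constraints: list[frozenset[int]]
    quota: QuotaRatio

    @property
    def n(self) -> int:
        return len(self.block_ids)

    @property
    def m(self) -> int:
        return len(self.x_constraints) + len(self.y_constraints)

    def iter_constraints(self):
        """Yield (member set, bound) for every inequality."""
        for members in self.x_constraints:
            yield members, self.quota.x_axis_bound
        for members in self.y_constraints:
            yield members, self.quota.y_axis_bound


@dataclass
class ScreeningResult:
    """Outcome of one screening run."""

    selected: frozenset[int]
    objective: float
    solver_status: str  # 'optimal' or 'time_limit'
    coverage: Optional[dict[str, float]] = None
    pct_exceeding_quota: Optional[float] = None


def build_instance(
    blocks: Sequence[SyntenyBlock],
    constraints: Sequence[ConstraintSet],
    quota: QuotaRatio,
) -> BipInstance:
    """Assemble the program from blocks and their 1D-overlap sets.

    Block weights are rounded to 3 decimals to keep the integer solvers
    away from float-equality edge cases.  Every constraint member must be
    a known block.
    """
    weights = {b.block_id: round(float(b.weight), WEIGHT_DECIMALS) for b in blocks}
    if len(weights) != len(blocks):
        raise ConsistencyError("duplicate block ids in input")
    xc: list[frozenset[int]] = []
    yc: list[frozenset[int]] = []
    for c in constraints:
        unknown = c.blocks - weights.keys()
        if unknown:
            raise ConsistencyError(f"constraint references unknown block ids {sorted(unknown)}")
        (xc if c.axis == "x" else yc).append(c.blocks)
    return BipInstance(
        block_ids=sorted(weights),
        weights=weights,
        x_constraints=xc,
        y_constraints=yc,
        quota=quota,
    )


def _perturbed_weights(instance: BipInstance) -> dict[int, float]:
    """Weights plus a tiny strictly-decreasing-in-id bonus to break ties.

    The bonus per block stays below half the smallest gap between distinct
    weights even when summed over all blocks, so the set of optimal base
    objectives is unchanged while lower block ids win ties (floor 1e-7 to
    stay above solver tolerances on tiny instances).
    """
    n = instance.n
    if n == 0:
        return {}
    values = sorted(set(instance.weights.values()))
    gaps = [b - a for a, b in zip(values, values[1:])]
    gap = min(gaps) if gaps else 1.0
    delta = gap / (n * (n + 1) + 2)
    delta = max(delta, 1e-7)
    return {
        bid: instance.weights[bid] + (n - rank) * delta
        for rank, bid in enumerate(instance.block_ids)
    }


def _solve_milp(instance: BipInstance, time_limit: float) -> tuple[frozenset[int], str]:
    ids = instance.block_ids
    idx = {bid: i for i, bid in enumerate(ids)}
    pert = _perturbed_weights(instance)
    c = -np.array([pert[bid] for bid in ids])
    cons = list(instance.iter_constraints())
    kwargs = {}
    if cons:
        n, m = len(ids), len(cons)
        # dense is cheapest to build at these sizes; HiGHS sparsifies internally
        if n * m <= 1_000_000:
            a = np.zeros((m, n))
            ub = np.empty(m)
            for r, (members, bound) in enumerate(cons):
                a[r, [idx[bid] for bid in members]] = 1.0
                ub[r] = bound
        else:
            rows = [r for r, (members, _) in enumerate(cons) for _ in members]
            col_idx = [idx[bid] for members, _ in cons for bid in members]
            a = csr_matrix((np.ones(len(rows)), (rows, col_idx)), shape=(m, n))
            ub = np.array([bound for _, bound in cons], dtype=float)
        kwargs["constraints"] = LinearConstraint(a, -np.inf, ub)
    res = milp(
        c=c,
        integrality=1,
        bounds=_BOUNDS_01,
        options={"time_limit": time_limit},
        **kwargs,
    )
    if res.x is None:
        raise ConsistencyError(f"MILP solver failed: {res.message}")
    selected = frozenset(bid for bid, xi in zip(ids, res.x) if xi > 0.5)
    status = "optimal" if res.status == 0 else "time_limit"
    return selected, status


def _solve_exact_bb(instance: BipInstance, time_limit: float) -> tuple[frozenset[int], str]:
    """Depth-first branch-and-bound with a remaining-weight upper bound.

    Blocks are explored in decreasing perturbed-weight order, include
    branch first, so the greedy solution is the first incumbent; a node is
    pruned when the current value plus the total weight of all unexplored
    blocks cannot beat the incumbent.
    """
    pert = _perturbed_weights(instance)
    order = sorted(instance.block_ids, key=lambda bid: -pert[bid])
    n = len(order)
    w = [pert[bid] for bid in order]
    suffix = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] + w[i]

    cons: list[list[int]] = []  # remaining capacity per constraint
    block_cons: list[list[int]] = [[] for _ in range(n)]
    pos = {bid: i for i, bid in enumerate(order)}
    caps: list[int] = []
    for members, bound in instance.iter_constraints():
        ci = len(caps)
        caps.append(bound)
        for bid in members:
            block_cons[pos[bid]].append(ci)

    best_val = -1.0
    best_sel: list[bool] = [False] * n
    cur_sel = [False] * n
    deadline = time.monotonic() + time_limit
    timed_out = False
    node_budget = 0

    def dfs(i: int, cur: float) -> None:
        nonlocal best_val, best_sel, timed_out, node_budget
        node_budget += 1
        if timed_out or (node_budget & 0x3FF) == 0 and time.monotonic() > deadline:
            timed_out = True
            return
        if cur + suffix[i] <= best_val + 1e-12:
            return
        if i == n:
            if cur > best_val:
                best_val = cur
                best_sel = cur_sel.copy()
            return
        feasible = all(caps[ci] > 0 for ci in block_cons[i])
        if feasible:
            for ci in block_cons[i]:
                caps[ci] -= 1
            cur_sel[i] = True
            dfs(i + 1, cur + w[i])
            cur_sel[i] = False
            for ci in block_cons[i]:
                caps[ci] += 1
        dfs(i + 1, cur)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, n + 1000))
    try:
        dfs(0, 0.0)
    finally:
        sys.setrecursionlimit(old_limit)
    selected = frozenset(order[i] for i in range(n) if best_sel[i])
    return selected, ("time_limit" if timed_out else "optimal")


def solve(
    instance: BipInstance,
    backend: str = "milp",
    time_limit: float = DEFAULT_TIME_LIMIT,
) -> ScreeningResult:
    """Solve the screening program; returns the selected block set.

    ``backend`` is ``'milp'`` (HiGHS, default) or ``'exact_bb'`` (built-in
    exact branch-and-bound).  An unconstrained instance selects every
    block.  Hitting the time limit is reported via ``solver_status``,
    never silently.
    """
    if backend not in ("milp", "exact_bb", "exact"):
        raise InvalidInputError(f"unknown backend {backend!r}; use 'milp' or 'exact_bb'")
    if instance.n == 0:
        return ScreeningResult(frozenset(), 0.0, "optimal")
    if instance.m == 0:
        selected = frozenset(instance.block_ids)
        status = "optimal"
    elif backend == "milp":
        selected, status = _solve_milp(instance, time_limit)
    else:
        selected, status = _solve_exact_bb(instance, time_limit)
    if status != "optimal":
        logger.warning("solver hit the time limit; returning best incumbent")
    objective = float(sum(instance.weights[bid] for bid in selected))
    return ScreeningResult(selected=selected, objective=objective, solver_status=status)


def verify_quota(
    blocks: Sequence[SyntenyBlock],
    selected: frozenset[int] | set[int],
    quota: QuotaRatio,
    nm: int,
) -> tuple[bool, list[tuple[str, str, int, int]]]:
    """Check that shrunken-interval depth respects the quota everywhere.

    Recomputes the depth of the selected blocks' shrunken projections at
    every event point on both axes.  Returns ``(ok, violations)`` where
    each violation is ``(axis, chrom, position, depth)``.
    """
    sel = [b for b in blocks if b.block_id in selected]
    violations: list[tuple[str, str, int, int]] = []
    for axis, bound in (("x", quota.x_axis_bound), ("y", quota.y_axis_bound)):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for b in sel:
            if axis == "x":
                chrom, iv = b.x_chrom, shrink_interval(b.x_start, b.x_stop, nm)
            else:
                chrom, iv = b.y_chrom, shrink_interval(b.y_start, b.y_stop, nm)
            per_chrom.setdefault(chrom, []).append(iv)
        for chrom, ivs in sorted(per_chrom.items()):
            events = []
            for lo, hi in ivs:
                events.append((lo, 0))
                events.append((hi, 1))
            events.sort()
            depth = 0
            for coord, kind in events:
                if kind == 0:
                    depth += 1
                    if depth > bound:
                        violations.append((axis, chrom, coord, depth))
                else:
                    depth -= 1
    return (not violations), violations


def _depth_excess_length(intervals: list[tuple[int, int]], bound: int) -> int:
    """Total length (half-open coords) where coverage depth exceeds ``bound``."""
    events: list[tuple[int, int]] = []
    for s, e in intervals:
        if e > s:
            events.append((s, 1))
            events.append((e, -1))
    events.sort()
    excess = 0
    depth = 0
    prev = None
    for coord, delta in events:
        if prev is not None and depth > bound:
            excess += coord - prev
        depth += delta
        prev = coord
    return excess


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if e <= s:
            continue
        if last_end is None or s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def quota_stats(
    blocks: Sequence[SyntenyBlock],
    selected: frozenset[int] | set[int],
    quota: QuotaRatio,
    x_layout: GenomeLayout,
    y_layout: GenomeLayout,
) -> tuple[dict[str, float], float]:
    """Coverage per genome and percentage of axis length exceeding quota.

    Both statistics use the *unshrunk* selected block intervals: coverage
    is covered length over total genome length per axis; the quota-excess
    percentage pools both axes and measures the fraction of total axis
    length where selected-block depth exceeds the allowed depth (small
    residual overlaps of up to ``2*Nm`` per block pair are expected when
    screening used ``Nm > 0``).
    """
    total_x, total_y = x_layout.total_length(), y_layout.total_length()
    if total_x <= 0 or total_y <= 0:
        raise InvalidInputError("genome layouts must have positive total length")
    sel = [b for b in blocks if b.block_id in selected]
    x_ivs: dict[str, list[tuple[int, int]]] = {}
    y_ivs: dict[str, list[tuple[int, int]]] = {}
    for b in sel:
        x_ivs.setdefault(b.x_chrom, []).append((b.x_start, b.x_stop))
        y_ivs.setdefault(b.y_chrom, []).append((b.y_start, b.y_stop))
    cov_x = sum(_union_length(ivs) for ivs in x_ivs.values()) / total_x
    cov_y = sum(_union_length(ivs) for ivs in y_ivs.values()) / total_y
    excess = sum(_depth_excess_length(ivs, quota.x_axis_bound) for ivs in x_ivs.values())
    excess += sum(_depth_excess_length(ivs, quota.y_axis_bound) for ivs in y_ivs.values())
    pct = 100.0 * excess / (total_x + total_y)
    return {"x": cov_x, "y": cov_y}, pct


def export_lp(instance: BipInstance, path: str | Path) -> None:
    """Write the instance in CPLEX LP format for external solvers."""
    with open(path, "w") as handle:
        handle.write("Maximize\n obj: ")
        terms = [f"{instance.weights[bid]:g} x{bid}" for bid in instance.block_ids]
        handle.write(" + ".join(terms) or "0")
        handle.write("\nSubject To\n")
        for r, (members, bound) in enumerate(instance.iter_constraints()):
            lhs = " + ".join(f"x{bid}" for bid in sorted(members))
            handle.write(f" c{r}: {lhs} <= {bound}\n")
        handle.write("Binary\n")
        for bid in instance.block_ids:
            handle.write(f" x{bid}\n")
        handle.write("End\n")


def screen_blocks(
    blocks: Sequence[SyntenyBlock],
    quota: QuotaRatio,
    nm: int = 10,
    backend: str = "milp",
    time_limit: float = DEFAULT_TIME_LIMIT,
    x_layout: Optional[GenomeLayout] = None,
    y_layout: Optional[GenomeLayout] = None,
) -> tuple[ScreeningResult, list[SyntenyBlock]]:
    """Convenience wrapper: constraints -> instance -> solve -> stats.

    Returns the screening result and the retained blocks (input order).
    Coverage and quota-excess statistics are filled in when both layouts
    are provided.
    """
    from .conflicts import build_constraints

    constraints = build_constraints(blocks, nm)
    instance = build_instance(blocks, constraints, quota)
    result = solve(instance, backend=backend, time_limit=time_limit)
    if x_layout is not None and y_layout is not None:
        result.coverage, result.pct_exceeding_quota = quota_stats(
            blocks, result.selected, quota, x_layout, y_layout
        )
    kept = [b for b in blocks if b.block_id in result.selected]
    logger.info(
        "screened %d blocks -> %d (quota %s, %d constraints, status %s)",
        len(blocks), len(kept), quota, instance.m, result.solver_status,
    )
    return result, kept
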