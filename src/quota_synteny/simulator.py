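"""Genome-evolution simulator: the validation harness for quota screening.

The simulation emulates a pair of polyploid genomes descended from one
ancestor with ``n_genes`` distinct genes: genome A receives a whole-genome
duplication (x2) and genome B a triplication (x3), each concatenated and
treated as a single chromosome of signed gene symbols.  Each genome then
evolves for ``n_steps`` mutation steps; at every step, with probability
``p_inversion`` a macro-inversion occurs (two uniform breakpoints, the
intervening segment is flipped and its signs negated), with probability
``p_loss`` one uniformly chosen gene occurrence is deleted, and otherwise
nothing happens.

All surviving cross-genome copy pairs of the same ancestral gene are the
*gold standard*; feeding the same-symbol pairs as unit-weight point anchors
through chain -> constraints -> screen at quota 2:3 and counting how many
gold pairs land inside retained blocks gives the *recovery rate*, i.e. the
fraction of true homologies the screening preserves.

What this emulates — and what it does not: gene order, polyploidy depth,
inversions and losses are modelled; translocations, chromosome
fission/fusion, gene gain, tandem duplication and any sequence-level noise
(so also spurious anchors) are not.  Every anchor fed to the pipeline is a
true pair, so recovery below 100% measures losses caused by screening
itself, not anchor noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .anchors import Anchor, GenomeLayout, point_anchor
from .bip_screen import QuotaRatio, screen_blocks
from .chaining import SyntenyBlock, chain_anchors
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_N_GENES = 10_000
DEFAULT_N_STEPS = 20_000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated genome pair.

    ``n_steps`` mutation steps are applied to each genome independently
    (both lineages evolve); set ``shared_clock=True`` to instead apply
    ``n_steps`` steps total, each to one randomly chosen genome.
    """

    n_genes: int = DEFAULT_N_GENES
    n_steps: int = DEFAULT_N_STEPS
    p_inversion: float = 0.0
    p_loss: float = 0.0
    ploidy_a: int = 2
    ploidy_b: int = 3
    seed: int = 0
    shared_clock: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidInputError("n_genes must be >= 1")
        if self.n_steps < 0:
            raise InvalidInputError("n_steps must be >= 0")
        if not (0 <= self.p_inversion <= 1 and 0 <= self.p_loss <= 1):
            raise InvalidInputError("probabilities must lie in [0, 1]")
        if self.p_inversion + self.p_loss > 1:
            raise InvalidInputError("p_inversion + p_loss must be <= 1")
        if self.ploidy_a < 1 or self.ploidy_b < 1:
            raise InvalidInputError("ploidies must be >= 1")


@dataclass
class SimGenome:
    """One evolved genome: a single chromosome of signed gene symbols."""

    genome_id: str
    genes: list[int]

    def __len__(self) -> int:
        return len(self.genes)

    def positions_by_symbol(self) -> dict[int, list[int]]:
        pos: dict[int, list[int]] = {}
        for i, g in enumerate(self.genes):
            pos.setdefault(abs(g), []).append(i)
        return pos


@dataclass(frozen=True)
class GoldStandard:
    """All surviving cross-genome copy pairs ``(position_in_A, position_in_B)``."""

    pairs: frozenset[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.pairs)


# event tuples: ("inv", genome_idx, i, j) | ("loss", genome_idx, pos) | ("noop", genome_idx)
Event = tuple


def _evolve_step(genome: list[int], rng: np.random.Generator,
                 p_inversion: float, p_loss: float, genome_idx: int) -> Event:
    u = rng.random()
    length = len(genome)
    if u < p_inversion and length > 0:
        i, j = sorted(int(v) for v in rng.integers(0, length + 1, size=2))
        genome[i:j] = [-g for g in reversed(genome[i:j])]
        return ("inv", genome_idx, i, j)
    if u < p_inversion + p_loss and length > 0:
        pos = int(rng.integers(length))
        del genome[pos]
        return ("loss", genome_idx, pos)
    return ("noop", genome_idx)


def apply_events(config: SimConfig, events: Sequence[Event]) -> tuple[list[int], list[int]]:
    """Replay a logged event list on fresh post-polyploidy genomes.

    Independent of the random stream: useful for verifying that a
    simulation is fully determined by its event log.
    """
    ancestral = list(range(1, config.n_genes + 1))
    genomes = [ancestral * config.ploidy_a, ancestral * config.ploidy_b]
    for ev in events:
        kind, gi = ev[0], ev[1]
        g = genomes[gi]
        if kind == "inv":
            i, j = ev[2], ev[3]
            g[i:j] = [-v for v in reversed(g[i:j])]
        elif kind == "loss":
            del g[ev[2]]
    return genomes[0], genomes[1]


def gold_standard(a: SimGenome, b: SimGenome) -> GoldStandard:
    """All cross-genome position pairs carrying the same ancestral symbol."""
    pos_b = b.positions_by_symbol()
    pairs: set[tuple[int, int]] = set()
    for pa, g in enumerate(a.genes):
        for pb in pos_b.get(abs(g), ()):
            pairs.add((pa, pb))
    return GoldStandard(frozenset(pairs))


def simulate_pair(
    config: SimConfig, return_events: bool = False
) -> tuple[SimGenome, SimGenome, GoldStandard] | tuple[SimGenome, SimGenome, GoldStandard, list[Event]]:
    """Simulate the evolved genome pair and its gold standard.

    Fully reproducible from ``config.seed``.  With ``return_events`` the
    logged mutation events are returned as well (see :func:`apply_events`).
    """
    rng = np.random.default_rng(config.seed)
    ancestral = list(range(1, config.n_genes + 1))
    genome_a = ancestral * config.ploidy_a
    genome_b = ancestral * config.ploidy_b
    events: list[Event] = []
    if config.shared_clock:
        for _ in range(config.n_steps):
            gi = int(rng.integers(2))
            g = genome_a if gi == 0 else genome_b
            events.append(_evolve_step(g, rng, config.p_inversion, config.p_loss, gi))
    else:
        for gi, g in ((0, genome_a), (1, genome_b)):
            for _ in range(config.n_steps):
                events.append(_evolve_step(g, rng, config.p_inversion, config.p_loss, gi))
    a = SimGenome("A", genome_a)
    b = SimGenome("B", genome_b)
    gold = gold_standard(a, b)
    if return_events:
        return a, b, gold, events
    return a, b, gold


def sim_layouts(a: SimGenome, b: SimGenome) -> tuple[GenomeLayout, GenomeLayout]:
    """Gene-rank axis layouts for the two simulated single-chromosome genomes."""
    return (
        GenomeLayout(a.genome_id, (("1", max(len(a), 1)),)),
        GenomeLayout(b.genome_id, (("1", max(len(b), 1)),)),
    )


def anchors_from_sim(a: SimGenome, b: SimGenome) -> list[Anchor]:
    """Point anchors (weight 1) for every same-symbol cross-genome pair.

    Coordinates are gene ranks in the evolved genomes, so the anchor set
    equals the gold standard as a set of coordinate pairs.
    """
    pos_b = b.positions_by_symbol()
    anchors: list[Anchor] = []
    for pa, g in enumerate(a.genes):
        for pb in pos_b.get(abs(g), ()):
            anchors.append(point_anchor("1", pa, "1", pb, weight=1.0))
    return anchors


def recovery_rate(gold: GoldStandard, screened_blocks: Sequence[SyntenyBlock]) -> float:
    """Percentage of gold pairs retained inside the screened blocks."""
    if len(gold) == 0:
        return 100.0
    kept = {
        (anchor.x_start, anchor.y_start)
        for block in screened_blocks
        for anchor in block.anchors
    }
    return 100.0 * len(kept & gold.pairs) / len(gold)


def replicate_seed(base_seed: int, cell: int, rep: int) -> int:
    """Derive a per-replicate seed (< 2**31) from a base seed."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(cell, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def run_sim_pipeline(
    config: SimConfig,
    quota: QuotaRatio = QuotaRatio(2, 3),
    dm: int = 20,
    nm: int = 10,
    backend: str = "milp",
    time_limit: float = 60.0,
) -> dict:
    """Run simulate -> anchors -> chain -> screen and score the recovery.

    Returns a flat dict of per-run numbers (sizes, objective, coverage,
    quota-excess percentage, recovery rate) suitable for JSON logging.
    """
    a, b, gold = simulate_pair(config)
    anchors = anchors_from_sim(a, b)
    blocks = chain_anchors(anchors, dm=dm)
    x_layout, y_layout = sim_layouts(a, b)
    result, kept = screen_blocks(
        blocks, quota, nm=nm, backend=backend, time_limit=time_limit,
        x_layout=x_layout, y_layout=y_layout,
    )
    return {
        "seed": config.seed,
        "p_inversion": config.p_inversion,
        "p_loss": config.p_loss,
        "n_genes": config.n_genes,
        "n_steps": config.n_steps,
        "len_a": len(a),
        "len_b": len(b),
        "n_gold": len(gold),
        "n_anchors": len(anchors),
        "n_blocks": len(blocks),
        "n_selected": len(kept),
        "objective": result.objective,
        "solver_status": result.solver_status,
        "coverage_x": result.coverage["x"],
        "coverage_y": result.coverage["y"],
        "pct_exceeding_quota": result.pct_exceeding_quota,
        "recovery": recovery_rate(gold, kept),
    }


def run_table1(
    p_inversions: Sequence[float] = (0.0, 0.005, 0.01, 0.015, 0.02),
    p_losses: Sequence[float] = (0.0, 0.3, 0.6, 0.9),
    replicates: int = 5,
    n_genes: int = DEFAULT_N_GENES,
    n_steps: int = DEFAULT_N_STEPS,
    quota: QuotaRatio = QuotaRatio(2, 3),
    dm: int = 20,
    nm: int = 10,
    backend: str = "milp",
    seed: int = 0,
    shared_clock: bool = False,
    return_runs: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[dict]]:
    """Mean recovery rate over a (p_inversion x p_loss) grid.

    Each cell averages ``replicates`` independent simulations (seeds derived
    deterministically from ``seed``).  Returns a DataFrame indexed by
    ``p_inversion`` with one column per ``p_loss`` value; with
    ``return_runs`` also the list of per-replicate pipeline outputs.
    """
    matrix = np.zeros((len(p_inversions), len(p_losses)))
    runs: list[dict] = []
    for i, p_inv in enumerate(p_inversions):
        for j, p_loss in enumerate(p_losses):
            cell = i * len(p_losses) + j
            rates = []
            for rep in range(replicates):
                config = SimConfig(
                    n_genes=n_genes, n_steps=n_steps,
                    p_inversion=p_inv, p_loss=p_loss,
                    seed=replicate_seed(seed, cell, rep),
                    shared_clock=shared_clock,
                )
                out = run_sim_pipeline(config, quota=quota, dm=dm, nm=nm, backend=backend)
                rates.append(out["recovery"])
                runs.append(out)
            matrix[i, j] = float(np.mean(rates))
            logger.info(
                "grid cell p_inv=%g p_loss=%g: mean recovery %.1f over %d replicates",
                p_inv, p_loss, matrix[i, j], replicates,
            )
    grid = pd.DataFrame(
        matrix,
        index=pd.Index(p_inversions, name="p_inversion"),
        columns=pd.Index(p_losses, name="p_loss"),
    )
    return (grid, runs) if return_runs else grid
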