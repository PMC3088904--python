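"""End-to-end pipeline: anchors -> chain -> constraints -> screen -> exports."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import anchors as anchors_mod
from .anchors import GenomeLayout
from .bip_screen import QuotaRatio, build_instance, solve, quota_stats
from .chaining import chain_anchors, write_blocks
from .conflicts import build_constraints, write_constraints
from .errors import InvalidInputError
from .plotting import infer_layout, read_anchor_colors, render_dotplot
from .rearrange import encode_permutations, write_grimm

logger = logging.getLogger(__name__)

STATS_SCHEMA = 1


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (flags win over any config file)."""

    anchors_path: Optional[str] = None  # native anchor TSV
    blast_path: Optional[str] = None  # alternatively: BLAST -m8 ...
    gene_positions_path: Optional[str] = None  # ... plus BED-like positions
    outdir: str = "quota_synteny_out"
    quota: QuotaRatio = field(default_factory=lambda: QuotaRatio(1, 1))
    dm: int = 20
    nm: int = 10
    min_anchors: int = 1
    local_dup_window: int = 10
    backend: str = "milp"
    time_limit: float = 60.0
    make_plot: bool = False
    x_layout: Optional[GenomeLayout] = None
    y_layout: Optional[GenomeLayout] = None


def load_anchors(config: PipelineConfig):
    if config.anchors_path is not None:
        return anchors_mod.read_anchors(config.anchors_path)
    if config.blast_path is not None:
        if config.gene_positions_path is None:
            raise InvalidInputError("BLAST input requires a gene position table")
        positions = anchors_mod.read_gene_positions(config.gene_positions_path)
        raw = anchors_mod.parse_blast_tab(
            config.blast_path, positions, config.x_layout, config.y_layout
        )
        return anchors_mod.filter_redundant(raw, local_dup_window=config.local_dup_window)
    raise InvalidInputError("no input: set anchors_path or blast_path")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full screening pipeline and write all artifacts.

    Writes, under ``config.outdir``: ``blocks_before.tsv`` (+ member
    anchors), ``blocks_after.tsv`` (+ member anchors), ``constraints.txt``,
    ``stats.json`` and — when the quota is 1:1 and the screened blocks are
    projection-disjoint — ``grimm.txt``.  Returns the stats dict.  An empty
    anchor input produces empty outputs and a warning, not an error.
    """
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    anchor_list = load_anchors(config)
    logger.info("stage anchors: %d anchors in", len(anchor_list))
    if not anchor_list:
        logger.warning("no anchors in input; writing empty outputs")

    blocks = chain_anchors(anchor_list, dm=config.dm, min_anchors=config.min_anchors)
    n_member_anchors = sum(b.n_anchors for b in blocks)
    logger.info("stage chaining: %d blocks (%d anchors chained)", len(blocks), n_member_anchors)
    write_blocks(blocks, outdir / "blocks_before.tsv", outdir / "blocks_before.anchors.tsv")

    constraints = build_constraints(blocks, nm=config.nm)
    write_constraints(constraints, outdir / "constraints.txt")
    instance = build_instance(blocks, constraints, config.quota)
    logger.info("stage conflicts: n=%d variables, m=%d constraints", instance.n, instance.m)

    result = solve(instance, backend=config.backend, time_limit=config.time_limit)
    kept = [b for b in blocks if b.block_id in result.selected]
    logger.info("stage screen: %d blocks kept, objective %.3f, status %s",
                len(kept), result.objective, result.solver_status)
    write_blocks(kept, outdir / "blocks_after.tsv", outdir / "blocks_after.anchors.tsv")

    x_layout = config.x_layout or infer_layout(anchor_list, "x", "genome_x")
    y_layout = config.y_layout or infer_layout(anchor_list, "y", "genome_y")
    if anchor_list:
        coverage, pct = quota_stats(blocks, result.selected, config.quota, x_layout, y_layout)
    else:
        coverage, pct = {"x": 0.0, "y": 0.0}, 0.0

    grimm_file = None
    if config.quota == QuotaRatio(1, 1) and kept:
        try:
            perms = encode_permutations(kept, x_layout, y_layout)
            grimm_file = outdir / "grimm.txt"
            write_grimm(perms, grimm_file)
            logger.info("stage grimm: wrote %s", grimm_file)
        except Exception as exc:  # residual overlaps when Nm > 0
            logger.warning("GRIMM export skipped: %s", exc)

    if config.make_plot and anchor_list:
        colors = read_anchor_colors(config.anchors_path) if config.anchors_path else None
        render_dotplot(
            anchor_list, blocks, result.selected, x_layout, y_layout,
            outdir / "dotplot.png", colors=colors,
            title=f"quota {config.quota}, Dm={config.dm}, Nm={config.nm}",
        )

    stats = {
        "schema": STATS_SCHEMA,
        "quota": str(config.quota),
        "dm": config.dm,
        "nm": config.nm,
        "backend": config.backend,
        "n_anchors": len(anchor_list),
        "n_before": len(blocks),
        "n_after": len(kept),
        "n_variables": instance.n,
        "m_constraints": instance.m,
        "objective": result.objective,
        "solver_status": result.solver_status,
        "coverage_x": coverage["x"],
        "coverage_y": coverage["y"],
        "pct_exceeding_quota": pct,
        "grimm": str(grimm_file) if grimm_file else None,
        "runtime": time.monotonic() - t0,
    }
    with open(outdir / "stats.json", "w") as handle:
        json.dump(stats, handle, indent=2)
        handle.write("\n")
    return stats
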