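"""Partition a sorted marker map into fixed-size haplotype blocks.

Blocks are runs of ``block_size`` consecutive markers on one chromosome
whose total span is below ``max_span_bp`` and whose adjacent inter-marker
gaps are each below ``max_gap_bp`` (strict inequalities).  The defaults —
4 SNPs, < 150 kb span, < 50 kb gaps — trade off packing many SNPs per
block against the recombination probability within it.

The partition is a single greedy left-to-right scan per chromosome: a
marker joins the current candidate run iff its gap to the previous run
member and the resulting span both satisfy the constraints; once the run
reaches ``block_size`` markers it is emitted and the scan restarts at the
next marker; a marker that cannot join restarts the run at itself, and
markers of runs that are never emitted are recorded as unassigned.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import SnpMap


@dataclasses.dataclass(frozen=True)
class Block:
    chrom: str
    indices: tuple[int, ...]  # global marker indices into the sorted map
    start: int  # bp, 1-based inclusive
    end: int  # bp, 1-based inclusive

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class BlockPartition:
    blocks: list[Block]
    unassigned: list[int]
    block_size: int
    max_span_bp: int
    max_gap_bp: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def assigned_indices(self) -> list[int]:
        return [i for b in self.blocks for i in b.indices]

    def index_array(self) -> np.ndarray:
        """(n_blocks, block_size) marker-index array."""
        if not self.blocks:
            return np.empty((0, self.block_size), dtype=np.intp)
        return np.array([b.indices for b in self.blocks], dtype=np.intp)


def partition_blocks(
    smap: SnpMap,
    block_size: int = 4,
    max_span_bp: int = 150_000,
    max_gap_bp: int = 50_000,
) -> BlockPartition:
    """Greedy fixed-size block partition of a sorted marker map."""
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    if max_span_bp < max_gap_bp:
        raise ValueError("max_span_bp must be >= max_gap_bp")
    if not smap.is_sorted():
        raise ValueError("marker map must be sorted by (chromosome, position)")

    chroms = smap.chroms
    pos = smap.positions
    blocks: list[Block] = []
    run: list[int] = []

    def emit(run_idx: list[int]) -> None:
        blocks.append(
            Block(
                chrom=str(chroms[run_idx[0]]),
                indices=tuple(run_idx),
                start=int(pos[run_idx[0]]),
                end=int(pos[run_idx[-1]]),
            )
        )

    prev_chrom: object = None
    for i in range(len(smap)):
        if chroms[i] != prev_chrom:
            run = [i]
            prev_chrom = chroms[i]
        elif run:
            gap = pos[i] - pos[run[-1]]
            span = pos[i] - pos[run[0]]
            if gap < max_gap_bp and span < max_span_bp:
                run.append(i)
            else:
                run = [i]
        else:
            run = [i]
        if len(run) == block_size:
            emit(run)
            run = []

    assigned = {i for b in blocks for i in b.indices}
    unassigned = [i for i in range(len(smap)) if i not in assigned]
    return BlockPartition(blocks, unassigned, block_size, max_span_bp, max_gap_bp)


def block_coverage_stats(bp: BlockPartition, smap: SnpMap) -> dict:
    """Summarise a partition: counts, assigned fraction, span/gap spread."""
    n = len(smap)
    for b in bp.blocks:
        if max(b.indices) >= n:
            raise ValueError("partition refers to markers beyond the map")
        if int(smap.positions[b.indices[0]]) != b.start or int(
            smap.positions[b.indices[-1]]
        ) != b.end:
            raise ValueError("partition does not match the supplied map")
    n_assigned = len(bp.assigned_indices())
    spans = [b.span for b in bp.blocks]
    gaps = [
        int(smap.positions[b.indices[k + 1]] - smap.positions[b.indices[k]])
        for b in bp.blocks
        for k in range(len(b.indices) - 1)
    ]
    per_chrom: dict[str, int] = {}
    for b in bp.blocks:
        per_chrom[b.chrom] = per_chrom.get(b.chrom, 0) + 1

    def _spread(xs: list[int]) -> dict:
        if not xs:
            return {"min": None, "median": None, "max": None}
        return {
            "min": int(np.min(xs)),
            "median": float(np.median(xs)),
            "max": int(np.max(xs)),
        }

    return {
        "n_blocks": bp.n_blocks,
        "n_markers": n,
        "assigned_fraction": (n_assigned / n) if n else 0.0,
        "blocks_per_chromosome": per_chrom,
        "span_bp": _spread(spans),
        "gap_bp": _spread(gaps),
    }


def write_blocks_bed(bp: BlockPartition, path) -> None:
    """BED-like export (0-based half-open) of the emitted blocks."""
    with open(path, "w") as fh:
        for k, b in enumerate(bp.blocks):
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\tblock{k:05d}\n")
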