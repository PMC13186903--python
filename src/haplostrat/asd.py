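"""Allele-sharing distances over haplotype blocks.

The per-marker sharing between two unphased diploid genotypes is the
identity-by-state fraction: the number of alleles the two genotypes share
divided by 2, i.e. ``s(a, b) = 1 - |a - b| / 2`` on dosage codes.  Block
sharing is the mean per-marker sharing over the block's markers, defined
only when both animals are fully observed on the block; the pairwise
distance is one minus the mean block sharing over the blocks defined for
that pair (whole-block pairwise deletion, equal block weights).

This is a genotype-level sharing statistic: the chip data are unphased and
no phasing is performed, so blocks matter through missing-data handling
and per-block averaging rather than through haplotype identity.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .blocks import BlockPartition
from .io import MISSING, GenotypeMatrix

#: Returned by :func:`pair_block_sharing` when either animal has a missing
#: call inside the block.
UNDEFINED = None


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal.

    Allele-sharing distances produced by :func:`asd_matrix` always lie in
    [0, 1]; the container itself accepts any non-negative dissimilarity so
    the MDS / UPGMA views apply to general inputs.
    ``valid_block_fraction[i, j]`` is the fraction of all blocks that were
    fully observed in both animals i and j and therefore contributed to
    ``values[i, j]``.
    """

    ids: list[str]
    values: np.ndarray
    valid_block_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicated animal id")
        if n and not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if n and np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")
        if n and np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(a) for a in ids]
        vb = (
            None
            if self.valid_block_fraction is None
            else self.valid_block_fraction[np.ix_(idx, idx)]
        )
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], vb)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def pair_block_sharing(g_i: np.ndarray, g_j: np.ndarray) -> float | None:
    """Mean per-marker IBS sharing of one block for one pair of animals.

    Returns :data:`UNDEFINED` (``None``) when either vector has a missing
    call; the block is then dropped from the pair's distance.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape:
        raise ValueError("block vectors have different lengths")
    if np.any(g_i == MISSING) or np.any(g_j == MISSING):
        return UNDEFINED
    return float(np.mean(1.0 - np.abs(g_i.astype(float) - g_j.astype(float)) / 2.0))


def asd_matrix(
    gm: GenotypeMatrix,
    bp: BlockPartition,
    min_valid_fraction: float = 0.5,
) -> DistanceMatrix:
    """All-pairs allele-sharing distance over the emitted blocks.

    A pair with fewer than ``min_valid_fraction`` of blocks fully observed
    in both animals (or with no usable block at all) raises, listing the
    offending pairs — missing-data problems are loud, never silent.
    """
    if gm.n_animals < 2:
        raise ValueError("need at least 2 animals")
    if bp.n_blocks == 0:
        raise ValueError("empty block partition")
    idx = bp.index_array()  # (B, k)
    n_blocks, k = idx.shape
    X = gm.values.astype(np.float64)
    obs_marker = gm.values != MISSING

    # per-animal indicator of fully observed blocks, expanded to markers
    block_obs = obs_marker[:, idx].all(axis=2)  # (n, B)
    marker_mask = np.repeat(block_obs, k, axis=1)  # (n, B*k) aligned with idx.ravel()
    Xb = X[:, idx.reshape(-1)] * marker_mask  # masked dosages over block markers

    # For markers where both animals' blocks are observed:
    #   sum |x_i - x_j| = sum x_i^2 + sum x_j^2 - 2 sum x_i x_j - 2 * N02,
    # since (a-b)^2 differs from |a-b| only for opposite homozygotes.
    M = marker_mask.astype(np.float64)
    sq = (Xb * Xb) @ M.T  # (n, n): sum of x_i^2 over jointly-valid markers
    cross = Xb @ Xb.T
    hom0 = ((X[:, idx.reshape(-1)] == 0) & marker_mask).astype(np.float64)
    hom2 = ((X[:, idx.reshape(-1)] == 2) & marker_mask).astype(np.float64)
    n02 = hom0 @ hom2.T
    sum_abs_diff = sq + sq.T - 2.0 * cross - 2.0 * (n02 + n02.T)

    valid_blocks = block_obs.astype(np.float64) @ block_obs.T.astype(np.float64)
    np.fill_diagonal(sum_abs_diff, 0.0)

    bad_pairs = []
    n = gm.n_animals
    frac = valid_blocks / n_blocks
    for i in range(n):
        for j in range(i + 1, n):
            if valid_blocks[i, j] == 0:
                bad_pairs.append((gm.ids[i], gm.ids[j], 0.0))
            elif frac[i, j] < min_valid_fraction:
                bad_pairs.append((gm.ids[i], gm.ids[j], float(frac[i, j])))
    if bad_pairs:
        shown = ", ".join(f"({a},{b}: {f:.2f})" for a, b, f in bad_pairs[:10])
        raise ValueError(
            f"{len(bad_pairs)} pairs below min_valid_fraction="
            f"{min_valid_fraction}: {shown}"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        d = 0.5 * sum_abs_diff / (bp.block_size * valid_blocks)
    d = 0.5 * (d + d.T)  # enforce exact symmetry against BLAS round-off
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(list(gm.ids), d, frac)


def write_valid_fractions(dm: DistanceMatrix, path) -> None:
    """Companion TSV of per-pair valid-block fractions."""
    if dm.valid_block_fraction is None:
        raise ValueError("distance matrix carries no valid-block fractions")
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for i, animal in enumerate(dm.ids):
            row = "\t".join(f"{v:.6f}" for v in dm.valid_block_fraction[i])
            fh.write(animal + "\t" + row + "\n")
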