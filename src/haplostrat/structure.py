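"""Population structure from a distance matrix.

Three views of the same allele-sharing distance matrix:

* classical (Torgerson) multidimensional scaling onto the plane,
* a UPGMA dendrogram (size-weighted average linkage, ultrametric),
* a nearest-mean-panel breed-dominance assignment of each experimental
  animal against two purebred reference panels, with a continuous
  dominance score ``(d_B - d_A) / (d_A + d_B)`` in [-1, 1].

The MDS plot and heatmap ordering are diagnostics; the assignment rule is
the reproducible classifier that converts "visibly closer to one panel"
into a label.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .asd import DistanceMatrix
from .io import PanelLabels

A_DOMINANT = "A_DOMINANT"
B_DOMINANT = "B_DOMINANT"
UNASSIGNED = "UNASSIGNED"


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MdsEmbedding:
    ids: list[str]
    coordinates: np.ndarray  # (n, dims)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    stress: float
    n_negative_axes: int = 0  # requested axes whose eigenvalue was negative


def classical_mds(
    dm: DistanceMatrix, dims: int = 2, panels: PanelLabels | None = None
) -> MdsEmbedding:
    """Torgerson double-centering embedding of a distance matrix.

    Axes whose eigenvalue is negative (the distance is then not Euclidean
    in that direction) are zero-filled and counted, never silently clipped
    into coordinates.  Each axis is oriented so the reference-panel-A
    centroid coordinate is >= 0 (first animal >= 0 without panels).
    """
    n = dm.n
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if dims > n:
        raise ValueError(f"dims={dims} exceeds animal count {n}")
    D = dm.values
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D * D) @ J
    B = 0.5 * (B + B.T)
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]

    coords = np.zeros((n, dims))
    n_negative = 0
    for a in range(dims):
        if eigval[a] > 0:
            coords[:, a] = eigvec[:, a] * np.sqrt(eigval[a])
        else:
            n_negative += 1  # axis left at zero

    # deterministic sign convention
    if panels is not None and panels.ref_a_ids:
        anchor = [dm.ids.index(i) for i in panels.ref_a_ids]
    else:
        anchor = [0]
    for a in range(dims):
        c = coords[anchor, a].mean()
        if c < 0 or (c == 0 and coords[0, a] < 0):
            coords[:, a] = -coords[:, a]

    emb_d = _pairwise_euclidean(coords)
    stress = float(np.sum((np.triu(D - emb_d, 1)) ** 2))
    return MdsEmbedding(list(dm.ids), coords, eigval, stress, n_negative)


def _pairwise_euclidean(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff * diff).sum(axis=2))


def write_embedding(emb: MdsEmbedding, path) -> None:
    with open(path, "w") as fh:
        dims = emb.coordinates.shape[1]
        fh.write("id\t" + "\t".join(f"dim{a + 1}" for a in range(dims)) + "\n")
        for i, animal in enumerate(emb.ids):
            row = "\t".join(f"{v:.10g}" for v in emb.coordinates[i])
            fh.write(animal + "\t" + row + "\n")


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class UpgmaNode:
    """Node of a rooted ultrametric tree; ``height`` is half the merge
    distance (leaves sit at height 0)."""

    height: float
    name: str | None = None
    children: tuple["UpgmaNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        return [leaf for c in self.children for leaf in c.leaves()]

    def min_leaf(self) -> str:
        return min(self.leaves())


@dataclasses.dataclass
class UpgmaTree:
    root: UpgmaNode
    ids: list[str]

    def cophenetic(self) -> np.ndarray:
        """Matrix of cophenetic distances (2 x height of the lowest common
        ancestor), in the order of ``ids``."""
        n = len(self.ids)
        pos = {a: i for i, a in enumerate(self.ids)}
        out = np.zeros((n, n))

        def visit(node: UpgmaNode) -> list[str]:
            if node.is_leaf:
                return [node.name]  # type: ignore[list-item]
            below = [visit(c) for c in node.children]
            for ci in range(len(below)):
                for cj in range(ci + 1, len(below)):
                    for a in below[ci]:
                        for b in below[cj]:
                            out[pos[a], pos[b]] = out[pos[b], pos[a]] = 2 * node.height
            return [a for sub in below for a in sub]

        visit(self.root)
        return out


def upgma(dm: DistanceMatrix) -> UpgmaTree:
    """Size-weighted average-linkage agglomeration (UPGMA).

    Ties in the closest-pair search break on the lexicographically
    smallest pair of cluster representatives (each cluster represented by
    its smallest leaf id), which makes dendrograms and heatmap orderings
    byte-reproducible.
    """
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 animals")
    nodes: dict[str, UpgmaNode] = {
        a: UpgmaNode(height=0.0, name=a) for a in dm.ids
    }
    sizes: dict[str, int] = {a: 1 for a in dm.ids}
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.ids[i], dm.ids[j]))] = float(dm.values[i, j])

    active = sorted(nodes)
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                d = dist[frozenset((a, b))]
                key = (d, a, b)  # active is sorted -> (a, b) lexicographic
                if best is None or key < best:
                    best = key
        d, a, b = best  # type: ignore[misc]
        merged = UpgmaNode(height=d / 2.0, children=(nodes[a], nodes[b]))
        rep = min(a, b)
        other = max(a, b)
        for c in active:
            if c in (a, b):
                continue
            da = dist[frozenset((a, c))]
            db = dist[frozenset((b, c))]
            dist[frozenset((rep, c))] = (sizes[a] * da + sizes[b] * db) / (
                sizes[a] + sizes[b]
            )
        sizes[rep] = sizes[a] + sizes[b]
        nodes[rep] = merged
        active.remove(other)
        del nodes[other]
        del sizes[other]
    return UpgmaTree(root=nodes[active[0]], ids=list(dm.ids))


def leaf_order(tree: UpgmaTree) -> list[str]:
    """Deterministic left-to-right leaf traversal: at every internal node
    the child with the lexicographically smaller minimal leaf goes left."""

    def visit(node: UpgmaNode) -> list[str]:
        if node.is_leaf:
            return [node.name]  # type: ignore[list-item]
        ordered = sorted(node.children, key=lambda c: c.min_leaf())
        return [leaf for c in ordered for leaf in visit(c)]

    return visit(tree.root)


def to_newick(tree: UpgmaTree) -> str:
    """Newick string with branch lengths (parent height - child height)."""

    def fmt(node: UpgmaNode, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{node.name}:{bl:.10g}"
        ordered = sorted(node.children, key=lambda c: c.min_leaf())
        inner = ",".join(fmt(c, node.height) for c in ordered)
        return f"({inner}):{bl:.10g}"

    root = tree.root
    ordered = sorted(root.children, key=lambda c: c.min_leaf())
    inner = ",".join(fmt(c, root.height) for c in ordered)
    return f"({inner});"


# ---------------------------------------------------------------------------
# breed assignment
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BreedAssignment:
    """Per-animal panel distances, dominance score and label.

    ``frame`` columns: id, d_a, d_b, score, label.  Positive scores mean
    the animal is closer to panel A (score = (d_B - d_A)/(d_A + d_B)).
    """

    frame: pd.DataFrame
    breed_a: str
    breed_b: str
    tie_band: float

    def label_of(self, animal_id: str) -> str:
        row = self.frame.loc[self.frame["id"] == animal_id]
        if row.empty:
            raise KeyError(animal_id)
        return str(row["label"].iloc[0])

    def labels(self) -> dict[str, str]:
        return dict(zip(self.frame["id"], self.frame["label"]))


def assign_breed(
    dm: DistanceMatrix, labels: PanelLabels, tie_band: float = 0.0
) -> BreedAssignment:
    """Assign each experimental animal the breed of the nearer panel.

    ``tie_band`` widens the UNASSIGNED band around score 0 for animals of
    genuinely intermediate background; the default 0 labels every animal
    that is not exactly equidistant.
    """
    if not labels.ref_a_ids or not labels.ref_b_ids:
        raise ValueError("both reference panels must be non-empty")
    missing = [
        a for a in labels.experimental_ids + labels.ref_a_ids + labels.ref_b_ids
        if a not in dm.ids
    ]
    if missing:
        raise ValueError(f"animals absent from distance matrix: {missing[:5]}")
    if not (0 <= tie_band <= 1):
        raise ValueError("tie_band must be in [0, 1]")

    idx = {a: i for i, a in enumerate(dm.ids)}
    ia = [idx[a] for a in labels.ref_a_ids]
    ib = [idx[a] for a in labels.ref_b_ids]
    rows = []
    for animal in labels.experimental_ids:
        i = idx[animal]
        d_a = float(np.mean(dm.values[i, ia]))
        d_b = float(np.mean(dm.values[i, ib]))
        denom = d_a + d_b
        score = 0.0 if denom == 0 else (d_b - d_a) / denom
        if score > tie_band:
            label = A_DOMINANT
        elif score < -tie_band:
            label = B_DOMINANT
        else:
            label = UNASSIGNED
        rows.append((animal, d_a, d_b, score, label))
    frame = pd.DataFrame(rows, columns=["id", "d_a", "d_b", "score", "label"])
    return BreedAssignment(frame, labels.breed_a, labels.breed_b, tie_band)


def write_assignment(ba: BreedAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# breed_a={ba.breed_a} breed_b={ba.breed_b} tie_band={ba.tie_band}\n")
        fh.write("id\td_a\td_b\tscore\tlabel\n")
        for _, r in ba.frame.iterrows():
            fh.write(
                f"{r['id']}\t{r['d_a']:.10g}\t{r['d_b']:.10g}\t"
                f"{r['score']:.10g}\t{r['label']}\n"
            )
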