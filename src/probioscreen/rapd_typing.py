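"""RAPD fingerprint typing: band binning, Jaccard, UPGMA, and the 85% cut.

A RAPD-PCR lane is a list of amplicon sizes (bp) read off a gel. Lanes are
matched across isolates by binning fragments whose sizes agree within a
relative tolerance (default 5%, a typical agarose sizing error) under
single-linkage chaining. The resulting binary band matrix is compared with
the Jaccard coefficient, clustered with UPGMA (average linkage, implemented
here from scratch with deterministic tie-breaking), and the dendrogram is
cut so that isolates with more than 85% similarity — similarity being
(1 - cophenetic distance) x 100 on the tree — are assigned to the same
strain. The cut is strict: a pair at exactly 85% falls in two strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_model_io import ValidationError

__all__ = [
    "UndefinedSimilarityError",
    "RAPDLane",
    "BandMatrix",
    "Node",
    "Dendrogram",
    "bin_fragments",
    "jaccard_similarity",
    "jaccard_distance_matrix",
    "upgma",
    "assign_strains",
    "write_newick",
]


class UndefinedSimilarityError(ValueError):
    """Both fingerprints are empty; their Jaccard similarity is undefined."""


@dataclass(frozen=True)
class RAPDLane:
    isolate_id: str
    fragment_sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.fragment_sizes):
            raise ValidationError(
                f"lane {self.isolate_id}: fragment sizes must be positive"
            )


@dataclass
class BandMatrix:
    isolate_ids: list[str]
    bin_centers: list[float]
    presence: np.ndarray  # (isolates, bins) in {0, 1}

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if self.presence.shape != (len(self.isolate_ids), len(self.bin_centers)):
            raise ValidationError("presence matrix shape mismatch")
        centers = np.asarray(self.bin_centers)
        if len(centers) > 1 and not (np.diff(centers) > 0).all():
            raise ValidationError("bin centers must be strictly increasing")


@dataclass(frozen=True)
class Node:
    """A dendrogram node; leaves have height 0 and carry a name."""

    height: float
    children: tuple["Node", ...] = ()
    name: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.name,)
        out: tuple[str, ...] = ()
        for c in self.children:
            out += c.leaves
        return out


@dataclass
class Dendrogram:
    root: Node
    leaf_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.leaf_order:
            self.leaf_order = list(self.root.leaves)

    def internal_nodes(self) -> list[Node]:
        out = []

        def walk(n: Node) -> None:
            if not n.is_leaf:
                out.append(n)
                for c in n.children:
                    walk(c)

        walk(self.root)
        return out


def bin_fragments(lanes: Sequence[RAPDLane], rel_tolerance: float = 0.05) -> BandMatrix:
    """Chain fragments into shared size bins and build the presence matrix.

    Two fragments belong to the same bin iff their sizes differ by at most
    ``rel_tolerance`` times the smaller size, chained transitively
    (single linkage). An empty (failed) lane keeps its all-zero row.
    """
    if not lanes:
        raise ValidationError("no lanes provided")
    if not (0 < rel_tolerance <= 0.2):
        raise ValidationError("rel_tolerance must be in (0, 0.2]")

    frags = [
        (size, lane_idx)
        for lane_idx, lane in enumerate(lanes)
        for size in lane.fragment_sizes
    ]
    frags.sort()
    # chain sorted sizes: adjacent fragments within tolerance share a bin
    bins: list[list[tuple[float, int]]] = []
    for size, lane_idx in frags:
        if bins and size - bins[-1][-1][0] <= rel_tolerance * min(
            bins[-1][-1][0], size
        ):
            bins[-1].append((size, lane_idx))
        else:
            bins.append([(size, lane_idx)])

    centers = [float(np.mean([s for s, _ in b])) for b in bins]
    presence = np.zeros((len(lanes), len(bins)), dtype=np.int8)
    for j, b in enumerate(bins):
        for _, lane_idx in b:
            presence[lane_idx, j] = 1
    return BandMatrix([l.isolate_id for l in lanes], centers, presence)


def jaccard_similarity(row_a, row_b) -> float:
    """Shared bands over the union of bands, in [0, 1]."""
    a = np.asarray(row_a, dtype=bool)
    b = np.asarray(row_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("fingerprints must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise UndefinedSimilarityError(
            "two empty fingerprints (failed lanes) cannot be compared"
        )
    return float(np.logical_and(a, b).sum() / union)


def jaccard_distance_matrix(matrix: BandMatrix) -> np.ndarray:
    """Pairwise Jaccard distances (1 - similarity) between lanes."""
    n = len(matrix.isolate_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - jaccard_similarity(
                matrix.presence[i], matrix.presence[j]
            )
    return d


def _validate_distance_matrix(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValidationError("distance matrix must have a zero diagonal")
    if (d < 0).any() or (d > 1 + 1e-12).any():
        raise ValidationError("distances must lie in [0, 1]")
    return d


def upgma(dist, labels: Optional[Sequence[str]] = None) -> Dendrogram:
    """Average-linkage agglomeration of a distance matrix into an ultrametric tree.

    At each step the pair of clusters at minimal distance is merged (ties
    broken by the lowest (row, column) index pair, for determinism); the
    merged node sits at height = distance / 2, and distances to the new
    cluster are size-weighted arithmetic means, which keeps every
    cluster-to-cluster distance equal to the mean of the original pairwise
    leaf distances.
    """
    d = _validate_distance_matrix(dist)
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValidationError("labels length must match matrix size")
    if n == 1:
        return Dendrogram(Node(0.0, name=str(labels[0])), [str(labels[0])])

    nodes: list[Node] = [Node(0.0, name=str(lab)) for lab in labels]
    sizes = [1] * n
    dmat = d.copy()
    active = list(range(n))

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = dmat[i, j]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, ai, aj)
        dij, ai, aj = best
        i, j = active[ai], active[aj]
        merged = Node(dij / 2.0, children=(nodes[i], nodes[j]))
        # update distances into slot i, retire slot j
        for k in active:
            if k in (i, j):
                continue
            dmat[i, k] = dmat[k, i] = (
                sizes[i] * dmat[i, k] + sizes[j] * dmat[j, k]
            ) / (sizes[i] + sizes[j])
        nodes[i] = merged
        sizes[i] += sizes[j]
        active.pop(aj)

    root = nodes[active[0]]
    return Dendrogram(root, [str(lab) for lab in labels])


def _cluster_labels() -> "list[str]":
    # A, B, ... Z, AA, AB, ...
    import itertools
    import string

    singles = list(string.ascii_uppercase)
    doubles = ["".join(p) for p in itertools.product(string.ascii_uppercase, repeat=2)]
    return singles + doubles


def assign_strains(tree: Dendrogram, similarity_cutoff: float = 85.0) -> dict:
    """Cut the dendrogram so same-strain isolates share > ``similarity_cutoff`` %.

    Tree similarity of a merge at height h is (1 - 2h) x 100 (the cophenetic
    distance between leaves joined there is 2h). Clusters are the maximal
    subtrees in which every internal merge strictly exceeds the cutoff.
    Labels run A, B, C... in order of first isolate appearance.
    """
    if not (0 < similarity_cutoff < 100):
        raise ValidationError("similarity cutoff must be in (0, 100)")

    clusters: list[tuple[str, ...]] = []

    def walk(node: Node) -> None:
        if node.is_leaf or (1.0 - 2.0 * node.height) * 100.0 > similarity_cutoff:
            clusters.append(node.leaves)
        else:
            for c in node.children:
                walk(c)

    walk(tree.root)

    first_seen = {iso: k for k, iso in enumerate(tree.leaf_order)}
    clusters.sort(key=lambda leaves: min(first_seen[x] for x in leaves))
    labels = _cluster_labels()
    assignment: dict = {}
    for label, leaves in zip(labels, clusters):
        for iso in leaves:
            assignment[iso] = label
    return assignment


def write_newick(tree: Dendrogram) -> str:
    """Serialize the dendrogram to Newick; branch lengths encode heights."""

    def fmt(node: Node, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.name}:{length:g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{length:g}"

    root = tree.root
    if root.is_leaf:
        return f"{root.name};"
    inner = ",".join(fmt(c, root.height) for c in root.children)
    return f"({inner});"
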