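"""Window-haplotype distances and neighbour-joining trees.

Genotype calls are grouped into non-overlapping windows of w consecutive
markers per chromosome (default w = 5); a sample's window haplotype is the
concatenated call string, set to missing whenever the block contains a
NoCall. Pairwise distance is the fraction of mutually defined windows with
unequal haplotypes (pairwise deletion). Trees come from the canonical
Saitou-Nei neighbour joining with the Studier-Keppler Q criterion,
deterministic tie-breaking, negative branch lengths clamped to zero, and
Newick output with a fixed child ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import CODE_TO_CALL, NOCALL, GenotypeMatrix

DEFAULT_WINDOW = 5


@dataclass
class TreeNode:
    """A rooted view of the (unrooted) NJ tree; the root is the final join."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        names: list[str] = []
        for child, _ in self.children:
            names.extend(child.leaf_names())
        return names

    def min_leaf(self) -> str:
        return min(self.leaf_names())


@dataclass
class WindowHaplotypes:
    """Ordered marker windows and the samples x windows haplotype table."""

    sample_ids: list[str]
    windows: list[tuple[str, int, int]]      # (chrom, first, last marker index)
    hap: list[list[str | None]]              # [sample][window]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def window_haplotypes(
    matrix: GenotypeMatrix, w: int = DEFAULT_WINDOW
) -> WindowHaplotypes:
    """Collapse calls into non-overlapping w-marker windows per chromosome.

    A trailing remainder of fewer than w markers on a chromosome is
    dropped. Any NoCall inside a window makes that sample's haplotype
    missing there.
    """
    if w < 1:
        raise ValueError("window width must be >= 1")
    windows: list[tuple[str, int, int]] = []
    blocks: list[np.ndarray] = []
    for chrom in matrix.chromosomes():
        idx = matrix.chrom_indices(chrom)
        for k in range(len(idx) // w):
            block = idx[k * w: (k + 1) * w]
            windows.append((chrom, int(block[0]), int(block[-1])))
            blocks.append(block)

    hap: list[list[str | None]] = []
    for i in range(matrix.n_samples):
        row = matrix.calls[i]
        sample_haps: list[str | None] = []
        for block in blocks:
            calls = row[block]
            if np.any(calls == NOCALL):
                sample_haps.append(None)
            else:
                sample_haps.append(
                    "".join(CODE_TO_CALL[int(c)] for c in calls)
                )
        hap.append(sample_haps)
    return WindowHaplotypes(list(matrix.sample_ids), windows, hap)


def haplotype_distance(
    hap_i: list[str | None], hap_j: list[str | None]
) -> float:
    """Fraction of mutually defined windows with unequal haplotypes."""
    comparable = diff = 0
    for a, b in zip(hap_i, hap_j):
        if a is None or b is None:
            continue
        comparable += 1
        if a != b:
            diff += 1
    if comparable == 0:
        raise ValueError("no comparable windows between the two samples")
    return diff / comparable


def distance_matrix(haps: WindowHaplotypes) -> DistanceMatrix:
    n = len(haps.sample_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = haplotype_distance(haps.hap[i], haps.hap[j])
            except ValueError:
                raise ValueError(
                    f"no comparable windows for pair "
                    f"({haps.sample_ids[i]}, {haps.sample_ids[j]})"
                ) from None
    return DistanceMatrix(list(haps.sample_ids), d)


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Canonical neighbour joining (Saitou-Nei, Studier-Keppler Q).

    At each step the pair minimising
    ``Q(i,j) = (m - 2) d(i,j) - r_i - r_j`` is joined; exact Q ties break
    on the lexicographically smallest pair of current node labels (a
    node's label is its smallest leaf id). The last three nodes join at a
    single internal node; negative branch lengths clamp to zero.
    """
    n = len(dist.sample_ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dist.sample_ids]
    labels: list[str] = list(dist.sample_ids)
    D = dist.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best: tuple[float, tuple[str, str], int, int] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[:2]:
                    best = (q, key[1], i, j)
        _, _, i, j = best  # type: ignore[misc]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])

        dk = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = dk[keep]
        D = newD
        new_label = min(labels[i], labels[j])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    (d01, d02, d12) = (D[0, 1], D[0, 2], D[1, 2])
    l0 = max(0.5 * (d01 + d02 - d12), 0.0)
    l1 = max(0.5 * (d01 + d12 - d02), 0.0)
    l2 = max(0.5 * (d02 + d12 - d01), 0.0)
    return TreeNode(
        children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)]
    )


def write_newick(tree: TreeNode) -> str:
    """Newick with 6-decimal branch lengths and deterministic child order.

    Children sort by the smallest leaf id in their subtree, so isomorphic
    trees serialise identically regardless of construction order.
    """

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name  # type: ignore[return-value]
        ordered = sorted(node.children, key=lambda cl: cl[0].min_leaf())
        inner = ",".join(
            f"{render(child)}:{length:.6f}" for child, length in ordered
        )
        return f"({inner})"

    return render(tree) + ";"


def tree_path_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances implied by the tree."""
    leaves = sorted(tree.leaf_names())
    index = {name: i for i, name in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def depths(node: TreeNode, acc: float) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: acc}  # type: ignore[dict-item]
        out: dict[str, float] = {}
        for child, length in node.children:
            out.update(depths(child, acc + length))
        return out

    def visit(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}  # type: ignore[dict-item]
        sub = [
            {k: v + length for k, v in visit(child).items()}
            for child, length in node.children
        ]
        for a in range(len(sub)):
            for b in range(a + 1, len(sub)):
                for la, da in sub[a].items():
                    for lb, db in sub[b].items():
                        d[index[la], index[lb]] = d[index[lb], index[la]] = (
                            da + db
                        )
        merged: dict[str, float] = {}
        for s in sub:
            merged.update(s)
        return merged

    visit(tree)
    return DistanceMatrix(leaves, d)


def build_tree(
    matrix: GenotypeMatrix, w: int = DEFAULT_WINDOW
) -> tuple[TreeNode, DistanceMatrix]:
    """Full pipeline: windows -> distances -> NJ tree."""
    haps = window_haplotypes(matrix, w)
    dist = distance_matrix(haps)
    return neighbor_joining(dist), dist
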