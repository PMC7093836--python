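"""Distance matrices and distance-based trees for consensus monomers.

Maximum-likelihood tree building belongs to external tools; here the
sequence relationships are summarized by neighbor-joining on p or K2P
distances, which is sufficient for the structural questions the library
model asks (do same-clade species group together; is the outgroup basal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .seqcore import k2p_from_pair, p_distance

__all__ = [
    "DistanceMatrix",
    "pairwise_distance_matrix",
    "nj_tree",
    "monophyly_check",
    "read_newick",
    "write_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(float))


def pairwise_distance_matrix(
    sequences: Mapping[str, str], metric: str = "p"
) -> DistanceMatrix:
    """All-pairs p or K2P distances over aligned sequences (pairwise deletion)."""
    if metric not in ("p", "k2p"):
        raise ValueError(f"unknown metric {metric!r}")
    labels = tuple(sequences)
    seqs = [sequences[l] for l in labels]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences must be aligned to equal length")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if metric == "p":
                    dij = p_distance(seqs[i], seqs[j])
                else:
                    dij = k2p_from_pair(seqs[i], seqs[j]).k2p
            except ValueError as exc:
                raise ValueError(
                    f"incomparable pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels, d)


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted, trifurcating root node).

    Negative branch lengths produced by the NJ formulas are clamped to
    zero with the deficit transferred to the sibling branch, preserving
    the joined pair's summed length.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    d = matrix.values.astype(float).copy()
    nodes = [dendropy.Node() for _ in range(n)]
    taxa = dendropy.TaxonNamespace()
    for node, label in zip(nodes, matrix.labels):
        node.taxon = taxa.new_taxon(label)
    active = list(range(n))

    def _clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return max(la, 0.0), max(lb, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if j_ < i_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dij = d[a, b]
        la = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lb = dij - la
        la, lb = _clamp(la, lb)
        parent = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        # distances from the new node to the remaining ones
        new_row = 0.5 * (d[a, :] + d[b, :] - dij)
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        nodes.append(parent)
        active = [k for k in active if k not in (a, b)] + [len(nodes) - 1]

    # connect the last three nodes to a common (unrooted) junction
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for k, lk in zip((a, b, c), (la, lb, lc)):
        nodes[k].edge.length = max(lk, 0.0)
        root.add_child(nodes[k])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def monophyly_check(tree: dendropy.Tree, group: Iterable[str],
                    outgroup: str) -> bool:
    """True iff ``group`` forms a clade once the tree is rooted on ``outgroup``."""
    group = set(group)
    work = tree.clone(depth=1)
    labels = {leaf.taxon.label for leaf in work.leaf_node_iter()}
    unknown = (group | {outgroup}) - labels
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    og_node = next(leaf for leaf in work.leaf_node_iter()
                   if leaf.taxon.label == outgroup)
    work.reroot_at_edge(og_node.edge, update_bipartitions=True)
    mrca = work.mrca(taxon_labels=sorted(group))
    clade_leaves = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return clade_leaves == group


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)
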