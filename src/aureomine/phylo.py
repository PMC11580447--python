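"""Distance-based peptide phylogeny: neighbor joining on percent-identity
distances, outgroup rooting, Newick serialization.

Distances are ``d = 1 - pid/100`` from the all-vs-all identity matrix.
Neighbor joining follows Saitou-Nei with the usual Q-criterion; on an
additive distance matrix it recovers the generating tree exactly,
topology and branch lengths, which is the correctness oracle used in
the tests.  Negative estimated branch lengths are clamped to zero with
the deficit moved to the sister branch, preserving the pair's summed
length.  Ties in the Q-criterion go to the smallest (i, j) index pair
in the current taxon order, so the result is deterministic.

Trees are :class:`skbio.TreeNode` objects (unrooted, stored with a
trifurcating root) and serialize to Newick.  Rooting places the root at
the midpoint of the outgroup's pendant branch.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from .cluster_network import IdentityMatrix


class PhylogenyError(ValueError):
    pass


class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a zero diagonal."""

    def __init__(self, ids: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise PhylogenyError("distance matrix shape does not match ids")
        if not np.allclose(values, values.T):
            raise PhylogenyError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise PhylogenyError("distance matrix diagonal must be zero")
        if (values < -1e-12).any():
            raise PhylogenyError("distances must be nonnegative")
        self.ids = list(ids)
        self.values = np.clip(values, 0.0, None)

    def __len__(self) -> int:
        return len(self.ids)


def distances_from_identity(m: IdentityMatrix) -> DistanceMatrix:
    """d = 1 - pid/100; pid 100 -> 0, pid 26.9 -> 0.731."""
    return DistanceMatrix(m.ids, 1.0 - np.asarray(m.values, dtype=float) / 100.0)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns a trifurcating-rooted tree.

    Deterministic under the smallest-(i, j) tie-break; negative branch
    lengths are clamped to 0 with the deficit moved to the sister branch.
    """
    n = len(dm)
    if n < 3:
        raise PhylogenyError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    D = dm.values.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (i, j) pair on ties
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or Q[i, j] < Q[best] - 1e-12:
                    best = (i, j)
        i, j = best
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.extend([nodes[i], nodes[j]])

        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_D = np.zeros((m - 1, m - 1))
        new_D[:-1, :-1] = D[np.ix_(keep, keep)]
        new_D[-1, :-1] = d_new[keep]
        new_D[:-1, -1] = d_new[keep]
        D = new_D
        nodes = [nodes[k] for k in keep] + [parent]

    # final trifurcation: pendant lengths from the three-point formulas
    (a, b, c) = nodes
    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (d_ab + d_ac - d_bc)
    lb = 0.5 * (d_ab + d_bc - d_ac)
    lc = 0.5 * (d_ac + d_bc - d_ab)
    la, lb = _clamp_pair(la, lb)
    lb, lc = _clamp_pair(lb, lc)
    la, lc = _clamp_pair(la, lc)
    root = TreeNode()
    a.length, b.length, c.length = la, lb, lc
    root.extend([a, b, c])
    return root


def _clamp_pair(x: float, y: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sister."""
    if x < 0:
        y += x
        x = 0.0
        if y < 0:
            y = 0.0
    elif y < 0:
        x += y
        y = 0.0
        if x < 0:
            x = 0.0
    return x, y


def root_at_outgroup(tree: TreeNode, outgroup_label: str) -> TreeNode:
    """Root at the midpoint of the outgroup's pendant branch.

    The outgroup becomes one child of the new root; all other
    relationships are preserved.  A missing label is a hard error.
    """
    matches = [tip for tip in tree.tips() if tip.name == outgroup_label]
    if not matches:
        raise PhylogenyError(f"outgroup label {outgroup_label!r} not found among leaves")
    leaf = matches[0]
    length = leaf.length if leaf.length is not None else 0.0
    rooted = tree.root_at(leaf, above=length / 2.0, branch_attrs=[])
    return rooted
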