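"""Genetic distances, neighbor-joining trees and principal coordinates.

Distances between accessions are standard binary dissimilarities over the
0/1 allele-presence profiles (Dice / Nei-Li by default — the usual choice
for banded marker data — with Jaccard and simple matching as alternatives).
Trees are built with the Saitou-Nei neighbor-joining algorithm and exported
as Newick via scikit-bio's :class:`~skbio.tree.TreeNode`, so they can be fed
directly to any phylogenetic viewer.  Ordination is classical metric PCoA:
double-centering of the squared distance matrix followed by an
eigendecomposition, with negative eigenvalues reported rather than
corrected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genotype_io import BinaryMatrix

__all__ = [
    "genetic_distance",
    "nj_tree",
    "write_newick",
    "read_newick",
    "Ordination",
    "pcoa",
]

_METRICS = ("dice", "jaccard", "simple_matching")


def genetic_distance(
    bm: BinaryMatrix, metric: str = "dice", undefined: str = "nan"
) -> pd.DataFrame:
    """Pairwise binary dissimilarity between accessions.

    With ``a`` = shared bands, ``b``/``c`` = bands private to either
    accession (counted over columns of loci scored in both):

    * ``dice``            ``1 - 2a / (2a + b + c)``
    * ``jaccard``         ``1 - a / (a + b + c)``
    * ``simple_matching`` ``(b + c) / m`` over ``m`` shared columns

    Pairs with no commonly scored locus are undefined: kept as NaN by
    default, or mean-imputed from the defined distances with
    ``undefined="mean"`` (needed when the matrix feeds tree building or
    stepwise sampling, which require complete inputs).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    if undefined not in ("nan", "mean"):
        raise ValueError("undefined must be 'nan' or 'mean'")
    X = bm.data.to_numpy(dtype=float)
    scored = (~bm.missing).to_numpy(dtype=float)
    locus_of_col = bm.data.columns.get_level_values(0)
    loci = list(bm.missing.columns)
    col_block = np.array([[l == lo for lo in loci] for l in locus_of_col], dtype=float)
    bands = X @ col_block
    cols_per_locus = col_block.sum(axis=0)

    a = X @ X.T
    s = (bands * scored) @ scored.T  # bands of row accession within shared loci
    m = (cols_per_locus * scored) @ scored.T
    b_plus_c = s + s.T - 2.0 * a
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "dice":
            d = 1.0 - 2.0 * a / (s + s.T)
        elif metric == "jaccard":
            d = 1.0 - a / (a + b_plus_c)
        else:
            d = b_plus_c / m
    d = np.where(m == 0, np.nan, d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    if undefined == "mean":
        mask = np.isnan(d)
        if mask.any():
            off = ~np.eye(len(d), dtype=bool)
            if not (off & ~mask).any():
                raise ValueError("no defined pairwise distances at all")
            d[mask] = d[off & ~mask].mean()
            np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=bm.accession_ids, columns=bm.accession_ids)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(d: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie handling.

    At each step the pair minimizing the Q-criterion is joined; among tied
    pairs the lexicographically smallest (label1, label2) wins.  Negative
    branch lengths are clamped to zero with the deficit transferred to the
    sibling edge (total path length preserved).  Returns an unrooted tree
    as a :class:`skbio.TreeNode` with a trifurcating root.
    """
    labels = list(map(str, d.index))
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = d.to_numpy(dtype=float).copy()
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    # sort key per active node = smallest leaf label underneath, for tie order
    keys = list(labels)

    while len(nodes) > 3:
        n = len(nodes)
        row_sums = D.sum(axis=1)
        Q = (n - 2) * D - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((keys[i], keys[j]))), (i, j))
            for i, j in ties
            if i < j
        )[1]
        i, j = best
        li = 0.5 * D[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        # clamp-and-transfer for negative branch lengths
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        lj = max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    # resolve the final three nodes around an unrooted center
    l0 = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    l1 = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    l2 = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = float(max(ln, 0.0))
    root = TreeNode()
    order = np.argsort([keys[k] for k in range(3)], kind="stable")
    root.extend([nodes[k] for k in order])
    return root


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string (labels quoted as needed)."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    """PCoA result: ``coordinates`` are eigenvectors scaled by the square
    root of their (positive) eigenvalues; ``percent_variance`` is computed
    over positive eigenvalues only, and any negative-eigenvalue mass (a
    sign the input distances are non-Euclidean) is reported, not patched."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    negative_eigenvalue_mass: float
    degenerate: bool = False


def pcoa(d: pd.DataFrame, n_axes: int | None = None) -> Ordination:
    """Classical (metric) principal coordinates analysis of a distance
    matrix: Gower double-centering of ``-0.5 * d**2`` then
    eigendecomposition."""
    labels = list(d.index)
    D = d.to_numpy(dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")
    n = len(labels)
    if n < 3:
        raise ValueError("PCoA needs at least 3 items")
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12
    if not pos.any():
        coords = pd.DataFrame(
            np.zeros((n, 1)), index=labels, columns=["axis1"]
        )
        return Ordination(coords, evals, np.array([]), float(evals[evals < 0].sum()), True)
    k = int(pos.sum()) if n_axes is None else min(n_axes, int(pos.sum()))
    scaled = evecs[:, :k] * np.sqrt(evals[:k])
    coords = pd.DataFrame(
        scaled, index=labels, columns=[f"axis{i + 1}" for i in range(k)]
    )
    pct = evals[:k] / evals[pos].sum() * 100.0
    return Ordination(
        coordinates=coords,
        eigenvalues=evals,
        percent_variance=pct,
        negative_eigenvalue_mass=float(evals[evals < -1e-12].sum()),
    )
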