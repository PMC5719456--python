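"""Uncorrected p-distances and neighbor-joining trees.

The distance between two aligned sequences is the uncorrected
p-distance: the proportion of compared nucleotide sites at which they
differ, with no correction for multiple substitutions at a site, rate
bias or among-site rate variation.  Sites are compared under pairwise
deletion — a column is dropped for a pair when either row carries a gap
or any non-ACGT character (N and the other ambiguity codes are treated
as missing data).

Trees are built by the Saitou–Nei neighbor-joining algorithm and carried
as unrooted :class:`skbio.TreeNode` objects (trifurcating root);
distance matrices are :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import io as _io

import numpy as np
from skbio import DistanceMatrix, TreeNode

_UNAMBIGUOUS = frozenset("ACGT")


def p_distance_pair(a: str, b: str) -> tuple[int, int]:
    """(differences, comparable sites) between two equal-length gapped rows."""
    if len(a) != len(b):
        raise ValueError("rows of an alignment must have equal length")
    comparable = 0
    diffs = 0
    for x, y in zip(a, b):
        if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS:
            comparable += 1
            if x != y:
                diffs += 1
    return diffs, comparable


def p_distance_matrix(aln) -> DistanceMatrix:
    """Pairwise-deletion p-distance matrix of an alignment.

    *aln* is an :class:`firetrace.align.Alignment` (or anything with a
    ``.records`` list of ``(id, gapped_seq)`` pairs).  A pair with zero
    comparable sites is an error naming the pair.
    """
    records = list(aln.records)
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diffs, comparable = p_distance_pair(records[i][1], records[j][1])
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {records[i][0]!r} "
                    f"and {records[j][0]!r}"
                )
            d[i, j] = d[j, i] = diffs / comparable
    return DistanceMatrix(d, ids=[rid for rid, _ in records])


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``; ties break
    toward the lexicographically smallest (i, j) index pair.  Branch
    lengths come from the two-point formulas; a negative length is
    clamped to zero with the deficit moved to the sister branch so the
    pair's total is preserved.  Returns an unrooted tree (trifurcating
    root) for n >= 3.
    """
    labels = list(dm.ids)
    d = np.array(dm.data, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix entries must be finite")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]

    while n > 3:
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # np.argmin scans row-major -> first minimum is the lexicographically
        # smallest (i, j); restrict to i < j by symmetry
        flat = int(np.argmin(np.where(np.triu(np.ones_like(q, dtype=bool), 1), q, np.inf)))
        i, j = divmod(flat, n)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # distances from the new internal node to the remaining taxa
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        du = np.maximum(du, 0.0)
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.empty((n - 1, n - 1))
        d_new[: n - 2, : n - 2] = d[np.ix_(keep, keep)]
        d_new[: n - 2, n - 2] = d_new[n - 2, : n - 2] = du[keep]
        d_new[n - 2, n - 2] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]
        n -= 1

    # terminal three-taxon star: closed-form branch lengths
    a = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    b = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    c = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode(children=nodes)
    for node, length in zip(nodes, (a, b, c)):
        node.length = max(length, 0.0)
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


_NEWICK_SPECIALS = set(" ,:;()[]'\t")


def _newick_label(name: str | None) -> str:
    if not name:
        return ""
    if any(c in _NEWICK_SPECIALS for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode) -> str:
    if node.children:
        inner = ",".join(_newick_node(c) for c in node.children)
        text = f"({inner}){_newick_label(node.name)}"
    else:
        text = _newick_label(node.name)
    if node.length is not None:
        text += f":{node.length:.6g}"
    return text


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize a tree as Newick.

    Branch lengths are printed with 6 significant digits; labels
    containing spaces or Newick metacharacters are quoted.
    """
    text = _newick_node(tree) + ";\n"
    if path is not None:
        with open(path, "w") as handle:
            handle.write(text)
    return text


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string (labels with spaces must be quoted)."""
    try:
        return TreeNode.read(_io.StringIO(text), convert_underscores=False)
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}\n  in: {text[:120]!r}") from exc


def rf_distance(t1: TreeNode, t2: TreeNode) -> float:
    """Robinson–Foulds distance (count of bipartitions unique to one tree)."""
    return t1.compare_rfd(t2)


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    """Distance matrix as TSV, labels in the first row and column."""
    with open(path, "w") as handle:
        handle.write("\t" + "\t".join(dm.ids) + "\n")
        for i, lab in enumerate(dm.ids):
            row = "\t".join(f"{v:.6g}" for v in dm.data[i])
            handle.write(f"{lab}\t{row}\n")
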