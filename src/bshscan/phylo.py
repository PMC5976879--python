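"""Distance-based phylogenetics: p/Poisson distances, neighbor joining,
bootstrap support, and Newick I/O.

Used twice in the pipeline: for the tree of representative BSH proteins
(with bootstrap support at the nodes) and for the single-marker species
tree onto which presence/absence and lifestyle metadata are mapped.
Trees are :class:`skbio.TreeNode` objects; distance matrices are
:class:`skbio.DistanceMatrix`.

Neighbor joining follows the Saitou-Nei Q-criterion with two pinned-down
details: ties in the Q matrix break on the smallest (i, j) index pair,
and a negative branch length is clamped to zero with the deficit shifted
to its sister edge (total length preserved), so the method is exact on
additive matrices and deterministic everywhere.
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path
from typing import Literal

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import ConfigError, ParseError, ValidationError
from .seqio import Msa

_GAPS = {"-", "."}


def pairwise_distance(
    msa: Msa, model: Literal["p-distance", "poisson"] = "p-distance"
) -> DistanceMatrix:
    """Pairwise distances under pairwise gap deletion.

    ``p-distance``: mismatches over compared (both-ungapped) columns.
    ``poisson``: -ln(1 - p), the Poisson multiple-hit correction; a pair
    with p >= 1 (or with no compared columns at all) raises.
    """
    if msa.n_rows < 3:
        raise ConfigError("pairwise_distance needs at least 3 rows")
    ids = list(msa.ids)
    seqs = [seq for _, seq in msa.rows]
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            compared = mismatch = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in _GAPS or b in _GAPS:
                    continue
                compared += 1
                if a != b:
                    mismatch += 1
            if compared == 0:
                raise ValidationError(
                    f"rows {ids[i]!r} and {ids[j]!r} share no ungapped columns"
                )
            p = mismatch / compared
            if model == "poisson":
                if p >= 1.0:
                    raise ValidationError(
                        f"rows {ids[i]!r} and {ids[j]!r}: p-distance {p} >= 1, "
                        "Poisson correction undefined"
                    )
                d = -np.log1p(-p)
            else:
                d = p
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids)


def _as_distance_matrix(dist) -> DistanceMatrix:
    if isinstance(dist, DistanceMatrix):
        return dist
    try:
        return DistanceMatrix(*dist) if isinstance(dist, tuple) else DistanceMatrix(dist)
    except Exception as exc:  # skbio validates symmetry/hollowness
        raise ValidationError(f"invalid distance matrix: {exc}") from exc


def neighbor_joining(dist) -> TreeNode:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root) tree.

    Exact on additive matrices: the path-length matrix of the returned
    tree reproduces the input.  Deterministic under the smallest-(i, j)
    tie-break.
    """
    dm = _as_distance_matrix(dist)
    n = dm.shape[0]
    if n < 3:
        raise ConfigError("neighbor joining needs at least 3 taxa")
    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]

    def _clamp_pair(a: float, b: float) -> tuple[float, float]:
        # Shift any deficit to the sister edge; never emit negatives.
        if a < 0:
            b += a
            a = 0.0
        if b < 0:
            a = max(0.0, a + b)
            b = 0.0
        return a, b

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin scans row-major: first minimum is the smallest (i, j) pair.
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)
        left, right = nodes[i], nodes[j]
        left.length, right.length = float(vi), float(vj)
        parent = TreeNode(children=[left, right])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # Final three-way join with closed-form branch lengths.
    a, b, c = nodes
    va = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    vb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    vc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length = _clamp_pair(va, vb)
    a.length = float(a.length)
    b.length = float(b.length)
    c.length = float(max(0.0, vc))
    return TreeNode(children=[a, b, c])


def path_length_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (for additivity checks)."""
    return tree.tip_tip_distances()


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of the unrooted tree.

    Each internal edge splits the leaves in two; the side not containing
    the alphabetically first leaf is the canonical representative.
    """
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    splits: set[frozenset] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        canonical = leaves - side if anchor in side else side
        if 2 <= len(canonical) <= len(leaves) - 2:
            splits.add(canonical)
    return splits


def bootstrap_support(
    msa: Msa,
    n_reps: int = 100,
    seed: int = 0,
    model: Literal["p-distance", "poisson"] = "p-distance",
) -> TreeNode:
    """NJ tree from the full alignment with column-bootstrap support.

    Alignment columns are resampled with replacement ``n_reps`` times,
    the tree is rebuilt per replicate, and each internal bipartition of
    the full-data tree receives the percentage of replicates containing
    it, stored as ``node.support`` (and as the internal node name for
    Newick output).  Deterministic under ``seed``.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    full = neighbor_joining(pairwise_distance(msa, model=model))
    counts: dict[frozenset, int] = {split: 0 for split in bipartitions(full)}
    rng = np.random.default_rng(seed)
    n_cols = msa.n_cols
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = Msa(
            rows=tuple(
                (rid, "".join(seq[c] for c in cols)) for rid, seq in msa.rows
            )
        )
        rep_tree = neighbor_joining(pairwise_distance(resampled, model=model))
        rep_splits = bipartitions(rep_tree)
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    leaves = frozenset(t.name for t in full.tips())
    anchor = min(leaves)
    for node in full.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        canonical = leaves - side if anchor in side else side
        if canonical in counts:
            # skbio's newick writer emits `support` as the internal label.
            node.support = 100.0 * counts[canonical] / n_reps
    return full


def read_newick(path: str | Path) -> TreeNode:
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ParseError(f"{path}: invalid Newick ({exc})") from exc


def write_newick(tree: TreeNode, path: str | Path) -> None:
    out = StringIO()
    tree.write(out, format="newick")
    Path(path).write_text(out.getvalue())
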