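"""Distance phylogenetics for ALP repeat domains.

Pairwise percent identities from a multiple sequence alignment are turned
into distances (d = 1 − pid/100), trees are built with the Saitou–Nei
neighbor-joining agglomeration, and branch robustness is assessed by
bootstrap resampling of alignment columns. Clade-averaged identity tables
summarize within- and between-group similarity.

Numerical conventions: negative NJ branch-length estimates are clamped to
zero with the deficit moved to the sibling edge; ties in the Q criterion
break to the lowest index pair so results are reproducible; bootstrap
replicate r draws from its own RNG substream keyed (seed, r), so supports
do not depend on evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .seqio import GAP, Alignment, SeqioError


# ---------------------------------------------------------------------------
# identities and distances
# ---------------------------------------------------------------------------

def percent_identity(row_i: str, row_j: str) -> float:
    """Percent identity between two gapped rows (pairwise gap deletion).

    Denominator: columns where both rows are non-gap. Numerator: those
    columns where the residues match and are not 'X'. A pair with no
    comparable columns scores 0 with a warning.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows have unequal lengths")
    comparable = 0
    matches = 0
    for a, b in zip(row_i, row_j):
        if a == GAP or b == GAP:
            continue
        comparable += 1
        if a == b and a != "X":
            matches += 1
    if comparable == 0:
        warnings.warn("no comparable columns between rows; identity set to 0")
        return 0.0
    return 100.0 * matches / comparable


def identity_to_distance(pid: float) -> float:
    """d = 1 − pid/100."""
    if not 0.0 <= pid <= 100.0:
        raise ValueError(f"percent identity out of range: {pid}")
    return 1.0 - pid / 100.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distance (or identity) matrix with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if np.isnan(v).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero diagonal")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def identity_matrix(aln: Alignment) -> pd.DataFrame:
    """All-pairs percent identities of an alignment (100 on the diagonal)."""
    n = aln.n_rows
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = percent_identity(aln.row(i), aln.row(j))
    return pd.DataFrame(m, index=aln.ids, columns=aln.ids)


def alignment_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """1 − identity/100 distances between all alignment rows."""
    n = aln.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = identity_to_distance(
                percent_identity(aln.row(i), aln.row(j))
            )
    return DistanceMatrix(labels=tuple(aln.ids), values=d)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    name: str | None = None
    length: float = 0.0           # edge length to parent (ignored at root)
    children: list["_Node"] = field(default_factory=list)
    support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _fmt_len(x: float) -> str:
    return format(float(x), ".10g")


class PhyloTree:
    """Unrooted tree with branch lengths and optional bootstrap supports.

    Stored rooted at an arbitrary internal node of degree 3 (degree 2 for
    the two-leaf case); all comparisons are on the unrooted structure via
    bipartitions and patristic distances.
    """

    def __init__(self, root: _Node):
        self.root = root

    # -- basic structure ----------------------------------------------------

    @property
    def leaf_labels(self) -> set[str]:
        return {n.name for n in self._iter_nodes() if n.is_leaf}

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self._iter_nodes() if n.is_leaf)

    def _iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        if self.n_leaves < 2:
            raise SeqioError("cannot serialize a tree with fewer than 2 leaves")

        def render(node: _Node, top: bool) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(render(c, False) for c in node.children)
                label = "" if node.support is None else str(node.support)
                body = f"({inner}){label}"
            return body if top else f"{body}:{_fmt_len(node.length)}"

        return render(self.root, True) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> _Node:
            node = _Node()
            if dnode.taxon is not None:
                node.name = dnode.taxon.label
            elif dnode.label is not None:
                try:
                    node.support = int(dnode.label)
                except ValueError:
                    node.name = dnode.label
            node.length = float(dnode.edge.length or 0.0)
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        return cls(convert(dtree.seed_node))

    # -- unrooted comparisons ------------------------------------------------

    def _leafset(self, node: _Node) -> frozenset[str]:
        return frozenset(n.name for n in PhyloTree(node)._iter_nodes() if n.is_leaf)

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Unrooted splits, each normalized to the side without the
        lexicographically smallest leaf."""
        all_leaves = self.leaf_labels
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            stack.extend(node.children)
            side = self._leafset(node)
            if ref in side:
                side = frozenset(all_leaves - side)
            if include_trivial or 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def patristic_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix."""
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def build(node: _Node) -> None:
            nid = id(node)
            adj.setdefault(nid, [])
            if node.is_leaf:
                names[nid] = node.name
            for c in node.children:
                cid = id(c)
                adj.setdefault(cid, [])
                adj[nid].append((cid, c.length))
                adj[cid].append((nid, c.length))
                build(c)

        build(self.root)
        labels = sorted(names.values())
        index = {lab: i for i, lab in enumerate(labels)}
        d = np.zeros((len(labels), len(labels)))
        for nid, lab in names.items():
            dist = {nid: 0.0}
            stack = [nid]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for mid, mlab in names.items():
                d[index[lab], index[mlab]] = dist[mid]
        return DistanceMatrix(labels=tuple(labels), values=d)

    def set_supports(self, supports: dict[frozenset[str], int]) -> None:
        """Attach bootstrap supports (percent) to matching internal edges."""
        all_leaves = self.leaf_labels
        ref = min(all_leaves)
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            stack.extend(node.children)
            if node.is_leaf:
                continue
            side = self._leafset(node)
            if ref in side:
                side = frozenset(all_leaves - side)
            if side in supports:
                node.support = supports[side]


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Exact on additive distance matrices (recovers topology and branch
    lengths); Q-criterion ties break to the lowest index pair; negative
    branch-length estimates are clamped to zero with the deficit moved to
    the sibling edge.
    """
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        half = float(dm.values[0, 1]) / 2.0
        root = _Node(children=[
            _Node(name=dm.labels[0], length=half),
            _Node(name=dm.labels[1], length=half),
        ])
        return PhyloTree(root)

    nodes: list[_Node] = [_Node(name=lab) for lab in dm.labels]
    D: list[list[float]] = [list(map(float, row)) for row in dm.values]

    while len(nodes) > 3:
        k = len(nodes)
        r = [sum(row) for row in D]
        best = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * D[i][j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i][j] + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = D[i][j] - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = _Node(children=[child_i, child_j])
        new_row = [
            0.5 * (D[i][m] + D[j][m] - D[i][j])
            for m in range(k) if m not in (i, j)
        ]
        for idx in sorted((i, j), reverse=True):
            nodes.pop(idx)
            D.pop(idx)
            for row in D:
                row.pop(idx)
        nodes.append(new)
        for row, d_new in zip(D, new_row):
            row.append(max(d_new, 0.0))
        D.append([max(x, 0.0) for x in new_row] + [0.0])

    # join the final three nodes at one internal vertex (closed form)
    a = 0.5 * (D[0][1] + D[0][2] - D[1][2])
    b = 0.5 * (D[0][1] + D[1][2] - D[0][2])
    c = 0.5 * (D[0][2] + D[1][2] - D[0][1])
    lengths = [max(x, 0.0) for x in (a, b, c)]
    for node, length in zip(nodes, lengths):
        node.length = length
    return PhyloTree(_Node(children=nodes))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _resample_columns(aln: Alignment, rng: np.random.Generator) -> Alignment:
    cols = rng.integers(0, aln.n_columns, size=aln.n_columns)
    rows = tuple(
        (rid, "".join(seq[c] for c in cols)) for rid, seq in aln.records
    )
    return Alignment(records=rows)


def bootstrap_support(aln: Alignment, n_reps: int = 1000, seed: int = 0) -> PhyloTree:
    """NJ tree of the full alignment with bootstrap supports on its edges.

    Columns are resampled with replacement ``n_reps`` times; each internal
    bipartition of the full-data tree is labeled with the percentage of
    replicate trees containing it, rounded to the nearest integer.
    Replicate r uses RNG substream (seed, r): supports are reproducible
    under a fixed seed regardless of evaluation order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be ≥ 1")
    if aln.n_rows < 3:
        raise ValueError("bootstrap needs an alignment with at least 3 rows")
    tree = nj_tree(alignment_distance_matrix(aln))
    targets = tree.bipartitions()
    counts = {split: 0 for split in targets}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        rep_tree = nj_tree(alignment_distance_matrix(_resample_columns(aln, rng)))
        for split in rep_tree.bipartitions() & targets:
            counts[split] += 1
    supports = {s: round(100.0 * c / n_reps) for s, c in counts.items()}
    tree.set_supports(supports)
    return tree


# ---------------------------------------------------------------------------
# clade identity table
# ---------------------------------------------------------------------------

def clade_identity_table(
    identities: pd.DataFrame,
    groups: dict[str, str],
) -> pd.DataFrame:
    """Within/between-group mean percent identities.

    ``identities`` is a symmetric id×id percent-identity frame (100 on the
    diagonal); every id must be grouped. Within-group means exclude
    self-pairs; a singleton group's within-mean is undefined (NaN).
    """
    missing = [i for i in identities.index if i not in groups]
    if missing:
        raise ValueError(f"ungrouped ids: {missing}")
    names = sorted(set(groups.values()))
    out = pd.DataFrame(np.nan, index=names, columns=names)
    members = {g: [i for i in identities.index if groups[i] == g] for g in names}
    for gi in names:
        for gj in names:
            a, b = members[gi], members[gj]
            if gi == gj:
                vals = [
                    identities.loc[x, y]
                    for k, x in enumerate(a) for y in a[k + 1:]
                ]
            else:
                vals = [identities.loc[x, y] for x in a for y in b]
            if vals:
                out.loc[gi, gj] = float(np.mean(vals))
    return out
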