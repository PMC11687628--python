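"""Rooted phylogenies: Newick I/O, pruning, regime painting and independent contrasts.

The central container is :class:`Phylogeny`, an array-backed rooted tree with
branch lengths in (relative) time units.  On top of it live the operations the
comparative pipeline needs: ultrametricity checks, pruning to a taxon subset
(preserving root-to-tip depths), Fitch-parsimony painting of categorical
regimes onto branches, and Felsenstein's phylogenetic independent contrasts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .exceptions import (
    MissingBranchLengthError,
    NewickParseError,
    PolytomyError,
    ValidationError,
)

__all__ = [
    "Phylogeny",
    "RegimeMap",
    "ContrastSet",
    "parse_newick",
    "check_ultrametric",
    "paint_regimes",
    "independent_contrasts",
]


class Phylogeny:
    """Rooted tree with branch lengths.

    Nodes are integers ``0..n_nodes-1``; ``parent[i]`` is the parent of node
    ``i`` (``-1`` for the root) and ``blen[i]`` is the length of the branch
    subtending node ``i``.  The root may carry a "root edge" length (a stub
    edge above the root, produced e.g. by pruning) in ``blen[root]``;
    otherwise ``blen[root]`` is 0.  Tip labels are unique strings.
    """

    def __init__(
        self,
        parent: np.ndarray,
        blen: np.ndarray,
        labels: dict[int, str],
        node_comments: dict[int, str] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        if np.any(self.blen < 0):
            raise ValidationError("negative branch length")
        self.labels = dict(labels)
        self.node_comments = dict(node_comments or {})
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        self.tip_ids = [i for i in range(n) if not self.children[i]]
        labset = [self.labels.get(i) for i in self.tip_ids]
        if any(l is None for l in labset):
            raise ValidationError("every tip must carry a label")
        if len(set(labset)) != len(labset):
            raise ValidationError("tip labels must be unique")

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def postorder(self) -> list[int]:
        """Children before parents; among siblings, child-list order."""
        out: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self.children[node]))
        out.reverse()
        return out

    def preorder(self) -> list[int]:
        out: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self.children[node]))
        return out

    def depths(self, include_root_edge: bool = False) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder():
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.blen[node]
        if include_root_edge:
            d = d + self.blen[self.root]
        return d

    def max_depth(self) -> float:
        d = self.depths()
        return float(max(d[i] for i in self.tip_ids))

    def has_polytomies(self) -> bool:
        return any(len(c) > 2 for c in self.children)

    # -------------------------------------------------------------- structure
    def mrca_matrix(self) -> np.ndarray:
        """n_tips x n_tips matrix of MRCA node ids (diagonal = the tip itself)."""
        nt = self.n_tips
        tip_index = {t: k for k, t in enumerate(self.tip_ids)}
        below: list[list[int]] = [[] for _ in range(self.n_nodes)]
        M = np.empty((nt, nt), dtype=np.int64)
        for node in self.postorder():
            if self.is_tip(node):
                k = tip_index[node]
                below[node] = [k]
                M[k, k] = node
            else:
                kids = self.children[node]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in below[kids[a]]:
                            for j in below[kids[b]]:
                                M[i, j] = M[j, i] = node
                below[node] = [k for c in kids for k in below[c]]
        return M

    def patristic_distances(self) -> np.ndarray:
        """Pairwise tip-to-tip path lengths (tips in ``tip_ids`` order)."""
        d = self.depths()
        M = self.mrca_matrix()
        td = np.array([d[i] for i in self.tip_ids])
        return td[:, None] + td[None, :] - 2.0 * d[M]

    # ------------------------------------------------------------------- I/O
    def to_newick(self, precision: int = 12) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{precision}g}"

        def rec(node: int) -> str:
            if self.is_tip(node):
                s = _quote_label(self.labels[node])
            else:
                s = "(" + ",".join(rec(c) for c in self.children[node]) + ")"
                if node in self.labels:
                    s += _quote_label(self.labels[node])
            if node in self.node_comments:
                s += f"[&{self.node_comments[node]}]"
            if self.parent[node] >= 0 or self.blen[node] > 0:
                s += ":" + fmt(self.blen[node])
            return s

        return rec(self.root) + ";"

    # ---------------------------------------------------------------- pruning
    def prune_to_taxa(self, keep: set[str] | list[str]) -> "Phylogeny":
        """Induced subtree on ``keep``; unary nodes collapsed, depths preserved.

        Branch lengths along collapsed paths are summed, so root-to-tip depths
        of retained tips are unchanged (a unary root chain becomes a root
        edge).
        """
        keep = set(keep)
        have = set(self.tip_labels)
        missing = sorted(keep - have)
        if missing:
            raise ValidationError(f"tip labels not in tree: {missing}")
        if not keep:
            raise ValidationError("keep set must be non-empty")

        keep_ids = {i for i in self.tip_ids if self.labels[i] in keep}
        retained = set()
        for node in self.postorder():
            if node in keep_ids or any(c in retained for c in self.children[node]):
                if self.is_tip(node) and node not in keep_ids:
                    continue
                retained.add(node)

        # new children lists restricted to retained nodes
        kids = {n: [c for c in self.children[n] if c in retained] for n in retained}

        new_parent: list[int] = []
        new_blen: list[float] = []
        new_labels: dict[int, str] = {}
        idmap: dict[int, int] = {}

        def add(old: int, par_new: int, length: float) -> int:
            new = len(new_parent)
            new_parent.append(par_new)
            new_blen.append(length)
            if old in self.labels:
                new_labels[new] = self.labels[old]
            idmap[old] = new
            return new

        # walk down from the old root, collapsing unary chains
        def descend(old: int, acc: float) -> tuple[int, float]:
            # follow single-child chains, accumulating length
            while old not in keep_ids and len(kids[old]) == 1:
                child = kids[old][0]
                acc += self.blen[child]
                old = child
            return old, acc

        top, root_edge = descend(self.root, self.blen[self.root])
        new_root = add(top, -1, root_edge)
        stack = [top]
        while stack:
            node = stack.pop()
            for c in kids[node]:
                tgt, length = descend(c, self.blen[c])
                add(tgt, idmap[node], length)
                stack.append(tgt)
        return Phylogeny(np.array(new_parent), np.array(new_blen), new_labels)

    # ----------------------------------------------------- polytomy handling
    def resolve_polytomies(self, epsilon_frac: float = 1e-8) -> "Phylogeny":
        """Arbitrarily bifurcate polytomies with tiny internal branches.

        New internal branches get length ``epsilon_frac * tree depth``.
        Deterministic: the first two children are grouped first.
        """
        eps = epsilon_frac * self.max_depth()
        parent = list(self.parent)
        blen = list(self.blen)
        labels = dict(self.labels)
        children = [list(c) for c in self.children]
        queue = [n for n in range(self.n_nodes) if len(children[n]) > 2]
        while queue:
            node = queue.pop()
            while len(children[node]) > 2:
                a = children[node].pop(0)
                b = children[node].pop(0)
                new = len(parent)
                parent.append(node)
                blen.append(eps)
                children.append([a, b])
                parent[a] = new
                parent[b] = new
                children[node].append(new)
        return Phylogeny(np.array(parent), np.array(blen), labels)


def _quote_label(label: str) -> str:
    if re.search(r"[\s,();:\[\]']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------- parse
def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are required on all non-root edges.  ``[&key=value]``
    comments are preserved per node (used for regime annotations).
    Polytomies are retained (``tree.has_polytomies()`` flags them).
    """
    if not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises various error types
        raise NewickParseError(f"malformed Newick: {exc}") from None

    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): k for k, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    blen = np.zeros(len(nodes))
    labels: dict[int, str] = {}
    comments: dict[int, str] = {}
    for nd in nodes:
        k = index[id(nd)]
        if nd.parent_node is not None:
            parent[k] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                name = _node_name(nd) or f"internal node #{k}"
                raise MissingBranchLengthError(
                    f"missing branch length on edge to {name}"
                )
            blen[k] = nd.edge.length
        elif nd.edge.length is not None:
            blen[k] = nd.edge.length
        name = _node_name(nd)
        if name is not None:
            labels[k] = name
        if nd.comments:
            comments[k] = ";".join(str(c).lstrip("&") for c in nd.comments)
    tree = Phylogeny(parent, blen, labels, comments)
    return tree


def _node_name(nd) -> str | None:
    if nd.taxon is not None and nd.taxon.label is not None:
        return nd.taxon.label
    if nd.label:
        return nd.label
    return None


def regime_from_comments(tree: Phylogeny) -> dict[str, str]:
    """Extract ``regime=...`` annotations from tip node comments."""
    out = {}
    for i in tree.tip_ids:
        c = tree.node_comments.get(i, "")
        m = re.search(r"regime=([A-Za-z_]+)", c)
        if m:
            out[tree.labels[i]] = m.group(1)
    return out


# ---------------------------------------------------------------- ultrametric
def check_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> tuple[bool, float]:
    """Return ``(is_ultrametric, max relative depth deviation)``."""
    d = tree.depths()
    td = np.array([d[i] for i in tree.tip_ids])
    dev = float((td.max() - td.min()) / td.max()) if td.max() > 0 else 0.0
    return dev <= rel_tol, dev


# -------------------------------------------------------------------- regimes
@dataclass
class RegimeMap:
    """Per-branch regime labels; the branch subtending node ``i`` carries
    ``branch_regime[i]``.  The root itself carries ``root_regime``."""

    branch_regime: dict[int, str]
    alphabet: tuple[str, ...]
    root_regime: str

    def __post_init__(self):
        if self.root_regime not in self.alphabet:
            raise ValidationError(f"root regime {self.root_regime!r} not in alphabet")
        for node, r in self.branch_regime.items():
            if r not in self.alphabet:
                raise ValidationError(f"regime {r!r} on branch {node} not in alphabet")

    def regime_index(self) -> dict[str, int]:
        return {r: k for k, r in enumerate(self.alphabet)}


def paint_regimes(
    tree: Phylogeny,
    tip_regimes: dict[str, str],
    root_regime: str,
    alphabet: tuple[str, ...] | None = None,
) -> RegimeMap:
    """Paint branch regimes from tip states by Fitch parsimony.

    Bottom-up pass forms Fitch state sets; the top-down pass resolves ties to
    the parent's assigned state (the root resolves to ``root_regime``).  Each
    branch carries the regime assigned to its child node.
    """
    missing = [l for l in tree.tip_labels if l not in tip_regimes]
    if missing:
        raise ValidationError(f"tips without regime assignment: {missing}")
    if alphabet is None:
        alphabet = tuple(sorted(set(tip_regimes.values()) | {root_regime}))
    bad = sorted(set(tip_regimes.values()) - set(alphabet))
    if bad or root_regime not in alphabet:
        raise ValidationError(f"regimes outside alphabet: {bad or [root_regime]}")

    state_sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if tree.is_tip(node):
            state_sets[node] = frozenset({tip_regimes[tree.labels[node]]})
        else:
            inter = frozenset.intersection(*(state_sets[c] for c in tree.children[node]))
            if inter:
                state_sets[node] = inter
            else:
                state_sets[node] = frozenset.union(
                    *(state_sets[c] for c in tree.children[node])
                )

    assigned: dict[int, str] = {}
    for node in tree.preorder():
        ss = state_sets[node]
        if node == tree.root:
            if len(ss) == 1:
                assigned[node] = next(iter(ss))
            elif root_regime in ss:
                assigned[node] = root_regime
            else:
                assigned[node] = sorted(ss)[0]
        else:
            par = assigned[tree.parent[node]]
            if len(ss) == 1:
                assigned[node] = next(iter(ss))
            elif par in ss:
                assigned[node] = par
            else:
                assigned[node] = sorted(ss)[0]

    branch_regime = {n: assigned[n] for n in range(tree.n_nodes) if n != tree.root}
    return RegimeMap(branch_regime, tuple(alphabet), assigned[tree.root])


def regime_changes(tree: Phylogeny, regimes: RegimeMap) -> int:
    """Number of branches whose regime differs from the parent's."""
    count = 0
    for node in range(tree.n_nodes):
        if node == tree.root:
            continue
        p = tree.parent[node]
        pr = regimes.root_regime if p == tree.root else regimes.branch_regime[p]
        if regimes.branch_regime[node] != pr:
            count += 1
    return count


# ------------------------------------------------------------------ contrasts
@dataclass
class ContrastSet:
    """Felsenstein's standardized independent contrasts.

    One contrast per internal node of a bifurcating tree, in postorder; the
    sign convention is first-listed child minus second.  ``variances`` are the
    sums of adjusted branch lengths; ``node_estimates`` the weighted ancestral
    values.
    """

    node_ids: np.ndarray
    contrasts: np.ndarray
    variances: np.ndarray
    node_estimates: np.ndarray
    tip_order: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contrasts)

    @property
    def root_estimate(self) -> float:
        return float(self.node_estimates[-1])


def independent_contrasts(tree: Phylogeny, tip_values: dict[str, float]) -> ContrastSet:
    """Phylogenetic independent contrasts on a fully bifurcating tree.

    At each internal node with child values ``x1, x2`` on adjusted branch
    lengths ``v1, v2``: the standardized contrast is ``(x1-x2)/sqrt(v1+v2)``,
    the node value the precision-weighted mean, and the node's own branch is
    lengthened by ``v1*v2/(v1+v2)``.
    """
    if tree.has_polytomies():
        raise PolytomyError(
            "tree contains polytomies; resolve first (Phylogeny.resolve_polytomies)"
        )
    missing = [l for l in tree.tip_labels if l not in tip_values]
    if missing:
        raise ValidationError(f"tips without trait values: {missing}")
    for node in range(tree.n_nodes):
        if node != tree.root and tree.blen[node] <= 0:
            raise ValidationError(f"non-positive branch length on edge to node {node}")

    val = np.zeros(tree.n_nodes)
    adj = tree.blen.astype(float).copy()
    node_ids, contrasts, variances, estimates = [], [], [], []
    for node in tree.postorder():
        if tree.is_tip(node):
            val[node] = tip_values[tree.labels[node]]
            continue
        kids = tree.children[node]
        if len(kids) == 1:  # unary (can arise only at a pruned root)
            c = kids[0]
            val[node] = val[c]
            adj[node] += adj[c]
            continue
        c1, c2 = kids
        v1, v2 = adj[c1], adj[c2]
        contrasts.append((val[c1] - val[c2]) / np.sqrt(v1 + v2))
        variances.append(v1 + v2)
        val[node] = (val[c1] / v1 + val[c2] / v2) / (1.0 / v1 + 1.0 / v2)
        estimates.append(val[node])
        adj[node] += v1 * v2 / (v1 + v2)
        node_ids.append(node)
    return ContrastSet(
        np.array(node_ids),
        np.array(contrasts),
        np.array(variances),
        np.array(estimates),
        tip_order=tree.tip_labels,
    )
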