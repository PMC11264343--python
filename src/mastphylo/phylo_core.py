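"""Rooted phylogenies, phylogenetic covariance matrices and independent contrasts.

Trees are parsed and pruned with :mod:`dendropy`; the quantitative layer
(shared-path covariance, Pagel-style lambda rescaling, Felsenstein's
independent contrasts) is implemented here on a flat array encoding of the
tree so that downstream Monte-Carlo work can be vectorised.

Tip labels are canonicalised on input: surrounding whitespace is trimmed,
internal whitespace runs collapse to one space, and underscores are treated
as spaces, so ``"Quercus_robur"`` and ``"Quercus robur"`` refer to the same
tip. No fuzzy taxonomic matching is attempted.
"""

from __future__ import annotations

import random
import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import DegenerateInputError, InvalidInputError, TreeError

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "ContrastSet",
    "PruneResult",
    "canonical_label",
    "read_newick",
    "prune_to",
    "covariance_from_tree",
    "lambda_rescale",
    "independent_contrasts",
]

_WS = re.compile(r"\s+")


def canonical_label(label: str) -> str:
    """Canonical form of a tip label: trimmed, underscores as spaces,
    internal whitespace collapsed."""
    return _WS.sub(" ", label.replace("_", " ").strip())


@dataclass(frozen=True)
class _TreeArrays:
    """Flat encoding of a rooted tree.

    Tips occupy indices ``0..n_tips-1`` in ``tip_labels`` order; internal
    nodes follow, numbered in postorder. ``parent[root] == -1`` and
    ``blen[root]`` is the root edge length (0 if absent).
    """

    n_tips: int
    n_nodes: int
    parent: np.ndarray          # (n_nodes,) int
    blen: np.ndarray            # (n_nodes,) float
    children: tuple             # children[i - n_tips] = int array for internal i
    postorder_internal: np.ndarray  # internal node ids, children-first
    preorder: np.ndarray        # all node ids, root-first
    depths: np.ndarray = field(init=False)

    def __post_init__(self):
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            d[v] = self.blen[v] + (d[p] if p >= 0 else 0.0)
        object.__setattr__(self, "depths", d)


class Phylogeny:
    """A validated rooted phylogeny with branch lengths.

    Parameters
    ----------
    tree : dendropy.Tree
        Ownership is taken; the tree is not copied.

    Raises
    ------
    TreeError
        Fewer than 2 tips, duplicate tip labels after canonicalisation, or
        a missing/negative/non-finite branch length.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        leaves = list(tree.leaf_node_iter())
        if len(leaves) < 2:
            raise TreeError(f"phylogeny must have >= 2 tips, got {len(leaves)}")
        labels = []
        for lf in leaves:
            raw = lf.taxon.label if lf.taxon is not None else None
            if raw is None:
                raise TreeError("unlabelled tip encountered")
            labels.append(canonical_label(raw))
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels after canonicalisation: {sorted(dupes)}")
        missing_bl = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue  # root edge length is optional
            bl = node.edge.length
            if bl is None:
                missing_bl.append(self._describe_node(node))
            elif not np.isfinite(bl) or bl < 0:
                raise TreeError(f"invalid branch length {bl!r} on edge to {self._describe_node(node)}")
        if missing_bl:
            raise TreeError(f"missing branch lengths on edges to: {missing_bl}")
        self.tip_labels: tuple = tuple(labels)
        self._leaves = leaves
        self._arrays_cache = None
        self.has_polytomies = any(
            len(n.child_nodes()) > 2 for n in tree.preorder_internal_node_iter()
        ) or len(tree.seed_node.child_nodes()) > 2
        if self.has_polytomies:
            warnings.warn("tree contains polytomies; they will be resolved (zero-length, "
                          "seeded) where a bifurcating tree is required", stacklevel=2)
        if not self.is_ultrametric(rtol=1e-6):
            warnings.warn("tree is not ultrametric (tip depths differ); accepted as-is",
                          stacklevel=2)

    @staticmethod
    def _describe_node(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        tips = [lf.taxon.label for lf in node.leaf_iter()][:3]
        return "MRCA(" + ",".join(tips) + ("..." if len(tips) == 3 else "") + ")"

    # ------------------------------------------------------------------ #

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def arrays(self) -> _TreeArrays:
        if self._arrays_cache is None:
            self._arrays_cache = self._build_arrays()
        return self._arrays_cache

    def _build_arrays(self) -> _TreeArrays:
        n = self.n_tips
        tip_index = {id(lf): i for i, lf in enumerate(self._leaves)}
        post = list(self._tree.postorder_node_iter())
        ids: dict = {}
        nxt = n
        for node in post:
            if node.is_leaf():
                ids[id(node)] = tip_index[id(node)]
            else:
                ids[id(node)] = nxt
                nxt += 1
        n_nodes = nxt
        parent = np.full(n_nodes, -1, dtype=np.int64)
        blen = np.zeros(n_nodes)
        children = [None] * (n_nodes - n)
        post_internal = []
        for node in post:
            i = ids[id(node)]
            if node.parent_node is not None:
                parent[i] = ids[id(node.parent_node)]
            if node.edge.length is not None:
                blen[i] = float(node.edge.length)
            if not node.is_leaf():
                children[i - n] = np.array([ids[id(c)] for c in node.child_nodes()],
                                           dtype=np.int64)
                post_internal.append(i)
        preorder = np.array([ids[id(node)] for node in self._tree.preorder_node_iter()],
                            dtype=np.int64)
        return _TreeArrays(n_tips=n, n_nodes=n_nodes, parent=parent, blen=blen,
                           children=tuple(children),
                           postorder_internal=np.array(post_internal, dtype=np.int64),
                           preorder=preorder)

    def tip_depths(self) -> np.ndarray:
        a = self.arrays()
        return a.depths[: a.n_tips]

    @property
    def height(self) -> float:
        return float(self.tip_depths().max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.tip_depths()
        h = d.max()
        return bool(h > 0 and (h - d.min()) <= rtol * h)

    def resolve_polytomies(self, seed: int = 0) -> "Phylogeny":
        """Return a bifurcating copy; polytomies are broken arbitrarily but
        deterministically (seeded) with zero-length edges."""
        if not self.has_polytomies:
            return self
        t = self._tree.clone(depth=1)
        t.resolve_polytomies(rng=random.Random(seed))
        for node in t.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                node.edge.length = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return Phylogeny(t)

    def write_newick(self, path=None) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def __repr__(self) -> str:
        return f"Phylogeny(n_tips={self.n_tips}, height={self.height:.4g})"


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree from ``path`` and validate it.

    Polytomies are allowed (and flagged); duplicate tip labels or missing
    branch lengths are hard errors.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick file {path}: {exc}") from exc
    return Phylogeny(tree)


def parse_newick(newick: str) -> Phylogeny:
    """Parse a Newick string (convenience twin of :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"could not parse Newick string: {exc}") from exc
    return Phylogeny(tree)


@dataclass
class PruneResult:
    tree: Phylogeny
    missing: tuple  # labels requested but absent from the source tree


def prune_to(tree: Phylogeny, keep, *, on_missing: str = "error") -> PruneResult:
    """Induced subtree on the tip set ``keep``.

    Path lengths between retained tips are preserved exactly; suppressed
    degree-2 nodes have their edge lengths summed. Labels in ``keep`` that
    are not tips of ``tree`` raise (``on_missing="error"``) or are returned
    in :attr:`PruneResult.missing` (``on_missing="report"``).
    """
    keep_canon = [canonical_label(k) for k in keep]
    have = set(tree.tip_labels)
    missing = tuple(sorted(set(k for k in keep_canon if k not in have)))
    if missing and on_missing == "error":
        raise InvalidInputError(f"labels not in tree: {list(missing)}")
    retained = [k for k in keep_canon if k in have]
    if len(set(retained)) < 2:
        raise InvalidInputError(
            f"pruning must retain >= 2 tips, got {sorted(set(retained))}")
    src = tree.dendropy_tree
    sub = src.extract_tree_with_taxa_labels(
        labels=set(l.taxon.label for l in src.leaf_node_iter()
                   if canonical_label(l.taxon.label) in set(retained)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pruned = Phylogeny(sub)
    return PruneResult(tree=pruned, missing=missing)


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance induced by a tree: C_ij is the root-to-MRCA
    path length shared by tips i and j."""

    matrix: np.ndarray
    labels: tuple
    normalized: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise InvalidInputError("covariance matrix / label length mismatch")
        if not np.allclose(m, m.T, atol=1e-10 * max(1.0, np.abs(m).max())):
            raise InvalidInputError("covariance matrix not symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def height(self) -> float:
        return float(np.diag(self.matrix).max())

    def restrict(self, labels) -> "PhyloCovariance":
        """Sub-covariance over ``labels``, reordered to match them."""
        pos = {l: i for i, l in enumerate(self.labels)}
        canon = [canonical_label(l) for l in labels]
        missing = [l for l in canon if l not in pos]
        if missing:
            raise InvalidInputError(f"labels not in covariance: {missing}")
        idx = np.array([pos[l] for l in canon])
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], tuple(canon),
                               normalized=self.normalized)


def covariance_from_tree(tree: Phylogeny, normalize: bool = True) -> PhyloCovariance:
    """Shared-path covariance matrix of the tips.

    With ``normalize=True`` the matrix is divided by its maximum diagonal
    entry so tree height is 1 — the convention used for model fitting so
    phylogenetic and residual variances live on the same scale.
    """
    a = tree.arrays()
    n = a.n_tips
    C = np.zeros((n, n))
    C[np.diag_indices(n)] = a.depths[:n]
    desc: dict = {i: np.array([i]) for i in range(n)}
    for v in a.postorder_internal:
        groups = [desc.pop(int(c)) for c in a.children[v - n]]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                C[np.ix_(groups[i], groups[j])] = a.depths[v]
                C[np.ix_(groups[j], groups[i])] = a.depths[v]
        desc[int(v)] = np.concatenate(groups)
    if normalize:
        h = C.diagonal().max()
        if h <= 0:
            raise DegenerateInputError("tree has zero height; cannot normalise")
        C = C / h
    return PhyloCovariance(C, tree.tip_labels, normalized=normalize)


def lambda_rescale(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel-style rescaling: multiply off-diagonal entries by ``lam`` in
    [0, 1]; the diagonal is unchanged."""
    if not (0.0 <= lam <= 1.0):
        raise InvalidInputError(f"lambda must be in [0, 1], got {lam}")
    d = np.diag(np.diag(C.matrix))
    return PhyloCovariance(lam * (C.matrix - d) + d, C.labels,
                           normalized=C.normalized)


@dataclass
class ContrastSet:
    """Felsenstein's phylogenetically independent contrasts for one trait."""

    contrasts: np.ndarray    # (n_tips - 1,) standardized contrasts
    node_ids: np.ndarray     # internal node id (array encoding) per contrast
    resolved_polytomies: bool = False

    @property
    def n(self) -> int:
        return len(self.contrasts)


def independent_contrasts(tree: Phylogeny, trait, *, seed: int = 0) -> ContrastSet:
    """Standardized independent contrasts of ``trait`` on ``tree``.

    ``trait`` is a mapping/Series from tip label to value; every tip must be
    covered. Polytomies are first resolved deterministically with zero-length
    edges. Each contrast is (x_i - x_j)/sqrt(b_i + b_j) with Felsenstein's
    branch-length adjustment of parent edges.
    """
    values = _trait_vector(tree, trait)
    work = tree.resolve_polytomies(seed=seed)
    resolved = work is not tree
    if resolved:
        # tip order may differ after cloning: re-extract in the new order
        values = _trait_vector(work, dict(zip(tree.tip_labels, values)))
    a = work.arrays()
    n = a.n_tips
    x = np.empty(a.n_nodes)
    b = np.empty(a.n_nodes)
    x[:n] = values
    b[:n] = a.blen[:n]
    cons, nodes = [], []
    for v in a.postorder_internal:
        kids = a.children[v - n]
        if len(kids) != 2:
            raise TreeError("internal error: tree not bifurcating after resolution")
        c1, c2 = int(kids[0]), int(kids[1])
        b1, b2 = b[c1], b[c2]
        tot = b1 + b2
        if tot <= 0:
            raise DegenerateInputError(
                "two lineages separated by zero total branch length; "
                "contrast is undefined")
        cons.append((x[c1] - x[c2]) / np.sqrt(tot))
        nodes.append(v)
        x[v] = (b2 * x[c1] + b1 * x[c2]) / tot          # weights 1/b
        b[v] = a.blen[v] + b1 * b2 / tot
    return ContrastSet(np.array(cons), np.array(nodes), resolved_polytomies=resolved)


def _trait_vector(tree: Phylogeny, trait) -> np.ndarray:
    """Align a {label: value} mapping (or pandas Series) to tip order."""
    if hasattr(trait, "to_dict"):
        trait = trait.to_dict()
    if isinstance(trait, dict):
        trait = {canonical_label(str(k)): v for k, v in trait.items()}
        missing = [l for l in tree.tip_labels if l not in trait]
        if missing:
            raise InvalidInputError(f"trait missing for tips: {missing[:10]}")
        vec = np.array([float(trait[l]) for l in tree.tip_labels])
    else:
        vec = np.asarray(trait, dtype=float)
        if vec.shape != (tree.n_tips,):
            raise InvalidInputError(
                f"trait vector length {vec.shape} != n_tips {tree.n_tips}")
    if not np.all(np.isfinite(vec)):
        bad = [tree.tip_labels[i] for i in np.where(~np.isfinite(vec))[0][:10]]
        raise InvalidInputError(f"non-finite trait values for tips: {bad}")
    return vec
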