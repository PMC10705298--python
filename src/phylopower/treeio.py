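"""Rooted, dated phylogenies: parsing, pruning, grafting, covariance structure.

Trees are stored as flat parent/child arrays with branch lengths in millions
of years (My).  Newick reading and writing is delegated to dendropy; all
structural operations (pruning with path preservation, fossil grafting,
variance-covariance computation, branch-length transforms) operate on the
array representation directly.

Branch-length unit is fixed as My throughout; no auto-detection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "FossilRecord",
    "TreeError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "graft_taxon",
    "vcv_matrix",
    "transform_branch_lengths",
    "load_fossil_records",
]

ROOT = -1

#: models accepted by :func:`transform_branch_lengths`
TRANSFORM_MODELS = ("lambda", "kappa", "delta", "OU", "EB")


class TreeError(ValueError):
    """Malformed tree, invalid labels, or an impossible structural operation."""


@dataclass
class FossilRecord:
    """A fossil (or outgroup) taxon to graft onto a dated host tree.

    ``attach_to`` names an existing tip or internal-node label; the fossil is
    added as its sister, with the new common node placed ``sister_divergence_age_my``
    before present.  ``age_my`` is the geological age of the fossil itself.
    """

    name: str
    attach_to: str
    age_my: float
    sister_divergence_age_my: float

    def __post_init__(self) -> None:
        if self.age_my < 0:
            raise TreeError(f"fossil {self.name!r}: age must be >= 0, got {self.age_my}")
        if self.sister_divergence_age_my < 0:
            raise TreeError(
                f"fossil {self.name!r}: sister divergence age must be >= 0"
            )


@dataclass
class PhyloTree:
    """Rooted tree with named tips, branch lengths in My, polytomies allowed.

    ``parent[i]`` is the parent index of node ``i`` (``-1`` for the root),
    ``blen[i]`` the length of the branch subtending node ``i`` (``nan`` at the
    root), ``label[i]`` the node label (mandatory and unique for tips).
    Node order is arbitrary but children always follow their parent
    (topological order), which the traversal code relies on.
    """

    parent: np.ndarray
    blen: np.ndarray
    label: list
    _children: list = field(default=None, repr=False, compare=False)

    # -- construction ------------------------------------------------------
    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.parent)
        if not (len(self.blen) == len(self.label) == n):
            raise TreeError("parent/blen/label arrays disagree in length")
        roots = np.flatnonzero(self.parent == ROOT)
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        # topological order: parents precede children; also rules out cycles
        order = np.arange(n)
        if not np.all(self.parent[1:] < order[1:]):
            raise TreeError("nodes are not in topological (parent-first) order")
        if self.parent[0] != ROOT:
            raise TreeError("node 0 must be the root")
        nonroot = self.blen[1:]
        if np.any(np.isnan(nonroot)):
            raise TreeError("every non-root node needs a branch length")
        if np.any(nonroot < 0):
            raise TreeError("negative branch length")
        if np.any(nonroot == 0):
            warnings.warn(
                "tree contains zero-length branches; degenerate for kappa/OU transforms",
                stacklevel=3,
            )
        tips = self.tip_indices()
        labels = [self.label[i] for i in tips]
        if any(lab in (None, "") for lab in labels):
            raise TreeError("every tip must be labelled")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        self._children = None

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def children(self, i: int) -> list:
        if self._children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for j in range(1, self.n_nodes):
                ch[self.parent[j]].append(j)
            self._children = ch
        return self._children[i]

    def tip_indices(self) -> np.ndarray:
        is_parent = np.zeros(self.n_nodes, dtype=bool)
        is_parent[self.parent[self.parent >= 0]] = True
        return np.flatnonzero(~is_parent)

    @property
    def tip_labels(self) -> list:
        return [self.label[i] for i in self.tip_indices()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.blen.copy(), list(self.label))

    # -- geometry ----------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root depth 0)."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.blen[i]
        return d

    def height(self) -> float:
        return float(self.depths().max())

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        d = self.depths()[self.tip_indices()]
        return bool(np.ptp(d) <= tol * max(1.0, d.max()))

    def node_ages(self) -> np.ndarray:
        """Age before present of every node (tips of an ultrametric tree: 0)."""
        return self.height() - self.depths()

    def index_of(self, label: str) -> int:
        try:
            return self.label.index(label)
        except ValueError:
            raise TreeError(f"no node labelled {label!r}") from None

    def ancestors(self, i: int) -> list:
        out = []
        while self.parent[i] != ROOT:
            i = self.parent[i]
            out.append(i)
        return out

    def mrca(self, labels) -> int:
        """Index of the most recent common ancestor of the named tips."""
        idx = [self.index_of(l) for l in labels]
        if len(idx) == 1:
            return idx[0]
        common = None
        for i in idx:
            anc = set(self.ancestors(i)) | {i}
            common = anc if common is None else common & anc
        depths = self.depths()
        return max(common, key=lambda j: depths[j])

    def patristic_distance(self, a: str, b: str) -> float:
        d = self.depths()
        i, j = self.index_of(a), self.index_of(b)
        m = self.mrca([a, b])
        return float(d[i] + d[j] - 2 * d[m])

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        if sorted(self.tip_labels) != sorted(other.tip_labels):
            return False
        labs = self.tip_labels
        for a in range(len(labs)):
            for b in range(a + 1, len(labs)):
                if not math.isclose(
                    self.patristic_distance(labs[a], labs[b]),
                    other.patristic_distance(labs[a], labs[b]),
                    rel_tol=1e-9,
                    abs_tol=1e-9,
                ):
                    return False
        da = dict(zip(self.tip_labels, self.depths()[self.tip_indices()]))
        db = dict(zip(other.tip_labels, other.depths()[other.tip_indices()]))
        return all(math.isclose(da[l], db[l], rel_tol=1e-9, abs_tol=1e-9) for l in labs)


# -- Newick I/O ------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (plain or quoted labels, decimal branch lengths).

    Raises :class:`TreeError` on malformed input or duplicate tip labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"malformed Newick: {exc}") from exc
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), ROOT, dtype=int)
    blen = np.full(len(nodes), np.nan)
    labels = []
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise TreeError(
                    f"missing branch length on node {nd.taxon.label if nd.taxon else i!r}"
                )
            blen[i] = nd.edge.length
        if nd.taxon is not None:
            labels.append(nd.taxon.label)
        else:
            labels.append(nd.label)
    return PhyloTree(parent, blen, labels)


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick with plain labels and decimal branch lengths."""

    def render(i: int) -> str:
        kids = tree.children(i)
        if kids:
            inner = ",".join(render(k) for k in kids)
            lab = tree.label[i] or ""
            s = f"({inner}){lab}"
        else:
            s = tree.label[i]
        if tree.parent[i] != ROOT:
            s += f":{tree.blen[i]:.10g}"
        return s

    root = int(np.flatnonzero(tree.parent == ROOT)[0])
    return render(root) + ";"


def read_newick_file(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# -- pruning and grafting --------------------------------------------------

def prune_to_taxa(tree: PhyloTree, keep) -> PhyloTree:
    """Restrict the tree to the given tips, preserving patristic distances.

    Internal nodes left with a single child are suppressed and their branch
    lengths summed; the root is collapsed downward if it becomes unbranched.
    """
    keep = set(keep)
    missing = keep - set(tree.tip_labels)
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError("need at least 2 tips to keep")

    n = tree.n_nodes
    retain = np.zeros(n, dtype=bool)
    for i in tree.tip_indices():
        if tree.label[i] in keep:
            retain[i] = True
            retain[tree.ancestors(i)] = True

    # count retained children to find pass-through nodes
    nkids = np.zeros(n, dtype=int)
    for i in range(1, n):
        if retain[i]:
            nkids[tree.parent[i]] += 1

    # a retained node survives if it is a kept tip or has >= 2 retained children
    is_tip = np.zeros(n, dtype=bool)
    is_tip[tree.tip_indices()] = True
    survive = retain & (is_tip | (nkids >= 2))

    # new root: deepest surviving ancestor-or-self common to all -> the first
    # surviving node in preorder whose retained subtree covers all kept tips.
    # Equivalently: walk from old root down through single-child chains.
    root = int(np.flatnonzero(tree.parent == ROOT)[0])
    new_root = root
    while not survive[new_root]:
        kids = [k for k in tree.children(new_root) if retain[k]]
        new_root = kids[0]

    # map each surviving node to its nearest surviving proper ancestor,
    # accumulating branch lengths through suppressed nodes
    new_index = {}
    order = [i for i in range(n) if survive[i]]
    # ensure new_root first
    order.remove(new_root)
    order = [new_root] + order
    for newi, old in enumerate(order):
        new_index[old] = newi
    parent = np.full(len(order), ROOT, dtype=int)
    blen = np.full(len(order), np.nan)
    labels = [tree.label[i] for i in order]
    for newi, old in enumerate(order):
        if old == new_root:
            continue
        b = tree.blen[old]
        p = tree.parent[old]
        while not survive[p]:
            b += tree.blen[p]
            p = tree.parent[p]
            if p == ROOT:
                break
        parent[newi] = new_index[p]
        blen[newi] = b
    # order may not be topological if new_root was deep; re-sort
    return _reorder(parent, blen, labels)


def _reorder(parent, blen, labels) -> PhyloTree:
    """Re-sort nodes into parent-first (preorder) order."""
    n = len(parent)
    kids = [[] for _ in range(n)]
    root = None
    for i in range(n):
        if parent[i] == ROOT:
            root = i
        else:
            kids[parent[i]].append(i)
    order = []
    stack = [root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(kids[i]))
    newpos = {old: new for new, old in enumerate(order)}
    np_parent = np.array(
        [ROOT if parent[o] == ROOT else newpos[parent[o]] for o in order], dtype=int
    )
    np_blen = np.array([blen[o] for o in order])
    np_labels = [labels[o] for o in order]
    return PhyloTree(np_parent, np_blen, np_labels)


def graft_taxon(tree: PhyloTree, record: FossilRecord) -> PhyloTree:
    """Graft a fossil tip as sister to ``record.attach_to``.

    The new common node is placed ``sister_divergence_age_my`` before present.
    When the fossil is younger than that divergence, its branch length is
    (divergence age - fossil age) + 1 My buffer; when its known age precedes
    the divergence, it gets a flat 1 My branch.  Path lengths among the
    original tips are unchanged.
    """
    attach = tree.index_of(record.attach_to)
    if tree.parent[attach] == ROOT:
        raise TreeError("cannot graft onto the root edge")
    ages = tree.node_ages()
    div = record.sister_divergence_age_my
    parent_age = ages[tree.parent[attach]]
    attach_age = ages[attach]
    if not (attach_age <= div <= parent_age + 1e-9):
        raise TreeError(
            f"divergence age {div} My does not fall on the edge above "
            f"{record.attach_to!r} (node age {attach_age:.4g}, parent age {parent_age:.4g})"
        )
    if record.age_my < div:
        fossil_blen = (div - record.age_my) + 1.0
    else:
        # known age precedes the divergence: flat one-million-year branch
        fossil_blen = 1.0
    if fossil_blen < 0:
        raise TreeError(f"negative branch length for fossil {record.name!r}")
    if record.name in tree.label:
        raise TreeError(f"label {record.name!r} already present in tree")

    n = tree.n_nodes
    parent = np.concatenate([tree.parent, [tree.parent[attach], n]]).astype(int)
    blen = np.concatenate([tree.blen, [parent_age - div, fossil_blen]])
    labels = list(tree.label) + [None, record.name]
    # re-hang attach under the new internal node (index n)
    parent[attach] = n
    blen[attach] = div - attach_age
    return _reorder(parent, blen, labels)


# -- covariance structure --------------------------------------------------

def vcv_matrix(tree: PhyloTree, order=None):
    """Phylogenetic variance-covariance matrix among tips.

    Entry (i, j) is the shared root-to-tip path length (depth of the MRCA);
    the diagonal holds root-to-tip distances.  Returns ``(labels, V)``.
    """
    tips = tree.tip_indices()
    labels = [tree.label[i] for i in tips]
    if order is not None:
        order = list(order)
        if sorted(order) != sorted(labels):
            raise TreeError("requested order does not match tip set")
        pos = {lab: k for k, lab in enumerate(labels)}
        tips = tips[[pos[lab] for lab in order]]
        labels = order
    depths = tree.depths()
    anc = {int(i): {int(i)} | set(tree.ancestors(int(i))) for i in tips}
    m = len(tips)
    V = np.zeros((m, m))
    for a in range(m):
        ia = int(tips[a])
        V[a, a] = depths[ia]
        for b in range(a + 1, m):
            shared = anc[ia] & anc[int(tips[b])]
            V[a, b] = V[b, a] = max(depths[j] for j in shared)
    return labels, V


# -- branch-length / covariance transforms ---------------------------------

def _check_param(model: str, p: float) -> None:
    ok = {
        "lambda": 0.0 <= p <= 1.0,
        "kappa": p >= 0.0,
        "delta": p > 0.0,
        "OU": p >= 0.0,
        "EB": p <= 0.0,
    }
    if model not in ok:
        raise TreeError(f"unknown transform model {model!r}; expected one of {TRANSFORM_MODELS}")
    if not ok[model]:
        raise TreeError(f"{model} parameter {p} out of admissible range")


def _depth_map(model: str, p: float, T: float):
    """Monotone map applied to node depths for depth-transform models."""
    if model == "delta":
        return lambda s: np.power(s, p)
    if model == "EB":
        if p == 0.0:
            return lambda s: s
        return lambda s: np.expm1(p * np.asarray(s, dtype=float)) / p
    if model == "OU":
        if p == 0.0:
            return lambda s: s
        a = 2.0 * p
        return lambda s: math.exp(-a * T) * np.expm1(a * np.asarray(s, dtype=float)) / a
    raise AssertionError(model)


def transform_branch_lengths(obj, model: str, parameter: float):
    """Apply an evolutionary-model rescaling to a tree or a VCV matrix.

    ``obj`` is either a :class:`PhyloTree` or a ``(labels, V)`` pair as
    returned by :func:`vcv_matrix`.  Semantics: lambda scales off-diagonal
    covariances; kappa raises each branch length to the power kappa; delta
    raises node depths to the power delta; OU applies the Ornstein-Uhlenbeck
    covariance decay (ultrametric trees only in tree form); EB applies an
    exponentially decelerating (rate <= 0) rate through time.  Neutral values
    (lambda=1, kappa=1, delta=1, OU=0, EB=0) return the input unchanged.
    """
    _check_param(model, parameter)
    if isinstance(obj, PhyloTree):
        return _transform_tree(obj, model, parameter)
    labels, V = obj
    return labels, _transform_vcv(np.asarray(V, dtype=float), model, parameter)


def _transform_tree(tree: PhyloTree, model: str, p: float) -> PhyloTree:
    if model == "lambda":
        if p == 1.0:
            return tree.copy()
        depths = tree.depths()
        tips = set(tree.tip_indices().tolist())
        blen = tree.blen.copy()
        for i in range(1, tree.n_nodes):
            if i in tips:
                # stretch terminal branch so the tip keeps its depth
                blen[i] = tree.blen[i] + (1.0 - p) * depths[tree.parent[i]]
            else:
                blen[i] = p * tree.blen[i]
        return PhyloTree(tree.parent.copy(), blen, list(tree.label))
    if model == "kappa":
        if p == 1.0:
            return tree.copy()
        blen = tree.blen.copy()
        blen[1:] = np.power(blen[1:], p)  # kappa of a zero branch stays zero
        return PhyloTree(tree.parent.copy(), blen, list(tree.label))
    # depth-map family
    if model == "OU" and p > 0 and not tree.is_ultrametric():
        raise TreeError("OU tree transform requires an ultrametric tree")
    if (model, p) in (("delta", 1.0), ("EB", 0.0), ("OU", 0.0)):
        return tree.copy()
    depths = tree.depths()
    f = _depth_map(model, p, tree.height())
    nd = f(depths)
    blen = tree.blen.copy()
    for i in range(1, tree.n_nodes):
        blen[i] = nd[i] - nd[tree.parent[i]]
    return PhyloTree(tree.parent.copy(), blen, list(tree.label))


def _transform_vcv(V: np.ndarray, model: str, p: float) -> np.ndarray:
    if model == "lambda":
        W = p * V
        np.fill_diagonal(W, np.diag(V))
        return W
    if model == "kappa":
        raise TreeError("kappa needs branch lengths; apply it to a tree, not a VCV")
    if model == "OU":
        if p == 0.0:
            return V.copy()
        a = 2.0 * p
        d = np.diag(V)
        Ti = d[:, None]
        Tj = d[None, :]
        return np.exp(-p * (Ti + Tj - 2 * V)) * (-np.expm1(-a * V)) / a
    f = _depth_map(model, p, float(np.max(np.diag(V))))
    return f(V)


# -- fossil records CSV ----------------------------------------------------

def load_fossil_records(path) -> list:
    """Read fossil records from a CSV with columns
    name, attach_to, age_my, sister_divergence_age_my."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"name", "attach_to", "age_my", "sister_divergence_age_my"}
    missing = required - set(df.columns)
    if missing:
        raise TreeError(f"fossil CSV missing columns: {sorted(missing)}")
    return [
        FossilRecord(
            name=row["name"],
            attach_to=row["attach_to"],
            age_my=float(row["age_my"]),
            sister_divergence_age_my=float(row["sister_divergence_age_my"]),
        )
        for _, row in df.iterrows()
    ]
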