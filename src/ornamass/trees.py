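"""Time-scaled phylogenies for fossil comparative analysis.

A :class:`TimeTree` is a rooted tree whose branch lengths are durations in
millions of years (Ma) and whose tips need not be contemporaneous: extinct
taxa sit at their stratigraphic ages above the present.  The module provides
Newick I/O (parsing via dendropy), the three a-posteriori time-scaling
methods used for fossil cladograms (ABA, MBL, Equal), branch-length
consensus over calibration replicates, clade trimming at a most recent
common ancestor, the phylogenetic variance-covariance matrix, and the Pagel
lambda/kappa/delta covariance transforms used by generalized least squares.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "TimeTree",
    "SimmapTree",
    "TipDateTable",
    "PhyloCov",
    "TransformParams",
    "NewickParseError",
    "TimescaleError",
    "parse_newick",
    "write_newick",
    "write_simmap",
    "timescale",
    "aba",
    "mbl",
    "equal",
    "consensus_tree",
    "mrca_trim",
    "phylo_vcv",
    "apply_transforms",
]


class NewickParseError(ValueError):
    """Malformed Newick input; message carries the character offset when known."""


class TimescaleError(ValueError):
    """A time-scaling request that cannot be satisfied."""


class Node:
    """Tree node. ``length`` is the duration (Ma) of the branch subtending it.

    ``segments`` (used by painted/SIMMAP trees) is an ordered list of
    ``(state, duration)`` pairs running rootward -> tipward whose durations
    sum to ``length``.
    """

    __slots__ = ("label", "length", "children", "parent", "segments")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.segments: list[tuple[str, float]] | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


class TimeTree:
    """Rooted tree with branch durations in Ma and (possibly fossil) tip ages.

    ``root_age`` is the age of the root in Ma before present; tip ages are
    derived as ``root_age - root_to_tip_path`` and may be positive for
    extinct taxa.
    """

    def __init__(self, root: Node, root_age: float | None = None):
        self.root = root
        if root_age is None:
            root_age = max(self.depths_of_tips().values(), default=0.0)
        self.root_age = float(root_age)
        self._check_labels()

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        stack, out = [self.root], []
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(v.children)
        return reversed(out)

    def preorder(self):
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(v.children))

    def tips(self) -> list[Node]:
        return [v for v in self.preorder() if v.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def _check_labels(self):
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")

    # -- geometry ----------------------------------------------------------
    def depths(self) -> dict[Node, float]:
        """Distance of every node from the root (root depth 0)."""
        d = {self.root: 0.0}
        for v in self.preorder():
            if v is not self.root:
                d[v] = d[v.parent] + (v.length or 0.0)
        return d

    def depths_of_tips(self) -> dict[str, float]:
        d = self.depths()
        return {v.label: d[v] for v in self.tips()}

    def tip_ages(self) -> dict[str, float]:
        """Age (Ma before present) of every tip; 0 = the youngest possible."""
        return {lab: self.root_age - dep for lab, dep in self.depths_of_tips().items()}

    def node_ages(self) -> dict[Node, float]:
        d = self.depths()
        return {v: self.root_age - dep for v, dep in d.items()}

    def is_binary(self) -> bool:
        return all(len(v.children) in (0, 2) for v in self.preorder())

    def find_tip(self, label: str) -> Node:
        for t in self.tips():
            if t.label == label:
                return t
        raise KeyError(f"tip {label!r} not in tree")

    def mrca(self, a: str, b: str) -> Node:
        na, nb = self.find_tip(a), self.find_tip(b)
        anc = set()
        v = na
        while v is not None:
            anc.add(id(v))
            v = v.parent
        v = nb
        while v is not None:
            if id(v) in anc:
                return v
            v = v.parent
        raise RuntimeError("disconnected tree")  # pragma: no cover

    def copy(self) -> "TimeTree":
        def rec(v: Node) -> Node:
            w = Node(v.label, v.length)
            if v.segments is not None:
                w.segments = list(v.segments)
            for c in v.children:
                w.add_child(rec(c))
            return w

        t = object.__new__(type(self))
        TimeTree.__init__(t, rec(self.root), self.root_age)
        return t

    def __repr__(self):
        return f"<{type(self).__name__} {self.n_tips} tips, root_age={self.root_age:.3g} Ma>"


class SimmapTree(TimeTree):
    """A TimeTree whose branches are partitioned into regime-painted segments.

    Every non-root node carries ``segments``: ordered ``(state, duration)``
    pairs, rootward to tipward, summing to the branch length.  The regime at
    the rootward end of the root's oldest segment is taken as the root state.
    """

    def __init__(self, root: Node, root_age: float | None = None):
        super().__init__(root, root_age)
        self.validate_segments()

    def validate_segments(self):
        for v in self.preorder():
            if v is self.root:
                continue
            if v.segments is None:
                raise ValueError(f"branch above {v.label or 'an internal node'} is unpainted")
            tot = sum(d for _, d in v.segments)
            if not math.isclose(tot, v.length or 0.0, rel_tol=1e-8, abs_tol=1e-10):
                raise ValueError("segment durations do not sum to branch length")

    def root_state(self):
        # oldest segment of any child of the root
        return self.root.children[0].segments[0][0]

    def node_state(self, v: Node):
        """Regime at a node: state of the tipward end of its branch painting."""
        if v is self.root:
            return self.root_state()
        return v.segments[-1][0]


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _precheck_newick(text: str):
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at character offset {i}")
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '(' at end of string (length {len(text)})")
    if ";" not in text:
        raise NewickParseError(f"missing ';' terminator (string length {len(text)})")


def parse_newick(text: str) -> TimeTree:
    """Parse a Newick string with branch lengths into a :class:`TimeTree`.

    Every branch except the root's must carry an explicit length; a missing
    length raises rather than being silently read as zero.
    """
    _precheck_newick(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"newick parse failed: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # root edge length, if any, is dropped
    missing = []
    stack = list(root.children)
    while stack:
        v = stack.pop()
        if v.length is None:
            missing.append(v.label or "<internal>")
        stack.extend(v.children)
    if missing:
        raise NewickParseError(
            f"branch length missing above: {sorted(missing)} (no silent zero)"
        )
    return TimeTree(root)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_newick(tree: TimeTree) -> str:
    def rec(v: Node) -> str:
        if v.is_tip:
            core = v.label or ""
        else:
            core = "(" + ",".join(rec(c) for c in v.children) + ")"
            if v.label:
                core += v.label
        if v.parent is not None:
            core += f":{_fmt(v.length)}"
        return core

    return rec(tree.root) + ";"


def write_simmap(tree: SimmapTree) -> str:
    """Serialize a painted tree in the SIMMAP segment notation.

    Each branch is written ``:{state,dur:state,dur}`` with segments ordered
    rootward to tipward.
    """

    def rec(v: Node) -> str:
        if v.is_tip:
            core = v.label or ""
        else:
            core = "(" + ",".join(rec(c) for c in v.children) + ")"
        if v.parent is not None:
            seg = ":".join(f"{s},{_fmt(d)}" for s, d in v.segments)
            core += ":{" + seg + "}"
        return core

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Tip dates and time-scaling
# ---------------------------------------------------------------------------

@dataclass
class TipDateTable:
    """First/last appearance dates (Ma before present) per taxon.

    ``fad >= lad`` per row (older bound first).
    """

    table: pd.DataFrame  # columns: taxon, fad, lad

    def __post_init__(self):
        t = self.table
        required = {"taxon", "fad", "lad"}
        if not required.issubset(t.columns):
            raise ValueError(f"tip date table needs columns {sorted(required)}")
        bad = t[t.fad < t.lad]
        if len(bad):
            raise ValueError(f"fad < lad for taxa: {list(bad.taxon)}")
        self._by_taxon = {r.taxon: (float(r.fad), float(r.lad)) for r in t.itertuples()}

    @classmethod
    def read_tsv(cls, path) -> "TipDateTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    def __contains__(self, taxon):
        return taxon in self._by_taxon

    def age(self, taxon: str, mode: str = "midpoint", rng: np.random.Generator | None = None) -> float:
        fad, lad = self._by_taxon[taxon]
        if mode == "midpoint":
            return 0.5 * (fad + lad)
        if mode == "uniform":
            if rng is None:
                raise ValueError("uniform tip dating needs an rng")
            return float(rng.uniform(lad, fad))
        raise ValueError(f"unknown dating mode {mode!r}")


def _ages_to_tree(tree: TimeTree, ages: dict[Node, float]) -> TimeTree:
    out = tree.copy()
    # rebuild mapping by parallel traversal
    pairs = list(zip(tree.preorder(), out.preorder()))
    for old, new in pairs:
        if old.parent is not None:
            new.length = ages[_parent_of(old)] - ages[old]
    out.root_age = ages[tree.root]
    return out


def _parent_of(v: Node) -> Node:
    return v.parent


def aba(tree: TimeTree, vartime: float = 1.0) -> TimeTree:
    """All Branches Additive: add ``vartime`` Ma to every branch.

    Root-to-tip paths grow by (number of edges on the path) x vartime, so
    relative tip ages are distorted; the root age is re-anchored so the
    oldest implied tip age is preserved.
    """
    out = tree.copy()
    for v in out.preorder():
        if v.parent is not None:
            v.length = v.length + vartime
    old_ages = tree.tip_ages()
    depths = out.depths_of_tips()
    out.root_age = max(old_ages[lab] + depths[lab] for lab in depths)
    return out


def mbl(tree: TimeTree, vartime: float = 1.0, max_root_age: float | None = None) -> TimeTree:
    """Minimum Branch Length: raise every branch to >= vartime.

    The extra time on a short branch is debited from its ancestor branches
    (a node needing room moves older, shortening its own subtending branch,
    cascading rootward).  Tip ages are untouched.  The root is free to move
    older unless ``max_root_age`` caps it, in which case infeasibility is an
    error rather than a silent clamp.
    """
    ages = tree.node_ages()
    new_ages: dict[Node, float] = {}
    for v in tree.postorder():
        if v.is_tip:
            new_ages[v] = ages[v]
        else:
            new_ages[v] = max(ages[v], max(new_ages[c] + vartime for c in v.children))
    if max_root_age is not None and new_ages[tree.root] > max_root_age + 1e-12:
        raise TimescaleError(
            f"MBL infeasible: root would need age {new_ages[tree.root]:.6g} Ma "
            f"> allowed {max_root_age:.6g} Ma"
        )
    return _ages_to_tree(tree, new_ages)


def equal(tree: TimeTree, vartime: float = 1.0) -> TimeTree:
    """Equal method: extend the root by ``vartime`` and absorb zero branches.

    Each zero-length branch borrows time from the nearest ancestral branch
    with positive duration: that donor's duration is divided equally among
    itself and the run of zero-length branches below it.  The root extension
    provides the donor of last resort.  Tip ages are preserved; branches are
    processed in preorder (documented order dependence for pathological
    paintings of multiple zero siblings).
    """
    ages = dict(tree.node_ages())
    root_stem = vartime  # donatable time above the root
    for v in tree.preorder():
        if v is tree.root:
            continue
        if ages[v.parent] - ages[v] > 1e-12:
            continue
        # rootward run of zero-length branches: v (tipward-most) .. chain[-1]
        chain = [v]
        a = v.parent
        while a is not tree.root and ages[a.parent] - ages[a] <= 1e-12:
            chain.append(a)
            a = a.parent
        k = len(chain)
        if a is tree.root:
            # donor of last resort: the root extension
            share = root_stem / (k + 1)
            ages[tree.root] = ages[tree.root] + share * k
            root_stem = share
            cur = ages[tree.root]
        else:
            # branch above `a` is the nearest positive ancestral branch
            donor_len = ages[a.parent] - ages[a]
            share = donor_len / (k + 1)
            ages[a] = ages[a.parent] - share
            cur = ages[a]
        # interpolate intermediate chain nodes; v itself keeps its age,
        # ending with a branch of exactly `share` above it
        for w in chain[::-1][:-1]:
            cur -= share
            ages[w] = cur
    # tips never moved; rebuild
    out = _ages_to_tree(tree, ages)
    bad = [v for v in out.preorder() if v.parent is not None and v.length < -1e-9]
    if bad:
        raise TimescaleError("equal scaling produced a negative branch")
    return out


def basic_timescale(
    tree: TimeTree,
    dates: TipDateTable,
    mode: str = "midpoint",
    rng: np.random.Generator | None = None,
) -> TimeTree:
    """Minimal a-posteriori scaling: each node as old as its oldest descendant.

    Produces zero-length branches wherever a node and its oldest descendant
    tip coincide; the ABA/MBL/Equal adjustments repair those.
    """
    missing = [lab for lab in tree.tip_labels if lab not in dates]
    if missing:
        raise TimescaleError(f"undatable tips (no date row): {sorted(missing)}")
    ages: dict[Node, float] = {}
    for v in tree.postorder():
        if v.is_tip:
            ages[v] = dates.age(v.label, mode=mode, rng=rng)
        else:
            ages[v] = max(ages[c] for c in v.children)
    return _ages_to_tree(tree, ages)


def timescale(
    tree: TimeTree,
    dates: TipDateTable,
    method: str = "MBL",
    vartime: float = 1.0,
    seed: int | None = None,
    date_mode: str = "midpoint",
    max_root_age: float | None = None,
) -> TimeTree:
    """Time-scale a cladogram against tip dates with ABA, MBL or Equal.

    ``date_mode='uniform'`` draws each tip age uniformly within its
    (FAD, LAD) interval using ``seed``, reproducing the replicate-calibration
    scheme; the default uses interval midpoints.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    base = basic_timescale(tree, dates, mode=date_mode, rng=rng)
    m = method.upper()
    if m == "ABA":
        return aba(base, vartime)
    if m == "MBL":
        return mbl(base, vartime, max_root_age=max_root_age)
    if m == "EQUAL":
        return equal(base, vartime)
    raise ValueError(f"unknown time-scaling method {method!r}")


# ---------------------------------------------------------------------------
# Consensus and trimming
# ---------------------------------------------------------------------------

def _clade_map(tree: TimeTree) -> dict[frozenset, float]:
    clades: dict[Node, frozenset] = {}
    out = {}
    for v in tree.postorder():
        if v.is_tip:
            clades[v] = frozenset([v.label])
        else:
            clades[v] = frozenset().union(*(clades[c] for c in v.children))
        if v.parent is not None:
            out[clades[v]] = v.length
    return out


def consensus_tree(trees: list[TimeTree]) -> TimeTree:
    """Mean-branch-length consensus over trees sharing one topology."""
    if not trees:
        raise ValueError("no trees given")
    maps = [_clade_map(t) for t in trees]
    ref = maps[0]
    for i, m in enumerate(maps[1:], start=2):
        if set(m) != set(ref):
            diff = sorted(set(m).symmetric_difference(set(ref)), key=sorted)[0]
            raise ValueError(
                f"topology mismatch at tree {i}: conflicting bipartition {sorted(diff)}"
            )
    out = trees[0].copy()
    clades: dict[Node, frozenset] = {}
    for v in out.postorder():
        if v.is_tip:
            clades[v] = frozenset([v.label])
        else:
            clades[v] = frozenset().union(*(clades[c] for c in v.children))
        if v.parent is not None:
            v.length = float(np.mean([m[clades[v]] for m in maps]))
    out.root_age = float(np.mean([t.root_age for t in trees]))
    return out


def mrca_trim(tree: TimeTree, tip_a: str, tip_b: str, keep: str = "outside") -> TimeTree:
    """Keep or drop the clade descending from MRCA(tip_a, tip_b).

    ``keep='outside'`` removes the clade and suppresses the resulting
    degree-2 nodes (their branch durations summed); ``keep='inside'``
    returns the clade itself as a tree rooted at the MRCA.  Tip ages of
    retained taxa are preserved.
    """
    node = tree.mrca(tip_a, tip_b)
    ages = tree.node_ages()
    if keep == "inside":
        if node is tree.root:
            return tree.copy()

        def rec(v: Node) -> Node:
            w = Node(v.label, v.length)
            if v.segments is not None:
                w.segments = list(v.segments)
            for c in v.children:
                w.add_child(rec(c))
            return w

        root = rec(node)
        root.length = None
        out = TimeTree(root, root_age=ages[node])
        if out.n_tips < 3:
            raise ValueError("trim would leave fewer than 3 tips")
        return out
    if keep != "outside":
        raise ValueError("keep must be 'inside' or 'outside'")
    if node is tree.root:
        raise ValueError("cannot drop the whole tree (MRCA is the root)")

    out = tree.copy()
    # find corresponding node in the copy by parallel traversal
    mapping = dict(zip(tree.preorder(), out.preorder()))
    target = mapping[node]
    parent = target.parent
    parent.children.remove(target)
    # suppress unifurcations up the tree
    v = parent
    while v is not None:
        if len(v.children) == 1 and v.parent is not None:
            (child,) = v.children
            child.length = child.length + v.length
            gp = v.parent
            gp.children[gp.children.index(v)] = child
            child.parent = gp
            v = gp
        else:
            v = v.parent
    root = out.root
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    new = TimeTree(root)
    # root age: preserve absolute calibration of retained tips
    old_tip_ages = tree.tip_ages()
    dep = new.depths_of_tips()
    new.root_age = max(old_tip_ages[lab] + dep[lab] for lab in dep)
    if new.n_tips < 3:
        raise ValueError("trim would leave fewer than 3 tips")
    return new


# ---------------------------------------------------------------------------
# Phylogenetic covariance and Pagel transforms
# ---------------------------------------------------------------------------

@dataclass
class PhyloCov:
    """Shared-path-length matrix: C[i,j] = depth of MRCA(i,j) from the root."""

    matrix: np.ndarray
    taxa: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix/taxa size mismatch")

    def reorder(self, taxa: list[str]) -> "PhyloCov":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCov(self.matrix[np.ix_(idx, idx)], list(taxa))


@dataclass(frozen=True)
class TransformParams:
    """Pagel branch-length/covariance transforms; (1, 1, 1) is the identity."""

    lam: float = 1.0
    kappa: float = 1.0
    delta: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lambda must be in [0,1], got {self.lam}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")


def phylo_vcv(tree: TimeTree) -> PhyloCov:
    """Build the n x n phylogenetic variance-covariance matrix."""
    tips = tree.tips()
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    depths = tree.depths()
    for v in tree.preorder():
        if v.parent is not None and v.length < 0:
            raise ValueError("negative branch length in tree")
    C = np.zeros((n, n))
    clade: dict[Node, list[int]] = {}
    for v in tree.postorder():
        if v.is_tip:
            clade[v] = [index[id(v)]]
            C[clade[v][0], clade[v][0]] = depths[v]
        else:
            kids = [clade[c] for c in v.children]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    C[np.ix_(kids[i], kids[j])] = depths[v]
                    C[np.ix_(kids[j], kids[i])] = depths[v]
            clade[v] = [x for k in kids for x in k]
    return PhyloCov(C, [t.label for t in tips])


def apply_transforms(cov: PhyloCov, tree: TimeTree, params: TransformParams) -> PhyloCov:
    """Apply kappa (branch powers), delta (depth powers), lambda (off-diagonal).

    Order: kappa reshapes branch lengths and the covariance is rebuilt from
    the tree; delta raises every matrix entry (an MRCA depth) to its power;
    lambda multiplies the off-diagonal entries only.
    """
    if params.kappa != 1.0:
        t2 = tree.copy()
        for v in t2.preorder():
            if v.parent is not None:
                v.length = float(v.length) ** params.kappa if v.length > 0 else 0.0
        C = phylo_vcv(t2).matrix
    else:
        C = cov.matrix.copy()
    if params.delta != 1.0:
        if (C < 0).any():
            raise ValueError("delta transform needs nonnegative covariances")
        C = C ** params.delta
    if params.lam != 1.0:
        diag = np.diag(C).copy()
        C = C * params.lam
        np.fill_diagonal(C, diag)
    return PhyloCov(C, list(cov.taxa))
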