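"""Ultrametric dated trees (chronograms) and branch segmentation.

Branch lengths are absolute time in millions of years (my); node ages are
measured in millions of years before present (mya), zero at the tips and
increasing rootward.  Time-stratified likelihoods require each branch to
be cut at stratum boundaries, which :func:`slice_branch` does under a
half-open convention: a boundary age belongs to the *younger* stratum.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy

__all__ = [
    "Node",
    "Chronogram",
    "BranchSegment",
    "parse_newick",
    "read_newick",
    "write_newick",
    "slice_branch",
    "ChronogramError",
]

#: Relative tolerance for the ultrametricity check, as a fraction of root age.
ULTRAMETRIC_RTOL = 1e-6


class ChronogramError(ValueError):
    """Raised for trees that violate chronogram invariants."""


@dataclass
class Node:
    """A node of a rooted binary chronogram; ``age`` is in mya (0 at tips)."""

    label: Optional[str] = None
    age: float = 0.0
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = field(default=None, repr=False)

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> float:
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


@dataclass
class Chronogram:
    """A rooted, binary, ultrametric dated tree."""

    root: Node

    def __post_init__(self) -> None:
        self.validate()

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.tips())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    @property
    def root_age(self) -> float:
        return self.root.age

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        labels = [t.label for t in self.tips()]
        if any(lb is None for lb in labels):
            raise ChronogramError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            raise ChronogramError("tip labels must be unique")
        for node in self.preorder():
            if not node.is_tip and len(node.children) != 2:
                raise ChronogramError(
                    "polytomy (or unary node) encountered; the cladogenesis "
                    "model is defined for strictly bifurcating trees"
                )
            for child in node.children:
                if child.age > node.age + ULTRAMETRIC_RTOL * max(self.root.age, 1.0):
                    raise ChronogramError(
                        f"child age {child.age} exceeds parent age {node.age}"
                    )
        tol = ULTRAMETRIC_RTOL * max(self.root.age, 1.0)
        for tip in self.tips():
            if abs(tip.age) > tol:
                raise ChronogramError(
                    f"tree is not ultrametric: tip {tip.label!r} sits at age "
                    f"{tip.age:.6g}, beyond tolerance {tol:.3g}"
                )

    def find(self, label: str) -> Node:
        for node in self.preorder():
            if node.label == label:
                return node
        raise KeyError(label)

    def mrca(self, labels: Sequence[str]) -> Node:
        """Most recent common ancestor of the given tip labels."""
        want = set(labels)
        below: dict[int, set] = {}
        for node in self.postorder():
            if node.is_tip:
                below[id(node)] = {node.label} & want
            else:
                below[id(node)] = set().union(*(below[id(c)] for c in node.children))
            if below[id(node)] == want:
                return node
        raise KeyError(f"labels not all present: {sorted(want)}")


@dataclass(frozen=True)
class BranchSegment:
    """A piece of a branch lying within a single time stratum."""

    older_age: float
    younger_age: float
    stratum_index: int

    @property
    def duration(self) -> float:
        return self.older_age - self.younger_age


def _ages_from_dendropy(tree: dendropy.Tree) -> Node:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ChronogramError("every branch must carry a length")
    # depth from root, then age = max depth - depth
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        depth[id(nd)] = depth[id(nd.parent_node)] + nd.edge.length
    max_depth = max(depth[id(lf)] for lf in tree.leaf_node_iter())

    def convert(nd: dendropy.Node) -> Node:
        label = nd.taxon.label if nd.taxon is not None else nd.label
        node = Node(label=label, age=max_depth - depth[id(nd)])
        for ch in nd.child_nodes():
            node.add_child(convert(ch))
        return node

    return convert(tree.seed_node)


def parse_newick(text: str) -> Chronogram:
    """Parse a Newick string with branch lengths into a validated Chronogram."""
    tree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    root = _ages_from_dendropy(tree)
    return Chronogram(root)


def read_newick(path) -> Chronogram:
    with open(path) as fh:
        return parse_newick(fh.read())


def _to_dendropy(chrono: Chronogram) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def convert(node: Node, dnode: dendropy.Node) -> None:
        for child in node.children:
            dchild = dendropy.Node()
            dchild.edge.length = node.age - child.age
            dnode.add_child(dchild)
            if child.is_tip:
                dchild.taxon = taxa.new_taxon(child.label)
            else:
                if child.label:
                    dchild.label = child.label
                convert(child, dchild)

    convert(chrono.root, tree.seed_node)
    return tree


def write_newick(chrono: Chronogram, path=None) -> str:
    """Serialize as Newick (branch lengths in my); returns the string."""
    tree = _to_dendropy(chrono)
    buf = io.StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def slice_branch(
    parent_age: float,
    child_age: float,
    boundaries: Sequence[float],
    oldest_bound: Optional[float] = None,
) -> list[BranchSegment]:
    """Cut a branch at stratum boundaries, rootward segment first.

    ``boundaries`` are the internal stratum boundary ages in increasing
    order (e.g. ``(3, 20, 30, 40)`` for strata 0-3, 3-20, 20-30, 30-40,
    40-oldest).  Strata are half-open ``[lower, upper)`` in age, so a
    segment ending exactly on a boundary produces no zero-length pieces.
    If ``oldest_bound`` is given, a branch extending to or beyond it is a
    configuration error.
    """
    if not parent_age > child_age >= 0:
        raise ValueError(f"need parent_age > child_age >= 0, got ({parent_age}, {child_age})")
    bnds = list(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bnds, bnds[1:])):
        raise ValueError("boundaries must be strictly increasing")
    if oldest_bound is not None and parent_age >= oldest_bound:
        raise ChronogramError(
            f"branch starts at {parent_age} mya, at or beyond the oldest "
            f"stratum bound {oldest_bound}"
        )

    def stratum_below(top: float) -> int:
        # stratum containing ages just below `top`
        idx = 0
        for b in bnds:
            if b < top:
                idx += 1
            else:
                break
        return idx

    segments: list[BranchSegment] = []
    top = parent_age
    while top > child_age:
        idx = stratum_below(top)
        lower = bnds[idx - 1] if idx > 0 else 0.0
        bottom = max(child_age, lower)
        segments.append(BranchSegment(top, bottom, idx))
        top = bottom
    return segments


def interpolate_ages(
    root: Node, tol: float = 0.0
) -> None:
    """Fill in missing internal-node ages (age ``None``) by even division.

    Each unconstrained node splits the age interval between its nearest
    fixed-age ancestor and the oldest fixed-age node (or tip, age 0) on
    the longest unconstrained chain below it, evenly by node count.
    Operates in place, top-down; the root must carry a fixed age.
    """
    if root.age is None:
        raise ChronogramError("root age must be fixed before interpolation")

    def chain(node: Node) -> tuple[int, float]:
        """(number of unconstrained nodes on chain incl. this one, target age)."""
        if node.age is not None:
            return 0, node.age
        best_k, best_age = 0, 0.0
        for child in node.children:
            k, a = chain(child)
            if (a, k) > (best_age, best_k):
                best_k, best_age = k, a
        return best_k + 1, best_age

    def assign(node: Node) -> None:
        for child in node.children:
            if child.age is None:
                k, target = chain(child)
                child.age = node.age - (node.age - target) / (k + 1)
            assign(child)

    assign(root)
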