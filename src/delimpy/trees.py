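"""Ultrametric genealogies.

Trees are consumed, not inferred: the delimitation model needs a rooted,
bifurcating, ultrametric genealogy (all tips contemporaneous) with node
heights measured backwards from the present, typically in expected
substitutions per site.  Newick parsing is delegated to dendropy; internally
the tree is held as a minimal node structure keyed by height, which is what
the likelihood machinery consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy

from .errors import TreeError

#: jitter applied to zero-length internal branches
EPSILON = 1e-8


@dataclass(eq=False)  # identity hashing: nodes are keys in tipset index
class Node:
    height: float
    children: list["Node"] = field(default_factory=list)
    label: str | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children


class UltrametricTree:
    """Rooted binary ultrametric tree with tips at height zero."""

    def __init__(self, root: Node, tol: float = 1e-6):
        self.root = root
        self.tol = tol
        self._validate_and_index()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, tol: float = 1e-6) -> "UltrametricTree":
        """Parse a rooted Newick string with branch lengths.

        Tip root-to-tip distances must agree within ``tol``; zero-length
        internal branches are jittered by 1e-8 with a warning.  Polytomies
        and unrooted (trifurcating-root) trees are rejected.
        """
        dtree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
        seed = dtree.seed_node
        # root-to-node depths
        depths: dict = {seed: 0.0}
        for nd in dtree.preorder_node_iter():
            if nd is seed:
                continue
            el = nd.edge.length if nd.edge.length is not None else 0.0
            depths[nd] = depths[nd.parent_node] + el
        leaves = [nd for nd in dtree.leaf_node_iter()]
        if len(leaves) < 2:
            raise TreeError("tree must have at least 2 tips")
        H = max(depths[lf] for lf in leaves)
        dev = max(abs(H - depths[lf]) for lf in leaves)
        if dev > tol:
            raise TreeError(
                f"tree is not ultrametric: max tip-height deviation {dev:.3g} "
                f"exceeds tolerance {tol:.3g}"
            )

        def convert(nd) -> Node:
            if nd.is_leaf():
                lab = nd.taxon.label if nd.taxon is not None else nd.label
                if lab is None:
                    raise TreeError("unlabeled tip")
                return Node(0.0, label=lab.replace(" ", "_"))
            kids = nd.child_nodes()
            if len(kids) != 2:
                raise TreeError(
                    f"node with {len(kids)} children: tree must be strictly "
                    "bifurcating and rooted (resolve externally)"
                )
            return Node(H - depths[nd], children=[convert(k) for k in kids])

        return cls(convert(seed), tol=tol)

    @classmethod
    def read(cls, path, tol: float = 1e-6) -> "UltrametricTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), tol=tol)

    # -- validation / indexing --------------------------------------------

    def _validate_and_index(self) -> None:
        jittered = False
        order: list[Node] = []

        def walk(nd: Node, parent_height: float | None) -> frozenset:
            nonlocal jittered
            if nd.is_tip:
                if abs(nd.height) > self.tol:
                    raise TreeError(f"tip {nd.label!r} not at height 0")
                nd.height = 0.0
                return frozenset([nd.label])
            if len(nd.children) != 2:
                raise TreeError("tree must be strictly bifurcating")
            if parent_height is not None and nd.height >= parent_height:
                nd.height = parent_height - EPSILON
                jittered = True
            tips = frozenset()
            for ch in nd.children:
                tips |= walk(ch, nd.height)
            if nd.height <= 0:
                raise TreeError("internal node at non-positive height")
            order.append(nd)
            self._tipsets[nd] = tips
            return tips

        self._tipsets: dict[Node, frozenset] = {}
        all_tips = walk(self.root, None)
        if jittered:
            warnings.warn(
                "zero-length internal branch(es) jittered by 1e-8", stacklevel=3
            )
        self.tips: list[str] = sorted(all_tips)
        if len(all_tips) != len(list(self._iter_tips(self.root))):
            raise TreeError("duplicate tip labels")
        self.internal_nodes: list[Node] = sorted(order, key=lambda v: v.height)

    @staticmethod
    def _iter_tips(nd: Node):
        if nd.is_tip:
            yield nd
        else:
            for ch in nd.children:
                yield from UltrametricTree._iter_tips(ch)

    # -- queries -----------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def root_height(self) -> float:
        return self.root.height

    def node_heights(self) -> list[float]:
        """Internal node heights, ascending (with multiplicity)."""
        return [v.height for v in self.internal_nodes]

    def tipset(self, node: Node) -> frozenset:
        return self._tipsets[node]

    def entities_at(self, T: float) -> list[frozenset]:
        """Tip sets of the branches crossing height ``T``.

        ``T >= root height`` yields one entity; ``T = 0`` yields all tips as
        singletons.  Entity order follows a preorder traversal.
        """
        out: list[frozenset] = []

        def descend(nd: Node) -> None:
            if nd.is_tip:
                out.append(frozenset([nd.label]))
            elif nd.height <= T:
                out.append(self._tipsets[nd])
            else:
                for ch in nd.children:
                    descend(ch)

        if T >= self.root.height:
            return [frozenset(self.tips)]
        descend(self.root)
        return out

    def entity_map_at(self, T: float) -> dict[str, int]:
        """tip label -> entity index at threshold ``T``."""
        out: dict[str, int] = {}
        for k, ent in enumerate(self.entities_at(T)):
            for tip in ent:
                out[tip] = k
        return out

    # -- serialization -----------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        def write(nd: Node, parent_height: float | None) -> str:
            if nd.is_tip:
                body = nd.label
            else:
                body = "(" + ",".join(write(c, nd.height) for c in nd.children) + ")"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - nd.height:.{precision}g}"

        return write(self.root, None) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def scaled(self, factor: float) -> "UltrametricTree":
        """A copy with all heights multiplied by ``factor``."""

        def copy(nd: Node) -> Node:
            if nd.is_tip:
                return Node(0.0, label=nd.label)
            return Node(nd.height * factor, children=[copy(c) for c in nd.children])

        return UltrametricTree(copy(self.root), tol=self.tol)


def parse_newick_ultrametric(text: str, tol: float = 1e-6) -> UltrametricTree:
    """Module-level convenience wrapper around :meth:`UltrametricTree.from_newick`."""
    return UltrametricTree.from_newick(text, tol=tol)
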