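"""Rooted, fully labelled phylogenies (topology only).

The analysis is purely topological: branch lengths play no role, but every
internal node must carry a label because ancestral sequences are reported
per named ancestor (e.g. ``Eumalacostraca_LCA``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import dendropy

__all__ = ["Phylogeny"]


@dataclass
class Phylogeny:
    """A rooted tree as parent/children maps over unique node labels."""

    root: str
    children: Dict[str, Tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.children = {n: tuple(c) for n, c in self.children.items()}
        self._parent: Dict[str, str] = {}
        seen = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise ValueError(f"node label {n!r} occurs more than once")
            seen.add(n)
            for c in self.children.get(n, ()):
                if c in self._parent:
                    raise ValueError(f"node {c!r} has more than one parent")
                self._parent[c] = n
                stack.append(c)
        unreachable = set(self.children) - seen
        if unreachable:
            raise ValueError(f"nodes unreachable from root: {sorted(unreachable)}")

    # -- structure queries ---------------------------------------------
    def parent(self, node: str) -> Optional[str]:
        return self._parent.get(node)

    def children_of(self, node: str) -> Tuple[str, ...]:
        return self.children.get(node, ())

    def is_tip(self, node: str) -> bool:
        return not self.children.get(node)

    @property
    def tips(self) -> Tuple[str, ...]:
        return tuple(n for n in self.postorder() if self.is_tip(n))

    @property
    def internal_nodes(self) -> Tuple[str, ...]:
        return tuple(n for n in self.postorder() if not self.is_tip(n))

    @property
    def branches(self) -> Tuple[Tuple[str, str], ...]:
        """All (parent, child) edges, in postorder of the child."""
        return tuple((self._parent[n], n) for n in self.postorder() if n != self.root)

    @property
    def branches_preorder(self) -> Tuple[Tuple[str, str], ...]:
        """All (parent, child) edges, parents always before children."""
        return tuple((self._parent[n], n) for n in self.preorder() if n != self.root)

    def postorder(self) -> Iterator[str]:
        out: List[str] = []

        def walk(n: str) -> None:
            for c in self.children.get(n, ()):
                walk(c)
            out.append(n)

        walk(self.root)
        return iter(out)

    def preorder(self) -> Iterator[str]:
        out: List[str] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children.get(n, ())))
        return iter(out)

    def __contains__(self, node: str) -> bool:
        return node == self.root or node in self._parent

    # -- newick bridge --------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse a rooted newick string; internal nodes keep their labels.

        Unlabelled internal nodes are assigned ``node<N>`` in postorder.
        """
        t = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=False)
        return cls.from_dendropy(t)

    @classmethod
    def from_dendropy(cls, t: "dendropy.Tree") -> "Phylogeny":
        counter = [0]

        def label_of(nd: "dendropy.Node") -> str:
            if nd.taxon is not None and nd.taxon.label:
                return nd.taxon.label.replace(" ", "_")
            if nd.label:
                return nd.label.replace(" ", "_")
            counter[0] += 1
            return f"node{counter[0]}"

        labels: Dict[int, str] = {}
        children: Dict[str, Tuple[str, ...]] = {}
        for nd in t.postorder_node_iter():
            labels[id(nd)] = label_of(nd)
        for nd in t.postorder_node_iter():
            kids = nd.child_nodes()
            if kids:
                children[labels[id(nd)]] = tuple(labels[id(c)] for c in kids)
        return cls(root=labels[id(t.seed_node)], children=children)

    def to_newick(self) -> str:
        def render(n: str) -> str:
            kids = self.children.get(n)
            if not kids:
                return n
            return "(" + ",".join(render(c) for c in kids) + ")" + n
        return render(self.root) + ";"
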