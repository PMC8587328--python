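"""Taxonomy trees for categorical quasi-identifier attributes.

A taxonomy is a rooted tree of categorical labels; the root is the fully
generalized value (conventionally ``ANY``), leaves are the raw values a
report can carry, and inner nodes are intermediate generalizations.  Node
height is measured from the leaf level up: a leaf has height 0, the root
has the tree height ``h``.  This makes an ungeneralized group cost nothing
in information loss and a root-generalized group cost one full unit per
attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TaxonomyTree:
    """Rooted tree over categorical labels.

    Parameters
    ----------
    root:
        Label of the root node (by convention ``"ANY"``).
    parent:
        Mapping child label -> parent label; the root must not appear
        as a key.
    """

    root: str
    parent: dict[str, str]
    _depth: dict[str, int] = field(init=False, repr=False, compare=False)
    _height: dict[str, int] = field(init=False, repr=False, compare=False)
    _ancestors: dict[str, frozenset[str]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        children: dict[str, list[str]] = {self.root: []}
        for c, p in self.parent.items():
            children.setdefault(p, []).append(c)
            children.setdefault(c, [])
        if self.root in self.parent:
            raise ValueError("root must not have a parent")
        # depth + ancestor chains; also validates acyclicity / single root
        depth: dict[str, int] = {}
        anc: dict[str, frozenset[str]] = {}
        for node in children:
            chain = []
            cur = node
            seen = {node}
            while cur != self.root:
                if cur not in self.parent:
                    raise ValueError(f"node {cur!r} is not connected to root {self.root!r}")
                cur = self.parent[cur]
                if cur in seen:
                    raise ValueError(f"cycle detected at node {cur!r}")
                seen.add(cur)
                chain.append(cur)
            depth[node] = len(chain)
            anc[node] = frozenset(chain)
        # node height = longest downward path to a leaf
        height: dict[str, int] = {}

        def _h(node: str) -> int:
            if node not in height:
                kids = children[node]
                height[node] = 0 if not kids else 1 + max(_h(k) for k in kids)
            return height[node]

        _h(self.root)
        object.__setattr__(self, "_depth", depth)
        object.__setattr__(self, "_height", height)
        object.__setattr__(self, "_ancestors", anc)

    # -- basic queries ---------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._depth)

    @property
    def height(self) -> int:
        """Tree height h(C): height of the root."""
        return self._height[self.root]

    def node_height(self, label: str) -> int:
        """Height of ``label`` measured from the leaf level (leaf = 0)."""
        return self._height[label]

    def is_leaf(self, label: str) -> bool:
        return self._height[label] == 0

    def is_ancestor_or_self(self, a: str, b: str) -> bool:
        """True iff ``a`` equals ``b`` or is an ancestor of ``b``."""
        if a == b:
            return True
        if b not in self._ancestors:
            raise KeyError(f"unknown taxonomy node {b!r}")
        return a in self._ancestors[b]

    def lca(self, labels) -> str:
        """Lowest common ancestor of a nonempty collection of labels."""
        labels = list(labels)
        if not labels:
            raise ValueError("lca of empty collection")
        common = None
        for lab in labels:
            chain = self._ancestors[lab] | {lab}
            common = chain if common is None else common & chain
        # deepest node in the common ancestor set
        return max(common, key=lambda n: self._depth[n])

    def leaves(self) -> list[str]:
        return sorted(n for n in self._depth if self._height[n] == 0)

    def leaves_under(self, label: str) -> list[str]:
        return sorted(
            n for n in self._depth
            if self._height[n] == 0 and self.is_ancestor_or_self(label, n)
        )

    # -- file dialect ----------------------------------------------------

    @classmethod
    def from_edges(cls, edges) -> "TaxonomyTree":
        """Build from (parent, child) pairs; the root is the unique parent
        that never appears as a child."""
        parent = {c: p for p, c in edges}
        parents = {p for p, _ in edges}
        roots = parents - set(parent)
        if len(roots) != 1:
            raise ValueError(f"expected a single root, found {sorted(roots)}")
        return cls(root=roots.pop(), parent=parent)

    @classmethod
    def load(cls, path) -> "TaxonomyTree":
        """Load a two-column tab-separated edge list ``parent<TAB>child``."""
        edges = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{ln}: expected 'parent<TAB>child'")
                edges.append((parts[0], parts[1]))
        return cls.from_edges(edges)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for c in sorted(self.parent):
                fh.write(f"{self.parent[c]}\t{c}\n")


def binary_gender_tree() -> TaxonomyTree:
    """The two-level gender taxonomy ANY -> {Male, Female}."""
    return TaxonomyTree(root="ANY", parent={"Male": "ANY", "Female": "ANY"})
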