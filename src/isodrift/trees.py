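"""Population split trees with per-branch drift parameters.

A :class:`PopulationTree` describes the demographic ground truth used by the
synthetic-data generator: a rooted tree whose branches carry a length ``t``
(generations) and a diploid effective size ``Ne``.  Under pure drift a branch
accumulates a Balding-Nichols drift coefficient

    F = 1 - exp(-t / (2 * Ne))

and F composes along a path as ``F_path = 1 - prod(1 - F_branch)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable


@dataclass(frozen=True)
class Branch:
    """Parent link of one node: branch length in generations and diploid Ne."""

    parent: str
    length: float
    ne: float

    @property
    def drift_f(self) -> float:
        """Balding-Nichols F accumulated over this branch."""
        f = 1.0 - math.exp(-self.length / (2.0 * self.ne))
        if f >= 1.0:
            raise ValueError("branch drift F >= 1 (invalid branch)")
        return f


@dataclass
class PopulationTree:
    """Rooted population tree; ``branches`` maps child node -> :class:`Branch`.

    Parameters
    ----------
    root
        Label of the root node.
    branches
        Mapping from every non-root node label to its parent link.
    root_spectrum
        Allele-frequency spectrum at the root, ``(name, *params)``.
        Supported: ``("uniform", lo, hi)`` and ``("beta", a, b)``.
    """

    root: str
    branches: dict[str, Branch]
    root_spectrum: tuple = ("uniform", 0.05, 0.95)
    _children: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.root in self.branches:
            raise ValueError("root must not have a parent branch")
        children: dict[str, list[str]] = {self.root: []}
        for child, br in self.branches.items():
            if br.length <= 0:
                raise ValueError(f"branch length must be > 0 ({child})")
            if br.ne < 2:
                raise ValueError(f"branch Ne must be >= 2 ({child})")
            children.setdefault(child, [])
            children.setdefault(br.parent, []).append(child)
        for child, br in self.branches.items():
            if br.parent != self.root and br.parent not in self.branches:
                raise ValueError(f"parent {br.parent!r} of {child!r} is not in the tree")
        # reject cycles / multiple roots: every node must reach the root
        for node in self.branches:
            seen = set()
            cur = node
            while cur != self.root:
                if cur in seen:
                    raise ValueError("cycle in tree")
                seen.add(cur)
                cur = self.branches[cur].parent
        self._children = children

    @classmethod
    def from_dict(
        cls,
        root: str,
        branches: dict[str, tuple[str, float, float]],
        root_spectrum: tuple = ("uniform", 0.05, 0.95),
    ) -> "PopulationTree":
        """Build from ``{child: (parent, length_generations, Ne)}``."""
        return cls(
            root=root,
            branches={c: Branch(p, t, ne) for c, (p, t, ne) in branches.items()},
            root_spectrum=root_spectrum,
        )

    # ------------------------------------------------------------------ topology
    def children(self, node: str) -> list[str]:
        return self._children[node]

    @property
    def nodes(self) -> list[str]:
        return [self.root, *self.branches]

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.nodes if not self._children[n])

    def path_to_root(self, node: str) -> list[str]:
        """Nodes on the path from ``node`` up to (excluding) the root."""
        out = []
        cur = node
        while cur != self.root:
            out.append(cur)
            cur = self.branches[cur].parent
        return out

    def mrca(self, a: str, b: str) -> str:
        anc_a = {self.root, *self.path_to_root(a)}
        cur = b
        while cur not in anc_a:
            cur = self.branches[cur].parent
        return cur

    def leaves_below(self, node: str) -> list[str]:
        """Leaf labels in the subtree rooted at ``node`` (``node`` itself if a leaf)."""
        if node not in self._children:
            raise KeyError(f"node {node!r} not in tree")
        stack, out = [node], []
        while stack:
            cur = stack.pop()
            kids = self._children[cur]
            if kids:
                stack.extend(kids)
            else:
                out.append(cur)
        return sorted(out)

    # ------------------------------------------------------------------ drift
    def lineage_f(self, leaf: str, ancestor: str | None = None) -> float:
        """Drift F accumulated from ``ancestor`` (default: root) down to ``leaf``."""
        ancestor = ancestor or self.root
        keep = 1.0
        cur = leaf
        while cur != ancestor:
            keep *= 1.0 - self.branches[cur].drift_f
            cur = self.branches[cur].parent
        return 1.0 - keep

    def expected_fst(self, a: str, b: str) -> float:
        """Expected per-SNP Hudson FST between two leaves under pure drift.

        Equals the average of the two lineages' drift coefficients below the
        MRCA (the quantity the FST -> T transform converts back to a branch
        length in generations).
        """
        m = self.mrca(a, b)
        return 0.5 * (self.lineage_f(a, m) + self.lineage_f(b, m))

    def expected_pairwise_fst(self) -> dict[tuple[str, str], float]:
        lv = self.leaves
        return {
            (a, b): self.expected_fst(a, b)
            for i, a in enumerate(lv)
            for b in lv[i + 1 :]
        }


def two_population_tree(t: float, ne: float, labels: Iterable[str] = ("A", "B")) -> PopulationTree:
    """Two leaves splitting from a common root, each with branch ``t`` and ``Ne``."""
    a, b = labels
    return PopulationTree.from_dict("root", {a: ("root", t, ne), b: ("root", t, ne)})


def star_tree(t: float, ne: float, labels: Iterable[str]) -> PopulationTree:
    """Star topology: every leaf hangs directly off the root with equal drift."""
    return PopulationTree.from_dict("root", {lab: ("root", t, ne) for lab in labels})
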