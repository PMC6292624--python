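"""Haplogroup tree: hierarchy of named clades with defining variants.

The tree follows PhyloTree-style nomenclature: a single root (the mitochondrial
most recent common ancestor, "mt-MRCA") whose macro-level children are the deep
clades L0-L6, M, N and R, with haplogroups and sub-haplogroups nested below.
Each non-root node carries *defining variants* — (rCRS position, derived allele)
pairs whose joint presence diagnoses membership of the clade.

A tree on its own is panel-agnostic. Binding it to a genotyping panel
(:meth:`HaploTree.attach_panel`) resolves which defining variants are actually
typed; nodes with no typed defining variant are flagged *uncallable* and are
skipped during classification (e.g. arrays that cannot separate HV from R).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterable

__all__ = [
    "Variant",
    "HaploNode",
    "HaploTree",
    "TreeError",
    "load_tree",
    "bundled_tree",
    "ROOT_LEVEL",
    "LEVELS",
]

ROOT_LEVEL = "root"
LEVELS = ("macro", "hg", "subhg")

_ALLELES = frozenset("ACGT")


class TreeError(ValueError):
    """Structural problem in a haplogroup tree file or object."""


@dataclass(frozen=True)
class Variant:
    """A defining SNP: 1-based rCRS position and derived allele."""

    position: int
    allele: str

    def __post_init__(self):
        if not 1 <= self.position <= 16569:
            raise TreeError(f"rCRS position out of range: {self.position}")
        if self.allele not in _ALLELES:
            raise TreeError(f"invalid derived allele {self.allele!r} at {self.position}")


@dataclass
class HaploNode:
    name: str
    parent: str | None
    level: str
    variants: tuple[Variant, ...]
    children: list[str] = field(default_factory=list)
    # Set by HaploTree.attach_panel: locus column indices of panel-typed
    # defining variants. None until a panel is attached.
    covered_idx: tuple[int, ...] | None = None

    @property
    def callable_(self) -> bool:
        """True if at least one defining variant is typed on the active panel."""
        if self.covered_idx is None:
            raise TreeError(f"no panel attached; callability of {self.name} undefined")
        return len(self.covered_idx) > 0


class HaploTree:
    """Rooted haplogroup hierarchy.

    Parameters
    ----------
    nodes:
        Iterable of :class:`HaploNode`. Exactly one node must have
        ``parent is None`` (the root); parent references must resolve and the
        parent graph must be acyclic.
    """

    def __init__(self, nodes: Iterable[HaploNode]):
        self.nodes: dict[str, HaploNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise TreeError(f"duplicate node name: {node.name}")
            self.nodes[node.name] = node
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0].name
        for node in self.nodes.values():
            node.children = []
        for node in self.nodes.values():
            if node.parent is None:
                continue
            if node.parent not in self.nodes:
                raise TreeError(f"node {node.name} has unknown parent {node.parent}")
            self.nodes[node.parent].children.append(node.name)
        for node in self.nodes.values():
            node.children.sort()
        self._check_acyclic()
        self._panel_positions: dict[int, str] | None = None

    # -- structure ---------------------------------------------------------

    def _check_acyclic(self) -> None:
        for name in self.nodes:
            seen = set()
            cur: str | None = name
            while cur is not None:
                if cur in seen:
                    raise TreeError(f"cycle through node {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def path_to(self, name: str) -> list[str]:
        """Node names from the root down to (and including) ``name``."""
        if name not in self.nodes:
            raise KeyError(name)
        path = []
        cur: str | None = name
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent
        return path[::-1]

    def path_variants(self, name: str) -> list[Variant]:
        """All defining variants on the root→``name`` path."""
        out: list[Variant] = []
        for node_name in self.path_to(name):
            out.extend(self.nodes[node_name].variants)
        return out

    def level_of(self, name: str) -> str:
        return self.nodes[name].level

    def ancestor_at_level(self, name: str, level: str) -> str | None:
        """The (unique) ancestor-or-self of ``name`` with the given level tag."""
        for node_name in self.path_to(name):
            if self.nodes[node_name].level == level:
                return node_name
        return None

    def all_positions(self) -> set[int]:
        return {v.position for n in self.nodes.values() for v in n.variants}

    # -- panel binding -----------------------------------------------------

    def attach_panel(self, panel) -> None:
        """Bind the tree to a genotyping panel.

        ``panel`` is a pandas DataFrame with columns ``position``, ``ref``,
        ``alt`` (see :mod:`mitocline.matrix`). A defining variant is *covered*
        when its position is typed and the panel's ALT allele equals the
        derived allele. Nodes with zero covered variants become uncallable.
        """
        pos_to_idx = {int(p): i for i, p in enumerate(panel["position"])}
        alt = {int(p): a for p, a in zip(panel["position"], panel["alt"])}
        for node in self.nodes.values():
            covered = [
                pos_to_idx[v.position]
                for v in node.variants
                if v.position in pos_to_idx and alt[v.position] == v.allele
            ]
            node.covered_idx = tuple(covered)
        self._panel_positions = {int(p): str(a) for p, a in alt.items()}

    def uncallable_nodes(self) -> list[str]:
        return sorted(
            n.name
            for n in self.nodes.values()
            if n.parent is not None and n.covered_idx is not None and not n.covered_idx
        )

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "HaploTree":
        nodes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise TreeError(f"{path}:{lineno}: expected 4 tab-separated fields")
                name, parent, level, var_str = fields
                if parent == "-":
                    parent_ref: str | None = None
                    if level != ROOT_LEVEL:
                        raise TreeError(f"{path}:{lineno}: root must have level 'root'")
                else:
                    parent_ref = parent
                    if level not in LEVELS:
                        raise TreeError(
                            f"{path}:{lineno}: level {level!r} not in {LEVELS}"
                        )
                if name == parent:
                    raise TreeError(f"{path}:{lineno}: node {name} is its own parent")
                variants: list[Variant] = []
                if var_str not in ("-", ""):
                    for chunk in var_str.split(","):
                        pos_s, _, allele = chunk.partition(":")
                        variants.append(Variant(int(pos_s), allele))
                nodes.append(HaploNode(name, parent_ref, level, tuple(variants)))
        return cls(nodes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# name\tparent\tlevel\tvariants\n")
            for name in sorted(self.nodes, key=lambda n: (len(self.path_to(n)), n)):
                node = self.nodes[name]
                var_str = (
                    ",".join(f"{v.position}:{v.allele}" for v in node.variants) or "-"
                )
                fh.write(f"{name}\t{node.parent or '-'}\t{node.level}\t{var_str}\n")


def load_tree(path: str | Path) -> HaploTree:
    """Load and validate a haplogroup tree from its tab-separated file format."""
    return HaploTree.from_file(path)


def bundled_tree() -> HaploTree:
    """The example tree shipped with the package (Northern European label set)."""
    ref = _ilres.files("mitocline.resources").joinpath("haplotree.tsv")
    with _ilres.as_file(ref) as path:
        return HaploTree.from_file(path)
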