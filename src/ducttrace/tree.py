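"""Branching-tree data model and file I/O.

The ductal network of a gland lobe is represented as a rooted tree of duct
segments.  Each node is one duct; the main duct of the lobe is the root and
carries generation index ("level") 1, every daughter duct is one level deeper.
Terminal ducts may bear an acinus, which shares the address of its duct (an
acinus is an attribute of a terminal duct, not a separate node).  Duct width
is not modelled; only length enters downstream density calculations.
"""

from __future__ import annotations

import csv
import json
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "COLORS",
    "COMPARTMENTS",
    "DuctNode",
    "BranchingTree",
    "LabelledCell",
    "TreeStructureError",
    "TreeParseError",
    "CellTableError",
    "read_tree",
    "write_tree",
    "read_cells",
    "write_cells",
    "cells_to_frame",
    "topology_profile",
    "subtree_of",
    "full_binary_tree",
    "to_newick",
]

#: Closed vocabulary of confetti reporter colors.
COLORS = ("CFP", "YFP", "GFP", "RFP")

#: Closed vocabulary of epithelial cell compartments.
COMPARTMENTS = ("acinar", "luminal", "basal", "myoepithelial")


class TreeStructureError(ValueError):
    """Raised when a tree violates structural invariants (cycles, multiple
    roots, inconsistent levels, an acinus on a non-terminal duct...)."""


class TreeParseError(ValueError):
    """Raised when a tree file is malformed; names the offending record."""


class CellTableError(ValueError):
    """Raised when a labelled-cell table is malformed or does not resolve
    against the supplied tree."""


@dataclass
class DuctNode:
    """One duct segment of the branching network."""

    id: str
    parent_id: str | None
    level: int
    length_um: float
    has_acinus: bool = False
    child_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_um < 0:
            raise TreeStructureError(
                f"duct {self.id!r}: negative length {self.length_um}"
            )
        if self.level < 1:
            raise TreeStructureError(f"duct {self.id!r}: level must be >= 1")


@dataclass
class LabelledCell:
    """A single labelled cell assigned to a duct of the network.

    ``in_acinus`` is true when the cell lies in the terminal acinus rather
    than the duct lumen/wall.  An acinar-compartment cell with
    ``in_acinus=False`` is a "duct-associated acinar cell" and is excluded
    from potency and census calculations by default.
    """

    id: str
    duct_id: str
    color: str
    compartment: str
    in_acinus: bool = False

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise CellTableError(
                f"cell {self.id!r}: unknown color {self.color!r}; "
                f"expected one of {COLORS}"
            )
        if self.compartment not in COMPARTMENTS:
            raise CellTableError(
                f"cell {self.id!r}: unknown compartment {self.compartment!r}; "
                f"expected one of {COMPARTMENTS}"
            )


class BranchingTree:
    """Rooted duct network with levels, lengths, and terminal acini.

    Parameters
    ----------
    nodes
        DuctNode instances.  ``child_ids`` are recomputed from the parent
        links, and stored levels are checked against a traversal from the
        root (the root keeps its stated level, 1 for a whole lobe; a subtree
        extracted from a larger tree keeps its absolute levels).
    """

    def __init__(self, nodes: Iterable[DuctNode]):
        self._nodes: dict[str, DuctNode] = {}
        for n in nodes:
            if n.id in self._nodes:
                raise TreeStructureError(f"duplicate duct id {n.id!r}")
            self._nodes[n.id] = replace(n, child_ids=[])
        roots = [n.id for n in self._nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise TreeStructureError(
                f"tree must have exactly one root, found {len(roots)}: {roots[:5]}"
            )
        self._root_id = roots[0]
        for n in self._nodes.values():
            if n.parent_id is None:
                continue
            parent = self._nodes.get(n.parent_id)
            if parent is None:
                raise TreeStructureError(
                    f"duct {n.id!r}: parent {n.parent_id!r} does not resolve"
                )
            parent.child_ids.append(n.id)
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        queue = deque([self._root_id])
        while queue:
            nid = queue.popleft()
            if nid in seen:
                raise TreeStructureError(f"cycle detected at duct {nid!r}")
            seen.add(nid)
            node = self._nodes[nid]
            for cid in node.child_ids:
                child = self._nodes[cid]
                if child.level != node.level + 1:
                    raise TreeStructureError(
                        f"duct {cid!r}: level {child.level} != parent level "
                        f"{node.level} + 1"
                    )
                queue.append(cid)
            if node.has_acinus and node.child_ids:
                raise TreeStructureError(
                    f"duct {nid!r} has an acinus but is not terminal"
                )
        if len(seen) != len(self._nodes):
            orphans = sorted(set(self._nodes) - seen)
            raise TreeStructureError(
                f"{len(orphans)} duct(s) unreachable from root: {orphans[:5]}"
            )

    # -- basic access -----------------------------------------------------

    @property
    def root_id(self) -> str:
        return self._root_id

    @property
    def nodes(self) -> Mapping[str, DuctNode]:
        return self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __iter__(self) -> Iterator[str]:
        return iter(self._nodes)

    def node(self, node_id: str) -> DuctNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown duct id {node_id!r}") from None

    def children(self, node_id: str) -> list[str]:
        return list(self.node(node_id).child_ids)

    def parent(self, node_id: str) -> str | None:
        return self.node(node_id).parent_id

    def level_of(self, node_id: str) -> int:
        return self.node(node_id).level

    @property
    def depth(self) -> int:
        """Deepest occupied level."""
        return max(n.level for n in self._nodes.values())

    def terminal_ids(self) -> list[str]:
        return [nid for nid, n in self._nodes.items() if not n.child_ids]

    def acinus_ids(self) -> list[str]:
        return [nid for nid, n in self._nodes.items() if n.has_acinus]

    def nodes_at_level(self, level: int) -> list[str]:
        return [nid for nid, n in self._nodes.items() if n.level == level]

    # -- topology queries --------------------------------------------------

    def ancestor_path(self, node_id: str) -> list[str]:
        """Path from the root down to ``node_id``, inclusive."""
        path = []
        nid: str | None = node_id
        self.node(node_id)  # raise on unknown id
        while nid is not None:
            path.append(nid)
            nid = self._nodes[nid].parent_id
        path.reverse()
        return path

    def is_ancestor(self, anc_id: str, node_id: str) -> bool:
        """True when ``anc_id`` lies on the root path of ``node_id``
        (a node is its own ancestor)."""
        anc_level = self.level_of(anc_id)
        nid: str | None = node_id
        self.node(node_id)
        while nid is not None and self._nodes[nid].level >= anc_level:
            if nid == anc_id:
                return True
            nid = self._nodes[nid].parent_id
        return False

    def subtree_ids(self, node_id: str) -> list[str]:
        """Ids of every duct in the subtree rooted at ``node_id``
        (breadth-first order, root first)."""
        out = []
        queue = deque([node_id])
        self.node(node_id)
        while queue:
            nid = queue.popleft()
            out.append(nid)
            queue.extend(self._nodes[nid].child_ids)
        return out

    def ancestor_at_level(self, node_id: str, level: int) -> str | None:
        """The unique ancestor of ``node_id`` at ``level``, or None when the
        node itself is shallower than ``level``."""
        nid: str | None = node_id
        self.node(node_id)
        while nid is not None:
            n = self._nodes[nid]
            if n.level == level:
                return nid
            if n.level < level:
                return None
            nid = n.parent_id
        return None

    def total_length(self, node_ids: Iterable[str] | None = None) -> float:
        ids = self._nodes if node_ids is None else node_ids
        return float(sum(self._nodes[i].length_um for i in ids))

    def n_acini(self, node_ids: Iterable[str] | None = None) -> int:
        ids = self._nodes if node_ids is None else node_ids
        return sum(1 for i in ids if self._nodes[i].has_acinus)

    # -- conversions -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "root": self._root_id,
            "nodes": [
                {
                    "id": n.id,
                    "parent": n.parent_id,
                    "level": n.level,
                    "length_um": n.length_um,
                    "has_acinus": n.has_acinus,
                }
                for n in self._nodes.values()
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "BranchingTree":
        nodes = []
        for i, rec in enumerate(data.get("nodes", [])):
            try:
                nodes.append(
                    DuctNode(
                        id=str(rec["id"]),
                        parent_id=None if rec["parent"] is None else str(rec["parent"]),
                        level=int(rec["level"]),
                        length_um=float(rec["length_um"]),
                        has_acinus=bool(rec.get("has_acinus", False)),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise TreeParseError(f"malformed node record #{i}: {rec!r} ({exc})")
        tree = cls(nodes)
        declared_root = data.get("root")
        if declared_root is not None and str(declared_root) != tree.root_id:
            raise TreeParseError(
                f"declared root {declared_root!r} is not the structural root "
                f"{tree.root_id!r}"
            )
        return tree

    def to_networkx(self):
        """Directed graph (parent -> child) with node attributes."""
        import networkx as nx

        g = nx.DiGraph()
        for n in self._nodes.values():
            g.add_node(
                n.id, level=n.level, length_um=n.length_um, has_acinus=n.has_acinus
            )
        for n in self._nodes.values():
            if n.parent_id is not None:
                g.add_edge(n.parent_id, n.id)
        return g


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_tree(path) -> BranchingTree:
    """Read a branching tree from its JSON representation.

    The schema is ``{"root": id, "nodes": [{"id", "parent", "level",
    "length_um", "has_acinus"}]}``.
    """
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TreeParseError(f"{path}: invalid JSON ({exc})")
    return BranchingTree.from_dict(data)


def write_tree(tree: BranchingTree, path, metadata: Mapping | None = None) -> None:
    """Write the tree as JSON.  Optional ``metadata`` (e.g. generator seed
    and config hash) is embedded under a ``"_meta"`` key."""
    data = tree.to_dict()
    if metadata:
        data["_meta"] = dict(metadata)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


_CELL_COLUMNS = ["cell_id", "duct_id", "color", "compartment", "in_acinus"]


def read_cells(path, tree: BranchingTree | None = None) -> list[LabelledCell]:
    """Read a labelled-cell table (CSV with header
    ``cell_id,duct_id,color,compartment,in_acinus``).

    Lines starting with ``#`` are treated as comments.  When ``tree`` is
    given, every ``duct_id`` must resolve against it.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in _CELL_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableError(f"{path}: missing column(s) {missing}")
    cells = []
    for rec in df.itertuples(index=False):
        raw = str(rec.in_acinus).strip().lower()
        if raw not in {"true", "false"}:
            raise CellTableError(
                f"cell {rec.cell_id!r}: in_acinus must be true/false, got {raw!r}"
            )
        cells.append(
            LabelledCell(
                id=str(rec.cell_id),
                duct_id=str(rec.duct_id),
                color=str(rec.color),
                compartment=str(rec.compartment),
                in_acinus=raw == "true",
            )
        )
    if tree is not None:
        bad = sorted({c.duct_id for c in cells if c.duct_id not in tree})
        if bad:
            raise CellTableError(
                f"{len(bad)} duct id(s) do not resolve against the tree: {bad[:10]}"
            )
    return cells


def cells_to_frame(cells: Sequence[LabelledCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": c.id,
                "duct_id": c.duct_id,
                "color": c.color,
                "compartment": c.compartment,
                "in_acinus": c.in_acinus,
            }
            for c in cells
        ],
        columns=_CELL_COLUMNS,
    )


def write_cells(
    cells: Sequence[LabelledCell], path, header_comment: str | None = None
) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(_CELL_COLUMNS)
        for c in cells:
            writer.writerow(
                [c.id, c.duct_id, c.color, c.compartment, "true" if c.in_acinus else "false"]
            )


# ---------------------------------------------------------------------------
# Topology summaries
# ---------------------------------------------------------------------------


def topology_profile(tree: BranchingTree) -> pd.DataFrame:
    """Per-level summary: duct count, mean duct length, terminal count.

    One row per occupied level; ``n_ducts`` sums to the total node count.
    """
    rows = {}
    for n in tree.nodes.values():
        rec = rows.setdefault(n.level, {"n_ducts": 0, "total_length": 0.0, "n_terminal": 0})
        rec["n_ducts"] += 1
        rec["total_length"] += n.length_um
        if not n.child_ids:
            rec["n_terminal"] += 1
    out = pd.DataFrame(
        [
            {
                "level": lvl,
                "n_ducts": rec["n_ducts"],
                "mean_length_um": rec["total_length"] / rec["n_ducts"],
                "n_terminal": rec["n_terminal"],
            }
            for lvl, rec in sorted(rows.items())
        ]
    )
    return out


def subtree_of(tree: BranchingTree, node_id: str) -> BranchingTree:
    """The full subtree rooted at ``node_id``, including ducts with no
    labelled cells.  Absolute levels are preserved."""
    ids = tree.subtree_ids(node_id)
    id_set = set(ids)
    nodes = []
    for nid in ids:
        n = tree.node(nid)
        nodes.append(
            DuctNode(
                id=n.id,
                parent_id=n.parent_id if (nid != node_id and n.parent_id in id_set) else None,
                level=n.level,
                length_um=n.length_um,
                has_acinus=n.has_acinus,
            )
        )
    return BranchingTree(nodes)


def full_binary_tree(
    depth: int, root_length_um: float = 200.0, length_decay: float = 0.85
) -> BranchingTree:
    """Deterministic full binary tree of the given depth (root = level 1).

    Duct length follows a geometric schedule ``root_length_um *
    length_decay**(level-1)``; terminal ducts carry acini.  Used as the
    reference topology for simulator conservation laws and analytic
    merger-rate comparisons.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    nodes = []
    for level in range(1, depth + 1):
        length = root_length_um * length_decay ** (level - 1)
        for k in range(2 ** (level - 1)):
            nid = f"L{level}N{k}"
            parent = None if level == 1 else f"L{level-1}N{k // 2}"
            nodes.append(
                DuctNode(
                    id=nid,
                    parent_id=parent,
                    level=level,
                    length_um=length,
                    has_acinus=level == depth,
                )
            )
    return BranchingTree(nodes)


def to_newick(tree: BranchingTree) -> str:
    """Newick export with node labels ``id_level_length`` for interop with
    standard tree viewers.  Lossy: drops ``has_acinus``."""
    import dendropy

    dtree = dendropy.Tree()
    dnodes = {}
    for nid in tree.subtree_ids(tree.root_id):
        n = tree.node(nid)
        label = f"{n.id}_{n.level}_{n.length_um:g}"
        if n.parent_id is None:
            dnode = dtree.seed_node
            dnode.label = label
        else:
            dnode = dnodes[n.parent_id].new_child(label=label)
        if not n.child_ids:  # leaf labels live on taxa in newick
            dnode.taxon = dtree.taxon_namespace.new_taxon(label)
        dnode.edge.length = n.length_um
        dnodes[nid] = dnode
    return dtree.as_string(schema="newick", suppress_rooting=True).strip()
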