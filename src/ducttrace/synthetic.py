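"""Synthetic branching trees, induced clones and labelled-cell tables with
known ground truth.

The generator emulates the study design end to end so every analysis stage
is testable without external data:

1. a branching tree grows by synchronous rounds of stochastic tip
   bifurcation (one round per day), with duct length decaying geometrically
   with level;
2. at the induction round, each endbud receives Poisson labelling events per
   confetti color at unequal per-color intensities; each labelled progenitor
   is one member of the endbud's renewing pool and carries a potency state
   drawn from a mixture;
3. clones then grow to the collection-stage tree under the random-segregation
   tree-walk, and labelled cells are deposited into compartments according to
   each progenitor's potency, with counts consistent with the cell-census
   model, so that a clone's expected fractional contribution to a compartment
   is the reciprocal of the number of pool progenitors feeding it.

Ground truth records the true clone memberships, potencies, common
ancestors, per-endbud progenitor pools and the merger/co-labelling events
actually induced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .census import CensusModel, round_half_up
from .simulate import simulate_clone
from .tree import (
    BranchingTree,
    DuctNode,
    LabelledCell,
    COLORS,
    write_cells,
    write_tree,
)

__all__ = [
    "SyntheticConfig",
    "InducedProgenitor",
    "SyntheticGroundTruth",
    "SyntheticDataset",
    "generate_tree",
    "induction_endbuds",
    "induce_clones",
    "grow_and_populate",
    "generate_dataset",
]


@dataclass
class SyntheticConfig:
    """Generator parameters.

    Defaults reproduce the study conditions: induction when the tree has ~7
    generations (the average common-ancestor level), collection at 12
    generations (trees span 4-15), tip bifurcation once per round at
    probability 0.95, duct length decreasing geometrically with level,
    mean labelling events per color 10:11:3:13 (CFP:YFP:GFP:RFP), an endbud
    pool of ~117 renewing progenitors, and a potency mixture of 42% uni,
    37% bi, 21% multipotent.
    """

    generations_at_induction: int = 7
    generations_total: int = 12
    bifurcation_prob: float = 0.95
    guaranteed_generations: int = 4
    root_length_um: float = 250.0
    length_decay: float = 0.85
    length_noise_sd: float = 0.10  # lognormal sigma on duct lengths
    census: CensusModel = field(default_factory=CensusModel)
    pool_size: int = 117
    potency_mixture: dict = field(
        default_factory=lambda: {"uni": 0.42, "bi": 0.37, "multi": 0.21}
    )
    bi_acinar_luminal_prob: float = 0.75
    multi_quad_prob: float = 0.5
    uni_weights: dict = field(
        default_factory=lambda: {
            "acinar": 0.57,
            "luminal": 0.36,
            "basal": 0.035,
            "myoepithelial": 0.035,
        }
    )
    mean_events_per_color: dict = field(
        default_factory=lambda: {"CFP": 10.0, "YFP": 11.0, "GFP": 3.0, "RFP": 13.0}
    )
    duct_acinar_fraction: float = 0.04

    def __post_init__(self):
        if self.generations_total < 1 or self.generations_at_induction < 1:
            raise ValueError("generation counts must be >= 1")
        if self.generations_at_induction > self.generations_total:
            raise ValueError("induction cannot be later than collection")
        if not 0.0 <= self.bifurcation_prob <= 1.0:
            raise ValueError("bifurcation_prob must be in [0, 1]")
        mix = self.potency_mixture
        if any(not 0 <= v <= 1 for v in mix.values()) or abs(sum(mix.values()) - 1) > 1e-9:
            raise ValueError("potency mixture must be probabilities summing to 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Tree growth
# ---------------------------------------------------------------------------


def generate_tree(config: SyntheticConfig, rng: np.random.Generator | int | None = None) -> BranchingTree:
    """Grow a branching tree by synchronous rounds of tip bifurcation.

    Each round, every active tip bifurcates with ``bifurcation_prob``; a tip
    that fails to bifurcate terminates and keeps its acinus.  Bifurcation is
    certain through the first ``guaranteed_generations`` levels, reflecting
    that measured lobes always comprise at least ~4 generations of
    branching.  Duct length at
    level l is ``root_length_um * length_decay**(l-1)`` with lognormal
    noise, so mean length decreases with level.  Terminal ducts carry acini.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    def length_at(level: int) -> float:
        base = config.root_length_um * config.length_decay ** (level - 1)
        if config.length_noise_sd > 0:
            base *= float(np.exp(rng.normal(0.0, config.length_noise_sd)))
        return base

    nodes = [DuctNode(id="d0", parent_id=None, level=1, length_um=length_at(1))]
    active = ["d0"]
    counter = 1
    for level in range(2, config.generations_total + 1):
        next_active = []
        for tip in active:
            p_split = 1.0 if level <= config.guaranteed_generations else config.bifurcation_prob
            if rng.random() < p_split:
                for _ in range(2):
                    nid = f"d{counter}"
                    counter += 1
                    nodes.append(
                        DuctNode(
                            id=nid, parent_id=tip, level=level, length_um=length_at(level)
                        )
                    )
                    next_active.append(nid)
        active = next_active
        if not active:
            break
    children = {n.parent_id for n in nodes if n.parent_id is not None}
    final = [
        DuctNode(
            id=n.id,
            parent_id=n.parent_id,
            level=n.level,
            length_um=n.length_um,
            has_acinus=n.id not in children,
        )
        for n in nodes
    ]
    return BranchingTree(final)


def induction_endbuds(tree: BranchingTree, induction_level: int) -> list[str]:
    """Ducts that were endbuds when the tree had ``induction_level``
    generations: the synchronous tips at that level plus earlier-terminated
    tips (childless ducts at shallower levels)."""
    out = []
    for nid, n in tree.nodes.items():
        if n.level == induction_level or (not n.child_ids and n.level < induction_level):
            out.append(nid)
    return sorted(out)


# ---------------------------------------------------------------------------
# Induction
# ---------------------------------------------------------------------------


@dataclass
class InducedProgenitor:
    """One labelling event: a progenitor in an endbud pool acquires a color."""

    id: str
    endbud_id: str
    color: str
    lineages: frozenset  # potency state (compartments this progenitor feeds)
    pool_index: int

    @property
    def order(self) -> int:
        return len(self.lineages)


@dataclass
class SyntheticGroundTruth:
    """Generator-side truth for recovery tests."""

    progenitors: list[InducedProgenitor]
    pools: dict[str, dict]  # endbud -> {pool_size, contributing: {comp: n}}
    merger_groups: list[dict]  # same-endbud same-color progenitor groups
    colabelled_endbuds: list[str]
    labelled_endbuds: list[str]
    n_endbuds: int
    seed_info: str = ""
    clone_cells: dict[str, list[str]] = field(default_factory=dict)
    clone_occupied: dict[str, list[str]] = field(default_factory=dict)
    true_ca: dict[str, str] = field(default_factory=dict)

    def colabel_fraction(self) -> float:
        if not self.labelled_endbuds:
            return 0.0
        return len(self.colabelled_endbuds) / len(self.labelled_endbuds)

    def to_json_dict(self) -> dict:
        return {
            "seed_info": self.seed_info,
            "n_endbuds": self.n_endbuds,
            "labelled_endbuds": self.labelled_endbuds,
            "colabelled_endbuds": self.colabelled_endbuds,
            "merger_groups": self.merger_groups,
            "pools": self.pools,
            "progenitors": [
                {
                    "id": p.id,
                    "endbud_id": p.endbud_id,
                    "color": p.color,
                    "lineages": sorted(p.lineages),
                    "pool_index": p.pool_index,
                }
                for p in self.progenitors
            ],
            "clone_cells": self.clone_cells,
            "clone_occupied": self.clone_occupied,
            "true_ca": self.true_ca,
        }


def _draw_potency(config: SyntheticConfig, rng: np.random.Generator) -> frozenset:
    mix = config.potency_mixture
    kind = rng.choice(["uni", "bi", "multi"], p=[mix["uni"], mix["bi"], mix["multi"]])
    if kind == "uni":
        comps = list(config.uni_weights)
        w = np.array([config.uni_weights[c] for c in comps], dtype=float)
        return frozenset([str(rng.choice(comps, p=w / w.sum()))])
    if kind == "bi":
        if rng.random() < config.bi_acinar_luminal_prob:
            return frozenset({"acinar", "luminal"})
        return frozenset({"basal", "myoepithelial"})
    allc = ["acinar", "luminal", "basal", "myoepithelial"]
    if rng.random() < config.multi_quad_prob:
        return frozenset(allc)
    drop = rng.integers(4)
    return frozenset(c for i, c in enumerate(allc) if i != drop)


def induce_clones(
    tree: BranchingTree,
    config: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
    endbuds: Sequence[str] | None = None,
) -> SyntheticGroundTruth:
    """Poisson induction over the endbuds present at the induction round.

    Each endbud draws, per color, Poisson(mean_events[color]/N) labelling
    events; each event labels a distinct member of the endbud's progenitor
    pool, whose potency state comes from the configured mixture.  Same-endbud
    same-color groups are recorded as ground-truth mergers; endbuds labelled
    in more than one color as co-labelled.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if endbuds is None:
        endbuds = induction_endbuds(tree, config.generations_at_induction)
    endbuds = sorted(endbuds)
    n_endbuds = len(endbuds)
    if n_endbuds == 0:
        raise ValueError("tree has no endbuds at the induction level")

    progenitors: list[InducedProgenitor] = []
    pools: dict[str, dict] = {}
    merger_groups: list[dict] = []
    labelled: list[str] = []
    colabelled: list[str] = []
    counter = 0
    for endbud in endbuds:
        events = {
            color: int(rng.poisson(config.mean_events_per_color.get(color, 0.0) / n_endbuds))
            for color in COLORS
        }
        total = sum(events.values())
        if total == 0:
            continue
        # the endbud's renewing pool, drawn lazily only where needed
        pool_potencies = [_draw_potency(config, rng) for _ in range(config.pool_size)]
        contributing = {
            comp: sum(1 for pot in pool_potencies if comp in pot)
            for comp in ("acinar", "luminal", "basal", "myoepithelial")
        }
        pools[endbud] = {"pool_size": config.pool_size, "contributing": contributing}
        n_events = min(total, config.pool_size)
        indices = rng.choice(config.pool_size, size=n_events, replace=False)
        colors_expanded = [c for c in COLORS for _ in range(events[c])][:n_events]
        here: dict[str, list[str]] = {}
        for idx, color in zip(indices, colors_expanded):
            pid = f"p{counter:05d}"
            counter += 1
            prog = InducedProgenitor(
                id=pid,
                endbud_id=endbud,
                color=color,
                lineages=pool_potencies[int(idx)],
                pool_index=int(idx),
            )
            progenitors.append(prog)
            here.setdefault(color, []).append(pid)
        labelled.append(endbud)
        if len(here) > 1:
            colabelled.append(endbud)
        for color, pids in here.items():
            if len(pids) > 1:
                merger_groups.append(
                    {"endbud_id": endbud, "color": color, "progenitors": pids}
                )
    return SyntheticGroundTruth(
        progenitors=progenitors,
        pools=pools,
        merger_groups=merger_groups,
        colabelled_endbuds=colabelled,
        labelled_endbuds=labelled,
        n_endbuds=n_endbuds,
    )


# ---------------------------------------------------------------------------
# Clone growth and cell deposition
# ---------------------------------------------------------------------------

_DUCTAL = ("luminal", "basal")
_ACINAR_LIKE = ("acinar", "myoepithelial")


def grow_and_populate(
    tree: BranchingTree,
    truth: SyntheticGroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
) -> list[LabelledCell]:
    """Grow every induced progenitor's clone and deposit labelled cells.

    Each clone follows the random-segregation tree-walk from its endbud of
    origin; the founder additionally deposits one unit of residence in the
    origin duct itself, so clones carry subclones at their duct of origin
    (as measured clones do at their common ancestor).  Cell counts per
    duct/acinus follow the census model; a clone's
    labelled cells in a location are a binomial draw with success
    probability (clone's traversal units there) / (number of pool
    progenitors contributing to the compartment), so that on average a
    progenitor contributes a representative 1/n_c share of its compartment.
    A small fraction of acinar cells are placed inside ducts
    (``in_acinus=False``) to emulate duct-associated acinar cells.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    census = config.census
    cells: list[LabelledCell] = []
    counter = 0
    for prog in truth.progenitors:
        trace = simulate_clone(tree, prog.endbud_id, rng, rule="random")
        contributing = truth.pools[prog.endbud_id]["contributing"]
        # the founder resides in its endbud duct: one unit of residence there,
        # so clones carry subclones at their duct of origin
        duct_units = dict(trace.duct_units)
        duct_units[prog.endbud_id] = duct_units.get(prog.endbud_id, 0) + 1
        my_cells: list[str] = []
        occupied: set[str] = set()

        def emit(duct_id: str, compartment: str, in_acinus: bool) -> None:
            nonlocal counter
            cid = f"c{counter:06d}"
            counter += 1
            cells.append(
                LabelledCell(
                    id=cid,
                    duct_id=duct_id,
                    color=prog.color,
                    compartment=compartment,
                    in_acinus=in_acinus,
                )
            )
            my_cells.append(cid)
            occupied.add(duct_id)

        for comp in sorted(prog.lineages):
            n_c = max(contributing.get(comp, 1), 1)
            if comp in _DUCTAL:
                per_um = census.luminal_per_um if comp == "luminal" else census.basal_per_um
                for duct, units in sorted(duct_units.items()):
                    node = tree.node(duct)
                    n_cells_here = round_half_up(per_um * node.length_um)
                    if n_cells_here == 0:
                        continue
                    share = min(units / n_c, 1.0)
                    for _ in range(int(rng.binomial(n_cells_here, share))):
                        emit(duct, comp, in_acinus=False)
            else:
                per_acinus = (
                    census.acinar_per_acinus if comp == "acinar" else census.myo_per_acinus
                )
                for tip, t_cells in sorted(trace.tip_cells.items()):
                    if not tree.node(tip).has_acinus:
                        continue
                    share = min(t_cells / n_c, 1.0)
                    n_lab = int(rng.binomial(round_half_up(per_acinus), share))
                    for _ in range(n_lab):
                        in_acinus = True
                        if comp == "acinar" and rng.random() < config.duct_acinar_fraction:
                            in_acinus = False
                        emit(tip, comp, in_acinus=in_acinus)
        truth.clone_cells[prog.id] = my_cells
        truth.clone_occupied[prog.id] = sorted(occupied)
        truth.true_ca[prog.id] = prog.endbud_id
    return cells


# ---------------------------------------------------------------------------
# Convenience: full dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """A generated gland: tree, labelled cells and ground truth."""

    tree: BranchingTree
    cells: list[LabelledCell]
    ground_truth: SyntheticGroundTruth
    induction_endbud_ids: list[str]
    config: SyntheticConfig
    seed: int | None

    def write(self, outdir) -> dict[str, Path]:
        """Emit tree.json, cells.csv and ground_truth.json; each file embeds
        the seed and config hash."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"seed": self.seed, "config_hash": self.config.config_hash()}
        paths = {
            "tree": outdir / "tree.json",
            "cells": outdir / "cells.csv",
            "ground_truth": outdir / "ground_truth.json",
        }
        write_tree(self.tree, paths["tree"], metadata=meta)
        write_cells(
            self.cells,
            paths["cells"],
            header_comment=f"seed={self.seed} config_hash={meta['config_hash']}",
        )
        gt = self.ground_truth.to_json_dict()
        gt["_meta"] = meta
        with open(paths["ground_truth"], "w") as fh:
            json.dump(gt, fh, indent=1)
            fh.write("\n")
        return paths


def generate_dataset(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> SyntheticDataset:
    """Generate a complete synthetic gland from a single integer seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    tree = generate_tree(config, rng)
    endbuds = induction_endbuds(tree, min(config.generations_at_induction, tree.depth))
    truth = induce_clones(tree, config, rng, endbuds=endbuds)
    truth.seed_info = f"seed={seed} config={config.config_hash()}"
    cells = grow_and_populate(tree, truth, config, rng)
    return SyntheticDataset(
        tree=tree,
        cells=cells,
        ground_truth=truth,
        induction_endbud_ids=endbuds,
        config=config,
        seed=seed,
    )
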