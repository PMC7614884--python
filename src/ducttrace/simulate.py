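"""Stochastic null model of clone dynamics on a fixed branching tree.

A clone starts as a single tip cell placed on a duct of the tree.  Cells
advance one level per step toward the tree endpoints.  At each duct
bifurcation the cell number doubles and, under the default *random* rule,
each resulting cell independently chooses one daughter branch uniformly —
the well-mixed picture in which progenitor progeny are randomly segregated
between daughter endbuds.  Each branch traversal deposits one "unit" of duct
density in the traversed duct, so the units per duct record the number of
traversals.  The process iterates until every surviving lineage reaches an
endpoint of the tree.

The *coherent* rule is the alternative hypothesis in which renewing cells
maintain their position across rounds of bifurcation: the doubled clone
stays together and enters a single uniformly chosen daughter branch, so
2**delta cells run down one duct path and the occupied-duct density grows
exponentially with level, whereas random segregation produces only
linear-like growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import clones as _clones
from .tree import BranchingTree

__all__ = [
    "SimConfig",
    "CloneTrace",
    "EnsembleResult",
    "MergerSimResult",
    "simulate_clone",
    "simulate_ensemble",
    "estimate_merger_by_simulation",
]

_RULES = ("random", "coherent")


@dataclass
class SimConfig:
    """Parameters of a simulation run."""

    start_level: int | None = None
    start_node: str | None = None
    n_clones: int = 1000
    n_realizations: int = 1
    seed: int | None = None
    segregation_rule: str = "random"

    def __post_init__(self):
        if self.segregation_rule not in _RULES:
            raise ValueError(f"segregation_rule must be one of {_RULES}")
        if self.n_clones < 1 or self.n_realizations < 1:
            raise ValueError("n_clones and n_realizations must be >= 1")


@dataclass
class CloneTrace:
    """Outcome of one simulated clone."""

    start_node: str
    duct_units: dict[str, int]  # deposited density units per traversed duct
    tip_cells: dict[str, int]  # final cell counts per terminal duct

    @property
    def total_units(self) -> int:
        return sum(self.duct_units.values())

    @property
    def final_cells(self) -> int:
        return sum(self.tip_cells.values())

    def occupied_ducts(self) -> set[str]:
        """Ducts the clone touches: the start duct plus every traversed duct."""
        return {self.start_node} | {d for d, u in self.duct_units.items() if u > 0}


def simulate_clone(
    tree: BranchingTree,
    start_node: str,
    rng: np.random.Generator,
    rule: str = "random",
) -> CloneTrace:
    """Evolve a single clone from ``start_node`` to the tree endpoints.

    A terminal start yields the trivial trace: one final cell, no deposits.
    At a k-furcation the cell still duplicates once; under the random rule
    each daughter picks uniformly among the k branches, under the coherent
    rule the whole (doubled) clone enters one uniformly chosen branch.
    """
    if rule not in _RULES:
        raise ValueError(f"rule must be one of {_RULES}")
    tree.node(start_node)
    duct_units: dict[str, int] = {}
    tip_cells: dict[str, int] = {}
    # cells at the frontier, keyed by duct; processed level by level
    frontier = {start_node: 1}
    while frontier:
        next_frontier: dict[str, int] = {}
        for nid, n_cells in frontier.items():
            children = tree.node(nid).child_ids
            if not children:
                tip_cells[nid] = tip_cells.get(nid, 0) + n_cells
                continue
            k = len(children)
            movers = 2 * n_cells if k >= 2 else n_cells
            if k == 1:
                alloc = [movers]
            elif rule == "random":
                alloc = rng.multinomial(movers, [1.0 / k] * k)
            else:  # coherent: the clone stays together on one branch
                alloc = [0] * k
                alloc[rng.integers(k)] = movers
            for cid, m in zip(children, alloc):
                if m > 0:
                    duct_units[cid] = duct_units.get(cid, 0) + int(m)
                    next_frontier[cid] = next_frontier.get(cid, 0) + int(m)
        frontier = next_frontier
    return CloneTrace(start_node=start_node, duct_units=duct_units, tip_cells=tip_cells)


@dataclass
class EnsembleResult:
    """Summaries of a simulated clone ensemble."""

    clone_sizes: np.ndarray  # final tip-cell count per clone
    density_profile: pd.DataFrame  # mean unit density per occupied duct vs delta level
    start_levels: np.ndarray
    rule: str

    def size_distribution(self) -> pd.DataFrame:
        sizes, counts = np.unique(self.clone_sizes, return_counts=True)
        return pd.DataFrame(
            {"size": sizes, "count": counts, "fraction": counts / counts.sum()}
        )


def _pick_start_nodes(
    tree: BranchingTree,
    start_level: int | Sequence[int],
    n: int,
    rng: np.random.Generator,
) -> list[str]:
    """Uniform-with-replacement start nodes at the given level(s).

    Replacement is what creates same-endbud mergers, mirroring Poisson
    induction over endbuds."""
    levels = [start_level] if isinstance(start_level, (int, np.integer)) else list(start_level)
    pools = {}
    for lv in levels:
        pool = tree.nodes_at_level(int(lv))
        if not pool:
            raise ValueError(f"no ducts at start level {lv} (tree depth {tree.depth})")
        pools[int(lv)] = sorted(pool)
    chosen_levels = rng.choice(list(pools), size=n)
    return [pools[int(lv)][rng.integers(len(pools[int(lv)]))] for lv in chosen_levels]


def simulate_ensemble(
    tree: BranchingTree,
    n_clones: int = 1000,
    start_levels: int | Sequence[int] = 7,
    seed: int | None = None,
    rule: str = "random",
    rng: np.random.Generator | None = None,
) -> EnsembleResult:
    """Simulate an ensemble of clones and summarize with the same estimators
    as the measured-clone analysis (shared density aggregation code path).

    Density per duct is deposited units divided by duct length; the profile
    conditions on occupied ducts, indexed by level distance from the start
    node.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    starts = _pick_start_nodes(tree, start_levels, n_clones, rng)
    sizes = np.empty(n_clones, dtype=np.int64)
    levels = np.empty(n_clones, dtype=np.int64)
    records = []
    for i, s in enumerate(starts):
        trace = simulate_clone(tree, s, rng, rule=rule)
        sizes[i] = trace.final_cells
        start_level = tree.level_of(s)
        levels[i] = start_level
        for duct, units in trace.duct_units.items():
            node = tree.node(duct)
            if node.length_um > 0:
                records.append(
                    {
                        "delta_level": node.level - start_level,
                        "density": units / node.length_um,
                    }
                )
    profile = _clones.density_profile_from_records(
        pd.DataFrame(records, columns=["delta_level", "density"])
    )
    return EnsembleResult(
        clone_sizes=sizes, density_profile=profile, start_levels=levels, rule=rule
    )


@dataclass
class MergerSimResult:
    """Simulation-based merger-rate estimate.

    ``fraction`` is the pooled fraction of apparent clones (overlap
    components of same-color clones) that are mergers, i.e. contain two or
    more induced clones — the quantity the analytic ``1 - P_1/P_c`` model
    describes.  ``clone_involved_fraction`` is the fraction of induced
    clones belonging to a merged component.  ``se`` is the Monte-Carlo
    standard error of ``fraction`` (delta method on the ratio of sums).
    """

    fraction: float
    se: float
    clone_involved_fraction: float
    per_realization: np.ndarray
    n_clones: int
    n_realizations: int
    start_level: int


def _overlap_components(occupied: list[set]) -> list[list[int]]:
    """Union-find of clones sharing at least one duct."""
    parent = list(range(len(occupied)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(occupied)):
        for j in range(i + 1, len(occupied)):
            if occupied[i] & occupied[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, list[int]] = {}
    for i in range(len(occupied)):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def estimate_merger_by_simulation(
    tree: BranchingTree,
    n_clones: int = 10,
    start_level: int = 7,
    n_realizations: int = 100,
    seed: int | None = None,
    rule: str = "random",
    rng: np.random.Generator | None = None,
) -> MergerSimResult:
    """Estimate the clone-merger rate by simulating the simultaneous
    evolution of ``n_clones`` same-color clones from ``start_level``.

    Per realization, start nodes are sampled uniformly with replacement
    among the ducts at ``start_level``; two clones merge when their
    occupied-duct sets overlap.  The merger fraction pools merged and total
    apparent clones over all realizations, which on full binary trees is an
    unbiased ratio estimate of the closed-form ``1 - P_1/P_c`` with N the
    number of ducts at the start level and M = n_clones.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if start_level > tree.depth:
        raise ValueError(f"start_level {start_level} deeper than tree ({tree.depth})")
    merged_counts = np.empty(n_realizations, dtype=np.int64)
    comp_counts = np.empty(n_realizations, dtype=np.int64)
    involved = 0
    for r in range(n_realizations):
        starts = _pick_start_nodes(tree, start_level, n_clones, rng)
        occupied = [
            simulate_clone(tree, s, rng, rule=rule).occupied_ducts() for s in starts
        ]
        comps = _overlap_components(occupied)
        comp_counts[r] = len(comps)
        merged = [c for c in comps if len(c) > 1]
        merged_counts[r] = len(merged)
        involved += sum(len(c) for c in merged)
    total_m = merged_counts.sum()
    total_c = comp_counts.sum()
    fraction = float(total_m / total_c)
    # delta-method SE of the ratio of per-realization sums
    mbar, cbar = merged_counts.mean(), comp_counts.mean()
    if cbar > 0 and n_realizations > 1:
        cov = np.cov(merged_counts, comp_counts, ddof=1)
        var_ratio = (
            cov[0, 0] - 2 * fraction * cov[0, 1] + fraction**2 * cov[1, 1]
        ) / (cbar**2 * n_realizations)
        se = float(np.sqrt(max(var_ratio, 0.0)))
    else:
        se = float("nan")
    with np.errstate(invalid="ignore"):
        per_real = np.where(comp_counts > 0, merged_counts / comp_counts, np.nan)
    return MergerSimResult(
        fraction=fraction,
        se=se,
        clone_involved_fraction=float(involved / (n_clones * n_realizations)),
        per_realization=per_real,
        n_clones=n_clones,
        n_realizations=n_realizations,
        start_level=start_level,
    )
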