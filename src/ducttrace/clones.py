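"""Clone grouping, common-ancestor inference, potency classification and
dispersion statistics.

A clone is the set of same-color labelled cells lying on one subtree of the
ductal network.  Its common ancestor (CA) is the deepest duct whose subtree
contains every occupied duct — the proxy for the clone's duct of origin at
induction.  Clones confined to a single duct/acinus ("non-renewing") are
filtered out before population statistics, since their founders cannot have
multiplied through endbud bifurcations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tree import BranchingTree, LabelledCell, COMPARTMENTS

__all__ = [
    "PotencyClass",
    "Clone",
    "Subclone",
    "DensityGrowthFit",
    "CloneSizeStats",
    "find_common_ancestor",
    "group_clones",
    "filter_renewing",
    "classify_potency",
    "potency_proportions",
    "clone_span",
    "subclones_of",
    "subclone_density_profile",
    "density_profile_from_records",
    "fit_density_growth",
    "clone_size_stats",
    "clones_to_frame",
]

_POTENCY_GROUPS = {1: "uni", 2: "bi", 3: "multi", 4: "multi"}


@dataclass(frozen=True)
class PotencyClass:
    """Set of lineages represented in a clone; order 1-4 = uni/bi/tri/quad."""

    lineages: frozenset

    def __post_init__(self):
        if not self.lineages:
            raise ValueError("a potency class needs at least one lineage")
        bad = set(self.lineages) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown lineage(s): {sorted(bad)}")

    @property
    def order(self) -> int:
        return len(self.lineages)

    @property
    def group(self) -> str:
        """Coarse class: 'uni', 'bi' or 'multi' (tri- and quadripotent)."""
        return _POTENCY_GROUPS[self.order]

    def __str__(self) -> str:
        return "+".join(sorted(self.lineages))


@dataclass
class Clone:
    """Same-color labelled cells on one subtree, with CA and potency."""

    id: str
    color: str
    cells: list[LabelledCell]
    ca_duct_id: str
    renewing: bool
    potency: PotencyClass | None = None
    span_levels: tuple[int, int] | None = None

    @property
    def cell_ids(self) -> set[str]:
        return {c.id for c in self.cells}

    @property
    def size(self) -> int:
        return len(self.cells)

    def occupied_ducts(self) -> set[str]:
        return {c.duct_id for c in self.cells}


@dataclass
class Subclone:
    """The subset of a clone's ductal cells occupying a single duct."""

    clone_id: str
    duct_id: str
    n_cells: int
    density: float  # cells per micron of duct length
    delta_level: int  # duct level minus CA level


# ---------------------------------------------------------------------------
# Common ancestor
# ---------------------------------------------------------------------------


def find_common_ancestor(tree: BranchingTree, occupied_duct_ids: Iterable[str]) -> str:
    """Deepest duct whose subtree contains every occupied duct.

    Operationally the duct at the lowest level of the tree from which all
    labelled ducts and tips can be reached.  Raises on an empty set or on
    ducts that do not resolve against the tree.
    """
    ids = list(occupied_duct_ids)
    if not ids:
        raise ValueError("occupied duct set is empty")
    paths = [tree.ancestor_path(i) for i in ids]
    shortest = min(len(p) for p in paths)
    ca = None
    for depth in range(shortest):
        candidate = paths[0][depth]
        if all(p[depth] == candidate for p in paths):
            ca = candidate
        else:
            break
    if ca is None:  # cannot happen in a single rooted tree
        raise ValueError("occupied ducts do not share a common ancestor")
    return ca


# ---------------------------------------------------------------------------
# Grouping and filtering
# ---------------------------------------------------------------------------


def group_clones(
    tree: BranchingTree,
    cells: Sequence[LabelledCell],
    min_ca_level: int | None = None,
    id_prefix: str = "clone",
) -> list[Clone]:
    """Group labelled cells into putative clones.

    Cells of the same fluorophore color within one connected occupied
    subtree form a clone.  By default any two same-color cells in the lobe
    are co-clonal (their joint CA always exists in a single rooted tree).
    With ``min_ca_level`` set, two same-color cells are co-clonal only when
    their pairwise CA lies at that level or deeper — equivalently, cells are
    grouped by their ancestor duct at ``min_ca_level`` (cells shallower than
    the threshold group by their own duct).

    Each cell belongs to exactly one clone.  Potency, renewal flag, CA and
    span are filled in for every clone.
    """
    bad = sorted({c.duct_id for c in cells if c.duct_id not in tree})
    if bad:
        raise KeyError(f"cell duct id(s) not in tree: {bad[:10]}")

    groups: dict[tuple, list[LabelledCell]] = {}
    for cell in cells:
        if min_ca_level is None:
            key = (cell.color,)
        else:
            anc = tree.ancestor_at_level(cell.duct_id, min_ca_level)
            key = (cell.color, anc if anc is not None else f"duct:{cell.duct_id}")
        groups.setdefault(key, []).append(cell)

    clones = []
    for i, (key, members) in enumerate(sorted(groups.items(), key=lambda kv: kv[0])):
        occupied = {c.duct_id for c in members}
        ca = find_common_ancestor(tree, occupied)
        clone = Clone(
            id=f"{id_prefix}{i:04d}",
            color=key[0],
            cells=members,
            ca_duct_id=ca,
            renewing=len(occupied) > 1,
        )
        clone.potency = classify_potency(clone)
        clone.span_levels = clone_span(clone, tree)[1:]
        clones.append(clone)
    return clones


def filter_renewing(clones: Sequence[Clone]) -> tuple[list[Clone], list[Clone]]:
    """Partition clones into (renewing, non_renewing).

    Non-renewing clones are entirely contained within a single duct segment
    (the acinus of a terminal duct shares its duct's address); they likely
    derive from cells already committed at induction and are removed from
    downstream statistics.
    """
    renewing = [c for c in clones if c.renewing]
    non_renewing = [c for c in clones if not c.renewing]
    return renewing, non_renewing


# ---------------------------------------------------------------------------
# Potency
# ---------------------------------------------------------------------------


def classify_potency(
    clone: Clone, include_duct_acinar: bool = False
) -> PotencyClass | None:
    """Distinct compartments among the clone's counted cells.

    Acinar cells located within ducts (``in_acinus=False``) do not
    contribute to the formation of an acinus and are excluded from the
    acinar call unless ``include_duct_acinar`` is set.  Returns None when
    the exclusions empty the clone (flagged, excluded from proportions).
    """
    lineages = set()
    for cell in clone.cells:
        if (
            cell.compartment == "acinar"
            and not cell.in_acinus
            and not include_duct_acinar
        ):
            continue
        lineages.add(cell.compartment)
    if not lineages:
        return None
    return PotencyClass(frozenset(lineages))


def potency_proportions(
    clones: Iterable, by: str = "group"
) -> pd.DataFrame:
    """Per-class clone proportions with standard error of proportion.

    ``clones`` may be Clone objects or bare PotencyClass instances; clones
    whose potency is None (emptied by exclusions) are dropped.  ``by`` is
    ``"group"`` (uni/bi/multi), ``"order"`` (1-4) or ``"lineages"`` (the
    exact compartment combination).  SEP = sqrt(p(1-p)/n).
    """
    potencies = []
    for c in clones:
        p = c.potency if isinstance(c, Clone) else c
        if p is not None:
            potencies.append(p)
    if not potencies:
        raise ValueError("no classifiable clones")
    if by == "group":
        labels = [p.group for p in potencies]
        order = ["uni", "bi", "multi"]
    elif by == "order":
        labels = [p.order for p in potencies]
        order = [1, 2, 3, 4]
    elif by == "lineages":
        labels = [str(p) for p in potencies]
        order = sorted(set(labels))
    else:
        raise ValueError(f"unknown 'by': {by!r}")
    n = len(labels)
    rows = []
    for cls in order:
        k = labels.count(cls)
        if k == 0 and by == "lineages":
            continue
        p_hat = k / n
        rows.append(
            {
                "class": cls,
                "count": k,
                "n": n,
                "proportion": p_hat,
                "sep": float(np.sqrt(p_hat * (1 - p_hat) / n)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Span and dispersion
# ---------------------------------------------------------------------------


def clone_span(clone: Clone, tree: BranchingTree) -> tuple[int, int, int]:
    """(CA level, first occupied level, last occupied level)."""
    levels = [tree.level_of(d) for d in clone.occupied_ducts()]
    ca_level = tree.level_of(clone.ca_duct_id)
    return ca_level, min(levels), max(levels)


def subclones_of(
    clone: Clone,
    tree: BranchingTree,
    compartments: Sequence[str] | None = None,
) -> list[Subclone]:
    """Split a clone into subclones: its ductal cells per occupied duct.

    Ductal cells are cells not contained in an acinus; ``compartments``
    optionally restricts to e.g. ``("luminal",)``.  Density is cells per
    micron of the host duct.
    """
    ca_level = tree.level_of(clone.ca_duct_id)
    counts: dict[str, int] = {}
    for cell in clone.cells:
        if cell.in_acinus:
            continue
        if compartments is not None and cell.compartment not in compartments:
            continue
        counts[cell.duct_id] = counts.get(cell.duct_id, 0) + 1
    out = []
    for duct_id, n_cells in sorted(counts.items()):
        node = tree.node(duct_id)
        density = n_cells / node.length_um if node.length_um > 0 else np.nan
        out.append(
            Subclone(
                clone_id=clone.id,
                duct_id=duct_id,
                n_cells=n_cells,
                density=density,
                delta_level=node.level - ca_level,
            )
        )
    return out


def density_profile_from_records(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate (delta_level, density) records into a mean +/- SD profile.

    Shared estimator for measured clones and simulated ensembles: averages
    condition on occupied ducts only (unoccupied ducts contribute no zero).
    The SD of a single observation is reported as absent (NaN).
    """
    if records.empty:
        return pd.DataFrame(columns=["delta_level", "mean_density", "sd", "n_ducts"])
    grouped = records.groupby("delta_level")["density"]
    out = grouped.agg(mean_density="mean", sd=lambda x: x.std(ddof=1), n_ducts="count")
    out = out.reset_index()
    out.loc[out["n_ducts"] < 2, "sd"] = np.nan
    return out


def subclone_density_profile(
    clones: Sequence[Clone],
    tree: BranchingTree,
    compartments: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean labelled-cell density (cells/um) +/- SD per level distance from
    the CA, pooled over the occupied ducts of all clones."""
    records = []
    for clone in clones:
        for sc in subclones_of(clone, tree, compartments=compartments):
            if np.isfinite(sc.density):
                records.append({"delta_level": sc.delta_level, "density": sc.density})
    return density_profile_from_records(pd.DataFrame(records, columns=["delta_level", "density"]))


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------


@dataclass
class DensityGrowthFit:
    """Linear vs exponential fit of a subclone-density profile.

    The linear model (density ~ a + b*delta_level) is the signature of
    random segregation of progenitors between daughter endbuds; exponential
    growth (log density linear in level) is the signature of coherent,
    position-preserving dispersion.  Preference is decided by residual sum
    of squares on the common support, in density space.
    """

    linear_slope: float
    linear_intercept: float
    linear_rss: float
    exp_rate: float | None
    exp_log_intercept: float | None
    exp_rss: float | None
    preferred: str
    n_points: int
    max_level: int

    def predict_linear(self, delta):
        return self.linear_intercept + self.linear_slope * np.asarray(delta, float)

    def predict_exponential(self, delta):
        if self.exp_rate is None:
            raise ValueError("exponential fit unavailable")
        return np.exp(self.exp_log_intercept + self.exp_rate * np.asarray(delta, float))


def fit_density_growth(profile: pd.DataFrame, max_level: int = 18) -> DensityGrowthFit:
    """Fit linear and exponential growth models to a density profile.

    Ordinary least squares of mean density on delta_level over
    ``delta_level <= max_level``; the exponential fit is least squares on
    the log of the mean density (skipped with a warning when any mean is
    non-positive).  Requires at least 3 profile points.
    """
    sub = profile[profile["delta_level"] <= max_level]
    if len(sub) < 3:
        raise ValueError(f"need >=3 profile points within max_level, got {len(sub)}")
    x = sub["delta_level"].to_numpy(dtype=float)
    y = sub["mean_density"].to_numpy(dtype=float)

    slope, intercept = np.polyfit(x, y, 1)
    lin_rss = float(np.sum((y - (intercept + slope * x)) ** 2))

    exp_rate = exp_b = exp_rss = None
    if np.all(y > 0):
        rate, b = np.polyfit(x, np.log(y), 1)
        exp_rate, exp_b = float(rate), float(b)
        exp_rss = float(np.sum((y - np.exp(b + rate * x)) ** 2))
        preferred = "exponential" if exp_rss < lin_rss else "linear"
    else:
        warnings.warn(
            "non-positive mean densities: exponential fit skipped", RuntimeWarning
        )
        preferred = "linear"

    return DensityGrowthFit(
        linear_slope=float(slope),
        linear_intercept=float(intercept),
        linear_rss=lin_rss,
        exp_rate=exp_rate,
        exp_log_intercept=exp_b,
        exp_rss=exp_rss,
        preferred=preferred,
        n_points=len(sub),
        max_level=max_level,
    )


@dataclass
class CloneSizeStats:
    """Clone-size distribution summaries.

    ``survival`` tabulates S(s) = P(size > s) at the observed sizes; the
    exponential decay scale comes from least squares of log S on s with the
    final point (S = 0) excluded.  ``size_subtree_corr`` is the Spearman
    rank correlation between clone size and the number of ducts in the
    clone's CA subtree (midpoint ranks for ties).
    """

    sizes: np.ndarray
    survival: pd.DataFrame
    decay_scale: float | None
    degenerate: bool
    size_subtree_corr: float | None
    size_subtree_pvalue: float | None
    subtree_sizes: np.ndarray | None = None


def clone_size_stats(
    clones: Sequence[Clone], tree: BranchingTree | None = None
) -> CloneSizeStats:
    """Sizes, empirical survival function, exponential-decay fit and the
    clone-size vs subtree-size correlation (requires ``tree`` and >=2
    clones for the correlation)."""
    if not clones:
        raise ValueError("no clones")
    sizes = np.array(sorted(c.size for c in clones), dtype=float)
    n = len(sizes)
    uniq = np.unique(sizes)
    surv = np.array([(sizes > s).sum() / n for s in uniq])
    survival = pd.DataFrame({"size": uniq, "survival": surv})

    degenerate = len(uniq) < 2
    decay_scale = None
    if degenerate:
        warnings.warn("all clone sizes equal: exponential fit degenerate", RuntimeWarning)
    else:
        keep = surv > 0  # drop the final S=0 point
        if keep.sum() >= 2:
            slope, _ = np.polyfit(uniq[keep], np.log(surv[keep]), 1)
            if slope < 0:
                decay_scale = float(-1.0 / slope)

    corr = pval = None
    subtree_sizes = None
    if tree is not None and len(clones) >= 2:
        subtree_sizes = np.array(
            [len(tree.subtree_ids(c.ca_duct_id)) for c in clones], dtype=float
        )
        clone_sizes = np.array([c.size for c in clones], dtype=float)
        if len(np.unique(clone_sizes)) > 1 and len(np.unique(subtree_sizes)) > 1:
            rho = sps.spearmanr(clone_sizes, subtree_sizes)
            corr, pval = float(rho.statistic), float(rho.pvalue)
    return CloneSizeStats(
        sizes=sizes,
        survival=survival,
        decay_scale=decay_scale,
        degenerate=degenerate,
        size_subtree_corr=corr,
        size_subtree_pvalue=pval,
        subtree_sizes=subtree_sizes,
    )


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def clones_to_frame(clones: Sequence[Clone], tree: BranchingTree) -> pd.DataFrame:
    """Clones table: one row per clone with CA, potency and span columns."""
    rows = []
    for c in clones:
        ca_level, lo, hi = clone_span(c, tree)
        rows.append(
            {
                "clone_id": c.id,
                "color": c.color,
                "ca_duct": c.ca_duct_id,
                "ca_level": ca_level,
                "n_cells": c.size,
                "renewing": c.renewing,
                "potency_order": c.potency.order if c.potency else pd.NA,
                "lineages": str(c.potency) if c.potency else "",
                "span_min": lo,
                "span_max": hi,
            }
        )
    return pd.DataFrame(rows)
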