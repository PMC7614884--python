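"""Estimation of the number of renewing tip progenitors per compartment.

A renewing progenitor induced in an endbud contributes, on average, a
representative fraction of the cells of its compartment in the subtree that
derives from the clone's common ancestor.  If a unipotent acinar clone
contributes on average c_u percent of the acinar cells of its subtree, the
endbud held about 100/c_u unipotent renewing acinar progenitors.  With
uni-, bi- and multipotent progenitors coexisting at fractions f_u, f_b, f_m
(among clones contributing to compartment c) and mean percentage
contributions c_u, c_b, c_m, the total pool for compartment c is

    N_c = 100 / (f_u*c_u + f_b*c_b + f_m*c_m),

split as f_u*N_c, f_b*N_c, f_m*N_c per type.  Subtree compartment totals
come from a fixed cell census: mean acinar and myoepithelial cells per
acinus, and linear densities of luminal and basal cells per micron of duct.
The estimate assumes labelling is approximately representative of the endbud
composition; reports carry that caveat as an explicit flag rather than a
correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .clones import Clone, classify_potency
from .tree import BranchingTree, COMPARTMENTS

__all__ = [
    "CensusModel",
    "ProgenitorEstimate",
    "ProgenitorCensusResult",
    "subtree_cell_census",
    "fractional_contribution",
    "estimate_progenitors",
    "estimate_compartment",
    "estimate_all_compartments",
    "round_half_up",
]

#: Default bound on endbud size (cells) used as a plausibility flag.
DEFAULT_ENDBUD_BOUND = 117.0


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CensusModel:
    """Per-acinus cell counts and per-micron ductal cell densities.

    Defaults: 63 acinar (95% CI 48-79) and 6 myoepithelial (CI 5-7) cells
    per acinus; 0.29 +/- 0.02 (SEM) luminal and 0.25 +/- 0.04 (SEM) basal
    cells per micron of duct.
    """

    acinar_per_acinus: float = 63.0
    myo_per_acinus: float = 6.0
    luminal_per_um: float = 0.29
    basal_per_um: float = 0.25
    acinar_ci: tuple[float, float] = (48.0, 79.0)
    myo_ci: tuple[float, float] = (5.0, 7.0)

    def __post_init__(self):
        for name in ("acinar_per_acinus", "myo_per_acinus", "luminal_per_um", "basal_per_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_yaml(cls, path) -> "CensusModel":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def subtree_cell_census(
    tree: BranchingTree, node_id: str, census: CensusModel | None = None
) -> dict[str, float]:
    """Estimated cell counts per compartment in the subtree rooted at
    ``node_id``: acinar and myoepithelial scale with the number of acini,
    luminal and basal with total duct length."""
    census = census or CensusModel()
    ids = tree.subtree_ids(node_id)
    n_acini = tree.n_acini(ids)
    length = tree.total_length(ids)
    return {
        "acinar": census.acinar_per_acinus * n_acini,
        "myoepithelial": census.myo_per_acinus * n_acini,
        "luminal": census.luminal_per_um * length,
        "basal": census.basal_per_um * length,
    }


def fractional_contribution(
    clone: Clone,
    tree: BranchingTree,
    compartment: str,
    census: CensusModel | None = None,
    include_duct_acinar: bool = False,
) -> float:
    """Percentage of the subtree's compartment-c cells contributed by the
    clone: 100 x (clone cells of compartment c) / (subtree census of c).

    Duct-associated acinar cells (acinar compartment, ``in_acinus=False``)
    are excluded by default, as they do not contribute to forming an acinus.
    Raises when the subtree census for the compartment is zero.
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    totals = subtree_cell_census(tree, clone.ca_duct_id, census)
    denom = totals[compartment]
    if denom <= 0:
        raise ZeroDivisionError(
            f"subtree of {clone.ca_duct_id!r} has zero {compartment} census"
        )
    n = 0
    for cell in clone.cells:
        if cell.compartment != compartment:
            continue
        if compartment == "acinar" and not cell.in_acinus and not include_duct_acinar:
            continue
        n += 1
    return 100.0 * n / denom


@dataclass
class ProgenitorEstimate:
    """Progenitor-pool estimate for one compartment."""

    compartment: str | None
    f_u: float
    f_b: float
    f_m: float
    c_u: float  # mean percentage contributions per clone type
    c_b: float
    c_m: float
    n_raw: float  # N_c straight from the formula
    n_uni: int  # per-type counts, rounded half-up
    n_bi: int
    n_multi: int
    n_contributing_clones: int | None = None
    within_endbud_bound: bool | None = None
    representative_labelling_assumed: bool = True

    @property
    def n_rounded(self) -> int:
        """Total as the sum of the rounded per-type counts."""
        return self.n_uni + self.n_bi + self.n_multi


def estimate_progenitors(
    f_u: float,
    f_b: float,
    f_m: float,
    c_u: float,
    c_b: float,
    c_m: float,
    compartment: str | None = None,
    n_contributing_clones: int | None = None,
    endbud_bound: float | None = DEFAULT_ENDBUD_BOUND,
) -> ProgenitorEstimate:
    """Evaluate N_c = 100/(f_u*c_u + f_b*c_b + f_m*c_m).

    The c values are percentage contributions (a unipotent clone providing
    2% of its subtree's compartment enters as ``c_u=2``).  Inputs where all
    non-zero c values are below 0.1 are taken to be fractions and
    auto-scaled by 100 with a warning (genuine sub-0.1% contributions would
    imply pools far beyond the size of an endbud, so the heuristic is safe
    in-domain).  Per-type counts are rounded half-up; the total is reported
    both raw (``n_raw``) and as the rounded sum (``n_rounded``).
    """
    if abs((f_u + f_b + f_m) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {f_u + f_b + f_m!r}")
    if min(f_u, f_b, f_m) < 0 or min(c_u, c_b, c_m) < 0:
        raise ValueError("fractions and contributions must be non-negative")
    cs = [c_u, c_b, c_m]
    nonzero = [c for c in cs if c > 0]
    if not nonzero:
        raise ValueError("all contributions are zero: N_c undefined")
    if max(nonzero) < 0.1:
        warnings.warn(
            "all contributions < 0.1: interpreting as fractions and scaling "
            "to percentages",
            RuntimeWarning,
        )
        c_u, c_b, c_m = (100.0 * c for c in cs)
    denom = f_u * c_u + f_b * c_b + f_m * c_m
    if denom <= 0:
        raise ValueError("no clone type both contributes and is present (f.c = 0)")
    n_raw = 100.0 / denom
    est = ProgenitorEstimate(
        compartment=compartment,
        f_u=f_u,
        f_b=f_b,
        f_m=f_m,
        c_u=c_u,
        c_b=c_b,
        c_m=c_m,
        n_raw=n_raw,
        n_uni=round_half_up(f_u * n_raw),
        n_bi=round_half_up(f_b * n_raw),
        n_multi=round_half_up(f_m * n_raw),
        n_contributing_clones=n_contributing_clones,
    )
    if endbud_bound is not None:
        est.within_endbud_bound = n_raw <= endbud_bound
    return est


def _clone_type(clone: Clone, include_duct_acinar: bool) -> str | None:
    pot = classify_potency(clone, include_duct_acinar=include_duct_acinar)
    if pot is None:
        return None
    return {1: "uni", 2: "bi"}.get(pot.order, "multi")


def estimate_compartment(
    clones: Sequence[Clone],
    tree: BranchingTree,
    compartment: str,
    census: CensusModel | None = None,
    include_duct_acinar: bool = False,
    endbud_bound: float | None = DEFAULT_ENDBUD_BOUND,
) -> ProgenitorEstimate | None:
    """Progenitor estimate for one compartment from one gland's renewing
    clones.  Returns None when no clone contributes to the compartment."""
    contributions: dict[str, list[float]] = {"uni": [], "bi": [], "multi": []}
    for clone in clones:
        if not clone.renewing:
            continue
        ctype = _clone_type(clone, include_duct_acinar)
        if ctype is None:
            continue
        contrib = fractional_contribution(
            clone, tree, compartment, census, include_duct_acinar=include_duct_acinar
        )
        if contrib > 0:
            contributions[ctype].append(contrib)
    n_total = sum(len(v) for v in contributions.values())
    if n_total == 0:
        return None
    f_u = len(contributions["uni"]) / n_total
    f_b = len(contributions["bi"]) / n_total
    f_m = len(contributions["multi"]) / n_total
    c_u = float(np.mean(contributions["uni"])) if contributions["uni"] else 0.0
    c_b = float(np.mean(contributions["bi"])) if contributions["bi"] else 0.0
    c_m = float(np.mean(contributions["multi"])) if contributions["multi"] else 0.0
    return estimate_progenitors(
        f_u,
        f_b,
        f_m,
        c_u,
        c_b,
        c_m,
        compartment=compartment,
        n_contributing_clones=n_total,
        endbud_bound=endbud_bound,
    )


@dataclass
class ProgenitorCensusResult:
    """Per-gland and aggregated progenitor estimates."""

    per_gland: list[dict[str, ProgenitorEstimate]]
    summary: pd.DataFrame  # compartment, mean N, SD across glands, n_glands

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, ests in enumerate(self.per_gland):
            for comp, est in ests.items():
                rows.append(
                    {
                        "gland": g,
                        "compartment": comp,
                        "f_u": est.f_u,
                        "f_b": est.f_b,
                        "f_m": est.f_m,
                        "c_u": est.c_u,
                        "c_b": est.c_b,
                        "c_m": est.c_m,
                        "N_raw": est.n_raw,
                        "N_rounded": est.n_rounded,
                        "n_uni": est.n_uni,
                        "n_bi": est.n_bi,
                        "n_multi": est.n_multi,
                        "within_endbud_bound": est.within_endbud_bound,
                    }
                )
        return pd.DataFrame(rows)


def estimate_all_compartments(
    glands: Sequence[tuple[BranchingTree, Sequence[Clone]]] | tuple,
    census: CensusModel | None = None,
    include_duct_acinar: bool = False,
    endbud_bound: float = DEFAULT_ENDBUD_BOUND,
) -> ProgenitorCensusResult:
    """Estimate progenitor pools for every compartment, per gland, then
    aggregate across glands (mean +/- SD).

    ``glands`` is a sequence of ``(tree, clones)`` pairs; a single pair is
    also accepted.  Compartments with no contributing clones in a gland are
    absent from that gland's estimates, not zero.
    """
    if (
        isinstance(glands, tuple)
        and len(glands) == 2
        and isinstance(glands[0], BranchingTree)
    ):
        glands = [glands]
    per_gland = []
    for tree, clones in glands:
        ests = {}
        for comp in COMPARTMENTS:
            est = estimate_compartment(
                clones,
                tree,
                comp,
                census,
                include_duct_acinar=include_duct_acinar,
                endbud_bound=endbud_bound,
            )
            if est is not None:
                ests[comp] = est
        per_gland.append(ests)
    rows = []
    for comp in COMPARTMENTS:
        vals = [e[comp].n_raw for e in per_gland if comp in e]
        if not vals:
            continue
        rows.append(
            {
                "compartment": comp,
                "n_glands": len(vals),
                "N_mean": float(np.mean(vals)),
                "N_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "within_endbud_bound": bool(np.mean(vals) <= endbud_bound),
            }
        )
    return ProgenitorCensusResult(per_gland=per_gland, summary=pd.DataFrame(rows))
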