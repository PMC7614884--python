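"""Model-style front end: a :class:`CloneStudy` is built from a branching
tree plus a labelled-cell table; ``fit()`` runs the full clonal analysis and
returns a :class:`CloneStudyResults` carrying the estimates, their
uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import clones as _cl
from .census import CensusModel, ProgenitorCensusResult, estimate_all_compartments
from .merger import infer_merger_from_colabel
from .tree import BranchingTree, LabelledCell, read_cells, read_tree

__all__ = ["CloneStudy", "CloneStudyResults", "MergerInference"]


@dataclass
class MergerInference:
    """Observed co-labelling of common-ancestor endbuds and the implied
    same-color merger rate (C/3 small-p inference)."""

    n_ca_endbuds: int
    n_colabelled: int
    c_hat: float
    p_merger_hat: float


class CloneStudy:
    """Clonal lineage-tracing analysis of one gland lobe.

    Parameters
    ----------
    tree
        The reconstructed ductal network.
    cells
        Labelled cells assigned to ducts of the tree.
    census
        Cell-census constants used for the progenitor estimates.
    min_ca_level
        Optional maximal-CA-depth guard for clone grouping.
    include_duct_acinar
        Count duct-associated acinar cells toward potency and census
        (excluded by default).
    """

    def __init__(
        self,
        tree: BranchingTree,
        cells: Sequence[LabelledCell],
        census: CensusModel | None = None,
        min_ca_level: int | None = None,
        include_duct_acinar: bool = False,
    ):
        bad = sorted({c.duct_id for c in cells if c.duct_id not in tree})
        if bad:
            raise KeyError(f"cell duct id(s) not in tree: {bad[:10]}")
        self.tree = tree
        self.cells = list(cells)
        self.census = census or CensusModel()
        self.min_ca_level = min_ca_level
        self.include_duct_acinar = include_duct_acinar

    @classmethod
    def from_files(cls, tree_path, cells_path, **kwargs) -> "CloneStudy":
        tree = read_tree(tree_path)
        cells = read_cells(cells_path, tree=tree)
        return cls(tree, cells, **kwargs)

    def fit(self) -> "CloneStudyResults":
        tree = self.tree
        clones = _cl.group_clones(tree, self.cells, min_ca_level=self.min_ca_level)
        if self.include_duct_acinar:
            for c in clones:
                c.potency = _cl.classify_potency(c, include_duct_acinar=True)
        renewing, non_renewing = _cl.filter_renewing(clones)

        potency = (
            _cl.potency_proportions(renewing, by="group") if renewing else None
        )
        profile = _cl.subclone_density_profile(renewing, tree) if renewing else None
        density_fit = None
        if profile is not None and len(profile) >= 3:
            density_fit = _cl.fit_density_growth(profile)
        size_stats = _cl.clone_size_stats(renewing, tree) if renewing else None

        merger = None
        if renewing:
            by_ca: dict[str, set[str]] = {}
            for c in renewing:
                by_ca.setdefault(c.ca_duct_id, set()).add(c.color)
            n_ca = len(by_ca)
            n_colab = sum(1 for colors in by_ca.values() if len(colors) > 1)
            c_hat, p_hat = infer_merger_from_colabel(n_colab, n_ca)
            merger = MergerInference(
                n_ca_endbuds=n_ca,
                n_colabelled=n_colab,
                c_hat=c_hat,
                p_merger_hat=p_hat,
            )

        progenitors = None
        if renewing:
            progenitors = estimate_all_compartments(
                (tree, renewing),
                census=self.census,
                include_duct_acinar=self.include_duct_acinar,
            )

        return CloneStudyResults(
            study=self,
            clones=clones,
            renewing=renewing,
            non_renewing=non_renewing,
            potency_proportions=potency,
            density_profile=profile,
            density_fit=density_fit,
            size_stats=size_stats,
            merger=merger,
            progenitors=progenitors,
        )


@dataclass
class CloneStudyResults:
    """Fitted clonal-analysis results for one gland lobe."""

    study: CloneStudy
    clones: list[_cl.Clone]
    renewing: list[_cl.Clone]
    non_renewing: list[_cl.Clone]
    potency_proportions: pd.DataFrame | None
    density_profile: pd.DataFrame | None
    density_fit: _cl.DensityGrowthFit | None
    size_stats: _cl.CloneSizeStats | None
    merger: MergerInference | None
    progenitors: ProgenitorCensusResult | None

    def clones_frame(self) -> pd.DataFrame:
        return _cl.clones_to_frame(self.clones, self.study.tree)

    def ca_levels(self) -> pd.DataFrame:
        """Common-ancestor level per renewing clone, with its potency group."""
        tree = self.study.tree
        rows = []
        for c in self.renewing:
            if c.potency is None:
                continue
            rows.append(
                {
                    "clone_id": c.id,
                    "potency_group": c.potency.group,
                    "ca_level": tree.level_of(c.ca_duct_id),
                }
            )
        return pd.DataFrame(rows)

    def to_summary_dict(self) -> dict:
        """Machine-readable summary of the main quantities."""
        out: dict = {
            "n_cells": len(self.study.cells),
            "n_clones": len(self.clones),
            "n_renewing": len(self.renewing),
            "n_non_renewing": len(self.non_renewing),
        }
        if self.potency_proportions is not None:
            out["potency"] = {
                str(r["class"]): {"proportion": r["proportion"], "sep": r["sep"]}
                for r in self.potency_proportions.to_dict("records")
            }
        if self.merger is not None:
            out["merger"] = {
                "n_ca_endbuds": self.merger.n_ca_endbuds,
                "n_colabelled": self.merger.n_colabelled,
                "C_hat": self.merger.c_hat,
                "P_merger_hat": self.merger.p_merger_hat,
            }
        if self.density_fit is not None:
            out["density_growth"] = {
                "preferred": self.density_fit.preferred,
                "linear_slope": self.density_fit.linear_slope,
                "exp_rate": self.density_fit.exp_rate,
            }
        if self.size_stats is not None:
            out["clone_sizes"] = {
                "mean": float(np.mean(self.size_stats.sizes)),
                "decay_scale": self.size_stats.decay_scale,
                "size_subtree_spearman": self.size_stats.size_subtree_corr,
            }
        if self.progenitors is not None and not self.progenitors.summary.empty:
            out["progenitors"] = {
                r["compartment"]: {
                    "N_mean": r["N_mean"],
                    "N_sd": None if pd.isna(r["N_sd"]) else r["N_sd"],
                    "within_endbud_bound": bool(r["within_endbud_bound"]),
                }
                for r in self.progenitors.summary.to_dict("records")
            }
        return out

    def summary(self) -> str:
        """Human-readable report of the fitted study."""
        lines = []
        push = lines.append
        push("Clonal lineage-tracing study")
        push("=" * 60)
        push(f"Ducts: {len(self.study.tree)}   depth: {self.study.tree.depth}")
        push(
            f"Cells: {len(self.study.cells)}   clones: {len(self.clones)} "
            f"({len(self.renewing)} renewing, {len(self.non_renewing)} non-renewing)"
        )
        if self.potency_proportions is not None:
            push("")
            push("Potency of renewing clones (proportion +/- SEP)")
            for r in self.potency_proportions.to_dict("records"):
                push(
                    f"  {r['class']:>6}: {r['proportion']:6.3f} +/- {r['sep']:.3f}"
                    f"   (n={r['count']})"
                )
        if self.merger is not None:
            push("")
            push(
                f"Co-labelled CAs: {self.merger.n_colabelled}/{self.merger.n_ca_endbuds}"
                f"  C = {self.merger.c_hat:.3f}  =>  P_merger ~ C/3 = "
                f"{self.merger.p_merger_hat:.3f}"
            )
        if self.density_fit is not None:
            push("")
            push(
                f"Subclone density growth: preferred model = "
                f"{self.density_fit.preferred} "
                f"(linear slope {self.density_fit.linear_slope:.4f}/level)"
            )
        if self.size_stats is not None:
            push(
                f"Clone sizes: mean {np.mean(self.size_stats.sizes):.1f}, "
                f"exp decay scale "
                + (
                    f"{self.size_stats.decay_scale:.1f}"
                    if self.size_stats.decay_scale
                    else "n/a"
                )
                + (
                    f", size~subtree Spearman rho = {self.size_stats.size_subtree_corr:.2f}"
                    if self.size_stats.size_subtree_corr is not None
                    else ""
                )
            )
        if self.progenitors is not None and not self.progenitors.summary.empty:
            push("")
            push("Renewing tip progenitors per compartment (representative-")
            push("labelling assumption; flag = within endbud-size bound)")
            for r in self.progenitors.summary.to_dict("records"):
                sd = "" if pd.isna(r["N_sd"]) else f" +/- {r['N_sd']:.0f}"
                push(
                    f"  {r['compartment']:>14}: N = {r['N_mean']:6.1f}{sd}"
                    f"   [{'ok' if r['within_endbud_bound'] else 'EXCEEDS BOUND'}]"
                )
        return "\n".join(lines)
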