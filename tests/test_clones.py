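"""Clone grouping, CA inference, potency and dispersion statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ducttrace.clones import (
    Clone,
    PotencyClass,
    classify_potency,
    clone_size_stats,
    clone_span,
    filter_renewing,
    find_common_ancestor,
    fit_density_growth,
    group_clones,
    potency_proportions,
    subclone_density_profile,
    subclones_of,
)
from ducttrace.tree import full_binary_tree

from conftest import cell, make_chain, random_tree


def brute_force_ca(tree, occupied):
    """Independent oracle: test every node, keep the deepest whose subtree
    contains all occupied ducts."""
    best, best_level = None, 0
    occ = set(occupied)
    for nid in tree.nodes:
        if occ <= set(tree.subtree_ids(nid)) and tree.level_of(nid) > best_level:
            best, best_level = nid, tree.level_of(nid)
    return best


class TestCommonAncestor:
    def test_single_duct(self, binary3):
        assert find_common_ancestor(binary3, ["L3N2"]) == "L3N2"

    def test_sibling_terminals(self, binary3):
        assert find_common_ancestor(binary3, ["L3N0", "L3N1"]) == "L2N0"

    def test_empty_set_rejected(self, binary3):
        with pytest.raises(ValueError):
            find_common_ancestor(binary3, [])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            tree = random_tree(rng, n_nodes=int(rng.integers(5, 60)))
            ids = list(tree.nodes)
            k = int(rng.integers(1, 6))
            occupied = [ids[i] for i in rng.integers(0, len(ids), size=k)]
            assert find_common_ancestor(tree, occupied) == brute_force_ca(tree, occupied)


class TestGrouping:
    def test_single_cell_single_clone(self, binary3):
        clones = group_clones(binary3, [cell(0, "L3N0")])
        assert len(clones) == 1
        assert not clones[0].renewing
        assert clones[0].ca_duct_id == "L3N0"

    def test_color_partition(self, binary3):
        cells = [
            cell(0, "L3N0", "RFP"),
            cell(1, "L3N1", "RFP"),
            cell(2, "L3N3", "YFP"),
        ]
        clones = group_clones(binary3, cells)
        assert len(clones) == 2
        by_color = {c.color: c for c in clones}
        assert by_color["RFP"].ca_duct_id == "L2N0" and by_color["RFP"].renewing
        assert by_color["YFP"].size == 1

    def test_min_ca_level_splits_same_color(self, binary4):
        # same color in the two level-2 subtrees: one clone by default,
        # two with the CA-depth guard
        cells = [cell(0, "L4N0", "RFP"), cell(1, "L4N7", "RFP")]
        assert len(group_clones(binary4, cells)) == 1
        assert len(group_clones(binary4, cells, min_ca_level=2)) == 2

    def test_distinct_colors_in_distinct_subtrees_recovered(self, binary4):
        colors = ["RFP", "YFP", "GFP", "CFP"]
        cells = [cell(i, f"L3N{i}", color) for i, color in enumerate(colors)]
        clones = group_clones(binary4, cells, min_ca_level=3)
        assert len(clones) == 4
        assert {c.color for c in clones} == set(colors)

    def test_every_cell_in_exactly_one_clone(self, rng, binary4):
        ids = binary4.terminal_ids()
        cells = [
            cell(i, ids[rng.integers(len(ids))], ["RFP", "YFP"][int(rng.integers(2))])
            for i in range(30)
        ]
        clones = group_clones(binary4, cells)
        all_ids = [c.id for cl in clones for c in cl.cells]
        assert sorted(all_ids) == sorted(c.id for c in cells)


class TestRenewingFilter:
    def test_acinus_confined_clone_non_renewing(self, binary3):
        cells = [
            cell(0, "L3N0", "RFP", "acinar", in_acinus=True),
            cell(1, "L3N0", "RFP", "acinar", in_acinus=True),
        ]
        renewing, non_renewing = filter_renewing(group_clones(binary3, cells))
        assert renewing == [] and len(non_renewing) == 1

    def test_branch_spanning_clone_renewing(self, binary3):
        cells = [cell(0, "L3N0", "RFP"), cell(1, "L3N1", "RFP")]
        renewing, non_renewing = filter_renewing(group_clones(binary3, cells))
        assert len(renewing) == 1 and non_renewing == []

    def test_partition_matches_occupancy(self, rng, binary4):
        ids = list(binary4.nodes)
        cells = [
            cell(i, ids[rng.integers(len(ids))], "RFP")
            for i in range(20)
        ]
        clones = group_clones(binary4, cells, min_ca_level=2)
        renewing, non_renewing = filter_renewing(clones)
        assert len(renewing) + len(non_renewing) == len(clones)
        assert all(len(c.occupied_ducts()) > 1 for c in renewing)
        assert all(len(c.occupied_ducts()) == 1 for c in non_renewing)


class TestPotency:
    def make_clone(self, cells):
        return Clone(id="x", color="RFP", cells=cells, ca_duct_id="L1N0", renewing=True)

    def test_only_acinar_unipotent(self):
        c = self.make_clone([cell(0, "d", compartment="acinar", in_acinus=True)])
        pot = classify_potency(c)
        assert pot.order == 1 and pot.lineages == frozenset({"acinar"})

    def test_acinar_luminal_bipotent(self):
        c = self.make_clone(
            [
                cell(0, "d", compartment="acinar", in_acinus=True),
                cell(1, "d", compartment="luminal"),
            ]
        )
        assert classify_potency(c).lineages == frozenset({"acinar", "luminal"})

    def test_all_four_quadripotent(self):
        c = self.make_clone(
            [
                cell(0, "d", compartment="acinar", in_acinus=True),
                cell(1, "d", compartment="luminal"),
                cell(2, "d", compartment="basal"),
                cell(3, "d", compartment="myoepithelial"),
            ]
        )
        pot = classify_potency(c)
        assert pot.order == 4 and pot.group == "multi"

    def test_duct_associated_acinar_excluded(self):
        c = self.make_clone([cell(0, "d", compartment="acinar", in_acinus=False)])
        assert classify_potency(c) is None
        assert classify_potency(c, include_duct_acinar=True).order == 1

    def test_potency_monotone_under_censoring(self, rng):
        comps = ["acinar", "luminal", "basal", "myoepithelial"]
        for _ in range(50):
            k = int(rng.integers(1, 5))
            chosen = [comps[i] for i in rng.choice(4, size=k, replace=False)]
            cells = [
                cell(i, "d", compartment=chosen[int(rng.integers(k))],
                     in_acinus=chosen[int(rng.integers(k))] == "acinar")
                for i in range(12)
            ]
            full = self.make_clone(cells)
            sub = self.make_clone([c for c in cells if rng.random() < 0.5])
            pf = classify_potency(full, include_duct_acinar=True)
            ps = classify_potency(sub, include_duct_acinar=True)
            if ps is not None:
                assert ps.order <= pf.order
                assert ps.lineages <= pf.lineages


class TestProportions:
    def test_single_clone(self):
        df = potency_proportions([PotencyClass(frozenset({"acinar"}))])
        row = df[df["class"] == "uni"].iloc[0]
        assert row["proportion"] == 1.0 and row["sep"] == 0.0

    def test_half_split_closed_form(self):
        pots = [PotencyClass(frozenset({"acinar"}))] * 50 + [
            PotencyClass(frozenset({"acinar", "luminal"}))
        ] * 50
        df = potency_proportions(pots)
        uni = df[df["class"] == "uni"].iloc[0]
        assert uni["proportion"] == pytest.approx(0.5)
        assert uni["sep"] == pytest.approx(0.05)

    def test_proportions_sum_to_one(self, rng):
        pots = [
            PotencyClass(frozenset({"acinar"})),
            PotencyClass(frozenset({"basal", "myoepithelial"})),
            PotencyClass(frozenset({"acinar", "luminal", "basal"})),
        ] * 5
        df = potency_proportions(pots, by="group")
        assert df["proportion"].sum() == pytest.approx(1.0)

    def test_binomial_coverage_of_sep(self, rng):
        """Estimated class proportions lie within 2*SEP of the generating
        probabilities in >= 93% of seeded cohorts."""
        probs = np.array([0.42, 0.37, 0.21])
        reps = {
            0: PotencyClass(frozenset({"acinar"})),
            1: PotencyClass(frozenset({"acinar", "luminal"})),
            2: PotencyClass(frozenset({"acinar", "luminal", "basal"})),
        }
        n = 100
        n_runs = 1000
        hits = np.zeros(3)
        for _ in range(n_runs):
            counts = rng.multinomial(n, probs)
            pots = [reps[i] for i in range(3) for _ in range(counts[i])]
            df = potency_proportions(pots).set_index("class")
            for j, cls in enumerate(["uni", "bi", "multi"]):
                p_hat = df.loc[cls, "proportion"]
                sep = df.loc[cls, "sep"]
                hits[j] += abs(p_hat - probs[j]) <= 2 * sep
        assert (hits / n_runs >= 0.93).all()


class TestSpanAndDensity:
    def test_single_duct_span_all_equal(self, binary3):
        (clone,) = group_clones(binary3, [cell(0, "L3N0")])
        assert clone_span(clone, binary3) == (3, 3, 3)

    def test_sibling_tip_span(self, binary3):
        (clone,) = group_clones(
            binary3, [cell(0, "L3N0"), cell(1, "L3N1")]
        )
        assert clone_span(clone, binary3) == (2, 3, 3)

    def test_single_subclone_sd_absent(self, binary3):
        (clone,) = group_clones(binary3, [cell(0, "L3N0"), cell(1, "L3N0")])
        prof = subclone_density_profile([clone], binary3)
        assert len(prof) == 1
        assert np.isnan(prof.iloc[0]["sd"])

    def test_acinus_cells_not_in_subclones(self, binary3):
        cells = [
            cell(0, "L3N0", compartment="acinar", in_acinus=True),
            cell(1, "L3N0", compartment="luminal"),
        ]
        (clone,) = group_clones(binary3, cells)
        subs = subclones_of(clone, binary3)
        assert len(subs) == 1 and subs[0].n_cells == 1

    def test_delta_levels_nonnegative(self, rng, binary4):
        ids = list(binary4.nodes)
        cells = [cell(i, ids[rng.integers(len(ids))], "RFP") for i in range(25)]
        clones = group_clones(binary4, cells)
        for c in clones:
            for sc in subclones_of(c, binary4):
                assert sc.delta_level >= 0


class TestDensityGrowthFit:
    @staticmethod
    def profile(x, y):
        return pd.DataFrame(
            {"delta_level": x, "mean_density": y, "sd": np.nan, "n_ducts": 10}
        )

    def test_exact_linear_prefers_linear(self):
        x = np.arange(1, 10)
        fit = fit_density_growth(self.profile(x, 0.5 + 0.3 * x))
        assert fit.preferred == "linear"
        assert fit.linear_slope == pytest.approx(0.3)

    def test_exact_geometric_prefers_exponential(self):
        x = np.arange(1, 10)
        fit = fit_density_growth(self.profile(x, 0.1 * 2.0**x))
        assert fit.preferred == "exponential"
        assert fit.exp_rate == pytest.approx(np.log(2.0))

    def test_max_level_truncation(self):
        x = np.arange(1, 30)
        fit = fit_density_growth(self.profile(x, 1.0 + x), max_level=18)
        assert fit.n_points == 18

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_density_growth(self.profile([1, 2], [1.0, 2.0]))

    def test_nonpositive_means_skip_exponential(self):
        x = np.arange(1, 6)
        with pytest.warns(RuntimeWarning, match="non-positive"):
            fit = fit_density_growth(self.profile(x, [1.0, 0.0, 1.0, 2.0, 3.0]))
        assert fit.exp_rate is None and fit.preferred == "linear"


class TestCloneSizes:
    @staticmethod
    def clone_of_size(i, n, duct="L3N0"):
        return Clone(
            id=f"cl{i}",
            color="RFP",
            cells=[cell(f"{i}_{j}", duct) for j in range(n)],
            ca_duct_id=duct,
            renewing=True,
        )

    def test_degenerate_equal_sizes_flagged(self):
        clones = [self.clone_of_size(i, 5) for i in range(4)]
        with pytest.warns(RuntimeWarning, match="degenerate"):
            stats = clone_size_stats(clones)
        assert stats.degenerate and stats.decay_scale is None

    def test_exponential_scale_recovery(self, rng):
        """Sizes with geometric survival exp(-s/s0): fitted scale within 10%
        at n=500."""
        s0 = 8.0
        p = 1.0 - np.exp(-1.0 / s0)
        sizes = rng.geometric(p, size=500)
        clones = [self.clone_of_size(i, int(s)) for i, s in enumerate(sizes)]
        stats = clone_size_stats(clones)
        assert stats.decay_scale == pytest.approx(s0, rel=0.10)

    def test_size_subtree_correlation_positive_on_simulated_clones(self):
        """Clones rooted deeper have smaller subtrees and smaller sizes, so
        size and subtree size correlate positively."""
        import ducttrace as dt

        data = dt.generate_dataset(dt.SyntheticConfig(), seed=11)
        res = dt.CloneStudy(
            data.tree, data.cells, min_ca_level=5
        ).fit()
        assert res.size_stats is not None
        assert res.size_stats.size_subtree_corr > 0


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(min_value=2, max_value=6), st.data())
def test_ca_is_ancestor_of_all_occupied(depth, data):
    tree = full_binary_tree(depth)
    ids = list(tree.nodes)
    occupied = data.draw(
        st.lists(st.sampled_from(ids), min_size=1, max_size=6)
    )
    ca = find_common_ancestor(tree, occupied)
    assert all(tree.is_ancestor(ca, d) for d in occupied)
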