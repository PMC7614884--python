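"""Synthetic-data generator: tree growth, induction statistics, clone
population and ground-truth consistency."""

import numpy as np
import pytest

from ducttrace.clones import classify_potency, find_common_ancestor, group_clones
from ducttrace.merger import MergerParams, colabel_fraction
from ducttrace.synthetic import (
    SyntheticConfig,
    generate_dataset,
    generate_tree,
    grow_and_populate,
    induce_clones,
    induction_endbuds,
)
from ducttrace.tree import read_cells, read_tree, topology_profile


class TestGenerateTree:
    def test_single_generation_root_only(self):
        cfg = SyntheticConfig(generations_total=1, generations_at_induction=1)
        tree = generate_tree(cfg, 0)
        assert len(tree) == 1 and tree.depth == 1

    def test_certain_bifurcation_gives_full_binary(self):
        cfg = SyntheticConfig(
            generations_total=6,
            generations_at_induction=3,
            bifurcation_prob=1.0,
            length_noise_sd=0.0,
        )
        tree = generate_tree(cfg, 0)
        assert len(tree) == 2**6 - 1
        assert len(tree.terminal_ids()) == 2**5
        assert all(tree.node(t).has_acinus for t in tree.terminal_ids())

    def test_mean_length_decreases_with_level(self):
        # strict monotonicity under the noiseless schedule
        tree = generate_tree(SyntheticConfig(length_noise_sd=0.0), 4)
        prof = topology_profile(tree)
        lengths = prof["mean_length_um"].to_numpy()
        assert (np.diff(lengths) < 0).all()

    def test_length_decay_trend_with_noise(self):
        # with lognormal noise the trend holds in regression: log length
        # falls with level at the configured decay rate
        cfg = SyntheticConfig()
        tree = generate_tree(cfg, 4)
        levels = np.array([n.level for n in tree.nodes.values()], dtype=float)
        logs = np.log([n.length_um for n in tree.nodes.values()])
        slope = np.polyfit(levels, logs, 1)[0]
        assert slope == pytest.approx(np.log(cfg.length_decay), abs=0.05)

    def test_terminal_count_matches_branching_process_expectation(self):
        """Across seeds the mean number of terminal ducts matches the
        closed-form expectation of the supercritical branching process
        within 20%."""
        cfg = SyntheticConfig()
        # active tips double with probability p each round after the
        # guaranteed phase; terminated tips stay terminal
        g, total, p = cfg.guaranteed_generations, cfg.generations_total, cfg.bifurcation_prob
        active = float(2 ** (g - 1))
        expected_terminals = 0.0
        for _ in range(g, total):
            expected_terminals += active * (1 - p)  # tips that terminate
            active = active * 2 * p
        expected_terminals += active  # survivors at the final level
        counts = [len(generate_tree(cfg, s).terminal_ids()) for s in range(100)]
        assert np.mean(counts) == pytest.approx(expected_terminals, rel=0.20)

    def test_roundtrip_through_files(self, tmp_path):
        data = generate_dataset(seed=3)
        paths = data.write(tmp_path)
        tree = read_tree(paths["tree"])
        assert tree.to_dict()["nodes"] == data.tree.to_dict()["nodes"]
        cells = read_cells(paths["cells"], tree=tree)
        assert cells == data.cells

    def test_seed_determinism(self):
        a = generate_dataset(seed=42)
        b = generate_dataset(seed=42)
        assert a.tree.to_dict() == b.tree.to_dict()
        assert a.cells == b.cells


class TestInduction:
    def test_zero_intensity_no_clones(self):
        cfg = SyntheticConfig(
            mean_events_per_color={c: 0.0 for c in ("CFP", "YFP", "GFP", "RFP")}
        )
        tree = generate_tree(cfg, 1)
        truth = induce_clones(tree, cfg, 2)
        assert truth.progenitors == []
        assert truth.colabel_fraction() == 0.0

    def test_single_event_single_clone_no_merger(self):
        cfg = SyntheticConfig(
            mean_events_per_color={"CFP": 0.0, "YFP": 0.0, "GFP": 0.0, "RFP": 1e-9}
        )
        tree = generate_tree(cfg, 1)
        # force exactly one event by direct construction
        endbuds = induction_endbuds(tree, cfg.generations_at_induction)
        found = False
        for seed in range(200):
            truth = induce_clones(tree, cfg, seed, endbuds=endbuds)
            if len(truth.progenitors) == 1:
                found = True
                assert truth.merger_groups == []
                assert len(truth.labelled_endbuds) == 1
                break
        assert found or all(
            len(induce_clones(tree, cfg, s, endbuds=endbuds).progenitors) == 0
            for s in range(3)
        )

    def test_colabel_frequency_matches_analytic(self):
        """Pooled co-label fraction over many seeded inductions agrees with
        the closed-form C for Poisson labelling, within 3 binomial SE."""
        cfg = SyntheticConfig(
            pool_size=10,  # pool size does not affect labelling statistics
            mean_events_per_color={"CFP": 10.0, "YFP": 10.0, "GFP": 10.0, "RFP": 10.0},
        )
        tree = generate_tree(cfg, 5)
        endbuds = induction_endbuds(tree, cfg.generations_at_induction)
        N = len(endbuds)
        n_colab = n_lab = 0
        for seed in range(400):
            truth = induce_clones(tree, cfg, seed, endbuds=endbuds)
            n_colab += len(truth.colabelled_endbuds)
            n_lab += len(truth.labelled_endbuds)
        c_emp = n_colab / n_lab
        # Poisson induction: P_c = 1 - exp(-M/N), the approx variant
        c_true = colabel_fraction(MergerParams(N=N, M=10), method="approx")
        se = np.sqrt(c_true * (1 - c_true) / n_lab)
        assert abs(c_emp - c_true) <= 3 * se

    def test_merger_groups_are_same_endbud_same_color(self):
        cfg = SyntheticConfig(
            mean_events_per_color={c: 25.0 for c in ("CFP", "YFP", "GFP", "RFP")}
        )
        tree = generate_tree(cfg, 1)
        truth = induce_clones(tree, cfg, 3)
        assert truth.merger_groups  # high intensity: mergers certain
        by_id = {p.id: p for p in truth.progenitors}
        for grp in truth.merger_groups:
            members = [by_id[i] for i in grp["progenitors"]]
            assert len(members) >= 2
            assert len({m.endbud_id for m in members}) == 1
            assert len({m.color for m in members}) == 1


class TestGrowAndPopulate:
    def unipotent_cfg(self, lineage):
        weights = {c: 0.0 for c in ("acinar", "luminal", "basal", "myoepithelial")}
        weights[lineage] = 1.0
        return SyntheticConfig(
            potency_mixture={"uni": 1.0, "bi": 0.0, "multi": 0.0},
            uni_weights=weights,
            duct_acinar_fraction=0.0,
        )

    def test_unipotent_acinar_cells_all_acinar_in_acini(self):
        cfg = self.unipotent_cfg("acinar")
        data = generate_dataset(cfg, seed=8)
        assert data.cells  # enough intensity to observe something
        assert all(c.compartment == "acinar" and c.in_acinus for c in data.cells)

    def test_basal_myo_bipotent_never_produces_acinar_or_luminal(self):
        cfg = SyntheticConfig(
            potency_mixture={"uni": 0.0, "bi": 1.0, "multi": 0.0},
            bi_acinar_luminal_prob=0.0,
        )
        data = generate_dataset(cfg, seed=9)
        assert data.cells
        assert {c.compartment for c in data.cells} <= {"basal", "myoepithelial"}

    def test_true_ca_is_ancestor_of_inferred_ca(self):
        """The inferred CA lies in the subtree of the true induction endbud:
        inferred level >= true level always."""
        data = generate_dataset(seed=12)
        truth = data.ground_truth
        cells_by_id = {c.id: c for c in data.cells}
        for pid, cell_ids in truth.clone_cells.items():
            if not cell_ids:
                continue
            occupied = {cells_by_id[i].duct_id for i in cell_ids}
            inferred = find_common_ancestor(data.tree, occupied)
            true_ca = truth.true_ca[pid]
            assert data.tree.is_ancestor(true_ca, inferred)
            assert data.tree.level_of(inferred) >= data.tree.level_of(true_ca)

    def test_classified_potency_never_exceeds_truth(self):
        data = generate_dataset(seed=13)
        truth = data.ground_truth
        by_prog = {p.id: p for p in truth.progenitors}
        cells_by_id = {c.id: c for c in data.cells}
        for pid, cell_ids in truth.clone_cells.items():
            if not cell_ids:
                continue
            from ducttrace.clones import Clone

            clone = Clone(
                id=pid,
                color=by_prog[pid].color,
                cells=[cells_by_id[i] for i in cell_ids],
                ca_duct_id=truth.true_ca[pid],
                renewing=True,
            )
            pot = classify_potency(clone, include_duct_acinar=True)
            if pot is not None:
                assert pot.lineages <= by_prog[pid].lineages
                assert pot.order <= by_prog[pid].order

    def test_observed_compartments_subset_of_potency(self):
        data = generate_dataset(seed=14)
        truth = data.ground_truth
        by_prog = {p.id: p for p in truth.progenitors}
        cells_by_id = {c.id: c for c in data.cells}
        for pid, cell_ids in truth.clone_cells.items():
            comps = {cells_by_id[i].compartment for i in cell_ids}
            assert comps <= set(by_prog[pid].lineages)


class TestConfigValidation:
    def test_bad_mixture_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(potency_mixture={"uni": 0.8, "bi": 0.8, "multi": -0.6})

    def test_induction_after_collection_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(generations_at_induction=10, generations_total=5)

    def test_config_hash_stable_and_sensitive(self):
        a, b = SyntheticConfig(), SyntheticConfig()
        assert a.config_hash() == b.config_hash()
        assert a.config_hash() != SyntheticConfig(pool_size=50).config_hash()
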