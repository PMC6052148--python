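"""Simulator: determinism, structure, event-rate self-consistency."""

import numpy as np
import pytest

from hotrecon.reconcile import dtl_reconcile, event_summary
from hotrecon.simulate import (
    SimConfig,
    TransferEvent,
    assign_supports,
    perturb_topology,
    replay_operon_history,
    sample_noninteracting_tip_transfers,
    simulate_gene_trees,
    simulate_operon_history,
    simulate_species_tree,
    simulate_study,
)
from hotrecon.simulate import _node_times
from hotrecon.tree import TreeError, bipartition_set, parse_newick, prune_to_taxa, serialize_newick


class TestSpeciesTree:
    def test_two_leaves_is_cherry(self):
        t = simulate_species_tree(2, 1.0, 0)
        assert t.n_leaves() == 2 and t.is_binary()

    def test_deterministic_under_seed(self):
        a = simulate_species_tree(44, 1.0, 7)
        b = simulate_species_tree(44, 1.0, 7)
        assert serialize_newick(a) == serialize_newick(b)
        c = simulate_species_tree(44, 1.0, 8)
        assert serialize_newick(a) != serialize_newick(c)

    def test_ultrametric_with_n_leaves(self):
        t = simulate_species_tree(44, 1.0, 3)
        assert t.n_leaves() == 44
        times = _node_times(t)
        tips = [times[id(l)][1] for l in t.leaves()]
        assert max(tips) - min(tips) < 1e-9

    def test_too_few_species_rejected(self):
        with pytest.raises(TreeError):
            simulate_species_tree(1, 1.0, 0)


class TestOperonHistory:
    def test_zero_rates_pure_vertical(self):
        sp = simulate_species_tree(12, 1.0, 5)
        h = simulate_operon_history(sp, 0.0, 0.0, 5)
        assert all(h.presence.values())
        assert h.transfers == [] and h.losses == []
        assert h.operon_tree.isomorphic(sp, check_support=False)

    def test_loss_only_restriction(self):
        sp = simulate_species_tree(20, 1.0, 11)
        h = simulate_operon_history(sp, 0.0, 0.25, 11)
        assert h.transfers == []
        assert len(h.losses) >= 1
        carriers = h.carriers
        if len(carriers) >= 2:
            assert h.operon_tree.leaf_labels == carriers
            # operon tree is the induced species subtree
            induced = prune_to_taxa(sp, carriers)
            assert h.operon_tree.isomorphic(induced, check_support=False)

    def test_presence_agrees_with_operon_leaves(self):
        for seed in range(6):
            sp = simulate_species_tree(16, 1.0, seed)
            h = simulate_operon_history(sp, 0.3, 0.3, seed)
            if h.operon_tree is not None:
                assert h.operon_tree.leaf_labels == h.carriers

    def test_event_rate_self_consistency(self):
        """Mean transfer count over replicates is within 3 standard errors
        of rate x mean carrier branch length measured from the logs."""
        rate = 0.25
        counts, lengths = [], []
        for seed in range(1000):
            sp = simulate_species_tree(12, 1.0, seed)
            h = simulate_operon_history(sp, rate, 0.0, seed + 10**6)
            counts.append(len(h.transfers))
            lengths.append(h.carrier_length)
        counts = np.asarray(counts, dtype=float)
        expected = rate * np.mean(lengths)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_parsimony_never_overcounts_planted_transfers(self):
        for seed in range(8):
            sp = simulate_species_tree(14, 1.0, seed)
            h = simulate_operon_history(sp, 0.35, 0.2, seed + 99)
            if h.operon_tree is None or len(h.carriers) < 4:
                continue
            spp = prune_to_taxa(sp, h.carriers)
            rec = dtl_reconcile(h.operon_tree, spp)
            assert event_summary(rec)["transfers"] <= len(h.transfers)

    def test_non_ultrametric_rejected(self):
        t = parse_newick("((A:1,B:2):1,C:5);")
        with pytest.raises(TreeError, match="ultrametric"):
            simulate_operon_history(t, 0.1, 0.1, 0)


class TestReplay:
    def test_planted_transfers_replayed_exactly(self):
        sp = simulate_species_tree(20, 1.0, 3)
        ev = sample_noninteracting_tip_transfers(sp, 3, 3)
        h = replay_operon_history(sp, ev)
        assert h.transfers == ev
        assert all(h.presence.values())
        rec = dtl_reconcile(h.operon_tree, sp)
        assert event_summary(rec)["transfers"] == 3

    def test_invalid_planted_event_rejected(self):
        sp = simulate_species_tree(8, 1.0, 1)
        t_end = max(_node_times(sp)[id(l)][1] for l in sp.leaves())
        with pytest.raises(TreeError, match="donor"):
            replay_operon_history(sp, [TransferEvent(t_end * 0.99, "nope", "s1")])
        with pytest.raises(TreeError, match="beyond"):
            replay_operon_history(sp, [TransferEvent(1e9, "s1", "s2")])


class TestGeneTrees:
    def test_zero_rate_all_isomorphic_to_operon(self):
        sp = simulate_species_tree(14, 1.0, 2)
        h = simulate_operon_history(sp, 0.2, 0.1, 2)
        genes, logs = simulate_gene_trees(h, 0.0, 5, 2)
        assert all(len(v) == 0 for v in logs.values())
        for t in genes.values():
            assert t.isomorphic(h.operon_tree, check_support=False)

    def test_planted_gene_transfer_is_one_spr(self):
        sp = simulate_species_tree(12, 1.0, 6)
        h = replay_operon_history(sp, [])
        ev = sample_noninteracting_tip_transfers(sp, 1, 6)
        genes, logs = simulate_gene_trees(h, 0.0, 6, 6, planted={4: ev})
        names = sorted(genes)
        for i, name in enumerate(names):
            same = genes[name].isomorphic(h.operon_tree, check_support=False)
            assert same == (i != 4)
        moved = genes[names[4]]
        # exactly one bipartition differs per SPR of a single tip
        d = {b for b, _ in bipartition_set(moved)} ^ {
            b for b, _ in bipartition_set(h.operon_tree)
        }
        assert len(d) >= 1

    def test_gene_event_rate_poisson_consistent(self):
        rate = 0.1
        sp = simulate_species_tree(12, 1.0, 7)
        h = replay_operon_history(sp, [])
        counts = []
        for seed in range(300):
            _, logs = simulate_gene_trees(h, rate, 3, seed)
            counts += [len(v) for v in logs.values()]
        counts = np.asarray(counts, dtype=float)
        expected = rate * h.carrier_length
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_determinism(self):
        sp = simulate_species_tree(12, 1.0, 8)
        h = simulate_operon_history(sp, 0.2, 0.1, 8)
        g1, l1 = simulate_gene_trees(h, 0.05, 4, 8)
        g2, l2 = simulate_gene_trees(h, 0.05, 4, 8)
        assert l1 == l2
        for k in g1:
            assert serialize_newick(g1[k]) == serialize_newick(g2[k])


class TestSupportsAndPerturbation:
    def test_default_supports_all_true_value(self):
        t = assign_supports(simulate_species_tree(10, 1.0, 1))
        for n in t.postorder():
            if n is t.root or n.is_leaf():
                assert n.support is None
            else:
                assert n.support == 100

    def test_noisy_supports_reproducible_in_range(self):
        base = simulate_species_tree(10, 1.0, 1)
        a = assign_supports(base, 90, noise_sd=15, seed=4)
        b = assign_supports(base, 90, noise_sd=15, seed=4)
        assert serialize_newick(a) == serialize_newick(b)
        sups = [n.support for n in a.postorder() if n.support is not None]
        assert all(0 <= s <= 100 for s in sups)
        assert len(set(sups)) > 1

    def test_nni_zero_unchanged(self):
        t = assign_supports(simulate_species_tree(10, 1.0, 2))
        assert perturb_topology(t, 0).isomorphic(t)

    def test_single_nni_rf_distance_two(self):
        for seed in range(6):
            t = assign_supports(simulate_species_tree(10, 1.0, seed))
            p = perturb_topology(t, 1, low_support=40, seed=seed)
            a = {b for b, _ in bipartition_set(t)}
            b = {bp for bp, _ in bipartition_set(p)}
            assert len(a ^ b) == 2
            weak = [n.support for n in p.postorder() if n.support == 40]
            assert len(weak) == 1

    def test_excessive_nni_count_rejected(self):
        t = assign_supports(simulate_species_tree(6, 1.0, 0))
        with pytest.raises(TreeError):
            perturb_topology(t, 50)

    def test_fix_recovers_after_weak_nni(self):
        from hotrecon.fixing import fix_tree

        ref = assign_supports(simulate_species_tree(12, 1.0, 9))
        pert = perturb_topology(ref, 1, low_support=40, seed=9)
        fixed = fix_tree(pert, ref, 70).tree
        assert fixed.isomorphic(ref, check_support=False)


class TestStudyBundle:
    def test_full_determinism_byte_identical(self):
        cfg = SimConfig(n_species=16, n_genes=4, seed=123)
        h1, g1, l1 = simulate_study(cfg)
        h2, g2, l2 = simulate_study(cfg)
        assert serialize_newick(h1.species_tree) == serialize_newick(h2.species_tree)
        if h1.operon_tree is not None:
            assert serialize_newick(h1.operon_tree) == serialize_newick(h2.operon_tree)
        assert l1 == l2
        for k in g1:
            if g1[k] is not None:
                assert serialize_newick(g1[k]) == serialize_newick(g2[k])
        assert h1.transfers == h2.transfers and h1.losses == h2.losses

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_species=1)
        with pytest.raises(ValueError):
            SimConfig(hot_rate=-0.1)
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)
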