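"""DTL reconciliation: worked examples, oracle equivalence, laws."""

import pytest

from hotrecon.reconcile import (
    CostScheme,
    dollo_loss_count,
    dtl_reconcile,
    enumerate_scenarios,
    event_summary,
)
from hotrecon.tree import TreeError, parse_newick

from conftest import random_binary_tree
from _oracle import oracle_dollo, oracle_dtl


class TestWorkedExamples:
    def test_identical_trees_cost_zero(self):
        sp = parse_newick("((A,B),(C,D));")
        rec = dtl_reconcile(sp, sp)
        assert rec.cost == 0
        assert event_summary(rec) == {
            "speciations": 3,
            "duplications": 0,
            "transfers": 0,
            "losses": 0,
        }
        assert rec.n_optimal == 1
        assert rec.time_consistent

    def test_single_displacement_is_one_transfer(self):
        # oracle-verified: minimum 3 (one transfer); duplication routes >= 4
        sp = parse_newick("((A,B),C);")
        g = parse_newick("((A,C),B);")
        rec = dtl_reconcile(g, sp)
        assert rec.cost == 3
        assert event_summary(rec)["transfers"] == 1
        assert event_summary(rec)["losses"] == 0
        assert (rec.cost, rec.n_optimal) == oracle_dtl(g, sp)

    def test_missing_species_is_one_loss(self):
        sp = parse_newick("((A,B),(C,D));")
        g = parse_newick("((A,B),C);")
        rec = dtl_reconcile(g, sp)
        assert rec.cost == 1
        assert event_summary(rec)["losses"] == 1
        assert any(e.kind == "loss" and e.species_location == "D" for e in rec.events)
        assert (rec.cost, rec.n_optimal) == oracle_dtl(g, sp)

    def test_inparalogs_are_one_duplication(self):
        sp = parse_newick("((A,B),C);")
        g = parse_newick("((A1,A2),B);")
        lm = {"A1": "A", "A2": "A", "B": "B"}
        rec = dtl_reconcile(g, sp, leaf_map=lm)
        assert rec.cost == 2
        assert event_summary(rec)["duplications"] == 1
        dup = next(e for e in rec.events if e.kind == "duplication")
        assert dup.species_location == "A"
        assert (rec.cost, rec.n_optimal) == oracle_dtl(g, sp, lm)

    def test_missing_leaf_map_entry_rejected(self):
        sp = parse_newick("((A,B),C);")
        g = parse_newick("((A,X),B);")
        with pytest.raises(TreeError, match="X"):
            dtl_reconcile(g, sp, leaf_map={"A": "A", "B": "B"})

    def test_polytomy_rejected_with_pointer_to_fixing(self):
        sp = parse_newick("((A,B),C);")
        g = parse_newick("(A,B,C);")
        with pytest.raises(TreeError, match="resolve"):
            dtl_reconcile(g, sp)


class TestOracleEquivalence:
    def test_cost_and_count_match_brute_force(self, rng):
        """DP cost and co-optimal count equal the direct-definition
        enumeration on random gene/species pairs with <= 7 leaves."""
        for trial in range(220):
            n = int(rng.integers(3, 8))
            labels = [f"t{i}" for i in range(n)]
            sp = random_binary_tree(labels, rng)
            k = int(rng.integers(3, n + 1))
            sub = list(rng.choice(labels, k, replace=False))
            g = random_binary_tree(sub, rng)
            costs = CostScheme(
                float(rng.integers(1, 4)), float(rng.integers(1, 5)), 1.0
            )
            rec = dtl_reconcile(g, sp, costs=costs)
            oc, on = oracle_dtl(g, sp, None, costs)
            assert rec.cost == pytest.approx(oc)
            assert rec.n_optimal == on

    def test_exact_integer_fallback_agrees(self, rng):
        from hotrecon.reconcile import _Engine

        for _ in range(20):
            labels = [f"t{i}" for i in range(6)]
            sp = random_binary_tree(labels, rng)
            g = random_binary_tree(labels, rng)
            fast = _Engine(g, sp, None, CostScheme())
            slow = _Engine.__new__(_Engine)
            slow.costs = fast.costs
            slow.S, slow.G = fast.S, fast.G
            slow.desc, slow.anc, slow.incomp = fast.desc, fast.anc, fast.incomp
            slow.sigma = fast.sigma
            slow._run_dp_exact()
            assert slow.opt_cost == pytest.approx(fast.opt_cost)
            assert slow.n_optimal == fast.n_optimal


class TestScenarioEnumeration:
    def test_identical_trees_single_scenario(self):
        sp = parse_newick("((A,B),(C,D));")
        assert len(enumerate_scenarios(sp, sp)) == 1

    def test_enumeration_matches_count_and_is_distinct(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 7))
            labels = [f"t{i}" for i in range(n)]
            sp = random_binary_tree(labels, rng)
            g = random_binary_tree(labels, rng)
            rec = dtl_reconcile(g, sp)
            scens = enumerate_scenarios(g, sp, limit=100000)
            assert len(scens) == rec.n_optimal
            keys = {
                (
                    tuple(sorted(s.mapping.items())),
                    tuple(
                        sorted(
                            (e.kind, e.gene_node, e.species_location, e.donor, e.recipient)
                            for e in s.events
                        )
                    ),
                )
                for s in scens
            }
            assert len(keys) == rec.n_optimal

    def test_first_scenario_is_the_reported_one(self, rng):
        labels = [f"t{i}" for i in range(6)]
        sp = random_binary_tree(labels, rng)
        g = random_binary_tree(labels, rng)
        rec = dtl_reconcile(g, sp)
        first = enumerate_scenarios(g, sp, limit=1)[0]
        assert first.mapping == rec.mapping
        assert first.events == rec.events

    def test_limit_validated(self):
        sp = parse_newick("((A,B),C);")
        with pytest.raises(ValueError):
            enumerate_scenarios(sp, sp, limit=0)

    def test_every_scenario_satisfies_cost_identity(self, rng):
        costs = CostScheme()
        labels = [f"t{i}" for i in range(6)]
        sp = random_binary_tree(labels, rng)
        g = random_binary_tree(labels, rng)
        for s in enumerate_scenarios(g, sp, costs=costs, limit=10000):
            cnt = event_summary(s)
            assert s.cost == pytest.approx(
                costs.duplication * cnt["duplications"]
                + costs.transfer * cnt["transfers"]
                + costs.loss * cnt["losses"]
            )


class TestLaws:
    def test_zero_law(self, rng):
        for _ in range(20):
            t = random_binary_tree([f"t{i}" for i in range(8)], rng)
            rec = dtl_reconcile(t, t)
            assert rec.cost == 0 and rec.n_optimal == 1

    def test_single_spr_law(self, rng):
        """An SPR between incomparable edges costs <= the transfer cost and
        the 2-3-1 scenario contains exactly one transfer."""
        from hotrecon.simulate import replay_operon_history, simulate_species_tree
        from hotrecon.simulate import sample_noninteracting_tip_transfers

        done = 0
        for seed in range(40):
            sp = simulate_species_tree(7, 1.0, seed)
            try:
                ev = sample_noninteracting_tip_transfers(sp, 1, seed)
            except TreeError:
                continue
            hist = replay_operon_history(sp, ev)
            rec = dtl_reconcile(hist.operon_tree, sp)
            assert rec.cost <= CostScheme().transfer + CostScheme().loss
            assert event_summary(rec)["transfers"] == 1
            oc, on = oracle_dtl(hist.operon_tree, sp)
            assert rec.cost == pytest.approx(oc)
            done += 1
        assert done >= 20

    def test_cost_monotonicity(self, rng):
        base = CostScheme(2, 3, 1)
        for _ in range(20):
            labels = [f"t{i}" for i in range(7)]
            sp = random_binary_tree(labels, rng)
            g = random_binary_tree(labels, rng)
            c0 = dtl_reconcile(g, sp, costs=base).cost
            for bumped in (
                CostScheme(3, 3, 1),
                CostScheme(2, 4, 1),
                CostScheme(2, 3, 2),
            ):
                assert dtl_reconcile(g, sp, costs=bumped).cost >= c0 - 1e-9


class TestDollo:
    def test_all_present_no_losses(self):
        sp = parse_newick("((A,B),(C,D));")
        assert dollo_loss_count(sp, dict.fromkeys("ABCD", True)) == (0, [])

    def test_absent_cherry_is_one_stem_loss(self):
        sp = parse_newick("((A,B),(C,D));")
        n, edges = dollo_loss_count(sp, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert n == 1 and edges == ["C+2"]

    def test_scattered_absences(self):
        sp = parse_newick("((A,B),(C,D));")
        n, edges = dollo_loss_count(sp, {"A": 1, "B": 0, "C": 0, "D": 1})
        assert n == 2 and edges == ["B", "C"]

    def test_unknown_leaf_rejected(self):
        sp = parse_newick("((A,B),(C,D));")
        with pytest.raises(TreeError):
            dollo_loss_count(sp, {"A": 1, "B": 1, "C": 1, "D": 1, "Z": 0})

    def test_matches_exhaustive_oracle(self, rng):
        """Dollo count equals the exhaustive minimum over all internal
        single-origin state assignments on random 10-leaf trees."""
        for _ in range(30):
            t = random_binary_tree([f"t{i}" for i in range(10)], rng)
            presence = {l.label: bool(rng.integers(0, 2)) for l in t.leaves()}
            if not any(presence.values()):
                presence[t.leaves()[0].label] = True
            n, _ = dollo_loss_count(t, presence)
            assert n == oracle_dollo(t, presence)
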