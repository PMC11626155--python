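"""Hierarchical haplotype calling, test planning, imputation and encoding."""

from __future__ import annotations

import pandas as pd
import pytest

from msylineage import htcaller as hc
from msylineage.htcaller import SampleGenotypes, State, Status

D, A = State.DERIVED, State.ANCESTRAL


def geno(sample="s", **calls):
    return SampleGenotypes(sample, {k: v for k, v in calls.items()})


class TestCallHaplotype:
    def test_skip_ahead_bracketing_yields_terminal(self, toy_tree):
        """Typing only the branch-defining markers top to bottom (rAX, rW, rY)
        must resolve the terminal haplotype: untested markers between two
        derived ones on the path are bracketed as derived."""
        a = hc.call_haplotype(geno(rAX=D, rW=D, rY=D), toy_tree)
        assert (a.node, a.status, a.label) == (
            "daC_Ao-aA1a", Status.TERMINAL, "daC_Ao-aA1a",
        )

    def test_children_tested_ancestral_gives_confirmed_star_label(self, toy_tree):
        a = hc.call_haplotype(geno(rAX=D, tv=D, t1=A), toy_tree)
        assert (a.node, a.status, a.label) == (
            "daC_T1x", Status.INNER_CONFIRMED, "daC_T1x*",
        )

    def test_child_untested_gives_unresolved_star_label(self, toy_tree):
        a = hc.call_haplotype(geno(rAX=D, tv=D), toy_tree)
        assert (a.node, a.status, a.label) == (
            "daC_T1x", Status.INNER_UNRESOLVED, "daC_T1x*",
        )

    def test_fully_ancestral_sample_sits_at_root(self, toy_tree):
        a = hc.call_haplotype(geno(rAX=A, nv=A), toy_tree)
        assert (a.node, a.label, a.status) == ("root", "root*", Status.INNER_CONFIRMED)

    def test_all_missing_is_a_no_call(self, toy_tree):
        with pytest.raises(hc.NoCallError):
            hc.call_haplotype(geno(rAX=State.MISSING), toy_tree)

    def test_two_exclusive_derived_edges_are_ambiguous(self, toy_tree):
        with pytest.raises(hc.AmbiguousCallError) as exc:
            hc.call_haplotype(geno(rW=D, tv=D), toy_tree)
        assert len(exc.value.candidate_paths) == 2

    def test_single_off_path_derived_tolerated_and_flagged(self, toy_tree):
        a = hc.call_haplotype(geno(rAX=D, rW=D, rY=D, tv=D), toy_tree)
        assert a.node == "daC_Ao-aA1a" and a.conflicts == ["tv"]

    def test_path_consistency_every_derived_on_path_or_in_conflicts(self, toy_tree):
        a = hc.call_haplotype(geno(rAX=D, rW=D, rY=D, tv=D), toy_tree)
        on_path = set(toy_tree.path_variants(a.node))
        for v, s in a.tested_calls.items():
            if s is D:
                assert v in on_path or v in a.conflicts

    def test_clean_full_genotyping_recovers_generating_node(self, bundle_small):
        assignments, frame = hc.batch_call(
            hc.genotypes_from_matrix(bundle_small.complete),
            bundle_small.phylogeny.tree,
        )
        assert (frame["error"] == "").all()
        assert all(a.node == bundle_small.true_node[a.sample] for a in assignments)

    def test_masked_calls_stay_on_true_ancestral_path(self, bundle_masked):
        """With missingness but zero genotyping error the call may lose depth
        but must never leave the root path of the true node."""
        tree = bundle_masked.phylogeny.tree
        assignments, _ = hc.batch_call(bundle_masked.genotypes, tree)
        for a in assignments:
            assert tree.is_ancestor_or_self(a.node, bundle_masked.true_node[a.sample])

    def test_star_labels_mark_exactly_non_terminal_calls(self, bundle_masked):
        assignments, _ = hc.batch_call(
            bundle_masked.genotypes, bundle_masked.phylogeny.tree
        )
        for a in assignments:
            assert a.label.endswith("*") == (a.status is not Status.TERMINAL)


class TestBatchCall:
    def test_batch_equals_individual_calls_and_flags_failures(self, toy_tree):
        samples = [
            geno("ok1", rAX=D, rW=D, rY=D),
            geno("bad", rAX=State.MISSING),
            geno("ok2", rAX=A, nv=D, n1=D),
        ]
        assignments, frame = hc.batch_call(samples, toy_tree)
        assert [a.sample for a in assignments] == ["ok1", "ok2"]
        assert frame.loc[frame["sample"] == "bad", "error"].str.contains("NoCall").all()

    def test_permuting_input_order_gives_identical_output_set(self, toy_tree):
        samples = [
            geno("a", rAX=D, rW=D, rY=D),
            geno("b", rAX=D, tv=D),
            geno("c", rAX=A, nv=A),
        ]
        fwd, _ = hc.batch_call(samples, toy_tree)
        rev, _ = hc.batch_call(samples[::-1], toy_tree)
        as_set = lambda xs: {(a.sample, a.node, a.status, a.label) for a in xs}
        assert as_set(fwd) == as_set(rev)


class TestPlanTests:
    def test_priors_order_the_plan_top_down(self, toy_tree):
        plan = hc.plan_tests(
            toy_tree, geno("p"), {"daC_Ao-aA1a": 0.6, "daC_T1a": 0.4}
        )
        assert plan.variants[0] == "rAX"
        assert plan.variants.index("rW") < plan.variants.index("tv")

    def test_concentrated_prior_plans_the_exact_path(self, toy_tree):
        plan = hc.plan_tests(toy_tree, geno("p"), {"daC_Ao-aA1a": 1.0})
        assert plan.variants[:3] == ["rAX", "rW", "rY"]

    def test_terminal_reached_gives_empty_plan(self, toy_tree):
        plan = hc.plan_tests(toy_tree, geno("p", rAX=D, rW=D, rY=D), {})
        assert plan.variants == []

    def test_plan_excludes_branches_tested_ancestral(self, toy_tree):
        plan = hc.plan_tests(toy_tree, geno("p", rAX=D, rW=A), {})
        assert "rY" not in plan.variants and "tv" in plan.variants

    def test_greedy_plan_needs_no_more_assays_than_breadth_first(self, toy_tree):
        """Frequency-aware ordering beats naive level-order assaying on
        average over simulated samples drawn from the prior."""
        import numpy as np

        tree = toy_tree
        terminals = ["daC_Ao-aA1a", "daC_T1a", "nc1"]
        rng = np.random.default_rng(2024)

        def assays(true_node: str, prior: dict, breadth_first: bool) -> int:
            calls: dict[str, State] = {}
            truth = set(tree.path_variants(true_node))
            n = 0
            while True:
                plan = hc.plan_tests(tree, SampleGenotypes("q", calls), prior)
                order = plan.variants
                if breadth_first:
                    depth = {v: tree.depth(tree.variant_index[v].edge)
                             for v in order}
                    order = sorted(order, key=lambda v: (depth[v], v))
                if not order:
                    return n
                v = order[0]
                calls[v] = D if v in truth else A
                n += 1

        total_greedy = total_bf = 0
        for _ in range(1000):
            w = rng.dirichlet([0.5] * len(terminals))
            prior = dict(zip(terminals, w))
            true = terminals[int(rng.choice(len(terminals), p=w))]
            total_greedy += assays(true, prior, breadth_first=False)
            total_bf += assays(true, prior, breadth_first=True)
        assert total_greedy <= total_bf


class TestImputationAndEncoding:
    def test_node_sweep_imputation_matches_indicator_vectors(self, toy_tree):
        """For every backbone node, a fully genotyped sample at that node
        imputes to exactly the node's path-indicator vector (idempotence)."""
        for node in toy_tree.preorder():
            truth = set(toy_tree.path_variants(node))
            calls = {
                v: (D if v in truth else A) for v in toy_tree.panel_order
            }
            if not calls:
                continue
            a = hc.call_haplotype(SampleGenotypes(node, calls), toy_tree)
            vec = hc.impute_alleles(a, toy_tree)
            expect = [1 if v in truth else 0 for v in toy_tree.panel_order]
            assert list(vec) == expect
            # idempotence: fully genotyped output equals input states
            assert all(
                (vec[v] == 1) == (calls[v] is D) for v in toy_tree.panel_order
            )

    def test_partial_genotyping_imputes_path_ones_offpath_zeros(self, toy_tree):
        a = hc.call_haplotype(geno(rAX=D, rW=D, rY=D), toy_tree)
        vec = hc.impute_alleles(a, toy_tree)
        assert vec[["rAX", "rW", "rY"]].tolist() == [1, 1, 1]
        assert vec[["tv", "t1", "nv", "n1"]].tolist() == [0, 0, 0, 0]

    def test_conflict_variants_stay_derived_in_imputation(self, toy_tree):
        a = hc.call_haplotype(geno(rAX=D, rW=D, rY=D, tv=D), toy_tree)
        vec = hc.impute_alleles(a, toy_tree)
        assert vec["tv"] == 1  # flagged, never silently zeroed

    def test_encode_empty_assignments_gives_header_only(self, toy_tree):
        out = hc.encode_matrix([], toy_tree)
        assert list(out.columns) == toy_tree.panel_order and out.empty

    def test_sibling_terminals_differ_at_sibling_edges_only(self, toy_tree):
        a1 = hc.call_haplotype(geno("p", rAX=D, rW=D, rY=D), toy_tree)
        a2 = hc.call_haplotype(geno("q", rAX=D, tv=D, t1=D), toy_tree)
        m = hc.encode_matrix([a1, a2], toy_tree)
        diff = [v for v in m.columns if m.loc["p", v] != m.loc["q", v]]
        assert set(diff) == {"rW", "rY", "tv", "t1"}

    def test_encode_then_recall_reproduces_assignments(self, bundle_masked):
        """encode_matrix -> batch_call round trip is the identity on calls."""
        tree = bundle_masked.phylogeny.tree
        assignments, _ = hc.batch_call(bundle_masked.genotypes, tree)
        encoded = hc.encode_matrix(assignments, tree)
        recalled, frame = hc.batch_call(hc.genotypes_from_matrix(encoded), tree)
        assert (frame["error"] == "").all()
        before = {(a.sample, a.node) for a in assignments}
        after = {(a.sample, a.node) for a in recalled}
        assert before == after
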