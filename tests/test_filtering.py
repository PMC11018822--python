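"""Rule filters, degree statistics, G² association scoring, pruning."""

import math

import numpy as np
import pytest

from kgr import (
    ContingencyTable,
    EntityMeta,
    FilterConfig,
    apply_rule_filters,
    build_graph,
    combined_scores,
    contingency_from_stream,
    g2_statistic,
    node_degrees,
    prune_to_budget,
    triple_filter_hook,
)
from kgr.filtering import DEFAULT_RELATION_WHITELIST, g2_from_graph_counts

from conftest import make_pred, random_predications


def g2_oracle(n):
    """Independent brute-force G²: explicit marginals and cell-by-cell sum."""
    n = np.asarray(n, float)
    T = n.sum()
    total = 0.0
    for i in range(2):
        for j in range(2):
            for k in range(2):
                if n[i, j, k] == 0:
                    continue
                m = n[i].sum() * n[:, j].sum() * n[:, :, k].sum() / T**2
                total += n[i, j, k] * math.log(n[i, j, k] / m)
    return 2.0 * total


class TestRuleFilters:
    def test_non_whitelist_relation_dropped(self):
        kg = build_graph(
            [make_pred("C1", "TREATS", "C2"), make_pred("C1", "CONVERTS_TO", "C2")]
        )
        out = apply_rule_filters(kg, FilterConfig())
        assert len(out) == 1
        assert out.contains_triple("C1", "TREATS", "C2")

    def test_identity_config_is_identity(self, rng):
        preds = random_predications(rng, 60, n_rel=3)
        kg = build_graph(preds)
        cfg = FilterConfig(
            generic_concepts=frozenset(),
            excluded_groups=frozenset(),
            relation_whitelist=frozenset(kg.relations),
        )
        out = apply_rule_filters(kg, cfg)
        assert out.triples == kg.triples

    def test_generic_endpoints_removed_by_count(self, rng):
        preds = [make_pred(f"C{i}", "TREATS", f"C{i + 100}") for i in range(50)]
        kg = build_graph(preds)
        generic = frozenset(f"C{i}" for i in range(10))
        cfg = FilterConfig(generic_concepts=generic, relation_whitelist=frozenset({"TREATS"}))
        out = apply_rule_filters(kg, cfg)
        assert len(out) == 40

    def test_excluded_group_endpoints_removed(self):
        meta = {
            "C1": EntityMeta(concept_id="C1", semantic_group="Concepts & Ideas"),
            "C2": EntityMeta(concept_id="C2", semantic_group="Disorders"),
            "C3": EntityMeta(concept_id="C3", semantic_group="Disorders"),
        }
        kg = build_graph(
            [make_pred("C1", "TREATS", "C2"), make_pred("C3", "TREATS", "C2")], meta=meta
        )
        out = apply_rule_filters(kg, FilterConfig())
        assert list(out.triples) == [("C3", "TREATS", "C2")]

    def test_disjoint_whitelist_errors(self):
        kg = build_graph([make_pred("C1", "BINDS", "C2")])
        with pytest.raises(ValueError, match="whitelist"):
            apply_rule_filters(kg, FilterConfig())

    def test_stages_return_subgraphs(self, small_synth):
        _, _, _, kg = small_synth
        cfg = FilterConfig(budget=len(kg) // 2)
        kg1 = apply_rule_filters(kg, cfg)
        assert set(kg1.triples) <= set(kg.triples)
        scores = combined_scores(kg1)
        kg2 = prune_to_budget(kg1, scores, cfg.budget)
        assert set(kg2.triples) <= set(kg1.triples)
        kg3 = triple_filter_hook(kg2, lambda k: hash(k) % 3 != 0)
        assert set(kg3.triples) <= set(kg2.triples)
        assert set(kg3.entities) <= set(kg2.entities)


class TestNodeDegrees:
    def test_star_graph(self):
        preds = [make_pred("HUB", "TREATS", f"C{i}") for i in range(5)]
        deg = node_degrees(build_graph(preds))
        assert deg["HUB"] == (0, 5)
        assert deg["C0"] == (1, 0)

    def test_counts_distinct_triples_not_instances(self):
        preds = [make_pred("C1", "TREATS", "C2")] * 4
        deg = node_degrees(build_graph(preds))
        assert deg["C1"] == (0, 1)

    def test_random_graph_matches_bruteforce(self, rng):
        kg = build_graph(random_predications(rng, 200))
        deg = node_degrees(kg)
        for e in kg.entities:
            k_in = sum(1 for (h, r, t) in kg.triples if t == e)
            k_out = sum(1 for (h, r, t) in kg.triples if h == e)
            assert deg[e] == (k_in, k_out)


class TestContingency:
    def test_pure_target_stream(self):
        preds = [make_pred("S", "TREATS", "O")] * 10
        tab = contingency_from_stream(preds, "S", "TREATS", "O")
        assert tab.n[0, 0, 0] == 10 and tab.total == 10

    def test_no_occurrence_stream(self):
        preds = [make_pred("A", "CAUSES", "B")] * 7
        tab = contingency_from_stream(preds, "S", "TREATS", "O")
        assert tab.n[1, 1, 1] == 7 and tab.total == 7

    def test_random_stream_matches_per_instance_classification(self, rng):
        preds = random_predications(rng, 300, n_ent=6, n_rel=2)
        h, r, t = preds[0].subject_id, preds[0].predicate, preds[0].object_id
        tab = contingency_from_stream(preds, h, r, t)
        expected = np.zeros((2, 2, 2), dtype=int)
        for p in preds:
            expected[
                0 if p.subject_id == h else 1,
                0 if p.predicate == r else 1,
                0 if p.object_id == t else 1,
            ] += 1
        assert (tab.n == expected).all()


class TestG2:
    def test_perfect_independence_is_zero(self):
        # n_ijk proportional to product of marginals
        p = np.einsum("i,j,k->ijk", [0.4, 0.6], [0.5, 0.5], [0.25, 0.75])
        tab = ContingencyTable(n=np.rint(p * 400).astype(int))
        assert abs(g2_statistic(tab)) < 1e-9

    def test_reference_table_matches_bruteforce(self):
        n = np.array([20, 5, 5, 20, 5, 20, 20, 5]).reshape(2, 2, 2)
        tab = ContingencyTable(n=n)
        assert g2_statistic(tab) == pytest.approx(g2_oracle(n), rel=1e-12)

    def test_equals_scaled_kl_divergence(self, rng):
        for _ in range(50):
            n = rng.integers(1, 60, size=(2, 2, 2))
            tab = ContingencyTable(n=n)
            T = n.sum()
            p = n / T
            a, b, c = p.sum(axis=(1, 2)), p.sum(axis=(0, 2)), p.sum(axis=(0, 1))
            q = np.einsum("i,j,k->ijk", a, b, c)
            kl = float(np.sum(p * np.log(p / q)))
            assert g2_statistic(tab) == pytest.approx(2 * T * kl, rel=1e-9)

    def test_nonnegative_on_random_tables(self, rng):
        for _ in range(200):
            n = rng.integers(0, 30, size=(2, 2, 2))
            if n.sum() == 0:
                continue
            assert g2_statistic(ContingencyTable(n=n)) >= -1e-9

    def test_invariant_under_axis_relabeling(self, rng):
        for _ in range(20):
            n = rng.integers(1, 40, size=(2, 2, 2))
            g_base = g2_statistic(ContingencyTable(n=n))
            flipped = n[::-1, :, :][:, ::-1, :][:, :, ::-1]
            assert g2_statistic(ContingencyTable(n=flipped)) == pytest.approx(
                g_base, rel=1e-9
            )

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            g2_statistic(ContingencyTable(n=np.zeros((2, 2, 2), dtype=int)))


class TestCombinedScores:
    def test_extremes_map_to_three_and_zero(self, rng):
        kg = build_graph(random_predications(rng, 80))
        scores = combined_scores(kg)
        vals = {k: (s.k_in, s.k_out, s.g2) for k, s in scores.items()}
        k_in_max = max(v[0] for v in vals.values())
        k_out_max = max(v[1] for v in vals.values())
        g2_max = max(v[2] for v in vals.values())
        for k, s in scores.items():
            if (s.k_in, s.k_out, s.g2) == (k_in_max, k_out_max, g2_max):
                assert s.combined == pytest.approx(3.0)
        assert min(s.combined for s in scores.values()) >= 0.0
        assert max(s.combined for s in scores.values()) <= 3.0

    def test_matches_spreadsheet_style_recomputation(self, rng):
        kg = build_graph(random_predications(rng, 20, n_ent=8, n_rel=2))
        degrees = node_degrees(kg)
        g2s = g2_from_graph_counts(kg)
        scores = combined_scores(kg, degrees, g2s)

        def minmax(vals):
            lo, hi = min(vals), max(vals)
            return [0.0 if hi == lo else (v - lo) / (hi - lo) for v in vals]

        keys = list(kg.triples)
        kin = minmax([degrees[t][0] for (_, _, t) in keys])
        kout = minmax([degrees[h][1] for (h, _, _) in keys])
        g2n = minmax([g2s[k] for k in keys])
        for idx, k in enumerate(keys):
            assert scores[k].combined == pytest.approx(kin[idx] + kout[idx] + g2n[idx])

    def test_constant_component_contributes_zero(self):
        # every head has out-degree 1 and tail in-degree 1: degree components
        # are constant and must contribute nothing
        preds = [make_pred(f"A{i}", "TREATS", f"B{i}") for i in range(6)]
        kg = build_graph(preds)
        scores = combined_scores(kg)
        for s in scores.values():
            assert s.combined == pytest.approx(0.0)  # g2 constant too


class TestPrune:
    def test_budget_at_least_size_is_identity(self, rng):
        kg = build_graph(random_predications(rng, 50))
        scores = combined_scores(kg)
        assert prune_to_budget(kg, scores, len(kg)).triples == kg.triples

    def test_zero_budget_empties(self, rng):
        kg = build_graph(random_predications(rng, 50))
        out = prune_to_budget(kg, combined_scores(kg), 0)
        assert len(out) == 0

    def test_matches_sort_and_slice_oracle(self, rng):
        kg = build_graph(random_predications(rng, 100))
        scores = combined_scores(kg)
        kept = set(prune_to_budget(kg, scores, 60).triples)
        expected = set(
            sorted(kg.triples, key=lambda k: (scores[k].combined, k))[:60]
        )
        assert kept == expected

    def test_nesting_across_budgets(self, rng):
        kg = build_graph(random_predications(rng, 120))
        scores = combined_scores(kg)
        prev: set = set()
        for budget in range(0, len(kg) + 1, 7):
            cur = set(prune_to_budget(kg, scores, budget).triples)
            assert prev <= cur
            prev = cur


class TestHook:
    def test_always_true_is_identity(self, rng):
        kg = build_graph(random_predications(rng, 30))
        assert triple_filter_hook(kg, lambda k: True).triples == kg.triples
        assert triple_filter_hook(kg).triples == kg.triples

    def test_always_false_empties(self, rng):
        kg = build_graph(random_predications(rng, 30))
        assert len(triple_filter_hook(kg, lambda k: False)) == 0

    def test_parity_hook_matches_direct_evaluation(self, rng):
        kg = build_graph(random_predications(rng, 50))
        hook = lambda k: (hash(k) & 1) == 0
        out = triple_filter_hook(kg, hook)
        assert set(out.triples) == {k for k in kg.triples if hook(k)}

    def test_raising_hook_identifies_triple(self, rng):
        kg = build_graph(random_predications(rng, 10))
        bad = next(iter(kg.triples))

        def hook(k):
            if k == bad:
                raise RuntimeError("boom")
            return True

        with pytest.raises(RuntimeError, match=str(bad[0])):
            triple_filter_hook(kg, hook)
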