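"""Contrast scoring, pattern selection, the hierarchy sampler, classification."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import fdrscope as f
from fdrscope.errors import DomainError
from fdrscope.msa import msa_from_strings
from fdrscope.partition import Hierarchy, HierarchyNode, patterns_to_tsv
from conftest import exact_hypergeom_tail


class TestContrastScore:
    def test_null_case_low(self):
        # equal fg and bg frequency carries no enrichment signal
        assert f.contrast_score(10, 20, 50, 100) <= 1.0

    def test_matches_enumeration_oracle(self):
        # perfect separation: fg 10/10 vs bg 0/100 (+1 pseudocount applied)
        score = f.contrast_score(10, 10, 0, 100)
        expected = exact_hypergeom_tail(x=10, K=10 + 1, n=10, N=10 + 101)
        assert score == pytest.approx(-np.log10(float(expected)), rel=1e-9)

    def test_zero_matches_zero_score(self):
        assert f.contrast_score(0, 10, 5, 100) == pytest.approx(0.0, abs=1e-12)

    def test_zero_totals_rejected(self):
        with pytest.raises(DomainError):
            f.contrast_score(0, 0, 1, 10)

    @pytest.mark.parametrize("fg_t,bg_t", [(5, 7), (12, 13), (3, 20)])
    def test_small_n_exact(self, fg_t, bg_t):
        for fg_m in range(fg_t + 1):
            for bg_m in range(bg_t + 1):
                got = f.contrast_score(fg_m, fg_t, bg_m, bg_t)
                tail = exact_hypergeom_tail(
                    x=fg_m, K=fg_m + bg_m + 1, n=fg_t, N=fg_t + bg_t + 1
                )
                want = max(0.0, -np.log10(float(tail)))
                assert got == pytest.approx(want, rel=1e-10, abs=1e-12)


class TestSelectPattern:
    def test_perfect_signal_recovers_planted(self, planted_msa_small):
        msa, truth = planted_msa_small
        fg = {i for i, n in truth.assignment.items() if n == 1}
        bg = set(msa.ids) - fg
        pattern = f.select_pattern(msa, fg, bg)
        cols = {p.column for p in pattern}
        assert set(truth.pattern_columns[1]) <= cols
        for p in pattern:
            if p.column in truth.pattern_columns[1]:
                idx = truth.pattern_columns[1].index(p.column)
                assert truth.pattern_residues[1][idx] in p.residue_set

    def test_null_data_nearly_empty(self):
        rng = np.random.default_rng(0)
        rows = {
            f"s{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
            for i in range(200)
        }
        msa = msa_from_strings(rows)
        fg = set(list(rows)[:100])
        bg = set(list(rows)[100:])
        pattern = f.select_pattern(msa, fg, bg)
        assert len(pattern) <= 2  # false positives bounded by the penalty

    def test_disjoint_required(self, planted_msa_small):
        msa, _ = planted_msa_small
        ids = set(msa.ids)
        with pytest.raises(DomainError):
            f.select_pattern(msa, ids, ids)

    def test_sorted_by_score_then_column(self, fitted_small):
        est, msa, truth = fitted_small
        for node in est.hierarchy_.nodes.values():
            scores = [(p.score, -p.column) for p in node.pattern]
            assert scores == sorted(scores, reverse=True)


class TestSampler:
    def test_root_only_config(self, planted_msa_small):
        msa, _ = planted_msa_small
        h = f.sample_hierarchy(msa, f.SamplerConfig(fixed_shape=(), n_sweeps=2, n_restarts=1))
        assert len(h.nodes) == 1
        assert h.nodes[h.root_id].member_ids == set(msa.ids)
        assert h.nodes[h.root_id].pattern == []

    def test_two_leaf_perfect_recovery(self, fitted_small):
        est, msa, truth = fitted_small
        true_labels = [truth.assignment[i] for i in msa.ids]
        assert adjusted_rand_score(true_labels, est.labels_) == pytest.approx(1.0)

    def test_adaptive_finds_planted_split(self, planted_msa_small):
        msa, truth = planted_msa_small
        est = f.PatternHierarchyClusterer(max_depth=2, n_sweeps=8, n_restarts=2, random_state=1)
        est.fit(msa)
        true_labels = [truth.assignment[i] for i in msa.ids]
        assert adjusted_rand_score(true_labels, est.labels_) == pytest.approx(1.0)

    def test_membership_is_partition(self, fitted_small):
        est, msa, _ = fitted_small
        h = est.hierarchy_
        assert h.all_member_ids() == set(msa.ids)
        total = sum(len(h.nodes[n].member_ids) for n in h.nodes)
        assert total == len(msa)

    def test_deterministic_given_seed(self, planted_msa_small):
        msa, _ = planted_msa_small
        cfg = f.SamplerConfig(fixed_shape=((), ()), n_sweeps=5, n_restarts=1, seed=9)
        h1 = f.sample_hierarchy(msa, cfg)
        h2 = f.sample_hierarchy(msa, cfg)
        assert h1.to_json() == h2.to_json()

    def test_null_data_rarely_splits(self):
        # adaptive search on exchangeable sequences should stay at the root
        accepts = 0
        for s in range(10):
            spec = f.PlantedHierarchySpec(
                children={0: []}, n_sequences={0: 80},
                pattern_columns={}, pattern_residues={},
                pattern_strength=0.5, sequence_length=50, seed=900 + s,
            )
            msa, _ = f.gen_hierarchical_msa(spec)
            est = f.PatternHierarchyClusterer(
                max_depth=2, n_sweeps=6, n_restarts=1, random_state=s
            )
            est.fit(msa)
            accepts += len(est.hierarchy_.nodes) > 1
        assert accepts <= 1


class TestObjective:
    def test_root_only_zero(self, planted_msa_small):
        msa, _ = planted_msa_small
        h = Hierarchy([HierarchyNode(0, None, set(msa.ids), [])])
        assert f.objective(msa, h) == 0.0

    def test_low_scoring_position_lowers_objective(self, fitted_small):
        est, msa, _ = fitted_small
        from fdrscope.partition import PatternPosition

        h = est.hierarchy_
        base = f.objective(msa, h)
        nid = next(n for n in h.nodes if n != h.root_id)
        h.nodes[nid].pattern.append(
            PatternPosition(column=1, residue_set="A", fg_matches=1,
                            fg_total=50, bg_matches=1, bg_total=50, score=0.5)
        )
        try:
            assert f.objective(msa, h) < base
        finally:
            h.nodes[nid].pattern.pop()

    def test_truth_beats_random_partitions(self, planted_msa_small):
        msa, truth = planted_msa_small
        cfg = f.SamplerConfig()
        fg1 = {i for i, n in truth.assignment.items() if n == 1}
        fg2 = set(msa.ids) - fg1

        def build(a, b):
            return Hierarchy([
                HierarchyNode(0, None, set(), []),
                HierarchyNode(1, 0, a, f.select_pattern(msa, a, b, cfg)),
                HierarchyNode(2, 0, b, f.select_pattern(msa, b, a, cfg)),
            ])

        truth_obj = f.objective(msa, build(fg1, fg2))
        rng = np.random.default_rng(0)
        ids = np.array(msa.ids)
        for _ in range(100):
            perm = rng.permutation(len(ids))
            a, b = set(ids[perm[:50]]), set(ids[perm[50:]])
            assert truth_obj >= f.objective(msa, build(a, b))

    def test_membership_mismatch_rejected(self, planted_msa_small):
        msa, _ = planted_msa_small
        h = Hierarchy([HierarchyNode(0, None, {"nope"}, [])])
        with pytest.raises(DomainError):
            f.objective(msa, h)


class TestClassify:
    def test_foreground_member_reaches_its_leaf(self, fitted_small):
        est, msa, truth = fitted_small
        h = est.hierarchy_
        seq = msa[next(i for i, n in truth.assignment.items() if n == 1)]
        path = f.classify(h, msa, seq)
        # terminal node's foreground contains the true leaf-1 members
        fg = h.foreground(path[-1])
        leaf1 = {i for i, n in truth.assignment.items() if n == 1}
        assert len(fg & leaf1) / len(leaf1) > 0.9

    def test_background_sequence_stops_at_root(self, fitted_small):
        est, msa, _ = fitted_small
        rng = np.random.default_rng(5)
        seq = f.AlignedSequence(
            "bg", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), msa.n_columns))
        )
        path = f.classify(est.hierarchy_, msa, seq)
        assert path == [est.hierarchy_.root_id]

    def test_held_out_assignment_accuracy(self):
        spec = f.PlantedHierarchySpec(
            children={0: [1, 2]}, n_sequences={1: 60, 2: 60},
            pattern_columns={1: [5, 15, 25, 35, 45], 2: [10, 20, 30, 40, 50]},
            pattern_residues={1: "WWWWW", 2: "CCCCC"}, pattern_strength=0.95,
            sequence_length=60, seed=21,
        )
        msa, truth = f.gen_hierarchical_msa(spec)
        train_ids = [i for i in msa.ids if int(i.split("_s")[1]) < 50]
        test_ids = [i for i in msa.ids if i not in set(train_ids)]
        est = f.PatternHierarchyClusterer(
            fixed_shape=((), ()), n_sweeps=8, n_restarts=2, random_state=2
        ).fit(msa.subset(train_ids))
        h = est.hierarchy_
        # map learned leaves to true leaves by training membership overlap
        correct = 0
        for tid in test_ids:
            path = f.classify(h, msa, msa[tid])
            fg = h.foreground(path[-1])
            true_leaf = truth.assignment[tid]
            same = {i for i in train_ids if truth.assignment[i] == true_leaf}
            correct += len(fg & same) > len(same) / 2
        assert correct / len(test_ids) >= 0.9


def test_hierarchy_json_roundtrip(fitted_small):
    est, _, _ = fitted_small
    h = est.hierarchy_
    again = Hierarchy.from_json(h.to_json())
    assert again.to_json() == h.to_json()
    assert again.to_newick() == h.to_newick()


def test_patterns_tsv_has_all_positions(fitted_small):
    est, _, _ = fitted_small
    h = est.hierarchy_
    tsv = patterns_to_tsv(h)
    n_rows = len(tsv.strip().splitlines()) - 1
    assert n_rows == sum(len(h.nodes[n].pattern) for n in h.nodes)
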