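"""The accumulator classifier: per-node checks, ranking, descent, and the
equivalence/monotonicity/degradation properties that pin its semantics."""

import numpy as np
import pytest

from mitoclass.classifier import (
    classify_dataset,
    classify_sample,
    node_satisfied,
    rank_accumulator,
)
from mitoclass.genotype_io import MISSING, SampleGenotypes
from mitoclass.synthetic_data import genotypes_for_haplogroup

from conftest import random_sample


class TestNodeSatisfied:
    def test_jt_supporting_genotypes(self, tree):
        sample = genotypes_for_haplogroup(tree, "JT")
        assert sample.calls[11251] == "G" and sample.calls[15452] == "A"
        assert node_satisfied(tree.node("JT"), sample)

    def test_empty_requirements_vacuously_true(self, tree):
        empty = SampleGenotypes(family_id="F", individual_id="I", calls={})
        assert node_satisfied(tree.root, empty)

    def test_missing_required_call_fails(self, tree):
        sample = genotypes_for_haplogroup(tree, "JT")
        sample.calls[11251] = MISSING
        assert not node_satisfied(tree.node("JT"), sample)

    def test_mismatching_call_fails(self, tree):
        sample = genotypes_for_haplogroup(tree, "JT")
        sample.calls[15452] = "C"
        assert not node_satisfied(tree.node("JT"), sample)


class TestRankAccumulator:
    def test_deeper_label_wins(self, tree):
        assert rank_accumulator(tree, ["MRCA", "N", "JT"]) == ["JT"]

    def test_root_only_survives_as_root(self, tree):
        assert rank_accumulator(tree, ["MRCA"]) == ["MRCA"]

    def test_empty_accumulator(self, tree):
        assert rank_accumulator(tree, []) == []

    def test_tie_returns_both_in_tree_order(self, toy_tree):
        # Q1 and Q2 are depth-2 siblings
        assert rank_accumulator(toy_tree, ["ROOT", "P", "Q2", "Q1"]) == [
            "Q1", "Q2",
        ]

    def test_unknown_label_raises(self, tree):
        with pytest.raises(KeyError):
            rank_accumulator(tree, ["nonesuch"])


class TestClassifySample:
    def test_l0_supporting_genotypes(self, tree):
        sample = SampleGenotypes(
            family_id="F",
            individual_id="I",
            calls={
                p: tree.panel[p].ancestral_allele
                for p in tree.panel_positions()
            },
        )
        sample.calls.update({9042: "T", 9347: "G", 5442: "C"})
        result = classify_sample(tree, sample)
        assert result.haplogroups == ["L0"]
        assert result.paths == [["MRCA", "L0"]]

    def test_all_missing_is_unclassified(self, tree):
        sample = SampleGenotypes(
            family_id="F",
            individual_id="I",
            calls={p: MISSING for p in tree.panel_positions()},
        )
        result = classify_sample(tree, sample)
        assert result.status == "unclassified"
        assert result.haplogroups == []
        assert set(result.missing_required) == {
            p for node in tree for p, _ in node.required_genotypes
        }

    def test_toy_tie_reports_both(self, toy_tree):
        sample = SampleGenotypes(
            family_id="F",
            individual_id="I",
            calls={100: "G", 200: "T", 300: "A", 400: "T"},
        )
        result = classify_sample(toy_tree, sample)
        assert result.haplogroups == ["Q1", "Q2"]
        assert result.paths == [["ROOT", "P", "Q1"], ["ROOT", "P", "Q2"]]

    def test_toy_reversion_reachable(self, toy_tree):
        # Q3 requires the ancestral state at 100, contradicting its parent P
        sample = SampleGenotypes(
            family_id="F",
            individual_id="I",
            calls={100: "A", 200: "C", 300: "G", 400: "C"},
        )
        assert classify_sample(toy_tree, sample).haplogroups == ["Q3"]

    def test_closure_every_node_recovers_itself(self, tree):
        for name in tree.nodes:
            if name == tree.root.name:
                continue
            result = classify_sample(tree, genotypes_for_haplogroup(tree, name))
            assert result.haplogroups == [name], name
            assert result.paths == [tree.path_to_root(name)]
            assert result.missing_required == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_samples_match_brute_force(self, tree, oracle, seed):
        rng = np.random.default_rng(seed)
        for i in range(150):
            sample = random_sample(tree, rng, sample_id=f"R{i}")
            recursive = classify_sample(tree, sample).haplogroups
            assert recursive == oracle(tree, sample), sample.calls

    def test_perfect_haplotypes_match_brute_force(self, tree, oracle):
        for name in tree.nodes:
            sample = genotypes_for_haplogroup(tree, name)
            recursive = classify_sample(tree, sample).haplogroups
            assert recursive == oracle(tree, sample), name

    def test_toy_tree_exhaustive(self, toy_tree, oracle):
        # all 3^4 = 81 call vectors over the toy panel
        states = {
            100: ["A", "G", MISSING],
            200: ["C", "T", MISSING],
            300: ["G", "A", MISSING],
            400: ["T", "C", MISSING],
        }
        from itertools import product

        for combo in product(*states.values()):
            sample = SampleGenotypes(
                family_id="F",
                individual_id="I",
                calls=dict(zip(states, combo)),
            )
            assert classify_sample(toy_tree, sample).haplogroups == oracle(
                toy_tree, sample
            )


class TestMonotonicityAndDegradation:
    def test_completing_a_child_never_shallower(self, tree):
        """Adding the correct alleles for a child of the current call can
        only deepen (or keep) the classification."""
        for node in tree:
            for child in node.children:
                sample = genotypes_for_haplogroup(tree, node.name)
                before = classify_sample(tree, sample)
                sample.calls.update(dict(child.required_genotypes))
                after = classify_sample(tree, sample)
                assert after.is_classified
                depth_before = (
                    tree.depth(before.haplogroups[0])
                    if before.is_classified else 0
                )
                assert tree.depth(after.haplogroups[0]) >= depth_before

    def test_single_missing_call_degrades_on_path(self, tree):
        """Blanking one required call yields an ancestor of the original
        classification or unclassified — never an off-path haplogroup."""
        for name in tree.nodes:
            if name == tree.root.name:
                continue
            cumulative = tree.required_genotypes_cumulative(name)
            for position, _ in cumulative:
                sample = genotypes_for_haplogroup(tree, name)
                sample.calls[position] = MISSING
                result = classify_sample(tree, sample)
                for label in result.haplogroups:
                    assert label in tree.path_to_root(name), (
                        name, position, label,
                    )


class TestClassifyDataset:
    def test_empty_input(self, tree):
        assert classify_dataset(tree, []) == []

    def test_batch_equals_per_sample_map(self, tree):
        rng = np.random.default_rng(7)
        samples = [random_sample(tree, rng, f"S{i}") for i in range(20)]
        assert classify_dataset(tree, samples) == [
            classify_sample(tree, s) for s in samples
        ]

    def test_fully_missing_samples_exactly_unclassified(self, tree):
        from mitoclass.synthetic_data import SimulationConfig, simulate_dataset

        samples, truth = simulate_dataset(
            tree, SimulationConfig(n_samples=90, seed=5)
        )
        blanked = {s.sample_id for i, s in enumerate(samples) if i % 10 == 0}
        for s in samples:
            if s.sample_id in blanked:
                s.calls = {p: MISSING for p in s.calls}
        results = classify_dataset(tree, samples)
        unclassified = {r.sample_id for r in results if not r.is_classified}
        assert unclassified == blanked
        classified = [r for r in results if r.is_classified]
        assert all(r.haplogroups == [truth[r.sample_id]] for r in classified)

    def test_determinism(self, tree):
        rng = np.random.default_rng(13)
        samples = [random_sample(tree, rng, f"S{i}") for i in range(30)]
        assert classify_dataset(tree, samples) == classify_dataset(tree, samples)
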