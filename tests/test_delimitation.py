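import numpy as np
import pytest

from barcoderich.delimitation import (
    integer_percent,
    richness_estimate,
    score_discrimination,
    score_estimation,
    summarize,
    zero_distance_clusters,
)
from barcoderich.distances import distance_matrix
from barcoderich.errors import InputError
from barcoderich.njtree import is_clade, nj_build

from conftest import make_alignment, mutate, random_sequence
from oracles import brute_force_zero_clusters


def _pipeline(rows):
    aln = make_alignment(rows)
    dm = distance_matrix(aln)
    tree = nj_build(dm)
    return tree, dm


class TestIntegerPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(22, 30, 73), (29, 41, 71), (23, 33, 70), (28, 40, 70), (21, 35, 60),
         (1, 2, 50), (3, 4, 75), (1, 8, 13)],
    )
    def test_round_half_away_from_zero(self, num, den, expected):
        assert integer_percent(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(InputError):
            integer_percent(1, 0)


class TestZeroDistanceClusters:
    def test_all_distinct_gives_singletons(self, rng):
        base = random_sequence(rng, 80)
        rows = {c: mutate(base, [i * 7, i * 7 + 1], rng) for i, c in enumerate("abcd")}
        assert len(set(rows.values())) == 4
        tree, dm = _pipeline(rows)
        clusters = zero_distance_clusters(tree, dm)
        assert sorted(map(len, clusters)) == [1, 1, 1, 1]

    def test_identical_pair_fuses(self, rng):
        # c/d lie on one path away from the identical pair so the corrected
        # matrix stays tree-like and NJ keeps a,b as sisters
        base = random_sequence(rng, 80)
        c = mutate(base, [3, 9], rng)
        rows = {"a": base, "b": base, "c": c, "d": mutate(c, [20, 40, 60], rng)}
        tree, dm = _pipeline(rows)
        clusters = set(zero_distance_clusters(tree, dm))
        assert clusters == {
            frozenset({"a", "b"}),
            frozenset({"c"}),
            frozenset({"d"}),
        }

    def test_mismatched_tree_rejected(self, rng):
        base = random_sequence(rng, 50)
        rows = {c: mutate(base, [i], rng) for i, c in enumerate("abcd")}
        tree, _ = _pipeline(rows)
        _, dm_other = _pipeline({c: mutate(base, [i], rng) for i, c in enumerate("wxyz")})
        with pytest.raises(InputError):
            zero_distance_clusters(tree, dm_other)

    def test_matches_exhaustive_enumeration(self):
        # 200 random instances with heavy sequence duplication, <= 10 tips
        for seed in range(200):
            rng = np.random.default_rng(40_000 + seed)
            n_tips = int(rng.integers(4, 11))
            n_groups = int(rng.integers(1, n_tips + 1))
            base = random_sequence(rng, 30)
            group_seqs = [base] + [
                mutate(base, list(rng.integers(0, 30, size=2)), rng)
                for _ in range(n_groups - 1)
            ]
            rows = {
                f"t{i:02d}": group_seqs[int(rng.integers(n_groups))]
                for i in range(n_tips)
            }
            tree, dm = _pipeline(rows)
            clusters = set(zero_distance_clusters(tree, dm))
            expected = brute_force_zero_clusters(
                tree, list(dm.sample_ids), dm.d
            )
            assert clusters == expected, f"seed {seed}"

    def test_clusters_are_clades_with_zero_diameter(self, rng):
        base = random_sequence(rng, 40)
        seqs = [base, mutate(base, [5], rng), mutate(base, [9, 11], rng)]
        rows = {f"t{i}": seqs[i % 3] for i in range(9)}
        tree, dm = _pipeline(rows)
        for cluster in zero_distance_clusters(tree, dm):
            assert is_clade(tree, cluster)
            for a in cluster:
                for b in cluster:
                    assert dm.get(a, b) == 0.0

    def test_binary_characters_split_identical_rows(self, rng):
        base = random_sequence(rng, 60)
        c = mutate(base, [10, 30], rng)
        rows = {"a": base, "b": base, "c": c, "d": mutate(c, [15, 45], rng)}
        tree, dm = _pipeline(rows)
        no_binary = set(zero_distance_clusters(tree, dm))
        assert frozenset({"a", "b"}) in no_binary
        binary = {"a": "1", "b": "0", "c": "0", "d": "0"}
        split = set(zero_distance_clusters(tree, dm, binary))
        assert frozenset({"a"}) in split and frozenset({"b"}) in split


class TestRichnessEstimate:
    def test_plot_arithmetic(self):
        # 27 clusters, 1 amplification error -> corrected 26 (84% of 31)
        partition = [frozenset({f"s{i}"}) for i in range(27)]
        result = richness_estimate(partition, 1)
        assert result.corrected_estimate == 26
        assert score_estimation(result.corrected_estimate, 31) == 84

    def test_no_errors(self):
        partition = [frozenset({f"s{i}"}) for i in range(5)]
        assert richness_estimate(partition, 0).corrected_estimate == 5

    def test_excess_errors_rejected(self):
        partition = [frozenset({f"s{i}"}) for i in range(3)]
        with pytest.raises(InputError):
            richness_estimate(partition, 4)

    def test_negative_errors_rejected(self):
        with pytest.raises(InputError):
            richness_estimate([frozenset({"a"})], -1)


class TestScoreDiscrimination:
    def _labels(self, pairs):
        return dict(pairs)

    def test_printed_count_examples(self):
        # resolved/present pairs and their printed integer percentages
        for resolved, present, expected in [(22, 30, 73), (29, 41, 71)]:
            partition = [frozenset({f"r{i}a", f"r{i}b"}) for i in range(resolved)]
            labels = {}
            for i in range(resolved):
                labels[f"r{i}a"] = labels[f"r{i}b"] = f"sp{i}"
            # unresolved species: fused in pairs into shared clusters
            n_unresolved = present - resolved
            assert n_unresolved % 2 == 0
            for j in range(n_unresolved // 2):
                partition.append(frozenset({f"u{j}a", f"u{j}b"}))
                labels[f"u{j}a"] = f"spU{2 * j}"
                labels[f"u{j}b"] = f"spU{2 * j + 1}"
            score = score_discrimination(partition, labels)
            assert score.species_resolved == resolved
            assert score.present_in_alignment == present
            assert score.discrimination_accuracy == expected

    def test_every_sample_own_species(self):
        partition = [frozenset({f"s{i}"}) for i in range(6)]
        labels = {f"s{i}": f"sp{i}" for i in range(6)}
        score = score_discrimination(partition, labels)
        assert score.discrimination_accuracy == 100
        assert score.not_resolved == 0

    def test_split_species_not_resolved(self):
        # one species split into two clusters: contributes 2 to the estimate
        # but counts as unresolved
        partition = [frozenset({"a"}), frozenset({"b"})]
        labels = {"a": "sp1", "b": "sp1"}
        score = score_discrimination(partition, labels)
        assert score.species_resolved == 0
        assert score.present_in_alignment == 1

    def test_missing_label_rejected(self):
        with pytest.raises(InputError):
            score_discrimination([frozenset({"a"})], {})


class TestScoreEstimation:
    def test_worked_four_taxon_example(self, rng):
        # two closely related species fuse -> estimate 3 of 4 -> 75%,
        # while discrimination is 2 of 4 -> 50%
        base = random_sequence(rng, 120)
        c = mutate(base, [10, 20, 30], rng)
        rows = {"a": base, "b": base, "c": c, "d": mutate(c, [50, 60, 70, 80], rng)}
        tree, dm = _pipeline(rows)
        clusters = zero_distance_clusters(tree, dm)
        result = richness_estimate(clusters, 0)
        assert result.corrected_estimate == 3
        assert score_estimation(result.corrected_estimate, 4) == 75
        labels = {"a": "spA", "b": "spB", "c": "spC", "d": "spD"}
        assert score_discrimination(clusters, labels).discrimination_accuracy == 50

    def test_perfect_estimate(self):
        assert score_estimation(10, 10) == 100

    def test_zero_plot_size_rejected(self):
        with pytest.raises(InputError):
            score_estimation(3, 0)


class TestSummarize:
    def test_unknown_flora_mode_leaves_fields_absent(self, rng):
        base = random_sequence(rng, 60)
        rows = {"a": base, "b": mutate(base, [5, 6], rng), "c": mutate(base, [9], rng)}
        tree, dm = _pipeline(rows)
        result = richness_estimate(zero_distance_clusters(tree, dm), 0)
        summary = summarize(result, present_in_plot=None, species_labels=None)
        assert summary.estimated_from_data == 3
        assert summary.species_resolved is None
        assert summary.discrimination_accuracy is None
        assert summary.estimation_accuracy is None

    def test_fusion_only_failures_keep_estimation_above_discrimination(self, rng):
        # when the only failures are pairwise fusions of sister species,
        # estimation accuracy >= discrimination accuracy
        for seed in range(10):
            local = np.random.default_rng(seed)
            base = random_sequence(local, 100)
            n_species = int(local.integers(4, 9))
            n_fused_pairs = int(local.integers(1, n_species // 2 + 1))
            rows, labels = {}, {}
            sp = 0
            for j in range(n_fused_pairs):
                seq = mutate(base, list(local.integers(0, 100, 3)), local)
                rows[f"f{j}a"], rows[f"f{j}b"] = seq, seq
                labels[f"f{j}a"], labels[f"f{j}b"] = f"sp{sp}", f"sp{sp + 1}"
                sp += 2
            while sp < n_species:
                key = f"s{sp}"
                rows[key] = mutate(base, list(local.integers(0, 100, 5)), local)
                labels[key] = f"sp{sp}"
                sp += 1
            if len(set(rows.values())) != n_fused_pairs + (n_species - 2 * n_fused_pairs):
                continue  # accidental extra collision; scenario not fusion-only
            tree, dm = _pipeline(rows)
            clusters = zero_distance_clusters(tree, dm)
            result = richness_estimate(clusters, 0)
            summary = summarize(result, n_species, labels)
            assert summary.estimation_accuracy >= summary.discrimination_accuracy
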