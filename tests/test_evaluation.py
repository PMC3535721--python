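"""Vote-strategy accuracy, weighted F-measure, and novel-family typing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirnaclust.evaluation import (
    cluster_compositions,
    evaluate,
    type_clusters,
    vote_accuracy,
    weighted_f_measure,
)
from mirnaclust.io import UNCLASSIFIED


def flat(composition_per_cluster):
    """Expand {cluster: {family: count}} into parallel label lists."""
    clusters, families = [], []
    for c, comp in composition_per_cluster.items():
        for fam, count in comp.items():
            clusters.extend([c] * count)
            families.extend([fam] * count)
    return np.array(clusters), families


class TestVoteAccuracy:
    def test_second_family_qualifies_above_third(self):
        clusters, fams = flat({0: {"famA": 10, "famB": 4}})
        acc, n_correct, _, dead = vote_accuracy(clusters, fams)
        assert n_correct == 14  # 4 > 10/3, both credited
        assert acc == 1.0 and dead == []

    def test_second_family_fails_at_third_boundary(self):
        clusters, fams = flat({0: {"famA": 10, "famB": 3}})
        acc, n_correct, _, dead = vote_accuracy(clusters, fams)
        assert n_correct == 10  # 3 <= 10/3: strict inequality
        assert dead == ["famB"]

    def test_exact_third_is_not_enough(self):
        clusters, fams = flat({0: {"famA": 9, "famB": 3}})
        _, n_correct, _, _ = vote_accuracy(clusters, fams)
        assert n_correct == 9  # 3 == 9/3 exactly; "exceeds" is strict

    def test_small_cluster_filtered(self):
        clusters, fams = flat({0: {"famA": 4}})
        acc, n_correct, _, dead = vote_accuracy(clusters, fams, min_cluster_size=5)
        assert n_correct == 0 and acc == 0.0
        assert dead == ["famA"]

    def test_min_cluster_size_four_variant(self):
        clusters, fams = flat({0: {"famA": 4}})
        acc, n_correct, _, dead = vote_accuracy(clusters, fams, min_cluster_size=4)
        assert n_correct == 4 and acc == 1.0 and dead == []

    def test_perfect_clustering(self):
        clusters, fams = flat({i: {f"fam{i}": 6} for i in range(5)})
        acc, n_correct, comps, dead = vote_accuracy(clusters, fams)
        assert acc == 1.0 and n_correct == 30 and dead == []

    def test_tied_largest_families_all_credited(self):
        clusters, fams = flat({0: {"famA": 5, "famB": 5}})
        _, n_correct, _, dead = vote_accuracy(clusters, fams)
        assert n_correct == 10 and dead == []

    def test_sentinel_never_correct_and_never_votes(self):
        clusters, fams = flat({0: {UNCLASSIFIED: 20, "famA": 4}})
        acc, n_correct, _, _ = vote_accuracy(clusters, fams)
        # famA is the largest *known* family despite the sentinel mass
        assert n_correct == 4 and acc == 1.0

    def test_denominator_includes_filtered_members(self):
        clusters, fams = flat({0: {"famA": 10}, 1: {"famA": 3}})
        acc, n_correct, _, _ = vote_accuracy(clusters, fams)
        assert n_correct == 10
        assert acc == pytest.approx(10 / 13)

    def test_accuracy_monotone_in_min_cluster_size(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 40))
            clusters = rng.integers(0, 5, size=n)
            fams = [f"fam{int(f)}" for f in rng.integers(0, 4, size=n)]
            accs = [
                vote_accuracy(clusters, fams, min_cluster_size=m)[0]
                for m in (1, 3, 5, 8)
            ]
            assert all(a >= b - 1e-12 for a, b in zip(accs, accs[1:]))

    def test_all_sentinel_errors(self):
        clusters, fams = flat({0: {UNCLASSIFIED: 6}})
        with pytest.raises(ValueError):
            vote_accuracy(clusters, fams)


def brute_force_f(clusters, fams):
    """Independent O(families x clusters) oracle."""
    known = sorted(set(f for f in fams if f != UNCLASSIFIED))
    cs = sorted(set(int(c) for c in clusters))
    total = sum(1 for f in fams if f != UNCLASSIFIED)
    out = 0.0
    for fam in known:
        fam_size = sum(1 for f in fams if f == fam)
        best = 0.0
        for c in cs:
            csize = sum(1 for x in clusters if x == c)
            nij = sum(1 for x, f in zip(clusters, fams) if x == c and f == fam)
            if nij:
                p, r = nij / csize, nij / fam_size
                best = max(best, 2 * p * r / (p + r))
        out += fam_size / total * best
    return out


class TestWeightedFMeasure:
    def test_perfect_clustering_is_one(self):
        clusters, fams = flat({i: {f"fam{i}": 5} for i in range(4)})
        assert weighted_f_measure(clusters, fams) == pytest.approx(1.0)

    def test_family_split_across_two_pure_clusters(self):
        clusters, fams = flat({0: {"famA": 5}, 1: {"famA": 5}})
        assert weighted_f_measure(clusters, fams) == pytest.approx(2 / 3)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        clusters = rng.integers(0, 6, size=n)
        fams = [f"fam{int(f)}" for f in rng.integers(0, 5, size=n)]
        got = weighted_f_measure(clusters, fams)
        assert got == pytest.approx(brute_force_f(clusters, fams))
        assert 0.0 <= got <= 1.0


class TestTypeClusters:
    def run(self, comp_dict, min_cluster_size=5, vote_fraction=1 / 3):
        clusters, fams = flat(comp_dict)
        comps = cluster_compositions(clusters, fams)
        return type_clusters(comps, min_cluster_size, vote_fraction)

    def test_majority_novel(self):
        typing, tallies = self.run({0: {UNCLASSIFIED: 8, "famA": 1}})
        assert typing[0] == "novel"
        assert tallies["novel_families"] == 1 and tallies["novel_members"] == 8

    def test_mixed_rule(self):
        typing, tallies = self.run({0: {"famA": 9, UNCLASSIFIED: 4}})
        assert typing[0] == "mixed"  # 4 > 9/3
        assert tallies["mixed_members"] == 4

    def test_existing_rule(self):
        typing, tallies = self.run({0: {"famA": 9, UNCLASSIFIED: 2}})
        assert typing[0] == "existing"  # 2 <= 9/3
        assert tallies["to_existing_members"] == 2

    def test_small_cluster_fails(self):
        typing, tallies = self.run({0: {UNCLASSIFIED: 2, "famA": 1}})
        assert 0 not in typing
        assert tallies["failed_members"] == 2

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_tallies_partition_sentinel_members(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        clusters = rng.integers(0, 6, size=n)
        fams = [
            UNCLASSIFIED if rng.random() < 0.4 else f"fam{int(rng.integers(0, 4))}"
            for _ in range(n)
        ]
        comps = cluster_compositions(clusters, fams)
        _, tallies = type_clusters(comps)
        total_sentinel = sum(1 for f in fams if f == UNCLASSIFIED)
        assert (
            tallies["novel_members"] + tallies["mixed_members"]
            + tallies["to_existing_members"] + tallies["failed_members"]
            == total_sentinel
        )


class TestEvaluate:
    def test_report_fields_consistent(self):
        clusters, fams = flat({0: {"famA": 10, "famB": 4}, 1: {"famC": 3}})
        report = evaluate(clusters, fams)
        assert report.n_total == 17
        assert report.n_correct == 14
        assert report.accuracy == pytest.approx(14 / 17)
        assert report.dead_families == ["famC"]
        assert 0.0 <= report.f_measure <= 1.0
        d = report.to_dict()
        assert d["n_correct"] == 14 and len(d["clusters"]) == 2

    def test_metrics_bounded(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 40))
            clusters = rng.integers(0, 5, size=n)
            fams = [f"fam{int(f)}" for f in rng.integers(0, 4, size=n)]
            report = evaluate(clusters, fams)
            assert 0.0 <= report.accuracy <= 1.0
            assert 0.0 <= report.f_measure <= 1.0
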