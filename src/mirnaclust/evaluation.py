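"""Scoring clusterings against known miRNA families.

Two metrics are computed. The *vote strategy* discards clusters smaller
than ``min_cluster_size`` (default 5) as bad quality, credits each kept
cluster to its largest known family, and additionally credits the
second-largest family when its count strictly exceeds ``vote_fraction``
(default 1/3) of the largest — near-identical families (e.g. plant
MIR169_1 / MIR169_2) frequently co-cluster and should not be penalized.
Accuracy is the credited fraction of all labeled sequences. The
*weighted F-measure* matches each family to its best cluster by the
harmonic mean of precision and recall and averages, weighted by family
size.

Clusters containing unclassified sequences are additionally typed for
novel-family discovery: NOVEL (unclassified members form a strict
majority), MIXED (unclassified group and largest known family both
present at a considerable rate), EXISTING (a known family dominates and
the unclassified minority folds into it), else FAILED. The four tallies
partition all unclassified members exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import UNCLASSIFIED

DEFAULT_MIN_CLUSTER_SIZE = 5
DEFAULT_VOTE_FRACTION = 1 / 3


@dataclass
class ClusterComposition:
    """Family membership counts of one cluster."""

    cluster_index: int
    size: int
    family_counts: dict[str, int]
    largest_family: str | None = None
    largest_count: int = 0
    second_family: str | None = None
    second_count: int = 0

    @classmethod
    def from_counts(cls, index: int, counts: Mapping[str, int]) -> "ClusterComposition":
        size = sum(counts.values())
        known = [(f, c) for f, c in counts.items() if f != UNCLASSIFIED]
        # deterministic: count desc, then name
        known.sort(key=lambda fc: (-fc[1], fc[0]))
        largest = known[0] if known else (None, 0)
        second = known[1] if len(known) > 1 else (None, 0)
        return cls(
            cluster_index=index,
            size=size,
            family_counts=dict(counts),
            largest_family=largest[0],
            largest_count=largest[1],
            second_family=second[0],
            second_count=second[1],
        )

    @property
    def sentinel_count(self) -> int:
        return self.family_counts.get(UNCLASSIFIED, 0)


@dataclass
class EvaluationReport:
    """Full evaluation of one clustering against family labels.

    ``accuracy``/``f_measure`` are None for label-free runs, where only
    cluster typing against the unclassified sentinel is meaningful.
    """

    accuracy: float | None
    f_measure: float | None
    n_correct: int
    n_total: int
    K: int
    dead_families: list[str]
    compositions: list[ClusterComposition]
    typing: dict[int, str]
    params: dict
    correct_ids: list[str] = field(default_factory=list)
    credited_families_by_cluster: dict[int, tuple[str, ...]] = field(default_factory=dict)
    tallies: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f_measure": self.f_measure,
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "K": self.K,
            "dead_families": sorted(self.dead_families),
            "clusters": [
                {
                    "index": c.cluster_index,
                    "size": c.size,
                    "composition": dict(sorted(c.family_counts.items())),
                    "type": self.typing.get(c.cluster_index, "na"),
                }
                for c in self.compositions
            ],
            "typing_tallies": dict(self.tallies),
            "params": dict(self.params),
        }


def cluster_compositions(
    cluster_labels: Sequence[int], family_labels: Sequence[str]
) -> list[ClusterComposition]:
    """Per-cluster family counts, ordered by cluster index."""
    if len(cluster_labels) != len(family_labels):
        raise ValueError("cluster and family label lengths differ")
    counters: dict[int, Counter] = {}
    for c, fam in zip(cluster_labels, family_labels):
        counters.setdefault(int(c), Counter())[fam] += 1
    return [
        ClusterComposition.from_counts(c, counters[c]) for c in sorted(counters)
    ]


def _credited_families(
    comp: ClusterComposition, vote_fraction: float
) -> tuple[str, ...]:
    """Families credited in one kept cluster under the vote strategy.

    All families tied for the largest count are dominant. Runner-up
    families (the next distinct count) are credited iff their count
    strictly exceeds vote_fraction × largest_count.
    """
    known = [
        (f, c) for f, c in comp.family_counts.items() if f != UNCLASSIFIED and c > 0
    ]
    if not known:
        return ()
    known.sort(key=lambda fc: (-fc[1], fc[0]))
    top = known[0][1]
    credited = [f for f, c in known if c == top]
    runner_counts = [c for _, c in known if c < top]
    if runner_counts:
        second = runner_counts[0]
        if second > vote_fraction * top:
            credited.extend(f for f, c in known if c == second)
    return tuple(credited)


def vote_accuracy(
    cluster_labels: Sequence[int] | "np.ndarray",
    family_labels: Sequence[str],
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    vote_fraction: float = DEFAULT_VOTE_FRACTION,
) -> tuple[float, int, list[ClusterComposition], list[str]]:
    """Vote-strategy accuracy.

    Returns ``(accuracy, n_correct, compositions, dead_families)``.
    Unclassified sequences never count as correct and never vote; the
    denominator is every labeled sequence, including members of
    discarded small clusters. A known family is *dead* when it is
    credited in no kept cluster — either its members fell into filtered
    small clusters or they were absorbed by a bigger family.
    """
    cluster_labels = np.asarray(
        getattr(cluster_labels, "labels", cluster_labels), dtype=np.int64
    )
    family_labels = list(family_labels)
    all_families = {f for f in family_labels if f != UNCLASSIFIED}
    n_total = sum(1 for f in family_labels if f != UNCLASSIFIED)
    if n_total == 0:
        raise ValueError("no labeled records to evaluate")
    comps = cluster_compositions(cluster_labels, family_labels)
    n_correct = 0
    alive: set[str] = set()
    for comp in comps:
        if comp.size < min_cluster_size:
            continue
        credited = _credited_families(comp, vote_fraction)
        alive.update(credited)
        n_correct += sum(comp.family_counts[f] for f in credited)
    dead = sorted(all_families - alive)
    return n_correct / n_total, n_correct, comps, dead


def weighted_f_measure(
    cluster_labels: Sequence[int] | "np.ndarray",
    family_labels: Sequence[str],
) -> float:
    """Family-size-weighted average of each family's best-cluster F-measure.

    For family i and cluster j with overlap n_ij: precision = n_ij /
    |cluster j|, recall = n_ij / |family i|, F_ij their harmonic mean;
    F_i = max_j F_ij; result = Σ_i (|family i| / total labeled) · F_i.
    Unclassified sequences contribute to cluster sizes (diluting
    precision) but form no family of their own.
    """
    cluster_labels = np.asarray(
        getattr(cluster_labels, "labels", cluster_labels), dtype=np.int64
    )
    family_labels = list(family_labels)
    families = sorted({f for f in family_labels if f != UNCLASSIFIED})
    if not families:
        raise ValueError("no labeled records to evaluate")
    cluster_sizes = Counter(int(c) for c in cluster_labels)
    family_sizes = Counter(f for f in family_labels if f != UNCLASSIFIED)
    overlap: dict[tuple[str, int], int] = Counter()
    for c, fam in zip(cluster_labels, family_labels):
        if fam != UNCLASSIFIED:
            overlap[(fam, int(c))] += 1
    total = sum(family_sizes.values())
    score = 0.0
    for fam in families:
        best = 0.0
        for c in cluster_sizes:
            n_ij = overlap.get((fam, c), 0)
            if n_ij == 0:
                continue
            p = n_ij / cluster_sizes[c]
            r = n_ij / family_sizes[fam]
            best = max(best, 2 * p * r / (p + r))
        score += family_sizes[fam] / total * best
    return score


def type_clusters(
    compositions: Sequence[ClusterComposition],
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    vote_fraction: float = DEFAULT_VOTE_FRACTION,
) -> tuple[dict[int, str], dict[str, int]]:
    """Type each kept cluster for novel-family discovery and tally members.

    Kept clusters (size ≥ min_cluster_size) are typed:

    * ``novel`` — unclassified members are a strict majority;
    * ``mixed`` — the unclassified group and the largest known family
      are both present and min(group) > vote_fraction × max(group);
    * ``existing`` — a known family dominates, unclassified members are
      present but at or below the vote_fraction ratio;
    * clusters whose unclassified members fit none of the above, and all
      discarded small clusters, send their unclassified members to the
      ``failed`` tally.

    The four member tallies partition all unclassified members exactly.
    """
    typing: dict[int, str] = {}
    tallies = {
        "novel_families": 0,
        "novel_members": 0,
        "mixed_members": 0,
        "to_existing_members": 0,
        "failed_members": 0,
    }
    for comp in compositions:
        s = comp.sentinel_count
        if comp.size < min_cluster_size:
            tallies["failed_members"] += s
            continue
        L = comp.largest_count
        if s > comp.size - s:
            typing[comp.cluster_index] = "novel"
            tallies["novel_families"] += 1
            tallies["novel_members"] += s
        elif s > 0 and L > 0 and min(s, L) > vote_fraction * max(s, L):
            typing[comp.cluster_index] = "mixed"
            tallies["mixed_members"] += s
        elif s > 0 and L >= s and s <= vote_fraction * L:
            typing[comp.cluster_index] = "existing"
            tallies["to_existing_members"] += s
        elif s > 0:
            typing[comp.cluster_index] = "failed"
            tallies["failed_members"] += s
        else:
            typing[comp.cluster_index] = "existing"
    return typing, tallies


def typing_report(
    clustering,
    family_labels: Sequence[str],
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    vote_fraction: float = DEFAULT_VOTE_FRACTION,
) -> EvaluationReport:
    """Label-free report: compositions and novel-family typing only."""
    cluster_labels = np.asarray(
        getattr(clustering, "labels", clustering), dtype=np.int64
    )
    K = int(getattr(clustering, "K", cluster_labels.max() + 1 if cluster_labels.size else 0))
    comps = cluster_compositions(cluster_labels, list(family_labels))
    typing, tallies = type_clusters(comps, min_cluster_size, vote_fraction)
    return EvaluationReport(
        accuracy=None,
        f_measure=None,
        n_correct=0,
        n_total=0,
        K=K,
        dead_families=[],
        compositions=comps,
        typing=typing,
        params={
            "min_cluster_size": min_cluster_size,
            "vote_fraction": vote_fraction,
        },
        tallies=tallies,
    )


def evaluate(
    clustering,
    family_labels: Sequence[str],
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    vote_fraction: float = DEFAULT_VOTE_FRACTION,
    ids: Sequence[str] | None = None,
) -> EvaluationReport:
    """Full evaluation: vote accuracy, F-measure, dead families, typing."""
    cluster_labels = np.asarray(
        getattr(clustering, "labels", clustering), dtype=np.int64
    )
    K = int(getattr(clustering, "K", cluster_labels.max() + 1 if cluster_labels.size else 0))
    family_labels = list(family_labels)
    if ids is None:
        ids = [str(i) for i in range(len(family_labels))]
    accuracy, n_correct, comps, dead = vote_accuracy(
        cluster_labels, family_labels, min_cluster_size, vote_fraction
    )
    fm = weighted_f_measure(cluster_labels, family_labels)
    typing, tallies = type_clusters(comps, min_cluster_size, vote_fraction)

    credited = {
        comp.cluster_index: _credited_families(comp, vote_fraction)
        for comp in comps
        if comp.size >= min_cluster_size
    }
    correct_ids = [
        ids[row]
        for row in range(len(family_labels))
        if family_labels[row] in credited.get(int(cluster_labels[row]), ())
    ]
    n_total = sum(1 for f in family_labels if f != UNCLASSIFIED)
    return EvaluationReport(
        accuracy=accuracy,
        f_measure=fm,
        n_correct=n_correct,
        n_total=n_total,
        K=K,
        dead_families=dead,
        compositions=comps,
        typing=typing,
        params={
            "min_cluster_size": min_cluster_size,
            "vote_fraction": vote_fraction,
        },
        correct_ids=correct_ids,
        credited_families_by_cluster=credited,
        tallies=tallies,
    )
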