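"""Scoring of pipeline output against simulated ground truth.

Fitted clusters are matched to true clusters by majority vote over their
member variants; the reconstructed lineage is then compared with the true
clone tree as an unordered rooted tree over cluster labels, and the
diagnosis->relapse founder mapping is checked against the designated
surviving clone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cli_report import RunReport
from .synthetic_data import SimTruth

__all__ = ["RecoveryScore", "score_recovery", "adjusted_rand_index"]


@dataclass(frozen=True)
class RecoveryScore:
    clusters_matched: bool
    topology_correct: bool
    founder_correct: bool
    ari: float
    n_true_clusters: int
    n_fitted_clusters: int

    @property
    def fully_recovered(self) -> bool:
        return (
            self.clusters_matched
            and self.topology_correct
            and self.founder_correct
        )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    n = a.size
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(table).sum()
    sum_a = comb(table.sum(axis=1)).sum()
    sum_b = comb(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _true_cluster_by_pos(truth: SimTruth) -> dict[int, str]:
    # simulate_reads assigns pos = 1000 * (rank + 1) over sorted variant ids
    ids = sorted(truth.cluster_of_variant)
    return {
        1000 * (i + 1): truth.cluster_of_variant[v]
        for i, v in enumerate(ids)
    }


def score_recovery(report: RunReport, truth: SimTruth | None = None) -> RecoveryScore:
    """Compare a simulated run's reconstruction with its ground truth."""
    truth = truth if truth is not None else report.truth
    if truth is None:
        raise ValueError("report carries no simulation ground truth")
    pos_to_true = _true_cluster_by_pos(truth)
    assign = report.assignments
    true_labels = [pos_to_true[p] for p in assign["pos"]]
    fitted_labels = list(assign["cluster"])
    ari = adjusted_rand_index(true_labels, fitted_labels)

    # majority-vote mapping fitted -> true cluster
    mapping: dict[str, str] = {}
    for lab in set(fitted_labels):
        members = [t for t, f in zip(true_labels, fitted_labels) if f == lab]
        mapping[lab] = max(set(members), key=members.count)
    true_clusters = set(truth.category_of_cluster)
    clusters_matched = (
        len(mapping) == len(true_clusters)
        and set(mapping.values()) == true_clusters
    )

    topology_correct = False
    founder_correct = False
    if clusters_matched:
        tree = report.tree
        # recovered parent edges over true-cluster labels
        edges = set()
        for parents in (tree.parent_dx, tree.parent_rel):
            for child, parent in parents.items():
                child_cl = mapping[tree.clones[child].own_cluster]
                parent_cl = mapping[tree.clones[parent].own_cluster]
                edges.add((child_cl, parent_cl))
        true_edges = {
            (truth.cluster_of_clone[c], truth.cluster_of_clone[p])
            for c, p in truth.clone_tree.items()
            if p is not None
        }
        topology_correct = edges == true_edges

        anchors = {
            mapping[tree.clones[dx].own_cluster]
            for dx, _ in tree.founder_edges
        }
        founder_correct = anchors == {
            truth.cluster_of_clone[truth.surviving_clone]
        }

    return RecoveryScore(
        clusters_matched=clusters_matched,
        topology_correct=topology_correct,
        founder_correct=founder_correct,
        ari=ari,
        n_true_clusters=len(true_clusters),
        n_fitted_clusters=len(set(fitted_labels)),
    )
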