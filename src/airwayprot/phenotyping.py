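"""Responder phenotyping and hierarchical clustering of protein profiles.

Patients are labelled omalizumab responders (OR) when RBM thickness falls
between baseline and 12 months (ties and increases are non-responders,
NOR), and galectin-3-positive when the baseline galectin-3 score is
nonzero.  Protein profiles are clustered agglomeratively on Euclidean
distances over raw consensus scores; cluster structure is summarized by
the agglomerative coefficient

    AC = mean_i (1 - h_first(i) / h_final)

where h_first(i) is the height at which observation i first merges and
h_final the height of the last merge; AC near 1 indicates tight, well-
separated groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .quantitation import ScorePanel

__all__ = [
    "PhenotypeLabel",
    "ClusterResult",
    "classify_responder",
    "gal3_status",
    "hierarchical_cluster",
    "agglomerative_coefficient",
    "evaluate_segregation",
    "to_newick",
]


@dataclass(frozen=True)
class PhenotypeLabel:
    patient_id: str
    responder: str      # "OR" or "NOR"
    gal3_baseline: str  # "positive" or "negative"

    def __post_init__(self) -> None:
        if self.responder not in ("OR", "NOR"):
            raise ValueError(f"unknown responder label {self.responder!r}")
        if self.gal3_baseline not in ("positive", "negative"):
            raise ValueError(f"unknown Gal-3 status {self.gal3_baseline!r}")


def classify_responder(rbm_t0: float, rbm_t12: float) -> str:
    """OR iff RBM thickness strictly decreased from baseline to 12 months;
    no reduction (including equality) is NOR."""
    if rbm_t0 <= 0 or rbm_t12 <= 0:
        raise ValueError("thickness values must be positive")
    return "OR" if rbm_t12 < rbm_t0 else "NOR"


def gal3_status(gal3_score_t0: float) -> str:
    """Baseline galectin-3 presence: positive iff the score is nonzero
    (any protein surviving the consensus filter counts as present)."""
    if gal3_score_t0 < 0:
        raise ValueError("score must be nonnegative")
    return "positive" if gal3_score_t0 > 0 else "negative"


@dataclass
class ClusterResult:
    """Dendrogram, agglomerative coefficient, and 2-cluster cut."""

    patient_ids: list[str]
    linkage_matrix: np.ndarray = field(repr=False)
    merge_sequence: list[tuple[frozenset, frozenset, float]] = field(repr=False)
    agglomerative_coefficient: float = 0.0
    labels_k2: dict[str, int] = field(default_factory=dict)
    linkage_method: str = "average"

    def __post_init__(self) -> None:
        if not 0.0 <= self.agglomerative_coefficient <= 1.0:
            raise ValueError("agglomerative coefficient must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps({
            "patients": self.patient_ids,
            "agglomerative_coefficient": self.agglomerative_coefficient,
            "labels_k2": self.labels_k2,
            "linkage": self.linkage_method,
        }, indent=2)


def _merge_sequence(Z: np.ndarray, ids: Sequence[str]
                    ) -> list[tuple[frozenset, frozenset, float]]:
    n = len(ids)
    members: dict[int, frozenset] = {i: frozenset([ids[i]]) for i in range(n)}
    seq = []
    for row_i, (a, b, h, _) in enumerate(Z):
        sa, sb = members[int(a)], members[int(b)]
        seq.append((sa, sb, float(h)))
        members[n + row_i] = sa | sb
    return seq


def agglomerative_coefficient(merge_sequence: Sequence[tuple],
                              patient_ids: Sequence[str] | None = None) -> float:
    """AC = mean over observations of 1 - h_first/h_final.

    Accepts a :class:`ClusterResult` or a raw merge sequence of
    (member-set, member-set, height) triples.  A flat dendrogram (all
    merges at the final height, including the two-observation case) has
    AC = 0.
    """
    if isinstance(merge_sequence, ClusterResult):
        merge_sequence = merge_sequence.merge_sequence
    if not merge_sequence:
        raise ValueError("empty merge sequence")
    heights = [h for _, _, h in merge_sequence]
    if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
        raise ValueError("merge heights must be non-decreasing")
    h_final = heights[-1]
    if h_final == 0:
        return 0.0
    h_first: dict = {}
    for sa, sb, h in merge_sequence:
        for member in sa | sb:
            h_first.setdefault(member, h)
    return float(np.mean([1.0 - h / h_final for h in h_first.values()]))


def hierarchical_cluster(profiles, timepoint: str | None = None,
                         linkage: str = "average",
                         standardize: bool = False) -> ClusterResult:
    """Agglomerative clustering of patient profiles.

    ``profiles`` is a :class:`ScorePanel` (with ``timepoint`` selecting
    the slice) or a patients x features DataFrame.  Euclidean distances on
    raw scores (optionally z-scored per feature); patients are ordered
    lexicographically so the result is input-order invariant.
    """
    if isinstance(profiles, ScorePanel):
        if timepoint is None:
            tps = profiles.timepoints
            if len(tps) != 1:
                raise ValueError("specify a timepoint for a multi-time panel")
            timepoint = tps[0]
        mat = profiles.matrix(timepoint)
    else:
        mat = pd.DataFrame(profiles).sort_index()
    if len(mat) < 2:
        raise ValueError("need at least two patients to cluster")
    X = mat.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    ids = [str(i) for i in mat.index]
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage)
    seq = _merge_sequence(Z, ids)
    flat = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    # deterministic label orientation: cluster of the first (lexicographically
    # smallest) patient is cluster 1
    first = flat[0]
    labels = {pid: (1 if c == first else 2) for pid, c in zip(ids, flat)}
    return ClusterResult(
        patient_ids=ids, linkage_matrix=Z, merge_sequence=seq,
        agglomerative_coefficient=agglomerative_coefficient(seq),
        labels_k2=labels, linkage_method=linkage)


def evaluate_segregation(result: ClusterResult,
                         labels: Sequence[PhenotypeLabel] | Mapping[str, str]
                         ) -> dict:
    """Compare the 2-cluster cut with OR/NOR phenotype labels.

    Returns the per-cluster composition, the majority phenotype of each
    cluster, and the crossover patients (those sitting in the cluster
    dominated by the opposite phenotype, e.g. a non-responder clustering
    with the responders).  A degenerate cut with an empty cluster is an
    error.
    """
    if isinstance(labels, Mapping):
        resp = dict(labels)
    else:
        resp = {l.patient_id: l.responder for l in labels}
    missing = [p for p in result.patient_ids if p not in resp]
    if missing:
        raise ValueError(f"phenotype labels missing for {missing}")
    if len(set(result.labels_k2.values())) < 2:
        raise ValueError("degenerate 2-cut: one cluster is empty")

    composition: dict[int, dict[str, list[str]]] = {1: {}, 2: {}}
    for pid, c in result.labels_k2.items():
        composition[c].setdefault(resp[pid], []).append(pid)
    majority = {}
    for c, groups in composition.items():
        majority[c] = max(sorted(groups), key=lambda g: len(groups[g]))
    crossovers = sorted(
        pid for pid, c in result.labels_k2.items() if resp[pid] != majority[c])
    return {
        "composition": {c: {g: sorted(p) for g, p in groups.items()}
                        for c, groups in composition.items()},
        "majority": majority,
        "crossovers": crossovers,
        "n_crossovers": len(crossovers),
    }


def to_newick(result: ClusterResult) -> str:
    """Dendrogram as a Newick string with branch lengths taken from merge
    heights (parent height minus child height)."""
    tree = hierarchy.to_tree(result.linkage_matrix)

    def walk(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{result.patient_ids[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    root = tree
    left = walk(root.left, root.dist)
    right = walk(root.right, root.dist)
    return f"({left},{right});"
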