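"""Responder / Gal-3 classification, hierarchical clustering, the
agglomerative coefficient, and group-segregation reporting."""

import io
import subprocess

import numpy as np
import pandas as pd
import pytest

from airwayprot.phenotyping import (
    PhenotypeLabel,
    agglomerative_coefficient,
    classify_responder,
    evaluate_segregation,
    gal3_status,
    hierarchical_cluster,
    to_newick,
)
from airwayprot.quantitation import ScorePanel
from airwayprot.synth import SyntheticCohortConfig, generate_cohort


class TestResponderClassification:
    @pytest.mark.parametrize("t0,t12,expected", [
        (8.0, 6.5, "OR"),
        (6.0, 6.0, "NOR"),   # "no reduction" includes equality
        (5.0, 7.0, "NOR"),
    ])
    def test_rbm_reduction_rule(self, t0, t12, expected):
        assert classify_responder(t0, t12) == expected

    def test_positive_thickness_required(self):
        with pytest.raises(ValueError):
            classify_responder(0.0, 5.0)


class TestGal3Status:
    def test_presence_rule(self):
        assert gal3_status(10.0) == "positive"
        assert gal3_status(0.0) == "negative"

    def test_study_panel_baseline(self, panel):
        t0 = panel.values("galectin3", "T0")
        statuses = {p: gal3_status(v) for p, v in t0.items()}
        positives = sorted(p for p, s in statuses.items() if s == "positive")
        assert positives == ["OR1", "OR2", "OR3", "OR4"]


class TestAgglomerativeCoefficient:
    def test_two_points_zero(self):
        r = hierarchical_cluster(pd.DataFrame([[0.0], [3.0]], index=["a", "b"]))
        assert r.agglomerative_coefficient == 0.0

    def test_equal_pairwise_distances_zero(self):
        # equilateral triangle: every merge at the final height
        pts = pd.DataFrame([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]],
                           index=list("abc"), dtype=float)
        r = hierarchical_cluster(pts)
        assert r.agglomerative_coefficient == pytest.approx(0.0, abs=1e-12)

    def test_line_configuration_closed_form(self):
        """Points {0,1,10,11} on a line, average linkage: first merges at 1,
        final at mean cross distance 10, so AC = 1 - 1/10."""
        pts = pd.DataFrame([[0.0], [1.0], [10.0], [11.0]], index=list("abcd"))
        r = hierarchical_cluster(pts)
        assert r.agglomerative_coefficient == pytest.approx(0.9)

    def test_duplicated_points_far_clusters(self):
        pts = pd.DataFrame([[0.0], [0.0], [100.0], [100.0]], index=list("abcd"))
        r = hierarchical_cluster(pts)
        assert r.agglomerative_coefficient == pytest.approx(1.0)

    def test_direct_recomputation_from_definition(self, cohort):
        """AC from the merge sequence equals a recomputation straight from
        the linkage matrix."""
        profiles, _ = cohort
        r = hierarchical_cluster(ScorePanel(profiles), timepoint="T0")
        Z = r.linkage_matrix
        n = len(r.patient_ids)
        h_first = np.full(n, np.nan)
        members = {i: [i] for i in range(n)}
        for row_i, (a, b, h, _) in enumerate(Z):
            for leaf in members[int(a)] + members[int(b)]:
                if np.isnan(h_first[leaf]):
                    h_first[leaf] = h
            members[n + row_i] = members[int(a)] + members[int(b)]
        expected = np.mean(1.0 - h_first / Z[-1, 2])
        assert r.agglomerative_coefficient == pytest.approx(expected)

    def test_matches_agnes_reference(self, cohort):
        """AC and merge structure agree with the AGNES reference
        implementation (R cluster::agnes, average linkage, Euclidean)."""
        profiles, _ = cohort
        sp = ScorePanel(profiles)
        mat = sp.matrix("T0")
        csv = io.StringIO()
        mat.to_csv(csv)
        script = (
            "x <- read.csv('stdin', row.names=1);"
            "a <- cluster::agnes(x, metric='euclidean', method='average');"
            "cat(sprintf('%.10f', a$ac))"
        )
        out = subprocess.run(["Rscript", "-e", script], input=csv.getvalue(),
                             capture_output=True, text=True, check=True)
        ref_ac = float(out.stdout.strip())
        r = hierarchical_cluster(sp, timepoint="T0")
        assert r.agglomerative_coefficient == pytest.approx(ref_ac, abs=1e-6)


class TestClustering:
    def test_requires_two_patients(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(pd.DataFrame([[1.0]], index=["a"]))

    def test_input_order_invariance(self, cohort):
        profiles, _ = cohort
        shuffled = profiles.sample(frac=1.0, random_state=0)
        r1 = hierarchical_cluster(ScorePanel(profiles), timepoint="T0")
        r2 = hierarchical_cluster(ScorePanel(shuffled), timepoint="T0")
        assert r1.patient_ids == r2.patient_ids
        assert r1.labels_k2 == r2.labels_k2
        assert np.allclose(r1.linkage_matrix, r2.linkage_matrix)

    def test_two_tight_groups_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.05, size=(3, 4))
        b = rng.normal(10.0, 0.05, size=(3, 4))
        pts = pd.DataFrame(np.vstack([a, b]), index=list("abcdef"))
        r = hierarchical_cluster(pts)
        assert r.agglomerative_coefficient > 0.95
        assert {r.labels_k2[k] for k in "abc"} != {r.labels_k2[k] for k in "def"}

    def test_synthetic_cohort_baseline_separation(self, cohort):
        profiles, records = cohort
        r = hierarchical_cluster(ScorePanel(profiles), timepoint="T0")
        seg = evaluate_segregation(
            r, {x.patient_id: x.group for x in records})
        assert seg["n_crossovers"] == 0

    def test_crossover_patient_joins_responders_at_t36(self, cohort):
        profiles, records = cohort
        r = hierarchical_cluster(ScorePanel(profiles), timepoint="T36")
        seg = evaluate_segregation(
            r, {x.patient_id: x.group for x in records})
        assert seg["crossovers"] == ["NOR2"]

    def test_gal3_concordant_with_baseline_clusters(self):
        """Baseline Gal-3 positivity and the 2-cut agree for >= 95% of
        patients across seeded replicates."""
        agree = total = 0
        for seed in range(100):
            profiles, records = generate_cohort(SyntheticCohortConfig(seed=seed))
            r = hierarchical_cluster(ScorePanel(profiles), timepoint="T0")
            gal = {x.patient_id: gal3_status(x.gal3_baseline_score)
                   for x in records}
            pos_cluster = {c for p, c in r.labels_k2.items()
                           if gal[p] == "positive"}
            for pid, c in r.labels_k2.items():
                total += 1
                agree += (gal[pid] == "positive") == (
                    len(pos_cluster) == 1 and c in pos_cluster)
        assert agree / total >= 0.95


class TestSegregationReport:
    def test_perfect_segregation(self):
        pts = pd.DataFrame([[0.0], [0.1], [9.0], [9.1]],
                           index=["p1", "p2", "p3", "p4"])
        r = hierarchical_cluster(pts)
        labels = [PhenotypeLabel("p1", "OR", "positive"),
                  PhenotypeLabel("p2", "OR", "positive"),
                  PhenotypeLabel("p3", "NOR", "negative"),
                  PhenotypeLabel("p4", "NOR", "negative")]
        seg = evaluate_segregation(r, labels)
        assert seg["n_crossovers"] == 0

    def test_missing_labels_rejected(self):
        pts = pd.DataFrame([[0.0], [9.0]], index=["p1", "p2"])
        r = hierarchical_cluster(pts)
        with pytest.raises(ValueError, match="missing"):
            evaluate_segregation(r, {"p1": "OR"})

    def test_degenerate_cut_rejected(self):
        pts = pd.DataFrame([[0.0], [9.0]], index=["p1", "p2"])
        r = hierarchical_cluster(pts)
        r.labels_k2 = {"p1": 1, "p2": 1}
        with pytest.raises(ValueError, match="degenerate"):
            evaluate_segregation(r, {"p1": "OR", "p2": "NOR"})


def test_newick_export_parses(cohort):
    from Bio import Phylo

    profiles, _ = cohort
    r = hierarchical_cluster(ScorePanel(profiles), timepoint="T36")
    tree = Phylo.read(io.StringIO(to_newick(r)), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == sorted(r.patient_ids)
    # leaf depths equal the merge heights: root-to-leaf distance is h_final
    depths = tree.depths()
    h_final = r.linkage_matrix[-1, 2]
    for leaf in tree.get_terminals():
        assert depths[leaf] == pytest.approx(h_final, rel=1e-4)
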