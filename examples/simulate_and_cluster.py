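"""Synthesize a cohort and recover the responder phenotype by clustering.

Builds an 8-patient cohort (4 responders whose remodeling-related protein
classes fall 5-50-fold under treatment, 4 non-responders rising 2-10-fold,
one of which crosses over to responder-like dynamics), clusters the
546-protein profiles at each timepoint, and reports the agglomerative
coefficient and the 2-cluster cut.
"""

from airwayprot import evaluate_segregation, hierarchical_cluster
from airwayprot.quantitation import ScorePanel
from airwayprot.synth import SyntheticCohortConfig, generate_cohort

cfg = SyntheticCohortConfig(seed=11, crossover_nor=True)
profiles, records = generate_cohort(cfg)
labels = {r.patient_id: r.group for r in records}
panel = ScorePanel(profiles)

for tp in ("T0", "T36"):
    result = hierarchical_cluster(panel, timepoint=tp)
    seg = evaluate_segregation(result, labels)
    print(f"{tp}: agglomerative coefficient = "
          f"{result.agglomerative_coefficient:.3f}, "
          f"2-cut = {result.labels_k2}, crossovers = {seg['crossovers']}")

print("\nAt baseline the groups separate cleanly (no crossovers); at T36 "
      "the designated crossover non-responder (NOR2) joins the responder "
      "cluster, mirroring responder-like treatment dynamics.  Coefficients "
      "above 0.7 indicate well-structured dendrograms.")
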