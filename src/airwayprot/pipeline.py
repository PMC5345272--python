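"""End-to-end orchestration: filter -> assemble -> quantify -> morphometry
-> phenotype/cluster, with reproducible, machine-readable outputs.

``run_pipeline`` executes the stages a configuration asks for and writes
a report bundle (differential table TSV, phenotype labels JSON, Newick
dendrograms, 2D MW/pI map TSV, summary JSON).  Every output records the
seed and a hash of the configuration, so re-running with the same config
reproduces all deterministic outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import phenotyping, psm as psm_mod, quantitation, studydata, synth

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "export_mw_pi_map"]

log = logging.getLogger("airwayprot")

SUMMARY_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""


@dataclass
class PipelineConfig:
    """Pipeline settings; defaults reproduce the bundled-panel analysis.

    ``panel_source`` selects the quantitation input: "study" (the bundled
    eight-patient panel), "synthetic" (cohort synthesis under ``seed``),
    or a path to a ScorePanel TSV.
    """

    panel_source: str = "study"
    psm_path: str | None = None       # optional PSM TSV to filter/assemble
    fasta_path: str | None = None     # optional sequences for the MW/pI map
    xcorr_thresholds: dict = field(
        default_factory=lambda: dict(psm_mod.XCORR_THRESHOLDS))
    probability_cutoff: float = psm_mod.PROBABILITY_CUTOFF
    consensus_score_min: float = psm_mod.CONSENSUS_SCORE_MIN
    dave_cutoff: float = quantitation.DAVE_SIGNIFICANCE_CUTOFF
    zero_replacement: float = 1.0
    aggregate: str = "sum"
    linkage: str = "average"
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "airwayprot_out"

    def __post_init__(self) -> None:
        for name in ("probability_cutoff", "consensus_score_min",
                     "dave_cutoff", "zero_replacement", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.xcorr_thresholds.values()):
            raise ValueError("Xcorr thresholds must be positive")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["xcorr_thresholds"] = {
            int(k): float(v) for k, v in data.get("xcorr_thresholds", {}).items()}
        return cls(**data)

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (the output directory does
        not change results and is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def export_mw_pi_map(proteins: Sequence[psm_mod.ProteinEntry],
                     path_or_buf=None):
    """2D virtual-map table (accession, MW, pI, score), one row per entry.

    Extreme values (MW < 10 kDa, pI < 4 or > 10) are emitted verbatim —
    the map never clips.
    """
    df = pd.DataFrame(
        [{"accession": e.accession, "theoretical_mw": e.theoretical_mw,
          "theoretical_pi": e.theoretical_pi, "consensus_score": e.consensus_score}
         for e in proteins],
        columns=["accession", "theoretical_mw", "theoretical_pi",
                 "consensus_score"])
    return df.to_csv(path_or_buf, sep="\t", index=False)


def _load_panel(config: PipelineConfig):
    if config.panel_source == "study":
        return studydata.load_study_panel().to_score_panel(), None
    if config.panel_source == "synthetic":
        cohort_cfg = synth.SyntheticCohortConfig(seed=config.seed)
        profiles, records = synth.generate_cohort(cohort_cfg)
        return quantitation.ScorePanel(profiles), records
    path = Path(config.panel_source)
    if not path.exists():
        raise FileNotFoundError(f"panel input not found: {path}")
    return quantitation.ScorePanel.from_tsv(path), None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages and write the report bundle to
    ``config.outdir``.  Returns the summary dict.  A stage failure raises
    :class:`PipelineError` naming the stage, and partial outputs written
    by the failed run are removed."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    header = {"schema_version": SUMMARY_SCHEMA_VERSION,
              "config_hash": config.digest(), "seed": config.seed}
    summary: dict = dict(header)
    stage = "setup"
    try:
        # -- optional PSM stage ------------------------------------------
        if config.psm_path is not None:
            stage = "psm_filter"
            path = Path(config.psm_path)
            if not path.exists():
                raise FileNotFoundError(f"PSM input not found: {path}")
            records = psm_mod.read_psm_tsv(path)
            kept = psm_mod.filter_psms(records, config.xcorr_thresholds,
                                       config.probability_cutoff)
            log.info("psm_filter: %d in, %d kept, %d dropped",
                     len(records), len(kept), len(records) - len(kept))
            fdr = psm_mod.decoy_fdr(kept)
            stage = "assemble_proteins"
            entries = psm_mod.assemble_proteins(
                kept, min_score=config.consensus_score_min,
                class_map=quantitation.DEFAULT_CLASS_MAP)
            if config.fasta_path:
                seqs = psm_mod.read_fasta_sequences(config.fasta_path)
                entries = psm_mod.annotate_mw_pi(entries, seqs)
            p = outdir / "proteins.tsv"
            psm_mod.write_protein_tsv(entries, p); written.append(p)
            p = outdir / "mw_pi_map.tsv"
            export_mw_pi_map(entries, p); written.append(p)
            summary["psm"] = {"n_input": len(records), "n_kept": len(kept),
                              "n_dropped": len(records) - len(kept),
                              "decoy_fdr_percent": fdr.percent,
                              "fdr_flag": fdr.exceeds_threshold,
                              "n_proteins": len(entries)}

        # -- quantitation -------------------------------------------------
        stage = "quantify"
        panel, cohort_records = _load_panel(config)
        table = quantitation.differential_table(
            panel, zero_replacement=config.zero_replacement,
            aggregate=config.aggregate)
        p = outdir / "differential.tsv"
        table.to_csv(p, sep="\t", index=False); written.append(p)
        summary["differential"] = {
            f"{r.label}/{r.group}": {
                "mean_t0": r.mean_t0, "mean_t36": r.mean_t36,
                "dave": quantitation.round_half_up(r.dave, 2),
                "dci": r.dci,
                "mean_ln_fc": quantitation.round_half_up(r.mean_ln_fc, 1),
                "significant_dave": bool(r.significant_dave),
                "test": r.test_name, "p_value": r.p_value}
            for r in table.itertuples(index=False)}

        # -- phenotyping --------------------------------------------------
        stage = "phenotype"
        gal = panel.data[(panel.data["class"] == "galectin3")
                         & (panel.data["timepoint"] == "T0")]
        gal_by_patient = gal.groupby("patient_id")["value"].sum()
        groups = panel.data.drop_duplicates("patient_id").set_index(
            "patient_id")["group"]
        labels = [phenotyping.PhenotypeLabel(
                      patient_id=pid, responder=groups[pid],
                      gal3_baseline=phenotyping.gal3_status(
                          float(gal_by_patient.get(pid, 0.0))))
                  for pid in sorted(groups.index)]
        p = outdir / "phenotypes.json"
        p.write_text(json.dumps(
            [l.__dict__ for l in labels], indent=2)); written.append(p)
        summary["gal3_positive_baseline"] = sorted(
            l.patient_id for l in labels if l.gal3_baseline == "positive")

        # -- clustering ---------------------------------------------------
        stage = "cluster"
        summary["clustering"] = {}
        for tp in panel.timepoints:
            result = phenotyping.hierarchical_cluster(
                panel, timepoint=tp, linkage=config.linkage)
            seg = phenotyping.evaluate_segregation(result, labels)
            p = outdir / f"dendrogram_{tp}.nwk"
            p.write_text(phenotyping.to_newick(result) + "\n"); written.append(p)
            summary["clustering"][tp] = {
                "agglomerative_coefficient": result.agglomerative_coefficient,
                "labels_k2": result.labels_k2,
                "crossovers": seg["crossovers"]}

        stage = "report"
        p = outdir / "summary.json"
        p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(p)
        log.info("pipeline complete: %d outputs in %s", len(written), outdir)
        return summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
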