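"""Bundled study panel: per-patient biopsy scores from the eight-patient
omalizumab cohort.

Five quantities were measured per patient at baseline (T0) and after 36
months of anti-IgE treatment (T36): subepithelial eosinophil density
(cells/mm^2) and label-free consensus scores for smooth-muscle proteins,
periostin, keratins, and galectin-3.  Patients OR1-OR4 responded to
omalizumab with reduced reticular-basement-membrane thickness; NOR1-NOR4
did not.  This panel is the quantitation substrate every downstream stage
(differential indices, group tests, clustering) can be exercised on
without external data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .quantitation import ScorePanel

__all__ = [
    "PATIENTS",
    "QUANTITIES",
    "StudyPanel",
    "load_study_panel",
]

PATIENTS = ("OR1", "OR2", "OR3", "OR4", "NOR1", "NOR2", "NOR3", "NOR4")

#: quantity -> class label (eosinophil density is not a protein class)
QUANTITIES = {
    "eosinophils": "eosinophils",
    "smooth_muscle": "smooth_muscle",
    "periostin": "periostin",
    "keratins": "keratin",
    "galectin3": "galectin3",
}

# Per-patient values, column order OR1-OR4 then NOR1-NOR4.
_SCORES = {
    ("eosinophils", "T0"): (19, 31, 58, 115, 0, 10, 10, 9),
    ("eosinophils", "T36"): (3, 9, 4, 5, 11, 3, 20, 27),
    ("smooth_muscle", "T0"): (288, 80, 198, 494, 0, 0, 20, 0),
    ("smooth_muscle", "T36"): (10, 20, 0, 0, 168, 0, 30, 98),
    ("periostin", "T0"): (30, 160, 130, 150, 0, 30, 120, 0),
    ("periostin", "T36"): (0, 0, 0, 0, 20, 0, 106, 20),
    ("keratins", "T0"): (1990, 1902, 1630, 2047, 1404, 1910, 1892, 1676),
    ("keratins", "T36"): (574, 276, 100, 266, 2106, 40, 1330, 1400),
    ("galectin3", "T0"): (10, 10, 30, 20, 0, 0, 0, 0),
    ("galectin3", "T36"): (0, 0, 0, 0, 0, 0, 0, 0),
}


@dataclass
class StudyPanel:
    """The study panel as a typed, long-format score table.

    ``data`` columns: patient_id, group, timepoint, quantity, class, value.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        d = self.data
        if (d["value"] < 0).any():
            raise ValueError("study panel values must be nonnegative")
        n_cells = d.groupby(["patient_id", "timepoint"]).size()
        if not (n_cells == len(QUANTITIES)).all():
            raise ValueError("panel must be rectangular: 5 quantities per patient/timepoint")
        gal_t0 = d[(d["quantity"] == "galectin3") & (d["timepoint"] == "T0")]
        or_gal = gal_t0[gal_t0["group"] == "OR"]["value"]
        if not (or_gal > 0).all():
            raise ValueError("OR patients must be galectin-3 positive at baseline")
        gal_t36 = d[(d["quantity"] == "galectin3") & (d["timepoint"] == "T36")]
        if not (gal_t36["value"] == 0).all():
            raise ValueError("galectin-3 must be absent at T36")

    def to_score_panel(self) -> ScorePanel:
        return ScorePanel(self.data.copy())

    def to_tsv(self, path_or_buf=None):
        """Serialize as TSV (the interchange format used throughout)."""
        return self.data.to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "StudyPanel":
        if isinstance(path_or_buf, str) and "\t" in path_or_buf:
            path_or_buf = io.StringIO(path_or_buf)
        return cls(pd.read_csv(path_or_buf, sep="\t"))

    def values(self, quantity: str, timepoint: str, group: str | None = None) -> pd.Series:
        """Per-patient values for one quantity/timepoint, in panel order."""
        d = self.data
        m = (d["quantity"] == quantity) & (d["timepoint"] == timepoint)
        if group is not None:
            m &= d["group"] == group
        sub = d[m].set_index("patient_id")["value"]
        order = [p for p in PATIENTS if p in sub.index]
        return sub.loc[order]


def load_study_panel() -> StudyPanel:
    """Load the bundled eight-patient panel (OR1-OR4, NOR1-NOR4; T0 and T36)."""
    rows = []
    for (quantity, timepoint), vals in _SCORES.items():
        for patient, value in zip(PATIENTS, vals):
            rows.append(
                {
                    "patient_id": patient,
                    "group": "OR" if patient.startswith("OR") else "NOR",
                    "timepoint": timepoint,
                    "quantity": quantity,
                    "class": QUANTITIES[quantity],
                    "value": float(value),
                }
            )
    return StudyPanel(pd.DataFrame(rows))
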