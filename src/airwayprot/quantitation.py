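"""Label-free differential quantitation on consensus-score panels.

Implements the spectral-count comparison indices used for two-condition
biopsy proteomics:

* **DAVE**, the differential average index ``2(B - A)/(A + B)`` on
  condition-average scores, bounded in [-2, +2]; the bounds are attained
  exactly when a protein is absent (score 0) in one condition.  |DAVE| >
  0.4 is the conventional significance call.
* **DCI**, the magnitude-weighted companion index ``(A + B)(B - A)/2``.
* **ln fold change** ``ln(T36/T0)`` with absent scores (exact zeros)
  replaced by a configurable pseudo-score before the ratio.

Group tests follow a normality gate: Shapiro-Wilk on each sample, the
t-test when both pass, otherwise an exact small-sample Wilcoxon.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScorePanel",
    "ClassMap",
    "DEFAULT_CLASS_MAP",
    "DifferentialResult",
    "class_mean_score",
    "dave",
    "dci",
    "ln_fold_change",
    "group_mean_fold_change",
    "compare_groups",
    "significant_dave",
    "differential_table",
    "round_half_up",
]

DAVE_SIGNIFICANCE_CUTOFF = 0.4


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the convention used for
    comparisons against printed index values)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class ScorePanel:
    """Long-format panel of nonnegative scores.

    Required columns: ``patient_id``, ``timepoint``, ``quantity``,
    ``value``; optional ``group`` and ``class``.  A quantity missing for a
    patient is an absent protein and scores 0.
    """

    REQUIRED = ("patient_id", "timepoint", "quantity", "value")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"ScorePanel missing columns: {missing}")
        if (data["value"] < 0).any():
            raise ValueError("scores must be nonnegative")
        self.data = data.reset_index(drop=True)

    @property
    def timepoints(self) -> list[str]:
        return sorted(self.data["timepoint"].unique())

    def patients(self, group: str | None = None) -> list[str]:
        d = self.data
        if group is not None:
            if "group" not in d.columns:
                raise ValueError("panel carries no group labels")
            d = d[d["group"] == group]
        return sorted(d["patient_id"].unique())

    def matrix(self, timepoint: str) -> pd.DataFrame:
        """Patients x quantities wide matrix at one timepoint; absent = 0."""
        d = self.data[self.data["timepoint"] == timepoint]
        m = d.pivot_table(index="patient_id", columns="quantity", values="value",
                          aggfunc="sum", fill_value=0.0)
        return m.sort_index()

    def class_sums(self, class_map: "ClassMap | None" = None) -> pd.DataFrame:
        """Per patient/timepoint scores summed over each protein class.

        Columns: patient_id, timepoint, class, value (plus group if known).
        """
        d = self.data.copy()
        if class_map is not None:
            d["class"] = [class_map.assign(q) for q in d["quantity"]]
        elif "class" not in d.columns:
            raise ValueError("no class column and no class map supplied")
        keys = ["patient_id", "timepoint", "class"]
        if "group" in d.columns:
            keys.insert(1, "group")
        return d.groupby(keys, as_index=False)["value"].sum()

    def to_tsv(self, path_or_buf=None):
        return self.data.to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "ScorePanel":
        return cls(pd.read_csv(path_or_buf, sep="\t"))


_DEFAULT_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"galectin[\s_-]?3|lgals3", "galectin3"),
    (r"periostin|postn", "periostin"),
    (r"keratin|\bkrt\d", "keratin"),
    (r"myosin|tropomyosin|actin|smooth[\s_-]?muscle|desmin|caldesmon|calponin|transgelin",
     "smooth_muscle"),
    (r"collagen|fibronectin|laminin|lumican|decorin|fibrillin|tenascin|elastin|\becm\b",
     "ecm"),
)


class ClassMap:
    """Deterministic, case-insensitive mapping from accession/description
    patterns to a protein class; anything unmatched is ``other``.

    Patterns are tried in order; the first match wins (so galectin-3
    outranks the broader ECM patterns).
    """

    CLASSES = ("smooth_muscle", "keratin", "ecm", "periostin", "galectin3", "other")

    def __init__(self, patterns: Sequence[tuple[str, str]] = _DEFAULT_PATTERNS):
        for _, cls in patterns:
            if cls not in self.CLASSES:
                raise ValueError(f"unknown class label {cls!r}")
        self._compiled = [(re.compile(p, re.IGNORECASE), c) for p, c in patterns]

    def assign(self, label: str) -> str:
        for rx, cls in self._compiled:
            if rx.search(str(label)):
                return cls
        return "other"


DEFAULT_CLASS_MAP = ClassMap()


def dave(reference: float, sample: float) -> float:
    """Differential average index 2(B - A)/(A + B).

    ``reference`` is the baseline condition (T0).  Absence in the
    reference gives +2.0, absence in the sample -2.0; both absent is 0 by
    convention (no evidence of change).
    """
    if reference < 0 or sample < 0:
        raise ValueError("scores must be nonnegative")
    total = reference + sample
    if total == 0:
        return 0.0
    return 2.0 * (sample - reference) / total


def dci(reference: float, sample: float) -> float:
    """Differential coefficient index (A + B)(B - A)/2 — a magnitude-
    weighted companion to :func:`dave` with the same sign."""
    if reference < 0 or sample < 0:
        raise ValueError("scores must be nonnegative")
    return (sample + reference) * (sample - reference) / 2.0


def significant_dave(dave_value: float) -> bool:
    """Significance call |DAVE| > 0.4 (strict)."""
    if abs(dave_value) > 2.0 + 1e-12:
        raise ValueError("DAVE values lie in [-2, 2]")
    return abs(dave_value) > DAVE_SIGNIFICANCE_CUTOFF


def ln_fold_change(t0: float, t36: float, zero_replacement: float = 1.0) -> float:
    """ln(T36/T0) with absent scores (exact 0) replaced by
    ``zero_replacement`` before the ratio; (0, 0) maps to 0."""
    if t0 < 0 or t36 < 0:
        raise ValueError("scores must be nonnegative")
    if zero_replacement <= 0:
        raise ValueError("zero_replacement must be positive")
    if t0 == 0 and t36 == 0:
        return 0.0
    num = t36 if t36 > 0 else zero_replacement
    den = t0 if t0 > 0 else zero_replacement
    return float(np.log(num / den))


def _class_patient_scores(panel: ScorePanel, class_map: ClassMap | None,
                          cls: str, group: str, timepoint: str) -> pd.Series:
    sums = panel.class_sums(class_map)
    if "group" not in sums.columns:
        raise ValueError("panel carries no group labels")
    d = sums[(sums["group"] == group) & (sums["timepoint"] == timepoint)]
    patients = sorted(d["patient_id"].unique())
    if not patients:
        raise ValueError(f"group {group!r} empty at {timepoint!r}")
    s = d[d["class"] == cls].set_index("patient_id")["value"]
    return s.reindex(patients, fill_value=0.0)


def class_mean_score(panel: ScorePanel, class_map: ClassMap | None,
                     group: str, timepoint: str, cls: str) -> float:
    """Group mean of per-patient class-summed scores."""
    return float(_class_patient_scores(panel, class_map, cls, group, timepoint).mean())


def group_mean_fold_change(panel: ScorePanel, class_map: ClassMap | None,
                           cls: str, group: str, zero_replacement: float = 1.0,
                           t0: str = "T0", t36: str = "T36") -> float:
    """Per-patient ln fold change on class-summed scores, averaged over the
    group's patients."""
    a = _class_patient_scores(panel, class_map, cls, group, t0)
    b = _class_patient_scores(panel, class_map, cls, group, t36)
    return float(np.mean([ln_fold_change(x, y, zero_replacement)
                          for x, y in zip(a.values, b.values)]))


class GroupTestResult(NamedTuple):
    test_name: str        # "t" or "wilcoxon"
    statistic: float
    p_value: float


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   paired: bool = False, alpha: float = 0.05) -> GroupTestResult:
    """Normality-gated two-sample comparison.

    Shapiro-Wilk is run on each sample (n >= 3 required for the gate); if
    both pass at ``alpha`` the t-test is used (Welch for unpaired, paired t
    otherwise), else the Wilcoxon test (exact rank-sum unpaired, exact
    signed-rank paired).  A zero-variance sample cannot be gated and falls
    to the Wilcoxon branch with a warning; elementwise-identical samples
    are degenerate and return p = 1 under either branch.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least two observations per sample")

    degenerate = len(a) == len(b) and np.array_equal(a, b)
    if degenerate:
        warnings.warn("identical samples: degenerate comparison, p = 1",
                      stacklevel=2)

    normal = True
    for sample in (a, b):
        if len(sample) < 3 or np.ptp(sample) == 0:
            if np.ptp(sample) == 0 and not degenerate:
                warnings.warn("zero-variance sample: normality gate skipped, "
                              "using Wilcoxon", stacklevel=2)
            normal = False
            break
        if stats.shapiro(sample).pvalue <= alpha:
            normal = False
            break

    if degenerate:
        return GroupTestResult("t" if normal else "wilcoxon", 0.0, 1.0)

    if normal:
        if paired:
            res = stats.ttest_rel(a, b)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
        return GroupTestResult("t", float(res.statistic), float(res.pvalue))

    if paired:
        diffs = a - b
        if np.all(diffs == 0):
            return GroupTestResult("wilcoxon", 0.0, 1.0)
        method = "exact" if not np.any(diffs == 0) else "auto"
        res = stats.wilcoxon(a, b, method=method)
    else:
        method = "exact" if len(np.unique(np.concatenate([a, b]))) == len(a) + len(b) \
            else "auto"
        res = stats.mannwhitneyu(a, b, method=method, alternative="two-sided")
    return GroupTestResult("wilcoxon", float(res.statistic), float(res.pvalue))


@dataclass
class DifferentialResult:
    """One class x group row of the differential table."""

    label: str
    group: str
    mean_t0: float
    mean_t36: float
    dave: float
    dci: float
    mean_ln_fc: float
    significant_dave: bool
    test_name: str
    p_value: float

    def __post_init__(self) -> None:
        if abs(self.dave) > 2.0 + 1e-12:
            raise ValueError("DAVE out of [-2, 2]")
        if self.significant_dave != (abs(self.dave) > DAVE_SIGNIFICANCE_CUTOFF):
            raise ValueError("significance flag inconsistent with DAVE value")


def differential_table(panel: ScorePanel, class_map: ClassMap | None = None,
                       zero_replacement: float = 1.0,
                       aggregate: str = "sum",
                       paired_within_group: bool = True,
                       t0: str = "T0", t36: str = "T36") -> pd.DataFrame:
    """Full differential summary: one row per class x group.

    Per-patient class scores are sums over member proteins (``aggregate``
    may be "mean" instead); DAVE/DCI are computed on the T0 and T36 group
    means with T0 as reference; the within-group T0-vs-T36 comparison uses
    the normality-gated test.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")
    sums = panel.class_sums(class_map)
    if aggregate == "mean":
        d = panel.data.copy()
        if class_map is not None:
            d["class"] = [class_map.assign(q) for q in d["quantity"]]
        keys = ["patient_id", "timepoint", "class"]
        if "group" in d.columns:
            keys.insert(1, "group")
        sums = d.groupby(keys, as_index=False)["value"].mean()
    rows = []
    for (cls, group), _ in sums.groupby(["class", "group"]):
        sub = sums[sums["group"] == group]
        patients = sorted(sub["patient_id"].unique())
        def _vals(tp):
            s = sub[(sub["class"] == cls) & (sub["timepoint"] == tp)]
            return s.set_index("patient_id")["value"].reindex(patients, fill_value=0.0)
        va, vb = _vals(t0), _vals(t36)
        mean_a, mean_b = float(va.mean()), float(vb.mean())
        d_val = dave(mean_a, mean_b)
        fcs = [ln_fold_change(x, y, zero_replacement) for x, y in zip(va, vb)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                test = compare_groups(va.values, vb.values, paired=paired_within_group)
            except ValueError:
                test = GroupTestResult("t", float("nan"), float("nan"))
        rows.append(DifferentialResult(
            label=cls, group=group, mean_t0=mean_a, mean_t36=mean_b,
            dave=d_val, dci=dci(mean_a, mean_b), mean_ln_fc=float(np.mean(fcs)),
            significant_dave=significant_dave(d_val),
            test_name=test.test_name, p_value=test.p_value,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
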