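"""Synthetic cohorts, PSM tables, membrane sections, and cell fields.

These generators emulate the statistical structure the analysis assumes —
two patient groups (responders with baseline galectin-3 positivity whose
remodeling-related protein classes fall 5- to 50-fold under treatment,
non-responders whose classes rise 2- to 10-fold), ~546-protein score
profiles, membrane sections of known true thickness under a declared
obliquity model, and Poisson cell fields read by two noisy operators — so
every downstream stage is testable without external data.  All generators
are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate

from .morphometry import CellCountObservation, InterceptSet
from .psm import XCORR_THRESHOLDS, DECOY_PREFIX, PsmRecord

__all__ = [
    "PatientRecord",
    "SyntheticCohortConfig",
    "generate_cohort",
    "generate_psm_table",
    "generate_membrane_section",
    "generate_cell_field",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: protein classes that follow the group-level treatment dynamics
DYNAMIC_CLASSES = ("smooth_muscle", "keratin", "ecm", "periostin")

# proteins per class and per-protein baseline class means (score units),
# chosen to mirror the magnitudes of the study panel: responders carry
# high smooth-muscle/ECM/periostin/galectin-3 baselines, non-responders do
# not; keratins and the unclassified bulk are similar in both groups.
_CLASS_SIZES = {"smooth_muscle": 12, "keratin": 10, "ecm": 100,
                "periostin": 1, "galectin3": 1}
_BASELINE_MEAN = {
    "smooth_muscle": {"OR": 22.0, "NOR": 2.0},
    "keratin": {"OR": 190.0, "NOR": 180.0},
    "ecm": {"OR": 100.0, "NOR": 8.0},
    "periostin": {"OR": 120.0, "NOR": 30.0},
    "galectin3": {"OR": 18.0, "NOR": 0.0},
    "other": {"OR": 30.0, "NOR": 30.0},
}


@dataclass(frozen=True)
class PatientRecord:
    """Cohort membership and baseline galectin-3 status for one patient."""

    patient_id: str
    group: str                       # "OR" or "NOR"
    gal3_baseline_score: float
    timepoints: frozenset = frozenset({"T0", "T36"})

    def __post_init__(self) -> None:
        if self.group not in ("OR", "NOR"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.gal3_baseline_score < 0:
            raise ValueError("galectin-3 score must be nonnegative")


@dataclass
class SyntheticCohortConfig:
    """Study conditions for cohort synthesis.

    Defaults mirror the cohort the pipeline targets: 4 responders + 4
    non-responders, 546 distinct proteins, responder class-level decreases
    of 5-50-fold at T36, non-responder increases of 2-10-fold, and
    multiplicative log-normal score noise.
    """

    n_or: int = 4
    n_nor: int = 4
    n_proteins: int = 546
    or_decrease_fold_range: tuple[float, float] = (5.0, 50.0)
    nor_increase_fold_range: tuple[float, float] = (2.0, 10.0)
    crossover_nor: bool = False
    score_noise_cv: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_or < 1 or self.n_nor < 1:
            raise ValueError("each group needs at least one patient")
        n_classed = sum(_CLASS_SIZES.values())
        if self.n_proteins < n_classed:
            raise ValueError(f"need at least {n_classed} proteins")
        for rng_ in (self.or_decrease_fold_range, self.nor_increase_fold_range):
            lo, hi = rng_
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid fold range {rng_}")
        if self.score_noise_cv < 0:
            raise ValueError("noise CV must be nonnegative")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def generate_cohort(config: SyntheticCohortConfig
                    ) -> tuple[pd.DataFrame, list[PatientRecord]]:
    """Synthesize per-patient protein score profiles at T0 and T36.

    Returns a long-format DataFrame (patient_id, group, timepoint,
    quantity, class, value) and the patient records.  Responders carry
    positive galectin-3 at T0 and exact zeros at T36; class-level
    treatment dynamics are drawn per patient and class from the configured
    fold ranges (galectin-3 follows absence semantics instead of a fold,
    and unclassified proteins are stable).  With ``crossover_nor`` one
    non-responder (the second, when present) follows responder dynamics at
    T36 while remaining galectin-3-negative.
    """
    rng = np.random.default_rng(config.seed)
    classes = []
    for cls, n in _CLASS_SIZES.items():
        classes += [cls] * n
    classes += ["other"] * (config.n_proteins - len(classes))
    accessions = [f"P{i:04d}_{cls}" for i, cls in enumerate(classes)]

    # per-protein abundance heterogeneity, shared across patients
    protein_factor = _lognormal_factor(rng, 0.5, config.n_proteins)

    patients = [(f"OR{i + 1}", "OR") for i in range(config.n_or)]
    patients += [(f"NOR{i + 1}", "NOR") for i in range(config.n_nor)]
    crossover_id = None
    if config.crossover_nor:
        idx = min(1, config.n_nor - 1)  # the second non-responder, as available
        crossover_id = f"NOR{idx + 1}"

    def _draw_fold(fold_range: tuple[float, float]) -> float:
        lo, hi = fold_range
        return math.exp(rng.uniform(math.log(lo), math.log(hi)))

    # treatment dynamics are class-level group phenomena: one fold factor
    # per class per dynamics regime, shared by the patients following it
    fold_of = {("OR", cls): _draw_fold(config.or_decrease_fold_range)
               for cls in DYNAMIC_CLASSES}
    fold_of.update({("NOR", cls): _draw_fold(config.nor_increase_fold_range)
                    for cls in DYNAMIC_CLASSES})

    rows = []
    records = []
    for pid, group in patients:
        base = np.array([_BASELINE_MEAN[c][group] for c in classes])
        t0 = base * protein_factor * _lognormal_factor(
            rng, config.score_noise_cv, config.n_proteins)
        t0[base == 0] = 0.0

        dynamics_as = "OR" if (group == "OR" or pid == crossover_id) else "NOR"
        t36 = t0.copy()
        for cls in DYNAMIC_CLASSES:
            m = np.array([c == cls for c in classes])
            fold = fold_of[(dynamics_as, cls)]
            t36[m] = t0[m] / fold if dynamics_as == "OR" else t0[m] * fold
        t36 *= _lognormal_factor(rng, config.score_noise_cv, config.n_proteins)
        gal_mask = np.array([c == "galectin3" for c in classes])
        t36[gal_mask] = 0.0  # absent after treatment in every profile
        t36[t0 == 0] = 0.0

        gal3_t0 = float(t0[gal_mask].sum())
        records.append(PatientRecord(pid, group, gal3_t0))
        for tp, vals in (("T0", t0), ("T36", t36)):
            for acc, cls, v in zip(accessions, classes, vals):
                rows.append({"patient_id": pid, "group": group, "timepoint": tp,
                             "quantity": acc, "class": cls, "value": float(v)})
    return pd.DataFrame(rows), records


def generate_psm_table(n_target: int, n_decoy: int, frac_pass: float = 0.5,
                       seed: int | None = None, decoy_frac_pass: float = 0.0,
                       n_proteins: int = 50) -> list[PsmRecord]:
    """Synthesize a PSM table with a controlled pass rate.

    Each record draws a charge uniformly from {1, 2, 3} and passes the
    charge-dependent Xcorr + probability filters with probability
    ``frac_pass`` (``decoy_frac_pass`` for decoys, 0 by default so decoys
    sit strictly below the thresholds).  Passing records get Xcorr above
    the threshold (exponential tail) and probability <= 0.001; failing
    records miss on Xcorr or on probability with equal chance.
    """
    if n_target < 0 or n_decoy < 0:
        raise ValueError("counts must be nonnegative")
    for f in (frac_pass, decoy_frac_pass):
        if not 0.0 <= f <= 1.0:
            raise ValueError("pass fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for is_decoy, n, fp in ((False, n_target, frac_pass),
                            (True, n_decoy, decoy_frac_pass)):
        for i in range(n):
            charge = int(rng.integers(1, 4))
            thr = XCORR_THRESHOLDS[charge]
            peptide = "".join(rng.choice(_AA, size=int(rng.integers(8, 16))))
            if rng.random() < fp:
                xcorr = thr + 1e-6 + rng.exponential(0.8)
                prob = float(rng.uniform(1e-6, 1e-3))
            elif rng.random() < 0.5:  # fail on Xcorr
                xcorr = float(rng.uniform(0.1, thr))
                prob = float(rng.uniform(1e-6, 1e-3))
            else:                     # fail on probability
                xcorr = thr + 1e-6 + rng.exponential(0.8)
                prob = float(rng.uniform(2e-3, 0.5))
            prefix = DECOY_PREFIX if is_decoy else ""
            acc = f"{prefix}PROT{int(rng.integers(n_proteins)):04d}"
            records.append(PsmRecord(peptide=peptide, charge=charge,
                                     xcorr=float(xcorr),
                                     peptide_probability=prob,
                                     protein_accession=acc,
                                     is_decoy=is_decoy))
    return records


MAX_OBLIQUITY_SD = 0.6  # rad; beyond this the normalized model could emit
                        # intercepts shorter than the true thickness


@lru_cache(maxsize=64)
def _mean_secant(obliquity_sd: float, trunc: float = 1.4) -> float:
    """E[sec(theta)] for theta ~ half-normal(sd) truncated at ``trunc``."""
    if obliquity_sd == 0:
        return 1.0
    def density(t):
        return math.exp(-0.5 * (t / obliquity_sd) ** 2)
    num, _ = integrate.quad(lambda t: density(t) / math.cos(t), 0, trunc)
    den, _ = integrate.quad(density, 0, trunc)
    return num / den


def generate_membrane_section(true_thickness: float, n_intercepts: int = 40,
                              obliquity_sd: float = 0.35,
                              seed: int | None = None,
                              section_id: str = "") -> InterceptSet:
    """Synthesize an orthogonal-intercept set of known true thickness.

    Model: intercept_i = t * (4/pi) * sec(theta_i) / E[sec(theta)], with
    theta_i a truncated half-normal obliquity angle of scale
    ``obliquity_sd``.  The expected intercept is (4/pi)*t for every sd, so
    the pi/4-corrected thickness estimator is exactly unbiased under the
    model; with sd = 0 every intercept equals t*4/pi.  ``obliquity_sd`` is
    capped at 0.6 rad so intercepts never undershoot the true thickness.
    """
    if true_thickness <= 0:
        raise ValueError("true thickness must be positive")
    if n_intercepts < 1:
        raise ValueError("need at least one intercept")
    if not 0.0 <= obliquity_sd <= MAX_OBLIQUITY_SD:
        raise ValueError(f"obliquity_sd must lie in [0, {MAX_OBLIQUITY_SD}]")
    rng = np.random.default_rng(seed)
    trunc = 1.4
    if obliquity_sd == 0:
        factors = np.ones(n_intercepts)
    else:
        theta = np.abs(rng.normal(0.0, obliquity_sd, size=2 * n_intercepts))
        theta = theta[theta < trunc][:n_intercepts]
        while len(theta) < n_intercepts:  # top up after truncation
            extra = np.abs(rng.normal(0.0, obliquity_sd, size=n_intercepts))
            theta = np.concatenate([theta, extra[extra < trunc]])[:n_intercepts]
        factors = (1.0 / np.cos(theta)) / _mean_secant(obliquity_sd)
    lengths = true_thickness * (4.0 / math.pi) * factors
    sid = section_id or f"synthetic-t{true_thickness:g}"
    return InterceptSet(lengths, section_id=sid)


def generate_cell_field(true_density: float, band_area: float,
                        n_samples: int = 2, operator_cv: float = 0.05,
                        seed: int | None = None,
                        cell_type: str = "eosinophil"
                        ) -> list[CellCountObservation]:
    """Synthesize blinded two-operator counts over a subepithelial band.

    True counts are Poisson with mean density*area; each operator's
    reading multiplies the true count by log-normal noise of the given CV
    (rounded back to an integer).  ``operator_cv=0`` gives two identical
    readings.
    """
    if true_density < 0:
        raise ValueError("density must be nonnegative")
    if band_area <= 0:
        raise ValueError("band area must be positive")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    obs = []
    for i in range(n_samples):
        count = int(rng.poisson(true_density * band_area))
        readings = tuple(
            int(round(count * f))
            for f in _lognormal_factor(rng, operator_cv, 2))
        obs.append(CellCountObservation(cell_type=cell_type,
                                        counts_by_operator=readings,
                                        band_area=band_area,
                                        sample_id=f"sample{i + 1}"))
    return obs
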