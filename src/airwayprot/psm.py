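"""Post-search filtering of peptide-spectrum matches (PSMs) and assembly
of consensus-scored protein lists.

The filters mirror the conventional charge-dependent Xcorr acceptance for
database-search output: Xcorr strictly greater than 1.5 / 2.0 / 2.5 for
1+ / 2+ / >=3+ precursors, peptide probability <= 0.001 (lower is
better), and a protein consensus score >= 10.  The false-positive rate is
estimated from reverse-database (decoy) hits as decoys/targets.

Theoretical MW uses average residue masses; the isoelectric point is the
pH at which the peptide's net charge crosses zero, found by bisection
against a fixed Henderson-Hasselbalch charge model (Lehninger pKa set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from pyteomics import mass as _pt_mass

__all__ = [
    "PsmRecord",
    "ProteinEntry",
    "FdrResult",
    "XCORR_THRESHOLDS",
    "filter_psms",
    "assemble_proteins",
    "decoy_fdr",
    "theoretical_mw_pi",
    "net_charge",
    "read_psm_tsv",
    "write_psm_tsv",
    "write_protein_tsv",
    "read_fasta_sequences",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: charge state -> strict Xcorr lower bound; charges above 3 use the 3+ value
XCORR_THRESHOLDS: Mapping[int, float] = {1: 1.5, 2: 2.0, 3: 2.5}
PROBABILITY_CUTOFF = 0.001
CONSENSUS_SCORE_MIN = 10.0
FDR_FLAG_PERCENT = 3.0
DECOY_PREFIX = "DECOY_"

# Lehninger pKa set: side chains plus free termini. Basic groups carry +1
# when protonated; acidic groups -1 when deprotonated.
PKA_BASIC: Mapping[str, float] = {"K": 10.53, "R": 12.48, "H": 6.00}
PKA_ACIDIC: Mapping[str, float] = {"D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07}
PKA_NTERM = 9.69
PKA_CTERM = 2.34


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match from a database search."""

    peptide: str
    charge: int
    xcorr: float
    peptide_probability: float
    protein_accession: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.peptide or set(self.peptide) - AMINO_ACIDS:
            raise ValueError(f"invalid peptide sequence {self.peptide!r}")
        if self.charge < 1:
            raise ValueError(f"malformed charge state {self.charge}")
        if self.xcorr < 0:
            raise ValueError("Xcorr must be nonnegative")
        if not 0.0 <= self.peptide_probability <= 1.0:
            raise ValueError("peptide probability must lie in [0, 1]")


@dataclass
class ProteinEntry:
    """Filtered, consensus-scored protein list entry."""

    accession: str
    description: str = ""
    consensus_score: float = 0.0
    theoretical_mw: float | None = None   # Da
    theoretical_pi: float | None = None   # pH units
    class_label: str | None = None
    n_psms: int = 0

    def __post_init__(self) -> None:
        if self.consensus_score < 0:
            raise ValueError("consensus score must be nonnegative")
        if self.theoretical_mw is not None and self.theoretical_mw <= 0:
            raise ValueError("theoretical MW must be positive")
        if self.theoretical_pi is not None and not 0 < self.theoretical_pi < 14:
            raise ValueError("theoretical pI must lie in (0, 14)")


def _xcorr_threshold(charge: int,
                     thresholds: Mapping[int, float] = XCORR_THRESHOLDS) -> float:
    return thresholds.get(charge, thresholds[max(thresholds)])


def filter_psms(records: Iterable[PsmRecord],
                thresholds: Mapping[int, float] = XCORR_THRESHOLDS,
                probability_cutoff: float = PROBABILITY_CUTOFF) -> list[PsmRecord]:
    """Keep PSMs with Xcorr strictly above the charge-dependent threshold
    and peptide probability <= the cutoff.  Order-stable and idempotent."""
    kept = []
    for rec in records:
        if rec.charge < 1:
            raise ValueError(f"malformed charge state {rec.charge}")
        if rec.xcorr > _xcorr_threshold(rec.charge, thresholds) \
                and rec.peptide_probability <= probability_cutoff:
            kept.append(rec)
    return kept


def assemble_proteins(kept: Sequence[PsmRecord],
                      score_rule: Callable[[Sequence[PsmRecord]], float] | None = None,
                      min_score: float = CONSENSUS_SCORE_MIN,
                      decoy_prefix: str = DECOY_PREFIX,
                      descriptions: Mapping[str, str] | None = None,
                      class_map=None) -> list[ProteinEntry]:
    """Roll filtered PSMs up to a consensus-scored protein list.

    The default consensus score is the sum of member-PSM Xcorr values
    (``score_rule`` may replace it); entries below ``min_score`` are
    dropped and decoy accessions are excluded from the reported list
    (they are consumed separately by :func:`decoy_fdr`).
    """
    if score_rule is None:
        score_rule = lambda psms: sum(p.xcorr for p in psms)
    by_acc: dict[str, list[PsmRecord]] = {}
    for rec in kept:
        by_acc.setdefault(rec.protein_accession, []).append(rec)
    entries = []
    for acc in sorted(by_acc):
        psms = by_acc[acc]
        if any(p.is_decoy for p in psms) or acc.startswith(decoy_prefix):
            continue
        score = float(score_rule(psms))
        if score < min_score:
            continue
        desc = descriptions.get(acc, "") if descriptions else ""
        label = class_map.assign(desc or acc) if class_map is not None else None
        entries.append(ProteinEntry(accession=acc, description=desc,
                                    consensus_score=score, class_label=label,
                                    n_psms=len(psms)))
    return entries


class FdrResult(NamedTuple):
    percent: float
    exceeds_threshold: bool


def decoy_fdr(kept: Sequence[PsmRecord],
              flag_percent: float = FDR_FLAG_PERCENT) -> FdrResult:
    """Reverse-database false-positive estimate: decoys/targets as a
    percentage, flagged when it reaches ``flag_percent``."""
    decoys = sum(1 for r in kept if r.is_decoy)
    targets = len(kept) - decoys
    if targets == 0:
        if decoys:
            warnings.warn("no target PSMs survive filtering; FDR undefined, "
                          "reported as 0", stacklevel=2)
        return FdrResult(0.0, False)
    pct = 100.0 * decoys / targets
    return FdrResult(pct, pct >= flag_percent)


def net_charge(sequence: str, ph: float) -> float:
    """Net charge of a peptide at a given pH under the Henderson-
    Hasselbalch model with the module's pKa set."""
    q = 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM))
    q -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - ph))
    for aa in sequence:
        if aa in PKA_BASIC:
            q += 1.0 / (1.0 + 10.0 ** (ph - PKA_BASIC[aa]))
        elif aa in PKA_ACIDIC:
            q -= 1.0 / (1.0 + 10.0 ** (PKA_ACIDIC[aa] - ph))
    return q


def theoretical_mw_pi(sequence: str, tol: float = 1e-4) -> tuple[float, float]:
    """Theoretical average molecular weight (Da) and isoelectric point.

    MW is the sum of average residue masses plus one water; pI is found by
    bisection on [0, 14] to ``tol`` pH units.  Unknown residues raise with
    the offending position.
    """
    if not sequence:
        raise ValueError("empty sequence")
    for i, aa in enumerate(sequence):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
    mw = float(_pt_mass.calculate_mass(sequence=sequence, average=True))
    lo, hi = 0.0, 14.0
    if net_charge(sequence, lo) < 0 or net_charge(sequence, hi) > 0:
        raise ValueError("net charge does not cross zero in [0, 14]")
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return mw, (lo + hi) / 2.0


# -- tabular / FASTA interchange ------------------------------------------

PSM_COLUMNS = ["peptide", "charge", "xcorr", "peptide_probability",
               "protein_accession", "is_decoy"]


def write_psm_tsv(records: Sequence[PsmRecord], path_or_buf=None):
    df = pd.DataFrame([r.__dict__ for r in records], columns=PSM_COLUMNS)
    return df.to_csv(path_or_buf, sep="\t", index=False)


def read_psm_tsv(path_or_buf) -> list[PsmRecord]:
    df = pd.read_csv(path_or_buf, sep="\t")
    return [PsmRecord(peptide=str(r.peptide), charge=int(r.charge),
                      xcorr=float(r.xcorr),
                      peptide_probability=float(r.peptide_probability),
                      protein_accession=str(r.protein_accession),
                      is_decoy=bool(r.is_decoy))
            for r in df.itertuples(index=False)]


def write_protein_tsv(entries: Sequence[ProteinEntry], path_or_buf=None):
    cols = ["accession", "description", "consensus_score", "theoretical_mw",
            "theoretical_pi", "class_label", "n_psms"]
    df = pd.DataFrame([e.__dict__ for e in entries], columns=cols)
    return df.to_csv(path_or_buf, sep="\t", index=False)


def read_fasta_sequences(path) -> dict[str, str]:
    """Accession -> sequence from a FASTA file (for MW/pI annotation)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def annotate_mw_pi(entries: Sequence[ProteinEntry],
                   sequences: Mapping[str, str]) -> list[ProteinEntry]:
    """Fill theoretical MW/pI for entries whose sequence is known."""
    out = []
    for e in entries:
        seq = sequences.get(e.accession)
        if seq:
            mw, pi = theoretical_mw_pi(seq)
            e = ProteinEntry(**{**e.__dict__, "theoretical_mw": mw,
                                "theoretical_pi": pi})
        out.append(e)
    return out
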