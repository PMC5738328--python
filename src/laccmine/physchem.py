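"""Physicochemical characterization of candidate laccases.

GC content of the coding sequence, average molecular weight, theoretical
isoelectric point (Bjellqvist pKa set, bisection), N-glycosylation sequon
scanning, and a rule-based signal-peptide/cleavage-site heuristic.

The pI model treats each ionizable group independently
(Henderson-Hasselbalch): positive groups (N-terminus, H, K, R) contribute
``1/(1+10^(pH-pKa))`` and negative groups (C-terminus, D, E, C, Y)
contribute ``-1/(1+10^(pKa-pH))``. Net charge is strictly decreasing in
pH, so the isoelectric point is the unique zero on [2, 13].
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import NumericalError, ValidationError

# Average (not monoisotopic) residue masses in Da, plus one water per chain.
WATER_DA = 18.0153
RESIDUE_MASS_DA = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

# Bjellqvist pKa constants, matching the ExPASy ProtParam service.
# All live here so an alternative set can be swapped in via `pka_set`.
PKA_CTERM = 3.55
PKA_NTERM_DEFAULT = 7.50
PKA_NTERM_BY_RESIDUE = {
    "A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.70,
}
PKA_POSITIVE_SIDECHAIN = {"H": 5.98, "K": 10.00, "R": 12.00}
PKA_NEGATIVE_SIDECHAIN = {"D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00}

# Kyte-Doolittle hydropathy, used by the signal-peptide heuristic.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -0.2, "V": 4.2,
}

_SEQUON_RE = re.compile(r"(?=(N[^P\*](?:S|T)))")


@dataclass(frozen=True)
class GlycoSite:
    """An N-glycosylation sequon: N-X-[S/T] with X != P, 1-based Asn position."""

    position: int
    sequon: str


@dataclass(frozen=True)
class SignalPrediction:
    """Outcome of the rule-based secretion heuristic (see predict_signal_peptide)."""

    cleavage_after: Optional[int]
    score: float
    n_region_charge: float
    h_region_hydropathy: float

    @property
    def secreted(self) -> bool:
        return self.cleavage_after is not None


def _check_standard(aa_seq: str) -> None:
    for i, a in enumerate(aa_seq):
        if a not in RESIDUE_MASS_DA:
            raise ValidationError(f"nonstandard residue {a!r} at position {i + 1}")


def gc_content(nt: str) -> float:
    """GC percentage of a nucleotide sequence; N excluded from the denominator."""
    if not nt:
        raise ValidationError("empty sequence")
    counts = {b: nt.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise NumericalError("GC content undefined: no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def molecular_weight(aa_seq: str, kda: bool = True) -> float:
    """Average-mass molecular weight (one water added for the termini)."""
    if not aa_seq:
        raise ValidationError("empty peptide")
    _check_standard(aa_seq)
    da = sum(RESIDUE_MASS_DA[a] for a in aa_seq) + WATER_DA
    return da / 1000.0 if kda else da


def _ionizable_groups(aa_seq: str, pka_set=None) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """(positive, negative) lists of (count, pKa) for a peptide."""
    nterm = PKA_NTERM_BY_RESIDUE.get(aa_seq[0], PKA_NTERM_DEFAULT)
    pos = [(1.0, nterm)]
    neg = [(1.0, PKA_CTERM)]
    for res, pka in PKA_POSITIVE_SIDECHAIN.items():
        c = aa_seq.count(res)
        if c:
            pos.append((float(c), pka))
    for res, pka in PKA_NEGATIVE_SIDECHAIN.items():
        c = aa_seq.count(res)
        if c:
            neg.append((float(c), pka))
    return pos, neg


def net_charge(aa_seq: str, pH: float) -> float:
    """Modeled net charge at a given pH (Henderson-Hasselbalch sum)."""
    if not aa_seq:
        raise ValidationError("empty peptide")
    if not 0.0 < pH < 14.0:
        raise ValidationError(f"pH {pH} outside (0, 14)")
    _check_standard(aa_seq)
    pos, neg = _ionizable_groups(aa_seq)
    q = sum(c / (1.0 + 10.0 ** (pH - pka)) for c, pka in pos)
    q -= sum(c / (1.0 + 10.0 ** (pka - pH)) for c, pka in neg)
    return q


def isoelectric_point(aa_seq: str, tol: float = 1e-4) -> float:
    """The pH where net charge crosses zero, by bisection on [2, 13]."""
    lo, hi = 2.0, 13.0
    qlo, qhi = net_charge(aa_seq, lo), net_charge(aa_seq, hi)
    if qlo < 0 or qhi > 0:
        raise NumericalError(
            f"net charge does not cross zero on [2, 13] (q(2)={qlo:.3f}, q(13)={qhi:.3f})"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(aa_seq, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_sequons(aa_seq: str) -> list[GlycoSite]:
    """Every N-X-[S/T] sequon (X != P), ascending 1-based Asn positions."""
    return [
        GlycoSite(position=m.start() + 1, sequon=m.group(1))
        for m in _SEQUON_RE.finditer(aa_seq)
    ]


def _simple_charge(aa_seq: str) -> float:
    return sum(1.0 for a in aa_seq if a in "KR") - sum(1.0 for a in aa_seq if a in "DE")


def predict_signal_peptide(
    aa_seq: str,
    min_cleavage: int = 10,
    max_cleavage: int = 35,
    min_h_hydropathy: float = 1.6,
    score_threshold: float = 3.0,
) -> SignalPrediction:
    """Rule-based secretion heuristic in place of a trained predictor.

    A candidate cleavage position ``c`` (cleavage between residues c and
    c+1, 1-based) must satisfy three classical signal-peptide rules:

    1. small residues at c and c-2 (von Heijne -1/-3 rule: A, G, S, C, T);
    2. an h-region: some window of >= 7 residues within [1, c-3] with mean
       Kyte-Doolittle hydropathy >= ``min_h_hydropathy``;
    3. an n-region: net charge (K/R minus D/E) of residues [1, h-start] >= 0.

    Candidates are scored additively: h-region mean hydropathy + 2 for the
    -1/-3 rule + 1 for the n-region charge; the best-scoring candidate is
    reported if its score reaches ``score_threshold``. Absence of any valid
    candidate is a valid outcome (a non-secreted protein).
    """
    if len(aa_seq) < 40:
        raise ValidationError("signal-peptide heuristic requires >= 40 residues")
    small = set("AGSCT")
    kd = [KYTE_DOOLITTLE.get(a, 0.0) for a in aa_seq]
    best: Optional[SignalPrediction] = None
    for c in range(min_cleavage, min(max_cleavage, len(aa_seq) - 1) + 1):
        if aa_seq[c - 1] not in small or aa_seq[c - 3] not in small:
            continue
        h = _best_hydrophobic_window(kd, c - 3)
        if h is None:
            continue
        h_start, h_mean = h
        if h_mean < min_h_hydropathy:
            continue
        n_charge = _simple_charge(aa_seq[:h_start])
        if n_charge < 0:
            continue
        score = h_mean + 2.0 + 1.0
        cand = SignalPrediction(
            cleavage_after=c, score=score, n_region_charge=n_charge, h_region_hydropathy=h_mean
        )
        if best is None or cand.score > best.score:
            best = cand
    if best is None or best.score < score_threshold:
        return SignalPrediction(
            cleavage_after=None, score=0.0, n_region_charge=0.0, h_region_hydropathy=0.0
        )
    return best


def _best_hydrophobic_window(kd: Sequence[float], upto: int, width: int = 7):
    """(1-based start, mean) of the best hydropathy window of ``width`` in kd[:upto]."""
    if upto < width:
        return None
    best_start, best_mean = None, -1e9
    for s in range(0, upto - width + 1):
        m = sum(kd[s : s + width]) / width
        if m > best_mean:
            best_start, best_mean = s + 1, m
    return best_start, best_mean
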