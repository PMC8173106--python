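"""Chemical-shift perturbation (CSP), CHESPA projection, and homologue comparison.

CSPs combine amide 1H and 15N shift changes between two conditions into a
single weighted magnitude; residues above a data-derived threshold (mean
plus half a standard deviation) are flagged as perturbed.  CHESPA compares
the *direction* of a perturbation (e.g., induced by a point mutation) with
a reference perturbation (e.g., induced by coenzyme binding) via the cosine
of the angle between the two vectors in weighted shift space, plus the
fractional projected magnitude.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio import Align

__all__ = [
    "ShiftTable",
    "CSPRecord",
    "ChespaRecord",
    "N15_CSP_WEIGHT",
    "combined_csp",
    "csp_threshold",
    "select_perturbed",
    "chespa",
    "count_substitutions",
]

logger = logging.getLogger(__name__)

#: 15N scaling applied when combining amide 1H/15N shift changes.  The
#: conventional 1/5 factor compensates the larger 15N shift range.
N15_CSP_WEIGHT = 0.2


@dataclass(frozen=True)
class ShiftTable:
    """Per-residue amide chemical shifts for one construct/condition.

    ``shifts`` maps residue number -> (1H ppm, 15N ppm).  Residues present
    in ``unobserved`` are listed (so reports can grey them out) but carry
    no shifts and are excluded from all statistics.
    """

    shifts: dict[int, tuple[float, float]]
    unobserved: frozenset[int] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.shifts) & set(self.unobserved)
        if overlap:
            raise ValueError(f"residues both observed and unobserved: {sorted(overlap)}")
        object.__setattr__(self, "unobserved", frozenset(self.unobserved))

    @property
    def residues(self) -> list[int]:
        return sorted(self.shifts)

    def __contains__(self, residue: int) -> bool:
        return residue in self.shifts


@dataclass(frozen=True)
class CSPRecord:
    """One residue's shift perturbation between two conditions."""

    residue_id: int
    delta_h: float
    delta_n: float
    combined: float


@dataclass(frozen=True)
class ChespaRecord:
    """Projection of one perturbation vector onto a reference vector."""

    residue_id: int
    cos_theta: float
    fraction_x: float
    magnitude_a: float
    magnitude_b: float


def combined_csp(
    table_a: ShiftTable,
    table_b: ShiftTable,
    weight: float = N15_CSP_WEIGHT,
) -> tuple[list[CSPRecord], list[int]]:
    """Combined CSP per residue observed in both tables.

    ``combined = sqrt(delta_H^2 + (w * delta_N)^2)``.  Returns the records
    (sorted by residue) and the residues missing from either table.
    """
    common = sorted(set(table_a.shifts) & set(table_b.shifts))
    if not common:
        raise ValueError("shift tables share no observed residues")
    missing = sorted(
        (set(table_a.shifts) | set(table_b.shifts)
         | set(table_a.unobserved) | set(table_b.unobserved))
        - set(common)
    )
    records = []
    for rid in common:
        ha, na = table_a.shifts[rid]
        hb, nb = table_b.shifts[rid]
        dh, dn = hb - ha, nb - na
        records.append(
            CSPRecord(rid, dh, dn, math.hypot(dh, weight * dn))
        )
    if missing:
        logger.info("%d residue(s) missing from one table: %s", len(missing), missing)
    return records, missing


def csp_threshold(csps: list[float] | np.ndarray) -> float:
    """Significance threshold: mean plus half a (sample) standard deviation."""
    vals = np.asarray(csps, dtype=float)
    if vals.size < 2:
        raise ValueError("at least 2 combined CSP values required")
    return float(vals.mean() + 0.5 * vals.std(ddof=1))


def select_perturbed(
    csps: list[CSPRecord], threshold: float
) -> list[int]:
    """Residues whose combined CSP exceeds the threshold, sorted by number."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return sorted(r.residue_id for r in csps if r.combined > threshold)


def _vector(table_from: ShiftTable, table_to: ShiftTable, rid: int, weight: float):
    h0, n0 = table_from.shifts[rid]
    h1, n1 = table_to.shifts[rid]
    return np.array([h1 - h0, weight * (n1 - n0)])


def chespa(
    apo_wt: ShiftTable,
    holo_wt: ShiftTable,
    mutant_apo: ShiftTable,
    min_magnitude: float = 0.02,
    weight: float = N15_CSP_WEIGHT,
) -> tuple[list[ChespaRecord], list[int]]:
    """Chemical-shift projection analysis.

    Per residue, the reference vector A is the apo->holo WT perturbation
    and B the apo WT -> mutant perturbation, both in weighted 2D shift
    space ``(delta_H, w * delta_N)``.  Reports ``cos_theta = A.B/(|A||B|)``
    and the fractional projection ``fraction_x = |B| cos_theta / |A|``.
    Residues with |A| or |B| below ``min_magnitude`` (ppm) are excluded
    (noise-dominated angles) and returned separately.
    """
    common = sorted(set(apo_wt.shifts) & set(holo_wt.shifts) & set(mutant_apo.shifts))
    if not common:
        raise ValueError("shift tables share no observed residues")
    records, excluded = [], []
    for rid in common:
        a = _vector(apo_wt, holo_wt, rid, weight)
        b = _vector(apo_wt, mutant_apo, rid, weight)
        mag_a, mag_b = float(np.linalg.norm(a)), float(np.linalg.norm(b))
        if mag_a < min_magnitude or mag_b < min_magnitude:
            excluded.append(rid)
            continue
        cos_theta = float(np.dot(a, b) / (mag_a * mag_b))
        cos_theta = max(-1.0, min(1.0, cos_theta))
        records.append(
            ChespaRecord(rid, cos_theta, mag_b * cos_theta / mag_a, mag_a, mag_b)
        )
    if excluded:
        logger.info(
            "%d residue(s) below the %g ppm CHESPA magnitude filter: %s",
            len(excluded), min_magnitude, excluded,
        )
    return records, excluded


_AA = set("ACDEFGHIKLMNPQRSTVWY")


def count_substitutions(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """Substitution count between two protein sequences.

    Equal-length sequences are compared positionally.  Unequal lengths are
    globally aligned first (match +1, mismatch 0, linear gap -5).  Returns
    ``(substitutions, aligned_length, gapped_positions)``; gapped columns
    are counted separately, not as substitutions.
    """
    seq_a, seq_b = seq_a.strip().upper(), seq_b.strip().upper()
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    for s in (seq_a, seq_b):
        bad = set(s) - _AA
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    if len(seq_a) == len(seq_b):
        subs = sum(1 for x, y in zip(seq_a, seq_b) if x != y)
        return subs, len(seq_a), 0
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-5,
        extend_gap_score=-5,
    )
    aln = aligner.align(seq_a, seq_b)[0]
    col_a, col_b = str(aln[0]), str(aln[1])
    subs = gaps = aligned = 0
    for x, y in zip(col_a, col_b):
        if x == "-" or y == "-":
            gaps += 1
        else:
            aligned += 1
            if x != y:
                subs += 1
    return subs, aligned, gaps
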