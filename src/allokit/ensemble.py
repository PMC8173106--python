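"""Superposition and per-residue RMSD profiling of structural ensembles.

A conformational ensemble (e.g., chemical-shift-driven solution models) is
summarized by superposing every model onto the iteratively refined ensemble
mean over a chosen fit range and reporting, per residue, the RMS deviation
of its backbone atoms from the mean — flexible loops stand out as peaks
over a rigid core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StructureEnsemble",
    "kabsch_superpose",
    "per_residue_rmsd",
    "BACKBONE_ATOMS",
]

logger = logging.getLogger(__name__)

#: Backbone atoms used for superposition and RMSD (no carbonyl O).
BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass(frozen=True)
class StructureEnsemble:
    """Multi-model backbone coordinates.

    ``coords`` has shape (n_models, n_residues, n_atoms, 3) in Angstrom,
    with a common residue numbering (author numbering, 1-based) and atom
    order across models.
    """

    coords: np.ndarray
    residue_numbers: np.ndarray
    atom_names: tuple[str, ...] = BACKBONE_ATOMS
    chain_id: str = "A"

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        r = np.asarray(self.residue_numbers, dtype=int)
        if c.ndim != 4 or c.shape[3] != 3:
            raise ValueError("coords must have shape (models, residues, atoms, 3)")
        if c.shape[1] != r.size:
            raise ValueError("residue_numbers length must match coords")
        if c.shape[2] != len(self.atom_names):
            raise ValueError("atom_names length must match coords")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "residue_numbers", r)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired coordinate sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to
    ``reference``.  The rotation is proper (determinant +1; reflections
    rejected by sign-flipping the smallest singular vector).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    if mob.shape[0] < 3:
        raise ValueError("at least 3 atom pairs required")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    cov = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    # collinear point sets leave the rotation under-determined
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError(
            "degenerate (collinear) coordinate set: superposition under-determined"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    moved = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def _apply(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return coords @ rot.T + trans


def per_residue_rmsd(
    ensemble: StructureEnsemble,
    fit_range: tuple[int, int] | None = None,
    n_mean_passes: int = 2,
) -> tuple[np.ndarray, float, float]:
    """Per-residue backbone RMSD profile against the iterated ensemble mean.

    Every model is superposed onto the ensemble mean over the backbone
    atoms of ``fit_range`` (inclusive residue interval; default all
    residues), the mean is recomputed, and the superposition is repeated
    (``n_mean_passes`` passes).  Returns ``(profile, overall, overall_sd)``
    where ``profile[i]`` is the RMS over models and backbone atoms of the
    deviation of residue ``i`` from the final mean, and ``overall`` is the
    mean +/- SD over models of the whole-range backbone RMSD to the mean.
    """
    if ensemble.n_models < 2:
        raise ValueError("at least 2 models required for RMSD profiling")
    resnum = ensemble.residue_numbers
    if fit_range is None:
        sel = np.ones(resnum.size, dtype=bool)
    else:
        lo, hi = fit_range
        sel = (resnum >= lo) & (resnum <= hi)
        if not sel.any():
            raise ValueError(f"fit range {fit_range} selects no residues")

    n_models, n_res, n_at, _ = ensemble.coords.shape
    flat = ensemble.coords.reshape(n_models, n_res * n_at, 3)
    sel_atoms = np.repeat(sel, n_at)

    coords = flat.copy()
    mean = coords.mean(axis=0)
    for _ in range(n_mean_passes):
        for i in range(n_models):
            rot, trans, _ = kabsch_superpose(coords[i][sel_atoms], mean[sel_atoms])
            coords[i] = _apply(coords[i], rot, trans)
        mean = coords.mean(axis=0)

    dev2 = np.sum((coords - mean) ** 2, axis=2)  # (models, res*atoms)
    profile = np.sqrt(
        dev2.reshape(n_models, n_res, n_at).mean(axis=(0, 2))
    )
    per_model = np.sqrt(dev2[:, sel_atoms].mean(axis=1))
    return profile, float(per_model.mean()), float(per_model.std(ddof=1))
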