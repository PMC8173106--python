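"""One-site isothermal-titration-calorimetry binding isotherm.

Forward model and least-squares fit for a standard overflow-cell ITC
titration (VP-ITC geometry): each injection displaces cell volume, the
one-site binding quadratic is solved for the bound-ligand concentration,
and the measured heat is the enthalpy released by the change in bound
ligand inside the active cell volume plus a constant per-injection
baseline.  Fitted parameters are the stoichiometry ``n``, dissociation
constant ``K_D``, enthalpy ``dH``, and baseline; duplicate experiments are
summarized as mean +/- sample SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ITCExperiment",
    "BindingParams",
    "itc_forward",
    "ITCModel",
    "ITCResults",
    "fit_itc",
    "average_duplicates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingParams:
    """One-site binding parameters."""

    n: float                 # stoichiometry (sites per macromolecule)
    kd_um: float             # dissociation constant (uM)
    dh_kcal: float           # binding enthalpy (kcal/mol)
    baseline_ucal: float = 0.0  # constant heat per injection (ucal)

    def __post_init__(self) -> None:
        if self.kd_um <= 0:
            raise ValueError("K_D must be positive")
        if self.n <= 0:
            raise ValueError("stoichiometry must be positive")


@dataclass(frozen=True)
class ITCExperiment:
    """Cell/syringe geometry and the observed injection heats."""

    cell_ml: float
    cell_um: float           # macromolecule concentration in the cell (uM)
    syringe_um: float        # ligand concentration in the syringe (uM)
    injections_ul: np.ndarray
    heats_ucal: np.ndarray | None = None
    temperature_c: float = 20.0

    def __post_init__(self) -> None:
        inj = np.asarray(self.injections_ul, dtype=float)
        if np.any(inj <= 0):
            raise ValueError("injection volumes must be positive")
        if self.cell_ml <= 0 or self.cell_um <= 0 or self.syringe_um <= 0:
            raise ValueError("volumes and concentrations must be positive")
        object.__setattr__(self, "injections_ul", inj)
        if self.heats_ucal is not None:
            h = np.asarray(self.heats_ucal, dtype=float)
            if h.size != inj.size:
                raise ValueError("heats and injections must have equal length")
            object.__setattr__(self, "heats_ucal", h)

    @property
    def n_injections(self) -> int:
        return self.injections_ul.size


def _bound_um(m_tot: float, x_tot: float, n: float, kd: float) -> float:
    """Bound-ligand concentration from the one-site quadratic (uM)."""
    b = n * m_tot + x_tot + kd
    disc = b * b - 4.0 * n * m_tot * x_tot
    return 0.5 * (b - math.sqrt(max(disc, 0.0)))


def itc_forward(params: BindingParams, expt: ITCExperiment) -> np.ndarray:
    """Predicted heat per injection (ucal).

    Stepwise displaced-volume dilution: an injection of ``dV`` into cell
    volume ``V0`` dilutes everything already in the cell by
    ``(1 - dV/V0)`` (the displaced liquid overflows and is no longer
    sensed) and adds ``X_syr * dV / V0`` of ligand.  The heat of injection
    ``i`` is ``dH * V0 * (B_i - B_{i-1} (1 - dV_i/V0)) + baseline`` where
    ``B`` is the bound-ligand concentration: ligand leaving the cell bound
    does not unbind, so its heat is not recounted.
    """
    v0_l = expt.cell_ml * 1e-3
    m = expt.cell_um
    x = 0.0
    bound_prev = 0.0
    heats = np.empty(expt.n_injections)
    # dH (kcal/mol) * V (L) * d[bound] (uM=1e-6 mol/L) -> kcal*1e-6 = ucal*1e-3...
    # 1 kcal = 1e9 ucal; dH*V0*dB(uM) = kcal/mol * L * 1e-6 mol/L = 1e-6 kcal = 1e3 ucal
    scale = params.dh_kcal * v0_l * 1e3  # ucal per uM of newly bound ligand
    for i, dv_ul in enumerate(expt.injections_ul):
        f = dv_ul * 1e-6 / v0_l  # injected fraction of the cell volume
        m *= (1.0 - f)
        x = x * (1.0 - f) + expt.syringe_um * f
        bound = _bound_um(m, x, params.n, params.kd_um)
        heats[i] = scale * (bound - bound_prev * (1.0 - f)) + params.baseline_ucal
        bound_prev = bound
    return heats


class ITCResults:
    """One-site ITC fit with covariance-based uncertainties."""

    def __init__(self, model, params: BindingParams, bse: dict[str, float],
                 rss: float, c_value: float, low_confidence: bool):
        self.model = model
        self.binding = params
        self.bse = bse
        self.rss = rss
        self.c_value = c_value
        self.low_confidence = low_confidence

    @property
    def params(self) -> dict[str, float]:
        return {
            "n": self.binding.n,
            "kd_um": self.binding.kd_um,
            "dh_kcal": self.binding.dh_kcal,
            "baseline_ucal": self.binding.baseline_ucal,
        }

    def predict(self) -> np.ndarray:
        return itc_forward(self.binding, self.model.expt)

    def plot(self, ax=None):
        """Plot observed and fitted injection heats."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        idx = np.arange(1, self.model.expt.n_injections + 1)
        ax.plot(idx, self.model.expt.heats_ucal, "ko", ms=4, label="observed")
        ax.plot(idx, self.predict(), "r-", lw=1, label="one-site fit")
        ax.set_xlabel("injection")
        ax.set_ylabel("heat (ucal)")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        lines = [
            "One-site ITC fit",
            f"  n        = {self.binding.n:.4g} +/- {self.bse['n']:.3g}",
            f"  K_D      = {self.binding.kd_um:.4g} +/- {self.bse['kd_um']:.3g} uM",
            f"  dH       = {self.binding.dh_kcal:.4g} +/- {self.bse['dh_kcal']:.3g} kcal/mol",
            f"  baseline = {self.binding.baseline_ucal:.4g} +/- {self.bse['baseline_ucal']:.3g} ucal",
            f"  c = n[M]/K_D = {self.c_value:.3g}   rss = {self.rss:.4g}",
        ]
        if self.low_confidence:
            lines.append(
                "  warning: c outside the well-conditioned 1-1000 range; "
                "parameters are low-confidence"
            )
        return "\n".join(lines)


class ITCModel:
    """Least-squares one-site model for a single titration.

    ``skip_first`` optionally drops the first injection from the residuals
    (the customary guard against syringe-diffusion artifacts); the forward
    model still propagates its dilution.
    """

    def __init__(self, expt: ITCExperiment, skip_first: bool = False):
        if expt.heats_ucal is None:
            raise ValueError("experiment carries no observed heats")
        if expt.n_injections < 10:
            raise ValueError("at least 10 injections required for fitting")
        self.expt = expt
        self.skip_first = skip_first

    def fit(self) -> ITCResults:
        expt = self.expt
        obs = expt.heats_ucal
        mask = np.ones(expt.n_injections, dtype=bool)
        if self.skip_first:
            mask[0] = False

        def predict(_x, n, kd, dh, base):
            return itc_forward(BindingParams(n, kd, dh, base), expt)[mask]

        total_heat = float(np.sum(obs))
        dh0 = total_heat / (expt.cell_um * expt.cell_ml * 1e-3 * 1e3) or -1.0
        p0 = [1.0, expt.cell_um / 5.0, dh0, 0.0]
        popt, pcov = curve_fit(
            predict, None, obs[mask], p0=p0,
            bounds=([1e-3, 1e-6, -1e3, -1e6], [100.0, 1e9, 1e3, 1e6]),
            maxfev=20000,
        )
        perr = np.sqrt(np.diag(pcov))
        params = BindingParams(*map(float, popt))
        bse = dict(zip(("n", "kd_um", "dh_kcal", "baseline_ucal"), map(float, perr)))
        rss = float(np.sum((obs[mask] - predict(None, *popt)) ** 2))
        c_value = params.n * expt.cell_um / params.kd_um
        low_conf = not (1.0 <= c_value <= 1000.0)
        if low_conf:
            logger.warning("c-value %.3g outside [1, 1000]; fit flagged", c_value)
        return ITCResults(self, params, bse, rss, c_value, low_conf)


def fit_itc(expt: ITCExperiment, skip_first: bool = False) -> ITCResults:
    """Fit a one-site binding isotherm (convenience wrapper)."""
    return ITCModel(expt, skip_first=skip_first).fit()


def average_duplicates(results: list[ITCResults]) -> dict[str, tuple[float, float]]:
    """Mean +/- sample SD of parameters over duplicate titrations."""
    if len(results) < 2:
        raise ValueError("at least two duplicate fits required")
    out = {}
    for key in ("n", "kd_um", "dh_kcal"):
        vals = np.array([r.params[key] for r in results])
        out[key] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out
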