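"""Fitting of R2-CPMG relaxation dispersion and R1 relaxation data.

The central objects follow the model/results pattern: a
:class:`DispersionModel` is built from one residue's dispersion curves
(one per static field) and its :meth:`~DispersionModel.fit` returns a
:class:`DispersionResults` carrying the exchange parameters, their
uncertainties, fit diagnostics and a ``summary()`` table.
:class:`GlobalDispersionModel` fits a group of residues with a shared
exchange rate (and optionally a shared minor-state population), as done
when several residues report on one concerted motion.

Thin functional wrappers (:func:`fit_residue`, :func:`fit_global`,
:func:`fit_r1`) expose the same operations for pipeline use.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import lmfit
import numpy as np
from scipy.optimize import curve_fit

from allokit.exchange import ExchangeParams, FieldContext, r2eff_carver_richards

__all__ = [
    "DispersionCurve",
    "RelaxationSeries",
    "DispersionModel",
    "DispersionResults",
    "GlobalDispersionModel",
    "GlobalDispersionResults",
    "R1Model",
    "R1Results",
    "compute_r2eff",
    "rex_metric",
    "fit_residue",
    "select_model",
    "fit_global",
    "classify_kex",
    "detect_fast_component",
    "fit_r1",
]

logger = logging.getLogger(__name__)

#: Multi-start initialization grid (kex s^-1 x p_b); the Carver-Richards
#: chi-square surface is multimodal, best-of-starts is reported.
KEX_STARTS = (500.0, 1500.0, 3000.0, 6000.0)
PB_STARTS = (0.01, 0.05, 0.1)

#: Fit bounds: kex (s^-1), p_b (fraction), delta-omega (ppm), r2_0 (s^-1).
BOUNDS = {
    "kex": (10.0, 1e5),
    "p_b": (1e-6, 0.5),
    "dw_ppm": (1e-6, 15.0),
    "r2_0": (1e-6, 100.0),
}


@dataclass(frozen=True)
class DispersionCurve:
    """One residue's R2eff dispersion at one static field."""

    residue_id: str
    field: FieldContext
    nu_cpmg: np.ndarray
    r2eff: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu_cpmg, dtype=float)
        r2 = np.asarray(self.r2eff, dtype=float)
        sg = np.asarray(self.sigma, dtype=float)
        if nu.size == 0:
            raise ValueError("empty dispersion curve")
        if not (nu.size == r2.size == sg.size):
            raise ValueError("nu_cpmg, r2eff and sigma must have equal length")
        if np.any(nu <= 0):
            raise ValueError("nu_cpmg values must be strictly positive")
        if len(np.unique(nu)) != nu.size:
            raise ValueError("nu_cpmg values must be unique within a curve")
        if np.any(sg <= 0):
            raise ValueError("sigma values must be strictly positive")
        object.__setattr__(self, "nu_cpmg", nu)
        object.__setattr__(self, "r2eff", r2)
        object.__setattr__(self, "sigma", sg)

    def __len__(self) -> int:
        return self.nu_cpmg.size


@dataclass(frozen=True)
class RelaxationSeries:
    """Intensity versus relaxation delay for one residue (R1)."""

    residue_id: str
    delays: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.delays, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.size != y.size:
            raise ValueError("delays and intensities must have equal length")
        if np.any(t < 0):
            raise ValueError("delays must be non-negative")
        if len(np.unique(t)) < 3:
            raise ValueError("at least 3 distinct delays required")
        object.__setattr__(self, "delays", t)
        object.__setattr__(self, "intensities", y)


def compute_r2eff(
    intensity: float,
    reference_intensity: float,
    t_relax: float,
    sigma_intensity: float,
) -> tuple[float, float] | None:
    """Constant-time intensity-to-R2eff conversion with error propagation.

    ``r2eff = -(1/t_relax) ln(I/I0)``; ``sigma = sigma_I / (I * t_relax)``.
    Returns ``None`` for non-positive intensities (flagged unusable rather
    than aborting a whole-table conversion).
    """
    if t_relax <= 0:
        raise ValueError("t_relax must be positive")
    if reference_intensity <= 0:
        raise ValueError("reference intensity must be positive")
    if intensity <= 0:
        logger.warning("non-positive intensity %g flagged unusable", intensity)
        return None
    r2eff = -math.log(intensity / reference_intensity) / t_relax
    sigma = sigma_intensity / (intensity * t_relax)
    return r2eff, sigma


def rex_metric(curve: DispersionCurve, nu_low: float = 50.0) -> tuple[float, float]:
    """R2eff at the lowest refocusing field and the exchange-contribution estimate.

    Returns ``(r2eff_low, delta_r2)`` where ``r2eff_low`` is the R2eff at
    ``nu_low`` (exact grid match preferred, otherwise the curve's lowest
    refocusing frequency) and ``delta_r2 = r2eff_low - r2eff(max nu)``.
    """
    exact = np.flatnonzero(np.isclose(curve.nu_cpmg, nu_low))
    idx = int(exact[0]) if exact.size else int(np.argmin(curve.nu_cpmg))
    r2_low = float(curve.r2eff[idx])
    r2_high = float(curve.r2eff[np.argmax(curve.nu_cpmg)])
    return r2_low, r2_low - r2_high


def classify_kex(kex: float) -> str:
    """Exchange-rate class: slow (<1000), intermediate (1000-3000), fast (>3000 s^-1).

    Boundaries follow the convention half-open at 1000 and closed at 3000:
    ``[0, 1000) -> slow_blue``, ``[1000, 3000] -> intermediate_yellow``,
    ``(3000, inf) -> fast_red``.
    """
    if kex < 0:
        raise ValueError(f"kex must be non-negative, got {kex}")
    if kex < 1000.0:
        return "slow_blue"
    if kex <= 3000.0:
        return "intermediate_yellow"
    return "fast_red"


def _pooled_sigma(curves: list[DispersionCurve]) -> float:
    allsig = np.concatenate([c.sigma for c in curves])
    return float(np.sqrt(np.mean(allsig**2)))


def _field_key(fctx: FieldContext) -> str:
    return f"{fctx.proton_mhz:g}"


class DispersionResults:
    """Per-residue dispersion fit: parameters, uncertainties, diagnostics.

    Attributes
    ----------
    model_id : str
        ``"carver_richards"`` or ``"flat"``.
    status : str
        ``"ok"``, ``"too_low_to_fit"`` or ``"failed"``.
    params : dict
        Fitted values: ``kex``, ``p_b``, ``dw_ppm`` (exchange model only)
        and ``r2_0_<field>`` per static field.
    bse : dict
        Standard errors from the fit covariance (present when status ok).
    """

    def __init__(
        self,
        model,
        model_id: str,
        status: str,
        params: dict[str, float],
        bse: dict[str, float] | None,
        chi2: float,
        rss: float,
        n_points: int,
        n_params: int,
        message: str = "",
        single_field_degenerate: bool = False,
    ) -> None:
        self.model = model
        self.model_id = model_id
        self.status = status
        self.params = params
        self.bse = bse if bse is not None else {}
        self.chi2 = chi2
        self.rss = rss
        self.n_points = n_points
        self.n_params = n_params
        self.message = message
        self.single_field_degenerate = single_field_degenerate

    @property
    def aicc(self) -> float:
        """Corrected Akaike information criterion (Gaussian, known sigma)."""
        n, k = self.n_points, self.n_params
        if n - k - 1 <= 0:
            return math.inf
        return self.chi2 + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    @property
    def reduced_chi2(self) -> float:
        dof = max(self.n_points - self.n_params, 1)
        return self.chi2 / dof

    def exchange_params(self, fctx: FieldContext) -> ExchangeParams:
        """Fitted state as :class:`ExchangeParams` at one field."""
        if self.model_id != "carver_richards":
            raise ValueError("flat model carries no exchange parameters")
        return ExchangeParams(
            r2_0=self.params[f"r2_0_{_field_key(fctx)}"],
            kex=self.params["kex"],
            p_b=self.params["p_b"],
            delta_omega_ppm=self.params["dw_ppm"],
        )

    def predict(self, nu_cpmg, fctx: FieldContext):
        """Model R2eff at the requested refocusing frequencies."""
        r2_0 = self.params[f"r2_0_{_field_key(fctx)}"]
        if self.model_id == "flat":
            return np.full_like(np.asarray(nu_cpmg, dtype=float), r2_0)
        return r2eff_carver_richards(self.exchange_params(fctx), nu_cpmg, fctx)

    def summary(self) -> str:
        lines = [
            f"Dispersion fit: residue {getattr(self.model, 'residue_id', '?')}",
            f"  model: {self.model_id}   status: {self.status}",
            f"  n={self.n_points}  k={self.n_params}  chi2={self.chi2:.3g}  "
            f"red.chi2={self.reduced_chi2:.3g}  AICc={self.aicc:.4g}",
        ]
        for name, val in self.params.items():
            err = self.bse.get(name)
            lines.append(
                f"  {name:>12s} = {val:10.4g}"
                + (f" +/- {err:.3g}" if err is not None else "")
            )
        if self.single_field_degenerate:
            lines.append(
                "  warning: single-field fit; p_b and dw are degenerate "
                "(only p_b*dw^2/kex is determined in fast exchange)"
            )
        if self.message:
            lines.append(f"  note: {self.message}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the dispersion data and the fitted model per field."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c in self.model.curves:
            label = f"{c.field.proton_mhz:g} MHz"
            ax.errorbar(c.nu_cpmg, c.r2eff, yerr=c.sigma, fmt="o", ms=3,
                        label=label)
            grid = np.linspace(c.nu_cpmg.min(), c.nu_cpmg.max(), 200)
            ax.plot(grid, self.predict(grid, c.field), "-", lw=1)
        ax.set_xlabel(r"$\nu_{CPMG}$ (Hz)")
        ax.set_ylabel(r"$R_{2,eff}$ (s$^{-1}$)")
        ax.legend(frameon=False)
        return ax

    def __repr__(self) -> str:
        return (
            f"<DispersionResults {self.model_id} status={self.status} "
            f"params={self.params}>"
        )


class DispersionModel:
    """Two-site exchange model for one residue's dispersion curves.

    Parameters
    ----------
    curves : list of DispersionCurve
        One curve per static field for a single residue.
    fittability_factor : float
        A residue whose largest exchange contribution (``delta_r2`` from
        :func:`rex_metric`) is below ``fittability_factor`` times the
        pooled measurement sigma is reported ``too_low_to_fit`` and no
        exchange parameters are extracted.
    """

    def __init__(
        self, curves: list[DispersionCurve], fittability_factor: float = 2.0
    ) -> None:
        if not curves:
            raise ValueError("at least one dispersion curve required")
        ids = {c.residue_id for c in curves}
        if len(ids) > 1:
            raise ValueError(f"curves belong to multiple residues: {sorted(ids)}")
        if sum(len(c) for c in curves) < 6:
            raise ValueError("at least 6 points total required for fitting")
        self.curves = list(curves)
        self.residue_id = curves[0].residue_id
        self.fittability_factor = fittability_factor

    # -- flat (no-exchange) model ------------------------------------
    def _fit_flat(self) -> DispersionResults:
        params: dict[str, float] = {}
        bse: dict[str, float] = {}
        chi2 = 0.0
        rss = 0.0
        for c in self.curves:
            w = 1.0 / c.sigma**2
            mean = float(np.sum(w * c.r2eff) / np.sum(w))
            key = f"r2_0_{_field_key(c.field)}"
            params[key] = mean
            bse[key] = float(1.0 / math.sqrt(np.sum(w)))
            chi2 += float(np.sum(((c.r2eff - mean) / c.sigma) ** 2))
            rss += float(np.sum((c.r2eff - mean) ** 2))
        n = sum(len(c) for c in self.curves)
        return DispersionResults(
            self, "flat", "ok", params, bse, chi2, rss, n, len(params)
        )

    # -- Carver-Richards model ---------------------------------------
    def _residuals(self, lm_params: lmfit.Parameters) -> np.ndarray:
        out = []
        for c in self.curves:
            p = ExchangeParams(
                r2_0=lm_params[f"r2_0_{_field_key(c.field)}"].value,
                kex=lm_params["kex"].value,
                p_b=lm_params["p_b"].value,
                delta_omega_ppm=lm_params["dw_ppm"].value,
            )
            model = r2eff_carver_richards(p, c.nu_cpmg, c.field)
            out.append((c.r2eff - model) / c.sigma)
        return np.concatenate(out)

    def _make_params(self, kex0: float, pb0: float) -> lmfit.Parameters:
        lp = lmfit.Parameters()
        lp.add("kex", value=kex0, min=BOUNDS["kex"][0], max=BOUNDS["kex"][1])
        lp.add("p_b", value=pb0, min=BOUNDS["p_b"][0], max=BOUNDS["p_b"][1])
        lp.add("dw_ppm", value=2.0, min=BOUNDS["dw_ppm"][0], max=BOUNDS["dw_ppm"][1])
        for c in self.curves:
            r2_high = float(c.r2eff[np.argmax(c.nu_cpmg)])
            lp.add(
                f"r2_0_{_field_key(c.field)}",
                value=min(max(r2_high, 0.5), 99.0),
                min=BOUNDS["r2_0"][0],
                max=BOUNDS["r2_0"][1],
            )
        return lp

    def _fit_carver_richards(self) -> DispersionResults:
        best: lmfit.minimizer.MinimizerResult | None = None
        for kex0 in KEX_STARTS:
            for pb0 in PB_STARTS:
                try:
                    res = lmfit.minimize(
                        self._residuals,
                        self._make_params(kex0, pb0),
                        method="leastsq",
                    )
                except Exception as exc:  # pragma: no cover - optimizer edge
                    logger.debug("start (%g, %g) failed: %s", kex0, pb0, exc)
                    continue
                if best is None or res.chisqr < best.chisqr:
                    best = res
        n = sum(len(c) for c in self.curves)
        if best is None:
            return DispersionResults(
                self,
                "carver_richards",
                "failed",
                {},
                None,
                math.inf,
                math.inf,
                n,
                3 + len(self.curves),
                message="optimizer did not converge from any start",
            )
        params = {k: float(v.value) for k, v in best.params.items()}
        bse = {
            k: float(v.stderr)
            for k, v in best.params.items()
            if v.stderr is not None
        }
        rss = 0.0
        for c in self.curves:
            p = ExchangeParams(
                r2_0=params[f"r2_0_{_field_key(c.field)}"],
                kex=params["kex"],
                p_b=params["p_b"],
                delta_omega_ppm=params["dw_ppm"],
            )
            rss += float(
                np.sum((c.r2eff - r2eff_carver_richards(p, c.nu_cpmg, c.field)) ** 2)
            )
        return DispersionResults(
            self,
            "carver_richards",
            "ok",
            params,
            bse,
            float(best.chisqr),
            rss,
            n,
            3 + len(self.curves),
            single_field_degenerate=len(self.curves) == 1,
        )

    def fit(self, model_id: str = "carver_richards") -> DispersionResults:
        """Weighted (1/sigma^2) least-squares fit with multi-start initialization."""
        if model_id == "flat":
            return self._fit_flat()
        if model_id != "carver_richards":
            raise ValueError(f"unknown model_id {model_id!r}")
        delta_r2 = max(rex_metric(c)[1] for c in self.curves)
        if delta_r2 < self.fittability_factor * _pooled_sigma(self.curves):
            flat = self._fit_flat()
            return DispersionResults(
                self,
                "carver_richards",
                "too_low_to_fit",
                flat.params,
                None,
                flat.chi2,
                flat.rss,
                flat.n_points,
                flat.n_params,
                message=(
                    f"exchange contribution {delta_r2:.3g} s^-1 below "
                    f"{self.fittability_factor} x pooled sigma"
                ),
            )
        res = self._fit_carver_richards()
        if res.single_field_degenerate:
            logger.warning(
                "residue %s: single-field fit; p_b*dw^2/kex degeneracy applies",
                self.residue_id,
            )
        return res


def fit_residue(
    curves: list[DispersionCurve], model_id: str = "carver_richards"
) -> DispersionResults:
    """Fit one residue's dispersion curves (convenience wrapper)."""
    return DispersionModel(curves).fit(model_id)


def select_model(
    curves: list[DispersionCurve],
    candidates: tuple[str, ...] = ("flat", "carver_richards"),
) -> tuple[str, dict[str, DispersionResults]]:
    """Choose between no-exchange and two-site exchange by AICc.

    Returns ``(model_id, fits)`` with both fits retained.  Ties
    (|delta AICc| < 2) and unfittable/failed exchange fits resolve to the
    flat model.
    """
    model = DispersionModel(curves)
    fits = {m: model.fit(m) for m in candidates}
    if "carver_richards" not in fits or fits["carver_richards"].status != "ok":
        return "flat", fits
    delta = fits["flat"].aicc - fits["carver_richards"].aicc
    chosen = "carver_richards" if delta >= 2.0 else "flat"
    return chosen, fits


def detect_fast_component(
    fit: DispersionResults, baseline_r2: float | None, threshold: float = 2.0
) -> bool:
    """Flag a residual fast exchange process.

    A fitted intrinsic rate well above a reference baseline (e.g., the
    group median r2_0) indicates the dispersion plateaus above the true
    intrinsic rate — the signature of an additional exchange process too
    fast for the sampled CPMG fields to refocus.
    """
    if baseline_r2 is None:
        raise ValueError("baseline_r2 is required")
    if fit.status != "ok":
        raise ValueError("fast-component detection requires a successful fit")
    fitted = max(v for k, v in fit.params.items() if k.startswith("r2_0_"))
    return fitted - baseline_r2 > threshold


# ---------------------------------------------------------------------
# Grouped (global) fitting


class GlobalDispersionResults:
    """Grouped fit with shared exchange parameters across residues."""

    def __init__(
        self,
        model,
        params: dict[str, float],
        bse: dict[str, float],
        chi2: float,
        n_points: int,
        n_params: int,
        excluded: list[str],
        per_residue: dict[str, DispersionResults],
    ) -> None:
        self.model = model
        self.params = params
        self.bse = bse
        self.chi2 = chi2
        self.n_points = n_points
        self.n_params = n_params
        self.excluded = excluded
        self.per_residue = per_residue

    @property
    def kex(self) -> float:
        return self.params["kex"]

    @property
    def reduced_chi2(self) -> float:
        dof = max(self.n_points - self.n_params, 1)
        return self.chi2 / dof

    def dw_ppm(self, residue_id: str) -> float:
        return self.params[f"dw_ppm_{residue_id}"]

    def summary(self) -> str:
        shared = ", ".join(self.model.shared)
        lines = [
            f"Global dispersion fit ({len(self.model.groups)} residues; "
            f"shared: {shared})",
            f"  n={self.n_points}  k={self.n_params}  chi2={self.chi2:.4g}  "
            f"red.chi2={self.reduced_chi2:.3g}",
        ]
        for name, val in sorted(self.params.items()):
            err = self.bse.get(name)
            lines.append(
                f"  {name:>16s} = {val:10.4g}"
                + (f" +/- {err:.3g}" if err is not None else "")
            )
        if self.excluded:
            lines.append(f"  excluded (too low to fit): {', '.join(self.excluded)}")
        return "\n".join(lines)


class GlobalDispersionModel:
    """Shared-parameter fit over several residues' dispersion curves.

    Parameters
    ----------
    groups : dict
        Mapping residue_id -> list of that residue's curves.
    shared : tuple of str
        Parameters shared across the group: ``("kex",)`` or
        ``("kex", "p_b")``.  Shift differences and intrinsic rates are
        always per-residue (and per-field for r2_0).
    """

    def __init__(
        self,
        groups: dict[str, list[DispersionCurve]],
        shared: tuple[str, ...] = ("kex", "p_b"),
    ) -> None:
        if not set(shared) <= {"kex", "p_b"}:
            raise ValueError("shared parameters must be among {'kex', 'p_b'}")
        if "kex" not in shared:
            raise ValueError("a global fit must at least share kex")
        self.shared = tuple(shared)
        self.groups: dict[str, list[DispersionCurve]] = {}
        self.excluded: list[str] = []
        for rid, curves in groups.items():
            m = DispersionModel(curves)
            delta_r2 = max(rex_metric(c)[1] for c in curves)
            if delta_r2 < m.fittability_factor * _pooled_sigma(curves):
                logger.warning(
                    "residue %s excluded from global fit: exchange too low", rid
                )
                self.excluded.append(rid)
            else:
                self.groups[rid] = list(curves)
        if len(self.groups) < 1:
            raise ValueError("no fittable residues in the group")

    def _make_params(self, kex0: float, pb0: float) -> lmfit.Parameters:
        lp = lmfit.Parameters()
        lp.add("kex", value=kex0, min=BOUNDS["kex"][0], max=BOUNDS["kex"][1])
        if "p_b" in self.shared:
            lp.add("p_b", value=pb0, min=BOUNDS["p_b"][0], max=BOUNDS["p_b"][1])
        for rid, curves in self.groups.items():
            if "p_b" not in self.shared:
                lp.add(
                    f"p_b_{rid}", value=pb0, min=BOUNDS["p_b"][0], max=BOUNDS["p_b"][1]
                )
            lp.add(
                f"dw_ppm_{rid}",
                value=2.0,
                min=BOUNDS["dw_ppm"][0],
                max=BOUNDS["dw_ppm"][1],
            )
            for c in curves:
                r2_high = float(c.r2eff[np.argmax(c.nu_cpmg)])
                lp.add(
                    f"r2_0_{rid}_{_field_key(c.field)}",
                    value=min(max(r2_high, 0.5), 99.0),
                    min=BOUNDS["r2_0"][0],
                    max=BOUNDS["r2_0"][1],
                )
        return lp

    def _residuals(self, lp: lmfit.Parameters) -> np.ndarray:
        out = []
        for rid, curves in self.groups.items():
            pb = lp["p_b"].value if "p_b" in self.shared else lp[f"p_b_{rid}"].value
            for c in curves:
                p = ExchangeParams(
                    r2_0=lp[f"r2_0_{rid}_{_field_key(c.field)}"].value,
                    kex=lp["kex"].value,
                    p_b=pb,
                    delta_omega_ppm=lp[f"dw_ppm_{rid}"].value,
                )
                out.append(
                    (c.r2eff - r2eff_carver_richards(p, c.nu_cpmg, c.field)) / c.sigma
                )
        return np.concatenate(out)

    def fit(self) -> GlobalDispersionResults:
        best = None
        for kex0 in KEX_STARTS:
            for pb0 in (0.02, 0.05):
                try:
                    res = lmfit.minimize(
                        self._residuals, self._make_params(kex0, pb0), method="leastsq"
                    )
                except Exception as exc:  # pragma: no cover
                    logger.debug("global start (%g, %g) failed: %s", kex0, pb0, exc)
                    continue
                if best is None or res.chisqr < best.chisqr:
                    best = res
        if best is None:
            raise RuntimeError("global fit did not converge from any start")
        params = {k: float(v.value) for k, v in best.params.items()}
        bse = {
            k: float(v.stderr)
            for k, v in best.params.items()
            if v.stderr is not None
        }
        per_residue = {
            rid: DispersionModel(curves).fit() for rid, curves in self.groups.items()
        }
        n = sum(len(c) for curves in self.groups.values() for c in curves)
        return GlobalDispersionResults(
            self,
            params,
            bse,
            float(best.chisqr),
            n,
            len(best.params),
            list(self.excluded),
            per_residue,
        )


def fit_global(
    groups: dict[str, list[DispersionCurve]],
    shared: tuple[str, ...] = ("kex", "p_b"),
) -> GlobalDispersionResults:
    """Group fit with shared exchange parameters (convenience wrapper)."""
    return GlobalDispersionModel(groups, shared=shared).fit()


# ---------------------------------------------------------------------
# R1 relaxation


class R1Results:
    """Monoexponential R1 fit for one residue."""

    def __init__(self, model, status, r1, r1_err, i0, i0_err, rss):
        self.model = model
        self.status = status
        self.r1 = r1
        self.r1_err = r1_err
        self.i0 = i0
        self.i0_err = i0_err
        self.rss = rss

    @property
    def params(self) -> dict[str, float]:
        return {"r1": self.r1, "i0": self.i0}

    @property
    def bse(self) -> dict[str, float]:
        return {"r1": self.r1_err, "i0": self.i0_err}

    def summary(self) -> str:
        return (
            f"R1 fit: residue {self.model.series.residue_id}\n"
            f"  status: {self.status}\n"
            f"  r1 = {self.r1:.6g} +/- {self.r1_err:.3g} s^-1\n"
            f"  i0 = {self.i0:.6g} +/- {self.i0_err:.3g}\n"
            f"  rss = {self.rss:.4g}"
        )


class R1Model:
    """Monoexponential longitudinal-relaxation model ``I(t) = I0 exp(-r1 t)``."""

    def __init__(self, series: RelaxationSeries) -> None:
        self.series = series

    def fit(self) -> R1Results:
        t, y = self.series.delays, self.series.intensities
        # log-linear start where intensities allow it
        pos = y > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
            p0 = [math.exp(intercept), max(-slope, 1e-3)]
        else:
            p0 = [float(np.max(np.abs(y)) or 1.0), 1.0]

        def decay(tt, i0, r1):
            return i0 * np.exp(-r1 * tt)

        try:
            popt, pcov = curve_fit(decay, t, y, p0=p0, maxfev=10000)
        except Exception:
            return R1Results(self, "failed", math.nan, math.nan, math.nan, math.nan,
                             math.nan)
        i0, r1 = popt
        rss = float(np.sum((y - decay(t, *popt)) ** 2))
        # non-decaying data: negative rate, or no measurable decay across
        # the sampled window
        if r1 <= 0 or r1 * float(t.max()) < 1e-6:
            return R1Results(self, "failed", float(r1), math.nan, float(i0), math.nan,
                             rss)
        perr = np.sqrt(np.diag(pcov))
        return R1Results(
            self, "ok", float(r1), float(perr[1]), float(i0), float(perr[0]), rss
        )


def fit_r1(series: RelaxationSeries) -> R1Results:
    """Fit a monoexponential R1 decay (convenience wrapper)."""
    return R1Model(series).fit()
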