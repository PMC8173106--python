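"""Steady-state and pre-steady-state enzyme kinetics.

Steady-state: initial velocities versus substrate concentration fitted to
the Michaelis-Menten equation ``v = Vmax [S] / (K_M + [S])``; absorbance
slopes from a plate reader are first converted to molar velocities with
the chromophore extinction coefficient (NADPH at 340 nm by default) and
well pathlength.

Pre-steady-state: stopped-flow traces fitted to a single-exponential burst
(the chemical step, here hydride transfer ``k_hyd``) superimposed on a
linear steady-state phase, ``S(t) = a exp(-k_hyd t) + m t + c``.  Because
the hydride-transfer rate is substrate-concentration independent, rates
measured at several substrate concentrations are averaged, with their
standard deviation as the reported uncertainty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "VelocityDataset",
    "BurstTrace",
    "NADPH_EXTINCTION_M",
    "PLATE_PATHLENGTH_CM",
    "absorbance_to_velocity",
    "MichaelisMentenModel",
    "MichaelisMentenResults",
    "BurstModel",
    "BurstResults",
    "fit_michaelis_menten",
    "fit_burst",
    "aggregate_khyd",
]

logger = logging.getLogger(__name__)

#: NADPH molar extinction coefficient at 340 nm (M^-1 cm^-1).
NADPH_EXTINCTION_M = 6222.0
#: Pathlength of a 200 uL well in a standard 96-well plate (cm).
PLATE_PATHLENGTH_CM = 0.625


def absorbance_to_velocity(
    slope: float,
    epsilon: float = NADPH_EXTINCTION_M,
    path: float = PLATE_PATHLENGTH_CM,
) -> float:
    """Convert an absorbance slope (A340/s) to a molar velocity (M/s)."""
    if epsilon <= 0 or path <= 0:
        raise ValueError("extinction coefficient and pathlength must be positive")
    return slope / (epsilon * path)


@dataclass(frozen=True)
class VelocityDataset:
    """Initial velocities versus substrate concentration.

    Concentrations in uM, velocities in uM/s; ``enzyme_um`` is required to
    convert Vmax to a turnover number k_cat.
    """

    substrate_um: np.ndarray
    velocity_um_s: np.ndarray
    enzyme_um: float | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_um, dtype=float)
        v = np.asarray(self.velocity_um_s, dtype=float)
        if s.size != v.size:
            raise ValueError("substrate and velocity arrays must match")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be positive")
        if len(np.unique(s)) < 4:
            raise ValueError("at least 4 distinct substrate levels required")
        if self.enzyme_um is not None and self.enzyme_um <= 0:
            raise ValueError("enzyme concentration must be positive")
        object.__setattr__(self, "substrate_um", s)
        object.__setattr__(self, "velocity_um_s", v)


@dataclass(frozen=True)
class BurstTrace:
    """A stopped-flow time trace."""

    time_s: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.size != y.size:
            raise ValueError("time and signal arrays must match")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "signal", y)


def _mm(s, vmax, km):
    return vmax * s / (km + s)


class MichaelisMentenResults:
    """Michaelis-Menten fit: Vmax, K_M and (when [E] is known) k_cat."""

    def __init__(self, model, vmax, km, vmax_err, km_err, rss, extrapolated):
        self.model = model
        self.vmax = vmax
        self.km = km
        self.vmax_err = vmax_err
        self.km_err = km_err
        self.rss = rss
        self.extrapolated = extrapolated

    @property
    def params(self) -> dict[str, float]:
        out = {"vmax": self.vmax, "km": self.km}
        if self.kcat is not None:
            out["kcat"] = self.kcat
        return out

    @property
    def bse(self) -> dict[str, float]:
        out = {"vmax": self.vmax_err, "km": self.km_err}
        if self.kcat is not None:
            out["kcat"] = self.kcat_err
        return out

    @property
    def kcat(self) -> float | None:
        e = self.model.data.enzyme_um
        return None if e is None else self.vmax / e

    @property
    def kcat_err(self) -> float | None:
        e = self.model.data.enzyme_um
        return None if e is None else self.vmax_err / e

    def predict(self, substrate_um):
        return _mm(np.asarray(substrate_um, dtype=float), self.vmax, self.km)

    def plot(self, ax=None):
        """Plot the velocity data and the fitted hyperbola."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.data.substrate_um
        ax.plot(s, self.model.data.velocity_um_s, "ko", ms=4)
        grid = np.linspace(0.0, float(s.max()), 200)
        ax.plot(grid, self.predict(grid), "-", lw=1)
        ax.set_xlabel("[S] (uM)")
        ax.set_ylabel("v (uM/s)")
        return ax

    def summary(self) -> str:
        lines = [
            "Michaelis-Menten fit",
            f"  Vmax = {self.vmax:.5g} +/- {self.vmax_err:.3g} uM/s",
            f"  K_M  = {self.km:.5g} +/- {self.km_err:.3g} uM",
        ]
        if self.kcat is not None:
            lines.append(
                f"  k_cat = {self.kcat:.5g} +/- {self.kcat_err:.3g} s^-1 "
                f"([E] = {self.model.data.enzyme_um:g} uM)"
            )
        lines.append(f"  rss = {self.rss:.4g}")
        if self.extrapolated:
            lines.append(
                "  warning: K_M exceeds the largest substrate concentration "
                "(non-saturating data; estimate extrapolated)"
            )
        return "\n".join(lines)


class MichaelisMentenModel:
    """Nonlinear least-squares Michaelis-Menten model.

    Initialized at Vmax = max(v) and K_M = [S] nearest half-maximal
    velocity; per-point weights are optional (the default is unweighted).
    """

    def __init__(self, data: VelocityDataset, weights: np.ndarray | None = None):
        self.data = data
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    def fit(self) -> MichaelisMentenResults:
        s, v = self.data.substrate_um, self.data.velocity_um_s
        vmax0 = float(np.max(v))
        half = vmax0 / 2.0
        km0 = float(s[np.argmin(np.abs(v - half))])
        sigma = None if self.weights is None else 1.0 / np.sqrt(self.weights)
        popt, pcov = curve_fit(
            _mm, s, v, p0=[vmax0, max(km0, 1e-6)], sigma=sigma, maxfev=10000
        )
        perr = np.sqrt(np.diag(pcov))
        rss = float(np.sum((v - _mm(s, *popt)) ** 2))
        extrapolated = popt[1] > float(np.max(s))
        if extrapolated:
            logger.warning(
                "K_M estimate %.3g uM exceeds max [S] %.3g uM: extrapolated",
                popt[1], float(np.max(s)),
            )
        return MichaelisMentenResults(
            self, float(popt[0]), float(popt[1]), float(perr[0]), float(perr[1]),
            rss, extrapolated,
        )


def fit_michaelis_menten(
    data: VelocityDataset, weights: np.ndarray | None = None
) -> MichaelisMentenResults:
    """Fit the Michaelis-Menten equation (convenience wrapper)."""
    return MichaelisMentenModel(data, weights=weights).fit()


def _burst(t, a, k, m, c):
    return a * np.exp(-k * t) + m * t + c


class BurstResults:
    """Burst-phase fit: amplitude, k_hyd, steady-state slope, offset."""

    def __init__(self, model, a, k_hyd, slope, offset, bse, rss, no_burst):
        self.model = model
        self.amplitude = a
        self.k_hyd = k_hyd
        self.slope = slope
        self.offset = offset
        self._bse = bse
        self.rss = rss
        self.no_burst = no_burst

    @property
    def params(self) -> dict[str, float]:
        return {
            "amplitude": self.amplitude,
            "k_hyd": self.k_hyd,
            "slope": self.slope,
            "offset": self.offset,
        }

    @property
    def bse(self) -> dict[str, float]:
        return dict(self._bse)

    def predict(self, time_s):
        return _burst(
            np.asarray(time_s, dtype=float),
            self.amplitude, self.k_hyd, self.slope, self.offset,
        )

    def plot(self, ax=None):
        """Plot the trace and the fitted burst-plus-line model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.trace.time_s
        ax.plot(t, self.model.trace.signal, ".", ms=2, color="0.6")
        ax.plot(t, self.predict(t), "k-", lw=1)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("signal (a.u.)")
        return ax

    def summary(self) -> str:
        lines = [
            "Pre-steady-state burst fit: S(t) = a exp(-k_hyd t) + m t + c",
            f"  a      = {self.amplitude:.5g} +/- {self._bse['amplitude']:.3g}",
            f"  k_hyd  = {self.k_hyd:.5g} +/- {self._bse['k_hyd']:.3g} s^-1",
            f"  m      = {self.slope:.5g} +/- {self._bse['slope']:.3g} /s",
            f"  c      = {self.offset:.5g} +/- {self._bse['offset']:.3g}",
            f"  rss = {self.rss:.4g}",
        ]
        if self.no_burst:
            lines.append(
                "  warning: exponential amplitude indistinguishable from zero "
                "(|a| < 2 sigma_a); no burst phase detected"
            )
        return "\n".join(lines)


class BurstModel:
    """Exponential-burst-plus-line model for a stopped-flow trace.

    Samples earlier than the instrument dead time are discarded, not
    extrapolated.  The decaying-exponential sign convention matches an
    absorbance decrease during the first turnover.
    """

    def __init__(self, trace: BurstTrace, dead_time: float = 0.0):
        keep = trace.time_s >= dead_time
        if keep.sum() < 5:
            raise ValueError("fewer than 5 samples after the dead time")
        self.trace = trace
        self.dead_time = dead_time
        self._t = trace.time_s[keep]
        self._y = trace.signal[keep]

    def fit(self) -> BurstResults:
        t, y = self._t, self._y
        # tail estimates the line; the early excess estimates the burst
        n_tail = max(t.size // 3, 2)
        m0, c0 = np.polyfit(t[-n_tail:], y[-n_tail:], 1)
        resid0 = y - (m0 * t + c0)
        a0 = float(resid0[0])
        span = float(t[-1] - t[0])
        best = None
        for k0 in (2.0 / span, 10.0 / span, 50.0 / span):
            try:
                popt, pcov = curve_fit(
                    _burst, t, y, p0=[a0 if a0 != 0 else 1e-3, k0, m0, c0],
                    maxfev=20000,
                )
            except Exception:
                continue
            rss = float(np.sum((y - _burst(t, *popt)) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
        if best is None:
            raise RuntimeError("burst fit did not converge from any start")
        popt, pcov, rss = best
        perr = np.sqrt(np.diag(pcov))
        bse = dict(zip(("amplitude", "k_hyd", "slope", "offset"), map(float, perr)))
        no_burst = abs(popt[0]) < 2.0 * perr[0]
        if no_burst:
            logger.warning("no burst phase detected (|a| < 2 sigma_a)")
        return BurstResults(
            self, float(popt[0]), float(popt[1]), float(popt[2]), float(popt[3]),
            bse, rss, no_burst,
        )


def fit_burst(trace: BurstTrace, dead_time: float = 0.0) -> BurstResults:
    """Fit an exponential burst plus linear steady state (convenience wrapper)."""
    return BurstModel(trace, dead_time=dead_time).fit()


def aggregate_khyd(rates: list[float]) -> tuple[float, float]:
    """Mean and sample SD of hydride-transfer rates across concentrations.

    The chemical step is concentration-independent, so rates measured at
    different substrate concentrations estimate one quantity; a single
    rate is returned with an undefined (NaN) SD and a warning.
    """
    vals = np.asarray(rates, dtype=float)
    if vals.size == 0:
        raise ValueError("no rates supplied")
    if vals.size == 1:
        logger.warning("single rate supplied; SD undefined")
        return float(vals[0]), math.nan
    return float(vals.mean()), float(vals.std(ddof=1))
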