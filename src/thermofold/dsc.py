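"""Differential scanning calorimetry: baseline correction and two-state fits.

A thermogram is the heat signal recorded while scanning temperature at a
constant rate.  After subtracting a low-order polynomial baseline anchored
in the pre- and post-transition flanks, the excess heat capacity of a
scaled two-state transition is

    Cp(T) = s * dH_vH^2 * K / (R T^2 (1 + K)^2),
    K(T)  = exp(-(dH_vH / R) (1/T - 1/T_m)),

with T in kelvin internally, dH_vH the van't Hoff enthalpy (kcal/mol), s a
free amplitude scale, and T_m the midpoint (K = 1).  The model integrates
to s * dH_vH over the scan, which ties the peak area to the enthalpy.
Complex profiles can optionally be resolved as a sum of such components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import R_KCAL, celsius_to_kelvin

__all__ = [
    "Thermogram",
    "DSCFitResults",
    "DSCTwoStateModel",
    "baseline_correct",
    "two_state_fit",
    "two_state_excess_heat_capacity",
]


@dataclass
class Thermogram:
    """Heat signal vs temperature from a constant-rate scan.

    ``temperature`` in degrees Celsius, strictly increasing; ``heat_signal``
    in arbitrary heat-capacity units; ``scan_rate`` (degC/min) is metadata.
    """

    temperature: np.ndarray
    heat_signal: np.ndarray
    scan_rate: float | None = 1.0

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.heat_signal = np.asarray(self.heat_signal, dtype=float)
        if self.temperature.shape != self.heat_signal.shape or self.temperature.ndim != 1:
            raise ValueError("temperature and heat_signal must be 1-D, equal length")
        if len(self.temperature) < 50:
            raise ValueError("need at least 50 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


def two_state_excess_heat_capacity(
    temperature_C, T_m_C: float, dH_vH: float, scale: float = 1.0
) -> np.ndarray:
    """Scaled two-state excess heat capacity on a Celsius grid."""
    T = celsius_to_kelvin(np.asarray(temperature_C, dtype=float))
    Tm = celsius_to_kelvin(T_m_C)
    K = np.exp(-(dH_vH / R_KCAL) * (1.0 / T - 1.0 / Tm))
    return scale * dH_vH**2 * K / (R_KCAL * T**2 * (1.0 + K) ** 2)


def _flank_mask(t: np.ndarray, y: np.ndarray, flank_fraction: float) -> np.ndarray:
    span = t[-1] - t[0]
    mask = (t <= t[0] + flank_fraction * span) | (t >= t[-1] - flank_fraction * span)
    if mask.sum() < 4:
        raise ValueError("too few flank points for baseline estimation")
    return mask


def baseline_correct(
    raw: Thermogram, degree: int = 1, flank_fraction: float = 0.15
) -> Thermogram:
    """Subtract a polynomial baseline fitted to the scan flanks.

    The transition must not occupy the whole scan: the corrected signal is
    required to be flat (within 10% of the peak excursion) in the flanks.
    """
    if degree > 3 or degree < 0:
        raise ValueError("baseline degree must be between 0 and 3")
    t, y = raw.temperature, raw.heat_signal
    mask = _flank_mask(t, y, flank_fraction)
    # centered fit for numerical conditioning
    t0 = t.mean()
    coeffs = np.polyfit(t[mask] - t0, y[mask], degree)
    corrected = y - np.polyval(coeffs, t - t0)
    peak = np.max(np.abs(corrected))
    significant = peak > 1e-8 * (np.max(np.abs(y)) + 1.0)
    if significant and np.max(np.abs(corrected[mask])) > 0.35 * peak:
        raise ValueError(
            "no flat pre/post-transition flanks: transition may occupy the "
            "whole scan or the baseline degree is too low"
        )
    return Thermogram(t.copy(), corrected, raw.scan_rate)


class DSCTwoStateModel:
    """Two-state (optionally multi-component) model for a corrected thermogram.

    Parameters
    ----------
    corrected : Thermogram
        Baseline-corrected thermogram (use :func:`baseline_correct`).
    n_components : int
        Number of two-state components to resolve (1 = single transition).

    ``fit()`` returns :class:`DSCFitResults`.
    """

    def __init__(self, corrected: Thermogram, n_components: int = 1):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.thermogram = corrected
        self.n_components = n_components
        self._raw: Thermogram | None = None
        self.baseline_degree: int | None = None

    @classmethod
    def from_raw(cls, raw: Thermogram, baseline_degree: int = 1, **kw) -> "DSCTwoStateModel":
        """Build from an uncorrected thermogram.

        The flank-anchored polynomial correction is refined against the
        fitted transition (baseline re-estimated on the model-subtracted
        signal over the whole scan), which removes the bias the transition
        tails would otherwise leave in the flanks.
        """
        model = cls(baseline_correct(raw, degree=baseline_degree), **kw)
        model._raw = raw
        model.baseline_degree = baseline_degree
        return model

    def _initial_guesses(self):
        t, y = self.thermogram.temperature, self.thermogram.heat_signal
        ymax = float(y.max())
        noise = float(np.std(np.diff(y)) / np.sqrt(2.0)) if len(y) > 1 else 0.0
        if ymax <= 0 or (noise > 0 and ymax < 5.0 * noise):
            raise ValueError("no peak above noise: cannot fit a transition")
        area = float(np.trapezoid(np.clip(y, 0, None), t))
        guesses = []
        yy = y.copy()
        for _ in range(self.n_components):
            i = int(np.argmax(yy))
            tm0 = float(t[i])
            TmK = celsius_to_kelvin(tm0)
            # width of a two-state peak: Cp_max = dH^2 s/(4 R Tm^2); area = s dH
            dh0 = 4.0 * R_KCAL * TmK**2 * float(yy[i]) / max(area / self.n_components, 1e-12)
            dh0 = float(np.clip(dh0, 10.0, 500.0))
            s0 = max(area / self.n_components, 1e-12) / dh0
            guesses.append((tm0, dh0, s0))
            yy = yy - two_state_excess_heat_capacity(t, tm0, dh0, s0)
        return guesses

    def fit(self) -> "DSCFitResults":
        results = self._fit_corrected()
        if self._raw is None:
            return results
        # iterate: re-estimate the polynomial on the model-subtracted raw
        # signal (all points), re-correct, re-fit
        t, raw = self._raw.temperature, self._raw.heat_signal
        t0 = t.mean()
        for _ in range(6):
            residual = raw - results.fitted_curve()
            coeffs = np.polyfit(t - t0, residual, self.baseline_degree)
            self.thermogram = Thermogram(
                t.copy(), raw - np.polyval(coeffs, t - t0), self._raw.scan_rate
            )
            tm_prev = results.T_m
            results = self._fit_corrected()
            if abs(results.T_m - tm_prev) < 1e-5:
                break
        return results

    def _fit_corrected(self) -> "DSCFitResults":
        t, y = self.thermogram.temperature, self.thermogram.heat_signal
        guesses = self._initial_guesses()

        def model(t, *params):
            out = np.zeros_like(t)
            for j in range(self.n_components):
                tm, dh, s = params[3 * j : 3 * j + 3]
                out = out + two_state_excess_heat_capacity(t, tm, dh, s)
            return out

        p0 = [v for g in guesses for v in g]
        lo = [t[0], 1.0, 0.0] * self.n_components
        hi = [t[-1], 2000.0, np.inf] * self.n_components
        popt, pcov = curve_fit(model, t, y, p0=p0, bounds=(lo, hi), maxfev=50000)
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        components = [
            {
                "T_m_C": float(popt[3 * j]),
                "dH_vH_kcal_mol": float(popt[3 * j + 1]),
                "scale": float(popt[3 * j + 2]),
                "T_m_se": float(perr[3 * j]),
                "dH_vH_se": float(perr[3 * j + 1]),
            }
            for j in range(self.n_components)
        ]
        components.sort(key=lambda c: c["T_m_C"])
        resid = y - model(t, *popt)
        return DSCFitResults(
            model=self,
            components=components,
            fit_quality=float(np.linalg.norm(resid)),
        )


@dataclass
class DSCFitResults:
    """Fitted two-state DSC parameters (main component first by T_m order)."""

    model: DSCTwoStateModel
    components: list[dict]
    fit_quality: float

    @property
    def _main(self) -> dict:
        # dominant component: largest area s*dH
        return max(self.components, key=lambda c: c["scale"] * c["dH_vH_kcal_mol"])

    @property
    def T_m(self) -> float:
        """Melting temperature of the dominant component, degrees Celsius."""
        return self._main["T_m_C"]

    @property
    def dH_vH(self) -> float:
        """Van't Hoff enthalpy of the dominant component, kcal/mol."""
        return self._main["dH_vH_kcal_mol"]

    @property
    def amplitude_scale(self) -> float:
        return self._main["scale"]

    def fitted_curve(self) -> np.ndarray:
        t = self.model.thermogram.temperature
        out = np.zeros_like(t)
        for c in self.components:
            out += two_state_excess_heat_capacity(
                t, c["T_m_C"], c["dH_vH_kcal_mol"], c["scale"]
            )
        return out

    def report(self) -> dict:
        return {
            "T_m_C": self.T_m,
            "dH_vH_kcal_mol": self.dH_vH,
            "amplitude_scale": self.amplitude_scale,
            "n_components": len(self.components),
            "components": self.components,
            "residual_norm": self.fit_quality,
        }

    def summary(self) -> str:
        lines = [f"DSC two-state fit ({len(self.components)} component(s))"]
        for i, c in enumerate(self.components, 1):
            lines.append(
                f"  component {i}: T_m = {c['T_m_C']:.2f} C "
                f"(+/- {c['T_m_se']:.2f}), dH_vH = {c['dH_vH_kcal_mol']:.1f} "
                f"kcal/mol, scale = {c['scale']:.3g}"
            )
        lines.append(f"  residual norm: {self.fit_quality:.3e}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        tg = self.model.thermogram
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(tg.temperature, tg.heat_signal, ".", ms=3, label="corrected signal")
        ax.plot(tg.temperature, self.fitted_curve(), "-", label="two-state fit")
        ax.axvline(self.T_m, ls=":", color="gray")
        ax.set_xlabel("temperature (deg C)")
        ax.set_ylabel("excess heat capacity (a.u.)")
        ax.legend()
        return ax


def two_state_fit(corrected: Thermogram, n_components: int = 1) -> DSCFitResults:
    """Fit a (sum of) scaled two-state transition(s) to a corrected thermogram."""
    return DSCTwoStateModel(corrected, n_components=n_components).fit()
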