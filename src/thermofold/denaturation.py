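"""Two-state chemical denaturation by the linear extrapolation model (LEM).

A reversible native (N) <-> unfolded (U) equilibrium monitored by the mean
residue ellipticity at 222 nm as guanidine hydrochloride is titrated in.
The unfolding free energy is assumed linear in denaturant,

    dG(D) = dG_global - m * D,

so the native fraction follows a sigmoid between two sloping baselines.
The default fit is the classical two-step route: estimate baselines,
convert signal to f_N, transform transition-zone points to per-point
free energies dG_i = -R T ln((1 - f_N)/f_N), and fit the line above.
The midpoint is D_1/2 = dG_global / m and the headline free energy is
reported as m * D_1/2.  A one-step global nonlinear fit of the full
sigmoid-plus-baselines model is available as ``method="global"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import R_KCAL

__all__ = [
    "DenaturationCurve",
    "TwoStateFitResults",
    "LinearExtrapolationModel",
    "mean_residue_ellipticity",
    "fraction_native",
    "point_free_energy",
    "lem_fit",
]


def mean_residue_ellipticity(
    raw_ellipticity_mdeg: float,
    concentration_M: float,
    path_length_cm: float,
    n_residues: int,
) -> float:
    """Convert a raw CD signal (millidegrees) to mean residue ellipticity.

    theta_MRE = theta_mdeg / (10 * l_cm * c_M * (n_residues - 1)),
    in deg cm^2 dmol^-1, normalizing per peptide bond.
    """
    if concentration_M <= 0 or path_length_cm <= 0:
        raise ValueError("concentration and path length must be positive")
    if n_residues < 2:
        raise ValueError("need at least 2 residues (1 peptide bond)")
    return raw_ellipticity_mdeg / (
        10.0 * path_length_cm * concentration_M * (n_residues - 1)
    )


@dataclass(frozen=True)
class Baseline:
    """A straight pre- or post-transition baseline, signal = intercept + slope*D."""

    intercept: float
    slope: float

    def __call__(self, denaturant) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(denaturant, dtype=float)


@dataclass
class DenaturationCurve:
    """Mean residue ellipticity at 222 nm vs denaturant concentration.

    ``denaturant`` in M (Gdn-HCl), non-negative and sorted; ``signal`` in
    deg cm^2 dmol^-1; ``temperature`` in kelvin.  ``equilibration_h``
    records the incubation time (metadata only, not modeled).
    """

    denaturant: np.ndarray
    signal: np.ndarray
    temperature: float = 298.15
    equilibration_h: float | None = None

    def __post_init__(self):
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.denaturant.shape != self.signal.shape or self.denaturant.ndim != 1:
            raise ValueError("denaturant and signal must be 1-D arrays of equal length")
        if len(self.denaturant) < 8:
            raise ValueError("need at least 8 points spanning baselines and transition")
        if np.any(self.denaturant < 0):
            raise ValueError("denaturant concentrations must be non-negative")
        if np.any(np.diff(self.denaturant) < 0):
            raise ValueError("denaturant grid must be sorted ascending")


def fraction_native(
    signal,
    native_baseline: Baseline,
    unfolded_baseline: Baseline,
    denaturant,
    clip_warn_band: float = 0.05,
) -> np.ndarray:
    """Native fraction from a signal between two baselines, clipped to [0, 1].

    Values outside [-band, 1+band] trigger a warning before clipping.
    """
    signal = np.asarray(signal, dtype=float)
    nat = native_baseline(denaturant)
    unf = unfolded_baseline(denaturant)
    span = nat - unf
    if np.any(np.abs(span) < 1e-12 * (np.abs(nat) + np.abs(unf) + 1.0)):
        raise ValueError("native and unfolded baselines coincide at some denaturant")
    f = (signal - unf) / span
    if np.any(f < -clip_warn_band) or np.any(f > 1.0 + clip_warn_band):
        warnings.warn("fraction native outside [-0.05, 1.05]; check baselines")
    return np.clip(f, 0.0, 1.0)


def point_free_energy(f_N: float, temperature: float) -> float:
    """Per-point unfolding free energy -R T ln((1-f_N)/f_N), kcal/mol.

    Only defined strictly inside (0, 1); endpoints carry no free-energy
    information and are excluded from the linear fit.
    """
    if not 0.0 < f_N < 1.0:
        raise ValueError("f_N must lie strictly inside (0, 1)")
    return -R_KCAL * temperature * math.log((1.0 - f_N) / f_N)


class LinearExtrapolationModel:
    """Two-state LEM model for one denaturation curve.

    Parameters
    ----------
    curve : DenaturationCurve
    transition_window : (float, float)
        f_N window whose points enter the per-point free-energy line fit.
    baseline_fraction : float
        Fraction of the denaturant range, at each end, used for the initial
        straight-line baseline estimates.
    refine_baselines : bool
        Iterate baseline estimation using model-predicted pure-state points
        (f_N > 0.999 / < 0.001); removes the small contamination of the
        flanks by the transition tails.

    ``fit(method="two_step" | "global")`` returns :class:`TwoStateFitResults`.
    """

    def __init__(
        self,
        curve: DenaturationCurve,
        transition_window: tuple[float, float] = (0.05, 0.95),
        baseline_fraction: float = 0.2,
        refine_baselines: bool = True,
    ):
        self.curve = curve
        self.transition_window = transition_window
        self.baseline_fraction = baseline_fraction
        self.refine_baselines = refine_baselines

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, temperature: float = 298.15, **kw):
        """Build from a table with columns ``denaturant_M`` and ``theta_mre``."""
        return cls(
            DenaturationCurve(
                df["denaturant_M"].to_numpy(), df["theta_mre"].to_numpy(),
                temperature=temperature,
            ),
            **kw,
        )

    # -- baseline handling -------------------------------------------------

    def _flank_baselines(self) -> tuple[Baseline, Baseline]:
        D, y = self.curve.denaturant, self.curve.signal
        span = D[-1] - D[0]
        lo = D <= D[0] + self.baseline_fraction * span
        hi = D >= D[-1] - self.baseline_fraction * span
        if lo.sum() < 2 or hi.sum() < 2:
            raise ValueError("too few points in the baseline flanks")
        nat = Baseline(*np.polyfit(D[lo], y[lo], 1)[::-1])
        unf = Baseline(*np.polyfit(D[hi], y[hi], 1)[::-1])
        return nat, unf

    def _refit_baselines(self, nat, unf, dG, m) -> tuple[Baseline, Baseline]:
        """De-contaminate the flank baselines using the current model.

        Points dominated by one state are corrected for the (small)
        population of the other state predicted by the current (dG, m)
        before re-fitting the straight line, so the sigmoid tails do not
        bias the baselines.
        """
        D, y = self.curve.denaturant, self.curve.signal
        RT = R_KCAL * self.curve.temperature
        f = 1.0 / (1.0 + np.exp(-(dG - m * D) / RT))
        nat_pts = f > 0.95
        unf_pts = f < 0.05
        if nat_pts.sum() >= 2:
            y_nat = (y[nat_pts] - (1.0 - f[nat_pts]) * unf(D[nat_pts])) / f[nat_pts]
            nat = Baseline(*np.polyfit(D[nat_pts], y_nat, 1)[::-1])
        if unf_pts.sum() >= 2:
            y_unf = (y[unf_pts] - f[unf_pts] * nat(D[unf_pts])) / (1.0 - f[unf_pts])
            unf = Baseline(*np.polyfit(D[unf_pts], y_unf, 1)[::-1])
        return nat, unf

    # -- fitting -----------------------------------------------------------

    def _two_step_pass(self, nat, unf, dG_m=None, warn: bool = False):
        """One baseline -> f_N -> free-energy-line pass.

        When a previous (dG, m) estimate is available the transition zone
        is selected on the *model-predicted* f_N, so a noisy baseline
        point cannot enter the line fit as a high-leverage outlier.
        """
        D = self.curve.denaturant
        T = self.curve.temperature
        band = 0.05 if warn else np.inf
        f = fraction_native(self.curve.signal, nat, unf, D, clip_warn_band=band)
        if dG_m is None:
            f_sel = f
        else:
            RT = R_KCAL * T
            f_sel = 1.0 / (1.0 + np.exp(-(dG_m[0] - dG_m[1] * D) / RT))
        wlo, whi = self.transition_window
        in_zone = (f_sel >= wlo) & (f_sel <= whi) & (f > 0.0) & (f < 1.0)
        if in_zone.sum() < 4:
            raise ValueError(
                "fewer than 4 transition-zone points; curve does not sample "
                "the unfolding transition"
            )
        dG_pts = np.array([point_free_energy(fi, T) for fi in f[in_zone]])
        # inverse-variance weights: for signal noise sigma, the per-point
        # free-energy noise scales as 1/(f(1-f)), so weight by f(1-f)
        w = f_sel[in_zone] * (1.0 - f_sel[in_zone])
        slope, intercept = np.polyfit(D[in_zone], dG_pts, 1, w=w)
        return f, in_zone, dG_pts, intercept, -slope

    def fit(self, method: str = "two_step") -> "TwoStateFitResults":
        if method not in ("two_step", "global"):
            raise ValueError("method must be 'two_step' or 'global'")
        nat, unf = self._flank_baselines()
        f, in_zone, dG_pts, dG0, m = self._two_step_pass(nat, unf)
        if self.refine_baselines:
            for _ in range(8):
                nat, unf = self._refit_baselines(nat, unf, dG0, m)
                prev = (dG0, m)
                f, in_zone, dG_pts, dG0, m = self._two_step_pass(nat, unf, dG_m=prev)
                if abs(dG0 - prev[0]) < 1e-10 and abs(m - prev[1]) < 1e-10:
                    break
            f, in_zone, dG_pts, dG0, m = self._two_step_pass(nat, unf, dG_m=(dG0, m), warn=True)

        if method == "global":
            nat, unf, dG0, m = self._global_fit(nat, unf, dG0, m)
            f = self._model_fraction(dG0, m)
            in_zone = (f >= self.transition_window[0]) & (f <= self.transition_window[1])
            dG_pts = dG0 - m * self.curve.denaturant[in_zone]

        if m <= 0:
            raise ValueError("fitted m-value is non-positive; no unfolding transition")
        midpoint = dG0 / m
        trans_f = f[in_zone]
        if np.any(np.diff(trans_f) > 0.05):
            warnings.warn("non-monotone transition region")
        return TwoStateFitResults(
            model=self,
            method=method,
            dG_global=m * midpoint,
            m_value=m,
            midpoint=midpoint,
            native_baseline=nat,
            unfolded_baseline=unf,
            fraction_native=f,
            transition_mask=in_zone,
            point_dG=dG_pts,
        )

    def _model_fraction(self, dG, m):
        RT = R_KCAL * self.curve.temperature
        return 1.0 / (1.0 + np.exp(-(dG - m * self.curve.denaturant) / RT))

    def _global_fit(self, nat, unf, dG0, m0):
        D, y = self.curve.denaturant, self.curve.signal
        RT = R_KCAL * self.curve.temperature

        def model(D, dG, m, an, bn, au, bu):
            f = 1.0 / (1.0 + np.exp(-(dG - m * D) / RT))
            return f * (an + bn * D) + (1 - f) * (au + bu * D)

        p0 = (dG0, m0, nat.intercept, nat.slope, unf.intercept, unf.slope)
        popt, _ = curve_fit(model, D, y, p0=p0, maxfev=50000)
        dG, m, an, bn, au, bu = popt
        return Baseline(an, bn), Baseline(au, bu), float(dG), float(m)


@dataclass
class TwoStateFitResults:
    """Fitted LEM parameters and per-point diagnostics.

    ``dG_global`` (kcal/mol) is reported as ``m_value * midpoint``, which
    for the two-step route equals the intercept of the free-energy line by
    construction.
    """

    model: LinearExtrapolationModel
    method: str
    dG_global: float
    m_value: float
    midpoint: float
    native_baseline: Baseline
    unfolded_baseline: Baseline
    fraction_native: np.ndarray
    transition_mask: np.ndarray
    point_dG: np.ndarray

    @property
    def fraction_unfolded(self) -> np.ndarray:
        return 1.0 - self.fraction_native

    def point_table(self) -> pd.DataFrame:
        c = self.model.curve
        df = pd.DataFrame(
            {
                "denaturant_M": c.denaturant,
                "theta_mre": c.signal,
                "f_N": self.fraction_native,
                "f_U": self.fraction_unfolded,
                "in_transition_zone": self.transition_mask,
                "dG_point_kcal_mol": np.nan,
            }
        )
        df.loc[self.transition_mask, "dG_point_kcal_mol"] = self.point_dG
        return df

    def report(self) -> dict:
        return {
            "method": self.method,
            "dG_kcal_mol": self.dG_global,
            "m_kcal_mol_M": self.m_value,
            "midpoint_M": self.midpoint,
            "native_baseline": [self.native_baseline.intercept, self.native_baseline.slope],
            "unfolded_baseline": [self.unfolded_baseline.intercept, self.unfolded_baseline.slope],
            "temperature_K": self.model.curve.temperature,
            "n_transition_points": int(self.transition_mask.sum()),
        }

    def summary(self) -> str:
        return "\n".join(
            [
                f"Two-state LEM fit ({self.method})",
                f"  dG_global : {self.dG_global:.3f} kcal/mol",
                f"  m-value   : {self.m_value:.3f} kcal mol^-1 M^-1",
                f"  midpoint  : {self.midpoint:.3f} M",
                f"  baselines : native {self.native_baseline.intercept:.1f} "
                f"{self.native_baseline.slope:+.2f}*D, unfolded "
                f"{self.unfolded_baseline.intercept:.1f} "
                f"{self.unfolded_baseline.slope:+.2f}*D",
                f"  transition points: {int(self.transition_mask.sum())}",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        c = self.model.curve
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(c.denaturant, c.signal, "o", label="observed")
        dd = np.linspace(c.denaturant[0], c.denaturant[-1], 200)
        RT = R_KCAL * c.temperature
        f = 1.0 / (1.0 + np.exp(-(self.dG_global - self.m_value * dd) / RT))
        y = f * self.native_baseline(dd) + (1 - f) * self.unfolded_baseline(dd)
        ax.plot(dd, y, "-", label="two-state model")
        ax.axvline(self.midpoint, ls=":", color="gray")
        ax.set_xlabel("[Gdn-HCl] (M)")
        ax.set_ylabel(r"$[\theta]_{222}$ (deg cm$^2$ dmol$^{-1}$)")
        ax.legend()
        return ax


def lem_fit(curve: DenaturationCurve, method: str = "two_step", **kw) -> TwoStateFitResults:
    """Fit the linear extrapolation model to a denaturation curve."""
    return LinearExtrapolationModel(curve, **kw).fit(method=method)
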