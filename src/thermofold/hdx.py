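"""H/D-exchange kinetics: peak-decay fitting, protection energies, EX1/EX2.

The observable is the height of a residue's HSQC cross peak as a function
of time after dissolution in D2O.  For an amide exchanging with rate
``k_HDX`` the height decays as ``I(t) = A exp(-k t)``; in the EX2 limit
``k_HDX = K_unfold * k_rc`` so the equilibrium constant of the local
opening reaction is ``K_unfold = k_HDX / k_rc`` and

    dG_local = -R T ln(K_unfold)        (kcal/mol, R = 1.987e-3)

Amides whose peaks do not measurably decay over the whole observation
window are *hyperprotected*: ``k_HDX`` cannot be determined, only an upper
bound set by the detection limit of the experiment.

EX1 vs EX2 is diagnosed from measurements at two pD values: in the EX2
limit log10(k_HDX) tracks pD one-for-one (base catalysis), in the EX1
limit ``k_HDX = k_unfold`` is pD-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import R_KCAL

__all__ = [
    "PeakDecaySeries",
    "ExchangeRateEstimate",
    "ProtectionResult",
    "RegimeClassification",
    "PeakDecayModel",
    "fit_decay",
    "protection_energy",
    "classify_regime",
    "count_survivors",
]


@dataclass
class PeakDecaySeries:
    """Per-residue peak-height time series at one pD/temperature.

    ``times`` are minutes (strictly increasing, first point >= 0);
    ``heights`` are peak heights, normalized to the first post-exchange
    spectrum unless ``normalized=True`` already.
    """

    residue_index: int
    residue: str
    times: np.ndarray
    heights: np.ndarray
    pD: float
    temperature: float = 298.0
    normalized: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.heights.shape:
            raise ValueError("times and heights must be 1-D arrays of equal length")
        if len(self.times) < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0:
            raise ValueError("times must start at or after 0")
        if np.any(self.heights < 0):
            raise ValueError("heights must be non-negative")

    def normalized_heights(self) -> np.ndarray:
        """Heights anchored to the first post-exchange spectrum."""
        if self.normalized:
            return self.heights
        first = self.heights[0]
        if first == 0:
            raise ValueError("cannot normalize: first height is zero")
        return self.heights / first

    @property
    def label(self) -> str:
        return f"{self.residue}{self.residue_index}"


@dataclass(frozen=True)
class ExchangeRateEstimate:
    """Fitted exchange rate for one amide.

    ``k_HDX`` is NaN when ``hyperprotected``; then ``resolvable_lower_bound``
    is the smallest rate the observation window could have detected.
    """

    residue_index: int
    residue: str
    k_HDX: float
    confidence_interval: tuple[float, float]
    amplitude: float
    fit_quality: float
    hyperprotected: bool = False
    resolvable_lower_bound: float | None = None

    @property
    def resolvable(self) -> bool:
        """True when the rate is determined: positive, finite, and with a
        95% interval excluding zero (a peak already gone at the first
        spectrum yields an unconstrained fit, not a rate)."""
        return (
            not self.hyperprotected
            and np.isfinite(self.k_HDX)
            and self.k_HDX > 0
            and self.confidence_interval[0] > 0
        )


@dataclass(frozen=True)
class ProtectionResult:
    """Local-unfolding thermodynamics for one amide."""

    residue_index: int
    residue: str
    K_unfold: float
    dG_local: float
    temperature: float


@dataclass(frozen=True)
class RegimeClassification:
    """EX1/EX2/intermediate label from a paired-pD comparison."""

    residue_index: int
    residue: str
    label: str
    log_rate_shift: float


class PeakDecayModel:
    """Single-exponential decay model ``I(t) = A exp(-k t)`` for one peak.

    Parameters
    ----------
    series : PeakDecaySeries
        The observed decay.  Heights are normalized to the first spectrum.
    plateau : bool
        Add a floating baseline term ``I(t) = A exp(-k t) + c``.  Off by
        default: fully exchanged amides vanish in D2O.
    detection_limit : float
        Peaks whose height never reaches this fraction of the reference
        intensity are treated as already exchanged out before the first
        spectrum: no rate can be determined from them.

    ``fit()`` returns a :class:`PeakDecayResults`.
    """

    #: final/first height ratio above which a flat series is called
    #: hyperprotected (together with a k interval containing zero).
    HYPER_HEIGHT_RATIO = 0.8

    def __init__(self, series: PeakDecaySeries, plateau: bool = False,
                 detection_limit: float = 0.01):
        self.series = series
        self.plateau = plateau
        self.detection_limit = detection_limit

    @classmethod
    def from_arrays(cls, times, heights, residue_index=0, residue="X",
                    pD=float("nan"), temperature=298.0, **kw) -> "PeakDecayModel":
        return cls(PeakDecaySeries(residue_index, residue, np.asarray(times),
                                   np.asarray(heights), pD, temperature), **kw)

    def _initial_guess(self, t, y):
        pos = y > max(1e-3, 0.05 * y.max(initial=1.0))
        if pos.sum() >= 2:
            # log-linear slope on the clearly positive points
            slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
            k0 = max(-slope, 1e-9)
        else:
            k0 = 1.0 / max(t[-1], 1.0)
        return float(y[0] if y[0] > 0 else 1.0), float(k0)

    def fit(self) -> "PeakDecayResults":
        s = self.series
        t = s.times
        y = s.normalized_heights() if np.any(s.heights > 0) else s.heights
        if np.all(y == 0):
            raise ValueError("all-zero heights: nothing to fit")
        if y.max() < self.detection_limit:
            # peak already exchanged out before the first spectrum
            return PeakDecayResults(
                model=self,
                params=np.array([0.0, np.nan]),
                bse=np.array([np.nan, np.nan]),
                k_HDX=np.nan,
                conf_int=(np.nan, np.nan),
                hyperprotected=False,
                resolvable_lower_bound=None,
                fit_quality=np.nan,
            )
        a0, k0 = self._initial_guess(t, y)

        if self.plateau:
            def model(t, a, k, c):
                return a * np.exp(-k * t) + c
            p0, bounds = (a0, k0, 0.0), ([0, 0, -1], [np.inf, np.inf, 1])
        else:
            def model(t, a, k):
                return a * np.exp(-k * t)
            p0, bounds = (a0, k0), ([0, 0], [np.inf, np.inf])

        popt, pcov = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000)
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        k, k_sd = float(popt[1]), float(perr[1])
        ci = (k - 1.96 * k_sd, k + 1.96 * k_sd)
        resid = y - model(t, *popt)
        fit_quality = float(np.linalg.norm(resid))

        t_span = t[-1] - t[0]
        bound = math.log(1.0 / self.HYPER_HEIGHT_RATIO) / t_span if t_span > 0 else np.nan
        # hyperprotected: essentially no decay over the window AND the rate
        # is either indistinguishable from zero or below the smallest rate
        # the window could resolve
        hyper = y[-1] / y[0] > self.HYPER_HEIGHT_RATIO and (ci[0] <= 0.0 or k < bound)
        return PeakDecayResults(
            model=self,
            params=np.asarray(popt, dtype=float),
            bse=np.asarray(perr, dtype=float),
            k_HDX=np.nan if hyper else k,
            conf_int=ci,
            hyperprotected=hyper,
            resolvable_lower_bound=bound if hyper else None,
            fit_quality=fit_quality,
        )


@dataclass
class PeakDecayResults:
    """Results of a :class:`PeakDecayModel` fit."""

    model: PeakDecayModel
    params: np.ndarray
    bse: np.ndarray
    k_HDX: float
    conf_int: tuple[float, float]
    hyperprotected: bool
    resolvable_lower_bound: float | None
    fit_quality: float

    @property
    def amplitude(self) -> float:
        return float(self.params[0])

    def as_estimate(self) -> ExchangeRateEstimate:
        s = self.model.series
        return ExchangeRateEstimate(
            residue_index=s.residue_index,
            residue=s.residue,
            k_HDX=self.k_HDX,
            confidence_interval=self.conf_int,
            amplitude=self.amplitude,
            fit_quality=self.fit_quality,
            hyperprotected=self.hyperprotected,
            resolvable_lower_bound=self.resolvable_lower_bound,
        )

    def summary(self) -> str:
        s = self.model.series
        lines = [
            f"Peak decay fit: {s.label}  (pD {s.pD}, T {s.temperature:.2f} K)",
            f"  n points          : {len(s.times)}",
            f"  amplitude A       : {self.amplitude:.4f} +/- {self.bse[0]:.4f}",
        ]
        if self.hyperprotected:
            lines += [
                "  k_HDX             : hyperprotected (no measurable decay)",
                f"  detectable k >=   : {self.resolvable_lower_bound:.3e} /min",
            ]
        else:
            lines += [
                f"  k_HDX             : {self.k_HDX:.4e} /min",
                f"  95% CI            : [{self.conf_int[0]:.4e}, {self.conf_int[1]:.4e}]",
            ]
        lines.append(f"  residual norm     : {self.fit_quality:.4e}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted curve on a log time axis (requires matplotlib)."""
        import matplotlib.pyplot as plt

        s = self.model.series
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(s.times, s.normalized_heights(), "o", label="observed")
        tt = np.linspace(s.times[0], s.times[-1], 200)
        a = self.amplitude
        k = 0.0 if self.hyperprotected else self.k_HDX
        ax.plot(tt, a * np.exp(-k * tt), "-", label="fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("normalized peak height")
        ax.set_title(s.label)
        ax.legend()
        return ax


def fit_decay(series: PeakDecaySeries, plateau: bool = False) -> ExchangeRateEstimate:
    """Least-squares fit of ``A exp(-k t)`` to one peak-decay series."""
    return PeakDecayModel(series, plateau=plateau).fit().as_estimate()


def protection_energy(
    k_HDX: float,
    k_rc: float,
    temperature: float,
    residue_index: int = 0,
    residue: str = "X",
) -> ProtectionResult:
    """Local-unfolding equilibrium constant and free energy (EX2 limit).

    ``K_unfold = k_HDX / k_rc`` and ``dG_local = -R T ln(K_unfold)``.
    """
    if k_HDX <= 0 or not np.isfinite(k_HDX):
        raise ValueError("k_HDX must be positive and finite")
    if k_rc <= 0 or not np.isfinite(k_rc):
        raise ValueError("k_rc must be positive and finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    K = k_HDX / k_rc
    dG = -R_KCAL * temperature * math.log(K)
    return ProtectionResult(residue_index, residue, K, dG, temperature)


def classify_regime(
    estimate_low_pD: ExchangeRateEstimate,
    estimate_high_pD: ExchangeRateEstimate,
    delta_pD: float,
    tolerance: float = 0.3,
) -> RegimeClassification:
    """EX1/EX2 diagnosis from the log10 rate shift between two pD values.

    EX2 if the shift matches ``delta_pD`` within ``tolerance`` log units,
    EX1 if it matches 0; anything else (including ties) is intermediate.
    """
    if delta_pD <= 0:
        raise ValueError("delta_pD must be positive")
    for est in (estimate_low_pD, estimate_high_pD):
        if not est.resolvable:
            raise ValueError(
                f"residue {est.residue}{est.residue_index}: hyperprotected or "
                "unresolvable rate cannot be regime-classified"
            )
    shift = math.log10(estimate_high_pD.k_HDX) - math.log10(estimate_low_pD.k_HDX)
    is_ex2 = abs(shift - delta_pD) <= tolerance
    is_ex1 = abs(shift) <= tolerance
    if is_ex2 and not is_ex1:
        label = "EX2"
    elif is_ex1 and not is_ex2:
        label = "EX1"
    else:
        label = "intermediate"
    return RegimeClassification(
        residue_index=estimate_low_pD.residue_index,
        residue=estimate_low_pD.residue,
        label=label,
        log_rate_shift=shift,
    )


def count_survivors(
    series_set: Iterable[PeakDecaySeries],
    at_time: float,
    threshold: float = 0.1,
) -> int:
    """Number of residues whose normalized height at ``at_time`` >= threshold.

    Heights are linearly interpolated on each series' own time grid;
    ``at_time`` must lie inside every observed range.
    """
    count = 0
    for s in series_set:
        if not (s.times[0] <= at_time <= s.times[-1]):
            raise ValueError(
                f"t={at_time} min outside observed range "
                f"[{s.times[0]}, {s.times[-1]}] for {s.label}"
            )
        h = float(np.interp(at_time, s.times, s.normalized_heights()))
        if h >= threshold:
            count += 1
    return count


def protection_table(
    estimates: Sequence[ExchangeRateEstimate],
    k_rc_map: dict[int, float],
    temperature: float,
) -> pd.DataFrame:
    """Per-residue table of k_HDX, K_unfold and dG_local.

    Hyperprotected residues appear with NaN thermodynamics and the
    ``hyperprotected`` flag set; residues lacking an intrinsic rate are
    skipped.
    """
    rows = []
    for est in estimates:
        if est.residue_index not in k_rc_map:
            continue
        row = {
            "residue_index": est.residue_index,
            "residue": est.residue,
            "k_HDX_per_min": est.k_HDX,
            "k_rc_per_min": k_rc_map[est.residue_index],
            "hyperprotected": est.hyperprotected,
            "K_unfold": np.nan,
            "dG_local_kcal_mol": np.nan,
        }
        if est.resolvable:
            pr = protection_energy(
                est.k_HDX, k_rc_map[est.residue_index], temperature,
                est.residue_index, est.residue,
            )
            row["K_unfold"] = pr.K_unfold
            row["dG_local_kcal_mol"] = pr.dG_local
        rows.append(row)
    return pd.DataFrame(rows).sort_values("residue_index").reset_index(drop=True)
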