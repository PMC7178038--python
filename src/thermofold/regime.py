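"""Global-vs-local unfolding regime classification.

An amide whose local-opening free energy approaches the global unfolding
free energy can only exchange through the global unfolding reaction.  The
decision rule: a residue is in the global-unfolding regime when

    dG_local > threshold_fraction * dG_global     (strict inequality),

with ``threshold_fraction`` defaulting to 0.85.  Hyperprotected residues
(no measurable exchange) are assigned ``dG_local = dG_global`` and are in
the regime by definition, at any threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ResidueRegime", "RegimeReport", "classify_global_regime"]


@dataclass(frozen=True)
class ResidueRegime:
    residue_index: int
    dG_local: float
    in_global_regime: bool
    hyperprotected: bool


@dataclass
class RegimeReport:
    """Per-residue regime labels against one global free energy."""

    threshold_fraction: float
    dG_global: float
    residues: list[ResidueRegime] = field(default_factory=list)

    @property
    def in_regime(self) -> list[int]:
        return [r.residue_index for r in self.residues if r.in_global_regime]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.residues])
        df["dG_global_kcal_mol"] = self.dG_global
        df["threshold_kcal_mol"] = self.threshold_fraction * self.dG_global
        return df


def classify_global_regime(
    dG_local_map: dict[int, float],
    dG_global: float,
    threshold_fraction: float = 0.85,
    hyperprotected: set[int] | None = None,
    dG_lower_bounds: dict[int, float] | None = None,
) -> RegimeReport:
    """Label residues whose local unfolding is identical to global unfolding.

    Parameters
    ----------
    dG_local_map : dict
        Residue index -> dG_local (kcal/mol).  Negative values are excluded
        with a warning; NaN entries for hyperprotected residues are allowed.
    dG_global : float
        Global unfolding free energy (kcal/mol), must be positive.
    threshold_fraction : float
        Fraction of dG_global defining the regime boundary, in (0, 1).
    hyperprotected : set
        Residues with no measurable exchange; assigned dG_local = dG_global
        and always in the regime.
    dG_lower_bounds : dict, optional
        When given, a residue additionally needs its lower confidence bound
        to clear the threshold (uncertainty-aware variant).
    """
    if dG_global <= 0:
        raise ValueError("dG_global must be positive")
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    hyperprotected = hyperprotected or set()
    threshold = threshold_fraction * dG_global

    report = RegimeReport(threshold_fraction=threshold_fraction, dG_global=dG_global)
    indices = sorted(set(dG_local_map) | hyperprotected)
    for idx in indices:
        if idx in hyperprotected:
            report.residues.append(ResidueRegime(idx, dG_global, True, True))
            continue
        dg = dG_local_map[idx]
        if not np.isfinite(dg):
            continue
        if dg < 0:
            warnings.warn(f"residue {idx}: negative dG_local excluded")
            continue
        in_regime = dg > threshold
        if in_regime and dG_lower_bounds is not None:
            in_regime = dG_lower_bounds.get(idx, dg) > threshold
        report.residues.append(ResidueRegime(idx, dg, in_regime, False))
    return report
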