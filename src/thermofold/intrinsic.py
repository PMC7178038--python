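"""Random-coil (intrinsic) backbone-amide exchange rates.

Computes per-residue intrinsic H->D exchange rate constants ``k_rc`` for an
unstructured chain as a function of sequence context, pD and temperature.
The reference rates are for poly-DL-alanine in D2O; the inductive and steric
effects of the two flanking side chains are applied as multiplicative
correction factors per catalysis channel (acid, base, water).  Both the
reference rates and the correction factors ship with the package as a
versioned data resource (``data/intrinsic_exchange_factors.tsv`` and
``data/intrinsic_exchange_reference.json``); see the file headers for
provenance.

The temperature dependence of each channel is Arrhenius,

    k(T) = k(T_ref) * exp(-(E_a/R) (1/T - 1/T_ref)),

with the channel activation energy expressed as ``E_a/R`` in kelvin.

Rates are per minute.  Proline (no amide proton after the correction-scheme
convention is applied to its tertiary amide) and the first residue of a
chain (free alpha-amino group, no backbone amide) have no observable
exchange signal and are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

STANDARD_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Marker for a chain terminus in a residue context.
TERMINUS = "-"

_CHANNELS = ("acid", "base", "water")


class NoAmideError(ValueError):
    """Raised for residues without an observable backbone amide signal."""


def _load_resource_text(name: str) -> str:
    return resources.files("thermofold.data").joinpath(name).read_text()


def _load_tables() -> tuple[pd.DataFrame, dict]:
    factors = pd.read_csv(
        resources.files("thermofold.data").joinpath("intrinsic_exchange_factors.tsv"),
        sep="\t",
        comment="#",
        index_col="residue",
    )
    ref = json.loads(_load_resource_text("intrinsic_exchange_reference.json"))
    return factors, ref


_FACTORS, _REFERENCE = _load_tables()


@dataclass(frozen=True)
class ExchangeConditions:
    """Solvent and temperature conditions for intrinsic-rate evaluation.

    Parameters
    ----------
    pD : float
        Direct pD reading of the D2O buffer (the 5-7 base-catalysed window
        is the intended domain).  Set ``from_meter_reading=True`` if the
        value is an uncorrected pH-meter reading; the standard +0.4 glass
        electrode isotope correction is then applied.
    temperature : float
        Sample temperature in kelvin.
    reference_temperature : float
        Temperature of the packaged reference rates, kelvin.
    activation_energy_over_R : mapping
        Per-channel Arrhenius slope ``E_a/R`` in kelvin.
    """

    pD: float
    temperature: float = 298.0
    reference_temperature: float = float(_REFERENCE["reference_temperature_K"])
    activation_energy_over_R: Mapping[str, float] = field(
        default_factory=lambda: dict(_REFERENCE["activation_energy_over_R_K"])
    )
    from_meter_reading: bool = False

    def __post_init__(self):
        if not np.isfinite(self.pD):
            raise ValueError("pD must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.reference_temperature <= 0:
            raise ValueError("reference temperature must be positive (kelvin)")

    @property
    def corrected_pD(self) -> float:
        """pD on the corrected scale (meter reading + 0.4 if requested)."""
        return self.pD + 0.4 if self.from_meter_reading else self.pD


@dataclass(frozen=True)
class ResidueContext:
    """One residue and its sequence neighbors.

    ``left_neighbor``/``right_neighbor`` are one-letter codes or the
    terminus marker ``"-"``.  ``position`` is the 1-based sequence index.
    """

    residue: str
    left_neighbor: str
    right_neighbor: str
    position: int = 2

    def __post_init__(self):
        for code, what in ((self.residue, "residue"),
                           (self.left_neighbor, "left neighbor"),
                           (self.right_neighbor, "right neighbor")):
            if code != TERMINUS and code not in STANDARD_AMINO_ACIDS:
                raise ValueError(f"unknown {what} code {code!r}")


@dataclass(frozen=True)
class IntrinsicRate:
    """Intrinsic exchange rate with its per-channel breakdown (per minute)."""

    k_rc: float
    channel_contributions: Mapping[str, float]

    def __post_init__(self):
        if self.k_rc <= 0:
            raise ValueError("k_rc must be positive")


def _factor(table_row: str, column: str) -> float:
    try:
        return float(_FACTORS.at[table_row, column])
    except KeyError as exc:
        raise ValueError(f"no correction factor for residue {table_row!r}") from exc


def _channel_log_factors(context: ResidueContext) -> dict[str, float]:
    """Summed log10 neighbor corrections per channel for one amide."""
    own = context.residue
    prev = context.left_neighbor
    log_acid = _factor(own, "acid_left")
    log_base = _factor(own, "base_left")
    if prev == TERMINUS:
        # residue 2: the preceding "residue" is the free alpha-amino group
        log_acid += _factor("N_TERM", "acid_right")
        log_base += _factor("N_TERM", "base_right")
    else:
        log_acid += _factor(prev, "acid_right")
        log_base += _factor(prev, "base_right")
    if context.right_neighbor == TERMINUS:
        # last residue: its own carboxylate adds a left-type factor
        log_acid += _factor("C_TERM", "acid_left")
        log_base += _factor("C_TERM", "base_left")
    # the water channel follows the base-channel correction factors
    return {"acid": log_acid, "base": log_base, "water": log_base}


def krc_base(context: ResidueContext, conditions: ExchangeConditions) -> IntrinsicRate:
    """Intrinsic rate at the reference temperature for one amide.

    Returns the poly-DL-alanine reference rate at the given pD, multiplied
    by the packaged left/right neighbor correction factors, with the acid,
    base and water catalysis channels reported separately.

    Raises
    ------
    NoAmideError
        For proline or a chain-initial residue (no observable amide).
    ValueError
        For unknown residue codes.
    """
    if context.residue not in STANDARD_AMINO_ACIDS:
        raise ValueError(f"unknown residue code {context.residue!r}")
    if context.residue == "P":
        raise NoAmideError("proline has no observable backbone amide signal")
    if context.position == 1:
        raise NoAmideError("chain-initial residue has no backbone amide")
    pD = conditions.corrected_pD
    logs = _channel_log_factors(context)
    channels = {
        "acid": 10.0 ** (_REFERENCE["log10_k_acid"] + logs["acid"] - pD),
        "base": 10.0 ** (_REFERENCE["log10_k_base"] + logs["base"] + pD - _REFERENCE["pK_D2O"]),
        "water": 10.0 ** (_REFERENCE["log10_k_water"] + logs["water"]),
    }
    return IntrinsicRate(k_rc=sum(channels.values()), channel_contributions=channels)


def temperature_correct(
    k_ref: float, conditions: ExchangeConditions, channel: str = "base"
) -> float:
    """Arrhenius-scale a reference-temperature rate to ``conditions.temperature``.

    ``channel`` selects the activation energy (``E_a/R`` in kelvin) from the
    conditions; pass a numeric value as ``conditions.activation_energy_over_R
    = {"base": value}`` to override.
    """
    if k_ref <= 0:
        raise ValueError("k_ref must be positive")
    if conditions.temperature <= 0:
        raise ValueError("temperature must be positive")
    ea_over_r = float(conditions.activation_energy_over_R[channel])
    t, t_ref = conditions.temperature, conditions.reference_temperature
    return k_ref * np.exp(-ea_over_r * (1.0 / t - 1.0 / t_ref))


def _corrected_rate(context: ResidueContext, conditions: ExchangeConditions) -> IntrinsicRate:
    base = krc_base(context, conditions)
    channels = {
        ch: temperature_correct(k, conditions, channel=ch)
        for ch, k in base.channel_contributions.items()
    }
    return IntrinsicRate(k_rc=sum(channels.values()), channel_contributions=channels)


def iter_contexts(sequence: str) -> Iterator[ResidueContext]:
    """Residue contexts for every position with an observable amide."""
    seq = sequence.upper()
    for i, aa in enumerate(seq, start=1):
        if i == 1 or aa == "P":
            continue
        yield ResidueContext(
            residue=aa,
            left_neighbor=seq[i - 2],
            right_neighbor=seq[i] if i < len(seq) else TERMINUS,
            position=i,
        )


def krc_profile(sequence: str, conditions: ExchangeConditions) -> dict[int, IntrinsicRate]:
    """Temperature-corrected intrinsic rates for a whole sequence.

    One entry per residue with an observable amide; position 1 and prolines
    are absent.  Keys are 1-based positions.
    """
    seq = sequence.upper().strip()
    if len(seq) < 2:
        raise ValueError("sequence must contain at least 2 residues")
    bad = set(seq) - STANDARD_AMINO_ACIDS
    if bad:
        raise ValueError(f"unknown residue codes in sequence: {sorted(bad)}")
    return {ctx.position: _corrected_rate(ctx, conditions) for ctx in iter_contexts(seq)}


def profile_frame(sequence: str, conditions: ExchangeConditions) -> pd.DataFrame:
    """``krc_profile`` as a tidy table (one row per observable amide)."""
    rows = []
    seq = sequence.upper().strip()
    for pos, rate in krc_profile(seq, conditions).items():
        rows.append(
            {
                "residue_index": pos,
                "residue": seq[pos - 1],
                "k_rc_per_min": rate.k_rc,
                **{f"k_{ch}_per_min": v for ch, v in rate.channel_contributions.items()},
            }
        )
    return pd.DataFrame(rows)
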