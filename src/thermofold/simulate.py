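"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators produce exactly the inputs the analysis modules consume —
peak-decay series, denaturation curves, thermograms, coordinate ensembles —
from forward models with known parameters, so parameter recovery can be
tested end to end without any measured spectra.

Forward models
--------------
HDX (EX2):   k_HDX = exp(-dG_local / RT) * k_rc(context, pD, T); by default
             only the base-catalysed channel of k_rc is used, matching the
             base-catalysed window (pD 5-7) where log10 k_HDX rises one
             unit per pD unit.
HDX (EX1):   k_HDX = k_unfold, independent of pD.
Denaturation: f_N(D) = 1 / (1 + exp(-(dG - m D)/RT)), signal interpolates
             between sloping native/unfolded baselines.
DSC:         scaled two-state excess heat capacity plus a polynomial
             baseline.
Ensembles:   idealized four-helix-bundle backbone, per-model isotropic
             Gaussian jitter, then a random rigid transform.

Noise is multiplicative Gaussian on peak heights and additive Gaussian on
CD/DSC signals.  All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .constants import R_KCAL
from .denaturation import Baseline, DenaturationCurve
from .dsc import Thermogram, two_state_excess_heat_capacity
from .geometry import Ensemble, StructureModel
from .hdx import PeakDecaySeries
from .intrinsic import ExchangeConditions, krc_profile

__all__ = [
    "HDXSimulationSpec",
    "DenaturationSimulationSpec",
    "DSCSimulationSpec",
    "simulate_hdx",
    "simulate_denaturation",
    "simulate_thermogram",
    "simulate_helix_bundle_ensemble",
    "synthetic_acp_sequence",
    "acp_like_preset",
]


def synthetic_acp_sequence() -> str:
    """The packaged synthetic 81-residue ACP-like sequence.

    A constructed stand-in for a hyperthermophilic acyl-carrier-protein
    sequence (not a deposited sequence): four-helix-protein length, the
    hydrophobic-core and ionic-cluster residue identities at their
    conventional positions, and a charged-residue composition of
    10 Glu / 11 Asp / 1 Arg / 8 Lys.
    """
    lines = (
        resources.files("thermofold.data")
        .joinpath("acp_like_synthetic.fasta")
        .read_text()
        .splitlines()
    )
    return "".join(line.strip() for line in lines if not line.startswith(">"))


# ---------------------------------------------------------------------------
# H/D exchange


@dataclass
class HDXSimulationSpec:
    """Ground truth for a simulated H/D-exchange experiment.

    ``dG_local`` maps 1-based residue positions to local-unfolding free
    energies (kcal/mol); positions in ``hyperprotected`` get no decay at
    all; positions in ``mechanism_ex1`` exchange with the pD-independent
    rate ``k_unfold[pos]``.  Residues of the sequence absent from
    ``dG_local`` (and not hyperprotected/EX1) are not emitted.
    """

    sequence: str
    dG_local: dict[int, float]
    pD_values: tuple[float, ...] = (5.5, 6.5)
    temperature: float = 298.15
    times: np.ndarray = field(
        default_factory=lambda: np.arange(10.0, 1001.0, 10.0)
    )
    noise_sd: float = 0.0
    hyperprotected: frozenset[int] = frozenset()
    mechanism_ex1: frozenset[int] = frozenset()
    k_unfold: dict[int, float] = field(default_factory=dict)
    base_channel_only: bool = True
    seed: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        missing = self.mechanism_ex1 - set(self.k_unfold)
        if missing:
            raise ValueError(f"EX1 residues without k_unfold: {sorted(missing)}")


def _ex2_rate(dG: float, k_rc_channels, temperature: float, base_only: bool) -> float:
    K_unfold = math.exp(-dG / (R_KCAL * temperature))
    k_rc = (
        k_rc_channels.channel_contributions["base"]
        if base_only
        else k_rc_channels.k_rc
    )
    return K_unfold * k_rc


def simulate_hdx(spec: HDXSimulationSpec) -> dict[float, list[PeakDecaySeries]]:
    """Simulate peak-decay series for every pD in the spec.

    Returns a mapping pD -> list of :class:`PeakDecaySeries`, one per
    simulated residue, with multiplicative Gaussian height noise.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[float, list[PeakDecaySeries]] = {}
    seq = spec.sequence.upper()
    positions = sorted(set(spec.dG_local) | spec.hyperprotected | spec.mechanism_ex1)
    for pD in spec.pD_values:
        conditions = ExchangeConditions(pD=pD, temperature=spec.temperature)
        rates = krc_profile(seq, conditions)
        series = []
        for pos in positions:
            if pos in spec.hyperprotected:
                k = 0.0
            elif pos in spec.mechanism_ex1:
                k = float(spec.k_unfold[pos])
            else:
                if pos not in rates:
                    raise ValueError(f"position {pos} has no observable amide")
                k = _ex2_rate(
                    spec.dG_local[pos], rates[pos], spec.temperature,
                    spec.base_channel_only,
                )
            with np.errstate(under="ignore"):
                heights = np.exp(-k * spec.times)
            if spec.noise_sd > 0:
                heights = heights * (1.0 + rng.normal(0.0, spec.noise_sd, heights.shape))
            heights = np.clip(heights, 0.0, None)
            series.append(
                PeakDecaySeries(
                    residue_index=pos,
                    residue=seq[pos - 1],
                    times=spec.times.copy(),
                    heights=heights,
                    pD=pD,
                    temperature=spec.temperature,
                    normalized=True,
                )
            )
        out[pD] = series
    return out


def true_ex2_rates(spec: HDXSimulationSpec, pD: float) -> dict[int, float]:
    """Noise-free k_HDX values the spec implies at one pD (EX2/EX1 only)."""
    conditions = ExchangeConditions(pD=pD, temperature=spec.temperature)
    rates = krc_profile(spec.sequence, conditions)
    out = {}
    for pos in sorted(set(spec.dG_local) | spec.mechanism_ex1):
        if pos in spec.hyperprotected:
            continue
        if pos in spec.mechanism_ex1:
            out[pos] = float(spec.k_unfold[pos])
        else:
            out[pos] = _ex2_rate(
                spec.dG_local[pos], rates[pos], spec.temperature,
                spec.base_channel_only,
            )
    return out


# ---------------------------------------------------------------------------
# chemical denaturation


@dataclass
class DenaturationSimulationSpec:
    """Ground truth for a simulated Gdn-HCl denaturation curve."""

    dG_global: float = 8.47
    m_value: float = 1.85
    native_baseline: Baseline = field(default_factory=lambda: Baseline(-12500.0, 50.0))
    unfolded_baseline: Baseline = field(default_factory=lambda: Baseline(-3000.0, 100.0))
    denaturant: np.ndarray = field(default_factory=lambda: np.arange(0.0, 8.01, 0.25))
    noise_sd: float = 0.0
    temperature: float = 298.15
    seed: int = 0

    def __post_init__(self):
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        if self.m_value <= 0:
            raise ValueError("m_value must be positive")
        mid = self.dG_global / self.m_value
        if not (self.denaturant[0] < mid < self.denaturant[-1]):
            raise ValueError("denaturant grid must span the transition midpoint")

    @property
    def midpoint(self) -> float:
        return self.dG_global / self.m_value


def simulate_denaturation(spec: DenaturationSimulationSpec) -> DenaturationCurve:
    """Two-state sigmoid between sloping baselines, additive Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    D = spec.denaturant
    RT = R_KCAL * spec.temperature
    f = 1.0 / (1.0 + np.exp(-(spec.dG_global - spec.m_value * D) / RT))
    signal = f * spec.native_baseline(D) + (1.0 - f) * spec.unfolded_baseline(D)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
    return DenaturationCurve(D.copy(), signal, temperature=spec.temperature)


# ---------------------------------------------------------------------------
# DSC


@dataclass
class DSCSimulationSpec:
    """Ground truth for a simulated DSC thermogram."""

    T_m: float = 101.4
    dH_vH: float = 100.0
    scale: float = 1.0
    baseline_coefficients: tuple[float, ...] = (0.0,)
    temperature: np.ndarray = field(default_factory=lambda: np.arange(50.0, 120.01, 0.5))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        if not (self.temperature[0] < self.T_m < self.temperature[-1]):
            raise ValueError("T_m must lie inside the temperature grid")


def simulate_thermogram(spec: DSCSimulationSpec) -> Thermogram:
    """Two-state excess heat capacity + polynomial baseline + noise."""
    rng = np.random.default_rng(spec.seed)
    t = spec.temperature
    signal = two_state_excess_heat_capacity(t, spec.T_m, spec.dH_vH, spec.scale)
    signal = signal + np.polyval(spec.baseline_coefficients, t - t.mean())
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
    return Thermogram(t.copy(), signal, scan_rate=1.0)


# ---------------------------------------------------------------------------
# coordinate ensembles


def _ideal_helix_bundle(n_per_helix: int = 15) -> pd.DataFrame:
    """Idealized antiparallel four-helix-bundle backbone (N, CA, C), poly-Ala.

    Helical geometry uses the canonical 1.5 A rise and 100 degree twist per
    residue for C-alpha; N and C are placed on the same helical path with
    fixed angular/axial offsets.  Good enough as a geometry fixture; not a
    stereochemically exact backbone.
    """
    rows = []
    centers = [(-4.7, -4.7), (4.7, -4.7), (4.7, 4.7), (-4.7, 4.7)]
    resnum = 0
    for h, (cx, cy) in enumerate(centers):
        direction = 1.0 if h % 2 == 0 else -1.0
        for i in range(n_per_helix):
            resnum += 1
            phase = math.radians(100.0 * i)
            z = direction * 1.5 * i
            for name, element, dphi, dz, radius in (
                ("N", "N", -0.45, -0.55, 1.6),
                ("CA", "C", 0.0, 0.0, 2.3),
                ("C", "C", 0.45, 0.55, 1.7),
            ):
                rows.append(
                    (
                        name, element, resnum, "ALA", "A",
                        cx + radius * math.cos(phase + dphi),
                        cy + radius * math.sin(phase + dphi),
                        z + dz,
                    )
                )
    return pd.DataFrame(
        rows, columns=["name", "element", "resnum", "resname", "chain", "x", "y", "z"]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def simulate_helix_bundle_ensemble(
    n_models: int, jitter_sd: float, seed: int = 0, n_per_helix: int = 15
) -> Ensemble:
    """Jittered, randomly rigid-transformed copies of an ideal helix bundle."""
    if n_models < 2:
        raise ValueError("need at least 2 models")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    template = _ideal_helix_bundle(n_per_helix)
    xyz0 = template[["x", "y", "z"]].to_numpy(dtype=float)
    models = []
    for m in range(1, n_models + 1):
        xyz = xyz0 + rng.normal(0.0, jitter_sd, xyz0.shape)
        R = _random_rotation(rng)
        t = rng.uniform(-20.0, 20.0, size=3)
        df = template.copy()
        df[["x", "y", "z"]] = xyz @ R.T + t
        models.append(StructureModel(df, model_id=str(m)))
    return Ensemble(models, source="synthetic_helix_bundle")


# ---------------------------------------------------------------------------
# the packaged study-like preset


#: Residues whose peaks persist for a month in the wild-type protein.
PRESET_MONTH_SURVIVORS = (11, 12, 15, 69, 72, 73, 76, 77)

#: Residues with dG_local > 5 kcal/mol in the wild-type protein.
PRESET_HIGH_DG = (11, 12, 14, 15, 16, 30, 31, 47, 50, 69, 70, 73, 74, 75, 76, 77)

#: Positions excluded from the observed set (fast loop amides lost before
#: the first spectrum); leaves 60 observed residues of the 80 possible.
PRESET_UNOBSERVED = (3, 5, 9, 13, 20, 21, 24, 27, 29, 33, 37, 38, 42, 45, 52, 55, 56, 58, 60, 66)

#: Residues in the global-unfolding regime: one hyperprotected plus two
#: whose dG_local exceeds 0.85 * dG_global.
PRESET_GLOBAL_REGIME = (15, 75, 76)


@dataclass
class StudyPreset:
    """A fully specified synthetic study mirroring the wild-type experiments."""

    hdx: HDXSimulationSpec
    denaturation_wt: DenaturationSimulationSpec
    denaturation_i15a: DenaturationSimulationSpec
    dsc: DSCSimulationSpec
    survivor_threshold: float = 0.1
    survivor_time_min: float = 10.0


def acp_like_preset(seed: int = 0, noise_sd: float = 0.02) -> StudyPreset:
    """The packaged ACP-like synthetic study.

    An 81-residue sequence with 60 observed amides; one hyperprotected
    residue (position 15) and two residues (75, 76) above 0.85 * dG_global;
    46 of the 60 observed peaks survive past 10 min at pD 6.5; wild-type
    denaturation parameters (dG, m) = (8.47 kcal/mol, 1.85 kcal/mol/M),
    destabilized-mutant-like parameters (5.18, 1.80); a DSC transition at
    101.4 degC.  Per-residue dG_local values are drawn reproducibly from
    bands chosen so the survivor split is robust at the 2% noise level.
    """
    seq = synthetic_acp_sequence()
    rng = np.random.default_rng(seed + 1_000_003)
    temperature = 298.15
    RT = R_KCAL * temperature
    rates = krc_profile(seq, ExchangeConditions(pD=6.5, temperature=temperature))

    observed = [p for p in range(2, len(seq) + 1) if p not in set(PRESET_UNOBSERVED)]
    assert len(observed) == 60

    high = set(PRESET_HIGH_DG)
    dG_local: dict[int, float] = {}
    slow_pool = [p for p in observed if p in high and p not in (15, 75, 76)]
    mid_pool = [p for p in observed if p not in high and p != 15]
    # 46 survivors at 10 min: 15 (hyperprotected), 75, 76, the 13 other
    # high-dG residues, and 30 of the mid pool; the remaining 14 exchange
    # out before the first spectrum can resolve them.
    fast = sorted(rng.choice(mid_pool, size=len(mid_pool) - 30, replace=False).tolist())

    dG_local[75], dG_local[76] = 7.8, 7.6
    for p in slow_pool:
        dG_local[p] = float(rng.uniform(5.3, 6.9))
    for p in mid_pool:
        k_rc = rates[p].channel_contributions["base"]
        if p in fast:
            # fully exchanged by 10 min: k >= 0.5 / min
            cap = -RT * math.log(0.5 / k_rc)
            dG_local[p] = float(min(rng.uniform(1.0, 2.2), cap - 0.05))
        else:
            # still visible at 10 min with margin: k <= 0.1 / min
            floor = -RT * math.log(0.1 / k_rc)
            dG_local[p] = float(max(rng.uniform(4.3, 5.0), floor + 0.05))

    times = np.concatenate(
        [np.arange(10.0, 1001.0, 10.0), [4320.0, 10080.0, 20160.0, 30240.0, 40320.0]]
    )
    hdx = HDXSimulationSpec(
        sequence=seq,
        dG_local=dG_local,
        pD_values=(5.5, 6.5),
        temperature=temperature,
        times=times,
        noise_sd=noise_sd,
        hyperprotected=frozenset({15}),
        seed=seed,
    )
    denat_wt = DenaturationSimulationSpec(
        dG_global=8.47, m_value=1.85, noise_sd=190.0 * (noise_sd / 0.02) if noise_sd else 0.0,
        temperature=temperature, seed=seed + 1,
    )
    denat_mut = DenaturationSimulationSpec(
        dG_global=5.18, m_value=1.80, noise_sd=190.0 * (noise_sd / 0.02) if noise_sd else 0.0,
        temperature=temperature, seed=seed + 2,
    )
    dsc = DSCSimulationSpec(
        T_m=101.4, dH_vH=100.0, baseline_coefficients=(0.05, 2.0),
        noise_sd=0.09 * (noise_sd / 0.02) if noise_sd else 0.0, seed=seed + 3,
    )
    return StudyPreset(hdx=hdx, denaturation_wt=denat_wt,
                       denaturation_i15a=denat_mut, dsc=dsc)
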