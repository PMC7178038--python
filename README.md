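# thermofold

Per-residue and global protein-stability analysis for small helical
proteins — the kind of workup used to explain why a hyperthermophilic
protein (a bacterial acyl carrier protein melting above 100 °C, say)
stays folded: which amides are protected against hydrogen/deuterium
exchange and by how much, what the global unfolding free energy is, and
which structural features (buried packing contacts, surface ionic
clusters, a widened substrate-pocket entrance) carry the stability.

**Who it is for.** Anyone with per-residue HSQC peak-decay tables,
CD denaturation titrations, DSC thermograms, or coordinate ensembles who
wants the standard thermodynamic quantities out of them — plus a
synthetic-data generator so every stage can be validated with known
ground truth first.

## The models

**H/D exchange.** A peak decays as I(t) = A·exp(−k_HDX·t).  In the EX2
limit (base-catalysed window, pD 5–7) the observed rate factorizes as
k_HDX = K_unfold · k_rc, where k_rc is the residue's random-coil
(intrinsic) rate from packaged poly-DL-alanine reference rates with
neighbor corrections.  The local opening free energy is

    ΔG_local = −RT ln(K_unfold),   K_unfold = k_HDX / k_rc .

EX2 vs EX1 is diagnosed from the pD dependence: log₁₀(k_HDX) rises one
unit per pD unit under EX2 and is flat under EX1 (k_HDX = k_unfold).
Amides that never measurably decay are *hyperprotected*: only a lower
resolvable bound can be stated.

**Chemical denaturation.** Two-state linear extrapolation model:
ΔG(D) = ΔG_global − m·[GdnHCl], fit either by the classical per-point
free-energy line (f_N from sloping baselines, ΔG_i = −RT ln((1−f_N)/f_N))
or by a one-step global sigmoid fit; midpoint D₁/₂ = ΔG_global/m and the
headline energy is m·D₁/₂.

**DSC.** Scaled two-state excess heat capacity
Cp(T) = s·ΔH²_vH·K/(RT²(1+K)²), K = exp(−(ΔH_vH/R)(1/T−1/T_m)), after
polynomial baseline correction; T_m is where K = 1.

**Regime rule.** A residue unfolds only globally when
ΔG_local > 0.85·ΔG_global (strict); hyperprotected residues are in the
regime by definition.

**Geometry.** Kabsch superposition and ensemble RMSD-to-mean, pocket
entrance Cα distances, closest side-chain proton contacts, Arg/Lys–Asp/Glu
salt-bridge clusters, sequence charge census with Henderson–Hasselbalch
pI, and the RDC quality factor Q = rms(D_meas − D_calc)/rms(D_meas).

## Worked example

Simulate the packaged ACP-like study, fit the global unfolding, then fit
one protected residue's exchange:

```python
from thermofold import LinearExtrapolationModel, PeakDecayModel, protection_energy
from thermofold.intrinsic import ExchangeConditions, krc_profile
from thermofold.simulate import acp_like_preset, simulate_denaturation, simulate_hdx

preset = acp_like_preset(seed=0)                      # 2% noise study
fit = LinearExtrapolationModel(
    simulate_denaturation(preset.denaturation_wt)
).fit(method="global")
print(fit.summary())

series = simulate_hdx(preset.hdx)[6.5]                # pD 6.5 condition
res = PeakDecayModel([s for s in series if s.residue_index == 76][0]).fit()
print(res.summary())

krc = krc_profile(preset.hdx.sequence, ExchangeConditions(pD=6.5, temperature=298.15))
pr = protection_energy(res.k_HDX, krc[76].channel_contributions["base"], 298.15)
print(f"K_unfold = {pr.K_unfold:.3e}, dG_local = {pr.dG_local:.2f} kcal/mol")
```

prints

```
Two-state LEM fit (global)
  dG_global : 8.807 kcal/mol
  m-value   : 1.925 kcal mol^-1 M^-1
  midpoint  : 4.574 M
  baselines : native -12457.4 +46.71*D, unfolded -3418.7 +154.33*D
  transition points: 7
Peak decay fit: I76  (pD 6.5, T 298.15 K)
  n points          : 105
  amplitude A       : 0.9985 +/- 0.0020
  k_HDX             : 3.9189e-05 /min
  95% CI            : [3.7081e-05, 4.1296e-05]
  residual norm     : 1.8463e-01
K_unfold = 2.655e-06, dG_local = 7.61 kcal/mol
```

The titration midpoint comes back at 4.57 M with ΔG_global ≈ 8.8 kcal/mol
(generated: 8.47 — a 2%-noise realization), and residue 76's exchange rate
of 3.9e-5 /min converts to ΔG_local = 7.61 kcal/mol (generated: 7.60) —
above 0.85·ΔG_global, i.e. in the global unfolding regime.  Residue 15 in
the same run is hyperprotected: its fit reports no measurable decay and a
resolvable bound of 5.5e-6 /min instead of a rate.

The same workflow is scriptable from the shell:

```sh
thermofold simulate --seed 0 --out study
thermofold hdx-fit study/peaks.tsv study/sequence.fasta --out hdx.tsv
thermofold denat-fit study/denaturation.tsv --out denat.json
thermofold regime hdx.tsv denat.json
thermofold dsc-fit study/thermogram.tsv
thermofold census study/sequence.fasta
thermofold pipeline --seed 0 --out run   # everything, with a JSON summary
```

## Layout

| module | contents |
|---|---|
| `thermofold.intrinsic` | random-coil exchange rates (packaged reference/factor tables) |
| `thermofold.hdx` | `PeakDecayModel` fits, ΔG_local, EX1/EX2, survivor counts |
| `thermofold.denaturation` | `LinearExtrapolationModel` (two-step and global routes) |
| `thermofold.dsc` | baseline correction, `DSCTwoStateModel`, multi-component option |
| `thermofold.regime` | global-unfolding regime rule |
| `thermofold.geometry` | superposition, distances, salt bridges, census/pI, Q factor |
| `thermofold.simulate` | all generators + the `acp_like_preset()` synthetic study |
| `thermofold.tableio`, `thermofold.pipeline`, `thermofold.cli` | IO, orchestration, CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
their rationale, and what the synthetic benchmarks do and do not
demonstrate.
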