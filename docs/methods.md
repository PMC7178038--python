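# Methods

`thermofold` quantifies how a small helical protein resists unfolding, at
two scales: per-residue opening free energies from hydrogen/deuterium (H/D)
exchange, and the global unfolding free energy from chemical denaturation
and calorimetry.  A geometry module measures the structural correlates
(packing contacts, ionic clusters, pocket-entrance width) on coordinate
ensembles, and a synthetic-data module generates every input with known
ground truth so the whole chain is testable without measured spectra.

## Intrinsic exchange rates (`thermofold.intrinsic`)

The observed exchange rate of a backbone amide is interpreted against the
rate the same amide would show in a random coil, `k_rc`.  We evaluate
`k_rc` as the sum of acid-, base- and water-catalysed channels:

    k_rc = k_A [D+] F_A  +  k_B [OD-] F_B  +  k_W F_B

with `[D+] = 10^-pD`, `[OD-] = 10^(pD - pK_D2O)` and per-channel
correction factors `F = 10^(L(res_i) + R(res_{i-1}))` for the inductive
and steric effects of the residue's own side chain (L) and its
predecessor's (R).  The reference rates (poly-DL-alanine, D2O, 293 K:
log10 k_A = 1.62, log10 k_B = 10.18, log10 k_W = -1.5, pK_D2O = 15.05) and
the factor table follow Bai, Milne, Mayne & Englander (Proteins 17:75,
1993) and ship as a text resource with provenance in its header.  Asp/Glu
rows are the carboxylate forms and His the protonated form, appropriate to
the pD 5–7 window the package targets; the pD handed in is used directly
(an optional flag applies the +0.4 glass-electrode correction to raw meter
readings).

Temperature scaling is Arrhenius per channel,
`k(T) = k(T_ref) exp(-(E_a/R)(1/T - 1/T_ref))`, with `E_a/R` exposed in
kelvin.  Defaults correspond to 14/17/19 kcal/mol for the acid/base/water
channels, taken from the same correction-rate source; they are documented
defaults, not a claim about any particular study's choice.  The ion
product `pK_D2O` is held at its reference value — a deliberate
simplification that is excellent within a few kelvin of the reference
temperature and progressively cruder far from it.

Residue 1 (no backbone amide) and prolines are excluded; residue 2
carries the extra N-terminal (free amino group) factor, the last residue
the C-terminal carboxylate factor.

## Peak-decay kinetics (`thermofold.hdx`)

Peak heights vs time are fit to `I(t) = A exp(-k t)` by nonlinear least
squares (`PeakDecayModel.fit()` → results object with standard errors and
a 95% interval on `k`).  There is no floating baseline by default —
a fully exchanged amide's peak vanishes in D2O — but a plateau term is
available behind a flag.  Three outcomes are distinguished:

- **resolvable**: the interval on `k` excludes zero; `K_unfold =
  k_HDX/k_rc` and `dG_local = -RT ln K_unfold` (R = 1.987e-3 kcal/mol/K)
  follow, using the base-channel `k_rc` in the base-catalysed window.
- **hyperprotected**: the final/first height ratio exceeds 0.8 over the
  whole window and the fitted rate is indistinguishable from zero (or
  below the smallest resolvable rate `ln(1/0.8)/t_max`).  No `dG_local`
  can be assigned from exchange alone; only the resolvable lower bound is
  reported.
- **undetected**: the peak never reaches the detection limit (default 1%
  of the reference intensity) — it exchanged out before the first
  spectrum, and fitting noise would produce a number, not a measurement.
  Flagged unresolvable.

The EX1/EX2 diagnosis compares fits at two pD values: the log10 rate
shift equals the pD difference in the EX2 limit (base catalysis carries
the pD dependence) and zero in the EX1 limit (`k_HDX = k_unfold`).  The
band is ±0.3 log units around each limit, ties going to "intermediate";
the published treatments plot the limits as lines without a numeric band,
so the width is a package choice sized to typical fit scatter.

Survivor counting (how many peaks remain above a height threshold at a
given time) interpolates each series linearly; the default threshold of
0.1 reflects a conservative notion of "visible above the noise floor" and
is configurable, since the underlying studies do not state one.

## Chemical denaturation (`thermofold.denaturation`)

Mean residue ellipticity is `theta_mdeg / (10 l c (n-1))` (per peptide
bond).  The linear extrapolation model (LEM) assumes
`dG(D) = dG_global - m D` for the two-state N↔U equilibrium, so the
native fraction between two straight baselines is a sigmoid in
denaturant.  Two fitting routes are provided:

- **two-step** (default, as the thermodynamic relations read): estimate
  baselines from the flanking 20% of the denaturant range, convert to
  f_N, transform points with 0.05 ≤ f_N ≤ 0.95 to per-point free energies
  `-RT ln((1-f_N)/f_N)`, and fit the line.  Two refinements make this
  classical route numerically sound: (i) baselines are iteratively
  de-contaminated using the current model's predicted minority-state
  population in the flanks, and (ii) the transition zone and the
  inverse-variance weights `f(1-f)` are taken from the model-predicted
  f_N once available, so a noisy baseline point cannot enter the line fit
  as a high-leverage outlier.
- **global**: one-step nonlinear fit of the full sigmoid-plus-baselines
  model (6 parameters).  This is the maximum-likelihood route and has
  visibly lower variance on noisy curves (the per-point log-transform
  amplifies noise near the window edges); the pipeline uses it, and it is
  recommended when baselines slope strongly.

The midpoint is `dG_global/m` and the headline free energy is reported as
`m × midpoint` — identical to the line intercept for the two-step route,
asserted to 1e-9 relative.  Both routes agree to <0.1% on noiseless
curves.  The 12-h equilibration of a titration is recorded as metadata
only.

## DSC (`thermofold.dsc`)

Thermograms are baseline-corrected with a polynomial (degree ≤ 3) fitted
to the scan flanks, then fit to the scaled two-state excess heat
capacity

    Cp(T) = s ΔH² K / (R T² (1+K)²),   K = exp(-(ΔH/R)(1/T - 1/T_m)),

temperatures in kelvin internally and reported in °C.  The model's area
over temperature is `s ΔH` exactly, which the tests assert (van't Hoff /
calorimetric consistency of the pure two-state form).  Because a real
transition's tails leak into any finite flank, `DSCTwoStateModel.from_raw`
iterates correction and fit: the polynomial is re-estimated on the
model-subtracted signal over the whole scan until T_m moves <1e-5 °C.
This makes T_m invariant to adding any polynomial of the chosen degree
and recovers noiseless round trips to millikelvin accuracy.  Complex
profiles can be resolved as a user-specified number of summed two-state
components.  No ΔCp term is modeled (the headline quantity is T_m), and
no kinetic (scan-rate) effects.

## Unfolding regime (`thermofold.regime`)

A residue exchanges only through global unfolding when its local opening
free energy approaches the global one.  The rule is strict:
`dG_local > 0.85 × dG_global` (threshold configurable in (0,1); the
boundary itself is *not* in the regime, following the "higher than"
wording of the underlying criterion).  Hyperprotected residues are
assigned `dG_local = dG_global` and are in the regime at any threshold.
An optional uncertainty gate additionally requires the lower confidence
bound to clear the threshold.  Both H/D exchange and denaturation are
referenced to the same temperature (298.15 K default), so no cross-
condition correction is applied.

## Structure geometry (`thermofold.geometry`)

- Superposition: Kabsch (SVD with determinant correction), atom
  correspondence by sorted (chain, residue, atom name).  The independent
  check in the tests is `scipy.spatial.transform.Rotation.align_vectors`.
- Ensemble precision: all models are superposed onto the running mean and
  the mean recomputed until it moves <1e-6 Å; the reported value is the
  average over models of the RMSD to the converged mean (backbone
  N/CA/C by default).
- Pocket-entrance width: the three pairwise Cα distances among a residue
  triplet, with min/max/mean summaries (the mapping of printed values to
  pairs can be ambiguous, so validation uses the extremes).
- Closest contacts: minimum distance between side-chain hydrogens of two
  residues (NMR models); falls back to heavy atoms with a warning.
- Salt bridges: Arg NH1/NH2/NE and Lys NZ vs Asp OD1/OD2 and Glu OE1/OE2
  within 4.0 Å (community-standard cutoff, configurable); connected
  components of the bridge graph are reported as ionic clusters.
- Charge census/pI: Glu/Asp vs Arg/Lys counts (His reported separately,
  not in the basic total), pI by bisection of the Henderson–Hasselbalch
  net charge with the Bjellqvist pKa set used by the ProtParam tool,
  including residue-specific N-terminal pKa values.
- RDC quality: `Q = rms(measured - calculated)/rms(measured)`.

Files are read with gemmi (mmCIF or PDB), author residue numbering
throughout.  `fetch_pdb` downloads deposited entries when a network is
available; all tests that do not involve deposited entries run on
synthetic structures.

## Synthetic data (`thermofold.simulate`)

The generators emit exactly the formats the analysis consumes, from the
forward models above.  Noise is multiplicative Gaussian on peak heights
(spectral intensities scale with the peak) and additive Gaussian on
CD/DSC signals; everything is bit-reproducible from a seed.  For EX2
residues the generated rate uses the base-catalysed channel only, which
is the regime the pD 5–7 window isolates and makes the one-log-unit-per-
pD-unit law exact; the full multi-channel rate is available via
`base_channel_only=False` (the water channel then contributes ~1% at
pD 5.5, bending the shift to ≈0.997).

`acp_like_preset()` packages a complete study-like synthetic experiment:

- an 81-residue synthetic ACP-like sequence (shipped FASTA, labelled
  synthetic) with a 10 Glu / 11 Asp / 1 Arg / 8 Lys charge composition —
  strongly acidic, pI 4.13;
- 60 observed amides, of which one (position 15, the buried core Ile
  site) is hyperprotected and two (75, 76) have dG_local above 85% of the
  global value (7.8 and 7.6 kcal/mol vs dG_global 8.47);
- per-residue dG_local values drawn reproducibly from bands arranged so
  that exactly 46 of the 60 peaks survive the first spectrum at 10 min
  (fast band capped at rates ≥0.5/min, surviving band floored at
  ≤0.1/min at pD 6.5) — margins sized so the 46/60 split is stable at the
  2% noise level;
- a time grid of every 10 min to 1000 min plus five long points out to
  28 days, mirroring how slow exchangers are followed;
- wild-type-like denaturation parameters (ΔG, m) = (8.47 kcal/mol,
  1.85 kcal/mol/M) and destabilized-mutant-like (5.18, 1.80), on a
  0–8 M grid in 0.25 M steps with 2% amplitude noise;
- a DSC transition at T_m = 101.4 °C with ΔH_vH = 100 kcal/mol on a
  sloping linear baseline, scanned 50–120 °C at 0.5 °C spacing with 1%
  peak-amplitude noise.

The four-helix-bundle generator produces an idealized poly-Ala backbone
(canonical 1.5 Å rise / 100° twist; N and C placed on the same helical
path with fixed offsets — a geometry fixture, not a stereochemically
exact backbone), jittered isotropically per model and randomly rigidly
transformed.

**What passing these tests shows — and does not.**  The synthetic data
share the real measurements' model class by construction, so round-trip
tests demonstrate estimator correctness (no bias, correct propagation,
correct wiring between stages), not robustness to model violations real
spectra carry: peak overlap, baseline drift, non-two-state intermediates,
EX1/EX2 mixtures, proline cis/trans effects, or aggregation above the
melting transition.  The survivor count and regime membership are
constructed properties of the preset, and the pI check validates the
charge-composition arithmetic and pKa set, not a sequence database.

## Numerical choices

- R = 1.987e-3 kcal/mol/K everywhere; energies kcal/mol, rates /min,
  temperatures K internally and °C at DSC interfaces.
- Decay fits: `scipy.optimize.curve_fit` with non-negative bounds and a
  log-linear initial slope estimate; 95% intervals from the covariance.
- LEM transition window 0.05–0.95 in f_N (the endpoint transform
  diverges); at least 4 transition points required.
- pI bisection on [0, 14] to 1e-6, verified against a 1e-4 grid scan.
- Ensemble-mean convergence 1e-6 Å, max 100 iterations.
- Degenerate inputs fail loudly: all-zero decays, coincident baselines,
  transitions spanning a whole DSC scan, sub-3-atom superpositions.

## Problem sizes

Defaults throughout are the sizes a desk re-analysis of one small protein
would use: 60 residues × 2 pD × 105 time points for exchange; 33-point
titrations (200 replicates for the noisy-recovery benchmarks); 141-point
thermograms (100 replicates); 20-model ensembles.  `scripts/acceptance.py`
re-runs all of these from scratch in a few seconds.

## Known limitations

- The neighbor-factor table is transcribed at two-decimal log10
  precision; absolute `k_rc` values inherit that (±ca. 5%) uncertainty,
  which cancels in the pD-shift law and largely cancels in dG_local
  differences.
- No D/E/H protonation-state switching below pD ≈ 5; the package targets
  the base-catalysed window.
- The two-step LEM route, though refined, remains noisier than the global
  fit on strongly sloping baselines; both are exposed deliberately.
- Hyperprotection is a decision rule on one series; it cannot distinguish
  "no exchange" from "exchange slower than the window resolves" — that is
  the point of the reported lower bound.
- Deposited-entry geometry requires the coordinate files; nothing is
  bundled, only fetched on demand.
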