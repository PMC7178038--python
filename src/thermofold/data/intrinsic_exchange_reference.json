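{
  "_comment": [
    "Poly-DL-alanine reference rate constants for backbone amide H->D",
    "exchange in D2O at the 293 K reference temperature, log10 scale,",
    "after Bai, Milne, Mayne & Englander, Proteins 17:75-86 (1993).",
    "Units: acid channel M^-1 min^-1 (combined with 10^-pD), base channel",
    "M^-1 min^-1 (combined with 10^(pD - pK_D2O)), water channel min^-1.",
    "Activation energies are defaults from the same source (14/17/19",
    "kcal/mol for acid/base/water), expressed as E_a/R in kelvin."
  ],
  "log10_k_acid": 1.62,
  "log10_k_base": 10.18,
  "log10_k_water": -1.5,
  "pK_D2O": 15.05,
  "reference_temperature_K": 293.0,
  "activation_energy_over_R_K": {
    "acid": 7045.8,
    "base": 8555.6,
    "water": 9562.2
  }
}
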