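{
  "comment": "Ac-225 decay series, yield-weighted emission energies per decay of each nuclide (MeV). Half-lives and mean emission energies compiled from public evaluated nuclear data (NNDC/ENSDF, ICRP-107 style totals). Yields are decays of the nuclide per Ac-225 decay; the Bi-213 branch is carried as 2% Tl-209 / 98% Po-213 and the Bi-213 per-decay alpha energy uses the same 2% alpha branch. e_beta is the yield-weighted MEAN beta energy (spectrum average), e_gamma the yield-weighted total photon energy including X-rays. The stable endpoint Bi-209 is omitted.",
  "nuclides": [
    {"name": "Ac-225", "half_life_h": 238.1,    "yield": 1.0,  "e_alpha_mev": 5.785, "e_beta_mev": 0.020,  "e_gamma_mev": 0.016},
    {"name": "Fr-221", "half_life_h": 0.0801,   "yield": 1.0,  "e_alpha_mev": 6.301, "e_beta_mev": 0.010,  "e_gamma_mev": 0.031},
    {"name": "At-217", "half_life_h": 9.06e-06, "yield": 1.0,  "e_alpha_mev": 7.066, "e_beta_mev": 0.0001, "e_gamma_mev": 0.0002},
    {"name": "Bi-213", "half_life_h": 0.7602,   "yield": 1.0,  "e_alpha_mev": 0.1175, "e_beta_mev": 0.435, "e_gamma_mev": 0.133},
    {"name": "Po-213", "half_life_h": 1.17e-09, "yield": 0.98, "e_alpha_mev": 8.376, "e_beta_mev": 0.0,    "e_gamma_mev": 0.0},
    {"name": "Tl-209", "half_life_h": 0.0360,   "yield": 0.02, "e_alpha_mev": 0.0,   "e_beta_mev": 0.659,  "e_gamma_mev": 2.18},
    {"name": "Pb-209", "half_life_h": 3.253,    "yield": 1.0,  "e_alpha_mev": 0.0,   "e_beta_mev": 0.198,  "e_gamma_mev": 0.0}
  ]
}
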