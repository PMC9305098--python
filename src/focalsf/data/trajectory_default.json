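{
  "name": "tanh-powerlaw-v1",
  "description": "Default nerve-fiber bundle trajectory atlas. Disc-centered polar frame; phi0 is the disc-entry angle measured from the fovea-disc axis pointing nasally (away from the fovea), counterclockwise positive (superior hemiretina phi0 > 0). Trajectories follow phi(r) = phi0 + b(phi0) * (r - r0)^c(phi0) with hemifield-specific tanh coefficient tables; b is tapered to zero at the nasal horizontal so nasal bundles run radially.",
  "r0_deg": 4.0,
  "variability_sd_deg": 5.0,
  "canonical_disc_xy_deg": [15.0, 2.0],
  "nasal_taper_deg": 10.0,
  "hemifields": {
    "superior": {
      "sign": 1.0,
      "beta0": -1.9,
      "beta1": 3.9,
      "center_deg": 121.0,
      "width_deg": 14.0,
      "c0": 1.9,
      "c1": 1.4
    },
    "inferior": {
      "sign": -1.0,
      "beta0": 0.7,
      "beta1": 1.5,
      "center_deg": 90.0,
      "width_deg": 25.0,
      "c0": 1.0,
      "c1": 0.5
    }
  }
}
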