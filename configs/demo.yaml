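# End-to-end demo: small two-population study (Lau Basin pair), synthetic
# westward jet with eddies, stepping-stone connectivity, and the
# genetics-vs-dispersal comparison. Runs in well under five minutes.
seed: 42
out_dir: results/demo
stages: [simulate, popgen, neutrality, dispersal, stepping_stone, compare]

simulate:
  preset: strummeri-like
  theta: 2.0
  m_within: 10.0
  m_between: 1.0
  asymmetry: 0.0

popgen:
  n_boot: 200

neutrality:
  alpha: 0.05
  n_sims: 500
  free_k_loci: [mtCOI]

dispersal:
  domain: {x_km: 600.0, y_km: 300.0, dx_km: 10.0}
  components:
    - {type: uniform_jet, u: -0.05, v: 0.0}
    - {type: eddy_field, amplitude: 0.03, n_modes: 4, length_scale_km: 80.0}
  dispersal_depth_m: 1500.0
  sites:
    - {id: THM, x_km: 420.0, y_km: 150.0, depth_m: 2275.0}
    - {id: TM, x_km: 300.0, y_km: 140.0, depth_m: 1845.0}
    - {id: STEP, x_km: 180.0, y_km: 150.0, depth_m: 2100.0}
  n_particles: 400
  dt_seconds: 3600.0
  radius_km: 8.0
  jitter_km: 3.0
  min_competency: 0.02
  store_every: 2

stepping_stone:
  max_steps: 100
  tol: 1.0e-12

compare:
  threshold_d: 1.0e-3
  mapping: {THM: THM, TM: TM}
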