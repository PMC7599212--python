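# Bundled demo study: a 60x60 synthetic landscape, three focal species with
# distinct ground-truth niches plus one broad outgroup.  Sized to finish in a
# few minutes on one CPU; raise n_background / n_replicates / n_permutations
# toward the full-protocol values (10000 / 10 / 1000) for a production run.
seed: 42
outdir: scratch/demo_run

grid:
  shape: [60, 60]
  k: 4
  autocorr_range: 3.0
  n_regions: 3
  n_landcover: 3

descriptors:
  v1: climate
  v2: climate
  v3: topography
  v4: human

cutoff_year: 1990

species:
  - name: coolcat          # heat-limited: negative response to v1
    coefficients: {v1: [-2.5, -0.5]}
    prevalence: 120
  - name: warmcat          # warm-adapted: positive response to v1
    coefficients: {v1: [2.5, -0.5]}
    prevalence: 120
  - name: lowlander        # tied to topography
    coefficients: {v3: [-2.5, 0.0]}
    prevalence: 100
  - name: outgroup         # broad generalist
    coefficients: {v1: [1.0, -0.2], v3: [0.8, 0.0]}
    prevalence: 140

protected:
  n_polygons: 5
  total_fraction: 0.2

tuning:
  feature_classes: [L, LQ]
  rms: [1.0, 2.0]
  datasets: [RD]
  bias_variants: [BM01]

maxent:
  n_background: 2000
  n_replicates: 3
  train_fraction: 0.7

overlap:
  n_permutations: 199
  r: 60

scenarios:
  n_gcms: 2
  gcm_sd: 0.1
  drift:
    MH:   {v1: {add: -0.3}}
    2070-RCP4.5: {v1: {add: 0.8}}
    2070-RCP8.5: {v1: {add: 1.5}}

refugia_quorum: 0.9
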