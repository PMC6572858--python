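# Annotated default pipeline configuration for `luxsat run --config ...`.
# Every field shown here matches the built-in default; delete anything you
# do not want to override.

# Ground-truth light-response parameters for the synthetic experiment.
truth:
  alpha0: 0.1          # initial slope scale, µmol CO2 per µmol photons
  beta: 2.4e-4         # baseline photoinhibition coefficient, per µmol m-2 s-1
  gamma: 2.0e-3        # saturation coefficient (> beta), per µmol m-2 s-1
  rd: 1.5              # dark respiration, µmol CO2 m-2 s-1
  topt: 30.0           # temperature optimum, °C
  tsigma: 14.0         # temperature breadth of the initial slope, °C
  km_co2: 600.0        # half-saturation CO2 of the initial slope, µmol/mol
  noise_sd: 0.15       # additive Gaussian noise s.d., µmol CO2 m-2 s-1
  beta_t_width: 20.0   # U-shaped beta(T) width; null disables T-dependence
  beta_co2_km: 400.0   # beta(C) half-saturation; null disables C-dependence
  beta_co2_floor: 0.45 # high-CO2 asymptote of the beta(C) factor

# Nested experimental design (Cartesian product, 7 x 6 x 10 = 420 rows).
grid:
  co2_levels: [600, 800, 1000, 1200, 1500, 1700, 2000]   # µmol/mol
  temp_levels: [12, 15, 20, 25, 30, 33]                  # °C
  ppfd_levels: [100, 200, 300, 400, 500, 600, 800, 1000, 1200, 1400]

surrogate_kind: svm    # svm | rbf | bp
svm:
  c: 2.82              # SVR penalty (used when tune: false)
  g: 0.50              # RBF kernel parameter (used when tune: false)
  epsilon: 0.001       # regression tube width, normalized target units
tune: true             # cross-validate (c, g) over a log2 grid
train_frac: 0.85       # 85% train / 15% held-out split

optimizer_algo: aco    # aco | ga
aco:
  n_ants: 50
  subinterval_length: 20.0   # D, µmol m-2 s-1
  evaporation: 0.1           # pheromone evaporation alpha
  eta: 1.0                   # residual-pheromone carry-over weight
  max_iters: 200
  domain: [800.0, 1800.0]    # PPFD search interval
  quad_points: 5             # trapezoid nodes per subinterval
ga:
  pop_size: 40
  max_gen: 200
  chrom_bits: 20
  ggap: 0.95
  px: 0.7
  pm: 0.01
  domain: [800.0, 1800.0]

# Saturation-point sweep: arithmetic grids, stop is a bound (CO2 ends at 1900).
sweep:
  temp_start: 12.0
  temp_stop: 36.0
  temp_step: 3.0
  co2_start: 300.0
  co2_stop: 2000.0
  co2_step: 200.0

co2_scale: 100.0       # CO2 divisor in the polynomial surface (C in hundreds)

# Off-grid validation set, scored against analytic saturation points.
validation:
  temp_levels: [12, 15, 20, 25, 30]
  co2_levels: [300, 600, 800, 1000, 1200, 1500]

seed: 0
outdir: luxsat_run
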