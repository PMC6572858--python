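# Methods

## Ground-truth light-response model

The synthetic generator draws net photosynthetic rate Pn (µmol CO₂ m⁻² s⁻¹)
from the modified rectangular hyperbola

P(I) = a_eff(T, C) · I (1 − β(T, C) I) / (1 + γ I) − R_d,

with I the PPFD (µmol photons m⁻² s⁻¹), T leaf temperature (°C) and C the
CO₂ concentration (µmol/mol). This family was chosen over other
light-response families (rectangular / non-rectangular hyperbola,
exponential) because its maximum has a closed form,

I_sat = (√((β+γ)/β) − 1) / γ,

which gives every simulated curve an analytic saturation point — an exact
oracle for the optimizer and for end-to-end validation. The environment
enters twice:

* **Initial slope.** a_eff = α₀ · exp(−(T−T_opt)²/(2σ_T²)) · C/(C+K_m).
  A multiplicative slope factor scales the whole curve and does not move
  I_sat.
* **Photoinhibition coefficient.** Optionally β is multiplied by
  (1 + ((T−T_opt)/w_T)²) — U-shaped in temperature, so I_sat peaks at
  T_opt — and by (floor + (1−floor)·K_β/(K_β+C)) — decreasing in CO₂, so
  I_sat rises quickly at low CO₂ and then flattens. Both match the
  qualitative physiology of cucumber: saturation points climb with CO₂
  enrichment, and rise then fall with temperature around ≈30 °C.

Defaults (α₀ = 0.1, β₀ = 2.4 × 10⁻⁴, γ = 2 × 10⁻³, R_d = 1.5,
T_opt = 30 °C, σ_T = 14 °C, K_m = 600 µmol/mol, w_T = 20 °C,
K_β = 400 µmol/mol, floor = 0.45) put the analytic saturation points in
≈825–1517 µmol m⁻² s⁻¹ across the sweep grid — inside the optimizer's
[800, 1800] search interval — and the Pn range at 0.3–21.7 µmol m⁻² s⁻¹,
typical of cucumber seedling gas exchange. Measurement noise is additive
homoscedastic Gaussian with σ = 0.15 µmol m⁻² s⁻¹, the scale of
triplicate-averaged readings from a portable gas-exchange system; replicate
averaging is the reason no heteroscedasticity is modelled. The generator
does not emulate stomatal dynamics, humidity effects, spectral quality, or
diurnal drift — so passing tests demonstrate the pipeline's numerical
behaviour under a clean, known response surface, not robustness to those
real-data effects.

## Surrogate models

All three surrogates map raw (T, C, I) to Pn through min–max normalization
of inputs *and* target onto [0.2, 0.9]; statistics come from the training
split only (no leakage; predictions are de-normalized). The split is random
with |train| = round(0.85·n).

* **ε-SVR (primary).** RBF kernel K(xᵢ,x) = exp(−g‖xᵢ−x‖²), solved by
  libsvm via scikit-learn; support vectors, dual coefficients and bias are
  extracted and prediction runs through an explicit kernel expansion, which
  makes the JSON persistence round trip exact. Hyperparameters (c, g) are
  selected by 5-fold cross-validated RMSE over a log₂ grid
  (c ∈ 2^{−1..9}, g ∈ 2^{−3..3}), with ties broken toward the smaller,
  smoother model. The shipped default (c = 2.82, g = 0.50) is the published
  optimum for a measured cucumber dataset and is kept for reference; CV
  re-selection is on by default because kernel hyperparameters are
  dataset-specific.
* **ε tube width.** Default ε = 0.001 in normalized target units
  (≈0.03 µmol m⁻² s⁻¹ on a typical Pn range). The sizing argument: near the
  saturation point the light-response curve varies by only ~0.03 µmol m⁻²
  s⁻¹ over ±100 PPFD, so any tube wider than that leaves the argmax
  completely unconstrained inside it. Empirically, a 0.01 tube produces
  saturation-point errors of several hundred µmol m⁻² s⁻¹ even on noiseless
  data; 0.001 reduces them by an order of magnitude.
* **RBF network.** Gaussian hidden layer (φ = exp(−d²/spread²),
  spread = 0.30 normalized units), linear output re-solved by least squares
  after each greedy center addition (the worst-fit training point), until
  training MSE ≤ 10⁻⁴ or a center cap; an unreached goal is flagged
  `converged=False` rather than raised.
* **BP network.** 3-5-1, tanh hidden / linear output, trained by a damped
  Gauss–Newton (Levenberg–Marquardt) loop with an analytic Jacobian; one
  epoch = one accepted LM step, λ scaled ×10 / ÷10 on reject/accept.
  Training stops at MSE ≤ 10⁻⁴ (normalized) or 1000 epochs. The explicit
  stop-at-goal rule is why LM is hand-rolled rather than delegated to a
  generic least-squares driver: the goal is part of the model contract, and
  it also caps how far the BP baseline can fit, which is what keeps the
  SVR ahead of it on clean data.

Metrics: MAE, RMSE, R² = 1 − SSE/SST, and MRE = 100·mean(|e|/|Pn|)
restricted to |Pn| ≥ 0.1 µmol m⁻² s⁻¹ — relative error explodes near the
light-compensation point where Pn crosses zero; if every observation is
excluded MRE is NaN with a warning. The slope/intercept regress predicted
on measured.

## Continuous ant colony optimizer

The PPFD domain [800, 1800] is divided into K = 50 subintervals of
D = 20 µmol m⁻² s⁻¹. Per iteration (200 total, N = 50 ants, evaporation
α = 0.1):

1. **Pheromone.** τᵢ = (1−α)(max(0, ∫ f dx over subinterval i) + ηᵢ τᵢ′),
   the integral by a composite trapezoid rule on 5 shared nodes per
   subinterval (exact for linear f, ~10⁻⁶ relative error for the smooth
   light-response curves). The floor at zero keeps pheromone meaningful
   when Pn is negative below the compensation point; the heuristic ηᵢ
   defaults to 1 (pure carry-over) and is configurable per subinterval.
2. **Allocation.** Nᵢ = N·τᵢ/Στ, rounded by largest remainder (ties to the
   lower index) so ΣNᵢ = N exactly. Total pheromone collapse (all τ = 0,
   e.g. an everywhere-negative objective) re-seeds uniformly and logs a
   warning.
3. **Movement.** Each subinterval's ants are placed uniformly at random
   inside it from the run's seeded generator — the simplest rule that
   realizes "ants concentrate where pheromone is high" while keeping the
   Δn = Δx/D bookkeeping consistent at subinterval granularity.

Ants start at subinterval midpoints (ant i in subinterval ((i−1) mod K)+1);
with N = K that is one ant per midpoint. A literal published placement
formula that crowds all ants near the lower domain edge is kept behind
`literal_placement=True` for documentation only. The reported optimum is
the best ant position ever evaluated, so the f_best trace is monotone.
x_best resolution is limited by within-subinterval sampling, in practice
≪ D: on the noiseless truth sweep the ACO recovers the closed-form
saturation points with MAE < 0.1 µmol m⁻² s⁻¹.

The GA baseline uses the classical configuration: 40 individuals, 20-bit
binary encoding on the domain, 200 generations, roulette selection on
min-shifted fitness, generation gap 0.95 with offspring replacing the worst
parents (elitism), single-point crossover (p = 0.7), bit-flip mutation
(p = 0.01).

## Control surface

PPFD = Σ cₖ·termₖ(T, C/s) over the fixed 12-term basis
[1, T, C, T², TC, C², T²C, TC², C³, T²C², TC³, C⁴] — nonlinear in (T, C),
linear in cₖ, hence fitted by ordinary least squares (rank-checked;
deficient terms are named via column-pivoted QR). The CO₂ scale s is an
explicit parameter defaulting to 100 (C in hundreds of µmol/mol): the
reference coefficient set's units are ambiguous, and evaluating it across
the sweep grid shows only s = 100 keeps its output inside a physically
plausible PPFD range (≈330–1100 µmol m⁻² s⁻¹); raw µmol/mol or thousands
produce values far outside any usable control target. Validation regresses
surface predictions on reference saturation points; its r² is the squared
correlation and is insensitive to a pure offset or gain miscalibration.

## Conditioning of the end-to-end chain

The chain's accuracy is bounded by a genuine ill-conditioning, worth
stating plainly. Near its maximum a light-response curve is almost flat
(second derivative ≈ 6 × 10⁻⁶ µmol m⁻² s⁻¹ per (µmol m⁻² s⁻¹)²), so a
surrogate error of δ shifts the extracted argmax by roughly √(2δ/|P″|):
δ = 0.1 µmol m⁻² s⁻¹ — far better than typical measurement noise — already
moves the saturation point by ~180 µmol m⁻² s⁻¹. Moreover, held-out
prediction R² does not discriminate between argmax-faithful and
argmax-distorting surrogates (it is ≈0.999 for every hyperparameter pair
tried), so cross-validation on prediction error cannot select for argmax
fidelity. Consequently the surrogate-based sweep carries errors of order
50–150 µmol m⁻² s⁻¹ against the analytic saturation points (with the worst
distortion at sweep conditions outside the training envelope, CO₂ < 600
µmol/mol and T > 33 °C, where the kernel model extrapolates), and the
end-to-end validation r² fluctuates strongly between seeds. The optimizer
contributes < 0.1 to this budget. Accurate saturation-point control
therefore hinges on the surrogate's shape fidelity near the optimum, not on
the optimizer, and prediction-error model selection is the weak link.

## Problem sizes and determinism

Default runs use the 420-row design, a 357/63 split, a 9 × 9 (T, C) sweep
(81 ACO runs of 200 iterations) and a 30-point validation grid; the
optimizer benchmark uses 10 random curves × 20 seeds per algorithm. One
global seed derives per-stage seeds (stage-name CRC keyed, < 2³¹), so every
stage — and the whole pipeline — is a pure function of its configuration.
All artifacts are text (CSV at fixed precision, JSON), and a resumed run
consumes the serialized artifacts, making fresh and resumed runs
bit-identical.

## Known limitations

* The synthetic truth is smooth and separable in its environment
  modulation; real canopies show interactions (e.g. vapour-pressure
  deficit) the generator omits.
* The GA and ACO movement/selection rules follow standard textbook forms;
  where the original continuous-ACO description is qualitative (movement
  rule, heuristic η), the choices here are documented defaults, not
  reconstructions.
* The reference polynomial is reproduced bit-exactly but its CO₂ unit
  convention is inferred from a plausibility range check, not stated by its
  source.
* MRE is undefined when all observations sit below the 0.1 µmol m⁻² s⁻¹
  guard; callers see NaN plus a warning rather than an exception.
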