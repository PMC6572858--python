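"""Continuous-domain ant colony optimization of light-response curves, plus a GA baseline.

The search maximizes a one-dimensional objective f(PPFD) — typically a
surrogate light-response curve at fixed temperature and CO2 — over a bounded
PPFD domain.  The continuous ACO partitions the domain [lower, upper] into
K = (upper - lower)/D equal subintervals; each iteration

1. deposits pheromone per subinterval,
   tau_i = (1 - alpha) * (integral of f over subinterval i + eta_i * tau_i'),
   with the integral taken by a composite trapezoid rule and floored at zero
   (Pn below the light-compensation point must not produce negative
   pheromone),
2. re-allocates the N ants proportionally to tau (largest-remainder
   rounding), and
3. places each subinterval's ants uniformly at random inside it.

The reported optimum x_best is the best ant position ever evaluated, so the
f_best trace is monotone non-decreasing.  The GA baseline is a classical
binary-encoded genetic algorithm with roulette selection, a generation gap
with elitist reinsertion, single-point crossover and bit-flip mutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AcoConfig",
    "GaConfig",
    "ColonyState",
    "OptimizationResult",
    "SaturationPoint",
    "init_colony",
    "pheromone_update",
    "allocate_ants",
    "move_colony",
    "aco_maximize",
    "ga_maximize",
    "arith_grid",
    "sweep_saturation_points",
    "SWEEP_COLUMNS",
]

logger = logging.getLogger(__name__)

SWEEP_COLUMNS = ("temp_c", "co2_umol_mol", "ppfd_sat", "pn_max")


@dataclass(frozen=True)
class AcoConfig:
    """Continuous-ACO parameters.

    Defaults are the published configuration: N = 50 ants, subinterval length
    D = 20 µmol m-2 s-1, evaporation alpha = 0.1, 200 iterations on the PPFD
    domain [800, 1800].  ``eta`` is the heuristic carry-over weight of the
    previous generation's pheromone (scalar or per-subinterval vector).
    ``literal_placement`` switches initialization to the literal published
    placement formula x_i = lower + (i/N - 1/2) * D, which crowds every ant
    near the lower domain edge; it is retained for documentation and is not
    the default.
    """

    n_ants: int = 50
    subinterval_length: float = 20.0
    evaporation: float = 0.1
    eta: float | tuple = 1.0
    max_iters: int = 200
    domain: tuple[float, float] = (800.0, 1800.0)
    quad_points: int = 5
    seed: int = 0
    literal_placement: bool = False

    def __post_init__(self):
        object.__setattr__(self, "domain", tuple(float(v) for v in self.domain))
        lower, upper = self.domain
        if not upper > lower:
            raise ValueError("domain upper bound must exceed lower bound")
        if self.subinterval_length <= 0:
            raise ValueError("subinterval_length must be > 0")
        k = (upper - lower) / self.subinterval_length
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ValueError(
                f"domain width {upper - lower} is not a whole multiple of "
                f"D={self.subinterval_length} (K={k:.6g} subintervals)"
            )
        if not 0.0 <= self.evaporation <= 1.0:
            raise ValueError("evaporation must be in [0, 1]")
        if self.n_ants < 1:
            raise ValueError("n_ants must be >= 1")
        if self.quad_points < 2:
            raise ValueError("quad_points must be >= 2")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")

    @property
    def n_subintervals(self) -> int:
        lower, upper = self.domain
        return int(round((upper - lower) / self.subinterval_length))

    def eta_vector(self) -> np.ndarray:
        eta = np.asarray(self.eta, dtype=float)
        if eta.ndim == 0:
            return np.full(self.n_subintervals, float(eta))
        if eta.shape != (self.n_subintervals,):
            raise ValueError("eta vector length must equal the subinterval count")
        return eta

    def edges(self) -> np.ndarray:
        lower, upper = self.domain
        return lower + self.subinterval_length * np.arange(self.n_subintervals + 1)


@dataclass(frozen=True)
class GaConfig:
    """Binary-encoded GA parameters (published defaults)."""

    pop_size: int = 40
    max_gen: int = 200
    chrom_bits: int = 20
    ggap: float = 0.95
    px: float = 0.7
    pm: float = 0.01
    domain: tuple[float, float] = (800.0, 1800.0)
    seed: int = 0

    def __post_init__(self):
        if self.chrom_bits < 1:
            raise ValueError("chrom_bits must be >= 1")
        for name in ("ggap", "px", "pm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        object.__setattr__(self, "domain", tuple(float(v) for v in self.domain))
        lower, upper = self.domain
        if not upper > lower:
            raise ValueError("domain upper bound must exceed lower bound")


@dataclass
class ColonyState:
    positions: np.ndarray       # (N,) PPFD per ant
    tau: np.ndarray             # (K,) pheromone per subinterval
    tau_prev: np.ndarray        # (K,) previous-generation residual
    counts: np.ndarray          # (K,) ants per subinterval
    iteration: int = 0


@dataclass(frozen=True)
class OptimizationResult:
    x_best: float
    f_best: float
    trace: np.ndarray           # best-so-far f per iteration
    n_iters: int


@dataclass(frozen=True)
class SaturationPoint:
    """One optimized light saturation point at fixed (T, CO2)."""

    temp: float
    co2: float
    ppfd_sat: float
    pn_max: float


def _eval_objective(objective, x: np.ndarray) -> np.ndarray:
    """Evaluate a (preferably vectorized) scalar objective on an array."""
    x = np.asarray(x, dtype=float)
    try:
        f = np.asarray(objective(x), dtype=float)
        if f.shape != x.shape:
            raise TypeError
    except TypeError:
        f = np.array([float(objective(xi)) for xi in x])
    if not np.all(np.isfinite(f)):
        bad = x[~np.isfinite(f)][0]
        raise ValueError(f"objective is non-finite at x = {bad!r}")
    return f


def _subinterval_of(x: np.ndarray, config: AcoConfig) -> np.ndarray:
    lower, _ = config.domain
    k = config.n_subintervals
    idx = np.floor((x - lower) / config.subinterval_length).astype(int)
    return np.clip(idx, 0, k - 1)


def init_colony(config: AcoConfig) -> ColonyState:
    """Place the ants over the domain and zero the pheromone memory.

    Ant i (1-based) sits at the midpoint of subinterval ((i-1) mod K) + 1:
    x = lower + (((i-1) mod K) + 1/2) * D.  With N = K this is exactly one
    ant per subinterval midpoint.
    """
    k = config.n_subintervals
    lower, upper = config.domain
    i = np.arange(config.n_ants)
    if config.literal_placement:
        positions = lower + ((i + 1) / config.n_ants - 0.5) * config.subinterval_length
        positions = np.clip(positions, lower, upper)
    else:
        positions = lower + ((i % k) + 0.5) * config.subinterval_length
    counts = np.bincount(_subinterval_of(positions, config), minlength=k)
    return ColonyState(
        positions=positions,
        tau=np.zeros(k),
        tau_prev=np.zeros(k),
        counts=counts,
        iteration=0,
    )


def pheromone_update(state: ColonyState, objective, config: AcoConfig) -> np.ndarray:
    """Deposit pheromone per subinterval and advance the pheromone memory.

    tau_i = (1 - alpha) * (max(0, trapezoid integral of f over subinterval i)
    + eta_i * tau_i').  The state's ``tau`` and ``tau_prev`` are updated in
    place; the new tau is returned.
    """
    k = config.n_subintervals
    q = config.quad_points
    edges = config.edges()
    # shared node grid: q nodes per subinterval, endpoints shared between neighbours
    nodes = np.linspace(config.domain[0], config.domain[1], k * (q - 1) + 1)
    f = _eval_objective(objective, nodes)
    # composite trapezoid per subinterval, vectorized over the shared node grid
    h = config.subinterval_length / (q - 1)
    starts = (q - 1) * np.arange(k)
    csum = np.concatenate([[0.0], np.cumsum(f)])
    inner = csum[starts + q - 1] - csum[starts + 1]  # strictly interior nodes
    integrals = h * (0.5 * (f[starts] + f[starts + q - 1]) + inner)
    integrals = np.maximum(integrals, 0.0)
    tau = (1.0 - config.evaporation) * (integrals + config.eta_vector() * state.tau_prev)
    state.tau = tau
    state.tau_prev = tau.copy()
    return tau


def allocate_ants(tau: np.ndarray, n_ants: int) -> np.ndarray:
    """Integer ant counts proportional to pheromone, largest-remainder rounded.

    Counts sum exactly to ``n_ants``; remainder ties go to the lower
    subinterval index.  If all pheromone has collapsed to zero the ants are
    re-seeded uniformly (logged).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("pheromone must be non-negative")
    k = len(tau)
    total = tau.sum()
    if total <= 0:
        logger.warning("pheromone collapse: re-seeding %d ants uniformly over %d subintervals", n_ants, k)
        base, extra = divmod(n_ants, k)
        counts = np.full(k, base, dtype=int)
        counts[:extra] += 1
        return counts
    quota = n_ants * tau / total
    counts = np.floor(quota).astype(int)
    remainder = n_ants - counts.sum()
    if remainder > 0:
        frac = quota - np.floor(quota)
        order = np.lexsort((np.arange(k), -frac))  # largest fraction first, lower index on ties
        counts[order[:remainder]] += 1
    return counts


def move_colony(counts: np.ndarray, config: AcoConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Place each subinterval's ants uniformly at random inside it.

    The per-ant displacement Delta x implied by re-allocation respects the
    Delta n = Delta x / D bookkeeping at subinterval granularity: moving an
    ant by one subinterval length changes that subinterval's count by one.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.sum() != config.n_ants:
        raise ValueError("counts must sum to the configured ant number")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    edges = config.edges()
    parts = [
        rng.uniform(edges[i], edges[i + 1], size=c)
        for i, c in enumerate(counts)
        if c > 0
    ]
    positions = np.concatenate(parts) if parts else np.empty(0)
    return positions


def aco_maximize(objective, config: AcoConfig) -> OptimizationResult:
    """Run the continuous ACO loop; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    state = init_colony(config)
    x_best = float("nan")
    f_best = -np.inf
    trace = np.empty(config.max_iters)
    for it in range(config.max_iters):
        f = _eval_objective(objective, state.positions)
        i = int(np.argmax(f))
        if f[i] > f_best:
            f_best = float(f[i])
            x_best = float(state.positions[i])
        trace[it] = f_best
        tau = pheromone_update(state, objective, config)
        counts = allocate_ants(tau, config.n_ants)
        state.positions = move_colony(counts, config, rng)
        state.counts = counts
        state.iteration = it + 1
    return OptimizationResult(x_best=x_best, f_best=f_best, trace=trace, n_iters=config.max_iters)


# ---------------------------------------------------------------------------
# GA baseline

def _ga_decode(pop: np.ndarray, config: GaConfig) -> np.ndarray:
    bits = config.chrom_bits
    weights = 2.0 ** np.arange(bits - 1, -1, -1)
    ints = pop @ weights
    lower, upper = config.domain
    return lower + ints / (2.0**bits - 1.0) * (upper - lower)


def ga_maximize(objective, config: GaConfig) -> OptimizationResult:
    """Binary-encoded GA: roulette selection with generation gap and elitist
    reinsertion, single-point crossover, bit-flip mutation."""
    rng = np.random.default_rng(config.seed)
    nind, bits = config.pop_size, config.chrom_bits
    pop = rng.integers(0, 2, size=(nind, bits)).astype(float)
    x = _ga_decode(pop, config)
    fit = _eval_objective(objective, x)
    best_i = int(np.argmax(fit))
    x_best, f_best = float(x[best_i]), float(fit[best_i])
    trace = np.empty(config.max_gen)
    n_off = max(2, int(round(config.ggap * nind)))
    n_off -= n_off % 2  # crossover works on pairs
    for gen in range(config.max_gen):
        # fitness-proportional selection on min-shifted fitness
        shifted = fit - fit.min()
        if shifted.sum() <= 0:
            prob = np.full(nind, 1.0 / nind)
        else:
            prob = shifted / shifted.sum()
        parents = pop[rng.choice(nind, size=n_off, p=prob)]
        # single-point crossover
        offspring = parents.copy()
        for j in range(0, n_off, 2):
            if rng.random() < config.px:
                cut = int(rng.integers(1, bits))
                offspring[j, cut:], offspring[j + 1, cut:] = (
                    parents[j + 1, cut:].copy(),
                    parents[j, cut:].copy(),
                )
        # bit-flip mutation
        flips = rng.random(offspring.shape) < config.pm
        offspring = np.where(flips, 1.0 - offspring, offspring)
        # elitist reinsertion: offspring replace the worst parents
        off_x = _ga_decode(offspring, config)
        off_fit = _eval_objective(objective, off_x)
        worst = np.argsort(fit)[:n_off]
        pop[worst] = offspring
        x[worst] = off_x
        fit[worst] = off_fit
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > f_best:
            f_best = float(fit[gen_best])
            x_best = float(x[gen_best])
        trace[gen] = f_best
    return OptimizationResult(x_best=x_best, f_best=f_best, trace=trace, n_iters=config.max_gen)


# ---------------------------------------------------------------------------
# saturation-point sweeps

def arith_grid(start: float, stop: float, step: float) -> np.ndarray:
    """start, start+step, ... while <= stop (the stop is a bound, not
    necessarily attained; e.g. 300-2000 step 200 ends at 1900)."""
    if step <= 0:
        raise ValueError("step must be > 0")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    if n < 1:
        raise ValueError("empty grid: stop < start")
    grid = start + step * np.arange(n)
    if grid[-1] < stop - 1e-9:
        pass
    elif abs(grid[-1] - stop) > 1e-9:
        logger.info("grid endpoint convention: %s-%s step %s ends at %s", start, stop, step, grid[-1])
    return grid


def _as_objective(model_or_fn, temp: float, co2: float):
    predictor = getattr(model_or_fn, "predict", None)
    if predictor is not None:
        return lambda x: predictor(temp, co2, x)
    return lambda x: model_or_fn(x, temp, co2)


def sweep_saturation_points(
    model_or_fn,
    temp_grid,
    co2_grid,
    config: AcoConfig | GaConfig = AcoConfig(),
) -> pd.DataFrame:
    """One optimized saturation point per (T, CO2) pair.

    ``model_or_fn`` is either a fitted surrogate (``.predict(temp, co2,
    ppfd)``) or a truth function ``f(ppfd, temp, co2)``.  Per-pair runs use
    seeds derived deterministically from ``config.seed``.
    """
    temp_grid = np.asarray(temp_grid, dtype=float)
    co2_grid = np.asarray(co2_grid, dtype=float)
    if temp_grid.size == 0 or co2_grid.size == 0:
        raise ValueError("temperature and CO2 grids must be non-empty")
    runner = ga_maximize if isinstance(config, GaConfig) else aco_maximize
    rows = []
    idx = 0
    for temp in temp_grid:
        for co2 in co2_grid:
            run_cfg = replace(config, seed=(int(config.seed) * 100003 + idx) % (2**31))
            res = runner(_as_objective(model_or_fn, float(temp), float(co2)), run_cfg)
            rows.append((float(temp), float(co2), res.x_best, res.f_best))
            idx += 1
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))
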