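"""Synthetic leaf gas-exchange data with an analytically known light saturation point.

The generator emulates a nested gas-exchange experiment: net photosynthetic
rate Pn measured over a Cartesian grid of CO2 concentration, leaf temperature
and photosynthetic photon flux density (PPFD).  The ground-truth
light-response family is the modified rectangular hyperbola

    Pn(I) = a_eff * I * (1 - beta*I) / (1 + gamma*I) - Rd

whose maximum over PPFD has the closed form

    I_sat = (sqrt((beta + gamma) / beta) - 1) / gamma,

giving every simulated curve an exact, analytic light saturation point that
downstream optimizers can be scored against.  Environmental dependence enters
in two places:

* the initial slope ``a_eff`` is ``alpha0`` scaled by a Gaussian temperature
  factor exp(-(T - topt)^2 / (2 tsigma^2)) and a Michaelis-Menten CO2 factor
  C / (C + km_co2), and
* optionally, the photoinhibition coefficient ``beta`` is modulated by
  temperature (U-shaped around ``topt``) and CO2 (decreasing, saturating),
  which makes the saturation point itself rise with CO2 and peak near the
  temperature optimum — the qualitative behaviour reported for cucumber.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CSV_COLUMNS",
    "DEFAULT_CO2_LEVELS",
    "DEFAULT_TEMP_LEVELS",
    "DEFAULT_PPFD_LEVELS",
    "DesignGrid",
    "TruthParams",
    "Sample",
    "make_design_grid",
    "default_design_grid",
    "effective_beta",
    "true_photosynthesis",
    "analytic_saturation_point",
    "simulate_dataset",
    "write_samples_csv",
    "read_samples_csv",
]

#: Canonical CSV schema for sample tables (UTF-8, '.' decimal separator).
CSV_COLUMNS = ("temp_c", "co2_umol_mol", "ppfd_umol_m2_s", "pn_umol_m2_s")

#: The nested experimental design levels used throughout as the default fixture.
DEFAULT_CO2_LEVELS = (600.0, 800.0, 1000.0, 1200.0, 1500.0, 1700.0, 2000.0)
DEFAULT_TEMP_LEVELS = (12.0, 15.0, 20.0, 25.0, 30.0, 33.0)
DEFAULT_PPFD_LEVELS = (100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 800.0, 1000.0, 1200.0, 1400.0)


def _check_levels(name: str, levels) -> tuple[float, ...]:
    values = tuple(float(v) for v in levels)
    if len(values) == 0:
        raise ValueError(f"{name}: level list must be non-empty")
    if any(v <= 0 for v in values):
        raise ValueError(f"{name}: levels must be strictly positive, got {values}")
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError(f"{name}: levels must be strictly increasing, got {values}")
    return values


@dataclass(frozen=True)
class DesignGrid:
    """A nested CO2 x temperature x PPFD experimental design."""

    co2_levels: tuple[float, ...]
    temp_levels: tuple[float, ...]
    ppfd_levels: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "co2_levels", _check_levels("co2_levels", self.co2_levels))
        object.__setattr__(self, "temp_levels", _check_levels("temp_levels", self.temp_levels))
        object.__setattr__(self, "ppfd_levels", _check_levels("ppfd_levels", self.ppfd_levels))

    def __len__(self) -> int:
        return len(self.co2_levels) * len(self.temp_levels) * len(self.ppfd_levels)

    def to_frame(self) -> pd.DataFrame:
        """Expand the design to condition rows, CO2-major, then temperature, then PPFD."""
        rows = list(itertools.product(self.co2_levels, self.temp_levels, self.ppfd_levels))
        co2, temp, ppfd = zip(*rows)
        return pd.DataFrame({"co2_umol_mol": co2, "temp_c": temp, "ppfd_umol_m2_s": ppfd})


def make_design_grid(co2_levels, temp_levels, ppfd_levels) -> DesignGrid:
    """Build a validated nested design; the full design has |co2|*|temp|*|ppfd| rows."""
    return DesignGrid(tuple(co2_levels), tuple(temp_levels), tuple(ppfd_levels))


def default_design_grid() -> DesignGrid:
    """The 7 CO2 x 6 temperature x 10 PPFD nested design (420 condition rows)."""
    return make_design_grid(DEFAULT_CO2_LEVELS, DEFAULT_TEMP_LEVELS, DEFAULT_PPFD_LEVELS)


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth light-response parameters.

    Parameters
    ----------
    alpha0 : initial slope scale, µmol CO2 per µmol photons.
    beta : baseline photoinhibition coefficient, per µmol m-2 s-1.
    gamma : saturation coefficient, per µmol m-2 s-1 (must exceed beta).
    rd : dark respiration, µmol CO2 m-2 s-1.
    topt, tsigma : optimum (°C) and breadth (°C) of the Gaussian temperature
        modulation of the initial slope.
    km_co2 : half-saturation CO2 of the Michaelis-Menten slope modulation,
        µmol/mol.
    noise_sd : additive Gaussian measurement noise s.d., µmol CO2 m-2 s-1.
    beta_t_width : if not None, beta is multiplied by
        1 + ((T - topt)/beta_t_width)^2, making the saturation point peak at
        ``topt`` and fall off on both sides.
    beta_co2_km, beta_co2_floor : if ``beta_co2_km`` is not None, beta is
        multiplied by floor + (1-floor)*km/(km+C), so the saturation point
        rises with CO2, rapidly at first and then slowly.
    """

    alpha0: float = 0.1
    beta: float = 2.4e-4
    gamma: float = 2.0e-3
    rd: float = 1.5
    topt: float = 30.0
    tsigma: float = 14.0
    km_co2: float = 600.0
    noise_sd: float = 0.15
    beta_t_width: float | None = 20.0
    beta_co2_km: float | None = 400.0
    beta_co2_floor: float = 0.45

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.gamma <= self.beta:
            raise ValueError("gamma must exceed beta for a finite positive maximum")
        if self.rd < 0:
            raise ValueError("rd must be >= 0")
        if self.tsigma <= 0:
            raise ValueError("tsigma must be > 0")
        if self.km_co2 <= 0:
            raise ValueError("km_co2 must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.beta_t_width is not None and self.beta_t_width <= 0:
            raise ValueError("beta_t_width must be > 0 or None")
        if self.beta_co2_km is not None and self.beta_co2_km <= 0:
            raise ValueError("beta_co2_km must be > 0 or None")
        if not 0 <= self.beta_co2_floor <= 1:
            raise ValueError("beta_co2_floor must be in [0, 1]")


@dataclass(frozen=True)
class Sample:
    """One gas-exchange observation."""

    temp: float
    co2: float
    ppfd: float
    pn: float


def effective_beta(params: TruthParams, temp, co2):
    """Local photoinhibition coefficient beta(T, C) under the optional modulations."""
    temp = np.asarray(temp, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    beta = np.full(np.broadcast(temp, co2).shape, params.beta)
    if params.beta_t_width is not None:
        beta = beta * (1.0 + ((temp - params.topt) / params.beta_t_width) ** 2)
    if params.beta_co2_km is not None:
        km, floor = params.beta_co2_km, params.beta_co2_floor
        beta = beta * (floor + (1.0 - floor) * km / (km + co2))
    return beta if beta.shape else float(beta)


def _effective_alpha(params: TruthParams, temp, co2):
    temp = np.asarray(temp, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    t_factor = np.exp(-((temp - params.topt) ** 2) / (2.0 * params.tsigma**2))
    c_factor = co2 / (co2 + params.km_co2)
    return params.alpha0 * t_factor * c_factor


def true_photosynthesis(ppfd, temp, co2, params: TruthParams):
    """Noiseless net photosynthetic rate at (PPFD, T, C), µmol CO2 m-2 s-1.

    Vectorized over all arguments (numpy broadcasting).  At PPFD = 0 the value
    is -rd (dark respiration only).
    """
    ppfd = np.asarray(ppfd, dtype=float)
    if np.any(ppfd < 0):
        raise ValueError("ppfd must be >= 0")
    a_eff = _effective_alpha(params, temp, co2)
    beta = effective_beta(params, temp, co2)
    pn = a_eff * ppfd * (1.0 - beta * ppfd) / (1.0 + params.gamma * ppfd) - params.rd
    return pn if np.asarray(pn).shape else float(pn)


def analytic_saturation_point(params: TruthParams, temp, co2):
    """Closed-form PPFD maximizing :func:`true_photosynthesis` at fixed (T, C).

    I_sat = (sqrt((beta + gamma)/beta) - 1) / gamma evaluated at the local
    beta(T, C).  The multiplicative slope modulation does not move the argmax.
    """
    beta = np.asarray(effective_beta(params, temp, co2), dtype=float)
    if np.any(beta == 0):
        raise ValueError("no finite maximum: beta = 0 gives a monotone saturating curve")
    gamma = params.gamma
    i_sat = (np.sqrt((beta + gamma) / beta) - 1.0) / gamma
    return i_sat if i_sat.shape else float(i_sat)


def simulate_dataset(grid: DesignGrid, params: TruthParams, seed: int) -> pd.DataFrame:
    """Simulate one noisy Pn observation per design row.

    Pure function of (grid, params, seed): the same arguments always produce
    an identical table.  Returns a DataFrame with the canonical CSV columns.
    """
    conditions = grid.to_frame()
    pn = true_photosynthesis(
        conditions["ppfd_umol_m2_s"].to_numpy(),
        conditions["temp_c"].to_numpy(),
        conditions["co2_umol_mol"].to_numpy(),
        params,
    )
    rng = np.random.default_rng(int(seed))
    if params.noise_sd > 0:
        pn = pn + rng.normal(0.0, params.noise_sd, size=len(conditions))
    out = pd.DataFrame(
        {
            "temp_c": conditions["temp_c"],
            "co2_umol_mol": conditions["co2_umol_mol"],
            "ppfd_umol_m2_s": conditions["ppfd_umol_m2_s"],
            "pn_umol_m2_s": pn,
        }
    )
    return out


def random_curve_params(
    n: int,
    seed: int,
    sat_range: tuple[float, float] = (850.0, 1750.0),
) -> list[TruthParams]:
    """Draw ``n`` random single-condition light-response parameter sets whose
    analytic saturation points fall inside ``sat_range``.

    Used as a benchmark family for optimizer oracle tests: each parameter set
    defines one unimodal curve (no environment modulation, no noise) whose
    argmax is known in closed form.
    """
    rng = np.random.default_rng(int(seed))
    out: list[TruthParams] = []
    while len(out) < n:
        gamma = 10.0 ** rng.uniform(-3.0, -2.4)
        ratio = rng.uniform(4.0, 24.0)
        sat = (np.sqrt(1.0 + ratio) - 1.0) / gamma
        if not sat_range[0] <= sat <= sat_range[1]:
            continue
        out.append(
            TruthParams(
                alpha0=rng.uniform(0.02, 0.12),
                beta=gamma / ratio,
                gamma=gamma,
                rd=rng.uniform(0.0, 2.0),
                noise_sd=0.0,
                beta_t_width=None,
                beta_co2_km=None,
            )
        )
    return out


def write_samples_csv(samples: pd.DataFrame, path) -> None:
    """Write a sample table in the canonical schema at fixed precision."""
    samples.loc[:, list(CSV_COLUMNS)].to_csv(path, index=False, float_format="%.6f")


def read_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample CSV missing columns: {sorted(missing)}")
    return df
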