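"""Polynomial control surface PPFD = f(T, CO2) over optimized saturation points.

The surface is a 12-term polynomial in temperature T (°C) and scaled CO2
concentration C (CO2 in µmol/mol divided by ``co2_scale``), with the fixed
term order

    [1, T, C, T^2, T*C, C^2, T^2*C, T*C^2, C^3, T^2*C^2, T*C^3, C^4].

It is nonlinear in (T, C) but linear in its coefficients, so fitting is
ordinary least squares on the polynomial design matrix.  A reference
coefficient set for greenhouse cucumber is shipped in
:func:`reference_eq1`; its CO2 unit convention is ambiguous in the source
material, and numerically only C in hundreds of µmol/mol (co2_scale = 100)
keeps its output in a physically plausible PPFD range over the sweep grid,
so 100 is the default scale everywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "TERM_NAMES",
    "ControlSurface",
    "ValidationReport",
    "design_matrix",
    "fit_control_surface",
    "eval_control_surface",
    "reference_eq1",
    "validate_model",
    "save_surface",
    "load_surface",
]

TERM_NAMES = ("1", "T", "C", "T2", "TC", "C2", "T2C", "TC2", "C3", "T2C2", "TC3", "C4")

#: Reference cucumber control-surface coefficients, in TERM_NAMES order.
REFERENCE_EQ1_COEFFICIENTS = (
    159.1,
    -0.7938,
    80.32,
    0.0002105,
    0.162,
    -3.379,
    -2.577e-5,
    -0.00583,
    0.09797,
    3.792e-7,
    6.997e-5,
    -0.001279,
)

DEFAULT_CO2_SCALE = 100.0


def design_matrix(temp, co2, co2_scale: float) -> np.ndarray:
    """The 12-column polynomial basis at (T, C/co2_scale)."""
    t = np.atleast_1d(np.asarray(temp, dtype=float))
    c = np.atleast_1d(np.asarray(co2, dtype=float)) / float(co2_scale)
    t, c = np.broadcast_arrays(t, c)
    cols = [
        np.ones_like(t), t, c, t**2, t * c, c**2,
        t**2 * c, t * c**2, c**3, t**2 * c**2, t * c**3, c**4,
    ]
    return np.column_stack([col.ravel() for col in cols])


@dataclass(frozen=True)
class ControlSurface:
    """12 polynomial coefficients plus the CO2 unit-scale convention."""

    coefficients: np.ndarray
    co2_scale: float = DEFAULT_CO2_SCALE
    r2: float = float("nan")
    rmse: float = float("nan")

    def __post_init__(self):
        coef = np.asarray(self.coefficients, dtype=float).ravel()
        if coef.shape != (12,):
            raise ValueError(f"exactly 12 coefficients required, got {coef.shape}")
        if self.co2_scale <= 0:
            raise ValueError("co2_scale must be > 0")
        object.__setattr__(self, "coefficients", coef)

    def evaluate(self, temp, co2):
        return eval_control_surface(self, temp, co2)


@dataclass(frozen=True)
class ValidationReport:
    """OLS line of predicted vs reference saturation points."""

    slope: float
    intercept: float
    r2: float
    residuals: np.ndarray
    n: int


def fit_control_surface(
    points: pd.DataFrame,
    co2_scale: float = DEFAULT_CO2_SCALE,
) -> ControlSurface:
    """Least-squares fit of the 12-term surface to swept saturation points.

    ``points`` needs columns ``temp_c``, ``co2_umol_mol``, ``ppfd_sat`` with
    at least 12 distinct (T, C) pairs.  Raises on a rank-deficient design,
    naming the deficient terms.
    """
    temp = points["temp_c"].to_numpy(dtype=float)
    co2 = points["co2_umol_mol"].to_numpy(dtype=float)
    y = points["ppfd_sat"].to_numpy(dtype=float)
    distinct = len(set(zip(temp.tolist(), co2.tolist())))
    if distinct < 12:
        raise ValueError(f"need >= 12 distinct (T, CO2) points, got {distinct}")
    a = design_matrix(temp, co2, co2_scale)
    rank = np.linalg.matrix_rank(a)
    if rank < 12:
        # column-pivoted QR: the trailing pivots are the dependent terms
        _, _, piv = scipy.linalg.qr(a, pivoting=True, mode="economic")
        deficient = [TERM_NAMES[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design (rank {rank}/12); deficient terms: {deficient}")
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = a @ coef - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    return ControlSurface(coefficients=coef, co2_scale=float(co2_scale), r2=r2, rmse=rmse)


def eval_control_surface(surface: ControlSurface, temp, co2):
    """Sum of coefficient * term over the 12-term basis; vectorized."""
    temp_arr = np.asarray(temp, dtype=float)
    co2_arr = np.asarray(co2, dtype=float)
    shape = np.broadcast(temp_arr, co2_arr).shape
    out = design_matrix(temp_arr, co2_arr, surface.co2_scale) @ surface.coefficients
    return out.reshape(shape) if shape else float(out[0])


def reference_eq1(co2_scale: float = DEFAULT_CO2_SCALE) -> ControlSurface:
    """The published cucumber control surface, coefficients verbatim."""
    return ControlSurface(
        coefficients=np.array(REFERENCE_EQ1_COEFFICIENTS), co2_scale=float(co2_scale)
    )


def validate_model(surface: ControlSurface, reference_points: pd.DataFrame) -> ValidationReport:
    """Regress surface predictions on reference saturation points.

    ``reference_points`` needs columns ``temp_c``, ``co2_umol_mol``,
    ``ppfd_sat`` (the reference value) and at least 3 rows with non-constant
    reference values.
    """
    if len(reference_points) < 3:
        raise ValueError("need >= 3 reference points")
    temp = reference_points["temp_c"].to_numpy(dtype=float)
    co2 = reference_points["co2_umol_mol"].to_numpy(dtype=float)
    ref = reference_points["ppfd_sat"].to_numpy(dtype=float)
    if np.allclose(ref, ref[0]):
        raise ValueError("degenerate reference set: all saturation points equal")
    pred = eval_control_surface(surface, temp, co2)
    slope, intercept = np.polyfit(ref, pred, 1)
    fitted = slope * ref + intercept
    ss_res = float(np.sum((pred - fitted) ** 2))
    ss_tot = float(np.sum((pred - pred.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return ValidationReport(
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        residuals=pred - ref,
        n=len(ref),
    )


def save_surface(surface: ControlSurface, path) -> None:
    doc = {
        "co2_scale": surface.co2_scale,
        "coefficients": dict(zip(TERM_NAMES, surface.coefficients.tolist())),
        "r2": surface.r2,
        "rmse": surface.rmse,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_surface(path) -> ControlSurface:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    coef = np.array([doc["coefficients"][name] for name in TERM_NAMES])
    return ControlSurface(
        coefficients=coef,
        co2_scale=float(doc["co2_scale"]),
        r2=float(doc.get("r2", float("nan"))),
        rmse=float(doc.get("rmse", float("nan"))),
    )
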