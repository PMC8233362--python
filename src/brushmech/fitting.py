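"""Nonlinear least-squares estimation of (E, beta) from tensile curves.

Given a measured stress-elongation record, the strain-stiffening equation
of state is fitted by bounded trust-region least squares to recover the
structural modulus E and firmness beta, from which Young's modulus E0 and
the theoretical elongation at break beta^(-1/2) follow in closed form.

Measured curves may carry either true or engineering stress; fitting always
happens on true stress (sigma_true = lambda * sigma_eng under
incompressibility).  Points that an intermediate iterate would place at or
beyond its singular elongation contribute a large but finite and smooth
penalty, implemented by a smooth positive floor on the strain-stiffening
denominator, so the objective stays differentiable everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import lmfit
import numpy as np

from .constitutive import (
    MaterialParams,
    DomainError,
    lambda_max_theo,
    lambda_singular,
    engineering_to_true,
    true_stress,
    young_modulus,
)

MIN_FIT_POINTS = 5
_BETA_LO, _BETA_HI = 1e-6, 1.0 - 1e-6
# width of the smooth floor on the stiffening denominator; keeps residuals
# finite and C^1 when an iterate pushes a data point past its singularity
_DENOM_SMOOTH = 1e-6


class CurveError(ValueError):
    """Invalid stress-strain curve input."""


@dataclass(frozen=True)
class StressStrainCurve:
    """Ordered (lambda, sigma) samples from a uniaxial tensile test.

    ``sigma`` is in kPa; ``stress_kind`` declares whether the file carried
    true or engineering stress.  ``strain_rate_per_s`` defaults to the
    quasi-static protocol rate of 0.005 s^-1.
    """

    lam: np.ndarray
    sigma: np.ndarray
    stress_kind: Literal["true", "engineering"] = "true"
    sample_id: str = ""
    temperature_C: float = 20.0
    strain_rate_per_s: float = 0.005

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "sigma", sigma)
        if lam.ndim != 1 or sigma.ndim != 1 or lam.size != sigma.size:
            raise CurveError("lam and sigma must be 1-D arrays of equal length")
        if lam.size < 1:
            raise CurveError("a curve needs at least 1 sample")
        if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(sigma))):
            raise CurveError("curve contains non-finite values")
        if np.any(np.diff(lam) <= 0.0):
            raise CurveError("lambda must be strictly increasing")
        if lam[0] < 1.0:
            raise CurveError("tension records must start at lambda >= 1")
        if self.stress_kind not in ("true", "engineering"):
            raise CurveError(f"unknown stress_kind {self.stress_kind!r}")

    def __len__(self) -> int:
        return int(self.lam.size)

    def to_true(self) -> "StressStrainCurve":
        """Return the curve on a true-stress basis (identity if already true)."""
        if self.stress_kind == "true":
            return self
        return replace(self, sigma=engineering_to_true(self.lam, self.sigma), stress_kind="true")

    @property
    def lambda_max_exp(self) -> float:
        """Experimental elongation at break: the last recorded lambda."""
        return float(self.lam[-1])


@dataclass(frozen=True)
class FitResult:
    params: MaterialParams
    E0: float
    lambda_max_theo: float
    lambda_max_exp: float
    rmse: float
    relative_rmse: float
    param_uncertainties: dict
    converged: bool
    n_iter: int
    weighting: str = "uniform"

    def to_dict(self) -> dict:
        return {
            "E_struct_kPa": self.params.E_struct,
            "beta": self.params.beta,
            "E0_kPa": self.E0,
            "lambda_max_theo": self.lambda_max_theo,
            "lambda_max_exp": self.lambda_max_exp,
            "rmse_kPa": self.rmse,
            "relative_rmse": self.relative_rmse,
            "param_uncertainties": self.param_uncertainties,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "weighting": self.weighting,
        }


def _model_stress_safe(lam: np.ndarray, E: float, beta: float) -> np.ndarray:
    """Equation-of-state stress with a smooth positive denominator floor.

    Identical to the exact model wherever the denominator is comfortably
    positive; near and past the singularity it returns a large, finite,
    smoothly growing stress so the least-squares objective never blows up.
    """
    denom = 1.0 - beta * (lam**2 + 2.0 / lam) / 3.0
    denom_s = 0.5 * (denom + np.sqrt(denom**2 + _DENOM_SMOOTH**2))
    return (E / 9.0) * (lam**2 - 1.0 / lam) * (1.0 + 2.0 / denom_s**2)


def initial_guess(curve: StressStrainCurve) -> tuple[float, float]:
    """Starting values (E_init, beta_init) from curve geometry.

    The small-strain slope over the lowest-strain 20% of points (at least
    3) estimates E0; beta starts at 1/lambda_last^2 clamped to [0.01, 0.9];
    E follows by inverting E0 = (E/3)(1 + 2/(1-beta)^2).  A degenerate
    (non-positive-slope) toe region falls back to the global secant.
    """
    curve = curve.to_true()
    lam, sigma = curve.lam, curve.sigma
    k = max(3, int(math.ceil(0.2 * lam.size)))
    k = min(k, lam.size)
    slope = float(np.polyfit(lam[:k], sigma[:k], 1)[0]) if np.ptp(lam[:k]) > 0 else 0.0
    if not np.isfinite(slope) or slope <= 0.0:
        span = lam[-1] - lam[0]
        slope = float((sigma[-1] - sigma[0]) / span) if span > 0 else 1.0
    if not np.isfinite(slope) or slope <= 0.0:
        slope = 1.0
    beta_init = float(np.clip(1.0 / lam[-1] ** 2, 0.01, 0.9))
    E_init = 3.0 * slope / (1.0 + 2.0 / (1.0 - beta_init) ** 2)
    E_init = max(E_init, 1e-6)
    return E_init, beta_init


def fit_constitutive(
    curve: StressStrainCurve,
    weighting: Literal["uniform", "relative"] = "uniform",
    max_iter: int = 500,
) -> FitResult:
    """Fit (E, beta) to a tensile curve by bounded least squares.

    Residuals are uniform on true stress by default; ``relative`` weighting
    divides each residual by max(|sigma_i|, 0.1% of the peak stress), which
    can help when a curve spans two decades of stress.  Non-convergence is
    reported through ``converged``, never raised.
    """
    if len(curve) < MIN_FIT_POINTS:
        raise CurveError(f"fitting needs at least {MIN_FIT_POINTS} points, got {len(curve)}")
    if weighting not in ("uniform", "relative"):
        raise ValueError(f"unknown weighting {weighting!r}")
    curve = curve.to_true()
    lam, sigma = curve.lam, curve.sigma

    if weighting == "relative":
        floor = 1e-3 * float(np.max(np.abs(sigma))) or 1.0
        w = 1.0 / np.maximum(np.abs(sigma), floor)
    else:
        w = np.ones_like(sigma)

    E_init, beta_init = initial_guess(curve)
    pars = lmfit.Parameters()
    pars.add("E", value=E_init, min=1e-9)
    pars.add("beta", value=beta_init, min=_BETA_LO, max=_BETA_HI)

    def residual(p):
        return w * (_model_stress_safe(lam, p["E"].value, p["beta"].value) - sigma)

    out = lmfit.minimize(
        residual,
        pars,
        method="least_squares",
        max_nfev=max_iter * 10,
        xtol=1e-10,
        ftol=1e-14,
        gtol=1e-14,
    )
    E_fit = float(out.params["E"].value)
    beta_fit = float(out.params["beta"].value)
    params = MaterialParams(E_struct=E_fit, beta=beta_fit)

    model = _model_stress_safe(lam, E_fit, beta_fit)
    rmse = float(np.sqrt(np.mean((model - sigma) ** 2)))
    scale = float(np.sqrt(np.mean(sigma**2)))
    rel_rmse = rmse / scale if scale > 0 else float("nan")
    stderr = {
        name: (float(out.params[name].stderr) if out.params[name].stderr is not None else float("nan"))
        for name in ("E", "beta")
    }
    return FitResult(
        params=params,
        E0=young_modulus(params),
        lambda_max_theo=lambda_max_theo(beta_fit) if beta_fit > 0 else float("inf"),
        lambda_max_exp=curve.lambda_max_exp,
        rmse=rmse,
        relative_rmse=rel_rmse,
        param_uncertainties=stderr,
        converged=bool(out.success),
        n_iter=int(out.nfev),
        weighting=weighting,
    )


def predict_curve(params: MaterialParams, lambdas: Sequence[float], sample_id: str = "model") -> StressStrainCurve:
    """Evaluate the model on a lambda grid as a true-stress curve.

    Raises :class:`~brushmech.constitutive.DomainError` listing offending
    grid points beyond the singular elongation.
    """
    lam = np.asarray(lambdas, dtype=float)
    sigma = true_stress(lam, params)  # raises DomainError with bad points
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    lam = np.atleast_1d(lam)
    return StressStrainCurve(lam=lam, sigma=sigma, stress_kind="true", sample_id=sample_id)
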