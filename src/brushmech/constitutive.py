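"""Brush-network equation of state and derived mechanical quantities.

A crosslinked bottlebrush network under uniaxial deformation follows a
two-parameter constitutive relation between true stress and the elongation
ratio lambda = L/L0:

    sigma_true(lambda) = (E/9) (lambda^2 - lambda^-1)
                         [1 + 2 (1 - beta I1(lambda)/3)^-2],
    I1(lambda) = lambda^2 + 2/lambda,

where E is the structural modulus set by crosslink density (kPa) and beta
in (0, 1) is the firmness parameter, the squared ratio of a network
strand's initial end-to-end distance to its contour length.  beta controls
how violently the material strain-stiffens: the stress diverges at the
finite elongation where beta I1/3 reaches 1.

Two derived characteristics follow in closed form:

* Young's modulus, the initial slope of the true stress-elongation curve:
  E0 = (E/3) (1 + 2/(1-beta)^2);
* the theoretical elongation at break from finite strand extensibility:
  lambda_max = beta^(-1/2).

Stress is in kPa on the whole public surface.  Compression (lambda < 1) is
admitted and returns negative stress, with the same singular-denominator
guard applied on the compressive side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

# Boltzmann constant, J/K
K_BOLTZMANN = 1.380649e-23
# 1 J/nm^3 = 1e27 Pa = 1e24 kPa; converts k_B T l^{3/2}/v^{3/2} (l, v in
# nm, nm^3) to kPa.
_J_PER_NM3_TO_KPA = 1.0e24

DEFAULT_TEMPERATURE_K = 293.15
#: Backbone monomer length of the PDMS brush backbone, nm.
DEFAULT_MONOMER_LENGTH_NM = 0.25


class DomainError(ValueError):
    """Raised when an evaluation point lies outside the model's domain."""


@dataclass(frozen=True)
class MaterialParams:
    """The (E, beta) pair characterizing one elastomer formulation.

    Parameters
    ----------
    E_struct : float
        Structural modulus E, kPa; set by crosslink density. Must be > 0.
    beta : float
        Firmness parameter, dimensionless, in [0, 1). ``beta = 0`` is the
        explicit non-stiffening (neo-Hookean-like) limit.
    temperature : float
        Absolute temperature, K (metadata only).
    """

    E_struct: float
    beta: float
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not np.isfinite(self.E_struct) or self.E_struct <= 0:
            raise ValueError(f"E_struct must be a positive finite number, got {self.E_struct}")
        if not np.isfinite(self.beta) or not (0.0 <= self.beta < 1.0):
            raise ValueError(f"beta must lie in [0, 1), got {self.beta}")

    @property
    def E0(self) -> float:
        """Young's modulus (initial slope), kPa."""
        return young_modulus(self)

    @property
    def lambda_max(self) -> float:
        """Theoretical elongation at break beta^(-1/2); inf when beta = 0."""
        if self.beta == 0.0:
            return float("inf")
        return lambda_max_theo(self.beta)


@dataclass(frozen=True)
class Architecture:
    """Architectural triple [n_x, n_sc, n_bb] of a brush network.

    n_x is the backbone degree of polymerization (DP) between crosslinks,
    n_sc the side-chain DP, n_bb the precursor-brush backbone DP.  The
    spacer DP n_g between grafts is carried as metadata only.
    """

    n_x: int
    n_sc: int
    n_bb: int
    chemistry: str = ""
    ratio: str = ""
    n_g: int = 1

    def __post_init__(self) -> None:
        for name in ("n_x", "n_sc", "n_bb", "n_g"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_x > self.n_bb:
            raise ValueError(f"n_x ({self.n_x}) cannot exceed n_bb ({self.n_bb})")


@dataclass(frozen=True)
class ScalingConstants:
    """Constants of the architectural scaling law E ~ beta/(1+n_sc)^(3/2).

    In ``analytic`` mode the prefactor is 3 k_B T l^(3/2) / v^(3/2) with the
    backbone monomer length l (nm) and monomer volume v (nm^3); v has no
    established value for this chemistry, so ``calibrated`` mode — a slope C
    (kPa) fitted through the origin against reference data — is the default
    in the design layer.
    """

    prefactor_mode: Literal["analytic", "calibrated"] = "calibrated"
    l: float = DEFAULT_MONOMER_LENGTH_NM
    v: Optional[float] = None
    C: Optional[float] = None
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.prefactor_mode not in ("analytic", "calibrated"):
            raise ValueError(f"unknown prefactor_mode {self.prefactor_mode!r}")
        if self.l <= 0:
            raise ValueError("monomer length l must be > 0")
        if self.prefactor_mode == "analytic":
            if self.v is None or self.v <= 0:
                raise ValueError("analytic mode requires a positive monomer volume v (nm^3)")
        else:
            if self.C is None or self.C <= 0:
                raise ValueError("calibrated mode requires a positive slope C (kPa)")


def _first_invariant(lam):
    return lam * lam + 2.0 / lam


def stiffening_denominator(lam, beta):
    """1 - beta*(lambda^2 + 2/lambda)/3, the finite-extensibility factor."""
    return 1.0 - beta * _first_invariant(np.asarray(lam, dtype=float)) / 3.0


def true_stress(lam, params: MaterialParams):
    """Evaluate the equation of state at elongation ratio(s) ``lam``.

    Returns true stress in kPa, with the sign of (lambda - 1): positive in
    tension, negative in compression.  Raises :class:`DomainError` if any
    point is non-positive or lies at/beyond the singular elongation where
    the strain-stiffening denominator vanishes.
    """
    lam_arr = np.asarray(lam, dtype=float)
    scalar = lam_arr.ndim == 0
    lam_arr = np.atleast_1d(lam_arr)
    if np.any(~np.isfinite(lam_arr)) or np.any(lam_arr <= 0.0):
        raise DomainError("elongation ratio must be positive and finite")
    denom = stiffening_denominator(lam_arr, params.beta)
    if np.any(denom <= 0.0):
        bad = lam_arr[denom <= 0.0]
        raise DomainError(
            f"elongation at or beyond finite extensibility (denominator <= 0) at lambda = {bad.tolist()}"
        )
    sigma = (params.E_struct / 9.0) * (lam_arr**2 - 1.0 / lam_arr) * (1.0 + 2.0 / denom**2)
    return float(sigma[0]) if scalar else sigma


def young_modulus(params: MaterialParams) -> float:
    """Young's modulus E0 = (E/3)(1 + 2/(1-beta)^2), kPa.

    This is the lambda -> 1 slope of :func:`true_stress`.
    """
    if params.beta >= 1.0:
        raise DomainError("beta must be < 1")
    return (params.E_struct / 3.0) * (1.0 + 2.0 / (1.0 - params.beta) ** 2)


def lambda_max_theo(beta: float) -> float:
    """Theoretical elongation at break, beta^(-1/2)."""
    if not (0.0 < beta < 1.0):
        raise DomainError(f"beta must lie in (0, 1), got {beta}")
    return float(beta) ** -0.5


def lambda_singular(beta: float, tol: float = 1e-10) -> float:
    """Tensile singular elongation: the lambda > 1 root of beta*I1/3 = 1.

    Located by bisection on g(lambda) = beta*(lambda^2 + 2/lambda)/3 - 1
    over [1, 10/sqrt(beta)].  Returns inf for beta = 0.
    """
    if beta == 0.0:
        return float("inf")
    if not (0.0 < beta < 1.0):
        raise DomainError(f"beta must lie in [0, 1), got {beta}")
    lo, hi = 1.0, 10.0 / np.sqrt(beta)
    g = lambda x: beta * _first_invariant(x) / 3.0 - 1.0
    if g(hi) <= 0.0:  # pragma: no cover - 10/sqrt(beta) always brackets
        raise RuntimeError("bisection bracket failed")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def structural_modulus_predicted(beta: float, n_sc: int, constants: ScalingConstants) -> float:
    """Scaling-law prediction of the structural modulus E, kPa.

    E = P * beta / (1 + n_sc)^(3/2), with prefactor P either the analytic
    3 k_B T l^(3/2)/v^(3/2) (converted to kPa) or the calibrated slope C.
    """
    if not (0.0 <= beta < 1.0):
        raise DomainError(f"beta must lie in [0, 1), got {beta}")
    if n_sc < 0:
        raise ValueError("n_sc must be >= 0")
    if constants.prefactor_mode == "analytic":
        prefactor = (
            3.0
            * K_BOLTZMANN
            * constants.temperature
            * constants.l**1.5
            / constants.v**1.5
            * _J_PER_NM3_TO_KPA
        )
    else:
        prefactor = constants.C
    return prefactor * beta / (1.0 + n_sc) ** 1.5


def engineering_to_true(lam, sigma_eng):
    """Convert engineering to true stress under incompressibility: lambda * sigma_eng."""
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(np.atleast_1d(lam_arr) <= 0.0):
        raise DomainError("elongation ratio must be positive")
    return lam_arr * np.asarray(sigma_eng, dtype=float)


def true_to_engineering(lam, sigma_true):
    """Inverse of :func:`engineering_to_true`."""
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(np.atleast_1d(lam_arr) <= 0.0):
        raise DomainError("elongation ratio must be positive")
    return np.asarray(sigma_true, dtype=float) / lam_arr
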