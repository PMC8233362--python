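"""Instrument-like synthetic data with known ground truth.

Every analysis stage in this package consumes one of three record kinds —
tensile stress-elongation curves, oscillatory-rheology cure sweeps, and
double-compression TPA traces.  The generators here emulate each kind with
the model structure the analysis assumes, so parameter recovery, gel-point
detection and texture metrics can all be validated end to end:

* tensile curves are exact evaluations of the strain-stiffening equation
  of state on a uniform lambda grid capped at the theoretical break
  beta^(-1/2) (where real specimens rupture), optionally with
  multiplicative Gaussian noise — the instrument-realistic default, since
  load-cell error scales with load;
* cure sweeps use saturating Hill-type growth for both moduli, with the
  half-saturation time chosen in closed form so G' and G'' cross exactly
  at the requested t_gel; additive noise mimics the early-time floor;
* TPA traces are piecewise-linear two-cycle force profiles whose
  trapezoidal areas equal the requested areas exactly, so the ground-truth
  metrics are known in closed form.

All randomness flows through a seeded generator: equal specs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constitutive import MaterialParams, lambda_singular, true_stress
from .fitting import StressStrainCurve
from .gelation import RheologySweep
from .tpa import TPATrace
from .design import ReferenceTable


class SpecError(ValueError):
    """Inconsistent synthetic-data request."""


@dataclass(frozen=True)
class NoiseModel:
    """``none``, ``multiplicative`` Gaussian (sigma_rel), or ``additive`` (sigma_abs)."""

    kind: str = "none"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative", "additive"):
            raise SpecError(f"unknown noise model {self.kind!r}")
        if self.sigma < 0:
            raise SpecError("noise sigma must be >= 0")

    @property
    def is_noisy(self) -> bool:
        return self.kind != "none" and self.sigma > 0

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "multiplicative":
            return values * (1.0 + self.sigma * rng.standard_normal(values.shape))
        if self.kind == "additive":
            return values + self.sigma * rng.standard_normal(values.shape)
        return values


def _rng_for(noise: NoiseModel, seed: Optional[int]) -> Optional[np.random.Generator]:
    if not noise.is_noisy:
        return None
    if seed is None:
        raise SpecError("seed is mandatory whenever noise is requested")
    return np.random.default_rng(seed)


def gen_tensile(
    E: float,
    beta: float,
    n_points: int = 60,
    lam_max: Optional[float] = None,
    grid_fraction: Optional[float] = None,
    noise: NoiseModel = NoiseModel(),
    seed: Optional[int] = None,
    sample_id: str = "synthetic-tensile",
) -> tuple[StressStrainCurve, dict]:
    """Generate a tensile curve from known (E, beta).

    The lambda grid is uniform on [1, lam_max].  By default lam_max is the
    theoretical break beta^(-1/2) (always below the singular elongation);
    ``grid_fraction`` f < 1 instead caps the grid at min(f * lambda_sing,
    beta^(-1/2)).  For beta = 0 the model has no singularity and ``lam_max``
    must be given explicitly (default 3.0).

    Returns the curve together with a ground-truth record.
    """
    if n_points < 5:
        raise SpecError("n_points must be >= 5")
    params = MaterialParams(E_struct=E, beta=beta)
    if beta > 0:
        lam_sing = lambda_singular(beta)
        cap = beta**-0.5
        if grid_fraction is not None:
            if not (0 < grid_fraction < 1):
                raise SpecError("grid_fraction must lie in (0, 1)")
            cap = min(grid_fraction * lam_sing, cap)
        if lam_max is not None:
            if lam_max >= lam_sing:
                raise SpecError(f"lam_max {lam_max} is at/beyond the singular elongation {lam_sing:.4f}")
            cap = lam_max
    else:
        cap = lam_max if lam_max is not None else 3.0
    if cap <= 1.0:
        raise SpecError("grid cap must exceed 1")
    lam = np.linspace(1.0, cap, n_points)
    sigma = np.atleast_1d(true_stress(lam, params))
    rng = _rng_for(noise, seed)
    if rng is not None:
        sigma = noise.apply(sigma, rng)
    curve = StressStrainCurve(lam=lam, sigma=sigma, stress_kind="true", sample_id=sample_id)
    truth = {"E_kPa": E, "beta": beta, "lam_max": float(cap), "noise": noise.kind, "sigma": noise.sigma}
    return curve, truth


def gen_rheology(
    t_gel: float,
    G_prime_inf: float = 1e4,
    G_double_prime_inf: float = 1e3,
    G_double_prime_0: float = 50.0,
    shape_exponent: float = 2.0,
    n_points: int = 100,
    t_span: Optional[tuple[float, float]] = None,
    noise: NoiseModel = NoiseModel(),
    seed: Optional[int] = None,
    formulation: str = "synthetic-cure",
    temperature_C: float = 37.0,
    covariates: Optional[dict] = None,
) -> tuple[RheologySweep, dict]:
    """Generate a cure sweep whose G'/G'' crossover sits exactly at t_gel.

    Both moduli follow Hill-type growth x(t) = t^h / (t^h + t_c^h):
    G'(t) = G'_inf * x and G''(t) = G''_0 + (G''_inf - G''_0) * x.  Setting
    x(t_gel) = G''_0 / (G'_inf - G''_inf + G''_0) makes the curves
    intersect at t_gel; that requires G'_inf > G''_inf, otherwise the pair
    never crosses and the generator refuses.  The construction is verified
    by evaluating both moduli at t_gel before returning.
    """
    if t_gel <= 0 or shape_exponent <= 0:
        raise SpecError("t_gel and shape_exponent must be positive")
    if not (0 < G_double_prime_0 < G_double_prime_inf):
        raise SpecError("need 0 < G''_0 < G''_inf")
    if G_prime_inf <= G_double_prime_inf:
        raise SpecError("no crossover exists: G'_inf must exceed G''_inf")
    if n_points < 5:
        raise SpecError("n_points must be >= 5")
    x_cross = G_double_prime_0 / (G_prime_inf - G_double_prime_inf + G_double_prime_0)
    t_c = t_gel * ((1.0 - x_cross) / x_cross) ** (1.0 / shape_exponent)
    if t_span is None:
        t_span = (t_gel / 20.0, 5.0 * t_gel)
    t = np.linspace(t_span[0], t_span[1], n_points)
    x = t**shape_exponent / (t**shape_exponent + t_c**shape_exponent)
    gp = G_prime_inf * x
    gpp = G_double_prime_0 + (G_double_prime_inf - G_double_prime_0) * x

    # construction check: the analytic curves intersect at t_gel exactly
    xg = t_gel**shape_exponent / (t_gel**shape_exponent + t_c**shape_exponent)
    assert abs(G_prime_inf * xg - (G_double_prime_0 + (G_double_prime_inf - G_double_prime_0) * xg)) < 1e-6 * G_prime_inf

    rng = _rng_for(noise, seed)
    if rng is not None:
        gp = np.maximum(noise.apply(gp, rng), 1e-9 * G_prime_inf)
        gpp = np.maximum(noise.apply(gpp, rng), 1e-9 * G_prime_inf)
    sweep = RheologySweep(
        time=t,
        G_prime=gp,
        G_double_prime=gpp,
        temperature_C=temperature_C,
        formulation=formulation,
        covariates=covariates or {},
    )
    truth = {
        "t_gel_s": t_gel,
        "t_c_s": float(t_c),
        "grid_spacing_s": float(t[1] - t[0]),
        "G_prime_inf_Pa": G_prime_inf,
        "noise": noise.kind,
        "sigma": noise.sigma,
    }
    return sweep, truth


def gen_tpa(
    peak1: float = 10.0,
    peak2: Optional[float] = None,
    up_down_ratio1: float = 1.0,
    up_down_ratio2: Optional[float] = None,
    t_load: float = 1.0,
    rest: float = 0.5,
    samples_per_ramp: int = 25,
    noise: NoiseModel = NoiseModel(),
    seed: Optional[int] = None,
    strain_pct: float = 50.0,
    specimen: str = "synthetic-tpa",
) -> tuple[TPATrace, dict]:
    """Generate a piecewise-linear two-cycle TPA force trace.

    Each cycle is a triangle: force rises linearly from 0 to the peak over
    ``t_load`` seconds and falls back over ``up_down_ratio * t_load``
    seconds, so the withdrawal/compression area ratio equals
    ``up_down_ratio`` exactly (trapezoidal integration is exact on
    piecewise-linear signals).  ``peak2`` and ``up_down_ratio2`` default to
    the first cycle's values (a perfectly elastic second cycle).  Rest
    segments at exactly zero force separate and flank the cycles.

    Ground-truth metrics are computed in closed form from the requested
    quantities: cohesiveness = areas2/areas1, resilience = up_down_ratio1,
    springiness = 1 (both cycles load over the same duration).
    """
    peak2 = peak1 if peak2 is None else peak2
    up_down_ratio2 = up_down_ratio1 if up_down_ratio2 is None else up_down_ratio2
    if peak1 <= 0 or peak2 < 0:
        raise SpecError("peak forces must be positive (peak2 may be 0)")
    if up_down_ratio1 <= 0 or up_down_ratio2 <= 0:
        raise SpecError("up/down area ratios must be positive")
    if t_load <= 0 or rest <= 0:
        raise SpecError("timings must be positive")
    if samples_per_ramp < 3:
        raise SpecError("samples_per_ramp must be >= 3")

    def ramp(f0: float, f1: float, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        tt = np.linspace(t0, t1, samples_per_ramp + 1)[1:]
        ff = np.linspace(f0, f1, samples_per_ramp + 1)[1:]
        return tt, ff

    n_rest = 5
    times = [np.linspace(0.0, rest, n_rest)]
    forces = [np.zeros(n_rest)]
    t_cursor = rest
    truth_areas = []
    for peak, ratio in ((peak1, up_down_ratio1), (peak2, up_down_ratio2)):
        t_up, f_up = ramp(0.0, peak, t_cursor, t_cursor + t_load)
        t_cursor += t_load
        t_dn, f_dn = ramp(peak, 0.0, t_cursor, t_cursor + ratio * t_load)
        t_cursor += ratio * t_load
        times += [t_up, t_dn]
        forces += [f_up, f_dn]
        a_down = 0.5 * peak * t_load
        truth_areas += [a_down, ratio * a_down]
        t_r = np.linspace(t_cursor, t_cursor + rest, n_rest + 1)[1:]
        times.append(t_r)
        forces.append(np.zeros(n_rest))
        t_cursor += rest

    time = np.concatenate(times)
    force = np.concatenate(forces)
    rng = _rng_for(noise, seed)
    if rng is not None:
        force = np.clip(noise.apply(force, rng), 0.0, None)
    displacement = np.zeros_like(time)  # metrics are force-time based; displacement is metadata
    trace = TPATrace(time=time, displacement=displacement, force=force, strain_pct=strain_pct, specimen=specimen)
    a1d, a1u, a2d, a2u = truth_areas
    truth = {
        "areas_Ns": {"A1_down": a1d, "A1_up": a1u, "A2_down": a2d, "A2_up": a2u},
        "cohesiveness": (a2d + a2u) / (a1d + a1u),
        "resilience": up_down_ratio1,
        "springiness": 1.0,
        "peaks_N": [peak1, peak2],
        "noise": noise.kind,
        "sigma": noise.sigma,
    }
    return trace, truth


def gen_table1_fixture() -> ReferenceTable:
    """The packaged 11-row reference-formulation table."""
    return ReferenceTable.packaged()


def gen_tissue_curve(
    E0: float,
    beta: float,
    n_points: int = 40,
    lam_max: Optional[float] = None,
    noise: NoiseModel = NoiseModel(),
    seed: Optional[int] = None,
) -> tuple[StressStrainCurve, dict]:
    """A weakly strain-stiffening stand-in for a measured tissue curve.

    Parameterized by the observable pair (E0, beta); the structural modulus
    follows by inverting the Young's-modulus relation.  Synthetic: real
    tissue curves are user-supplied tables.
    """
    if not (0 < beta < 1) or E0 <= 0:
        raise SpecError("need E0 > 0 and beta in (0, 1)")
    E = 3.0 * E0 / (1.0 + 2.0 / (1.0 - beta) ** 2)
    return gen_tensile(
        E=E, beta=beta, n_points=n_points, lam_max=lam_max, noise=noise, seed=seed, sample_id="synthetic-tissue"
    )
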