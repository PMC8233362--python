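"""Gel-point detection from oscillatory rheology time sweeps.

During cure the storage modulus G' overtakes the loss modulus G''; the
crossover time is taken as the gel point t_gel.  Because both moduli grow
over decades, the detector works on d(t) = log G' - log G'' and
interpolates linearly in (time, log-modulus) coordinates inside the first
bracketing pair whose sign change is *sustained* — d must stay positive for
min(3, remaining) consecutive samples — so single-sample flickers from
noise are skipped (and counted).

Empirical curing-time trends across formulation covariates (stoichiometric
ratio, catalyst level, temperature) are summarized by simple regressions:
log t_gel vs log covariate, or log t_gel vs 1/T (Arrhenius form).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

DEFAULT_ANGULAR_FREQUENCY = 1.0  # rad/s
DEFAULT_STRAIN_PCT = 0.5


class SweepError(ValueError):
    """Invalid rheology sweep input."""


class NoGelPointError(RuntimeError):
    """No sustained G'/G'' crossover found in the sweep window."""


class AllLiquidError(NoGelPointError):
    """G'' dominates throughout: the sample never gels in the window."""


class AllSolidError(NoGelPointError):
    """G' dominates throughout: the sample was already gelled at the start."""


@dataclass(frozen=True)
class RheologySweep:
    """Timed (G', G'') record of an isothermal cure."""

    time: np.ndarray  # s
    G_prime: np.ndarray  # Pa
    G_double_prime: np.ndarray  # Pa
    temperature_C: float = 37.0
    angular_frequency_rad_s: float = DEFAULT_ANGULAR_FREQUENCY
    strain_pct: float = DEFAULT_STRAIN_PCT
    formulation: str = ""
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        gp = np.asarray(self.G_prime, dtype=float)
        gpp = np.asarray(self.G_double_prime, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "G_prime", gp)
        object.__setattr__(self, "G_double_prime", gpp)
        if not (t.ndim == gp.ndim == gpp.ndim == 1) or not (t.size == gp.size == gpp.size):
            raise SweepError("time, G_prime, G_double_prime must be 1-D arrays of equal length")
        if t.size < 4:
            raise SweepError("a sweep needs at least 4 samples")
        if np.any(np.diff(t) <= 0.0):
            raise SweepError("time must be strictly increasing")
        for name, arr in (("G_prime", gp), ("G_double_prime", gpp)):
            if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0):
                raise SweepError(f"{name} must be positive and finite everywhere")

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class GelationResult:
    t_gel: float  # s
    G_cross: float  # Pa
    bracket: tuple[float, float]
    n_crossings: int
    method: str = "first-sustained log-crossover"

    def to_dict(self) -> dict:
        return {
            "t_gel_s": self.t_gel,
            "G_cross_Pa": self.G_cross,
            "bracket_s": list(self.bracket),
            "n_crossings": self.n_crossings,
            "method": self.method,
        }


def _median3(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    for i in range(1, x.size - 1):
        out[i] = np.median(x[i - 1 : i + 2])
    return out


def find_gel_point(sweep: RheologySweep, median_filter: bool = False) -> GelationResult:
    """Locate the first sustained G'/G'' crossover of a cure sweep.

    Parameters
    ----------
    sweep : RheologySweep
    median_filter : bool
        Apply a 3-point running median to both moduli before detection
        (off by default; useful for noisy sweeps).

    Raises
    ------
    AllLiquidError / AllSolidError
        When d = log G' - log G'' never changes sign (loss- or
        storage-dominated throughout, respectively).
    NoGelPointError
        When sign changes exist but none is sustained.
    """
    gp, gpp = sweep.G_prime, sweep.G_double_prime
    if median_filter:
        gp, gpp = _median3(gp), _median3(gpp)
    t = sweep.time
    d = np.log(gp) - np.log(gpp)

    n_crossings = int(np.sum(np.sign(d[1:]) * np.sign(d[:-1]) < 0))
    if np.all(d < 0):
        raise AllLiquidError("no gel point in window: G'' exceeds G' throughout (still liquid)")
    if np.all(d > 0):
        raise AllSolidError("no gel point in window: G' exceeds G'' throughout (already solid)")

    n = d.size
    for i in range(n - 1):
        if d[i] < 0 and d[i + 1] >= 0:
            need = min(3, n - (i + 1))
            if np.all(d[i + 1 : i + 1 + need] > 0) or (d[i + 1] == 0 and np.all(d[i + 2 : i + 1 + need] > 0)):
                frac = -d[i] / (d[i + 1] - d[i]) if d[i + 1] != d[i] else 0.5
                t_gel = t[i] + frac * (t[i + 1] - t[i])
                log_g_cross = np.log(gp[i]) + frac * (np.log(gp[i + 1]) - np.log(gp[i]))
                return GelationResult(
                    t_gel=float(t_gel),
                    G_cross=float(np.exp(log_g_cross)),
                    bracket=(float(t[i]), float(t[i + 1])),
                    n_crossings=n_crossings,
                )
    raise NoGelPointError(
        f"sign changes found ({n_crossings}) but none sustained; likely noise flickers"
    )


@dataclass(frozen=True)
class TrendFit:
    model: str
    slope: float
    intercept: float
    r_squared: float
    covariate: str
    n: int

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "covariate": self.covariate,
            "n": self.n,
        }


def tgel_trend(
    results: Sequence[GelationResult],
    covariates: Sequence[float],
    model: Literal["loglog", "arrhenius"] = "loglog",
    covariate_name: str = "covariate",
) -> TrendFit:
    """Fit an empirical curing-time trend across a covariate axis.

    ``loglog`` regresses log t_gel on log covariate (power law); the
    ``arrhenius`` model regresses log t_gel on 1/T with the covariate in
    kelvin.  Requires at least 3 results with 3 distinct covariate values.
    """
    if model not in ("loglog", "arrhenius"):
        raise ValueError(f"unknown trend model {model!r}")
    if len(results) != len(covariates):
        raise ValueError("results and covariates must have equal length")
    if len(results) < 3:
        raise ValueError("trend fitting needs at least 3 gel points")
    cov = np.asarray(covariates, dtype=float)
    if np.unique(cov).size < 3:
        raise ValueError("covariate axis is rank-deficient: need >= 3 distinct values")
    if np.any(cov <= 0):
        raise ValueError("covariates must be positive (ratios, ppm, or kelvin)")
    t_gel = np.array([r.t_gel for r in results], dtype=float)
    y = np.log(t_gel)
    x = np.log(cov) if model == "loglog" else 1.0 / cov
    res = stats.linregress(x, y)
    return TrendFit(
        model=model,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        covariate=covariate_name,
        n=len(results),
    )
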