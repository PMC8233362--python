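"""Inverse architectural design of brush-network mechanics.

The structural modulus of a brush network scales with firmness and
side-chain length as E = C * beta / (1 + n_sc)^(3/2).  Calibrating the
slope C against a reference table of measured formulations turns this
proportionality into a forward predictor, which — combined with the
empirical beta(n_x) relationship anchored by the same table — lets the
designer map a target (E0, beta) pair onto candidate [n_x, n_sc]
architectures, or rank candidate formulations against a measured tissue
stress-strain curve.

The packaged reference table carries the eleven reported formulations
(chemistry, stoichiometry, architecture, fitted E and beta, and the
derived Young's modulus and elongations at break).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constitutive import (
    MaterialParams,
    ScalingConstants,
    lambda_max_theo,
    structural_modulus_predicted,
    young_modulus,
)
from .fitting import StressStrainCurve, _model_stress_safe

REFERENCE_ROW_COUNT = 11


class TableError(ValueError):
    """Invalid reference table."""


class DesignError(ValueError):
    """Invalid design input."""


@dataclass(frozen=True)
class DesignTarget:
    """Target mechanics with relative tolerance bands."""

    E0_target: float  # kPa
    beta_target: float
    E0_band: float = 0.15
    beta_band: float = 0.15

    def __post_init__(self) -> None:
        if self.E0_target <= 0 or not (0 < self.beta_target < 1):
            raise DesignError("target must have E0 > 0 and beta in (0, 1)")
        for b in (self.E0_band, self.beta_band):
            if not (0 < b <= 1):
                raise DesignError("tolerance bands must lie in (0, 1]")


class ReferenceTable:
    """Wrapper around the reference-formulation table (a DataFrame).

    Columns: chemistry, ratio, n_sc, n_bb, n_x, E_kPa, beta, E0_kPa,
    lambda_max_exp, lambda_max_calc.
    """

    COLUMNS = (
        "chemistry",
        "ratio",
        "n_sc",
        "n_bb",
        "n_x",
        "E_kPa",
        "beta",
        "E0_kPa",
        "lambda_max_exp",
        "lambda_max_calc",
    )

    def __init__(self, df: pd.DataFrame, validate_count: bool = False):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise TableError(f"reference table missing columns: {sorted(missing)}")
        numeric = df[list(self.COLUMNS[2:])]
        if (numeric <= 0).any().any():
            raise TableError("all numeric reference-table cells must be positive")
        if (df["beta"] >= 1).any():
            raise TableError("beta must be < 1 in every row")
        if validate_count and len(df) != REFERENCE_ROW_COUNT:
            raise TableError(f"expected {REFERENCE_ROW_COUNT} rows, got {len(df)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, chemistry: Optional[str] = None) -> "ReferenceTable":
        if chemistry is None:
            return self
        return ReferenceTable(self.df[self.df["chemistry"] == chemistry])

    @classmethod
    def packaged(cls) -> "ReferenceTable":
        """The reference table shipped with the package (11 rows)."""
        with importlib.resources.files("brushmech.data").joinpath("table1.csv").open() as fh:
            return cls(pd.read_csv(fh), validate_count=True)


@dataclass(frozen=True)
class CalibrationResult:
    constants: ScalingConstants
    residuals: np.ndarray
    pearson_r: float
    n: int


def scaling_predictor(beta, n_sc):
    """The scaling-law regressor x = beta / (1 + n_sc)^(3/2)."""
    return np.asarray(beta, dtype=float) / (1.0 + np.asarray(n_sc, dtype=float)) ** 1.5


def calibrate_scaling(table: ReferenceTable, chemistry: Optional[str] = None) -> CalibrationResult:
    """Fit the through-origin slope C of E vs beta/(1+n_sc)^(3/2).

    Returns the calibrated :class:`ScalingConstants` together with the
    per-row residuals and the Pearson correlation of the two columns.
    """
    sub = table.subset(chemistry)
    if len(sub) < 3:
        raise TableError(f"calibration needs >= 3 rows, got {len(sub)} after filtering")
    x = scaling_predictor(sub.df["beta"].to_numpy(), sub.df["n_sc"].to_numpy())
    y = sub.df["E_kPa"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise TableError("degenerate calibration: all predictor values identical")
    C = float(x @ y / (x @ x))
    resid = y - C * x
    r = float(np.corrcoef(x, y)[0, 1])
    return CalibrationResult(
        constants=ScalingConstants(prefactor_mode="calibrated", C=C),
        residuals=resid,
        pearson_r=r,
        n=len(sub),
    )


def required_beta(
    E0_target: float,
    n_sc: int,
    constants: ScalingConstants,
    max_iter: int = 100,
    tol: float = 1e-10,
    damping: float = 0.5,
) -> Optional[float]:
    """Solve for the beta that hits E0_target at fixed n_sc.

    The coupling E0 = (E/3)(1 + 2/(1-beta)^2) with E = C beta/(1+n_sc)^(3/2)
    is solved by damped fixed-point iteration: each step inverts the E0
    relation for the structural modulus at the current beta, then inverts
    the scaling law for a new beta.  Returns None when the iteration leaves
    (0, 1) (target infeasible at this n_sc) or fails to converge.
    """
    # prefactor/(1+n_sc)^1.5, i.e. dE/dbeta of the scaling law
    scale = structural_modulus_predicted(0.5, n_sc, constants) / 0.5
    beta = 0.1
    for _ in range(max_iter):
        E_needed = 3.0 * E0_target / (1.0 + 2.0 / (1.0 - beta) ** 2)
        beta_new = E_needed / scale
        if not np.isfinite(beta_new) or beta_new <= 0.0 or beta_new >= 1.0:
            return None
        step = damping * (beta_new - beta)
        beta += step
        if abs(step) < tol:
            return float(beta)
    return None


@dataclass(frozen=True)
class Candidate:
    n_x: int
    n_sc: int
    beta_pred: float
    E_struct_pred: float
    E0_pred: float
    rel_err_E0: float
    rel_err_beta: float
    combined_err: float
    extrapolated: bool

    def to_dict(self) -> dict:
        return {
            "n_x": self.n_x,
            "n_sc": self.n_sc,
            "beta_pred": self.beta_pred,
            "E_struct_pred_kPa": self.E_struct_pred,
            "E0_pred_kPa": self.E0_pred,
            "rel_err_E0": self.rel_err_E0,
            "rel_err_beta": self.rel_err_beta,
            "combined_err": self.combined_err,
            "extrapolated": self.extrapolated,
        }


def _loglog_interp(ux: np.ndarray, uy: np.ndarray, x: float) -> float:
    """Piecewise-linear interpolation in log-log space with linear extension."""
    if ux.size == 1:
        return float(uy[0])
    if x < ux[0]:
        slope = (uy[1] - uy[0]) / (ux[1] - ux[0])
        return float(uy[0] + slope * (x - ux[0]))
    if x > ux[-1]:
        slope = (uy[-1] - uy[-2]) / (ux[-1] - ux[-2])
        return float(uy[-1] + slope * (x - ux[-1]))
    return float(np.interp(x, ux, uy))


def _anchor_interp(table: ReferenceTable, n_sc: int, n_x: float) -> Optional[tuple[float, float, bool]]:
    """Empirical (beta, E_struct) at n_x within one n_sc anchor family.

    The reference rows are treated as empirical anchors — no closed form
    links n_x to beta or E — and are interpolated log-linearly in n_x;
    identical-n_x anchors are merged by their geometric mean.  Returns
    (beta, E_struct, extrapolated) or None when the family is empty.
    """
    fam = table.df[table.df["n_sc"] == n_sc].sort_values("n_x")
    if fam.empty:
        return None
    xs = np.log(fam["n_x"].to_numpy(dtype=float))
    x = np.log(float(n_x))
    ux, inv = np.unique(xs, return_inverse=True)
    extrapolated = bool(x < ux[0] or x > ux[-1])
    out = []
    for col in ("beta", "E_kPa"):
        ys = np.log(fam[col].to_numpy(dtype=float))
        uy = np.array([ys[inv == i].mean() for i in range(ux.size)])
        out.append(float(np.exp(_loglog_interp(ux, uy, x))))
    beta, e_struct = out
    return (min(beta, 1.0 - 1e-9), e_struct, extrapolated)


def propose_architectures(
    target: DesignTarget,
    constants: ScalingConstants,
    n_sc_choices: Sequence[int],
    n_x_range: Sequence[int],
    anchors: Optional[ReferenceTable] = None,
) -> tuple[list[Candidate], list[dict]]:
    """Rank [n_x, n_sc] grid points against a target (E0, beta).

    For each grid point the empirical anchor interpolation gives the
    predicted firmness and structural modulus, and the Young's-modulus
    relation gives E0.  Candidates whose relative errors fall inside the
    target's tolerance bands are returned ranked by the root-mean-square of
    the two relative errors; all grid points appear in the diagnostics list
    together with the calibrated-scaling-law modulus and the per-n_sc
    self-consistent beta from :func:`required_beta`.  The candidate list is
    empty — not an error — when nothing is feasible.
    """
    if len(n_sc_choices) == 0 or len(n_x_range) == 0:
        raise DesignError("grid must be nonempty")
    if anchors is None:
        anchors = ReferenceTable.packaged()
    candidates: list[Candidate] = []
    diagnostics: list[dict] = []
    for n_sc in n_sc_choices:
        beta_star = required_beta(target.E0_target, n_sc, constants)
        for n_x in n_x_range:
            anchor = _anchor_interp(anchors, int(n_sc), float(n_x))
            diag = {"n_x": int(n_x), "n_sc": int(n_sc), "beta_self_consistent": beta_star}
            if anchor is None:
                diag["status"] = "no empirical anchors for this n_sc family"
                diagnostics.append(diag)
                continue
            beta_pred, E_pred, extrapolated = anchor
            E0_pred = young_modulus(MaterialParams(E_struct=E_pred, beta=beta_pred))
            diag["E_scaling_kPa"] = structural_modulus_predicted(beta_pred, int(n_sc), constants)
            rel_e0 = abs(E0_pred - target.E0_target) / target.E0_target
            rel_b = abs(beta_pred - target.beta_target) / target.beta_target
            diag.update(
                {
                    "beta_pred": beta_pred,
                    "E0_pred_kPa": E0_pred,
                    "rel_err_E0": rel_e0,
                    "rel_err_beta": rel_b,
                    "extrapolated": extrapolated,
                    "status": "feasible" if (rel_e0 <= target.E0_band and rel_b <= target.beta_band) else "outside tolerance bands",
                }
            )
            diagnostics.append(diag)
            if rel_e0 <= target.E0_band and rel_b <= target.beta_band:
                candidates.append(
                    Candidate(
                        n_x=int(n_x),
                        n_sc=int(n_sc),
                        beta_pred=beta_pred,
                        E_struct_pred=E_pred,
                        E0_pred=E0_pred,
                        rel_err_E0=rel_e0,
                        rel_err_beta=rel_b,
                        combined_err=float(np.hypot(rel_e0, rel_b) / np.sqrt(2)),
                        extrapolated=extrapolated,
                    )
                )
    candidates.sort(key=lambda c: (c.combined_err, c.n_sc, c.n_x))
    return candidates, diagnostics


@dataclass(frozen=True)
class TissueMatch:
    params: MaterialParams
    distance: float  # RMS relative deviation over the overlapping lambda range
    n_points: int


def match_tissue(tissue: StressStrainCurve, candidates: Sequence[MaterialParams]) -> list[TissueMatch]:
    """Rank candidate formulations against a measured tissue curve.

    The distance is the root-mean-square relative deviation between each
    candidate's model curve and the tissue's true stress over the tissue's
    lambda range above 1 (the undeformed point carries zero stress and no
    information).  Candidate curves are evaluated with the smooth-floor
    model so a candidate whose extensibility the tissue exceeds simply
    scores a very large, finite distance.
    """
    if len(candidates) == 0:
        raise DesignError("candidate list is empty")
    tissue = tissue.to_true()
    mask = (tissue.lam > 1.0) & (tissue.sigma != 0.0)
    if not np.any(mask):
        raise DesignError("no overlapping lambda range with nonzero tissue stress")
    lam, sigma = tissue.lam[mask], tissue.sigma[mask]
    matches = []
    for p in candidates:
        model = _model_stress_safe(lam, p.E_struct, p.beta)
        dist = float(np.sqrt(np.mean(((model - sigma) / sigma) ** 2)))
        matches.append(TissueMatch(params=p, distance=dist, n_points=int(lam.size)))
    matches.sort(key=lambda m: m.distance)
    return matches


def recompute_derived_columns(table: ReferenceTable) -> pd.DataFrame:
    """Recompute E0 and lambda_max,calc from each row's printed (E, beta).

    Returns a DataFrame with the printed and recomputed values side by
    side, the recomputed values rounded half-up to one decimal (the table's
    printed precision), and per-row agreement flags.
    """
    import decimal

    def round1(v: float) -> float:
        return float(decimal.Decimal(repr(v)).quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))

    rows = []
    for _, r in table.df.iterrows():
        p = MaterialParams(E_struct=float(r["E_kPa"]), beta=float(r["beta"]))
        e0 = young_modulus(p)
        lmax = lambda_max_theo(float(r["beta"]))
        rows.append(
            {
                "chemistry": r["chemistry"],
                "ratio": r["ratio"],
                "E_kPa": r["E_kPa"],
                "beta": r["beta"],
                "E0_printed": r["E0_kPa"],
                "E0_recomputed": e0,
                "E0_recomputed_1dp": round1(e0),
                "E0_match_1dp": round1(e0) == float(r["E0_kPa"]),
                "E0_abs_diff": abs(e0 - float(r["E0_kPa"])),
                "lambda_max_calc_printed": r["lambda_max_calc"],
                "lambda_max_calc_recomputed": lmax,
                "lambda_max_calc_1dp": round1(lmax),
                "lambda_max_match_1dp": round1(lmax) == float(r["lambda_max_calc"]),
            }
        )
    return pd.DataFrame(rows)
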