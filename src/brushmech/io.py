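"""Strict CSV readers/writers for the three instrument record kinds.

All files are plain CSV with a fixed header plus optional ``# key: value``
comment lines carrying metadata, e.g.::

    # sample_id: NCO:OH 1:4
    # stress_kind: true
    lambda,sigma_kPa
    1.0,0.0
    ...

Parsing is strict: a malformed line raises :class:`ParseError` naming the
file and line number.
"""

from __future__ import annotations

import os
from typing import Optional, TextIO, Union

import numpy as np

from .fitting import StressStrainCurve
from .gelation import RheologySweep
from .tpa import TPATrace

PathLike = Union[str, os.PathLike]


class ParseError(ValueError):
    """Malformed input file; message carries file name and line number."""


def _read_table(path: PathLike, expected_header: list[str]):
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    header_seen = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            fields = [f.strip() for f in line.split(",")]
            if not header_seen:
                if fields != expected_header:
                    raise ParseError(
                        f"{path}:{lineno}: expected header {','.join(expected_header)!r}, got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != len(expected_header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(expected_header)} fields, got {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if not header_seen:
        raise ParseError(f"{path}: missing header line {','.join(expected_header)!r}")
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return meta, np.asarray(rows, dtype=float)


def _meta_float(meta: dict, key: str, default: float) -> float:
    return float(meta[key]) if key in meta else default


def read_stress_curve(path: PathLike) -> StressStrainCurve:
    """Read a ``lambda,sigma_kPa`` tensile-curve CSV."""
    meta, data = _read_table(path, ["lambda", "sigma_kPa"])
    kind = meta.get("stress_kind", "true")
    if kind not in ("true", "engineering"):
        raise ParseError(f"{path}: stress_kind must be 'true' or 'engineering', got {kind!r}")
    return StressStrainCurve(
        lam=data[:, 0],
        sigma=data[:, 1],
        stress_kind=kind,
        sample_id=meta.get("sample_id", ""),
        temperature_C=_meta_float(meta, "temperature_C", 20.0),
        strain_rate_per_s=_meta_float(meta, "strain_rate_per_s", 0.005),
    )


def write_stress_curve(curve: StressStrainCurve, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if curve.sample_id:
            fh.write(f"# sample_id: {curve.sample_id}\n")
        fh.write(f"# stress_kind: {curve.stress_kind}\n")
        fh.write(f"# temperature_C: {curve.temperature_C}\n")
        fh.write(f"# strain_rate_per_s: {curve.strain_rate_per_s}\n")
        fh.write("lambda,sigma_kPa\n")
        for l, s in zip(curve.lam, curve.sigma):
            fh.write(f"{float(l)!r},{float(s)!r}\n")


def read_rheology_sweep(path: PathLike) -> RheologySweep:
    """Read a ``time_s,G_prime_Pa,G_double_prime_Pa`` cure-sweep CSV."""
    meta, data = _read_table(path, ["time_s", "G_prime_Pa", "G_double_prime_Pa"])
    covariates = {}
    for key in ("ratio", "catalyst_ppm"):
        if key in meta:
            covariates[key] = float(meta[key])
    return RheologySweep(
        time=data[:, 0],
        G_prime=data[:, 1],
        G_double_prime=data[:, 2],
        temperature_C=_meta_float(meta, "temperature_C", 37.0),
        angular_frequency_rad_s=_meta_float(meta, "angular_frequency_rad_s", 1.0),
        strain_pct=_meta_float(meta, "strain_pct", 0.5),
        formulation=meta.get("formulation", ""),
        covariates=covariates,
    )


def write_rheology_sweep(sweep: RheologySweep, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if sweep.formulation:
            fh.write(f"# formulation: {sweep.formulation}\n")
        fh.write(f"# temperature_C: {sweep.temperature_C}\n")
        fh.write(f"# angular_frequency_rad_s: {sweep.angular_frequency_rad_s}\n")
        fh.write(f"# strain_pct: {sweep.strain_pct}\n")
        for k, v in sweep.covariates.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("time_s,G_prime_Pa,G_double_prime_Pa\n")
        for t, gp, gpp in zip(sweep.time, sweep.G_prime, sweep.G_double_prime):
            fh.write(f"{float(t)!r},{float(gp)!r},{float(gpp)!r}\n")


def read_tpa_trace(path: PathLike) -> TPATrace:
    """Read a ``time_s,displacement_mm,force_N`` TPA-trace CSV."""
    meta, data = _read_table(path, ["time_s", "displacement_mm", "force_N"])
    return TPATrace(
        time=data[:, 0],
        displacement=data[:, 1],
        force=data[:, 2],
        strain_pct=_meta_float(meta, "strain_pct", 50.0),
        specimen=meta.get("specimen", ""),
        diameter_mm=_meta_float(meta, "diameter_mm", 8.0),
    )


def write_tpa_trace(trace: TPATrace, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if trace.specimen:
            fh.write(f"# specimen: {trace.specimen}\n")
        fh.write(f"# strain_pct: {trace.strain_pct}\n")
        fh.write(f"# diameter_mm: {trace.diameter_mm}\n")
        fh.write("time_s,displacement_mm,force_N\n")
        for t, d, f in zip(trace.time, trace.displacement, trace.force):
            fh.write(f"{float(t)!r},{float(d)!r},{float(f)!r}\n")
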