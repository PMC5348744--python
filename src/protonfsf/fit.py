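"""Fit double-Gaussian fluence parameters to measured field-size factors.

For one energy the free parameters are (sigma1, sigma2) per measurement
plane plus a single halo weight w2 shared by all planes (the weight depends
on energy only, not on the plane).  The objective is the sum over all
records of squared relative FSF differences.  A coarse grid of candidate
parameters is scanned first — for a fixed w2 the planes decouple, so the
grid cost is linear in the number of planes.  Because the shared-w2
landscape is multimodal at grid resolution (a heavier halo can partly mimic
a wider core), refinement proceeds in two stages: each candidate w2 gets a
cheap per-plane (sigma1, sigma2) polish, which re-ranks the w2 candidates
reliably, and the winner seeds a bounded derivative-free (Powell) refinement
of the joint objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .fluence import FsfRecord, SpotFluenceParams, half_grid_count
from .geometry import BeamGeometry, projected_spacing


@dataclass(frozen=True)
class FitSettings:
    """Bounds, grid densities and refinement controls for one-energy fits."""

    sigma1_bounds_mm: tuple[float, float] = (0.5, 30.0)
    sigma2_max_mm: float = 150.0
    w2_bounds: tuple[float, float] = (0.0, 0.5)
    n_sigma1_grid: int = 20
    sigma1_grid_range_mm: tuple[float, float] = (1.0, 20.0)
    n_ratio_grid: int = 10
    ratio_grid_range: tuple[float, float] = (1.5, 10.0)
    n_w2_grid: int = 11
    w2_grid_range: tuple[float, float] = (0.0, 0.3)
    refine: bool = True
    ftol: float = 1e-10
    maxiter: int = 20000

    def sigma1_grid(self) -> np.ndarray:
        lo, hi = self.sigma1_grid_range_mm
        return np.geomspace(lo, hi, self.n_sigma1_grid)

    def ratio_grid(self) -> np.ndarray:
        lo, hi = self.ratio_grid_range
        return np.geomspace(lo, hi, self.n_ratio_grid)

    def w2_grid(self) -> np.ndarray:
        lo, hi = self.w2_grid_range
        return np.linspace(lo, hi, self.n_w2_grid)


@dataclass
class FitResult:
    """Fitted parameters for one energy with per-record residuals."""

    energy_MeV: float
    per_plane: dict[float, tuple[float, float]]  # plane_z_mm -> (sigma1, sigma2)
    w2: float
    residuals: list[tuple[FsfRecord, float]]  # (record, relative difference)
    objective_value: float
    converged: bool

    def params_for_plane(self, plane_z_mm: float, amplitude: float = 1.0) -> SpotFluenceParams:
        s1, s2 = self.per_plane[plane_z_mm]
        return SpotFluenceParams(s1, s2, self.w2, amplitude)


class IdentifiabilityError(ValueError):
    """Too few distinct field sizes on a plane to constrain the fit."""


# ---------------------------------------------------------------------------
# Fast forward model pieces
# ---------------------------------------------------------------------------


def _axis_sums(sigmas: np.ndarray, spacing: float, n: int) -> np.ndarray:
    """Vectorized 1-D Gaussian lattice sums for an array of sigma values."""
    x = np.arange(-n, n + 1, dtype=float) * spacing
    return np.exp(-(x[:, None] ** 2) / (2.0 * sigmas[None, :] ** 2)).sum(axis=0)


def _gaussian_pf(sigmas: np.ndarray, ssx: float, ssy: float, n: int) -> np.ndarray:
    """Central fluence of the (2n+1)^2 grid for unit-weight Gaussians."""
    return (
        _axis_sums(sigmas, ssx, n)
        * _axis_sums(sigmas, ssy, n)
        / (2.0 * math.pi * sigmas**2)
    )


@dataclass
class _PlaneData:
    """Pre-extracted measurements and grid sizes for one plane."""

    plane_z_mm: float
    records: list[FsfRecord]
    n_field: np.ndarray  # half-grid count per record
    n_ref: int
    measured: np.ndarray
    ssx: float
    ssy: float


def _plane_data(records: list[FsfRecord], geom: BeamGeometry) -> _PlaneData:
    z = records[0].plane_z_mm
    ss = geom.spot_spacing_mm
    refs = {r.ref_field_size_cm for r in records}
    if len(refs) != 1:
        raise ValueError(f"mixed reference field sizes on plane {z}: {sorted(refs)}")
    n_ref = half_grid_count(refs.pop() * 10.0, ss)
    n_field = np.array([half_grid_count(r.field_size_cm * 10.0, ss) for r in records])
    return _PlaneData(
        plane_z_mm=z,
        records=records,
        n_field=n_field,
        n_ref=n_ref,
        measured=np.array([r.value for r in records]),
        ssx=projected_spacing(geom, z, "x"),
        ssy=projected_spacing(geom, z, "y"),
    )


def _plane_model_fsf(pd_: _PlaneData, s1: float, s2: float, w2: float) -> np.ndarray:
    """Model FSFs of one plane for every record, given one parameter set."""
    sig = np.array([s1, s2])
    unique_n = sorted(set(pd_.n_field.tolist()) | {pd_.n_ref})
    pf = {n: _gaussian_pf(sig, pd_.ssx, pd_.ssy, n) for n in unique_n}

    def central(n: int) -> float:
        g = pf[n]
        return (1.0 - w2) * g[0] + w2 * g[1]

    den = central(pd_.n_ref)
    return np.array([central(n) for n in pd_.n_field]) / den


def _plane_objective(pd_: _PlaneData, s1: float, s2: float, w2: float) -> float:
    model = _plane_model_fsf(pd_, s1, s2, w2)
    rel = (model - pd_.measured) / pd_.measured
    return float((rel**2).sum())


# ---------------------------------------------------------------------------
# Coarse grid search
# ---------------------------------------------------------------------------


def _plane_grid_objective(
    pd_: _PlaneData, sig1: np.ndarray, sig2: np.ndarray, w2: np.ndarray
) -> np.ndarray:
    """Objective on the full (sigma1, ratio, w2) grid for one plane.

    sig1 has shape (n1,), sig2 shape (n1, nr) with sig2[a, b] = sig1[a] *
    ratio[b]; the result has shape (n1, nr, nw).
    """
    unique_n = sorted(set(pd_.n_field.tolist()) | {pd_.n_ref})
    g1 = {n: _gaussian_pf(sig1, pd_.ssx, pd_.ssy, n) for n in unique_n}  # (n1,)
    flat2 = sig2.ravel()
    g2 = {
        n: _gaussian_pf(flat2, pd_.ssx, pd_.ssy, n).reshape(sig2.shape)
        for n in unique_n
    }  # (n1, nr)

    w = w2[None, None, :]  # (1, 1, nw)

    def central(n: int) -> np.ndarray:
        return (1.0 - w) * g1[n][:, None, None] + w * g2[n][:, :, None]

    den = central(pd_.n_ref)
    obj = np.zeros((len(sig1), sig2.shape[1], len(w2)))
    for n, meas in zip(pd_.n_field, pd_.measured):
        rel = central(int(n)) / den / meas - 1.0
        obj += rel**2
    return obj


def _grid_argmin_per_plane(
    per_plane_obj: list[np.ndarray],
    planes: list[_PlaneData],
    sig1: np.ndarray,
    sig2: np.ndarray,
    kw: int,
) -> tuple[dict[float, tuple[float, float]], float]:
    """Best grid (sigma1, sigma2) per plane at one w2 index (smallest-sigma1 ties)."""
    best: dict[float, tuple[float, float]] = {}
    total = 0.0
    for p, obj in zip(planes, per_plane_obj):
        sl = obj[:, :, kw]
        m = sl.min()
        ia, ib = np.unravel_index(
            np.flatnonzero(sl.ravel() <= m + 1e-12 * max(m, 1e-300))[0], sl.shape
        )  # row-major flatnonzero: smallest sigma1 index first
        best[p.plane_z_mm] = (float(sig1[ia]), float(sig2[ia, ib]))
        total += float(sl[ia, ib])
    return best, total


def _coarse_search(
    planes: list[_PlaneData], settings: FitSettings
) -> tuple[float, dict[float, tuple[float, float]], float]:
    """Grid search with w2 shared across planes.

    Returns (w2, per-plane (sigma1, sigma2), total objective).  Ties are
    broken toward the smallest sigma1, then the smallest w2, so the result
    is deterministic.
    """
    sig1 = settings.sigma1_grid()
    ratio = settings.ratio_grid()
    w2 = settings.w2_grid()
    sig2 = sig1[:, None] * ratio[None, :]

    per_plane_obj = [_plane_grid_objective(p, sig1, sig2, w2) for p in planes]
    totals = np.zeros(len(w2))
    for obj in per_plane_obj:
        totals += obj.reshape(-1, len(w2)).min(axis=0)
    eps = 1e-12 * max(totals.min(), 1e-300)
    kw = int(np.flatnonzero(totals <= totals.min() + eps)[0])
    best, total = _grid_argmin_per_plane(per_plane_obj, planes, sig1, sig2, kw)
    return float(w2[kw]), best, total


def _refine_plane(
    p: _PlaneData,
    seed: tuple[float, float],
    w2: float,
    settings: FitSettings,
    xtol: float = 1e-6,
) -> tuple[tuple[float, float], float]:
    """Polish one plane's (sigma1, sigma2) at fixed w2."""
    s1_lo, s1_hi = settings.sigma1_bounds_mm

    def f(x: np.ndarray) -> float:
        s1 = x[0]
        return _plane_objective(p, s1, max(x[1], s1), w2)

    res = minimize(
        f,
        np.asarray(seed, dtype=float),
        method="Powell",
        bounds=[(s1_lo, s1_hi), (s1_lo, settings.sigma2_max_mm)],
        options={"ftol": settings.ftol, "xtol": xtol, "maxiter": settings.maxiter},
    )
    s1 = float(res.x[0])
    s2 = max(float(res.x[1]), s1)
    return (s1, s2), float(res.fun)


def _staged_refinement(
    planes: list[_PlaneData], settings: FitSettings
) -> tuple[float, dict[float, tuple[float, float]], float]:
    """Per-plane polish at every candidate w2, then pick the best w2.

    The coarse grid alone can rank w2 candidates wrongly because the plane
    minima sit between grid nodes; polishing (sigma1, sigma2) per plane at
    each w2 makes the shared-w2 profile objective reliable.
    """
    sig1 = settings.sigma1_grid()
    ratio = settings.ratio_grid()
    w2_grid = settings.w2_grid()
    sig2 = sig1[:, None] * ratio[None, :]
    per_plane_obj = [_plane_grid_objective(p, sig1, sig2, w2_grid) for p in planes]

    best_total = math.inf
    best_w2 = float(w2_grid[0])
    best_pp: dict[float, tuple[float, float]] = {}
    for kw, w2 in enumerate(w2_grid):
        seeds, _ = _grid_argmin_per_plane(per_plane_obj, planes, sig1, sig2, kw)
        total = 0.0
        pp: dict[float, tuple[float, float]] = {}
        for p in planes:
            pp[p.plane_z_mm], obj = _refine_plane(
                p, seeds[p.plane_z_mm], float(w2), settings, xtol=1e-4
            )
            total += obj
        if total < best_total:  # ties keep the smaller w2 (ascending scan)
            best_total = total
            best_w2 = float(w2)
            best_pp = pp
    return best_w2, best_pp, best_total


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------


def fit_energy(
    records: Sequence[FsfRecord],
    geom: BeamGeometry,
    settings: FitSettings | None = None,
) -> FitResult:
    """Fit (sigma1, sigma2) per plane and a shared w2 for one energy.

    Requires at least three distinct field sizes per plane (two Gaussian
    widths and a weight cannot be constrained by fewer ratios).  The fit is
    deterministic for fixed settings and input; on refinement failure the
    best point found so far is returned with ``converged=False``.
    """
    settings = settings or FitSettings()
    if not records:
        raise ValueError("no FSF records supplied")
    energies = {r.energy_MeV for r in records}
    if len(energies) != 1:
        raise ValueError(f"records span several energies: {sorted(energies)}")
    energy = energies.pop()

    by_plane: dict[float, list[FsfRecord]] = {}
    for r in records:
        by_plane.setdefault(r.plane_z_mm, []).append(r)
    for z, recs in sorted(by_plane.items()):
        n_fs = len({r.field_size_cm for r in recs})
        if n_fs < 3:
            raise IdentifiabilityError(
                f"plane z={z} mm has only {n_fs} distinct field sizes; "
                "at least 3 are needed to constrain (sigma1, sigma2, w2)"
            )
    planes = [_plane_data(recs, geom) for _, recs in sorted(by_plane.items())]

    w2_0, per_plane_0, obj_0 = _coarse_search(planes, settings)

    w2_best, per_plane_best, obj_best = w2_0, dict(per_plane_0), obj_0
    converged = True
    if settings.refine:
        w2_s, per_plane_s, obj_s = _staged_refinement(planes, settings)
        if obj_s <= obj_best:
            w2_best, per_plane_best, obj_best = w2_s, dict(per_plane_s), obj_s
        w2_0, per_plane_0 = w2_best, per_plane_best
        zs = [p.plane_z_mm for p in planes]
        s1_lo, s1_hi = settings.sigma1_bounds_mm
        x0 = [w2_0]
        bounds: list[tuple[float, float]] = [settings.w2_bounds]
        for z in zs:
            s1, s2 = per_plane_0[z]
            x0 += [s1, s2]
            bounds += [(s1_lo, s1_hi), (s1_lo, settings.sigma2_max_mm)]

        def objective(x: np.ndarray) -> float:
            w = x[0]
            total = 0.0
            for k, p in enumerate(planes):
                s1 = x[1 + 2 * k]
                s2 = max(x[2 + 2 * k], s1)  # keep the halo wider than the core
                total += _plane_objective(p, s1, s2, w)
            return total

        res = minimize(
            objective,
            np.asarray(x0, dtype=float),
            method="Powell",
            bounds=bounds,
            options={"ftol": settings.ftol, "xtol": 1e-8, "maxiter": settings.maxiter},
        )
        converged = bool(res.success)
        if res.fun <= obj_best:  # refinement never regresses past the grid
            obj_best = float(res.fun)
            w2_best = float(res.x[0])
            per_plane_best = {}
            for k, z in enumerate(zs):
                s1 = float(res.x[1 + 2 * k])
                s2 = max(float(res.x[2 + 2 * k]), s1)
                per_plane_best[z] = (s1, s2)

    residuals: list[tuple[FsfRecord, float]] = []
    for p in planes:
        s1, s2 = per_plane_best[p.plane_z_mm]
        model = _plane_model_fsf(p, s1, s2, w2_best)
        for rec, m in zip(p.records, model):
            residuals.append((rec, float((m - rec.value) / rec.value)))

    return FitResult(
        energy_MeV=energy,
        per_plane=per_plane_best,
        w2=w2_best,
        residuals=residuals,
        objective_value=obj_best,
        converged=converged,
    )


def fit_campaign(
    records: Sequence[FsfRecord],
    geom: BeamGeometry,
    settings: FitSettings | None = None,
) -> list[FitResult]:
    """Fit every energy present in a campaign, sorted by energy."""
    by_energy: dict[float, list[FsfRecord]] = {}
    for r in records:
        by_energy.setdefault(r.energy_MeV, []).append(r)
    return [
        fit_energy(recs, geom, settings) for _, recs in sorted(by_energy.items())
    ]


def fit_quality_summary(results: Sequence[FitResult]) -> dict:
    """Box-plot statistics of the relative residuals, in percent.

    Returns a dict with DataFrames grouped by field size and by plane
    (min, quartiles, median, max), the overall maximum absolute residual
    and the fraction of residuals within 2%.
    """
    if not results:
        raise ValueError("no fit results supplied")
    rows = [
        {
            "energy_MeV": res.energy_MeV,
            "plane_z_mm": rec.plane_z_mm,
            "field_size_cm": rec.field_size_cm,
            "residual_pct": 100.0 * d,
        }
        for res in results
        for rec, d in res.residuals
    ]
    df = pd.DataFrame(rows)

    def stats(group_col: str) -> pd.DataFrame:
        g = df.groupby(group_col)["residual_pct"]
        out = g.agg(
            n="count",
            min="min",
            q1=lambda s: s.quantile(0.25),
            median="median",
            q3=lambda s: s.quantile(0.75),
            max="max",
        )
        return out

    abs_res = df["residual_pct"].abs()
    return {
        "by_field_size": stats("field_size_cm"),
        "by_plane": stats("plane_z_mm"),
        "residuals": df,
        "max_abs_pct": float(abs_res.max()),
        "fraction_within_2pct": float((abs_res <= 2.0).mean()),
    }
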