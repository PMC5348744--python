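"""Interpolate fitted fluence parameters to the full energy-layer list.

A machine delivers many more energy layers than are practical to measure;
parameters fitted at a subset of energies are carried to the remaining
layers with a shape-preserving piecewise cubic (monotone Hermite, PCHIP)
in nominal energy.  PCHIP does not overshoot, so interpolated sigmas and
weights stay within the bracketing fitted values and never leave their
physical bounds.  Outside the fitted range the curve is continued linearly
with the end-point slope (clamped to bounds) and the event is logged.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .fit import FitResult
from .fluence import SpotFluenceParams

logger = logging.getLogger(__name__)

W2_MAX = 0.5
SIGMA_MIN_MM = 1e-3


@dataclass
class FluenceModelTable:
    """Fluence parameters for every (energy layer, plane); the model output."""

    energies_MeV: list[float]
    plane_offsets_mm: list[float]
    params: dict[float, dict[float, SpotFluenceParams]]  # energy -> plane -> params
    provenance: dict[float, str]  # energy -> "fitted" | "interpolated"

    def n_fitted(self) -> int:
        return sum(1 for v in self.provenance.values() if v == "fitted")

    def n_interpolated(self) -> int:
        return sum(1 for v in self.provenance.values() if v == "interpolated")


def build_layer_list(e_min_MeV: float, e_max_MeV: float, n_layers: int) -> np.ndarray:
    """Uniform layer list including both endpoints.

    Real machines have non-uniform layer spacing; arbitrary sorted lists are
    accepted everywhere a layer list is, this is only the default builder.
    """
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    if not e_min_MeV < e_max_MeV:
        raise ValueError("e_min must be below e_max")
    return np.linspace(e_min_MeV, e_max_MeV, n_layers)


def _clamped_pchip(x: np.ndarray, y: np.ndarray, lo: float, hi: float):
    """PCHIP inside the data range, linear end-slope continuation outside."""
    if len(x) == 1:
        const = float(y[0])
        return lambda e: np.clip(np.full_like(np.asarray(e, float), const), lo, hi)
    f = PchipInterpolator(x, y, extrapolate=False)
    d = f.derivative()
    x0, x1 = float(x[0]), float(x[-1])
    y0, y1 = float(y[0]), float(y[-1])
    d0, d1 = float(d(x0)), float(d(x1))

    def eval_(e):
        e = np.asarray(e, dtype=float)
        out = f(e)
        below = e < x0
        above = e > x1
        out = np.where(below, y0 + d0 * (e - x0), out)
        out = np.where(above, y1 + d1 * (e - x1), out)
        return np.clip(out, lo, hi)

    return eval_


def interpolate_table(
    fits: Sequence[FitResult],
    layer_list: Sequence[float],
) -> FluenceModelTable:
    """Build the full model table from per-energy fits.

    Fitted energies that appear in the layer list pass through exactly
    (the fit values are copied, not re-evaluated through the spline).
    Matching uses a 1e-9 relative tolerance so that energies surviving a
    text round trip (CSV/JSON) are still recognized as fitted layers.
    """
    if len(fits) < 2:
        raise ValueError("need fits at >= 2 energies to interpolate")
    fits = sorted(fits, key=lambda f: f.energy_MeV)
    e_fit = np.array([f.energy_MeV for f in fits])
    if len(set(e_fit.tolist())) != len(e_fit):
        raise ValueError("duplicate fitted energies")
    planes = sorted(fits[0].per_plane)
    for f in fits:
        if sorted(f.per_plane) != planes:
            raise ValueError("all fits must cover the same planes")

    layers = sorted(float(e) for e in layer_list)
    out_of_range = [e for e in layers if e < e_fit[0] or e > e_fit[-1]]
    if out_of_range:
        logger.warning(
            "extrapolating fluence parameters (clamped-linear) at %d layers "
            "outside the fitted range [%.1f, %.1f] MeV",
            len(out_of_range),
            e_fit[0],
            e_fit[-1],
        )

    w2_of = _clamped_pchip(e_fit, np.array([f.w2 for f in fits]), 0.0, W2_MAX)
    sig_of = {}
    for z in planes:
        s1 = np.array([f.per_plane[z][0] for f in fits])
        s2 = np.array([f.per_plane[z][1] for f in fits])
        sig_of[z] = (
            _clamped_pchip(e_fit, s1, SIGMA_MIN_MM, np.inf),
            _clamped_pchip(e_fit, s2, SIGMA_MIN_MM, np.inf),
        )

    def fitted_at(e: float) -> FitResult | None:
        k = int(np.searchsorted(e_fit, e))
        for f in (fits[max(k - 1, 0)], fits[min(k, len(fits) - 1)]):
            if math.isclose(f.energy_MeV, e, rel_tol=1e-9, abs_tol=1e-9):
                return f
        return None

    params: dict[float, dict[float, SpotFluenceParams]] = {}
    provenance: dict[float, str] = {}
    for e in layers:
        f = fitted_at(e)
        if f is not None:
            params[e] = {z: f.params_for_plane(z) for z in planes}
            provenance[e] = "fitted"
        else:
            w2 = float(w2_of(e))
            per = {}
            for z in planes:
                s1 = float(sig_of[z][0](e))
                s2 = max(float(sig_of[z][1](e)), s1)
                per[z] = SpotFluenceParams(s1, s2, w2)
            params[e] = per
            provenance[e] = "interpolated"
    return FluenceModelTable(layers, planes, params, provenance)


# ---------------------------------------------------------------------------
# JSON model-table I/O
# ---------------------------------------------------------------------------


def write_model_table(table: FluenceModelTable, path: str | Path) -> None:
    doc = {
        "plane_offsets_mm": table.plane_offsets_mm,
        "entries": [
            {
                "energy_MeV": e,
                "provenance": table.provenance[e],
                "planes": [
                    {
                        "plane_z_mm": z,
                        "sigma1_mm": p.sigma1_mm,
                        "sigma2_mm": p.sigma2_mm,
                        "w2": p.w2,
                    }
                    for z, p in sorted(table.params[e].items())
                ],
            }
            for e in table.energies_MeV
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model_table(path: str | Path) -> FluenceModelTable:
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict) or "entries" not in doc:
        raise ValueError("model table JSON must contain an 'entries' list")
    planes = [float(z) for z in doc.get("plane_offsets_mm", [])]
    energies: list[float] = []
    params: dict[float, dict[float, SpotFluenceParams]] = {}
    provenance: dict[float, str] = {}
    for entry in doc["entries"]:
        for key in ("energy_MeV", "provenance", "planes"):
            if key not in entry:
                raise ValueError(f"model table entry is missing {key!r}")
        if entry["provenance"] not in ("fitted", "interpolated"):
            raise ValueError(f"unknown provenance {entry['provenance']!r}")
        e = float(entry["energy_MeV"])
        energies.append(e)
        provenance[e] = entry["provenance"]
        per = {}
        for pl in entry["planes"]:
            per[float(pl["plane_z_mm"])] = SpotFluenceParams(
                float(pl["sigma1_mm"]), float(pl["sigma2_mm"]), float(pl["w2"])
            )
        params[e] = per
    if not planes:
        planes = sorted(params[energies[0]]) if energies else []
    return FluenceModelTable(energies, planes, params, provenance)
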