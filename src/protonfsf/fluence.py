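"""Double-Gaussian single-spot fluence and the field-size-factor forward model.

A spot behind a fixed range shifter is modelled as a weighted sum of a
narrow primary Gaussian (sigma1) and a wide secondary Gaussian (sigma2,
weight w2) describing the scattering halo.  The central fluence of a uniform
square spot field is the sum of all spot contributions at the field center,
and the field-size factor (FSF) is that fluence normalized to a 10 cm
reference field at the same energy and plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import BeamGeometry, projected_spacing

#: columns of the on-disk FSF table, in order
FSF_COLUMNS = ("energy_MeV", "plane_z_mm", "field_size_cm", "ref_field_size_cm", "fsf")


@dataclass(frozen=True)
class SpotFluenceParams:
    """Lateral fluence parameters of one spot at one (energy, plane).

    ``amplitude`` is the per-spot maximum-fluence factor; it cancels in
    every FSF and defaults to 1.  The bracketed double-Gaussian profile
    integrates to 1 over the plane, so the full fluence integrates to
    ``amplitude``.
    """

    sigma1_mm: float
    sigma2_mm: float
    w2: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma1_mm > 0:
            raise ValueError(f"sigma1 must be positive, got {self.sigma1_mm}")
        if not self.sigma2_mm >= self.sigma1_mm:
            raise ValueError(
                f"sigma2 ({self.sigma2_mm}) must be >= sigma1 ({self.sigma1_mm})"
            )
        if not 0.0 <= self.w2 < 1.0:
            raise ValueError(f"w2 must lie in [0, 1), got {self.w2}")


@dataclass(frozen=True)
class FsfRecord:
    """One normalized field-size factor with its measurement coordinates."""

    energy_MeV: float
    plane_z_mm: float
    field_size_cm: float
    value: float
    ref_field_size_cm: float = 10.0

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"FSF value must be positive, got {self.value}")
        if self.field_size_cm <= 0 or self.ref_field_size_cm <= 0:
            raise ValueError("field sizes must be positive")


def fluence_at(params: SpotFluenceParams, dx_mm, dy_mm):
    """Fluence density (1/mm^2) at offset (dx, dy) from the spot center.

    Accepts scalars or numpy arrays (broadcast).
    """
    r2 = np.asarray(dx_mm, dtype=float) ** 2 + np.asarray(dy_mm, dtype=float) ** 2
    s1sq = params.sigma1_mm**2
    s2sq = params.sigma2_mm**2
    g1 = (1.0 - params.w2) / (2.0 * math.pi * s1sq) * np.exp(-r2 / (2.0 * s1sq))
    g2 = params.w2 / (2.0 * math.pi * s2sq) * np.exp(-r2 / (2.0 * s2sq))
    return params.amplitude * (g1 + g2)


def half_grid_count(field_size_mm: float, spacing_mm: float) -> int:
    """N such that the square field holds the (2N+1)^2 spot grid.

    The field size is measured spot-center to spot-center, so N = FS/(2 SS)
    and must be integral; non-commensurate sizes are rejected rather than
    rounded (rounding silently changes FSFs).  A zero field size denotes the
    single-spot limit (N = 0).
    """
    if field_size_mm < 0 or spacing_mm <= 0:
        raise ValueError("field size must be >= 0 and spacing positive")
    n = 0.5 * field_size_mm / spacing_mm
    n_int = round(n)
    if abs(n - n_int) > 1e-9:
        raise ValueError(
            f"field size {field_size_mm} mm is not an even multiple of the "
            f"spot spacing {spacing_mm} mm"
        )
    return int(n_int)


def spot_grid(field_size_mm: float, spacing_mm: float) -> list[tuple[int, int]]:
    """All (i, j) grid indices of a square field, |i|,|j| <= N."""
    if field_size_mm <= 0:
        raise ValueError("field size must be positive")
    n = half_grid_count(field_size_mm, spacing_mm)
    rng = range(-n, n + 1)
    return [(i, j) for i in rng for j in rng]


def _axis_sum(sigma_mm: float, spacing_mm: float, n: int) -> float:
    """1-D Gaussian lattice sum sum_i exp(-(i*SS')^2 / (2 sigma^2))."""
    x = np.arange(-n, n + 1, dtype=float) * spacing_mm
    return float(np.exp(-(x**2) / (2.0 * sigma_mm**2)).sum())


def central_fluence(
    params: SpotFluenceParams,
    geom: BeamGeometry,
    z_mm: float,
    field_size_mm: float,
) -> float:
    """Fluence density at the center of a uniform square spot field.

    Sums the double-Gaussian contribution of every spot on the
    divergence-projected grid.  The Gaussian separates in x and y, so the
    2-D lattice sum is evaluated as a product of two 1-D sums per component
    (exactly equal to the naive double loop).
    """
    n = half_grid_count(field_size_mm, geom.spot_spacing_mm)
    ssx = projected_spacing(geom, z_mm, "x")
    ssy = projected_spacing(geom, z_mm, "y")
    s1, s2, w2 = params.sigma1_mm, params.sigma2_mm, params.w2
    term1 = (
        (1.0 - w2)
        / (2.0 * math.pi * s1**2)
        * _axis_sum(s1, ssx, n)
        * _axis_sum(s1, ssy, n)
    )
    term2 = (
        w2 / (2.0 * math.pi * s2**2) * _axis_sum(s2, ssx, n) * _axis_sum(s2, ssy, n)
    )
    return params.amplitude * (term1 + term2)


def fsf(
    params: SpotFluenceParams,
    geom: BeamGeometry,
    z_mm: float,
    field_size_cm: float,
    ref_field_size_cm: float = 10.0,
) -> float:
    """Field-size factor: central fluence ratio FS vs the reference field.

    Both fields are evaluated at the same plane, so the amplitude and any
    per-plane normalization cancel exactly; FSF(ref) == 1 identically.
    """
    num = central_fluence(params, geom, z_mm, field_size_cm * 10.0)
    den = central_fluence(params, geom, z_mm, ref_field_size_cm * 10.0)
    assert den > 0.0
    return num / den


# ---------------------------------------------------------------------------
# FSF table I/O (delimited text)
# ---------------------------------------------------------------------------


def records_to_frame(records: Iterable[FsfRecord]) -> pd.DataFrame:
    rows = [
        (r.energy_MeV, r.plane_z_mm, r.field_size_cm, r.ref_field_size_cm, r.value)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(FSF_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[FsfRecord]:
    missing = set(FSF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"FSF table is missing columns: {sorted(missing)}")
    return [
        FsfRecord(
            energy_MeV=float(row.energy_MeV),
            plane_z_mm=float(row.plane_z_mm),
            field_size_cm=float(row.field_size_cm),
            ref_field_size_cm=float(row.ref_field_size_cm),
            value=float(row.fsf),
        )
        for row in df.itertuples(index=False)
    ]


def write_fsf_table(records: Sequence[FsfRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_fsf_table(path: str | Path) -> list[FsfRecord]:
    return frame_to_records(pd.read_csv(path))
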