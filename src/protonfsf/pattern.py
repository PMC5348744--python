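"""Spiral spot-delivery pattern with control points.

All field-size factors of one energy and plane can be read from a single
beam delivery: the spots are delivered ring by ring from the center outward,
and the delivery is paused (a control point) each time a nested square field
is complete so the cumulative chamber charge can be recorded.  The prefix of
the sequence up to control point k is then exactly the spot grid of field
size k, and ratios of the cumulative charges are the FSFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .fluence import FsfRecord, half_grid_count, spot_grid
from .geometry import BeamGeometry


@dataclass(frozen=True)
class SpotPattern:
    """Ordered spot list with control-point markers.

    ``control_points`` holds ``(index_after, field_size_cm)`` pairs: the
    delivery pauses after the spot at 0-based index ``index_after - 1``,
    i.e. after ``index_after`` spots, which complete the given field size.
    """

    energy_MeV: float
    spots: tuple[tuple[float, float, float], ...]  # (x_mm, y_mm, weight)
    control_points: tuple[tuple[int, float], ...] = field(default_factory=tuple)


def _ring_spots(ring: int) -> list[tuple[int, int]]:
    """Grid indices on one Chebyshev ring, counter-clockwise from (ring, 0)."""
    if ring == 0:
        return [(0, 0)]
    cells = [
        (i, j)
        for i in range(-ring, ring + 1)
        for j in range(-ring, ring + 1)
        if max(abs(i), abs(j)) == ring
    ]
    cells.sort(key=lambda ij: (math.atan2(ij[1], ij[0]) % (2.0 * math.pi), ij[0], ij[1]))
    return cells


def spiral_pattern(
    geom: BeamGeometry,
    max_field_size_cm: float,
    pause_field_sizes_cm: Sequence[float] = (2.0, 4.0, 6.0, 8.0, 10.0),
    energy_MeV: float = 0.0,
    weight: float = 1.0,
) -> SpotPattern:
    """Build the outward ring-by-ring delivery pattern with pauses.

    Every pause field size must be smaller than the maximum field size and
    commensurate with the spot spacing; a pause is placed exactly when its
    nested square grid has been completed.
    """
    ss = geom.spot_spacing_mm
    n_max = half_grid_count(max_field_size_cm * 10.0, ss)
    pause_rings: dict[int, float] = {}
    for fs in pause_field_sizes_cm:
        if fs >= max_field_size_cm:
            raise ValueError(
                f"pause field size {fs} cm is not smaller than the maximum "
                f"field size {max_field_size_cm} cm"
            )
        try:
            n = half_grid_count(fs * 10.0, ss)
        except ValueError as exc:
            raise ValueError(f"incompatible pause field size {fs} cm: {exc}") from exc
        pause_rings[n] = fs

    spots: list[tuple[float, float, float]] = []
    control_points: list[tuple[int, float]] = []
    for ring in range(n_max + 1):
        for i, j in _ring_spots(ring):
            spots.append((i * ss, j * ss, weight))
        if ring in pause_rings:
            control_points.append((len(spots), pause_rings[ring]))
    return SpotPattern(energy_MeV, tuple(spots), tuple(control_points))


def cumulative_fsf_from_charges(
    charges: Sequence[float],
    pause_field_sizes_cm: Sequence[float],
    max_field_size_cm: float,
    ref_field_size_cm: float = 10.0,
    energy_MeV: float = 0.0,
    plane_z_mm: float = 0.0,
) -> list[FsfRecord]:
    """Turn cumulative control-point charges into FSF records.

    ``charges`` holds one reading per control point plus the final reading
    of the complete delivery; the corresponding field sizes are the pause
    sizes followed by the maximum field size.  Each charge is normalized to
    the reading at the reference field; the reference itself (FSF = 1 by
    definition) is not emitted.
    """
    sizes = list(pause_field_sizes_cm) + [max_field_size_cm]
    if len(charges) != len(sizes):
        raise ValueError(
            f"expected {len(sizes)} charge readings (one per control point plus "
            f"the final field), got {len(charges)}"
        )
    for a, b in zip(charges, charges[1:]):
        if b < a:
            raise ValueError("cumulative charges must be non-decreasing")
    try:
        ref_idx = sizes.index(ref_field_size_cm)
    except ValueError:
        raise ValueError(
            f"reference field size {ref_field_size_cm} cm is not among the "
            f"recorded field sizes {sizes}"
        ) from None
    ref_charge = charges[ref_idx]
    if not ref_charge > 0:
        raise ValueError("reference charge must be positive")
    return [
        FsfRecord(
            energy_MeV=energy_MeV,
            plane_z_mm=plane_z_mm,
            field_size_cm=fs,
            ref_field_size_cm=ref_field_size_cm,
            value=q / ref_charge,
        )
        for fs, q in zip(sizes, charges)
        if fs != ref_field_size_cm
    ]


def write_pattern(pattern: SpotPattern, path: str | Path) -> None:
    """Write the pattern as CSV: order, x_mm, y_mm, weight, control_point_after."""
    cp_after = {idx - 1 for idx, _ in pattern.control_points}
    df = pd.DataFrame(
        {
            "order": range(1, len(pattern.spots) + 1),
            "x_mm": [s[0] for s in pattern.spots],
            "y_mm": [s[1] for s in pattern.spots],
            "weight": [s[2] for s in pattern.spots],
            "control_point_after": [int(k in cp_after) for k in range(len(pattern.spots))],
        }
    )
    df.to_csv(path, index=False)
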