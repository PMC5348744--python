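"""Beamline geometry: virtual source distances and spot-spacing projection.

In a scanned proton beam the spots are steered by two magnets at different
distances upstream of isocenter, so each scanning axis has its own virtual
source-to-axis distance (VSAD).  A square spot map planned with spacing SS at
the isocenter plane is magnified on a plane at signed offset ``z`` from
isocenter (positive downstream, away from the nozzle) by the factor
``(VSAD + z) / VSAD`` per axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class GeometryError(ValueError):
    """Invalid beamline geometry or a plane behind the virtual source."""


@dataclass(frozen=True)
class BeamGeometry:
    """Scanning-beam geometry for fluence-summation on arbitrary planes.

    Parameters
    ----------
    vsad_x_mm, vsad_y_mm:
        Virtual source-to-axis distance per scanning axis, in mm.
        ``math.inf`` means a parallel (non-diverging) beam on that axis.
    spot_spacing_mm:
        Uniform spot spacing of the planned map at the isocenter plane.
    plane_offsets_mm:
        Signed measurement-plane offsets from isocenter, positive downstream.
    """

    vsad_x_mm: float = 2000.0
    vsad_y_mm: float = 2000.0
    spot_spacing_mm: float = 5.0
    plane_offsets_mm: tuple[float, ...] = (-200.0, -100.0, 0.0, 100.0, 200.0)

    def __post_init__(self) -> None:
        if not (self.vsad_x_mm > 0 and self.vsad_y_mm > 0):
            raise GeometryError("VSADs must be positive (use math.inf for parallel)")
        if not self.spot_spacing_mm > 0:
            raise GeometryError("spot spacing must be positive")
        for z in self.plane_offsets_mm:
            for v in (self.vsad_x_mm, self.vsad_y_mm):
                if math.isfinite(v) and v + z <= 0:
                    raise GeometryError(
                        f"plane offset {z} mm lies behind the virtual source (VSAD {v} mm)"
                    )

    @classmethod
    def parallel(
        cls,
        spot_spacing_mm: float = 5.0,
        plane_offsets_mm: tuple[float, ...] = (-200.0, -100.0, 0.0, 100.0, 200.0),
    ) -> "BeamGeometry":
        """Geometry with infinite VSADs: no magnification on any plane."""
        return cls(math.inf, math.inf, spot_spacing_mm, plane_offsets_mm)

    @property
    def is_parallel(self) -> bool:
        return math.isinf(self.vsad_x_mm) and math.isinf(self.vsad_y_mm)


def magnification(geom: BeamGeometry, z_mm: float, axis: str) -> float:
    """Plane magnification (VSAD + z)/VSAD for one scanning axis."""
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    vsad = geom.vsad_x_mm if axis == "x" else geom.vsad_y_mm
    if math.isinf(vsad):
        return 1.0
    if vsad + z_mm <= 0:
        raise GeometryError(
            f"plane at z={z_mm} mm lies behind the virtual source (VSAD {vsad} mm)"
        )
    return (vsad + z_mm) / vsad


def projected_spacing(geom: BeamGeometry, z_mm: float, axis: str) -> float:
    """Spot spacing projected onto the plane at signed offset ``z_mm``.

    Equals the isocenter spacing scaled by the divergence magnification;
    for a parallel beam it is the isocenter spacing on every plane.
    """
    return geom.spot_spacing_mm * magnification(geom, z_mm, axis)
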