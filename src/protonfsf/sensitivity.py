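"""One-at-a-time sensitivity of field-size factors to the fluence parameters.

Small fields probe the primary Gaussian (sigma1), the largest fields probe
the halo (sigma2), and all fields respond mildly to the halo weight (w2);
this split is what makes the parameters identifiable from an FSF set.  The
report perturbs each parameter separately by a relative amount and records
the percent change of the FSF at each field size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .fluence import SpotFluenceParams, fsf
from .geometry import BeamGeometry

#: default perturbation set: sigma1 +-10%, sigma2 +-20%, w2 +-20%
DEFAULT_PERTURBATIONS: tuple[tuple[str, float], ...] = (
    ("sigma1", +0.10),
    ("sigma1", -0.10),
    ("sigma2", +0.20),
    ("sigma2", -0.20),
    ("w2", +0.20),
    ("w2", -0.20),
)

_FIELD_OF = {"sigma1": "sigma1_mm", "sigma2": "sigma2_mm", "w2": "w2"}


@dataclass(frozen=True)
class SensitivityCell:
    parameter: str
    rel_change: float
    field_size_cm: float
    fsf_base: float
    fsf_perturbed: float | None
    pct_change: float | None
    valid: bool


@dataclass
class SensitivityReport:
    base: SpotFluenceParams
    plane_z_mm: float
    ref_field_size_cm: float
    cells: list[SensitivityCell]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": c.parameter,
                    "rel_change": c.rel_change,
                    "field_size_cm": c.field_size_cm,
                    "ref_field_size_cm": self.ref_field_size_cm,
                    "plane_z_mm": self.plane_z_mm,
                    "fsf_base": c.fsf_base,
                    "fsf_perturbed": c.fsf_perturbed,
                    "pct_change": c.pct_change,
                    "valid": c.valid,
                }
                for c in self.cells
            ]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _perturbed(params: SpotFluenceParams, name: str, rel: float) -> SpotFluenceParams | None:
    """Perturbed copy, or None if it would break sigma2 >= sigma1."""
    attr = _FIELD_OF[name]
    value = getattr(params, attr) * (1.0 + rel)
    if name == "sigma1" and value > params.sigma2_mm:
        return None
    if name == "sigma2" and value < params.sigma1_mm:
        return None
    if name == "w2" and not 0.0 <= value < 1.0:
        return None
    return replace(params, **{attr: value})


def perturb_and_compare(
    params: SpotFluenceParams,
    geom: BeamGeometry,
    z_mm: float = 0.0,
    field_sizes_cm: Sequence[float] = (2.0, 4.0, 6.0, 8.0, 20.0),
    perturbations: Sequence[tuple[str, float]] = DEFAULT_PERTURBATIONS,
    ref_field_size_cm: float = 10.0,
) -> SensitivityReport:
    """FSF change, in percent, for each (parameter, relative change, field size).

    Perturbations are applied one at a time.  A perturbation that would make
    the halo narrower than the core (sigma2 < sigma1) is recorded as an
    invalid cell rather than raised.
    """
    for name, _ in perturbations:
        if name not in _FIELD_OF:
            raise ValueError(f"unknown parameter {name!r}; expected one of {sorted(_FIELD_OF)}")
    base_fsf = {
        fs: fsf(params, geom, z_mm, fs, ref_field_size_cm) for fs in field_sizes_cm
    }
    cells: list[SensitivityCell] = []
    for name, rel in perturbations:
        pert = _perturbed(params, name, rel)
        for fs in field_sizes_cm:
            b = base_fsf[fs]
            if pert is None:
                cells.append(SensitivityCell(name, rel, fs, b, None, None, False))
                continue
            if rel == 0.0:
                # unperturbed model: exactly zero change by construction
                cells.append(SensitivityCell(name, rel, fs, b, b, 0.0, True))
                continue
            v = fsf(pert, geom, z_mm, fs, ref_field_size_cm)
            cells.append(
                SensitivityCell(name, rel, fs, b, v, 100.0 * (v - b) / b, True)
            )
    return SensitivityReport(params, z_mm, ref_field_size_cm, cells)
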