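"""Synthetic FSF measurement campaigns with known ground truth.

Emulates a full in-air field-size-factor commissioning campaign for a
range-shifter beamline: ten energies, five measurement planes (isocenter,
+-10 cm, +-20 cm), field sizes 2-20 cm on a 5 mm spot grid normalized to
the 10 cm field, with multiplicative chamber-reading noise (0.2% relative
standard deviation by default, matching the day-to-day reproducibility of
repeated charge measurements) and an optional Lorentzian tail admixture
that makes the generated spots deliberately non-double-Gaussian.

The truth parameters are smooth in energy so that interpolation to unfitted
layers is a meaningful test: the primary sigma shrinks with energy (less
scattering in the range shifter), grows downstream of it, the halo is a
fixed multiple of the core, and the halo weight decreases with energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fluence import FsfRecord, SpotFluenceParams, central_fluence, half_grid_count
from .geometry import BeamGeometry, projected_spacing

DEFAULT_FIELD_SIZES_CM = (2.0, 4.0, 6.0, 8.0, 10.0, 20.0)


@dataclass(frozen=True)
class TruthMachine:
    """Ground-truth fluence parameters as smooth functions of energy and plane.

    sigma1 interpolates linearly from ``sigma1_at_emin`` to ``sigma1_at_emax``
    at the isocenter plane and grows by ``sigma1_growth_per_100mm`` per
    100 mm of downstream plane offset; sigma2 = ``sigma2_ratio`` * sigma1;
    w2 interpolates linearly from ``w2_at_emin`` to ``w2_at_emax``.
    """

    e_min_MeV: float = 80.3
    e_max_MeV: float = 175.6
    sigma1_at_emin_mm: float = 9.0
    sigma1_at_emax_mm: float = 4.5
    sigma1_growth_per_100mm: float = 0.08
    sigma2_ratio: float = 3.5
    w2_at_emin: float = 0.12
    w2_at_emax: float = 0.04
    noise_sd: float = 0.002
    mismatch_fraction: float = 0.0
    mismatch_width_mm: float = 40.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.mismatch_fraction <= 0.1:
            raise ValueError("mismatch fraction must lie in [0, 0.1]")

    def _frac(self, energy_MeV: float) -> float:
        return (energy_MeV - self.e_min_MeV) / (self.e_max_MeV - self.e_min_MeV)

    def truth_params(self, energy_MeV: float, plane_z_mm: float) -> SpotFluenceParams:
        t = self._frac(energy_MeV)
        s1_iso = self.sigma1_at_emin_mm + t * (
            self.sigma1_at_emax_mm - self.sigma1_at_emin_mm
        )
        s1 = s1_iso * (1.0 + self.sigma1_growth_per_100mm * plane_z_mm / 100.0)
        w2 = self.w2_at_emin + t * (self.w2_at_emax - self.w2_at_emin)
        return SpotFluenceParams(s1, self.sigma2_ratio * s1, w2)

    def layer_list(self, n_layers: int = 68) -> np.ndarray:
        """The machine's deliverable energy layers (uniform by default)."""
        return np.linspace(self.e_min_MeV, self.e_max_MeV, n_layers)

    def _measured_indices(self, n: int, n_layers: int) -> np.ndarray:
        return np.unique(np.round(np.linspace(0, n_layers - 1, n)).astype(int))

    def measured_energies(self, n: int = 10, n_layers: int = 68) -> np.ndarray:
        """Energies chosen for measurement: n layers spread over the grid.

        Only deliverable layers can be measured, so these are exact elements
        of :meth:`layer_list`.
        """
        return self.layer_list(n_layers)[self._measured_indices(n, n_layers)]

    def validation_energies(self, n: int = 10, n_layers: int = 68) -> np.ndarray:
        """Held-out layers roughly midway between the measured ones."""
        layers = self.layer_list(n_layers)
        idx = self._measured_indices(n, n_layers)
        mid = (idx[:-1] + idx[1:]) // 2
        extra = (idx[0] + mid[0]) // 2
        held = np.unique(np.append(mid, extra))
        assert not set(held.tolist()) & set(idx.tolist())
        return layers[held]


def lorentzian_fluence_at(width_mm: float, dx_mm, dy_mm):
    """Areal Lorentzian profile w / (2 pi (r^2 + w^2)^(3/2)); unit integral."""
    r2 = np.asarray(dx_mm, dtype=float) ** 2 + np.asarray(dy_mm, dtype=float) ** 2
    return width_mm / (2.0 * math.pi * (r2 + width_mm**2) ** 1.5)


def _lorentzian_central(
    width_mm: float, geom: BeamGeometry, z_mm: float, field_size_mm: float
) -> float:
    n = half_grid_count(field_size_mm, geom.spot_spacing_mm)
    ssx = projected_spacing(geom, z_mm, "x")
    ssy = projected_spacing(geom, z_mm, "y")
    i = np.arange(-n, n + 1, dtype=float)
    xx, yy = np.meshgrid(i * ssx, i * ssy)
    return float(lorentzian_fluence_at(width_mm, xx, yy).sum())


def inject_mismatch(params: SpotFluenceParams, fraction: float, width_mm: float):
    """Central-fluence evaluator with a Lorentzian tail mixed into the spot.

    Returns ``f(geom, z_mm, field_size_mm)`` evaluating
    ``(1 - fraction) * double-Gaussian + fraction * Lorentzian`` summed over
    the field's spot grid.  The fitted model stays double-Gaussian, so this
    turns the residuals structured instead of purely noisy.
    """
    if not 0.0 <= fraction <= 0.1:
        raise ValueError("mismatch fraction must lie in [0, 0.1]")
    if fraction > 0 and width_mm <= params.sigma2_mm:
        raise ValueError(
            f"Lorentzian width ({width_mm} mm) must exceed sigma2 "
            f"({params.sigma2_mm} mm); the mismatch models a still-wider tail"
        )

    def evaluate(geom: BeamGeometry, z_mm: float, field_size_mm: float) -> float:
        dg = central_fluence(params, geom, z_mm, field_size_mm)
        if fraction == 0.0:
            return dg
        lz = _lorentzian_central(width_mm, geom, z_mm, field_size_mm)
        return (1.0 - fraction) * dg + fraction * lz

    return evaluate


def _truth_fsf(
    machine: TruthMachine,
    geom: BeamGeometry,
    energy: float,
    z: float,
    field_size_cm: float,
    ref_field_size_cm: float,
) -> float:
    params = machine.truth_params(energy, z)
    evaluate = inject_mismatch(
        params, machine.mismatch_fraction, machine.mismatch_width_mm
    )
    return evaluate(geom, z, field_size_cm * 10.0) / evaluate(
        geom, z, ref_field_size_cm * 10.0
    )


def generate_campaign(
    machine: TruthMachine,
    geom: BeamGeometry,
    seed: int,
    energies: Sequence[float] | None = None,
    planes: Sequence[float] | None = None,
    field_sizes_cm: Sequence[float] = DEFAULT_FIELD_SIZES_CM,
    ref_field_size_cm: float = 10.0,
    mode: str = "direct",
) -> tuple[list[FsfRecord], dict]:
    """Simulate one measured FSF campaign; same seed gives identical output.

    The default design (10 energies x 5 planes x field sizes 2-20 cm minus
    the reference) yields 250 records.  Two noise modes are provided:

    - ``"direct"``: the reference is exact by construction and each non-
      reference FSF gets independent multiplicative noise (noise applied
      after normalization);
    - ``"charges"``: every raw charge reading, including the reference,
      carries noise before the ratios are taken, as in a real cumulative-
      charge delivery.

    Returns the records and a truth dict mapping (energy, plane) to the
    generating :class:`SpotFluenceParams`.
    """
    if mode not in ("direct", "charges"):
        raise ValueError(f"mode must be 'direct' or 'charges', got {mode!r}")
    if energies is None:
        energies = machine.measured_energies(10)
    if planes is None:
        planes = geom.plane_offsets_mm
    rng = np.random.default_rng(seed)

    records: list[FsfRecord] = []
    truth: dict[tuple[float, float], SpotFluenceParams] = {}
    for e in energies:
        for z in planes:
            truth[(float(e), float(z))] = machine.truth_params(e, z)
            if mode == "charges":
                evaluate = inject_mismatch(
                    machine.truth_params(e, z),
                    machine.mismatch_fraction,
                    machine.mismatch_width_mm,
                )
                raw = {
                    fs: evaluate(geom, z, fs * 10.0)
                    * (1.0 + machine.noise_sd * rng.standard_normal())
                    for fs in field_sizes_cm
                }
                ref = raw[ref_field_size_cm]
                for fs in field_sizes_cm:
                    if fs == ref_field_size_cm:
                        continue
                    records.append(
                        FsfRecord(float(e), float(z), fs, raw[fs] / ref, ref_field_size_cm)
                    )
            else:
                for fs in field_sizes_cm:
                    if fs == ref_field_size_cm:
                        continue
                    value = _truth_fsf(machine, geom, e, z, fs, ref_field_size_cm)
                    value *= 1.0 + machine.noise_sd * rng.standard_normal()
                    records.append(
                        FsfRecord(float(e), float(z), fs, value, ref_field_size_cm)
                    )
    return records, truth


def generate_validation_campaign(
    machine: TruthMachine,
    geom: BeamGeometry,
    seed: int,
    n_energies: int = 10,
    field_sizes_cm: Sequence[float] = DEFAULT_FIELD_SIZES_CM,
) -> tuple[list[FsfRecord], dict]:
    """Held-out campaign at the isocenter plane only (50 records by default)."""
    return generate_campaign(
        machine,
        geom,
        seed=seed,
        energies=machine.validation_energies(n_energies),
        planes=(0.0,),
        field_sizes_cm=field_sizes_cm,
    )
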