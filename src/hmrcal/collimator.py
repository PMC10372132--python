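"""Parallel-hole collimator response quantities for :sup:`123`I imaging.

A parallel-hole collimator is characterized by three design parameters:
hole diameter ``d``, septal thickness ``t`` and length ``L`` (all mm).
This module provides the standard first-order design quantities derived
from them:

* effective length ``L_eff = L - 2/mu_Pb(E)`` (septa are not perfectly
  opaque, so the collimator behaves as if slightly shorter),
* geometric resolution ``R_g = d * (L_eff + b) / L_eff`` at source
  distance ``b``,
* geometric efficiency ``(K d^2 / (L_eff (d + t)))^2`` with ``K = 0.26``
  for hexagonal hole packing,
* minimal septal path ``w_min = L t / (2 d + t)`` — the shortest lead
  path a photon can take through a single septum,
* septal penetration fraction ``exp(-mu_Pb(E) w_min)``.

The penetration fraction is the quantity used to exclude unrealistic
designs (> 1% at the 159 keV photopeak) and, at the high-energy
:sup:`123`I lines (440-538 keV), the driver of the contrast loss that the
whole calibration pipeline quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CollimatorError",
    "CollimatorSpec",
    "EmissionLine",
    "AttenuationTable",
    "attenuation_table",
    "emission_spectrum",
    "effective_length",
    "geometric_fwhm",
    "geometric_efficiency",
    "minimal_septal_path",
    "penetration_fraction",
    "load_collimator_presets",
    "get_collimator_preset",
]

LEAD_DENSITY = 11.34  # g/cm^3, pure lead
HEX_PACKING_CONSTANT = 0.26  # K for hexagonal hole arrays

MATERIAL_DENSITIES = {"pb": 11.34, "nai": 3.667, "pmma": 1.19}


class CollimatorError(ValueError):
    """Invalid collimator specification or out-of-domain physics query."""


@dataclass(frozen=True)
class CollimatorSpec:
    """Hole diameter / septal thickness / length triple defining a design.

    ``material_density`` is the collimator alloy density in g/cm^3; pure
    lead (11.34) by default, lead-antimony alloys down to 11.0 are allowed.
    """

    hole_diameter: float
    septal_thickness: float
    length: float
    material_density: float = LEAD_DENSITY
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.hole_diameter > 0 and self.septal_thickness > 0 and self.length > 0):
            raise CollimatorError(
                f"collimator dimensions must be positive, got d={self.hole_diameter}, "
                f"t={self.septal_thickness}, L={self.length}"
            )
        if not (11.0 <= self.material_density <= 11.4):
            raise CollimatorError(
                f"material density {self.material_density} g/cm^3 outside the "
                "modelled lead-alloy range [11.0, 11.4]"
            )

    def as_features(self) -> tuple[float, float, float]:
        return (self.hole_diameter, self.septal_thickness, self.length)


@dataclass(frozen=True)
class EmissionLine:
    """One gamma line of the decay scheme: energy (keV) and photons/decay."""

    energy: float
    abundance: float

    def __post_init__(self) -> None:
        if not (0.0 < self.abundance <= 1.0):
            raise ValueError(f"abundance must be in (0, 1], got {self.abundance}")
        if self.energy <= 0:
            raise ValueError(f"energy must be positive, got {self.energy}")


# 123I decay scheme: the 159 keV principal line plus the four high-energy
# lines above 400 keV that survive septal penetration.  Low-energy X-rays
# (< 35 keV) are omitted: they cannot reach the 159 keV +/- 10% window.
_I123_LINES = (
    EmissionLine(159.0, 0.833),
    EmissionLine(440.0, 0.00428),
    EmissionLine(505.3, 0.00316),
    EmissionLine(529.0, 0.01390),
    EmissionLine(538.5, 0.00382),
)


def emission_spectrum() -> list[EmissionLine]:
    """The modelled :sup:`123`I emission spectrum, energies ascending."""
    return list(_I123_LINES)


class AttenuationTable:
    """Linear attenuation coefficients mu(E) for lead, NaI(Tl) and PMMA.

    Backed by a coarse embedded mass-attenuation table (100-600 keV)
    interpolated log-log, which is accurate to a few percent between the
    tabulated points for these smooth, edge-free energy ranges.
    """

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            with resources.files("hmrcal.data").joinpath("attenuation.csv").open() as fh:
                frame = pd.read_csv(fh, comment="#")
        self._energies = frame["energy_kev"].to_numpy(dtype=float)
        self._mass_mu = {
            m: frame[m].to_numpy(dtype=float) for m in ("pb", "nai", "pmma")
        }
        if not np.all(np.diff(self._energies) > 0):
            raise ValueError("attenuation table energies must be ascending")
        for m, mu in self._mass_mu.items():
            if not np.all(np.diff(mu) < 0):
                raise ValueError(f"mass attenuation for {m} must decrease with energy")

    @property
    def energy_range(self) -> tuple[float, float]:
        return float(self._energies[0]), float(self._energies[-1])

    def mass_mu(self, material: str, energy: float) -> float:
        """Mass attenuation coefficient (cm^2/g) at ``energy`` keV."""
        lo, hi = self.energy_range
        if not (lo <= energy <= hi):
            raise CollimatorError(
                f"energy {energy} keV outside attenuation table range [{lo}, {hi}]"
            )
        logmu = np.interp(
            math.log(energy), np.log(self._energies), np.log(self._mass_mu[material])
        )
        return float(math.exp(logmu))

    def linear_mu(self, material: str, energy: float, density: float | None = None) -> float:
        """Linear attenuation coefficient (mm^-1) at ``energy`` keV."""
        rho = MATERIAL_DENSITIES[material] if density is None else density
        return self.mass_mu(material, energy) * rho / 10.0  # cm^-1 -> mm^-1


#: Shared default table used across the package.
attenuation_table = AttenuationTable()


def effective_length(
    c: CollimatorSpec, energy: float, table: AttenuationTable = None
) -> float:
    """Effective collimator length ``L - 2/mu_Pb(E)`` in mm."""
    table = table or attenuation_table
    mu = table.linear_mu("pb", energy, density=c.material_density)
    if mu * c.length <= 2.0:
        raise CollimatorError(
            f"collimator transparent at {energy} keV: mu*L = {mu * c.length:.3f} <= 2"
        )
    return c.length - 2.0 / mu


def geometric_fwhm(
    c: CollimatorSpec,
    energy: float,
    source_distance: float,
    table: AttenuationTable = None,
) -> float:
    """Geometric resolution FWHM ``d (L_eff + b) / L_eff`` (mm) at distance b."""
    if source_distance < 0:
        raise CollimatorError(f"source distance must be >= 0, got {source_distance}")
    leff = effective_length(c, energy, table)
    return c.hole_diameter * (leff + source_distance) / leff


def geometric_efficiency(
    c: CollimatorSpec, energy: float, table: AttenuationTable = None
) -> float:
    """Geometric (collimated) sensitivity, fraction of emitted photons.

    ``(K d^2 / (L_eff (d + t)))^2`` with the hexagonal packing constant.
    """
    leff = effective_length(c, energy, table)
    d, t = c.hole_diameter, c.septal_thickness
    return (HEX_PACKING_CONSTANT * d * d / (leff * (d + t))) ** 2


def minimal_septal_path(c: CollimatorSpec) -> float:
    """Shortest lead path through a single septum, ``L t / (2 d + t)`` mm."""
    return c.length * c.septal_thickness / (2.0 * c.hole_diameter + c.septal_thickness)


def penetration_fraction(
    c: CollimatorSpec, energy: float, table: AttenuationTable = None
) -> float:
    """Single-septum minimal-path penetration, ``exp(-mu_Pb(E) w_min)``."""
    table = table or attenuation_table
    mu = table.linear_mu("pb", energy, density=c.material_density)
    return math.exp(-mu * minimal_septal_path(c))


def load_collimator_presets() -> pd.DataFrame:
    """Bundled commercial collimator presets (camera, label, d, t, L)."""
    with resources.files("hmrcal.data").joinpath("collimators.csv").open() as fh:
        return pd.read_csv(fh)


def get_collimator_preset(camera: str, label: str) -> CollimatorSpec:
    """Look up one bundled preset as a :class:`CollimatorSpec`."""
    presets = load_collimator_presets()
    row = presets[(presets["camera"] == camera) & (presets["collimator"] == label)]
    if row.empty:
        raise KeyError(f"no preset for camera={camera!r}, collimator={label!r}")
    r = row.iloc[0]
    return CollimatorSpec(
        hole_diameter=float(r["hole_diameter_mm"]),
        septal_thickness=float(r["septum_mm"]),
        length=float(r["length_mm"]),
        label=f"{camera} {label}",
    )
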