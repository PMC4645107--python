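"""Beam, focus and pulse modelling.

Photon counts from pulse energy and transmissions, Gaussian and
double-Gaussian focal fluence fields, flat-top temporal shapes with an
optional Bragg-termination gate, photon-weighted fluence quadratures, dose
estimates and the flat-attenuator transmission correction.

Fluences are photons/um^2, energies keV, times fs, lengths um unless noted.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from hiphase import defaults
from hiphase.errors import (
    ConfigError,
    DomainError,
    GeometryError,
    TableLookupError,
    UnsupportedProfileError,
)

__all__ = [
    "GaussianComponent",
    "SpatialProfile",
    "TemporalProfile",
    "BeamModel",
    "FluenceQuadrature",
    "photons_per_pulse",
    "peak_fluence",
    "fluence_quadrature",
    "average_dose",
    "attenuator_transmission",
    "fluence_ratio_to_saturation",
]


@dataclass(frozen=True)
class GaussianComponent:
    """One 2-D Gaussian focus component."""

    photon_fraction: float
    fwhm_um: float

    def __post_init__(self) -> None:
        if not 0 < self.photon_fraction <= 1:
            raise DomainError("photon_fraction must be in (0, 1]")
        if self.fwhm_um <= 0:
            raise DomainError("fwhm must be > 0")

    @property
    def sigma_um(self) -> float:
        return self.fwhm_um / defaults.FWHM_TO_SIGMA


@dataclass(frozen=True)
class SpatialProfile:
    """Focal fluence field F(r).

    ``gaussian``/``double_gaussian`` carry concentric Gaussian components
    whose photon fractions sum to 1; ``point`` and ``uniform`` carry a single
    effective fluence scale instead.
    """

    kind: str
    components: tuple[GaussianComponent, ...] = ()
    fluence_scale: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "uniform", "gaussian", "double_gaussian"):
            raise DomainError(f"unknown spatial profile kind {self.kind!r}")
        if self.kind in ("gaussian", "double_gaussian"):
            want = 1 if self.kind == "gaussian" else 2
            if len(self.components) != want:
                raise DomainError(
                    f"{self.kind} profile needs {want} component(s)"
                )
            total = sum(c.photon_fraction for c in self.components)
            if abs(total - 1.0) > 1e-9:
                raise DomainError("photon fractions must sum to 1")
        else:
            if self.fluence_scale is None or self.fluence_scale < 0:
                raise DomainError(
                    f"{self.kind} profile needs a nonnegative fluence_scale"
                )

    @classmethod
    def gaussian(cls, fwhm_um: float) -> "SpatialProfile":
        return cls("gaussian", (GaussianComponent(1.0, fwhm_um),))

    @classmethod
    def double_gaussian(
        cls,
        hot_fraction: float = 0.5,
        hot_fwhm_um: float = defaults.FOCUS_FWHM_UM,
        pedestal_fwhm_um: float = defaults.PEDESTAL_FWHM_UM,
    ) -> "SpatialProfile":
        return cls(
            "double_gaussian",
            (
                GaussianComponent(hot_fraction, hot_fwhm_um),
                GaussianComponent(1.0 - hot_fraction, pedestal_fwhm_um),
            ),
        )

    @classmethod
    def point(cls, fluence: float) -> "SpatialProfile":
        return cls("point", fluence_scale=fluence)


@dataclass(frozen=True)
class TemporalProfile:
    """Flat-top temporal pulse shape, unit integral over its support.

    ``gate_fs`` is an optional Bragg-termination cutoff: signal recorded
    only on [0, gate].
    """

    duration_fs: float = defaults.PULSE_DURATION_FS
    gate_fs: float | None = None
    kind: str = "flat_top"

    def __post_init__(self) -> None:
        if self.kind != "flat_top":
            raise DomainError(f"unsupported temporal shape {self.kind!r}")
        if self.duration_fs <= 0:
            raise DomainError("pulse duration must be > 0")
        if self.gate_fs is not None and not 0 < self.gate_fs <= self.duration_fs:
            raise DomainError("gate time must lie in (0, duration]")

    def density(self) -> float:
        """Normalized instantaneous weight g(t) on [0, duration]."""
        return 1.0 / self.duration_fs


@dataclass(frozen=True)
class BeamModel:
    """Beam parameters as measured upstream of the interaction region."""

    photon_energy_keV: float
    pulse_energy_mJ: float
    optics_transmission: float
    attenuation: float
    spatial: SpatialProfile
    temporal: TemporalProfile

    def __post_init__(self) -> None:
        if self.photon_energy_keV <= 0 or self.pulse_energy_mJ <= 0:
            raise DomainError("photon energy and pulse energy must be > 0")
        if not 0 < self.optics_transmission <= 1:
            raise DomainError("optics transmission must be in (0, 1]")
        if not 0 < self.attenuation <= 1:
            raise DomainError("attenuation must be in (0, 1]")


@dataclass(frozen=True)
class FluenceQuadrature:
    """Photon-weighted discretization of the focal fluence distribution."""

    nodes: np.ndarray  # fluence values, photons/um^2
    weights: np.ndarray  # photon-weight fractions, sum to 1

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if np.any(nodes < 0) or np.any(weights < 0):
            raise DomainError("quadrature nodes and weights must be >= 0")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise DomainError("quadrature weights must sum to 1")

    @property
    def mean_fluence(self) -> float:
        return float(np.dot(self.nodes, self.weights))


def photons_per_pulse(beam: BeamModel) -> float:
    """Photons delivered to the interaction region per pulse."""
    energy_j = beam.pulse_energy_mJ * 1e-3 * beam.attenuation * beam.optics_transmission
    return energy_j / (beam.photon_energy_keV * defaults.KEV_TO_J)


def peak_fluence(n_photons: float, spatial: SpatialProfile) -> float:
    """Peak fluence at the common centre of the Gaussian component(s).

    For a 2-D Gaussian, ``N / (2 pi sigma^2)``; for a double Gaussian, the
    sum of the concentric component peaks.
    """
    if spatial.kind not in ("gaussian", "double_gaussian"):
        raise UnsupportedProfileError(
            f"peak fluence undefined for {spatial.kind!r} profile"
        )
    return sum(
        c.photon_fraction * n_photons / (2.0 * math.pi * c.sigma_um**2)
        for c in spatial.components
    )


def fluence_quadrature(
    spatial: SpatialProfile, n_photons: float, n_nodes: int = defaults.N_QUADRATURE_NODES
) -> FluenceQuadrature:
    """Photon-weighted fluence quadrature over the focal plane.

    The photon-weighted fluence of a single 2-D Gaussian is uniform on
    (0, F_peak] (closed form), discretized with ``n_nodes`` midpoint nodes;
    a double Gaussian is treated as the photon-fraction-weighted mixture of
    its components' uniforms (component overlap neglected).  ``point``
    profiles collapse to one node at the fluence scale.
    """
    if spatial.kind in ("point", "uniform"):
        return FluenceQuadrature(
            np.array([spatial.fluence_scale]), np.array([1.0])
        )
    if n_nodes < 2:
        raise ConfigError("distributed profiles need n_nodes >= 2")
    nodes, weights = [], []
    for c in spatial.components:
        f_peak = c.photon_fraction * n_photons / (2.0 * math.pi * c.sigma_um**2)
        mid = (np.arange(n_nodes) + 0.5) / n_nodes
        nodes.append(mid * f_peak)
        weights.append(np.full(n_nodes, c.photon_fraction / n_nodes))
    return FluenceQuadrature(np.concatenate(nodes), np.concatenate(weights))


# -- material data ------------------------------------------------------------

def _coefficient_table() -> list[dict]:
    path = resources.files("hiphase").joinpath("data/mass_coefficients.csv")
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    header = rows[0]
    return [dict(zip(header, r)) for r in rows[1:]]


def _interp_coefficient(material: str, kind: str, energy_keV: float) -> tuple[float, float]:
    """Log-log interpolated mu/rho (cm^2/g) and density (g/cm^3)."""
    rows = [
        r
        for r in _coefficient_table()
        if r["material"] == material and r["kind"] == kind
    ]
    if not rows:
        raise TableLookupError(
            f"no {kind} coefficients for material {material!r}"
        )
    energies = np.array([float(r["energy_keV"]) for r in rows])
    coeffs = np.array([float(r["mu_rho_cm2_g"]) for r in rows])
    order = np.argsort(energies)
    energies, coeffs = energies[order], coeffs[order]
    if not energies[0] <= energy_keV <= energies[-1]:
        raise TableLookupError(
            f"{material}: {energy_keV} keV outside tabulated range "
            f"[{energies[0]}, {energies[-1]}]"
        )
    mu_rho = float(
        np.exp(np.interp(np.log(energy_keV), np.log(energies), np.log(coeffs)))
    )
    return mu_rho, float(rows[0]["density_g_cm3"])


def average_dose(
    fluence: float,
    photon_energy_keV: float,
    medium: str = "protein",
    *,
    convention: str = "gaussian_mean",
) -> float:
    """Estimated absorbed dose (Gy) for a given peak or local fluence.

    ``dose = fluence * E_photon * (mu_en/rho)``, unit-converted to Gy.  The
    default convention treats ``fluence`` as the peak of a Gaussian focus and
    averages over the photon-weighted fluence distribution (factor 1/2);
    ``convention='at_fluence'`` uses the value as is.  The absolute scale is
    an estimate: it depends on this averaging convention and on the reduced
    mass energy-absorption table.
    """
    if fluence < 0:
        raise DomainError("fluence must be >= 0")
    if convention not in ("gaussian_mean", "at_fluence"):
        raise DomainError(f"unknown dose convention {convention!r}")
    mu_rho, _ = _interp_coefficient(medium, "energy_absorption", photon_energy_keV)
    factor = 0.5 if convention == "gaussian_mean" else 1.0
    energy_fluence_j_cm2 = (
        fluence / defaults.UM2_TO_CM2 * photon_energy_keV * defaults.KEV_TO_J
    )
    return factor * energy_fluence_j_cm2 * mu_rho * 1e3  # J/g -> Gy


def attenuator_transmission(
    thickness_um: float,
    material: str,
    photon_energy_keV: float,
    two_theta: float = 0.0,
) -> float:
    """Transmission of a flat attenuator slab normal to the direct beam.

    ``exp(-mu * thickness / cos(two_theta))``; the path length grows with
    the scattering angle.  The intensity correction factor is ``1/T``.
    """
    if thickness_um < 0:
        raise DomainError("thickness must be >= 0")
    if not 0 <= two_theta < math.pi / 2:
        raise GeometryError("two_theta must lie in [0, pi/2)")
    mu_rho, density = _interp_coefficient(material, "attenuation", photon_energy_keV)
    mu_per_um = mu_rho * density * 1e-4  # cm^-1 -> um^-1
    return math.exp(-mu_per_um * thickness_um / math.cos(two_theta))


def fluence_ratio_to_saturation(peak: float, sat: float) -> float:
    """How many times the peak fluence exceeds the saturation fluence."""
    if sat <= 0:
        raise DomainError("saturation fluence must be > 0")
    return peak / sat
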