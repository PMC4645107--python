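"""Seeded generators for every input the pipeline consumes.

Three families: serial-crystallography pattern-metadata streams whose
observables (pulse-energy reading, peak count, mean peak intensity, best
resolution) are positively correlated with a ground-truth on-crystal
fluence; toy two-heavy-site structures with a planted ionization contrast
and a 48-electron reference group; and ready-made beam/atom fixture
configs at the reference experimental parameters.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hiphase import defaults
from hiphase.densitometry import AtomSite, DensityMap, render_map
from hiphase.errors import ConfigError

__all__ = [
    "StreamConfig",
    "ToyStructureConfig",
    "generate_stream",
    "generate_structure_pair",
    "render_structure_maps",
    "fixture_configs",
]


@dataclass(frozen=True)
class StreamConfig:
    """Distribution laws of the synthetic pattern-metadata stream.

    Pulse energies are gamma-distributed around the mean; a lognormal
    pointing/crystal-coupling factor links pulse energy to the true
    on-crystal fluence; the peak count grows with fluence (Poisson); the
    mean peak intensity is proportional to fluence times a lognormal
    crystal-size factor; the best resolution improves stochastically with
    the peak count.  Setting every fluctuation scale to zero collapses the
    stream to identical records.
    """

    n_patterns: int = 10_000
    seed: int = 0
    pulse_energy_mean_mJ: float = defaults.PULSE_ENERGY_MJ
    pulse_energy_cv: float = 0.2  # relative std of the gamma law
    coupling_sigma: float = 0.9  # lognormal sigma of the fluence coupling
    fluence_scale: float = 7.8e12  # photons/um^2 at nominal energy, ideal hit
    peak_base: float = 5.0
    peak_gain: float = 150.0
    peak_exponent: float = 0.6
    intensity_scale: float = 1000.0  # detector units at fluence_scale
    size_sigma: float = 0.35  # lognormal sigma of the crystal-size factor
    reading_sigma: float = 0.03  # monitor reading noise
    resolution_best_A: float = 1.8
    resolution_range_A: float = 2.5
    resolution_decay_peaks: float = 60.0
    resolution_sigma: float = 0.08

    def __post_init__(self) -> None:
        if self.n_patterns < 1:
            raise ConfigError("n_patterns must be >= 1")
        for name in (
            "pulse_energy_mean_mJ",
            "fluence_scale",
            "intensity_scale",
            "peak_gain",
            "resolution_best_A",
            "resolution_decay_peaks",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in (
            "pulse_energy_cv",
            "coupling_sigma",
            "size_sigma",
            "reading_sigma",
            "resolution_sigma",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


def generate_stream(cfg: StreamConfig) -> pd.DataFrame:
    """Synthetic pattern records including the true-fluence ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patterns

    if cfg.pulse_energy_cv > 0:
        shape = 1.0 / cfg.pulse_energy_cv**2
        pulse = cfg.pulse_energy_mean_mJ * rng.gamma(shape, 1.0 / shape, n)
    else:
        pulse = np.full(n, cfg.pulse_energy_mean_mJ)
    coupling = (
        rng.lognormal(-0.5 * cfg.coupling_sigma**2, cfg.coupling_sigma, n)
        if cfg.coupling_sigma > 0
        else np.ones(n)
    )
    fluence = cfg.fluence_scale * (pulse / cfg.pulse_energy_mean_mJ) * coupling
    rel = fluence / cfg.fluence_scale

    mean_peaks = cfg.peak_base + cfg.peak_gain * rel**cfg.peak_exponent
    deterministic = (
        cfg.pulse_energy_cv == 0
        and cfg.coupling_sigma == 0
        and cfg.size_sigma == 0
        and cfg.reading_sigma == 0
        and cfg.resolution_sigma == 0
    )
    n_peaks = (
        np.round(mean_peaks).astype(int)
        if deterministic
        else rng.poisson(mean_peaks)
    )
    size = (
        rng.lognormal(-0.5 * cfg.size_sigma**2, cfg.size_sigma, n)
        if cfg.size_sigma > 0
        else np.ones(n)
    )
    intensity = cfg.intensity_scale * rel * size
    reading = pulse * (
        rng.lognormal(-0.5 * cfg.reading_sigma**2, cfg.reading_sigma, n)
        if cfg.reading_sigma > 0
        else 1.0
    )
    res_noise = (
        rng.lognormal(-0.5 * cfg.resolution_sigma**2, cfg.resolution_sigma, n)
        if cfg.resolution_sigma > 0
        else np.ones(n)
    )
    resolution = (
        cfg.resolution_best_A
        + cfg.resolution_range_A * np.exp(-n_peaks / cfg.resolution_decay_peaks)
    ) * res_noise

    return pd.DataFrame(
        {
            "id": [f"p{i:07d}" for i in range(n)],
            "pulse_energy_reading_mJ": reading,
            "n_peaks": n_peaks,
            "mean_peak_intensity": intensity,
            "max_resolution_A": resolution,
            "true_fluence": fluence,
        }
    )


@dataclass(frozen=True)
class ToyStructureConfig:
    """Toy asymmetric unit: two heavy sites, a reference group, decoys."""

    heavy_positions: tuple[tuple[float, float, float], ...] = (
        (7.0, 7.0, 7.0),
        (17.0, 15.0, 9.0),
    )
    heavy_occupancies: tuple[float, ...] = (1.0, 0.7)
    electrons_lf: float = 57.0
    electrons_hf: float = 32.0
    reference_center: tuple[float, float, float] = (7.0, 17.0, 13.0)
    reference_n_atoms: int = 8
    reference_electrons_total: float = 48.0
    reference_ring_radius: float = 1.4
    n_decoys: int = 30
    decoy_exclusion_radius: float = 4.5
    noise_level: float = 0.3  # additive map noise, e-/A^3
    b_factor: float = 10.0
    box_A: float = 24.0
    voxel_A: float = 0.3
    integration_radius_A: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.heavy_positions) != len(self.heavy_occupancies):
            raise ConfigError("one occupancy per heavy site required")
        if self.noise_level < 0:
            raise ConfigError("noise level must be >= 0")
        pts = list(self.heavy_positions) + [self.reference_center]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = math.dist(pts[i], pts[j])
                if d <= 2.0 * self.integration_radius_A:
                    raise ConfigError(
                        f"sites {pts[i]} and {pts[j]} are {d:.2f} A apart; "
                        f"need > {2 * self.integration_radius_A} A separation"
                    )


def _reference_sites(cfg: ToyStructureConfig) -> list[AtomSite]:
    per_atom = cfg.reference_electrons_total / cfg.reference_n_atoms
    cx, cy, cz = cfg.reference_center
    sites = []
    for k in range(cfg.reference_n_atoms):
        ang = 2 * math.pi * k / cfg.reference_n_atoms
        sites.append(
            AtomSite(
                position=(
                    cx + cfg.reference_ring_radius * math.cos(ang),
                    cy + cfg.reference_ring_radius * math.sin(ang),
                    cz,
                ),
                element="C",
                n_electrons=per_atom,
                occupancy=1.0,
                b_factor=cfg.b_factor,
            )
        )
    return sites


def _decoy_sites(cfg: ToyStructureConfig, rng: np.random.Generator) -> list[AtomSite]:
    keep_out = list(cfg.heavy_positions) + [cfg.reference_center]
    margin = 2.5
    sites: list[AtomSite] = []
    while len(sites) < cfg.n_decoys:
        pos = tuple(rng.uniform(margin, cfg.box_A - margin, 3))
        if min(math.dist(pos, p) for p in keep_out) < cfg.decoy_exclusion_radius:
            continue
        element = rng.choice(["C", "N", "O"])
        sites.append(
            AtomSite(
                position=pos,
                element=str(element),
                n_electrons=float({"C": 6, "N": 7, "O": 8}[element]),
                occupancy=1.0,
                b_factor=cfg.b_factor,
            )
        )
    return sites


def generate_structure_pair(
    cfg: ToyStructureConfig,
) -> tuple[list[AtomSite], list[AtomSite]]:
    """Identical geometry under two conditions differing only in the
    effective electron count of the heavy sites (the planted contrast)."""
    rng = np.random.default_rng(cfg.seed)
    shared = _reference_sites(cfg) + _decoy_sites(cfg, rng)
    lf, hf = [], []
    for pos, occ in zip(cfg.heavy_positions, cfg.heavy_occupancies):
        lf.append(
            AtomSite(pos, "GD", cfg.electrons_lf, occupancy=occ, b_factor=cfg.b_factor)
        )
        hf.append(
            AtomSite(pos, "GD", cfg.electrons_hf, occupancy=occ, b_factor=cfg.b_factor)
        )
    return lf + shared, hf + shared


def render_structure_maps(
    cfg: ToyStructureConfig,
    sites_lf: list[AtomSite],
    sites_hf: list[AtomSite],
) -> tuple[DensityMap, DensityMap]:
    """Render both site lists on a common grid, adding seeded noise."""
    dims = (int(round(cfg.box_A / cfg.voxel_A)) + 1,) * 3
    rng = np.random.default_rng(cfg.seed + 1)
    maps = []
    for sites in (sites_lf, sites_hf):
        m = render_map(sites, origin=(0.0, 0.0, 0.0), voxel=cfg.voxel_A, dims=dims)
        if cfg.noise_level > 0:
            m = DensityMap(
                origin=m.origin,
                voxel=m.voxel,
                values=m.values + rng.normal(0.0, cfg.noise_level, m.dims),
            )
        maps.append(m)
    return maps[0], maps[1]


# -- fixture configs ----------------------------------------------------------

def _base_config() -> dict:
    return {
        "atom": {
            "element": "Gd",
            "table": None,
            "photon_energy_keV": defaults.PHOTON_ENERGY_KEV,
            "q_floor": defaults.Q_FLOOR_GD,
            "ladder_exponent": defaults.LADDER_EXPONENT,
            "cascade": {"min": defaults.CASCADE_MIN, "max": defaults.CASCADE_MAX},
        },
        "beam": {
            "photon_energy_keV": defaults.PHOTON_ENERGY_KEV,
            "pulse_energy_mJ": defaults.PULSE_ENERGY_MJ,
            "optics_transmission": defaults.OPTICS_TRANSMISSION,
            "attenuation": 1.0,
            "spatial": {
                "kind": "gaussian",
                "components": [
                    {"photon_fraction": 1.0, "fwhm_um": defaults.FOCUS_FWHM_UM}
                ],
            },
            "temporal": {
                "kind": "flat_top",
                "duration_fs": defaults.PULSE_DURATION_FS,
                "gate_fs": None,
            },
        },
        "simulation": {
            "mode": "point",
            "dt_fs": defaults.DT_FS,
            "n_nodes": defaults.N_QUADRATURE_NODES,
            "n_monte_carlo": 10_000,
        },
    }


def fixture_configs(out_dir: str | Path) -> dict[str, Path]:
    """Write the reference-parameter fixture configs (YAML) used by tests.

    ``hf``: unattenuated beam; ``lf``: 1.73% attenuation; ``hf_double_gaussian``:
    50/50 hot-spot/pedestal focus in spatial mode; ``hf_gated``: 20 fs
    Bragg-termination gate.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs: dict[str, dict] = {}

    hf = _base_config()
    configs["hf"] = hf

    lf = _base_config()
    lf["beam"]["attenuation"] = defaults.LF_ATTENUATION
    configs["lf"] = lf

    dg = _base_config()
    dg["beam"]["spatial"] = {
        "kind": "double_gaussian",
        "components": [
            {"photon_fraction": 0.5, "fwhm_um": defaults.FOCUS_FWHM_UM},
            {"photon_fraction": 0.5, "fwhm_um": defaults.PEDESTAL_FWHM_UM},
        ],
    }
    dg["simulation"]["mode"] = "spatial"
    configs["hf_double_gaussian"] = dg

    gated = _base_config()
    gated["beam"]["temporal"]["gate_fs"] = defaults.GATE_HF_FS
    configs["hf_gated"] = gated

    paths = {}
    for name, cfg in configs.items():
        path = out / f"{name}.yaml"
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
        paths[name] = path
    return paths
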