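"""Configuration schema: parsing, validation and model construction.

Configs are YAML or JSON mappings with three blocks::

    atom:        element, table, photon_energy_keV, q_floor,
                 ladder_exponent, cascade {min, max}
    beam:        photon_energy_keV, pulse_energy_mJ, optics_transmission,
                 attenuation, spatial {kind, components}, temporal
                 {kind, duration_fs, gate_fs}
    simulation:  mode, dt_fs, n_nodes, n_monte_carlo

Unknown keys produce warnings (forward compatibility), schema violations
produce error diagnostics with a JSON-pointer-style path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from hiphase import defaults
from hiphase.atomdata import AtomModel, load_atom_model
from hiphase.beam import (
    BeamModel,
    GaussianComponent,
    SpatialProfile,
    TemporalProfile,
)
from hiphase.errors import ConfigError, HiphaseError

__all__ = [
    "Diagnostic",
    "load_config",
    "validate_config",
    "atom_from_config",
    "beam_from_config",
    "simulation_from_config",
]


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    path: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:
        return f"{self.severity}: {self.path}: {self.message}"


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config mapping."""
    text = Path(path).read_text()
    data = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    )
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return data


def _check_number(
    out: list[Diagnostic],
    mapping: dict,
    path: str,
    key: str,
    *,
    lo: float | None = None,
    hi: float | None = None,
    lo_open: bool = False,
    required: bool = False,
    allow_none: bool = False,
) -> None:
    if key not in mapping or mapping[key] is None:
        if required and not allow_none:
            out.append(Diagnostic(f"{path}/{key}", "required value missing"))
        return
    value = mapping[key]
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        out.append(Diagnostic(f"{path}/{key}", f"expected a number, got {value!r}"))
        return
    if lo is not None and (value <= lo if lo_open else value < lo):
        op = ">" if lo_open else ">="
        out.append(Diagnostic(f"{path}/{key}", f"must be {op} {lo} (got {value})"))
    if hi is not None and value > hi:
        out.append(Diagnostic(f"{path}/{key}", f"must be <= {hi} (got {value})"))


def _warn_unknown(
    out: list[Diagnostic], mapping: dict, path: str, known: set[str]
) -> None:
    for key in mapping:
        if key not in known:
            out.append(
                Diagnostic(f"{path}/{key}", "unknown key ignored", "warning")
            )


def validate_config(config: dict | str | Path) -> list[Diagnostic]:
    """Schema diagnostics for a config mapping or file (empty = valid)."""
    if not isinstance(config, dict):
        config = load_config(config)
    out: list[Diagnostic] = []
    _warn_unknown(out, config, "", {"atom", "beam", "simulation", "sorting", "densitometry"})

    atom = config.get("atom", {})
    if not isinstance(atom, dict):
        out.append(Diagnostic("/atom", "must be a mapping"))
        atom = {}
    _warn_unknown(
        out, atom, "/atom",
        {"element", "table", "photon_energy_keV", "q_floor", "ladder_exponent", "cascade"},
    )
    if not isinstance(atom.get("element", "Gd"), str):
        out.append(Diagnostic("/atom/element", "must be an element symbol"))
    table = atom.get("table")
    if table is not None and not Path(table).exists():
        out.append(Diagnostic("/atom/table", f"table file not found: {table}"))
    _check_number(out, atom, "/atom", "photon_energy_keV", lo=0, lo_open=True)
    _check_number(out, atom, "/atom", "q_floor", lo=0)
    _check_number(out, atom, "/atom", "ladder_exponent", lo=0)
    cascade = atom.get("cascade", {})
    if cascade:
        _check_number(out, cascade, "/atom/cascade", "min", lo=0)
        _check_number(out, cascade, "/atom/cascade", "max", lo=0)
        if (
            isinstance(cascade.get("min"), int)
            and isinstance(cascade.get("max"), int)
            and cascade["min"] > cascade["max"]
        ):
            out.append(Diagnostic("/atom/cascade", "min must be <= max"))

    beam = config.get("beam", {})
    if not isinstance(beam, dict):
        out.append(Diagnostic("/beam", "must be a mapping"))
        beam = {}
    _warn_unknown(
        out, beam, "/beam",
        {
            "photon_energy_keV", "pulse_energy_mJ", "optics_transmission",
            "attenuation", "spatial", "temporal",
        },
    )
    _check_number(out, beam, "/beam", "photon_energy_keV", lo=0, lo_open=True)
    _check_number(out, beam, "/beam", "pulse_energy_mJ", lo=0, lo_open=True)
    _check_number(out, beam, "/beam", "optics_transmission", lo=0, hi=1, lo_open=True)
    _check_number(out, beam, "/beam", "attenuation", lo=0, hi=1, lo_open=True)

    spatial = beam.get("spatial", {})
    if spatial:
        kind = spatial.get("kind")
        if kind not in ("point", "uniform", "gaussian", "double_gaussian"):
            out.append(Diagnostic("/beam/spatial/kind", f"unknown kind {kind!r}"))
        components = spatial.get("components", [])
        total = 0.0
        for i, comp in enumerate(components):
            _check_number(
                out, comp, f"/beam/spatial/components/{i}", "photon_fraction",
                lo=0, hi=1, lo_open=True, required=True,
            )
            _check_number(
                out, comp, f"/beam/spatial/components/{i}", "fwhm_um",
                lo=0, lo_open=True, required=True,
            )
            frac = comp.get("photon_fraction")
            if isinstance(frac, (int, float)):
                total += frac
        if components and abs(total - 1.0) > 1e-6:
            out.append(
                Diagnostic("/beam/spatial/components", "photon fractions must sum to 1")
            )
    temporal = beam.get("temporal", {})
    if temporal:
        if temporal.get("kind", "flat_top") != "flat_top":
            out.append(
                Diagnostic("/beam/temporal/kind", "only flat_top is supported")
            )
        _check_number(out, temporal, "/beam/temporal", "duration_fs", lo=0, lo_open=True)
        _check_number(out, temporal, "/beam/temporal", "gate_fs", lo=0, lo_open=True)
        dur, gate = temporal.get("duration_fs"), temporal.get("gate_fs")
        if (
            isinstance(dur, (int, float))
            and isinstance(gate, (int, float))
            and gate > dur
        ):
            out.append(
                Diagnostic("/beam/temporal/gate_fs", "gate exceeds pulse duration")
            )

    sim = config.get("simulation", {})
    if not isinstance(sim, dict):
        out.append(Diagnostic("/simulation", "must be a mapping"))
        sim = {}
    _warn_unknown(
        out, sim, "/simulation", {"mode", "dt_fs", "n_nodes", "n_monte_carlo"}
    )
    if sim.get("mode", "point") not in ("point", "spatial"):
        out.append(Diagnostic("/simulation/mode", "must be 'point' or 'spatial'"))
    _check_number(out, sim, "/simulation", "dt_fs", lo=0, lo_open=True)
    _check_number(out, sim, "/simulation", "n_nodes", lo=2)
    _check_number(out, sim, "/simulation", "n_monte_carlo", lo=100)
    return out


def _require_valid(config: dict) -> None:
    errors = [d for d in validate_config(config) if d.severity == "error"]
    if errors:
        raise ConfigError("; ".join(str(d) for d in errors))


def atom_from_config(config: dict) -> AtomModel:
    """Build the AtomModel from the ``atom`` block (defaults applied)."""
    _require_valid(config)
    atom = config.get("atom", {})
    cascade = atom.get("cascade") or {}
    sizes = None
    if cascade:
        sizes = tuple(range(int(cascade["min"]), int(cascade["max"]) + 1))
    return load_atom_model(
        atom.get("table"),
        atom.get("element", "Gd"),
        atom.get("photon_energy_keV", defaults.PHOTON_ENERGY_KEV),
        q_floor=atom.get("q_floor"),
        ladder_exponent=atom.get("ladder_exponent"),
        cascade_sizes=sizes,
    )


def beam_from_config(config: dict) -> BeamModel:
    """Build the BeamModel from the ``beam`` block (defaults applied)."""
    _require_valid(config)
    beam = config.get("beam", {})
    spatial_cfg = beam.get("spatial") or {
        "kind": "gaussian",
        "components": [{"photon_fraction": 1.0, "fwhm_um": defaults.FOCUS_FWHM_UM}],
    }
    if spatial_cfg["kind"] in ("gaussian", "double_gaussian"):
        spatial = SpatialProfile(
            spatial_cfg["kind"],
            tuple(
                GaussianComponent(c["photon_fraction"], c["fwhm_um"])
                for c in spatial_cfg["components"]
            ),
        )
    else:
        spatial = SpatialProfile(
            spatial_cfg["kind"], fluence_scale=spatial_cfg.get("fluence_scale")
        )
    temporal_cfg = beam.get("temporal") or {}
    temporal = TemporalProfile(
        duration_fs=temporal_cfg.get("duration_fs", defaults.PULSE_DURATION_FS),
        gate_fs=temporal_cfg.get("gate_fs"),
    )
    try:
        return BeamModel(
            photon_energy_keV=beam.get("photon_energy_keV", defaults.PHOTON_ENERGY_KEV),
            pulse_energy_mJ=beam.get("pulse_energy_mJ", defaults.PULSE_ENERGY_MJ),
            optics_transmission=beam.get(
                "optics_transmission", defaults.OPTICS_TRANSMISSION
            ),
            attenuation=beam.get("attenuation", 1.0),
            spatial=spatial,
            temporal=temporal,
        )
    except HiphaseError as exc:
        raise ConfigError(f"/beam: {exc}") from exc


def simulation_from_config(config: dict) -> dict:
    """Numerics block with defaults filled in."""
    _require_valid(config)
    sim = config.get("simulation", {})
    return {
        "mode": sim.get("mode", "point"),
        "dt_fs": sim.get("dt_fs", defaults.DT_FS),
        "n_nodes": int(sim.get("n_nodes", defaults.N_QUADRATURE_NODES)),
        "n_monte_carlo": int(sim.get("n_monte_carlo", 10_000)),
    }
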