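"""Dynamical form factors and pulse-weighted effective scattering strengths.

The dynamical form factor is the population-weighted atomic scattering
factor f(t) = sum_q P_q(t) [f0_q(Q) + f'_q + i f''_q].  The effective
scattering strength averages its real part over the temporal pulse shape
and, in ``spatial`` mode, over the photon-weighted focal fluence
distribution; an optional gate restricts the time window to [0, gate]
(Bragg termination), renormalizing the temporal weight identically in
numerator and denominator.

The fluctuation measure (``scattering_strength_std``) is the standard
deviation of the *instantaneous* forward scattering strength under the same
joint weighting measure (fluence nodes x temporal weight x Monte Carlo
realizations) whose mean is the effective scattering strength, so the two
operations are consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hiphase import defaults
from hiphase.atomdata import AtomModel, ScatteringQuery
from hiphase.beam import (
    BeamModel,
    fluence_quadrature,
    peak_fluence,
    photons_per_pulse,
)
from hiphase.errors import ComparisonError, DomainError
from hiphase.iondyn import (
    ChargeStateTrajectory,
    evolve_populations,
    simulate_monte_carlo,
)

__all__ = [
    "DynamicalFormFactor",
    "EffectiveScatteringResult",
    "dynamical_form_factor",
    "effective_scattering_strength",
    "scattering_strength_std",
    "ionization_contrast",
    "gated_contrast",
]


@dataclass(frozen=True)
class DynamicalFormFactor:
    """Complex time-dependent form factor on the trajectory's time grid."""

    times: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class EffectiveScatteringResult:
    """Pulse-weighted scattering strength with mode/gate provenance."""

    f_eff: float
    std: float | None
    mode: str
    gate_fs: float | None
    provenance: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()


def dynamical_form_factor(
    atom: AtomModel,
    traj: ChargeStateTrajectory,
    query: ScatteringQuery | None = None,
) -> DynamicalFormFactor:
    """Population-weighted form factor along a trajectory."""
    query = query or ScatteringQuery()
    coeffs = np.array(
        [atom.form_factor(q, query) for q in range(atom.Z + 1)], dtype=complex
    )
    return DynamicalFormFactor(
        times=traj.times, values=traj.populations @ coeffs
    )


def _resolve_gate(
    temporal_duration: float, gate: float | None
) -> tuple[float, tuple[str, ...]]:
    if gate is None:
        return temporal_duration, ()
    if gate <= 0:
        raise DomainError("gate must be > 0")
    if gate > temporal_duration:
        return temporal_duration, (
            f"gate {gate} fs exceeds pulse duration "
            f"{temporal_duration} fs; clipped",
        )
    return gate, ()


def _time_average(times: np.ndarray, values: np.ndarray, gate: float) -> float:
    """Flat-top-weighted time average of ``values`` over [0, gate]."""
    mask = times <= gate + 1e-12
    t = times[mask]
    v = values[mask]
    if t[-1] < gate:  # close the window at the exact gate time
        t = np.append(t, gate)
        v = np.append(v, np.interp(gate, times, values))
    return float(np.trapezoid(v, t) / gate)


def _node_fluences(
    atom: AtomModel, beam: BeamModel, mode: str, n_nodes: int
) -> tuple[np.ndarray, np.ndarray]:
    n_photons = photons_per_pulse(beam)
    if mode == "point":
        if beam.spatial.kind in ("point", "uniform"):
            f = beam.spatial.fluence_scale
        else:
            f = peak_fluence(n_photons, beam.spatial)
        return np.array([f]), np.array([1.0])
    if mode == "spatial":
        quad = fluence_quadrature(beam.spatial, n_photons, n_nodes)
        return quad.nodes, quad.weights
    raise DomainError(f"unknown mode {mode!r} (expected 'point' or 'spatial')")


def effective_scattering_strength(
    atom: AtomModel,
    beam: BeamModel,
    query: ScatteringQuery | None = None,
    mode: str = "point",
    gate: float | None = None,
    *,
    n_nodes: int = defaults.N_QUADRATURE_NODES,
    dt: float = defaults.DT_FS,
) -> EffectiveScatteringResult:
    """Deterministic (rate-equation) effective scattering strength.

    ``point`` mode evaluates at the focal peak fluence with temporal
    weighting only; ``spatial`` mode additionally averages over the
    photon-weighted fluence quadrature of the spatial profile.
    """
    query = query or ScatteringQuery(photon_energy_keV=beam.photon_energy_keV)
    gate_eff, warns = _resolve_gate(beam.temporal.duration_fs, gate)
    nodes, wts = _node_fluences(atom, beam, mode, n_nodes)
    node_means = np.empty(len(nodes))
    for i, fluence in enumerate(nodes):
        traj = evolve_populations(atom, fluence, beam.temporal, dt=dt)
        ff = dynamical_form_factor(atom, traj, query)
        node_means[i] = _time_average(ff.times, ff.values.real, gate_eff)
    f_eff = float(np.dot(wts, node_means))
    return EffectiveScatteringResult(
        f_eff=f_eff,
        std=None,
        mode=mode,
        gate_fs=gate if gate is None else gate_eff,
        provenance={
            "nodes": len(nodes),
            "dt_fs": dt,
            "element": atom.element,
            "route": "rate_equation",
        },
        warnings=warns,
    )


def scattering_strength_std(
    atom: AtomModel,
    beam: BeamModel,
    query: ScatteringQuery | None = None,
    mode: str = "point",
    gate: float | None = None,
    n: int = 10_000,
    seed: int = 0,
    *,
    n_nodes: int = defaults.N_QUADRATURE_NODES,
) -> EffectiveScatteringResult:
    """Monte Carlo fluctuation of the forward scattering strength.

    Samples realizations of the ionization process (fluence node drawn
    photon-weighted in ``spatial`` mode) and returns the standard deviation
    of the instantaneous scattering strength under the joint weighting
    measure, together with its mean (which estimates ``f_eff`` of the same
    mode/gate).
    """
    if n < 100:
        raise DomainError("n must be >= 100")
    query = query or ScatteringQuery(photon_energy_keV=beam.photon_energy_keV)
    gate_eff, warns = _resolve_gate(beam.temporal.duration_fs, gate)
    nodes, wts = _node_fluences(atom, beam, mode, n_nodes)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, wts)
    m1_parts, m2_parts = [], []
    for fluence, n_i in zip(nodes, counts):
        if n_i == 0:
            continue
        ens = simulate_monte_carlo(
            atom, fluence, beam.temporal, int(n_i), seed=int(rng.integers(2**63))
        )
        m1, m2 = ens.bound_electron_moments(gate_eff)
        m1_parts.append(m1)
        m2_parts.append(m2)
    m1 = np.concatenate(m1_parts)
    m2 = np.concatenate(m2_parts)
    mean = float(m1.mean())
    var = max(float(m2.mean()) - mean**2, 0.0)
    std = var**0.5
    warns = list(warns)
    if std > 0 and std / (2.0 * n) ** 0.5 > 0.05 * std:
        warns.append(
            f"n = {n} gives a relative precision on the std worse than 5%"
        )
    return EffectiveScatteringResult(
        f_eff=mean,
        std=std,
        mode=mode,
        gate_fs=gate if gate is None else gate_eff,
        provenance={
            "nodes": len(nodes),
            "n": n,
            "seed": seed,
            "element": atom.element,
            "route": "monte_carlo",
        },
        warnings=tuple(warns),
    )


def ionization_contrast(
    lf: EffectiveScatteringResult, hf: EffectiveScatteringResult
) -> float:
    """Difference in effective scattering strength between two conditions."""
    if lf.mode != hf.mode:
        raise ComparisonError(
            f"cannot compare results of mode {lf.mode!r} and {hf.mode!r}"
        )
    return lf.f_eff - hf.f_eff


def gated_contrast(
    atom: AtomModel,
    beam_lf: BeamModel,
    beam_hf: BeamModel,
    gate_hf: float,
    mode: str = "point",
    *,
    n_nodes: int = defaults.N_QUADRATURE_NODES,
    dt: float = defaults.DT_FS,
) -> float:
    """Contrast with Bragg termination applied to the high-fluence side only.

    The low-fluence signal is not terminated during the exposure, so its
    average runs over the whole pulse; the high-fluence average is gated at
    ``gate_hf``.
    """
    lf = effective_scattering_strength(
        atom, beam_lf, mode=mode, gate=None, n_nodes=n_nodes, dt=dt
    )
    hf = effective_scattering_strength(
        atom, beam_hf, mode=mode, gate=gate_hf, n_nodes=n_nodes, dt=dt
    )
    return ionization_contrast(lf, hf)
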