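"""Shipped atomic data and the reduced heavy-atom ionization model.

The full configuration-resolved ionization dynamics of a heavy atom is
replaced by a charge-state ladder q = 0..Z: the total photoabsorption cross
section declines as a power law of the charge and vanishes at ``q_floor``
(the charge at which the remaining binding energies exceed the photon
energy), and each photoabsorption ejects the photoelectron plus a burst of
cascade electrons drawn from a discrete distribution.  The ladder constants
for Gd at 8.48 keV are frozen in :mod:`hiphase.defaults`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from hiphase import defaults
from hiphase.errors import DomainError, TableLookupError, TableParseError

__all__ = [
    "Subshell",
    "AtomModel",
    "ScatteringQuery",
    "builtin_table_path",
    "load_atom_model",
    "photoelectron_energy",
    "cross_section",
    "saturation_fluence",
]

#: Accepted aliases for subshell labels (spectroscopic shorthand).
_LABEL_ALIASES = {
    "K": "1s",
    "LI": "2s",
    "LII": "2p1/2",
    "LIII": "2p3/2",
    "L1": "2s",
    "L2": "2p1/2",
    "L3": "2p3/2",
}


@dataclass(frozen=True)
class Subshell:
    """One atomic subshell: label, electron occupancy, binding energy."""

    label: str
    occupancy: int
    binding_energy_keV: float

    def __post_init__(self) -> None:
        if self.occupancy < 0:
            raise DomainError(f"subshell {self.label}: occupancy must be >= 0")
        if self.binding_energy_keV <= 0:
            raise DomainError(
                f"subshell {self.label}: binding energy must be > 0"
            )


@dataclass(frozen=True)
class ScatteringQuery:
    """Momentum transfer magnitude (1/A, 0 = forward) and photon energy."""

    Q: float = 0.0
    photon_energy_keV: float = defaults.PHOTON_ENERGY_KEV

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise DomainError("momentum transfer Q must be >= 0")
        if self.photon_energy_keV <= 0:
            raise DomainError("photon energy must be > 0")


@dataclass(frozen=True)
class AtomModel:
    """Element data plus the reduced charge-ladder parameters.

    ``cascade_sizes``/``cascade_probs`` give the distribution of extra
    electrons ejected per photoabsorption (the photoelectron itself is not
    counted).  ``scattering_table`` optionally maps charge state q to
    ``(f0, fprime, fdouble)``; when absent the forward defaults
    ``f0_q = Z - q``, ``f' = f'' = 0`` apply.
    """

    element: str
    Z: int
    subshells: tuple[Subshell, ...]
    sigma_total_barn: float
    reference_energy_keV: float
    q_floor: int
    ladder_exponent: float = defaults.LADDER_EXPONENT
    cascade_sizes: tuple[int, ...] = tuple(
        range(defaults.CASCADE_MIN, defaults.CASCADE_MAX + 1)
    )
    cascade_probs: tuple[float, ...] = field(default=())
    scattering_table: dict[int, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if not self.cascade_probs:
            n = len(self.cascade_sizes)
            object.__setattr__(self, "cascade_probs", tuple([1.0 / n] * n))
        occ = sum(s.occupancy for s in self.subshells)
        if occ != self.Z:
            raise DomainError(
                f"{self.element}: subshell occupancies sum to {occ}, "
                f"expected Z = {self.Z}"
            )
        if self.sigma_total_barn <= 0:
            raise DomainError("sigma_total must be > 0")
        if not 0 <= self.q_floor <= self.Z:
            raise DomainError("q_floor must lie in [0, Z]")
        probs = np.asarray(self.cascade_probs, dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise DomainError("cascade pmf must be nonnegative and sum to 1")
        if len(self.cascade_sizes) != len(self.cascade_probs):
            raise DomainError("cascade sizes/probs length mismatch")
        if any(a < 0 for a in self.cascade_sizes):
            # bursts larger than the remaining electrons are legal in the
            # pmf; the charge cap truncates them during stepping
            raise DomainError("cascade sizes must be >= 0")

    # -- derived quantities ---------------------------------------------------
    @property
    def cascade_mean(self) -> float:
        return float(
            np.dot(self.cascade_sizes, self.cascade_probs)
        )

    @property
    def max_cascade(self) -> int:
        return max(self.cascade_sizes)

    @property
    def charge_cap(self) -> int:
        """Hard cap on the charge: min(Z, q_floor + largest cascade burst)."""
        return min(self.Z, self.q_floor + self.max_cascade)

    def subshell(self, label: str) -> Subshell:
        canon = _LABEL_ALIASES.get(label.upper(), label)
        for s in self.subshells:
            if s.label.lower() == canon.lower():
                return s
        raise TableLookupError(
            f"unknown subshell {label!r} for element {self.element}"
        )

    def form_factor(self, q: int, query: ScatteringQuery) -> complex:
        """Per-charge-state form factor f0_q(Q) + f'_q + i f''_q.

        Defaults to the bound-electron count Z - q with zero dispersion
        corrections.
        """
        if not 0 <= q <= self.Z:
            raise DomainError(f"charge state {q} outside [0, {self.Z}]")
        if self.scattering_table is not None:
            if q not in self.scattering_table:
                raise TableLookupError(
                    f"scattering table has no coefficients for charge {q}"
                )
            f0, fp, fpp = self.scattering_table[q]
            return complex(f0 + fp, fpp)
        return complex(self.Z - q)


def builtin_table_path() -> Path:
    """Path of the shipped atomic-data CSV."""
    return Path(str(resources.files("hiphase").joinpath("data/atomic_shells.csv")))


def _parse_table(table_path: str | Path) -> dict[str, dict]:
    """Parse the atomic CSV into per-element subshell and sigma records."""
    out: dict[str, dict] = {}
    with open(table_path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows or [c.strip() for c in rows[0][:2]] != ["element", "subshell"]:
        raise TableParseError(f"{table_path}: missing or wrong header row")
    for i, row in enumerate(rows[1:], start=2):
        try:
            element = row[0].strip()
            if not element:
                raise ValueError("empty element field")
            rec = out.setdefault(element, {"subshells": [], "sigma": None})
            if row[1].strip():  # subshell row
                rec["subshells"].append(
                    Subshell(row[1].strip(), int(row[2]), float(row[3]))
                )
            else:  # cross-section row
                rec["sigma"] = (float(row[4]), float(row[5]))
        except (IndexError, ValueError, DomainError) as exc:
            raise TableParseError(
                f"{table_path}: malformed row {i}: {exc}"
            ) from exc
    return out


def load_atom_model(
    table_path: str | Path | None,
    element: str,
    photon_energy_keV: float,
    *,
    q_floor: int | None = None,
    ladder_exponent: float | None = None,
    cascade_sizes: tuple[int, ...] | None = None,
    cascade_probs: tuple[float, ...] | None = None,
) -> AtomModel:
    """Load an element from a CSV table and apply the frozen defaults.

    ``table_path=None`` selects the shipped table.  The reference cross
    section stored in the table must match the requested photon energy to
    within 1%; the ladder is only valid at its calibration energy.
    """
    path = Path(table_path) if table_path is not None else builtin_table_path()
    if not path.exists():
        raise TableParseError(f"atomic data table not found: {path}")
    records = _parse_table(path)
    if element not in records:
        raise TableLookupError(f"element {element!r} not in table {path}")
    rec = records[element]
    if rec["sigma"] is None:
        raise TableParseError(f"{path}: no cross-section row for {element}")
    sigma, ref_energy = rec["sigma"]
    if abs(ref_energy - photon_energy_keV) > 0.01 * ref_energy:
        raise DomainError(
            f"table reference energy {ref_energy} keV does not match "
            f"requested photon energy {photon_energy_keV} keV"
        )
    subshells = tuple(rec["subshells"])
    Z = sum(s.occupancy for s in subshells)
    if q_floor is None:
        q_floor = defaults.Q_FLOOR_GD if element == "Gd" else Z
    kwargs = {}
    if cascade_sizes is not None:
        kwargs["cascade_sizes"] = tuple(cascade_sizes)
    if cascade_probs is not None:
        kwargs["cascade_probs"] = tuple(cascade_probs)
    return AtomModel(
        element=element,
        Z=Z,
        subshells=subshells,
        sigma_total_barn=sigma,
        reference_energy_keV=ref_energy,
        q_floor=q_floor,
        ladder_exponent=(
            defaults.LADDER_EXPONENT if ladder_exponent is None else ladder_exponent
        ),
        **kwargs,
    )


def photoelectron_energy(
    atom: AtomModel, subshell: str, photon_energy_keV: float
) -> float | None:
    """Kinetic energy of a photoelectron from ``subshell``, or None.

    Returns ``photon_energy - binding`` when positive; ``None`` when the
    subshell is inaccessible at this photon energy.
    """
    s = atom.subshell(subshell)
    e = photon_energy_keV - s.binding_energy_keV
    return e if e > 0 else None


def cross_section(atom: AtomModel, q: int) -> float:
    """Total photoabsorption cross section (barn) of charge state q.

    Power-law ladder: ``sigma_total * max(0, 1 - q/q_floor)**exponent``,
    exactly zero at and beyond ``q_floor``.
    """
    if not 0 <= q <= atom.Z:
        raise DomainError(f"charge state {q} outside [0, {atom.Z}]")
    if atom.q_floor == 0 or q >= atom.q_floor:
        return 0.0
    return atom.sigma_total_barn * (1.0 - q / atom.q_floor) ** atom.ladder_exponent


def saturation_fluence(atom: AtomModel) -> float:
    """Fluence (photons/um^2) at which each atom absorbs one photon on average.

    Reciprocal of the neutral-atom cross section, converted from barn.
    """
    if atom.sigma_total_barn <= 0:
        raise DomainError("sigma_total must be > 0")
    return 1.0 / (atom.sigma_total_barn * defaults.BARN_TO_UM2)
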