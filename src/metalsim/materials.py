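"""Material attenuation tables.

Each material is described by a tabulated mass attenuation coefficient
mu/rho (cm^2/g) on a standard reference energy grid plus a bulk density
(g/cm^3).  Lookups between tabulated nodes use log-log interpolation,
which is the conventional scheme for photon cross sections away from
absorption edges (no k-edges fall inside the packaged 10-150 keV range).
Extrapolation outside the tabulated range is refused.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "MaterialTable",
    "load_material",
    "available_materials",
    "material_mu_over_rho",
]


@dataclass(frozen=True)
class MaterialTable:
    """Energy -> mass attenuation coefficient table for one material."""

    name: str
    energies_keV: np.ndarray
    mu_over_rho_cm2_g: np.ndarray
    density_g_cm3: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        e = np.asarray(self.energies_keV, dtype=float)
        m = np.asarray(self.mu_over_rho_cm2_g, dtype=float)
        if e.ndim != 1 or e.size < 2 or m.shape != e.shape:
            raise ValueError("material table needs matching 1-D energy and mu/rho arrays")
        if not np.all(np.diff(e) > 0):
            raise ValueError("material table energies must be strictly increasing")
        if np.any(m <= 0):
            raise ValueError("mu/rho must be positive")
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "mu_over_rho_cm2_g", m)

    def mu_over_rho(self, energy_keV):
        """Log-log interpolated mu/rho (cm^2/g) at ``energy_keV``.

        Raises ``ValueError`` for energies outside the tabulated range:
        cross sections are not extrapolated.
        """
        e = np.asarray(energy_keV, dtype=float)
        lo, hi = self.energies_keV[0], self.energies_keV[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy out of range for {self.name!r}: requested "
                f"[{e.min():g}, {e.max():g}] keV, table covers [{lo:g}, {hi:g}] keV"
            )
        out = np.exp(
            np.interp(np.log(e), np.log(self.energies_keV), np.log(self.mu_over_rho_cm2_g))
        )
        return float(out) if np.isscalar(energy_keV) else out

    def mu(self, energy_keV):
        """Linear attenuation coefficient (1/cm) at ``energy_keV``."""
        return self.mu_over_rho(energy_keV) * self.density_g_cm3


def available_materials() -> list[str]:
    """Names of the materials packaged with the library."""
    pkg = resources.files("metalsim.data")
    return sorted(p.name[:-4] for p in pkg.iterdir() if p.name.endswith(".csv"))


def load_material(name: str) -> MaterialTable:
    """Load a packaged material table by name (e.g. ``"water"``, ``"titanium"``)."""
    pkg = resources.files("metalsim.data")
    csv_path = pkg / f"{name}.csv"
    json_path = pkg / f"{name}.json"
    try:
        text = csv_path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown material {name!r}; available: {', '.join(available_materials())}"
        ) from None
    rows = list(csv.DictReader(text.splitlines()))
    energies = np.array([float(r["energy_keV"]) for r in rows])
    mu_rho = np.array([float(r["mu_over_rho_cm2_g"]) for r in rows])
    meta = json.loads(json_path.read_text())
    return MaterialTable(
        name=name,
        energies_keV=energies,
        mu_over_rho_cm2_g=mu_rho,
        density_g_cm3=float(meta["density_g_cm3"]),
        meta=meta,
    )


def material_mu_over_rho(material, energy_keV):
    """Convenience lookup: mu/rho for a material name or :class:`MaterialTable`."""
    if isinstance(material, str):
        material = load_material(material)
    return material.mu_over_rho(energy_keV)
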