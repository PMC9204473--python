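"""Polychromatic x-ray spectra.

A :class:`Spectrum` is a discrete photon-fluence distribution w(E) on a
1-keV energy grid together with a detector weighting d(E).  The default
tube model is a Kramers-law bremsstrahlung continuum filtered by a
configurable thickness of aluminum; the default detector model is an
ideal energy-integrating detector, d(E) = E.  Vendor spectra and
detector responses are proprietary, so the generator is a stand-in of
the right qualitative shape; any externally measured spectrum can be
supplied as a two-column CSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .materials import load_material

__all__ = ["Spectrum", "generate_spectrum"]

ENERGY_STEP_KEV = 1.0
MIN_ENERGY_KEV = 10.0


@dataclass(frozen=True)
class Spectrum:
    """Discrete x-ray spectrum with detector weighting.

    ``fluence`` is the relative photon fluence per energy bin (>= 0, zero
    above the tube potential); ``detector_weight`` is the relative
    detector response d(E).  Effective quantities are always computed
    with the normalized product w(E) d(E).
    """

    energies_keV: np.ndarray
    fluence: np.ndarray
    kvp: float
    detector_weight: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        e = np.asarray(self.energies_keV, dtype=float)
        w = np.asarray(self.fluence, dtype=float)
        if e.ndim != 1 or w.shape != e.shape:
            raise ValueError("energies and fluence must be matching 1-D arrays")
        if e.size > 1 and not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("fluence weights must be nonnegative")
        if np.any(w[e > self.kvp] > 0):
            raise ValueError("fluence must vanish above the tube potential")
        d = self.detector_weight
        d = np.ones_like(w) if d is None else np.asarray(d, dtype=float)
        if d.shape != e.shape or np.any(d < 0):
            raise ValueError("detector weighting must be nonnegative and match the grid")
        if not np.any(w * d > 0):
            raise ValueError("spectrum has zero total weight")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "fluence", w)
        object.__setattr__(self, "detector_weight", d)

    # -- derived quantities -------------------------------------------------

    @property
    def weights(self) -> np.ndarray:
        """Normalized fluence x detector weight distribution."""
        wd = self.fluence * self.detector_weight
        return wd / wd.sum()

    def mean_energy(self) -> float:
        """Weighted mean energy (keV) of the detected spectrum."""
        return float(np.sum(self.weights * self.energies_keV))

    def normalized(self) -> "Spectrum":
        """Same spectrum with the fluence rescaled to unit sum."""
        return replace(self, fluence=self.fluence / self.fluence.sum())

    # -- constructors -------------------------------------------------------

    @classmethod
    def monochromatic(cls, energy_keV: float, kvp: float | None = None) -> "Spectrum":
        """Single-line spectrum, mostly used for tests and sanity checks."""
        return cls(
            energies_keV=np.array([float(energy_keV)]),
            fluence=np.array([1.0]),
            kvp=float(kvp if kvp is not None else energy_keV),
        )

    @classmethod
    def from_csv(cls, path, kvp: float | None = None) -> "Spectrum":
        """Read a two-column CSV ``energy_keV,relative_fluence``."""
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        e, w = arr[:, 0], arr[:, 1]
        return cls(energies_keV=e, fluence=w, kvp=float(kvp if kvp is not None else e.max()))

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.energies_keV, self.fluence]),
            delimiter=",",
            header="energy_keV,relative_fluence",
            comments="",
        )


def generate_spectrum(
    kvp: float,
    filtration_mm_al: float = 9.0,
    energy_step_keV: float = ENERGY_STEP_KEV,
    detector: str = "energy_integrating",
) -> Spectrum:
    """Filtered-Kramers bremsstrahlung spectrum.

    The photon fluence follows Kramers' law, w(E) ~ (kVp - E)/E, on a
    regular grid from 10 keV to the tube potential, attenuated by
    ``filtration_mm_al`` of aluminum (total equivalent filtration,
    inherent plus added).  The default 9 mm Al approximates the heavy
    total filtration of a clinical CT tube assembly.

    Parameters
    ----------
    kvp : tube potential in kV, accepted range 40-150.
    filtration_mm_al : aluminum-equivalent filtration thickness (mm).
    detector : ``"energy_integrating"`` (d(E) = E) or ``"photon_counting"``
        (d(E) = 1).
    """
    if kvp <= 0:
        raise ValueError("tube potential must be positive")
    if not (40.0 <= kvp <= 150.0):
        raise ValueError(f"tube potential {kvp} kV outside supported range [40, 150]")
    if filtration_mm_al < 0:
        raise ValueError("filtration must be nonnegative")
    e = np.arange(MIN_ENERGY_KEV, kvp + 0.5 * energy_step_keV, energy_step_keV)
    e = e[e <= kvp]
    w = (kvp - e) / e
    al = load_material("aluminum")
    w = w * np.exp(-al.mu(e) * filtration_mm_al / 10.0)
    w = w / w.sum()
    if detector == "energy_integrating":
        d = e.copy()
    elif detector == "photon_counting":
        d = np.ones_like(e)
    else:
        raise ValueError(f"unknown detector model {detector!r}")
    return Spectrum(
        energies_keV=e,
        fluence=w,
        kvp=float(kvp),
        detector_weight=d,
        meta={
            "model": "filtered_kramers",
            "filtration_mm_al": float(filtration_mm_al),
            "detector": detector,
        },
    )
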