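"""Acquisition defaults shared across the package.

The defaults emulate a routine single-energy abdominal acquisition:
120 kV tube potential with heavy (~9 mm Al equivalent) total
filtration, an energy-integrating detector, and an incident fluence of
1000 photons per detector element per view per effective mAs, so the
routine 200 eff. mAs corresponds to N0 = 2e5 and a low-dose 20 eff. mAs
scan to N0 = 2e4.  The electronic noise floor defaults to 20
noise-equivalent quanta, a typical magnitude for a modern solid-state
CT detector.
"""

from __future__ import annotations

from functools import lru_cache

from .spectrum import Spectrum, generate_spectrum

DEFAULT_KVP = 120.0
DEFAULT_FILTRATION_MM_AL = 9.0
N0_PER_EFF_MAS = 1000.0
DEFAULT_EFF_MAS = 200.0
DEFAULT_NE = 20.0
REFERENCE_METAL = "titanium"


@lru_cache(maxsize=8)
def default_spectrum(kvp: float = DEFAULT_KVP,
                     filtration_mm_al: float = DEFAULT_FILTRATION_MM_AL) -> Spectrum:
    """The package-wide reference spectrum (filtered Kramers, d(E) = E)."""
    return generate_spectrum(kvp, filtration_mm_al)


def n0_for_eff_mas(eff_mas: float = DEFAULT_EFF_MAS) -> float:
    """Incident photons per detector element per view for a tube load."""
    if eff_mas <= 0:
        raise ValueError("effective mAs must be positive")
    return N0_PER_EFF_MAS * eff_mas
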