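"""Named presets: crystals, beam spectra and the large flat detector.

The thaumatin cell and the two 6 keV spectra mirror a SASE-vs-pink-beam XFEL
comparison; the 5-HT2B receptor cell with a 4.5 keV top-hat spectrum is the
large-unit-cell spot-overlap scenario.
"""

from __future__ import annotations

from .beam import CrystalProfile, Spectrum
from .geometry import DetectorGeometry, SymmetrySpec, UnitCell, wavelength_from_energy

#: Thaumatin, tetragonal P41212.
THAUMATIN_CELL = UnitCell(58.52, 58.52, 151.30)
THAUMATIN_SYMMETRY = "P41212"

#: 5-HT2B serotonin receptor cell (orthorhombic lengths; treated as P1 for
#: the purely geometric overlap analysis).
RECEPTOR_5HT2B_CELL = UnitCell(61.5, 122.2, 168.5)

#: JUNGFRAU-16M-like flat square panel: 373.65 mm side, 75 um pixels, ~95 mm
#: from the interaction point.
JUNGFRAU_16M = DetectorGeometry(distance=95.0, side_length=373.65, pixel_size=0.075)

SPECTRA = {
    # narrow SASE lasing mode, 5.99 keV, 0.17% FWHM Gaussian
    "sase-6keV": Spectrum(wavelength_from_energy(5.99), 0.0017, "gaussian"),
    # chirped large-bandwidth mode, 6.02 keV, 2.2% FWHM Gaussian
    "pink-6keV": Spectrum(wavelength_from_energy(6.02), 0.022, "gaussian"),
    # top-hat spectra for the overlap study at 4.5 keV
    "tophat-4.5keV-3.5": Spectrum(wavelength_from_energy(4.5), 0.035, "tophat"),
    "tophat-4.5keV-3.0": Spectrum(wavelength_from_energy(4.5), 0.030, "tophat"),
}

#: Default reciprocal-point model for the merging studies: well-ordered
#: microcrystals, negligible mosaic spread, and the fixed prediction profile
#: radius of the study's processing (1e5 m^-1 = 1e-5 A^-1).
DEFAULT_PROFILE = CrystalProfile(mosaicity_fwhm=0.0, profile_radius=1e-5)


def spectrum(name: str) -> Spectrum:
    try:
        return SPECTRA[name]
    except KeyError:
        raise KeyError(
            f"unknown spectrum preset {name!r}; options: {sorted(SPECTRA)}"
        ) from None


def thaumatin_symmetry() -> SymmetrySpec:
    return SymmetrySpec.from_symbol(THAUMATIN_SYMMETRY)
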