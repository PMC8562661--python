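"""Flat key-value run configuration with a stable fingerprint.

Every published artefact carries the fingerprint of the configuration that
produced it, so any result can be regenerated bit-identically from
(config, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields

from . import presets
from .beam import CrystalProfile, Spectrum
from .errors import InvalidInputError
from .geometry import DetectorGeometry, SymmetrySpec, UnitCell
from .simulate import SimConfig


@dataclass
class RunConfig:
    """Full experiment description; defaults are the thaumatin comparison."""

    # beam
    energy_kev: float = 6.02
    bandwidth_fwhm: float = 0.022
    spectrum_shape: str = "gaussian"
    n_spectrum_samples: int = 50
    # crystal
    cell_a: float = presets.THAUMATIN_CELL.a
    cell_b: float = presets.THAUMATIN_CELL.b
    cell_c: float = presets.THAUMATIN_CELL.c
    cell_alpha: float = 90.0
    cell_beta: float = 90.0
    cell_gamma: float = 90.0
    space_group: str = "P41212"
    mosaicity_deg: float = 0.0
    profile_radius_invA: float = presets.DEFAULT_PROFILE.profile_radius
    # detector
    distance_mm: float = 95.0
    detector_side_mm: float = 373.65
    pixel_mm: float = 0.075
    beam_center_mm: float = -1.0  # -1: panel centre
    # truth
    d_min: float = 2.5
    wilson_b: float = 20.0
    target_bijvoet_ratio: float = 0.02
    # simulation
    n_patterns: int = 100
    fluence_scale: float = 2.0
    background_counts: float = 10.0
    scale_jitter_sd: float = 0.3
    # analysis
    n_shells: int = 10
    cc_ano_threshold: float = 0.3
    cc_ano_d_min: float = 3.0
    seed: int = 0

    def cell(self) -> UnitCell:
        return UnitCell(
            self.cell_a, self.cell_b, self.cell_c,
            self.cell_alpha, self.cell_beta, self.cell_gamma,
        )

    def symmetry(self) -> SymmetrySpec:
        return SymmetrySpec.from_symbol(self.space_group)

    def spectrum(self) -> Spectrum:
        from .geometry import wavelength_from_energy

        return Spectrum(
            wavelength_from_energy(self.energy_kev),
            self.bandwidth_fwhm,
            self.spectrum_shape,
            self.n_spectrum_samples,
        )

    def profile(self) -> CrystalProfile:
        return CrystalProfile(self.mosaicity_deg, self.profile_radius_invA)

    def detector(self) -> DetectorGeometry:
        bc = None
        if self.beam_center_mm >= 0:
            bc = (self.beam_center_mm, self.beam_center_mm)
        return DetectorGeometry(
            self.distance_mm, self.detector_side_mm, self.pixel_mm, bc
        )

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_patterns=self.n_patterns,
            fluence_scale=self.fluence_scale,
            background_counts=self.background_counts,
            scale_jitter_sd=self.scale_jitter_sd,
            seed=self.seed,
        )

    def fingerprint(self) -> str:
        """Stable short hash of the canonicalised configuration."""
        canon = "\n".join(f"{k}={v!r}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# pinksfx run configuration\n")
            for k, v in asdict(self).items():
                fh.write(f"{k} = {v}\n")


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file; unknown keys are rejected."""
    types = {f.name: f.type for f in fields(RunConfig)}
    kwargs = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InvalidInputError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise InvalidInputError(f"{path}:{lineno}: unknown key {key!r}")
            typ = types[key]
            try:
                if typ == "int":
                    kwargs[key] = int(val)
                elif typ == "float":
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: {exc}") from None
    return RunConfig(**kwargs)
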