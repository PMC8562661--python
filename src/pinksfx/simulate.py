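"""Reflection-level simulation of serial still-diffraction datasets.

Each pattern is one crystal in a random orientation hit by one polychromatic
pulse: every reflection whose reciprocal point intersects the Ewald shell
receives expected photon counts proportional to |F|^2 times its spectral
weight, modulated by a per-pattern crystal scale, and is read out with
Poisson noise over a flat background. No pixel images are rendered; merging
statistics operate on these per-spot observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import beam, geometry
from .errors import InvalidInputError
from .truth import StructureFactorSet

#: peak-counting threshold for hit bookkeeping: net counts >= 5 sigma of the
#: background floor (a minimal signal-to-noise ratio of 5).
HIT_SNR = 5.0
HIT_MIN_PEAKS = 10


@dataclass(frozen=True)
class SimConfig:
    """Per-dataset simulation knobs.

    ``fluence_scale`` is the expected photon count of a unit-intensity,
    full-weight reflection; ``scale_jitter_sd`` the lognormal sigma of the
    per-pattern crystal scale (crystal-size spread).
    """

    n_patterns: int = 100
    fluence_scale: float = 2.0
    background_counts: float = 10.0
    scale_jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patterns < 1:
            raise InvalidInputError("n_patterns must be >= 1")
        if self.fluence_scale <= 0:
            raise InvalidInputError("fluence_scale must be > 0")
        if self.background_counts < 0:
            raise InvalidInputError("background_counts must be >= 0")


@dataclass
class Pattern:
    """One simulated still: orientation plus per-spot observations.

    ``intensity`` is background-subtracted (net) counts and may be negative;
    ``sigma`` = sqrt(gross + background + 1). ``lam`` is the diffracting
    wavelength of each spot.
    """

    index: int
    rotation: np.ndarray
    spectrum_id: str
    scale: float
    miller: np.ndarray  # (m, 3) raw indices in this orientation
    asu: np.ndarray  # (m, 3) canonical representatives
    friedel_minus: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    partiality: np.ndarray
    lam: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def n_spots(self) -> int:
        return len(self.intensity)

    def n_peaks(self, background_counts: float) -> int:
        """Spots exceeding the SNR-5 peak threshold over the background."""
        return int(np.sum(self.intensity >= HIT_SNR * np.sqrt(background_counts + 1.0)))


@dataclass
class Dataset:
    """A simulated serial dataset: patterns plus provenance."""

    patterns: list[Pattern]
    cell: geometry.UnitCell
    symmetry: str
    spectrum_id: str
    d_min: float
    config: SimConfig
    fingerprint: str = ""
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def summary(self) -> dict:
        bg = self.config.background_counts
        n_peaks = [p.n_peaks(bg) for p in self.patterns]
        return {
            "n_patterns": self.n_patterns,
            "mean_spots_per_pattern": float(np.mean([p.n_spots for p in self.patterns])),
            "mean_peaks_per_pattern": float(np.mean(n_peaks)),
            "hit_fraction": float(np.mean([n > HIT_MIN_PEAKS for n in n_peaks])),
            "hit_definition": f"more than {HIT_MIN_PEAKS} peaks at SNR >= {HIT_SNR:g}",
        }

    def observations(self) -> pd.DataFrame:
        """All observations as one table (cached)."""
        if self._frame is None:
            cols = {}
            cat = lambda xs: np.concatenate(xs) if xs else np.zeros(0)
            pats = self.patterns
            cols["pattern"] = cat([np.full(p.n_spots, p.index) for p in pats]).astype(int)
            for j, name in enumerate(("h", "k", "l")):
                cols[name] = cat([p.miller[:, j] for p in pats]).astype(int)
            for j, name in enumerate(("ah", "ak", "al")):
                cols[name] = cat([p.asu[:, j] for p in pats]).astype(int)
            cols["minus"] = cat([p.friedel_minus for p in pats]).astype(bool)
            for name in ("intensity", "sigma", "partiality", "lam", "x", "y"):
                cols[name] = cat([getattr(p, name) for p in pats])
            self._frame = pd.DataFrame(cols)
        return self._frame


def candidate_reflections(cell: geometry.UnitCell, d_min: float) -> np.ndarray:
    """All raw Miller triples inside the resolution sphere |B m| <= 1/d_min."""
    return geometry.reflections_in_sphere(cell, d_min)


class StillSimulator:
    """Precomputes reciprocal vectors and truth lookup, then emits patterns.

    Deterministic: pattern ``i`` depends only on (config.seed, i).
    """

    def __init__(
        self,
        sf: StructureFactorSet,
        cell: geometry.UnitCell,
        sym: geometry.SymmetrySpec,
        spectrum: beam.Spectrum,
        profile: beam.CrystalProfile,
        det: geometry.DetectorGeometry,
        config: SimConfig,
        spectrum_id: str = "custom",
        d_min: float | None = None,
    ) -> None:
        if sf.cell is not None and sf.cell != cell:
            raise InvalidInputError("structure-factor set generated for a different cell")
        if sf.symmetry and geometry._normalise_symbol(sf.symmetry) != sym.space_group_symbol:
            raise InvalidInputError("structure-factor set uses a different symmetry")
        self.sf = sf
        self.cell = cell
        self.sym = sym
        self.spectrum = spectrum
        self.profile = profile
        self.det = det
        self.config = config
        self.spectrum_id = spectrum_id
        self.d_min = float(d_min if d_min is not None else sf.d.min())

        m = candidate_reflections(cell, self.d_min)
        m = m[~geometry.is_absent(m, sym)]
        canonical, minus, _ = geometry._asu_arrays(m, sym)
        # match candidates against the truth set via lexicographic keys
        sf_keys = geometry._lex_key(sf.miller)
        order = np.argsort(sf_keys)
        cand_keys = geometry._lex_key(canonical)
        pos = np.searchsorted(sf_keys[order], cand_keys)
        pos = np.clip(pos, 0, len(sf_keys) - 1)
        found = sf_keys[order][pos] == cand_keys
        self.m = m[found]
        self.minus = minus[found]
        self.sf_index = order[pos[found]]
        B = geometry.reciprocal_basis(cell)
        self.q0 = self.m @ B.T
        f = np.where(self.minus, sf.f_minus[self.sf_index], sf.f_plus[self.sf_index])
        self.f2 = f * f
        self.asu = sf.miller[self.sf_index]

    def simulate_pattern(self, index: int) -> Pattern:
        cfg = self.config
        rot = geometry.random_orientation(cfg.seed, substream=index)
        rng = np.random.default_rng([cfg.seed, index, 1])
        scale = float(np.exp(rng.normal(0.0, cfg.scale_jitter_sd)))
        q_lab = self.q0 @ rot.T
        part, w = beam.partiality_and_weight(q_lab, self.spectrum, self.profile)
        sel = np.flatnonzero(w > 0)
        lo, hi = self.spectrum.support()
        lam_star = np.clip(beam.diffracting_wavelength(q_lab[sel]), lo, hi)
        s = lam_star[:, None] * q_lab[sel] + beam.S0
        s /= np.linalg.norm(s, axis=1, keepdims=True)
        xy = geometry._project_direction(s, self.det)
        xy = np.atleast_2d(xy)
        on = ~np.isnan(xy[:, 0])
        sel = sel[on]
        expected = scale * cfg.fluence_scale * self.f2[sel] * w[sel]
        gross = rng.poisson(expected + cfg.background_counts).astype(float)
        return Pattern(
            index=index,
            rotation=rot,
            spectrum_id=self.spectrum_id,
            scale=scale,
            miller=self.m[sel],
            asu=self.asu[sel],
            friedel_minus=self.minus[sel],
            intensity=gross - cfg.background_counts,
            sigma=np.sqrt(gross + cfg.background_counts + 1.0),
            partiality=part[sel],
            lam=lam_star[on],
            x=xy[on, 0],
            y=xy[on, 1],
        )

    def simulate_dataset(self, fingerprint: str = "") -> Dataset:
        patterns = [self.simulate_pattern(i) for i in range(self.config.n_patterns)]
        return Dataset(
            patterns=patterns,
            cell=self.cell,
            symmetry=self.sym.space_group_symbol,
            spectrum_id=self.spectrum_id,
            d_min=self.d_min,
            config=self.config,
            fingerprint=fingerprint,
        )
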