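"""Ground-truth structure factors with controlled anomalous signal.

Synthetic stand-in for a sulfur-SAD protein dataset: acentric intensities
follow the Wilson (exponential) distribution with a configurable B-factor
falloff, centric intensities the centric Wilson distribution, and Bijvoet
differences are zero-mean Gaussian scaled to a target Bijvoet ratio
<|dF|>/<F> (about 2% for thaumatin sulfur at 6 keV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .errors import InvalidInputError

#: arbitrary intensity scale: mean acentric intensity extrapolated to d = inf.
INTENSITY_SCALE = 1000.0


@dataclass(frozen=True)
class AnomalousModel:
    """Counting model for the expected Bijvoet ratio of a protein.

    Defaults describe thaumatin: 17 sulfur atoms (16 Cys + 1 Met) among 1558
    protein atoms, sulfur f'' ~ 0.9 e at 6 keV, effective normal-scatterer
    atomic number 6.7.
    """

    n_anomalous: int = 17
    n_total_atoms: int = 1558
    f_double_prime: float = 0.9
    z_eff: float = 6.7

    def __post_init__(self) -> None:
        if self.n_anomalous < 0 or self.n_total_atoms < 0:
            raise InvalidInputError("atom counts must be >= 0")
        if self.f_double_prime < 0 or self.z_eff <= 0:
            raise InvalidInputError("f'' must be >= 0 and z_eff > 0")


def bijvoet_ratio_estimate(model: AnomalousModel) -> float:
    """Hendrickson-style estimate <|dF|>/<F> = sqrt(2 Na/Nt) * f'' / z_eff."""
    if model.n_total_atoms <= 0:
        raise InvalidInputError("total atom count must be > 0")
    return (
        math.sqrt(2.0 * model.n_anomalous / model.n_total_atoms)
        * model.f_double_prime
        / model.z_eff
    )


@dataclass
class StructureFactorSet:
    """Per-unique-reflection true amplitudes |F+| and |F-| (arbitrary scale).

    Centric reflections carry identical mates. Arrays are parallel and sorted
    from low to high resolution.
    """

    miller: np.ndarray  # (n, 3) canonical ASU representatives
    d: np.ndarray
    centric: np.ndarray
    f_plus: np.ndarray
    f_minus: np.ndarray
    wilson_b: float
    seed: int
    cell: geometry.UnitCell | None = None
    symmetry: str = ""

    def __post_init__(self) -> None:
        if np.any(self.f_plus < 0) or np.any(self.f_minus < 0):
            raise InvalidInputError("amplitudes must be >= 0")
        if np.any(self.f_plus[self.centric] != self.f_minus[self.centric]):
            raise InvalidInputError("centric mates must be equal")

    def __len__(self) -> int:
        return len(self.d)

    @property
    def mean_f(self) -> np.ndarray:
        return 0.5 * (self.f_plus + self.f_minus)

    def intensity(self, minus: np.ndarray | bool) -> np.ndarray:
        f = np.where(np.asarray(minus), self.f_minus, self.f_plus)
        return f * f

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# h k l F_plus F_minus d\n")
            for (h, k, l), fp, fm, d in zip(
                self.miller, self.f_plus, self.f_minus, self.d
            ):
                fh.write(f"{h} {k} {l} {fp:.17g} {fm:.17g} {d:.17g}\n")


def read_structure_factors(path) -> StructureFactorSet:
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    miller = data[:, :3].astype(int)
    fp, fm, d = data[:, 3], data[:, 4], data[:, 5]
    return StructureFactorSet(
        miller=miller,
        d=d,
        centric=fp == fm,
        f_plus=fp,
        f_minus=fm,
        wilson_b=float("nan"),
        seed=-1,
    )


def generate_structure_factors(
    cell: geometry.UnitCell,
    sym: geometry.SymmetrySpec,
    d_min: float,
    wilson_b: float = 20.0,
    target_bijvoet_ratio: float = 0.02,
    seed: int = 0,
    d_max: float = 1000.0,
) -> StructureFactorSet:
    """Draw a Wilson-distributed structure-factor set with a set Bijvoet ratio.

    Mean intensity falls off as exp(-wilson_b / (2 d^2)); acentric I is
    exponential, centric I follows the centric Wilson law. Anomalous
    differences are zero-mean Gaussian with sigma proportional to sqrt(F),
    rescaled so the empirical <|dF|>/<F> over acentrics equals the target.
    """
    if not 0.0 <= target_bijvoet_ratio <= 0.2:
        raise InvalidInputError("target Bijvoet ratio must be in [0, 0.2]")
    uniq = geometry.enumerate_unique(cell, sym, d_max, d_min, friedel_separate=True)
    miller, d, centric = uniq["miller"], uniq["d"], uniq["centric"]
    rng = np.random.default_rng(seed)
    mean_i = INTENSITY_SCALE * np.exp(-wilson_b / (2.0 * d * d))
    n = len(d)
    intens = np.where(
        centric,
        mean_i * rng.standard_normal(n) ** 2,  # centric Wilson: I ~ <I> chi^2_1
        rng.exponential(scale=1.0, size=n) * mean_i,
    )
    f = np.sqrt(intens)
    acent = ~centric
    delta = np.zeros(n)
    if target_bijvoet_ratio > 0 and np.any(acent):
        raw = rng.standard_normal(acent.sum()) * np.sqrt(f[acent])
        mean_abs = np.mean(np.abs(raw))
        if mean_abs > 0:
            scale = target_bijvoet_ratio * np.mean(f[acent]) / mean_abs
            delta[acent] = raw * scale
    f_plus = np.clip(f + delta / 2.0, 0.0, None)
    f_minus = np.clip(f - delta / 2.0, 0.0, None)
    f_minus[centric] = f_plus[centric]
    return StructureFactorSet(
        miller=miller,
        d=d,
        centric=centric,
        f_plus=f_plus,
        f_minus=f_minus,
        wilson_b=wilson_b,
        seed=seed,
        cell=cell,
        symmetry=sym.space_group_symbol,
    )


def empirical_bijvoet_ratio(sf: StructureFactorSet) -> float:
    """Mean |F+ - F-| over acentrics divided by the mean of (F+ + F-)/2."""
    acent = ~sf.centric
    if not np.any(acent):
        raise InvalidInputError("no acentric reflections")
    num = np.mean(np.abs(sf.f_plus[acent] - sf.f_minus[acent]))
    den = np.mean(0.5 * (sf.f_plus[acent] + sf.f_minus[acent]))
    return float(num / den)
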