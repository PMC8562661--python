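"""Polychromatic beam model, Ewald-sphere excitation and partiality.

A still snapshot records a reflection only while its reciprocal-lattice point
(of finite radius, set by mosaic spread and crystal size) intersects one of
the Ewald spheres spanned by the spectrum. The spectral weight of a
reflection is the fraction of the beam's spectral density falling inside its
rocking range; the partiality is the fraction of the rocking range the
spectrum manages to sweep. Wide bandwidths push partialities towards 1 and
excite more reflections per shot, at the price of spreading photons over a
thicker Ewald shell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .errors import DegenerateProfileError, InvalidInputError

#: FWHM of a unit-sigma Gaussian.
FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

S0 = np.array([0.0, 0.0, 1.0])  # incident beam direction, +z


@dataclass(frozen=True)
class Spectrum:
    """Normalised spectral density over wavelength.

    ``fwhm_bandwidth`` is the fractional FWHM (d-lambda/lambda, equal to dE/E);
    Gaussian support is truncated at ``truncation`` sigma each side so the
    limiting Ewald spheres stay finite.
    """

    central_wavelength: float
    fwhm_bandwidth: float
    shape: str = "gaussian"
    n_samples: int = 50
    truncation: float = 2.5

    def __post_init__(self) -> None:
        if self.central_wavelength <= 0:
            raise InvalidInputError("central wavelength must be > 0")
        if self.fwhm_bandwidth < 0:
            raise InvalidInputError("bandwidth must be >= 0")
        if self.n_samples < 3:
            raise InvalidInputError("need at least 3 spectral samples")
        if self.shape not in ("gaussian", "tophat"):
            raise InvalidInputError(f"unknown spectrum shape {self.shape!r}")

    @property
    def sigma(self) -> float:
        """Gaussian sigma in wavelength units (0 for tophat)."""
        return self.fwhm_bandwidth * self.central_wavelength / FWHM_SIGMA

    def support(self) -> tuple[float, float]:
        """Wavelength range of the limiting Ewald spheres."""
        l0 = self.central_wavelength
        if self.fwhm_bandwidth == 0:
            return (l0, l0)
        if self.shape == "tophat":
            half = l0 * self.fwhm_bandwidth / 2.0
        else:
            half = self.truncation * self.sigma
        return (l0 - half, l0 + half)

    def grid(self):
        """(edges, centers, density) with sum(density * d-lambda) == 1 exactly."""
        lo, hi = self.support()
        if hi == lo:
            raise InvalidInputError("monochromatic spectrum has no finite grid")
        edges = np.linspace(lo, hi, self.n_samples + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        if self.shape == "tophat":
            dens = np.ones(self.n_samples)
        else:
            dens = np.exp(-0.5 * ((centers - self.central_wavelength) / self.sigma) ** 2)
        dl = edges[1] - edges[0]
        dens = dens / (dens.sum() * dl)
        return edges, centers, dens


@dataclass(frozen=True)
class CrystalProfile:
    """Reciprocal-point size: mosaic FWHM (degrees) plus a constant radius
    (Angstrom^-1) from finite crystal size."""

    mosaicity_fwhm: float = 0.0
    profile_radius: float = 1e-5

    def __post_init__(self) -> None:
        if self.mosaicity_fwhm < 0 or self.profile_radius < 0:
            raise InvalidInputError("profile parameters must be >= 0")

    def effective_radius(self, q_norm) -> np.ndarray:
        """R_eff = profile_radius + (half mosaic FWHM in rad) * |q|."""
        half_mos = 0.5 * np.radians(self.mosaicity_fwhm)
        return self.profile_radius + half_mos * np.asarray(q_norm, dtype=float)


def spectral_support(spectrum: Spectrum) -> tuple[float, float]:
    return spectrum.support()


def diffracting_wavelength(q_lab) -> np.ndarray | float:
    """Wavelength at which a reciprocal vector sits exactly on the Ewald sphere.

    lambda* = -2 (q . s0) / |q|^2; non-positive values mean the reflection
    cannot diffract in this orientation.
    """
    q = np.asarray(q_lab, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    norm2 = np.einsum("ij,ij->i", q, q)
    if np.any(norm2 == 0):
        raise InvalidInputError("diffracting wavelength undefined for q = 0")
    lam = -2.0 * q[:, 2] / norm2
    return float(lam[0]) if single else lam


def excitation_offset(q_lab, wavelength) -> np.ndarray | float:
    """Distance of q from the Ewald sphere of the given wavelength (A^-1)."""
    lam = np.asarray(wavelength, dtype=float)
    if np.any(lam <= 0):
        raise InvalidInputError("wavelength must be > 0")
    q = np.asarray(q_lab, dtype=float)
    single = q.ndim == 1 and lam.ndim == 0
    q = np.atleast_2d(q)
    center = -S0 / lam[..., None] if lam.ndim else -S0 / lam
    diff = q - center
    e = np.abs(np.linalg.norm(np.atleast_2d(diff), axis=-1) - 1.0 / lam)
    return float(e.ravel()[0]) if single else e


def effective_radius(q_lab, profile: CrystalProfile) -> np.ndarray | float:
    q = np.asarray(q_lab, dtype=float)
    norm = np.linalg.norm(np.atleast_2d(q), axis=1)
    r = profile.effective_radius(norm)
    return float(r[0]) if q.ndim == 1 else r


def _offset_slope(q: np.ndarray, lam_star: np.ndarray) -> np.ndarray:
    """|d e / d lambda| at the diffraction condition, one-sided numerical.

    The analytic value is |q|^2 / 2; the numerical derivative keeps the
    computation honest for strongly curved low-resolution cases.
    """
    h = 1e-6 * np.maximum(lam_star, 1e-3)
    lam = lam_star + h
    center_z = -1.0 / lam
    dx = q[:, 0]
    dy = q[:, 1]
    dz = q[:, 2] - center_z
    e = np.abs(np.sqrt(dx * dx + dy * dy + dz * dz) - 1.0 / lam)
    return e / h


def rocking_width(q_lab, profile: CrystalProfile) -> np.ndarray | float:
    """Full wavelength extent needed to sweep the reciprocal point through the
    Ewald sphere (2 R_eff / |de/dlambda|)."""
    q = np.atleast_2d(np.asarray(q_lab, dtype=float))
    lam_star = np.atleast_1d(diffracting_wavelength(q))
    r_eff = profile.effective_radius(np.linalg.norm(q, axis=1))
    out = np.full(len(q), np.nan)
    ok = lam_star > 0
    slope = _offset_slope(q[ok], lam_star[ok])
    out[ok] = 2.0 * r_eff[ok] / slope
    if np.asarray(q_lab).ndim == 1:
        return float(out[0])
    return out


def partiality_and_weight(q_lab, spectrum: Spectrum, profile: CrystalProfile):
    """Partiality in [0,1] and spectral weight of reflections in a still.

    The excitation kernel is a top-hat in offset / R_eff. The spectral weight
    integrates the normalised spectral density over the excited wavelength
    range on the spectrum's ``n_samples`` grid, using the exact overlap of
    each wavelength bin with the kernel interval (whose edges are linearised
    endpoints refined by one Newton step on the true offset curve);
    partiality is the swept fraction of the rocking width. Vectorised over
    (N, 3) input; scalars returned for a single vector.
    """
    q = np.asarray(q_lab, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    n = len(q)
    q_norm = np.linalg.norm(q, axis=1)
    if np.any(q_norm == 0):
        raise InvalidInputError("q = 0 has no diffraction condition")
    r_eff = profile.effective_radius(q_norm)
    if np.any(r_eff <= 0):
        raise DegenerateProfileError("zero effective reciprocal-point radius")

    part = np.zeros(n)
    weight = np.zeros(n)
    lam_star = np.atleast_1d(diffracting_wavelength(q))
    lo, hi = spectrum.support()
    if hi > lo:
        slope = np.full(n, np.nan)
        ok = lam_star > 0
        slope[ok] = _offset_slope(q[ok], lam_star[ok])
        ok &= np.isfinite(slope) & (slope > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            width = np.where(ok, 2.0 * r_eff / slope, 0.0)
        # candidates whose rocking interval can intersect the support at all
        cand = ok & (lam_star + width / 2 >= lo) & (lam_star - width / 2 <= hi)
        idx = np.flatnonzero(cand)
        if idx.size:
            edges, _, dens = spectrum.grid()
            qe = q[idx]

            def offs(lams: np.ndarray) -> np.ndarray:
                lams = np.maximum(lams, 1e-6)
                dz = qe[:, 2] + 1.0 / lams
                return np.abs(
                    np.sqrt(qe[:, 0] ** 2 + qe[:, 1] ** 2 + dz * dz) - 1.0 / lams
                )

            # kernel-edge wavelengths: linearised endpoints refined by one
            # Newton step on the true offset curve
            r = r_eff[idx]
            delta = np.maximum(1e-4 * width[idx], 1e-9)
            lam_a0 = lam_star[idx] - width[idx] / 2
            lam_b0 = lam_star[idx] + width[idx] / 2
            e_a = offs(lam_a0)
            s_a = (offs(lam_a0 - delta) - e_a) / delta
            lam_a = np.where(s_a > 0, lam_a0 + (e_a - r) / np.where(s_a > 0, s_a, 1.0), lam_a0)
            e_b = offs(lam_b0)
            s_b = (e_b - offs(lam_b0 - delta)) / delta
            lam_b = np.where(s_b > 0, lam_b0 - (e_b - r) / np.where(s_b > 0, s_b, 1.0), lam_b0)
            lam_b = np.maximum(lam_b, lam_a)
            # exact overlap of the excited interval with each wavelength bin
            lo_edges = edges[:-1]
            hi_edges = edges[1:]
            ov = np.clip(
                np.minimum(hi_edges[None, :], lam_b[:, None])
                - np.maximum(lo_edges[None, :], lam_a[:, None]),
                0.0,
                None,
            )
            weight[idx] = (dens[None, :] * ov).sum(axis=1)
            extent = ov.sum(axis=1)
            full = np.maximum(lam_b - lam_a, 1e-300)
            part[idx] = np.clip(extent / full, 0.0, 1.0)
        weight[part == 0] = 0.0
    if single:
        return float(part[0]), float(weight[0])
    return part, weight


def mean_spots_per_pattern(
    cell: geometry.UnitCell,
    sym: geometry.SymmetrySpec,
    spectrum: Spectrum,
    profile: CrystalProfile,
    det: geometry.DetectorGeometry,
    d_min: float,
    n_orientations: int,
    seed: int,
) -> float:
    """Average number of excited, detector-hitting reflections per still."""
    if n_orientations < 1:
        raise InvalidInputError("need at least one orientation")
    m = geometry.reflections_in_sphere(cell, d_min)
    m = m[~geometry.is_absent(m, sym)]
    B = geometry.reciprocal_basis(cell)
    q0 = m @ B.T
    total = 0
    for i in range(n_orientations):
        rot = geometry.random_orientation(seed, substream=i)
        q_lab = q0 @ rot.T
        _, w = partiality_and_weight(q_lab, spectrum, profile)
        hit = w > 0
        if np.any(hit):
            lam_star = np.clip(
                diffracting_wavelength(q_lab[hit]), *spectrum.support()
            )
            s = lam_star[:, None] * q_lab[hit] + S0
            s /= np.linalg.norm(s, axis=1, keepdims=True)
            xy = geometry._project_direction(s, det)
            total += int(np.sum(~np.isnan(np.atleast_2d(xy)[:, 0])))
    return total / n_orientations
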