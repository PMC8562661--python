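"""Unit-cell and reciprocal-space geometry for still diffraction.

Conventions used throughout the package:

* Crystallographic reciprocal basis without the 2*pi factor, assembled as a
  Busing-Levy upper-triangular B matrix, so ``|B @ (h,k,l)| == 1/d``.
* Laboratory frame is right-handed with the incident beam along +z; the
  detector is a flat square panel normal to the beam at ``distance`` mm.
* Reflection indices transform under a symmetry operation (R, t) acting on
  fractional coordinates as ``h' = h @ R`` (row vector), with the phase shift
  ``exp(-2*pi*i h.t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import (
    GeometryInconsistencyError,
    InvalidInputError,
    UnsupportedSymmetryError,
)

#: keV * Angstrom photon conversion constant (h*c/e).
KEV_ANGSTROM = 12.3984


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in Angstrom from energy in keV."""
    if energy_kev <= 0:
        raise InvalidInputError(f"photon energy must be > 0, got {energy_kev}")
    return KEV_ANGSTROM / energy_kev


def energy_from_wavelength(wavelength: float) -> float:
    if wavelength <= 0:
        raise InvalidInputError(f"wavelength must be > 0, got {wavelength}")
    return KEV_ANGSTROM / wavelength


@dataclass(frozen=True)
class UnitCell:
    """Unit cell, lengths in Angstrom and angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise InvalidInputError(f"cell angle {name} must be in (0, 180)")
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise InvalidInputError("degenerate cell: non-positive volume")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            raise InvalidInputError("degenerate cell: metric determinant <= 0")
        return self.a * self.b * self.c * math.sqrt(arg)

    def metric(self) -> np.ndarray:
        """Direct-space metric tensor G (Angstrom^2)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric(self) -> np.ndarray:
        return np.linalg.inv(self.metric())


def reciprocal_basis(cell: UnitCell) -> np.ndarray:
    """Busing-Levy upper-triangular B matrix (columns a*, b*, c*; Angstrom^-1).

    ``q = B @ m`` has ``|q| = 1/d(m)`` for any integer Miller triple m.
    """
    if cell.volume < 1e-9:
        raise InvalidInputError("degenerate cell: volume ~ 0")
    g_star = cell.reciprocal_metric()
    a_s = math.sqrt(g_star[0, 0])
    b_s = math.sqrt(g_star[1, 1])
    c_s = math.sqrt(g_star[2, 2])
    cos_gs = g_star[0, 1] / (a_s * b_s)
    cos_bs = g_star[0, 2] / (a_s * c_s)
    sin_gs = math.sqrt(max(0.0, 1.0 - cos_gs * cos_gs))
    sin_bs = math.sqrt(max(0.0, 1.0 - cos_bs * cos_bs))
    cos_alpha = math.cos(math.radians(cell.alpha))
    return np.array(
        [
            [a_s, b_s * cos_gs, c_s * cos_bs],
            [0.0, b_s * sin_gs, -c_s * sin_bs * cos_alpha],
            [0.0, 0.0, 1.0 / cell.c],
        ]
    )


def d_spacing(cell: UnitCell, m) -> float:
    """Resolution d = 1/|B m| in Angstrom for one Miller triple."""
    m = np.asarray(m, dtype=float)
    if not np.any(m):
        raise InvalidInputError("d-spacing undefined for (0,0,0)")
    q = reciprocal_basis(cell) @ m
    return 1.0 / float(np.linalg.norm(q))


def edge_resolution(distance_mm: float, side_mm: float, wavelength: float) -> float:
    """Bragg resolution at the panel edge (centred beam), Angstrom.

    Uses the half side-length as the edge radius: theta = atan(r/D)/2 and
    d = lambda / (2 sin theta).
    """
    if wavelength <= 0:
        raise InvalidInputError("wavelength must be > 0")
    if distance_mm <= 0 or side_mm <= 0:
        raise InvalidInputError("detector dimensions must be > 0")
    theta = 0.5 * math.atan2(side_mm / 2.0, distance_mm)
    return wavelength / (2.0 * math.sin(theta))


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat square detector normal to the beam.

    Panel coordinates run over [0, side_length] in both x and y (mm); the
    direct beam hits ``beam_center`` (defaults to the panel centre).
    """

    distance: float
    side_length: float
    pixel_size: float
    beam_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0 or self.side_length <= 0 or self.pixel_size <= 0:
            raise InvalidInputError("detector dimensions must be > 0")
        if self.beam_center is None:
            object.__setattr__(
                self, "beam_center", (self.side_length / 2.0, self.side_length / 2.0)
            )

    @property
    def n_pixels(self) -> int:
        return int(round(self.side_length / self.pixel_size))

    def edge_resolution(self, wavelength: float) -> float:
        return edge_resolution(self.distance, self.side_length, wavelength)


# --------------------------------------------------------------------------
# symmetry


_SUPPORTED = {
    "P41212": ("P 41 21 2", "4/mmm"),
    "P1": ("P 1", "-1"),
}


def _normalise_symbol(symbol: str) -> str:
    return symbol.replace("(", "").replace(")", "").replace(" ", "").replace("_", "")


@dataclass(frozen=True)
class SymmetrySpec:
    """Space-group operators and derived bookkeeping for a supported preset.

    ``rotations[i]`` and ``translations[i]`` give the i-th operator acting on
    fractional coordinates as ``x' = R x + t``.
    """

    space_group_symbol: str
    laue_group: str
    rotations: np.ndarray = field(repr=False)  # (n_ops, 3, 3) int
    translations: np.ndarray = field(repr=False)  # (n_ops, 3) float in [0,1)

    @classmethod
    def from_symbol(cls, symbol: str) -> "SymmetrySpec":
        key = _normalise_symbol(symbol)
        if key not in _SUPPORTED:
            raise UnsupportedSymmetryError(
                f"space group {symbol!r} not supported (presets: P41212, P1)"
            )
        hm, laue = _SUPPORTED[key]
        ops = gemmi.SpaceGroup(hm).operations()
        rots, trans = [], []
        for op in ops:
            rots.append(np.array(op.rot, dtype=float) / op.DEN)
            trans.append(np.array(op.tran, dtype=float) / op.DEN)
        rotations = np.array(rots)
        if not np.allclose(rotations, np.round(rotations)):
            raise UnsupportedSymmetryError("non-integral rotation part")
        return cls(key, laue, np.round(rotations).astype(int), np.array(trans))

    @property
    def n_ops(self) -> int:
        return len(self.rotations)

    def equivalents(self, m: np.ndarray) -> np.ndarray:
        """All point-group equivalents h @ R (without Friedel inversion).

        m: (..., 3) int array -> (n_ops, ..., 3).
        """
        m = np.asarray(m)
        return np.einsum("...j,oji->o...i", m, self.rotations)


def is_absent(m, sym: SymmetrySpec) -> bool | np.ndarray:
    """Systematic absence test: h R == h with non-integral phase h.t.

    Accepts a single triple or an (N, 3) array.
    """
    arr = np.atleast_2d(np.asarray(m, dtype=int))
    absent = np.zeros(len(arr), dtype=bool)
    for rot, tran in zip(sym.rotations, sym.translations):
        fixed = np.all(arr @ rot == arr, axis=1)
        phase = arr @ tran
        nonint = np.abs(phase - np.round(phase)) > 1e-9
        absent |= fixed & nonint
    if np.asarray(m).ndim == 1:
        return bool(absent[0])
    return absent


def _lex_key(m: np.ndarray) -> np.ndarray:
    """Monotone scalar key for lexicographic (h, then k, then l) comparison."""
    base = np.int64(4096)
    off = base // 2
    h, k, l = m[..., 0], m[..., 1], m[..., 2]
    return ((h.astype(np.int64) + off) * base + (k + off)) * base + (l + off)


def _asu_arrays(m: np.ndarray, sym: SymmetrySpec):
    """Vectorised ASU mapping.

    Returns (canonical (N,3) int, is_minus (N,) bool, centric (N,) bool).
    Canonical representative is the lexicographically greatest equivalent over
    the full Laue orbit (point-group equivalents of both +m and -m).
    """
    m = np.atleast_2d(np.asarray(m, dtype=int))
    plus = sym.equivalents(m)  # (n_ops, N, 3)
    minus = -plus
    kp = _lex_key(plus)
    km = _lex_key(minus)
    best_p = kp.max(axis=0)
    best_m = km.max(axis=0)
    centric = best_p == best_m
    take_minus = best_m > best_p
    # gather representative triples
    idx_p = kp.argmax(axis=0)
    idx_m = km.argmax(axis=0)
    n = m.shape[0]
    rep_p = plus[idx_p, np.arange(n)]
    rep_m = minus[idx_m, np.arange(n)]
    canonical = np.where(take_minus[:, None], rep_m, rep_p)
    is_minus = take_minus & ~centric
    return canonical, is_minus, centric


def map_to_asu(m, sym: SymmetrySpec, friedel_separate: bool = True):
    """Map a Miller triple to its canonical ASU representative.

    Returns ``(asu_miller, is_friedel_minus)``. Friedel mates share the same
    representative; with ``friedel_separate`` the flag records which branch of
    the pair the input belongs to (always False for centrics or when mates are
    merged).
    """
    canonical, is_minus, _ = _asu_arrays(np.asarray(m), sym)
    flag = bool(is_minus[0]) if friedel_separate else False
    return tuple(int(x) for x in canonical[0]), flag


def is_centric(m, sym: SymmetrySpec) -> bool | np.ndarray:
    """True if -m belongs to the point-group orbit of m (Bijvoet difference 0)."""
    _, _, centric = _asu_arrays(np.asarray(m), sym)
    if np.asarray(m).ndim == 1:
        return bool(centric[0])
    return centric


def reflections_in_sphere(cell: UnitCell, d_min: float, d_max: float = math.inf) -> np.ndarray:
    """All integer Miller triples with d in [d_min, d_max], excluding (0,0,0)."""
    if d_min <= 0:
        raise InvalidInputError("d_min must be > 0")
    B = reciprocal_basis(cell)
    hmax = int(cell.a / d_min) + 1
    kmax = int(cell.b / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    h, k, l = np.mgrid[-hmax : hmax + 1, -kmax : kmax + 1, -lmax : lmax + 1]
    m = np.column_stack([h.ravel(), k.ravel(), l.ravel()]).astype(int)
    m = m[np.any(m != 0, axis=1)]
    q = m @ B.T
    inv_d = np.linalg.norm(q, axis=1)
    with np.errstate(divide="ignore"):
        d = 1.0 / inv_d
    keep = (d >= d_min * (1 - 1e-9)) & (d <= d_max * (1 + 1e-9))
    return m[keep]


def enumerate_unique(
    cell: UnitCell,
    sym: SymmetrySpec,
    d_max: float,
    d_min: float,
    friedel_separate: bool = True,
    include_absent: bool = False,
) -> dict:
    """Enumerate canonical unique reflections in a resolution range.

    Returns a dict of parallel arrays: ``miller`` (n,3), ``d`` (n,), ``centric``
    (n,) plus ``count`` where acentrics are counted twice when
    ``friedel_separate`` (Bijvoet pairs distinguished) and centrics once.

    Systematic absences are excluded by default. ``include_absent=True``
    reproduces the counting convention of serial-crystallography merging
    tools, which tabulate the full asymmetric unit without screw-axis
    knowledge; published unique-reflection counts follow that convention.
    """
    if not d_max > d_min > 0:
        raise InvalidInputError("need d_max > d_min > 0")
    m = reflections_in_sphere(cell, d_min, d_max)
    if len(m) == 0:
        return {"miller": m.reshape(0, 3), "d": np.zeros(0), "centric": np.zeros(0, bool), "count": 0}
    if not include_absent:
        m = m[~is_absent(m, sym)]
    canonical, _, centric = _asu_arrays(m, sym)
    uniq, idx = np.unique(canonical, axis=0, return_index=True)
    centric_u = centric[idx]
    B = reciprocal_basis(cell)
    d_u = 1.0 / np.linalg.norm(uniq @ B.T, axis=1)
    order = np.argsort(-d_u, kind="stable")
    uniq, centric_u, d_u = uniq[order], centric_u[order], d_u[order]
    n_acentric = int(np.sum(~centric_u))
    n_centric = int(np.sum(centric_u))
    count = n_acentric * (2 if friedel_separate else 1) + n_centric
    return {"miller": uniq, "d": d_u, "centric": centric_u, "count": count}


# --------------------------------------------------------------------------
# orientations and detector projection


def random_orientation(seed: int, substream: int | None = None) -> np.ndarray:
    """Uniform random rotation matrix, reproducible per (seed, substream).

    Uses a quaternion drawn from an isotropic 4D Gaussian; ``substream`` gives
    an independent stream per pattern index so parallel generation is stable.
    """
    key = seed if substream is None else [seed, substream]
    rng = np.random.default_rng(key)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def project_to_detector(q_lab, wavelength: float, det: DetectorGeometry):
    """Project a diffracting reciprocal vector onto the detector plane.

    The scattered direction is ``s = wavelength * q_lab + s0`` with s0 = +z;
    q_lab must satisfy the elastic condition so |s| = 1 within 1e-6. Returns
    (x, y) in panel mm or None for a backward ray / off-panel hit.
    """
    q_lab = np.asarray(q_lab, dtype=float)
    s = wavelength * q_lab + np.array([0.0, 0.0, 1.0])
    norm = np.linalg.norm(s)
    if abs(norm - 1.0) > 1e-6:
        raise GeometryInconsistencyError(
            f"|s| = {norm:.8f} deviates from 1 beyond tolerance; not on the Ewald sphere"
        )
    return _project_direction(s[None, :], det)[0]


def _project_direction(s: np.ndarray, det: DetectorGeometry):
    """Intersect unit-ish ray directions (N,3) with the panel; NaN for misses."""
    out = np.full((len(s), 2), np.nan)
    fwd = s[:, 2] > 1e-9
    bx, by = det.beam_center
    x = bx + det.distance * s[fwd, 0] / s[fwd, 2]
    y = by + det.distance * s[fwd, 1] / s[fwd, 2]
    on = (x >= 0) & (x <= det.side_length) & (y >= 0) & (y <= det.side_length)
    xy = np.column_stack([x, y])
    xy[~on] = np.nan
    out[fwd] = xy
    if s.shape[0] == 1:
        return [None if np.isnan(out[0, 0]) else (float(out[0, 0]), float(out[0, 1]))]
    return out
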