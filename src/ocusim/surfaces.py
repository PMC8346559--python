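"""Conic + Zernike freeform surface machinery.

Corneal surfaces are described as a conicoid base plus a sixth-order
Zernike height map fitted over a 6-mm zone (OSA double-index convention,
radial order ``i`` and meridional frequency ``j``).  Sag and coefficients
follow the usual topographer conventions: geometry in millimetres,
Zernike coefficients in micrometres over a normalization radius
(default 3 mm).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

MAX_ORDER = 6

__all__ = [
    "MAX_ORDER",
    "ZernikeIndexError",
    "SagDomainError",
    "osa_double_indices",
    "osa_single_index",
    "zernike_eval",
    "ZernikeCoefficientSet",
    "ConicZernikeSurface",
    "surface_sag",
    "fit_elevation",
    "rms_decompose",
    "read_elevation_csv",
    "write_elevation_csv",
]


class ZernikeIndexError(ValueError):
    """Invalid (radial order, meridional frequency) pairing."""


class SagDomainError(ValueError):
    """Conic square-root argument non-positive at the requested radius."""


def _check_index(i: int, j: int) -> None:
    if i < 0 or abs(j) > i or (i - abs(j)) % 2 != 0:
        raise ZernikeIndexError(
            f"invalid Zernike index (i={i}, j={j}): need |j| <= i and i-|j| even"
        )


def osa_double_indices(max_order: int = MAX_ORDER) -> list[tuple[int, int]]:
    """All (i, j) double indices through ``max_order``, OSA single-index order."""
    out = []
    for i in range(max_order + 1):
        for j in range(-i, i + 1, 2):
            out.append((i, j))
    return out


def osa_single_index(i: int, j: int) -> int:
    """Standard OSA/ANSI single index for double index (i, j)."""
    _check_index(i, j)
    return (i * (i + 2) + j) // 2


_INDICES = osa_double_indices(MAX_ORDER)
N_TERMS = len(_INDICES)  # 28 terms for orders 0..6


def _radial_coeffs(i: int, m: int) -> np.ndarray:
    """Coefficients of the radial polynomial R_i^m in powers rho^0..rho^MAX_ORDER."""
    c = np.zeros(MAX_ORDER + 1)
    for s in range((i - m) // 2 + 1):
        num = (-1) ** s * math.factorial(i - s)
        den = (
            math.factorial(s)
            * math.factorial((i + m) // 2 - s)
            * math.factorial((i - m) // 2 - s)
        )
        c[i - 2 * s] = num / den
    return c


class _Basis:
    """Precomputed vectorized Zernike basis for orders 0..6."""

    def __init__(self) -> None:
        self.indices = _INDICES
        self.m = np.array([abs(j) for _, j in _INDICES])
        self.is_sin = np.array([j < 0 for _, j in _INDICES])
        self.norm = np.array(
            [math.sqrt(2.0 * (i + 1) / (1.0 + (1.0 if j == 0 else 0.0))) for i, j in _INDICES]
        )
        self.radial = np.stack([_radial_coeffs(i, abs(j)) for i, j in _INDICES])
        # d/drho of the radial polynomial, same power layout
        self.dradial = np.zeros_like(self.radial)
        for p in range(1, MAX_ORDER + 1):
            self.dradial[:, p - 1] = self.radial[:, p] * p
        # R/rho (exact polynomial division; valid because lowest power is m>=1
        # for all terms with m >= 1)
        self.radial_over_rho = np.zeros_like(self.radial)
        self.radial_over_rho[:, : MAX_ORDER] = self.radial[:, 1:]
        self.low_order = np.array([i <= 2 for i, _ in _INDICES])

    def _powers(self, rho: np.ndarray) -> np.ndarray:
        out = np.empty((MAX_ORDER + 1,) + rho.shape)
        out[0] = 1.0
        for p in range(1, MAX_ORDER + 1):
            out[p] = out[p - 1] * rho
        return out

    def _trig(self, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # cos/sin of m*phi for m = 0..6 via the Chebyshev recurrence
        cm = np.empty((MAX_ORDER + 1,) + phi.shape)
        sm = np.empty_like(cm)
        cm[0] = 1.0
        sm[0] = 0.0
        cm[1] = np.cos(phi)
        sm[1] = np.sin(phi)
        two_c = 2.0 * cm[1]
        for m in range(2, MAX_ORDER + 1):
            cm[m] = two_c * cm[m - 1] - cm[m - 2]
            sm[m] = two_c * sm[m - 1] - sm[m - 2]
        return cm, sm

    def evaluate(self, rho: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """All 28 basis values; shape (28,) + rho.shape."""
        rho = np.asarray(rho, dtype=float)
        phi = np.asarray(phi, dtype=float)
        pw = self._powers(rho)
        cm, sm = self._trig(phi)
        r = np.tensordot(self.radial, pw, axes=(1, 0))
        t = np.where(self.is_sin.reshape((-1,) + (1,) * rho.ndim), sm[self.m], cm[self.m])
        return self.norm.reshape((-1,) + (1,) * rho.ndim) * r * t

    def gradient(self, rho: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """d/dxi, d/deta of all terms in normalized cartesian pupil coords."""
        _, dxi, deta = self.evaluate_and_gradient(np.asarray(rho, float),
                                                  np.asarray(phi, float))
        return dxi, deta

    def evaluate_and_gradient(self, rho: np.ndarray, phi: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(Z, dZ/dxi, dZ/deta) for all terms, sharing powers and trig tables."""
        rho = np.asarray(rho, dtype=float)
        phi = np.asarray(phi, dtype=float)
        pw = self._powers(rho)
        cm, sm = self._trig(phi)
        sel = self.is_sin.reshape((-1,) + (1,) * rho.ndim)
        mcol = self.m.reshape((-1,) + (1,) * rho.ndim)
        r = np.tensordot(self.radial, pw, axes=(1, 0))
        r_d = np.tensordot(self.dradial, pw, axes=(1, 0))
        r_over = np.tensordot(self.radial_over_rho, pw, axes=(1, 0))
        t = np.where(sel, sm[self.m], cm[self.m])
        # dT/dphi: -m sin(m phi) for cosine terms, +m cos(m phi) for sine terms
        dt = np.where(sel, mcol * cm[self.m], -mcol * sm[self.m])
        cphi, sphi = cm[1], sm[1]
        nrm = self.norm.reshape((-1,) + (1,) * rho.ndim)
        z = nrm * r * t
        dxi = nrm * (r_d * cphi * t - r_over * sphi * dt)
        deta = nrm * (r_d * sphi * t + r_over * cphi * dt)
        return z, dxi, deta


_BASIS = _Basis()


def zernike_eval(i: int, j: int, rho, phi):
    """Evaluate Z_i^j(rho, phi) with the sqrt(2(i+1)/(1+delta_j0)) normalization.

    Sine phase (with leading minus) for j < 0, cosine phase for j >= 0.
    The polynomial is extended naturally for rho > 1.
    """
    _check_index(i, j)
    if i > MAX_ORDER:
        raise ZernikeIndexError(f"radial order {i} > {MAX_ORDER} not supported")
    k = osa_single_index(i, j)
    out = _BASIS.evaluate(np.asarray(rho, dtype=float), np.asarray(phi, dtype=float))[k]
    return float(out) if np.isscalar(rho) and np.isscalar(phi) else out


@dataclass
class ZernikeCoefficientSet:
    """Complete coefficient set for orders 0..6 (28 terms, micrometres).

    Parameters
    ----------
    values : array of length 28 in OSA single-index order, units um.
    normalization_radius : radius (mm) at which rho = 1.
    """

    values: np.ndarray = field(default_factory=lambda: np.zeros(N_TERMS))
    normalization_radius: float = 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        if self.values.shape != (N_TERMS,):
            raise ValueError(f"expected {N_TERMS} coefficients, got {self.values.shape}")
        if self.normalization_radius <= 0:
            raise ValueError("normalization_radius must be positive")

    @classmethod
    def from_terms(
        cls,
        terms: Mapping[tuple[int, int], float] | Iterable[tuple[int, int, float]],
        normalization_radius: float = 3.0,
    ) -> "ZernikeCoefficientSet":
        values = np.zeros(N_TERMS)
        items = terms.items() if isinstance(terms, Mapping) else ((i, j, v) for i, j, v in terms)
        for entry in items:
            if isinstance(terms, Mapping):
                (i, j), v = entry
            else:
                i, j, v = entry
            if i > MAX_ORDER:
                raise ZernikeIndexError(f"radial order {i} > {MAX_ORDER}")
            values[osa_single_index(i, j)] = v
        return cls(values, normalization_radius)

    def get(self, i: int, j: int) -> float:
        return float(self.values[osa_single_index(i, j)])

    def _polar(self) -> dict:
        """Coefficient-contracted polar form for fast sag/gradient evaluation.

        z(rho, phi) = sum_m A_m(rho) cos(m phi) + B_m(rho) sin(m phi), with
        A_m/B_m degree-6 polynomials.  Cached; the coefficient array is
        treated as immutable after construction.
        """
        cache = getattr(self, "_polar_cache", None)
        if cache is not None:
            return cache
        A = np.zeros((MAX_ORDER + 1, MAX_ORDER + 1))  # (m, power)
        B = np.zeros_like(A)
        for k, (i, j) in enumerate(_INDICES):
            if self.values[k] == 0.0:
                continue
            m = abs(j)
            coef = self.values[k] * _BASIS.norm[k] * _BASIS.radial[k]
            if j >= 0:
                A[m] += coef
            else:
                B[m] += coef
        dA = np.zeros_like(A)
        dB = np.zeros_like(B)
        dA[:, :MAX_ORDER] = A[:, 1:] * np.arange(1, MAX_ORDER + 1)
        dB[:, :MAX_ORDER] = B[:, 1:] * np.arange(1, MAX_ORDER + 1)
        # m * A_m / rho as polynomials (lowest power of A_m is m >= 1)
        mAo = np.zeros_like(A)
        mBo = np.zeros_like(B)
        marr = np.arange(MAX_ORDER + 1)[:, None]
        mAo[:, :MAX_ORDER] = (marr * A)[:, 1:]
        mBo[:, :MAX_ORDER] = (marr * B)[:, 1:]
        cache = {"A": A, "B": B, "dA": dA, "dB": dB, "mAo": mAo, "mBo": mBo}
        self._polar_cache = cache
        return cache

    def is_zero(self) -> bool:
        return not np.any(self.values)

    def as_dict(self) -> dict:
        return {
            "norm_radius_mm": self.normalization_radius,
            "terms": [
                {"i": i, "j": j, "value_um": float(v)}
                for (i, j), v in zip(_INDICES, self.values)
                if v != 0.0
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ZernikeCoefficientSet":
        values = np.zeros(N_TERMS)
        for t in d.get("terms", []):
            values[osa_single_index(int(t["i"]), int(t["j"]))] = float(t["value_um"])
        return cls(values, float(d.get("norm_radius_mm", 3.0)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ZernikeCoefficientSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def rms_decompose(coeffs: ZernikeCoefficientSet) -> tuple[float, float]:
    """(low_order_rms, high_order_rms) in um.

    Low = orders 0-2 (piston, tilt, defocus/astigmatism), high = orders 3-6.
    The basis is orthonormal over the unit disk, so the coefficient RMS of
    each band equals the surface-height RMS of that band.
    """
    v = coeffs.values
    low = float(np.sqrt(np.sum(v[_BASIS.low_order] ** 2)))
    high = float(np.sqrt(np.sum(v[~_BASIS.low_order] ** 2)))
    return low, high


@dataclass
class ConicZernikeSurface:
    """Conicoid base plus an optional Zernike height deviation.

    R : vertex radius of curvature [mm], signed (positive = centre of
        curvature toward the retina).
    Q : conic constant.
    zernike : coefficient set (um over its normalization radius), may be None.
    semi_diameter : clear aperture radius [mm].
    vertex_z : axial vertex position [mm].
    """

    R: float
    Q: float = 0.0
    zernike: ZernikeCoefficientSet | None = None
    semi_diameter: float = 6.0
    vertex_z: float = 0.0

    def __post_init__(self) -> None:
        if self.R == 0:
            raise ValueError("vertex radius R must be nonzero")
        if self.semi_diameter <= 0:
            raise ValueError("semi_diameter must be positive")

    @property
    def curvature(self) -> float:
        return 1.0 / self.R

    def conic_sag(self, r2: np.ndarray) -> np.ndarray:
        c = self.curvature
        r2 = np.asarray(r2, dtype=float)
        arg = 1.0 - (1.0 + self.Q) * c * c * r2
        if np.any(arg <= 0):
            r_off = float(np.sqrt(np.max(np.where(arg <= 0, r2, -np.inf))))
            raise SagDomainError(
                f"conic sag undefined at radius {r_off:.4f} mm (R={self.R}, Q={self.Q})"
            )
        return c * r2 / (1.0 + np.sqrt(arg))

    def sag(self, x, y):
        """Surface sag z(x, y) [mm] relative to the vertex plane."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r2 = x * x + y * y
        z = self.conic_sag(r2)
        if self.zernike is not None and not self.zernike.is_zero():
            rn = self.zernike.normalization_radius
            rho = np.sqrt(r2) / rn
            phi = np.arctan2(y, x)
            pol = self.zernike._polar()
            pw = _BASIS._powers(np.asarray(rho, dtype=float))
            cm, sm = _BASIS._trig(np.asarray(phi, dtype=float))
            zern = (np.einsum("mp,p...,m...->...", pol["A"], pw, cm)
                    + np.einsum("mp,p...,m...->...", pol["B"], pw, sm))
            z = z + zern * 1e-3  # um -> mm
        return z

    def sag_and_gradient(self, x, y):
        """(z, dz/dx, dz/dy), all in mm (gradient dimensionless)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r2 = x * x + y * y
        c = self.curvature
        arg = 1.0 - (1.0 + self.Q) * c * c * r2
        arg = np.maximum(arg, 1e-14)
        s = np.sqrt(arg)
        z = c * r2 / (1.0 + s)
        g = c / s  # dz/dr = c r / s  => dz/dx = x * c/s
        gx = x * g
        gy = y * g
        if self.zernike is not None and not self.zernike.is_zero():
            rn = self.zernike.normalization_radius
            rho = np.asarray(np.sqrt(r2) / rn, dtype=float)
            phi = np.asarray(np.arctan2(y, x), dtype=float)
            pol = self.zernike._polar()
            pw = _BASIS._powers(rho)
            cm, sm = _BASIS._trig(phi)
            RA = np.tensordot(pol["A"], pw, axes=(1, 0))
            RB = np.tensordot(pol["B"], pw, axes=(1, 0))
            zern = np.sum(RA * cm + RB * sm, axis=0)
            u = np.sum(np.tensordot(pol["dA"], pw, axes=(1, 0)) * cm
                       + np.tensordot(pol["dB"], pw, axes=(1, 0)) * sm, axis=0)
            w = np.sum(np.tensordot(pol["mAo"], pw, axes=(1, 0)) * sm
                       - np.tensordot(pol["mBo"], pw, axes=(1, 0)) * cm, axis=0)
            cphi, sphi = cm[1], sm[1]
            z = z + zern * 1e-3
            gx = gx + (u * cphi + w * sphi) * 1e-3 / rn
            gy = gy + (u * sphi - w * cphi) * 1e-3 / rn
        return z, gx, gy


def surface_sag(surface: ConicZernikeSurface, x: float, y: float) -> float:
    """Sag of ``surface`` at (x, y) mm; raises SagDomainError outside the conic domain."""
    out = surface.sag(x, y)
    return float(out) if np.ndim(out) == 0 else out


class FitConditioningError(ValueError):
    """Rank-deficient sampling for the least-squares elevation fit."""


def fit_elevation(
    x,
    y,
    z,
    R: float,
    Q: float,
    max_order: int = MAX_ORDER,
    norm_radius: float = 3.0,
) -> ZernikeCoefficientSet:
    """Least-squares Zernike fit of an elevation grid against a fixed conic base.

    The conic (R, Q) is the instrument-supplied base and is not refit; the
    residual ``z - conic`` inside the normalization disk is projected onto
    the 28-term basis.  Inputs in mm; returned coefficients in um.
    """
    if max_order != MAX_ORDER:
        raise ValueError("only sixth-order fits are supported")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    r = np.hypot(x, y)
    inside = r <= norm_radius
    if int(inside.sum()) < N_TERMS:
        raise FitConditioningError(
            f"need >= {N_TERMS} samples inside the {norm_radius} mm disk, got {int(inside.sum())}"
        )
    x, y, z, r = x[inside], y[inside], z[inside], r[inside]
    base = ConicZernikeSurface(R=R, Q=Q, semi_diameter=max(norm_radius * 2, float(r.max()) + 1))
    resid_um = (z - base.sag(x, y)) * 1e3
    A = _BASIS.evaluate(r / norm_radius, np.arctan2(y, x)).T  # (n, 28)
    coef, _, rank, _ = np.linalg.lstsq(A, resid_um, rcond=None)
    if rank < N_TERMS:
        raise FitConditioningError(f"design matrix rank {rank} < {N_TERMS}")
    return ZernikeCoefficientSet(coef, norm_radius)


def read_elevation_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an elevation grid from plain CSV with columns x_mm, y_mm, z_mm."""
    xs, ys, zs = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            xs.append(float(row["x_mm"]))
            ys.append(float(row["y_mm"]))
            zs.append(float(row["z_mm"]))
    return np.array(xs), np.array(ys), np.array(zs)


def write_elevation_csv(path, x, y, z) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_mm", "y_mm", "z_mm"])
        for xi, yi, zi in zip(np.ravel(x), np.ravel(y), np.ravel(z)):
            w.writerow([repr(float(xi)), repr(float(yi)), repr(float(zi))])
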