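"""Sequential polychromatic ray tracing through a model eye.

Rays enter as collimated bundles tilted by the field angle in the x-z
(horizontal) meridian, are iteratively aimed so that their footprint fills
the physical stop, and are traced surface by surface: damped Newton
intersection with conic+Zernike sags (closed-form seed on the conic),
vector Snell refraction, and chromatic dispersion from a two-term Cauchy
model fixed by each medium's d-line index and Abbe number.

Coordinates are right-handed with z along the optical axis toward the
retina and the origin at the anterior corneal vertex.  All geometry in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .eye import (
    EyeModel,
    IdealLens,
    ImageSurface,
    Material,
    RefractingSurface,
    Stop,
    WAVE_GREEN,
)
from .surfaces import ConicZernikeSurface

__all__ = [
    "STATUS_LIVE",
    "STATUS_VIGNETTED",
    "STATUS_MISSED",
    "STATUS_TIR",
    "Ray",
    "FieldSpec",
    "PupilSampling",
    "TraceBundle",
    "refractive_index",
    "intersect",
    "refract",
    "trace_bundle",
    "paraxial_solve",
    "hexapolar_points",
    "grid_points",
    "image_space_state",
    "rms_spot_at_shift",
    "on_axis_rms_spot",
]

STATUS_LIVE = 0
STATUS_VIGNETTED = 1
STATUS_MISSED = 2
STATUS_TIR = 3

_AIM_TOL = 1e-4  # mm at the stop plane (0.1 um)
_AIM_MAX_ITER = 20
_NEWTON_TOL = 1e-9  # mm axial residual
_NEWTON_MAX_ITER = 50


class MissedSurfaceError(RuntimeError):
    pass


class FieldError(RuntimeError):
    """Chief-ray aiming failed for the requested field."""


def refractive_index(mat: Material, wavelength_nm: float) -> float:
    """n(lambda) of a medium from its two-term Cauchy model (400-750 nm)."""
    return mat.index(wavelength_nm)


@dataclass
class Ray:
    """Single ray: origin [mm], unit direction, wavelength [nm], OPL [mm]."""

    origin: np.ndarray
    direction: np.ndarray
    wavelength: float = WAVE_GREEN
    opl: float = 0.0
    status: int = STATUS_LIVE

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(d)
        if abs(nrm - 1.0) > 1e-9:
            d = d / nrm
        self.direction = d


@dataclass(frozen=True)
class FieldSpec:
    """Field angle [deg] in the horizontal meridian (0-30 evaluated)."""

    angle: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle <= 60.0):
            raise ValueError("field angle outside the supported range")

    @property
    def direction(self) -> np.ndarray:
        th = np.deg2rad(self.angle)
        return np.array([np.sin(th), 0.0, np.cos(th)])


@dataclass(frozen=True)
class PupilSampling:
    """Pupil-sampling specification.

    kind='hexapolar' fills the stop with ``rings`` concentric rings
    (1 + 3 K (K+1) rays); kind='grid' uses an n x n Cartesian grid over the
    stop with a circular mask (used for OPD/PSF sampling).
    """

    kind: str = "hexapolar"
    rings: int = 6
    grid_n: int = 64

    def unit_points(self) -> np.ndarray:
        if self.kind == "hexapolar":
            return hexapolar_points(self.rings)
        if self.kind == "grid":
            pts, _ = grid_points(self.grid_n)
            return pts
        raise ValueError(f"unknown sampling kind {self.kind!r}")


def hexapolar_points(rings: int) -> np.ndarray:
    """Unit-disk hexapolar pattern: centre point plus 6k points on ring k."""
    pts = [(0.0, 0.0)]
    for k in range(1, rings + 1):
        r = k / rings
        ang = np.arange(6 * k) * (2 * np.pi / (6 * k))
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    return np.array(pts)


def grid_points(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(points (m,2), flat indices into the n*n grid) for the unit-disk mask.

    Grid coordinates are pixel centres spanning (-1, 1) exclusive.
    """
    c = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    xx, yy = np.meshgrid(c, c, indexing="xy")
    mask = xx**2 + yy**2 <= 1.0
    idx = np.flatnonzero(mask.ravel())
    return np.column_stack([xx.ravel()[idx], yy.ravel()[idx]]), idx


# --------------------------------------------------------------------------
# Vectorized primitives

def _conic_intersect(o: np.ndarray, d: np.ndarray, surf: ConicZernikeSurface,
                     t_min: float = -1e-9) -> np.ndarray:
    """Parametric distance to the conic base of ``surf`` (nan where missed).

    Uses the implicit conicoid c r^2 + c (1+Q) z'^2 - 2 z' = 0 and keeps the
    root on the vertex branch (1 - c (1+Q) z' > 0) with the smallest
    admissible travel.
    """
    c = surf.curvature
    k = 1.0 + surf.Q
    oz = o[:, 2] - surf.vertex_z
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    ox, oy = o[:, 0], o[:, 1]
    A = c * (dx * dx + dy * dy + k * dz * dz)
    B = 2.0 * c * (ox * dx + oy * dy + k * oz * dz) - 2.0 * dz
    C = c * (ox * ox + oy * oy + k * oz * oz) - 2.0 * oz

    t = np.full(o.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        lin = np.abs(A) < 1e-14
        t_lin = -C / B
        disc = B * B - 4.0 * A * C
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, np.nan))
        # numerically stable pair of roots
        qq = -0.5 * (B + np.sign(B + (B == 0)) * sq)
        t1 = qq / A
        t2 = C / qq
        for cand in (t1, t2):
            zc = oz + cand * dz
            valid = ok & ~lin & (cand >= t_min) & (1.0 - c * k * zc > 0)
            take = valid & (np.isnan(t) | (cand < t))
            t = np.where(take, cand, t)
        zl = oz + t_lin * dz
        vlin = lin & (t_lin >= t_min) & (1.0 - c * k * zl > 0)
        t = np.where(vlin & np.isnan(t), t_lin, t)
    return t


def _intersect_surface(o: np.ndarray, d: np.ndarray, surf: ConicZernikeSurface,
                       live: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersection points, normals and travel for live rays.

    Returns (t, point (N,3), normal (N,3)); rays that miss get t = nan.
    Newton refinement on the axial residual when a Zernike deviation is
    present, seeded from the closed-form conic solution.
    """
    t = _conic_intersect(o, d, surf)
    t = np.where(live, t, np.nan)
    has_zern = surf.zernike is not None and not surf.zernike.is_zero()
    p = o + t[:, None] * d
    if has_zern:
        act = live & np.isfinite(t)
        for _ in range(_NEWTON_MAX_ITER):
            if not np.any(act):
                break
            x, y = p[act, 0], p[act, 1]
            z, gx, gy = surf.sag_and_gradient(x, y)
            F = p[act, 2] - surf.vertex_z - z
            dF = d[act, 2] - gx * d[act, 0] - gy * d[act, 1]
            step = F / np.where(np.abs(dF) < 1e-12, np.sign(dF) * 1e-12 + (dF == 0) * 1e-12, dF)
            # damping: cap the step to avoid overshooting on steep freeform slopes
            step = np.clip(step, -1.0, 1.0)
            tn = t.copy()
            tn[act] = t[act] - step
            t = tn
            p = o + t[:, None] * d
            conv = np.zeros_like(act)
            conv[act] = np.abs(F) < _NEWTON_TOL
            act = act & ~conv
        if np.any(act):  # non-converged rays are treated as missed
            t = np.where(act, np.nan, t)
            p = o + t[:, None] * d
    x, y = p[:, 0], p[:, 1]
    ok = np.isfinite(t)
    zg = np.zeros_like(x)
    gx = np.zeros_like(x)
    gy = np.zeros_like(x)
    if np.any(ok):
        zg_ok, gx_ok, gy_ok = surf.sag_and_gradient(x[ok], y[ok])
        gx[ok], gy[ok] = gx_ok, gy_ok
    nrm = np.column_stack([-gx, -gy, np.ones_like(gx)])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return t, p, nrm


def _refract_dirs(d: np.ndarray, normal: np.ndarray, n1: float, n2: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Vector Snell refraction; returns (new unit directions, TIR mask)."""
    nv = normal.copy()
    cosi = -np.sum(d * nv, axis=1)
    flip = cosi < 0
    nv[flip] = -nv[flip]
    cosi = np.abs(cosi)
    eta = n1 / n2
    sin2t = eta * eta * (1.0 - cosi * cosi)
    tir = sin2t > 1.0
    cost = np.sqrt(np.clip(1.0 - sin2t, 0.0, None))
    dn = eta * d + (eta * cosi - cost)[:, None] * nv
    dn /= np.linalg.norm(dn, axis=1, keepdims=True)
    return dn, tir


def intersect(ray: Ray, surface: ConicZernikeSurface) -> tuple[np.ndarray, np.ndarray]:
    """First intersection of a single ray with a surface: (point, unit normal).

    The normal has a positive z component (from the sag gradient).
    Raises MissedSurfaceError when there is no intersection inside the
    clear aperture.
    """
    o = ray.origin[None, :]
    d = ray.direction[None, :]
    t, p, nv = _intersect_surface(o, d, surface, np.array([True]))
    if not np.isfinite(t[0]):
        raise MissedSurfaceError("ray does not intersect the surface")
    if np.hypot(p[0, 0], p[0, 1]) > surface.semi_diameter + 1e-12:
        raise MissedSurfaceError("intersection outside the clear aperture")
    return p[0], nv[0]


def refract(ray: Ray, normal: np.ndarray, n1: float, n2: float) -> Ray:
    """Vector-Snell refraction of a single ray at a surface normal."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("indices must be positive")
    dn, tir = _refract_dirs(ray.direction[None, :], np.asarray(normal, float)[None, :],
                            n1, n2)
    if tir[0]:
        return replace(ray, status=STATUS_TIR)
    return replace(ray, direction=dn[0])


# --------------------------------------------------------------------------
# Bundle tracing

@dataclass
class _State:
    """Mutable vectorized ray state during a trace."""

    p: np.ndarray  # (N, 3)
    d: np.ndarray  # (N, 3)
    opl: np.ndarray  # (N,)
    status: np.ndarray  # (N,) int
    n_current: float
    outside_zone: int = 0
    stop_xy: Optional[np.ndarray] = None

    @property
    def live(self) -> np.ndarray:
        return self.status == STATUS_LIVE


def _entry_plane_z(eye: EyeModel) -> float:
    spec = eye.spectacle
    return (spec.z if spec is not None else 0.0) - 5.0


def _advance_to_plane(st: _State, z: float) -> None:
    live = st.live
    t = np.where(live, (z - st.p[:, 2]) / st.d[:, 2], 0.0)
    st.p = st.p + t[:, None] * st.d
    st.opl = st.opl + st.n_current * t


def _apply_element(st: _State, el, wavelength: float, stop_tol: float = 1e-3,
                   retina_shift: float = 0.0) -> None:
    if isinstance(el, IdealLens):
        _advance_to_plane(st, el.z)
        live = st.live
        p_mm = el.power / 1000.0
        x, y = st.p[:, 0], st.p[:, 1]
        tx = st.d[:, 0] / st.d[:, 2] - x * p_mm
        ty = st.d[:, 1] / st.d[:, 2] - y * p_mm
        nrm = np.sqrt(tx * tx + ty * ty + 1.0)
        dn = np.column_stack([tx / nrm, ty / nrm, 1.0 / nrm])
        st.d = np.where(live[:, None], dn, st.d)
        st.opl = st.opl + np.where(live, -p_mm * (x * x + y * y) / 2.0, 0.0)
        return
    if isinstance(el, Stop):
        _advance_to_plane(st, el.z)
        live = st.live
        r = np.hypot(st.p[:, 0], st.p[:, 1])
        st.status = np.where(live & (r > el.diameter / 2 + stop_tol),
                             STATUS_VIGNETTED, st.status)
        st.stop_xy = st.p[:, :2].copy()
        return
    if isinstance(el, (RefractingSurface, ImageSurface)):
        surf = el.surface
        if isinstance(el, ImageSurface) and retina_shift != 0.0:
            surf = replace(surf, vertex_z=surf.vertex_z + retina_shift)
        live = st.live
        t, p, nv = _intersect_surface(st.p, st.d, surf, live)
        missed = live & ~np.isfinite(t)
        st.status = np.where(missed, STATUS_MISSED, st.status)
        live = st.live
        r = np.hypot(p[:, 0], p[:, 1])
        vig = live & (r > surf.semi_diameter + 1e-9)
        st.status = np.where(vig, STATUS_VIGNETTED, st.status)
        live = st.live
        if surf.zernike is not None and not surf.zernike.is_zero():
            st.outside_zone += int(np.sum(live & (r > surf.zernike.normalization_radius)))
        st.p = np.where(live[:, None], p, st.p)
        st.opl = st.opl + np.where(live, st.n_current * t, 0.0)
        if isinstance(el, RefractingSurface):
            n2 = el.n_after.index(wavelength)
            dn, tir = _refract_dirs(st.d, nv, st.n_current, n2)
            st.status = np.where(live & tir, STATUS_TIR, st.status)
            live = st.live
            st.d = np.where(live[:, None], dn, st.d)
            st.n_current = n2
        return
    raise TypeError(f"unknown element {el!r}")


def _trace_elements(eye: EyeModel, elements, origins: np.ndarray, dirs: np.ndarray,
                    wavelength: float, n_start: float = 1.0) -> _State:
    n = origins.shape[0]
    # reference the OPL to the incoming plane wavefront (perpendicular to the
    # beam, through the coordinate origin): for a collimated bundle the
    # launch phase is the projection of each origin onto its direction
    opl0 = n_start * np.sum(origins * dirs, axis=1)
    st = _State(p=origins.copy(), d=dirs.copy(), opl=opl0,
                status=np.full(n, STATUS_LIVE), n_current=n_start)
    for el in elements:
        _apply_element(st, el, wavelength, retina_shift=eye.retina_shift)
    return st


def _split_at_stop(eye: EyeModel):
    els = eye.elements
    for i, el in enumerate(els):
        if isinstance(el, Stop):
            return els[: i + 1], els[i + 1 :]
    raise ValueError("eye has no stop")


def aim_bundle(eye: EyeModel, field: FieldSpec, wavelength: float,
               targets: np.ndarray, xy0: Optional[np.ndarray] = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Entry-plane origins whose stop-plane footprint matches ``targets``.

    Fixed-point iteration on the stop-plane landing error (<= 20 iterations,
    tolerance 0.1 um).  Returns (origins, dirs, converged mask).  ``xy0``
    seeds the iteration (e.g. the solution at a neighbouring wavelength).
    """
    pre_stop, _ = _split_at_stop(eye)
    z0 = _entry_plane_z(eye)
    d0 = field.direction
    stop_z = eye.stop.z
    n = targets.shape[0]
    dirs = np.tile(d0, (n, 1))
    # back-project the targets along the beam direction as the initial guess
    if xy0 is not None:
        xy = xy0.copy()
    else:
        xy = targets - (stop_z - z0) * (d0[:2] / d0[2])
    conv = np.zeros(n, dtype=bool)
    for _ in range(_AIM_MAX_ITER):
        origins = np.column_stack([xy[:, 0], xy[:, 1], np.full(n, z0)])
        st = _trace_elements(eye, pre_stop, origins, dirs, wavelength)
        landed = st.stop_xy
        alive = np.isin(st.status, (STATUS_LIVE, STATUS_VIGNETTED))
        err = np.where(alive[:, None], landed - targets, 0.0)
        conv = alive & (np.max(np.abs(err), axis=1) < _AIM_TOL)
        if np.all(conv | ~alive):
            break
        xy = xy - err
    origins = np.column_stack([xy[:, 0], xy[:, 1], np.full(n, z0)])
    return origins, dirs, conv


@dataclass
class WavelengthTrace:
    """Per-wavelength retina intersections for one traced bundle."""

    wavelength: float
    points: np.ndarray  # (N, 2) retina-frame coordinates [mm]
    status: np.ndarray  # (N,)
    opl: np.ndarray  # (N,)
    chief_point: np.ndarray  # (2,)
    pupil_xy: np.ndarray  # (N, 2) normalized stop coordinates of the targets

    @property
    def live_points(self) -> np.ndarray:
        return self.points[self.status == STATUS_LIVE]


@dataclass
class TraceBundle:
    """Retina-plane spot data for one (eye, field) over several wavelengths."""

    field: FieldSpec
    traces: dict
    outside_zone: int = 0

    def counts(self) -> dict:
        c = {"launched": 0, "live": 0, "vignetted": 0, "missed": 0, "tir": 0}
        for tr in self.traces.values():
            c["launched"] += tr.status.size
            c["live"] += int(np.sum(tr.status == STATUS_LIVE))
            c["vignetted"] += int(np.sum(tr.status == STATUS_VIGNETTED))
            c["missed"] += int(np.sum(tr.status == STATUS_MISSED))
            c["tir"] += int(np.sum(tr.status == STATUS_TIR))
        return c

    def all_live_points(self) -> np.ndarray:
        pts = [tr.live_points for tr in self.traces.values()]
        return np.vstack([p for p in pts if p.size]) if any(p.size for p in pts) else np.empty((0, 2))

    def to_csv(self, path) -> None:
        import csv as _csv

        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["wavelength_nm", "x_mm", "y_mm"])
            for wl, tr in self.traces.items():
                for x, y in tr.live_points:
                    w.writerow([wl, repr(float(x)), repr(float(y))])


def trace_bundle(eye: EyeModel, field: FieldSpec | float,
                 wavelengths: Sequence[float] = (WAVE_GREEN,),
                 sampling: PupilSampling = PupilSampling()) -> TraceBundle:
    """Aim and trace a collimated bundle at a field angle to the retina.

    The first ray of each wavelength is the chief ray (stop centre); aiming
    failure of the chief ray raises FieldError.
    """
    if not isinstance(field, FieldSpec):
        field = FieldSpec(float(field))
    stop_r = eye.stop_diameter / 2.0
    unit = sampling.unit_points()
    targets = np.vstack([[0.0, 0.0], unit * stop_r])
    pupil_xy = np.vstack([[0.0, 0.0], unit])
    traces = {}
    outside = 0
    xy_seed = None
    for wl in wavelengths:
        origins, dirs, conv = aim_bundle(eye, field, wl, targets, xy0=xy_seed)
        xy_seed = origins[:, :2]
        if not conv[0]:
            raise FieldError(f"chief-ray aiming failed at field {field.angle} deg")
        st = _trace_elements(eye, eye.elements, origins, dirs, wl)
        st.status = np.where(conv, st.status, np.where(st.status == STATUS_LIVE,
                                                       STATUS_VIGNETTED, st.status))
        outside += st.outside_zone
        traces[wl] = WavelengthTrace(
            wavelength=wl,
            points=st.p[:, :2].copy(),
            status=st.status.copy(),
            opl=st.opl.copy(),
            chief_point=st.p[0, :2].copy(),
            pupil_xy=pupil_xy,
        )
    return TraceBundle(field=field, traces=traces, outside_zone=outside)


# --------------------------------------------------------------------------
# Image-space caching for focus solves

@dataclass
class ImageSpaceState:
    """Rays traced to just before the retina, reusable across retina shifts."""

    p: np.ndarray
    d: np.ndarray
    opl: np.ndarray
    status: np.ndarray
    n_image: float
    wavelength: float


def image_space_state(eye: EyeModel, field_deg: float = 0.0,
                      wavelength: float = WAVE_GREEN,
                      sampling: PupilSampling = PupilSampling(rings=4)
                      ) -> ImageSpaceState:
    field = FieldSpec(field_deg)
    stop_r = eye.stop_diameter / 2.0
    targets = np.vstack([[0.0, 0.0], sampling.unit_points() * stop_r])
    origins, dirs, conv = aim_bundle(eye, field, wavelength, targets)
    if not conv[0]:
        raise FieldError(f"chief-ray aiming failed at field {field.angle} deg")
    st = _trace_elements(eye, eye.elements[:-1], origins, dirs, wavelength)
    st.status = np.where(conv, st.status, np.where(st.status == STATUS_LIVE,
                                                   STATUS_VIGNETTED, st.status))
    return ImageSpaceState(p=st.p, d=st.d, opl=st.opl, status=st.status,
                           n_image=st.n_current, wavelength=wavelength)


def retina_points_at_shift(eye: EyeModel, state: ImageSpaceState, shift: float
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(points (N,2), opl, live mask) on the retina displaced by ``shift``."""
    surf = replace(eye.retina.surface,
                   vertex_z=eye.retina.surface.vertex_z + shift)
    live = state.status == STATUS_LIVE
    t, p, _ = _intersect_surface(state.p, state.d, surf, live)
    ok = live & np.isfinite(t)
    opl = state.opl + np.where(ok, state.n_image * t, 0.0)
    return p[:, :2], opl, ok


def rms_spot_at_shift(eye: EyeModel, state: ImageSpaceState, shift: float) -> float:
    """RMS radial spot size [mm] about the centroid at a trial retina shift."""
    pts, _, ok = retina_points_at_shift(eye, state, shift)
    pts = pts[ok]
    if pts.shape[0] == 0:
        return np.inf
    ctr = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - ctr) ** 2, axis=1))))


def on_axis_rms_spot(eye: EyeModel, wavelength: float = WAVE_GREEN,
                     sampling: PupilSampling = PupilSampling(rings=4)) -> float:
    """On-axis RMS spot radius [mm] at the eye's current focus state."""
    state = image_space_state(eye, 0.0, wavelength, sampling)
    return rms_spot_at_shift(eye, state, 0.0)


# --------------------------------------------------------------------------
# Paraxial solve

@dataclass
class ParaxialSolution:
    power: float  # D
    efl: float  # image-space focal length [mm] (in image medium)
    back_focal_z: float  # axial position of the paraxial focus [mm]
    principal_plane_z: float  # image principal plane [mm]
    n_image: float


def paraxial_solve(eye: EyeModel, wavelength: float = WAVE_GREEN) -> ParaxialSolution:
    """First-order properties from the y-nu recursion on vertex radii."""
    y, u = 1.0, 0.0
    n = 1.0
    z_prev = None
    z_last = 0.0
    for el in eye.elements:
        if isinstance(el, ImageSurface):
            break
        if isinstance(el, Stop):
            continue
        z_el = el.z if isinstance(el, (IdealLens, Stop)) else el.surface.vertex_z
        if z_prev is not None:
            y = y + u * (z_el - z_prev)
        z_prev = z_el
        z_last = z_el
        if isinstance(el, IdealLens):
            u = u - y * el.power / 1000.0
        else:
            n2 = el.n_after.index(wavelength)
            c = el.surface.curvature
            u = (n * u - y * c * (n2 - n)) / n2
            n = n2
    if abs(u) < 1e-12:
        warnings.warn("afocal system: paraxial power is singular", RuntimeWarning)
        return ParaxialSolution(0.0, np.inf, np.inf, np.nan, n)
    power = -1000.0 * n * u  # y0 = 1
    efl = 1000.0 * n / power
    bfz = z_last - y / u
    return ParaxialSolution(power=power, efl=efl, back_focal_z=bfz,
                            principal_plane_z=bfz - efl, n_image=n)
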