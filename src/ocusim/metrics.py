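"""Optical quality metrics: spot RMS, chromatic aberrations, FFT PSF/MTF.

Spot metrics are geometric (ray-intersection) quantities in the plane
tangent to the retina vertex; PSF and MTF are diffraction quantities built
from pupil optical-path-difference (OPD) maps by FFT.  The Strehl ratio is
the peak of the polychromatic PSF relative to the peak of the same
computation with all OPDs set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize_scalar

from .eye import (
    EyeModel,
    RGB_WAVELENGTHS,
    WAVE_BLUE,
    WAVE_GREEN,
    WAVE_RED,
    with_stop_diameter,
    correct_with_spectacle,
    focus_by_retina_shift,
    IdealLens,
)
from .raytrace import (
    STATUS_LIVE,
    FieldError,
    FieldSpec,
    PupilSampling,
    TraceBundle,
    _trace_elements,
    aim_bundle,
    grid_points,
    image_space_state,
    rms_spot_at_shift,
    trace_bundle,
)

__all__ = [
    "NoRaysError",
    "GeometryError",
    "OpdMap",
    "PsfResult",
    "MtfCurve",
    "QualityReport",
    "spot_rms",
    "longitudinal_chromatic_shift",
    "lca_to_diopters",
    "transverse_chromatic",
    "opd_from_trace",
    "opd_maps",
    "psf_strehl",
    "mtf_curve",
    "geometric_mtf_curve",
    "geometric_mtf_from_maps",
    "evaluate_eye",
]


class NoRaysError(RuntimeError):
    pass


class GeometryError(ValueError):
    pass


def spot_rms(bundle: TraceBundle) -> float:
    """RMS radial spot size [um], all wavelengths pooled with equal weights.

    RMS radial distance of every live retina intersection about the common
    centroid of the pooled point set.
    """
    pts = bundle.all_live_points()
    if pts.shape[0] == 0:
        raise NoRaysError("bundle has no live rays")
    ctr = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - ctr) ** 2, axis=1)))) * 1e3


def _best_focus_shift(eye: EyeModel, wavelength: float, half_range: float = 1.5,
                      rings: int = 4) -> float:
    """Absolute retina shift minimizing the on-axis RMS spot at one wavelength."""
    state = image_space_state(eye, 0.0, wavelength, PupilSampling(rings=rings))
    s0 = eye.retina_shift

    res = minimize_scalar(lambda s: rms_spot_at_shift(eye, state, s),
                          bounds=(s0 - half_range, s0 + half_range),
                          method="bounded", options={"xatol": 1e-5})
    return float(res.x)


def longitudinal_chromatic_shift(eye: EyeModel, pupil: Optional[float] = None,
                                 wavelengths: Sequence[float] = RGB_WAVELENGTHS
                                 ) -> dict:
    """Axial best-focus position per wavelength relative to green [mm].

    For each wavelength the retina position minimizing the on-axis RMS spot
    is found with the same bounded solver used for focusing; the green
    entry is identically zero.
    """
    e = with_stop_diameter(eye, pupil) if pupil is not None else eye
    z_green = _best_focus_shift(e, WAVE_GREEN)
    out = {}
    for wl in wavelengths:
        out[wl] = 0.0 if wl == WAVE_GREEN else _best_focus_shift(e, wl) - z_green
    return out


def lca_to_diopters(shift_mm: float, eye: EyeModel) -> float:
    """Convert an axial focal shift [mm] to defocus [D] via the paraxial power."""
    from .raytrace import paraxial_solve

    sol = paraxial_solve(eye)
    # dP/dz at the image: P^2 / (1000 n')
    return shift_mm * sol.power**2 / (1000.0 * sol.n_image)


def transverse_chromatic(eye: EyeModel, field, pupil: Optional[float] = None,
                         rings: int = 4) -> float:
    """Blue-to-red centroid separation [um] at the retina for one field."""
    e = with_stop_diameter(eye, pupil) if pupil is not None else eye
    bundle = trace_bundle(e, field, (WAVE_RED, WAVE_BLUE), PupilSampling(rings=rings))
    cents = []
    for wl in (WAVE_BLUE, WAVE_RED):
        pts = bundle.traces[wl].live_points
        if pts.shape[0] == 0:
            raise NoRaysError(f"no live rays at {wl} nm")
        cents.append(pts.mean(axis=0))
    return float(np.linalg.norm(cents[0] - cents[1])) * 1e3


@dataclass
class OpdMap:
    """Pupil OPD map [waves] over the stop, with its aperture mask.

    ``opd`` is defined only on ``mask`` and has zero mean there (piston
    removed).  ``na`` is the measured image-side numerical aperture and
    ``chief_point`` the chief-ray retina coordinates, used to place the
    FFT PSF on a common retina grid across wavelengths.
    """

    opd: np.ndarray  # (n, n) waves
    mask: np.ndarray  # (n, n) bool
    wavelength: float  # nm
    na: float
    ref_sphere_radius: float  # mm
    chief_point: np.ndarray  # (2,) mm
    spot_points: Optional[np.ndarray] = None  # (m, 2) live retina hits [mm]

    @property
    def grid_n(self) -> int:
        return self.opd.shape[0]

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.opd[self.mask] ** 2)))

    @property
    def max_gradient(self) -> float:
        """Largest OPD step between adjacent pupil samples [waves/pixel].

        Values above ~0.5 mean the pupil function is phase-aliased and the
        FFT PSF/MTF of this map is unreliable at this sampling.
        """
        gx = np.abs(np.diff(self.opd, axis=1))[self.mask[:, 1:] & self.mask[:, :-1]]
        gy = np.abs(np.diff(self.opd, axis=0))[self.mask[1:, :] & self.mask[:-1, :]]
        vals = [g.max() for g in (gx, gy) if g.size]
        return float(max(vals)) if vals else 0.0


def opd_from_trace(eye: EyeModel, field, wavelength: float,
                   pupil: Optional[float] = None, grid_n: int = 128) -> OpdMap:
    """Pupil OPD map from ray optical path lengths.

    OPD = (chief OPL - ray OPL) referred to a sphere centred on the
    chief-ray retina point with radius equal to the stop-centre-to-image
    distance, converted to waves at the trace wavelength; piston removed.
    """
    m, _ = _opd_single(eye, field, wavelength, pupil, grid_n, None)
    return m


def opd_maps(eye: EyeModel, field, wavelengths: Sequence[float],
             pupil: Optional[float] = None, grid_n: int = 128) -> list:
    """Per-wavelength OPD maps, reusing the aiming solution across colours."""
    out = []
    xy = None
    for wl in wavelengths:
        m, xy = _opd_single(eye, field, wl, pupil, grid_n, xy)
        out.append(m)
    return out


def _opd_single(eye: EyeModel, field, wavelength: float, pupil: Optional[float],
                grid_n: int, xy0) -> tuple[OpdMap, np.ndarray]:
    if not isinstance(field, FieldSpec):
        field = FieldSpec(float(field))
    e = with_stop_diameter(eye, pupil) if pupil is not None else eye
    stop_r = e.stop_diameter / 2.0
    unit, idx = grid_points(grid_n)
    targets = np.vstack([[0.0, 0.0], unit * stop_r])
    origins, dirs, conv = aim_bundle(e, field, wavelength, targets, xy0=xy0)
    if not conv[0]:
        raise FieldError(f"chief-ray aiming failed at field {field.angle} deg")
    st = _trace_elements(e, e.elements, origins, dirs, wavelength)
    live = (st.status == STATUS_LIVE) & conv
    if not live[0]:
        raise FieldError("chief ray lost before the retina")
    n_img = st.n_current
    chief3 = st.p[0]
    stop_c = np.array([0.0, 0.0, e.stop.z])
    r_ref = float(np.linalg.norm(chief3 - stop_c))

    w = st.p - chief3  # from image point to each retina intersection
    wd = np.sum(w * st.d, axis=1)
    disc = wd * wd - np.sum(w * w, axis=1) + r_ref * r_ref
    ok = live & (disc >= 0)
    s_back = wd + np.sqrt(np.where(ok, disc, 0.0))  # backtrack distance along the ray
    opl_sphere = st.opl - n_img * s_back
    chief_sphere = st.opl[0] - n_img * r_ref
    lam_mm = wavelength * 1e-6
    opd_waves = (chief_sphere - opl_sphere) / lam_mm

    opd_grid = np.zeros((grid_n, grid_n))
    mask_grid = np.zeros((grid_n, grid_n), dtype=bool)
    ray_ok = ok[1:]  # drop chief
    flat_mask = np.zeros(grid_n * grid_n, dtype=bool)
    flat_mask[idx[ray_ok]] = True
    flat_opd = np.zeros(grid_n * grid_n)
    flat_opd[idx[ray_ok]] = opd_waves[1:][ray_ok]
    mask_grid = flat_mask.reshape(grid_n, grid_n)
    opd_grid = flat_opd.reshape(grid_n, grid_n)
    opd_grid[mask_grid] -= opd_grid[mask_grid].mean()

    # image-side NA from the steepest live marginal ray
    d_chief = st.d[0]
    cross = np.linalg.norm(np.cross(st.d[ok], d_chief), axis=1)
    na = n_img * float(np.max(cross)) if np.any(ok) else 0.0
    m = OpdMap(opd=opd_grid, mask=mask_grid, wavelength=wavelength, na=na,
               ref_sphere_radius=r_ref, chief_point=chief3[:2].copy(),
               spot_points=st.p[ok, :2].copy())
    return m, origins[:, :2]


@dataclass
class PsfResult:
    psf: np.ndarray  # polychromatic PSF, peak-normalized to the ideal peak
    pixel_mm: float  # retina-plane pixel pitch of the common grid
    strehl: float


def _single_psf(m: OpdMap, pad: int) -> tuple[np.ndarray, float]:
    """(PSF normalized to its own diffraction-limited peak, pixel pitch [mm])."""
    n = m.grid_n
    npad = pad * n
    pupil = np.where(m.mask, np.exp(2j * np.pi * m.opd), 0.0)
    psf = np.abs(np.fft.fftshift(np.fft.fft2(pupil, s=(npad, npad)))) ** 2
    ideal_peak = float(np.sum(m.mask)) ** 2
    if m.na <= 0:
        raise GeometryError("OPD map has no live rays (NA = 0)")
    pixel = (m.wavelength * 1e-6) * n / (2.0 * m.na * npad)
    return psf / ideal_peak, pixel


def psf_strehl(opds: Sequence[OpdMap], weights: Optional[Sequence[float]] = None,
               pad: int = 4) -> PsfResult:
    """Polychromatic FFT PSF and Strehl ratio from per-wavelength OPD maps.

    Each monochromatic PSF = |FFT(mask exp(i 2 pi OPD))|^2 on a grid
    zero-padded ``pad`` times, normalized to the peak of the same
    computation with zero OPD, then interpolated onto the reference
    (green-most) wavelength's retina grid including its transverse
    chromatic offset; the weighted sum is the polychromatic PSF and its
    peak is the Strehl ratio (exactly 1 for zero OPD and no offsets).
    """
    if pad < 2:
        raise ValueError("pad factor must be >= 2")
    opds = list(opds)
    if not opds:
        raise ValueError("need at least one OPD map")
    n = opds[0].grid_n
    for m in opds:
        if m.grid_n != n:
            raise GeometryError("OPD maps have mismatched grid sizes")
    if weights is None:
        weights = np.full(len(opds), 1.0 / len(opds))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(opds),) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must match the maps and sum to 1")

    ref = min(range(len(opds)), key=lambda k: abs(opds[k].wavelength - WAVE_GREEN))
    psf_ref, pix_ref = _single_psf(opds[ref], pad)
    npad = psf_ref.shape[0]
    ctr = npad // 2
    rows = (np.arange(npad) - ctr)
    poly = np.zeros_like(psf_ref)
    for k, m in enumerate(opds):
        psf_k, pix_k = _single_psf(m, pad)
        if k == ref:
            poly += weights[k] * psf_k
            continue
        # physical offset of this wavelength's chief point vs the reference
        off = m.chief_point - opds[ref].chief_point
        # sample psf_k at the reference grid's physical coordinates
        yy = (rows[:, None] * pix_ref - off[1]) / pix_k + ctr
        xx = (rows[None, :] * pix_ref - off[0]) / pix_k + ctr
        yy, xx = np.broadcast_arrays(yy, xx)
        poly += weights[k] * ndimage.map_coordinates(psf_k, [yy, xx], order=1,
                                                     mode="constant", cval=0.0)
    return PsfResult(psf=poly, pixel_mm=pix_ref, strehl=float(poly.max()))


@dataclass
class MtfCurve:
    freq: np.ndarray  # cyc/mm
    tangential: np.ndarray
    sagittal: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return 0.5 * (self.tangential + self.sagittal)

    def mean_at(self, f: float) -> float:
        return float(np.interp(f, self.freq, self.mean))


def mtf_curve(psf, pixel_mm: Optional[float] = None, max_freq: float = 60.0,
              n_freq: int = 61) -> MtfCurve:
    """Tangential/sagittal MTF cuts from a PSF, resampled to 0-60 cyc/mm.

    ``psf`` may be a PsfResult or a raw array plus ``pixel_mm``.  The PSF is
    normalized to unit sum; MTF = |FFT(PSF)| with MTF(0) = 1.  Tangential is
    the cut along the field (x) frequency axis, sagittal along y.
    """
    if isinstance(psf, PsfResult):
        arr, pixel_mm = psf.psf, psf.pixel_mm
    else:
        arr = np.asarray(psf, dtype=float)
        if pixel_mm is None:
            raise ValueError("pixel_mm required for a raw PSF array")
    arr = arr / arr.sum()
    otf = np.abs(np.fft.fft2(np.fft.ifftshift(arr)))
    otf = otf / otf[0, 0]
    n = arr.shape[0]
    f = np.fft.fftfreq(n, d=pixel_mm)
    keep = f >= 0
    fpos = f[keep]
    order = np.argsort(fpos)
    fpos = fpos[order]
    tan = otf[0, keep][order]  # frequencies along x
    sag = otf[keep, 0][order]
    fq = np.linspace(0.0, max_freq, n_freq)
    return MtfCurve(freq=fq,
                    tangential=np.interp(fq, fpos, tan),
                    sagittal=np.interp(fq, fpos, sag))


def geometric_mtf_curve(bundle: TraceBundle, max_freq: float = 60.0,
                        n_freq: int = 61) -> MtfCurve:
    """Ray-based (geometric) MTF from pooled spot coordinates.

    The modulus of the characteristic function of the pooled retina point
    set: MTF(f) = |mean exp(-2 pi i f x)| for tangential (x), y for
    sagittal.  Diffraction is neglected, which is the appropriate regime
    when aberrations are many waves and the FFT pupil sampling cannot
    resolve them.
    """
    pts = bundle.all_live_points()
    if pts.shape[0] == 0:
        raise NoRaysError("bundle has no live rays")
    return _char_function_mtf(pts, max_freq, n_freq)


def _char_function_mtf(pts: np.ndarray, max_freq: float, n_freq: int,
                       max_points: int = 8000) -> MtfCurve:
    if pts.shape[0] > max_points:  # deterministic stride subsample
        pts = pts[:: pts.shape[0] // max_points + 1]
    pts = pts - pts.mean(axis=0)
    fq = np.linspace(0.0, max_freq, n_freq)
    ph_t = np.exp(-2j * np.pi * np.outer(fq, pts[:, 0]))
    ph_s = np.exp(-2j * np.pi * np.outer(fq, pts[:, 1]))
    return MtfCurve(freq=fq,
                    tangential=np.abs(ph_t.mean(axis=1)),
                    sagittal=np.abs(ph_s.mean(axis=1)))


def geometric_mtf_from_maps(maps: Sequence[OpdMap], max_freq: float = 60.0,
                            n_freq: int = 61) -> MtfCurve:
    """Geometric MTF pooling the dense spot points carried by OPD maps."""
    pts = [m.spot_points for m in maps if m.spot_points is not None]
    if not pts:
        raise NoRaysError("OPD maps carry no spot points")
    return _char_function_mtf(np.vstack(pts), max_freq, n_freq)


# --------------------------------------------------------------------------
# Whole-eye evaluation

@dataclass
class QualityReport:
    """Tidy per-cell metric table (one row per eye/epoch/field/pupil/metric)."""

    df: pd.DataFrame

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "QualityReport":
        return cls(pd.read_csv(path, keep_default_na=True))

    def value(self, field: float, pupil: float, metric: str) -> float:
        sel = self.df[(self.df.field_deg == field) & (self.df.pupil_mm == pupil)
                      & (self.df.metric == metric)]
        return float(sel.value.iloc[0])


def refocus_for_epoch(eye: EyeModel) -> EyeModel:
    """Re-apply the epoch focusing rule (after e.g. a stop-diameter change)."""
    spec = eye.spectacle
    if spec is not None:
        els = [el for el in eye.elements if not isinstance(el, IdealLens)]
        bare = replace(eye, elements=els)
        return correct_with_spectacle(bare, S=-spec.power)
    return focus_by_retina_shift(replace(eye, retina_shift=0.0))


def evaluate_eye(eye: EyeModel, fields: Sequence[float] = (0.0, 10.0, 20.0, 30.0),
                 pupils: Sequence[float] = (2.0, 4.0, 6.0),
                 wavelengths: Sequence[float] = RGB_WAVELENGTHS,
                 weights: Optional[Sequence[float]] = None,
                 psf_grid: int = 36, spot_rings: int = 6,
                 refocus: bool = True, with_lca: bool = True,
                 pad: int = 2, grad_limit: float = 0.5) -> QualityReport:
    """Full metric grid over fields x pupils.

    Per cell: pooled-wavelength RMS spot radius, blue-red transverse
    chromatic offset, polychromatic and green-only Strehl ratios, and the
    tangential/sagittal-averaged MTF sampled at 30 and 60 cyc/mm (plus its
    0-60 cyc/mm area).  Longitudinal chromatic shifts are on-axis
    quantities, reported once per pupil.  Per-cell failures are recorded as
    NaN rows, not raised.

    The OPD grid scales with pupil diameter (``psf_grid`` at 2 mm) so the
    pupil phase stays resolved; when the steepest OPD step still exceeds
    ``grad_limit`` waves/pixel the FFT MTF of that cell is replaced by the
    ray-based geometric MTF (noted in the row), the appropriate estimator
    in the many-wave aberration regime.
    """
    rows = []

    def _add(field, pupil, metric, value, note=""):
        rows.append({
            "eye_id": eye.eye_id, "epoch": eye.epoch, "field_deg": field,
            "pupil_mm": pupil, "metric": metric, "value": value,
            "wavelengths": "/".join(f"{w:g}" for w in wavelengths), "note": note,
        })

    for pupil in pupils:
        e = with_stop_diameter(eye, pupil)
        if refocus:
            e = refocus_for_epoch(e)
        grid_n = int(8 * round(psf_grid * max(1.0, pupil / 2.0) / 8))
        if with_lca:
            try:
                lca = longitudinal_chromatic_shift(e, wavelengths=wavelengths)
                for wl, dz in lca.items():
                    _add(0.0, pupil, f"lca_shift_mm_{wl:g}", dz)
            except Exception as err:  # pragma: no cover - defensive
                _add(0.0, pupil, "lca_shift_mm", np.nan, f"{type(err).__name__}: {err}")
        for field in fields:
            try:
                bundle = trace_bundle(e, field, wavelengths,
                                      PupilSampling(rings=spot_rings))
                _add(field, pupil, "rms_spot_um", spot_rms(bundle))
                cb = bundle.traces.get(WAVE_BLUE)
                cr = bundle.traces.get(WAVE_RED)
                if cb is not None and cr is not None:
                    tca = np.linalg.norm(cb.live_points.mean(axis=0)
                                         - cr.live_points.mean(axis=0)) * 1e3
                    _add(field, pupil, "tca_um", float(tca))
                maps = opd_maps(e, field, wavelengths, grid_n=grid_n)
                res = psf_strehl(maps, weights, pad=pad)
                _add(field, pupil, "strehl", res.strehl)
                green = min(maps, key=lambda m: abs(m.wavelength - WAVE_GREEN))
                _add(field, pupil, "strehl_green",
                     psf_strehl([green], pad=pad).strehl)
                max_grad = max(m.max_gradient for m in maps)
                if max_grad > grad_limit:
                    mtf = geometric_mtf_from_maps(maps)
                    method = "geometric"
                else:
                    mtf = mtf_curve(res)
                    method = "fft"
                _add(field, pupil, "mtf_mean_30cpm", mtf.mean_at(30.0), method)
                _add(field, pupil, "mtf_mean_60cpm", mtf.mean_at(60.0), method)
                _add(field, pupil, "mtf_auc60",
                     float(np.trapezoid(mtf.mean, mtf.freq)), method)
            except Exception as err:
                _add(field, pupil, "error", np.nan, f"{type(err).__name__}: {err}")
    return QualityReport(pd.DataFrame(rows))
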