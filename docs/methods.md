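# Methods

This note documents the model, the numerical choices, and the limits of
what the package's simulations can show.

## Eye model

An eye is an ordered stack: anterior cornea, posterior cornea, iris stop,
anterior lens, posterior lens, retina, with z = 0 at the anterior corneal
vertex and vertex positions CCT, CCT + T_AC (stop and anterior lens vertex
plane), + T_L, + T_V. T_AC is the *aqueous* depth (posterior corneal
vertex to anterior lens vertex), so the axial length is
CCT + T_AC + T_L + T_V (25.31 mm for the cohort-mean eye). All tilts and
decentrations are zero; corneal asymmetry is carried entirely by the
Zernike height maps.

Corneal surfaces are conicoids plus sixth-order Zernike height deviations
(28 OSA terms, µm, normalization radius 3 mm). Zernike terms are
polynomials and are evaluated by natural analytic extension for ρ > 1,
which is needed when oblique beams strike the 12-mm cornea outside the
6-mm fit zone; each traced bundle counts such rays (`outside_zone`) so a
user can judge how much extrapolated surface a configuration touches.
The alternative — reverting to the bare conic outside the zone — would
introduce a slope discontinuity and spurious ray scatter.

The crystalline lens is homogeneous (n_d = 1.42): its equivalent power
comes from Bennett's formula and its radii from Rozema's regressions, with
fixed Navarro-style asphericities (−3.13 anterior, −1.00 posterior). These
ingredients are mutually inconsistent by construction: the regressions
describe *real*, gradient-index lenses, so a homogeneous lens built from
them carries several diopters less power than the Bennett estimate (about
5.9 D at the cohort mean; the test suite documents a 0–11 D shortfall over
the physiological range). The assembled model eye is therefore a few
diopters off its nominal refraction. This is a property of the published
recipe, not a bug, and the focusing rules absorb it:

- **Pre-operative eyes** wear an ideal thin phase lens at the
  ophthalmic-standard 12-mm vertex distance. Its power is *optimized*
  (bounded golden-section search over ±12 D around the prescription −S,
  tolerance 1e-3 D) to minimize the on-axis green RMS spot — the model
  analogue of spectacles worn for best corrected acuity. A fixed −S
  spectacle would leave the model eye several diopters defocused and is
  still available via `power=`/`optimize=False`.
- **Post-operative eyes** are focused by shifting the retina axially,
  |Δ| ≤ 2 mm, minimizing the on-axis green RMS spot with a bounded scalar
  solver (tolerance 0.1 µm in Δ); the retinal curvature is unchanged. In
  the default synthetic cohort roughly 5% of eyes meet the bound (the
  generator samples vitreous length independently of corneal power, so the
  model refraction scatters more than a real post-surgical population);
  these eyes raise a `FocusBoundaryWarning` and stay slightly defocused.

The refraction-dependent retina follows the published regressions
(R_R = −12.815 − 0.045 S mm, Q_R = 0.26 + 0.022 S).

The corneal power P_C entering Bennett's formula is computed from the
record's own corneal geometry by the Gaussian thick-lens formula — this
reproduces the published group means (42.44 D pre, 37.84 D post) from the
published mean radii/thickness to ≤ 0.15 D and keeps every record
internally consistent.

## Ray tracing

Right-handed coordinates, z toward the retina; field angles tilt the
incoming collimated beam in the x–z (horizontal) meridian. Rays start on a
plane 5 mm before the first element with their optical path referenced to
the tilted plane wavefront (the launch OPL is the projection of the origin
onto the beam direction).

- **Intersection.** The conic base has a closed-form quadratic solution
  (stable root selection on the vertex branch); when a Zernike deviation is
  present the solution seeds a damped Newton iteration on the axial
  residual (tolerance 1e-9 mm, ≤ 50 steps, step clamp 1 mm). Normals come
  from the analytic sag gradient (the Zernike gradient is evaluated from
  coefficient-contracted polar polynomials, exact at ρ = 0).
- **Refraction.** Vector Snell; total internal reflection flags the ray.
  Bookkeeping guarantees launched = live + vignetted + missed + TIR.
- **Dispersion.** Two-term Cauchy n(λ) = A + B/λ², the unique minimal
  model fixed by n_d at 587.562 nm and the Abbe number via n_F − n_C at
  486.133/656.273 nm; valid 400–750 nm.
- **Ray aiming.** Entering rays are iteratively corrected (fixed point on
  the stop-plane landing error, ≤ 20 iterations, tolerance 0.1 µm) so the
  bundle fills the *physical* stop uniformly. The stop sits at the
  anterior lens vertex plane and its diameter equals the requested pupil
  diameter; the ~13% entrance-pupil magnification is deliberately not
  modeled. Aiming solutions seed the next wavelength's iteration.
- **Pupil sampling.** Hexapolar rings (6 by default, 127 rays) for
  geometric spots; an n×n Cartesian grid over the stop for OPD maps.

A paraxial y–nu solver (vertex radii only) provides first-order powers and
focal positions and serves as an independent oracle in the tests.

## Metrics

- **Spot RMS**: RMS radial distance of all live retina intersections (all
  wavelengths pooled, equal weights) about their pooled centroid, in the
  plane tangent to the retina vertex (curvature projection ignored;
  sub-µm at these field sizes).
- **LCA**: per-wavelength axial best-focus position (same solver contract
  as the focusing rule) minus the green position; reported in mm, with a
  diopter conversion helper.
- **TCA**: blue-minus-red bundle-centroid separation at the retina.
  Centroids (not chief rays) are used for robustness when surface
  irregularity vignettes the chief ray.
- **OPD maps**: OPD = chief OPL − ray OPL referred to a sphere centred on
  the chief-ray retina point with radius equal to the stop-centre-to-image
  distance; piston removed; units of waves at the trace wavelength. The
  image-side numerical aperture is measured from the steepest live ray.
- **PSF/Strehl**: per wavelength, PSF = |FFT(mask·exp(i2π OPD))|² on a
  zero-padded grid (pad ≥ 2, default 4 for the public API, 2 inside the
  batch evaluator), normalized to its own diffraction-limited peak, then
  interpolated onto the green wavelength's retina grid including the
  transverse chromatic offset of its chief point; the polychromatic PSF is
  the weighted sum (equal R/G/B thirds by default, configurable) and the
  Strehl ratio is its peak — exactly 1 for zero OPD. The on-axis
  polychromatic Strehl of even an aberration-free eye is ≈ 0.6 because
  human-eye LCA (≈ 0.9 D across 486–656 nm here) defocuses the outer
  wavelengths; the green-only Strehl (`strehl_green`) isolates
  monochromatic quality and is ≈ 0.99 for the spectacle-corrected mean
  pre-operative eye at a 2-mm pupil.
- **MTF**: |FFT| of the unit-sum polychromatic PSF, tangential (x) and
  sagittal (y) axis cuts, resampled to 0–60 cyc/mm, and their mean.

### Sampling adequacy and the geometric MTF fallback

An FFT PSF is only meaningful while the pupil phase is resolved: the
batch evaluator scales the OPD grid with pupil diameter (36 samples across
a 2-mm pupil → 108 across 6 mm) and computes the largest OPD step between
adjacent pupil samples. When that exceeds 0.5 waves/pixel — deeply
aberrated cells, e.g. a 6-mm pupil at 30° where the OPD spans tens of
waves — the FFT image field of view cannot contain the spot and the
discrete MTF acquires a spurious wrap-around floor. For those cells the
reported MTF switches to the ray-based geometric estimator (modulus of the
characteristic function of the pooled dense spot coordinates), the
appropriate estimator in the many-wave regime where diffraction is
negligible; each MTF row records which estimator produced it. Strehl
ratios are always FFT-based (the peak converges much faster than the MTF
shape; grid-doubling changes it < 0.5% at a 2-mm pupil).

## Synthetic cohort generator

The generator emulates the modeled study population; per-eye measured
topographies are replaced by draws that match the published group
statistics:

- **Initial myopia S**: uniform over −10.5 to −1.25 D, sampled by
  stratified (systematic) sampling with within-stratum jitter and
  shuffling — marginally uniform, with guaranteed even coverage of the
  myopia range and stable group sizes at n = 134.
- **Pre-operative parameters**: truncated Gaussians (±4 SD and physical
  bounds) at the published pre-operative means/SDs, independent of S.
- **Post-operative link**: post = µ_post + β_S(S − S̄) + κ(pre − µ_pre) + ε.
  κ and σ_ε are chosen per parameter; β_S is then *solved in closed form*
  from the published pre/post SDs and the S variance so the
  post-operative marginal mean and SD are reproduced exactly in
  expectation. Anterior radius, asphericity and high-order RMS get β_S < 0
  (more myopia → more flattening, more oblate, more irregular; the induced
  changes correlate with S at P ≪ 0.01), central thickness β_S > 0 (more
  ablation); the posterior cornea and anterior chamber depth change with
  no S dependence, matching the published non-correlations while still
  hitting the slightly different post-operative marginals. Residuals are
  re-drawn (conditioning on S and the pre value) until pairing constraints
  hold: post-operative anterior radius strictly larger, central thickness
  strictly smaller. Positivity truncation of RMS-valued marginals biases
  their means upward by ≲ 1.5% of an SD, well inside sampling error at
  n = 134.
- **Zernike patterns**: band RMS targets are distributed over isotropic
  random directions (6 low-order, 22 high-order terms); the post-operative
  pattern blends the pre-operative direction with a fresh one before
  rescaling, so surgery changes the aberration pattern, not just its
  magnitude. Astigmatism has no published distribution and is not
  modeled beyond the random low-order surface terms; records carry sphere
  only.
- Lens thickness, vitreous length, S and the retina are identical pre/post
  for each eye.

All draws flow from one `numpy` Generator seeded by the config; parameters
are consumed in sorted name order so configs survive JSON round trips with
bit-identical output.

### What the generator does not emulate

Real corneal topographies have structured (not isotropic) aberration
profiles; real post-LASIK high-order change is dominated by spherical
aberration and coma tied to the ablation profile; real vitreous length
correlates with refraction. Passing group-trend tests on this cohort shows
that the *optical engine* turns the published biometric shifts into the
published quality trends; it does not validate ablation-profile physics or
per-patient prediction.

## Evaluation protocol and problem sizes

The default grid is fields 0/10/20/30°, pupils 2/4/6 mm, wavelengths
656.273/587.562/486.133 nm, with refocusing per pupil (the spectacle power
or retina shift is re-solved at each pupil). The full default pipeline
(134 eyes × 2 epochs × 4 fields × 3 pupils) runs in about 14 minutes on
one CPU at default sampling. The test suite exercises the same protocol on
an 18-eye cohort (~2 minutes); the acceptance script reports generator
statistics at the full n = 134.

Group-level findings asserted on the seeded cohort: post-operative Strehl
and mean MTF decline monotonically in group mean across the field and
pupil grids (grid-marginal means; at the 6-mm pupil the per-cell MTF is
non-monotonic between fields because an astigmatic line focus lands near
the curved peripheral retina — a real feature of the model, visible in the
tangential/sagittal split); at 6 mm the high-myopia group's Strehl is below
the mild group's; at 2 mm pre- and post-operative group means agree within
20%; the post-operative red-to-blue focal span shrinks slightly as the
pupil opens while TCA stays within 15% across pupils.

## Known limitations

- Homogeneous lens: no gradient index, no accommodation, no age
  dependence; the documented power shortfall is absorbed by focusing.
- No element tilt or decentration; no Stiles–Crawford apodization; no
  neural transfer function; no polarization or Fresnel losses; diffraction
  enters only through the pupil-function PSF.
- The stop is the physical pupil; entrance-pupil magnification is not
  modeled, so "pupil diameter" means stop diameter throughout.
- Surgery is represented statistically (sampled post-operative corneas),
  not by ablation-profile physics.
- FFT MTF values below ~0.01 sit at the numerical floor of the estimator
  and should be read as "no contrast".
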