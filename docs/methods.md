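# Methods

## Scene model

The patient frame is right-handed and fixed to the supine patient: x
transverse (toward the patient's left), y longitudinal (cranial), z vertical
(anterior, away from the table).  The acetabular opening is an ideal circle
of radius `radius_mm` (default 24 mm, a 48 mm cup); under orthographic
projection neither the radius nor any translation affects a measured angle,
which is property-tested.

**Angle convention.** Cup orientation uses Murray's *radiographic*
definitions taken relative to the coronal plane of the pelvis at natural
tilt: anteversion A is the angle between the acetabular axis and the coronal
plane, inclination I the angle between the coronal-plane projection of the
axis and the longitudinal axis.  For a right cup the axis is
n(A, I) = (cos A sin I, −cos A cos I, sin A); a left cup is the exact mirror
across the sagittal plane.  This convention was chosen because the
measurement being modelled is radiographic, and because it has a strong
internal consistency property: with the standard 45° beam and a 45°-inclined
cup, the film measurement at natural tilt equals the set anteversion
*exactly* (see below), matching the near-identity 60°-row of the published
grid.  Note the convention's degenerate pole: at A = I = 0 the axis is
longitudinal, not anterior.

**Pelvic tilt.** Tilt is a pure sagittal rotation: the rim rotates about the
transverse axis through the cup centre by (PT − 60)°, the sign fixed so that
increasing PT (posterior tilt) decreases the measured version, the direction
shown by the published grid.  No coupling with pelvic obliquity or axial
rotation is modelled.

## Film formation and measurement

The beam is horizontal at 45° to the long axis (configurable); the film is
perpendicular to the beam and contains the vertical axis, so film
coordinates are (u, v) with v the room vertical.  Projection is
orthographic: the published simulation used screenshots of a 3-D scene and
explicitly could not reproduce divergent-beam edge magnification, so
perspective is out of scope here too.

The projected rim is an exact ellipse.  It is recovered by second-moment
eigen-decomposition: for a full period of equally spaced circle samples the
covariance of the image points is exactly M Mᵀ/2 (M the 2×3 plane-to-film
map restricted to the rim plane), so the semi-axes (√(2λ)) and axis
directions are exact up to float rounding for any sample count ≥ 3 — the
default 256 points and the 128/512 variants agree to well below 1e−6°.
Equivalence with an algebraic conic fit and with the closed-form singular
values is tested.

The Woo–Morrey version angle is the angle between the ellipse major axis and
the film vertical, signed (anteversion positive), reported in (−90°, 90°]
with ties at ±90° reported as +90°.  A circular projection (axis ratio
within 1e−9 of 1) has no rim line; measurement raises a degenerate-input
error.  Since the image minor axis lies along the film projection of the rim
normal, the measurement has the closed form

    tan(VA_m) = n_z′ / (n′ · u),

with n′ the tilted rim normal — at natural tilt this reduces to
tan(VA_m) = tan A / sin(I + β), hence the exact identity at I = β = 45°.
The test suite uses this closed form, derived independently of the
point-sampling pipeline, as the projection oracle (1e−6° over an
anteversion × inclination × tilt grid).

**Observer noise** is additive Gaussian on the final angle (SD in degrees,
default 0), the simplest model consistent with the ~1° scatter of the
published grid's residuals; no structured reader bias is modelled.

## Regression and correction

The error regression pools all grid cells: OLS of (measured − actual) on
(PT − 60).  On the packaged grid this gives slope −0.7579, intercept −0.133,
R² 0.9951, |r| 0.9975 — the published −0.76 / −0.13 / 0.995 / 0.998.

The intercept model regresses per-column y-intercepts b on actual VA.  By
default each column's b comes from its own OLS line of measured VA on PT
(free slopes); this is the derivation that reproduces the published
intercept equation essentially exactly (0.9925, 45.4898 vs the printed 0.99,
45.49).  The single-common-slope variant (b = mean(measured) −
s·mean(PT) with s the pooled slope) is available via `common_slope=`; on the
same grid it lands at (1.0143, 45.054), visibly off the published
coefficients, which is why it is not the default.

The forward model is VA_m = −tilt·PT + va_coef·VA + offset (the printed
forward equation's positive tilt sign contradicts both the grid's trend and
the fitted slope; the negative sign makes the published correction the exact
algebraic inverse, verified to 1e−12).  The canonical `CorrectionModel`
carries the published (0.76, 0.99, 45.49); refits from any sweep are
separate instances and never silently substituted.

## Agreement statistics

ICC uses the two-way random-effects, absolute-agreement, single-measure
form: ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n), with the
McGraw–Wong F-based 95% interval (Satterthwaite degrees of freedom) and the
F = MSR/MSE test of ICC = 0.  The average-measure form ICC(2,k) is behind a
flag.  The implementation is cross-checked in tests against an explicit
sum-of-squares oracle (1e−10) and against `pingouin.intraclass_corr`.

## Synthetic cohort

The cohort emulates a 50-patient CL-vs-CT comparison.  Per patient:
true VA ~ N(15°, 5°) (safe-zone centred), inclination ~ N(45°, 5°),
CL-session tilt ~ N(60°, 8°) (contralateral hip flexion), CT-session tilt ~
N(60°, 4°), angle-reading noise 1.5°, film tilt-reading noise 2.0°, CT
noise 0.5° (CT treated as gold standard).  None of these dispersions are
published quantities; they are modelling assumptions.  The CL value comes
from the full geometric simulator at the patient's true tilt plus noise;
the corrected value applies the canonical published formula at the
*measured* tilt; the unadjusted CT reference is truth plus CT noise; the
tilt-adjusted reference is the simulator evaluated at the measured CL tilt
plus CT noise (the CT model re-posed to the film's tilt).  Out-of-domain or
degenerate draws are redrawn; more than 10% redraws is an error.

`run_validation` reports three ICCs: raw-vs-adjusted (high — both sides
carry the same distortion), corrected-vs-unadjusted (high — the formula
removes the distortion), raw-vs-unadjusted (poor — the tilt effect in
full).  What passing cohort tests show is internal consistency of the
generating model and the correction, not clinical performance: real
readers, anatomy and posture are not modelled, and the clinical ICC values
depend on a tilt distribution that is not published.

## Known gaps between the ideal geometry and the published grid

The ideal orthographic circle projection, under exactly the stated study
conditions (Murray convention, beam 45°, inclination 45°, natural tilt 60°),
is *more* curved and *shallower* in tilt than the published hand-measured
grid: its pooled slope is −0.676 (local slope −0.707 at natural tilt)
against the published −0.76, and individual low-tilt cells differ by up to
~4.6° (e.g. simulated 40.92° vs printed 44.59° at PT 20, VA 15).  A
diagnostic scan shows an effective beam of 55–60° (or inclination ≈ 40°)
would reproduce the grid substantially better, but those values contradict
the stated setup, so the defaults follow the stated setup and the gap is
reported rather than tuned away.  Consequences worth knowing:

- regenerated sweeps reproduce the direction, approximate linearity
  (R² ≈ 0.998) and rough size of the tilt effect, not its printed slope;
- applying the published correction to simulator output leaves a small
  systematic residual (≈ 0.06° per degree of tilt difference);
- on the published grid itself, the published correction leaves two cells
  beyond 3° even after excluding the two flagged PT = 55 anomalies — cells
  (70,15) = 3.59 and (75,10) = 2.31 break their columns' trends and look
  like further transcription slips, but are kept verbatim.

Similarly, under the default cohort noise levels the corrected-vs-reference
ICC concentrates near 0.89–0.91 (subject variance 25 deg² against ≈ 2.6 deg²
of residual error variance): clearly and stably above the uncorrected
comparison (≈ 0.55–0.60), which is the contrast the validation is designed
to show, but not above 0.95 — that would require either wider true-VA
dispersion or smaller reading noise than the defaults assume.

## Numerical notes

- Angles are degrees at every interface; radians only internally.
- Ellipse fitting: eigenvalues are clipped at 0 before the square root;
  collinear input is a valid degenerate ellipse (semi-minor 0); coincident
  points are rejected.
- OLS via `scipy.stats.linregress`; rotations via
  `scipy.spatial.transform.Rotation`; all randomness through
  `numpy.random.default_rng` with explicit seeds threaded through every
  API and CLI surface.
- CSVs round-trip at full float precision (`%.17g` out,
  `float_precision="round_trip"` in); the packaged grid is integrity-checked
  by SHA-256 at load.
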