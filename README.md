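# cupsim

Simulation and correction of pelvic-tilt error in acetabular-cup version
measurement on cross-table lateral (CL) radiographs.

After total hip arthroplasty the cup's version angle (VA) is commonly read
off a CL film with the Woo–Morrey method: the angle between a line along the
projected cup rim and a line perpendicular to the horizontal plane.  The
film, however, is taken with the contralateral hip flexed, which tips the
pelvis sagittally away from its natural supine tilt (PT ≈ 60°, the angle of
the first-sacral-midpoint-to-pubic-symphysis line to the vertical), and
every degree of tilt distorts the measured angle.  `cupsim` is for
researchers and engineers studying this measurement chain: it provides

- a 3-D geometric simulator of the CL film — the cup opening as a circle
  oriented by radiographic anteversion/inclination, tilted with the pelvis,
  orthographically projected along a horizontal beam at 45° to the body's
  long axis, and measured on the resulting ellipse;
- the published 13 × 9 measurement grid (PT 20–80°, VA 0–40°) as a
  checksummed fixture, plus regeneration of that sweep from the simulator;
- the error regression and correction formula.  Pooled over the grid the
  measurement error is linear in tilt,

      VA_m − VA = s·(PT − 60) + c,      s ≈ −0.76 °/°,  R² ≈ 0.995,

  and combining the per-column intercepts b = 0.99·VA + 45.49 gives the
  correction

      VA = (0.76·PT + VA_m − 45.49) / 0.99 ;

- two-way random-effects absolute-agreement ICC(2,1) with F-based
  confidence intervals, and a synthetic 50-patient CL-vs-CT cohort that
  exercises the corrected-vs-uncorrected agreement contrast end to end.

## Worked example

Correct a film measurement of 40.44° taken at a measured pelvic tilt of 40°:

```
$ cupsim correct --pt 40 --measured 40.44
{
  "pelvic_tilt_deg": 40.0,
  "measured_va_deg": 40.44,
  "corrected_va_deg": 25.60606060606061
}
```

The cell (PT = 40, VA_m = 40.44) of the published grid belongs to an actual
anteversion of 25°: the correction recovers it to within 0.6°.  The same
formula can be re-derived from the packaged grid:

```
$ cupsim derive --fixture
{
  "slope": -0.7578962148962152,
  "intercept": -0.13315018315018712,
  "r": -0.9975258893923833,
  "r2": 0.9950579000080653,
  "n": 117,
  "va_coefficient": 0.9925395604395606,
  "offset_deg": 45.4898315018315,
  "tilt_coefficient": 0.7578962148962152
}
```

i.e. each degree of pelvic tilt shifts the measured version by −0.76°, and
the per-column intercepts reproduce the published coefficients (0.99,
45.49).  A purely geometric film of the same scene:

```
$ cupsim project --anteversion 25 --pelvic-tilt 40
{
  "measured_va_deg": 38.429694763087184,
  "semi_major_mm": 23.999999999999993,
  "semi_minor_mm": 3.1088768856031233,
  "major_axis_deg": -38.429694763087184
}
```

— the ideal projection of a 25°-anteverted cup at PT 40 reads 38.4°, a
+13.4° tilt artefact of the same sign and similar size as the +15.4° in the
published grid.  Other subcommands: `sweep` (simulate a PT × VA grid),
`icc` (agreement of a ratings CSV), `cohort`/`validate` (synthetic
CL-vs-CT cohort and its three-way ICC report).

The library mirrors the CLI: `make_rim`, `apply_pelvic_tilt`, `project`,
`fit_ellipse`, `measure_va`, `simulate_cl_measurement`, `run_sweep`,
`fit_error_regression`, `fit_intercept_model`, `correct_va`,
`icc_two_way_random_absolute`, `generate_cohort`, `run_validation`.

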