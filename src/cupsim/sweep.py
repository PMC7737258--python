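"""Tilt-versus-version sweep tables, error regression and correction formula.

The central empirical object is the sweep table: measured version angle over
a grid of pelvic tilts (PT) and set ("actual") anteversions (VA).  Two
sources exist: the geometric simulator (:func:`run_sweep`) and the packaged
transcription of the published 13x9 measurement grid
(:func:`load_table2_fixture`).

From a sweep table three fits are derived:

* the pooled error regression of ``measured - actual`` on ``PT - natural``
  (one line through all cells; slope approx -0.76 deg/deg on the published
  grid),
* the intercept model: the y-intercept ``b`` of each actual-VA column's
  measured-vs-PT line, regressed on actual VA (``b = 0.99 VA + 45.49`` on
  the published grid),
* the correction model combining both, whose inverse converts a film
  measurement made at pelvic tilt PT back to the anteversion that would be
  observed at natural tilt:

      VA = (tilt_coeff * PT + VA_measured - offset) / va_coeff .

The published forward equation is printed with a positive tilt coefficient,
which contradicts both the falling trend of the measurement grid and the
negative fitted slope; the forward model here is
``VA_m = -tilt_coeff * PT + va_coeff * VA + offset`` so that the correction
above is its exact algebraic inverse.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, FixtureIntegrityError, ParameterError
from .geometry import CupOrientation, PelvisPose
from .projection import BeamConfig, simulate_cl_measurement

__all__ = [
    "SweepTable",
    "LinearErrorModel",
    "InterceptModel",
    "CorrectionModel",
    "PUBLISHED_CORRECTION",
    "TABLE2_SHA256",
    "run_sweep",
    "load_table2_fixture",
    "fit_error_regression",
    "fit_intercept_model",
    "derive_correction",
    "correct_va",
    "predict_measurement",
]

#: checksum of the packaged 13x9 measurement-grid transcription
TABLE2_SHA256 = "c803cb1b1befadfc51fd06f2fe924a18e75d78e90d525c22f1ab080998b08d56"

SWEEP_COLUMNS = ("pelvic_tilt_deg", "actual_va_deg", "measured_va_deg")


@dataclass
class SweepTable:
    """Grid of (pelvic tilt, actual VA, measured VA) triples plus metadata."""

    data: pd.DataFrame
    inclination_deg: float = 45.0
    noise_sd: float = 0.0
    seed: int | None = None
    source: str = "simulator"
    natural_tilt_deg: float = 60.0

    def __post_init__(self) -> None:
        missing = [c for c in SWEEP_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParameterError(f"sweep table missing columns {missing}")
        self.validate()

    @property
    def pt_values(self) -> np.ndarray:
        return np.sort(self.data["pelvic_tilt_deg"].unique())

    @property
    def va_values(self) -> np.ndarray:
        return np.sort(self.data["actual_va_deg"].unique())

    def validate(self) -> None:
        """Check grid completeness (every PT x VA cell exactly once)."""
        n_expected = len(self.pt_values) * len(self.va_values)
        cells = self.data[["pelvic_tilt_deg", "actual_va_deg"]]
        if len(self.data) != n_expected or cells.duplicated().any():
            raise ParameterError(
                f"incomplete or duplicated grid: {len(self.data)} rows for "
                f"{n_expected} cells"
            )
        if self.source == "fixture":
            if not (
                np.array_equal(self.pt_values, np.arange(20, 85, 5))
                and np.array_equal(self.va_values, np.arange(0, 45, 5))
            ):
                raise ParameterError("fixture table must be the 13x9 grid "
                                     "(PT 20-80 step 5, VA 0-40 step 5)")

    def cell(self, pelvic_tilt: float, actual_va: float) -> float:
        """Measured VA of one grid cell."""
        m = self.data[
            (self.data["pelvic_tilt_deg"] == pelvic_tilt)
            & (self.data["actual_va_deg"] == actual_va)
        ]
        if len(m) != 1:
            raise KeyError(f"no unique cell (PT={pelvic_tilt}, VA={actual_va})")
        return float(m["measured_va_deg"].iloc[0])


@dataclass(frozen=True)
class LinearErrorModel:
    """Pooled OLS of measurement error on pelvic-tilt difference."""

    slope: float
    intercept_deg: float
    pearson_r: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ParameterError("pearson_r out of [-1, 1]")


@dataclass(frozen=True)
class InterceptModel:
    """Regression of per-column y-intercepts ``b`` on actual VA.

    ``intercepts`` maps each actual VA to its column's y-intercept (the
    value of the measured-vs-PT line at PT = 0).  ``free_slope`` records
    whether each column's line used its own OLS slope (the derivation that
    reproduces the published coefficients) or one common pooled slope.
    """

    va_coefficient: float
    offset_deg: float
    intercepts: dict[float, float] = field(default_factory=dict)
    free_slope: bool = True

    def monotone(self) -> bool:
        b = [self.intercepts[v] for v in sorted(self.intercepts)]
        return bool(np.all(np.diff(b) > 0))


@dataclass(frozen=True)
class CorrectionModel:
    """Coefficients of the forward/inverse tilt-correction formula.

    Forward:  VA_m = -tilt_coefficient * PT + va_coefficient * VA + offset_deg
    Inverse:  VA   = (tilt_coefficient * PT + VA_m - offset_deg) / va_coefficient
    """

    tilt_coefficient: float = 0.76
    va_coefficient: float = 0.99
    offset_deg: float = 45.49

    def __post_init__(self) -> None:
        vals = (self.tilt_coefficient, self.va_coefficient, self.offset_deg)
        if not all(np.isfinite(vals)):
            raise ParameterError("correction coefficients must be finite")
        if self.va_coefficient == 0:
            raise ParameterError("va_coefficient must be nonzero")

    def correct(self, pt: float, measured_va: float) -> float:
        return (self.tilt_coefficient * pt + measured_va - self.offset_deg) / (
            self.va_coefficient
        )

    def predict(self, pt: float, actual_va: float) -> float:
        return (
            self.va_coefficient * actual_va
            + self.offset_deg
            - self.tilt_coefficient * pt
        )


#: the published coefficients; refits from any sweep are separate instances
PUBLISHED_CORRECTION = CorrectionModel()


def run_sweep(
    pt_values,
    va_values,
    inclination: float = 45.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    beam: BeamConfig | None = None,
    natural_tilt: float = 60.0,
    radius_mm: float = 24.0,
    n_points: int = 256,
) -> SweepTable:
    """Simulate one cross-table lateral measurement per grid cell."""
    pt_values = np.asarray(list(pt_values), dtype=float)
    va_values = np.asarray(list(va_values), dtype=float)
    if pt_values.size == 0 or va_values.size == 0:
        raise ParameterError("pt_values and va_values must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for pt in pt_values:
        pose = PelvisPose(pelvic_tilt_deg=pt, natural_tilt_deg=natural_tilt)
        for va in va_values:
            cup = CupOrientation(
                anteversion_deg=va, inclination_deg=inclination, radius_mm=radius_mm
            )
            m = simulate_cl_measurement(
                cup, pose, beam=beam, noise_sd=noise_sd, rng=rng, n_points=n_points
            )
            rows.append((pt, va, m))
    df = pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))
    return SweepTable(
        data=df,
        inclination_deg=inclination,
        noise_sd=noise_sd,
        seed=seed,
        source="simulator",
        natural_tilt_deg=natural_tilt,
    )


def load_table2_fixture() -> SweepTable:
    """Load the packaged 13x9 published measurement grid (verbatim).

    The file's SHA-256 is checked against the recorded value; any alteration
    raises :class:`FixtureIntegrityError`.  Known oddities are preserved
    as printed, including the two off-trend cells in the PT = 55 row
    (VA 0 and VA 5).
    """
    ref = resources.files("cupsim").joinpath("data/table2.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE2_SHA256:
        raise FixtureIntegrityError(
            f"fixture data/table2.csv checksum mismatch: {digest}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    return SweepTable(data=df, inclination_deg=45.0, noise_sd=float("nan"),
                      seed=None, source="fixture")


def fit_error_regression(
    table: SweepTable, natural_tilt: float | None = None
) -> LinearErrorModel:
    """Pooled OLS of y = measured - actual on x = PT - natural, over all cells."""
    if natural_tilt is None:
        natural_tilt = table.natural_tilt_deg
    if len(table.pt_values) < 3:
        raise FitError("need at least 3 distinct pelvic-tilt levels")
    x = table.data["pelvic_tilt_deg"].to_numpy(dtype=float) - natural_tilt
    y = (
        table.data["measured_va_deg"].to_numpy(dtype=float)
        - table.data["actual_va_deg"].to_numpy(dtype=float)
    )
    if np.ptp(x) == 0:
        raise FitError("pelvic tilt has zero variance; cannot regress")
    res = stats.linregress(x, y)
    return LinearErrorModel(
        slope=float(res.slope),
        intercept_deg=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def fit_intercept_model(
    table: SweepTable, common_slope: float | None = None
) -> InterceptModel:
    """Fit per-column y-intercepts and regress them on actual VA.

    By default each actual-VA column gets its own OLS line of measured VA on
    PT and contributes its y-intercept ``b`` — the derivation that reproduces
    the published intercept equation.  Passing ``common_slope`` instead fixes
    every column's slope to that pooled value, so
    ``b = mean(measured) - common_slope * mean(PT)`` (sensitivity variant).
    """
    va_levels = table.va_values
    if len(va_levels) < 2:
        raise FitError("need at least 2 actual-VA columns")
    if len(table.pt_values) < 2:
        raise FitError("need at least 2 pelvic-tilt levels")
    intercepts: dict[float, float] = {}
    for va in va_levels:
        col = table.data[table.data["actual_va_deg"] == va]
        pt = col["pelvic_tilt_deg"].to_numpy(dtype=float)
        m = col["measured_va_deg"].to_numpy(dtype=float)
        if common_slope is None:
            b = float(stats.linregress(pt, m).intercept)
        else:
            b = float(m.mean() - common_slope * pt.mean())
        intercepts[float(va)] = b
    res = stats.linregress(
        np.array(sorted(intercepts)), np.array([intercepts[v] for v in sorted(intercepts)])
    )
    return InterceptModel(
        va_coefficient=float(res.slope),
        offset_deg=float(res.intercept),
        intercepts=intercepts,
        free_slope=common_slope is None,
    )


def derive_correction(
    table: SweepTable, common_slope_intercepts: bool = False
) -> CorrectionModel:
    """Fit a full correction model from a sweep table.

    The tilt coefficient is the magnitude of the pooled error slope; the VA
    coefficient and offset come from the intercept model (free per-column
    slopes unless ``common_slope_intercepts``).
    """
    err = fit_error_regression(table)
    icpt = fit_intercept_model(
        table, common_slope=err.slope if common_slope_intercepts else None
    )
    return CorrectionModel(
        tilt_coefficient=abs(err.slope),
        va_coefficient=icpt.va_coefficient,
        offset_deg=icpt.offset_deg,
    )


def correct_va(model: CorrectionModel, pt: float, measured_va: float) -> float:
    """Anteversion at natural tilt implied by a film measurement at tilt ``pt``."""
    return model.correct(pt, measured_va)


def predict_measurement(model: CorrectionModel, pt: float, actual_va: float) -> float:
    """Forward-predicted film measurement; exact inverse of :func:`correct_va`."""
    return model.predict(pt, actual_va)
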