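"""Synthetic postoperative cohort for the film-versus-CT agreement contrast.

Each synthetic patient has a true cup anteversion and inclination, a pelvic
tilt during the cross-table lateral (CL) exposure (perturbed away from the
natural 60 deg by contralateral hip flexion), and a pelvic tilt during the
CT session.  The CL version measurement is produced by the full geometric
simulator at the patient's true CL tilt plus Gaussian observer noise; the
pelvic tilt itself is measured on a lateral film with its own noise.  Three
reference/derived values follow:

* ``va_ct_reference_deg`` — the CT value without tilt adjustment: true
  anteversion plus small CT measurement noise (CT at neutral position is
  treated as near-truth),
* ``va_ct_adjusted_deg`` — the CT model re-tilted to the measured CL tilt
  and read through the same projection geometry (noiseless simulator at the
  measured tilt) plus CT noise: the tilt-matched comparator,
* ``va_corrected_deg`` — the CL measurement passed through the canonical
  published correction formula with the measured tilt.

``run_validation`` mirrors the clinical comparison with three
absolute-agreement ICCs: raw CL vs tilt-adjusted CT (high because both carry
the same distortion), corrected CL vs unadjusted CT (high because the
formula removes the distortion), and raw CL vs unadjusted CT (poor — the
tilt effect in full).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import DegenerateMeasurementError, ParameterError
from .geometry import CupOrientation, PelvisPose
from .projection import BeamConfig, simulate_cl_measurement
from .agreement import ICCResult, icc_two_way_random_absolute
from .sweep import PUBLISHED_CORRECTION, CorrectionModel

__all__ = [
    "CohortParams",
    "COHORT_COLUMNS",
    "generate_cohort",
    "run_validation",
    "ValidationReport",
]

COHORT_COLUMNS = (
    "patient_id",
    "true_va_deg",
    "inclination_deg",
    "pt_cl_true_deg",
    "pt_cl_measured_deg",
    "pt_ct_true_deg",
    "va_cl_measured_deg",
    "va_ct_reference_deg",
    "va_ct_adjusted_deg",
    "va_corrected_deg",
)


@dataclass(frozen=True)
class CohortParams:
    """Generating distributions of the synthetic cohort (degrees).

    Defaults: anteversion centred on the 15 deg safe-zone target (SD 5),
    inclination centred on 45 (SD 5), CL-session tilt Normal(60, 8) — the
    flexed contralateral hip perturbs the pelvis well away from natural —
    CT-session tilt Normal(60, 4), observer noise 1.5 on angles and 2.0 on
    the film-measured tilt, and 0.5 of CT measurement noise.
    """

    n_patients: int = 50
    true_va_mean: float = 15.0
    true_va_sd: float = 5.0
    inclination_mean: float = 45.0
    inclination_sd: float = 5.0
    pt_cl_mean: float = 60.0
    pt_cl_sd: float = 8.0
    pt_ct_mean: float = 60.0
    pt_ct_sd: float = 4.0
    angle_noise_sd: float = 1.5
    pt_noise_sd: float = 2.0
    ct_noise_sd: float = 0.5
    natural_tilt_deg: float = 60.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ParameterError("n_patients must be >= 3")
        for name in (
            "true_va_sd", "inclination_sd", "pt_cl_sd", "pt_ct_sd",
            "angle_noise_sd", "pt_noise_sd", "ct_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def _noiseless_cl(va: float, incl: float, pt: float, natural: float) -> float:
    cup = CupOrientation(anteversion_deg=va, inclination_deg=incl)
    pose = PelvisPose(pelvic_tilt_deg=pt, natural_tilt_deg=natural)
    return simulate_cl_measurement(cup, pose, beam=BeamConfig())


def generate_cohort(
    params: CohortParams, model: CorrectionModel = PUBLISHED_CORRECTION
) -> pd.DataFrame:
    """Draw a reproducible cohort; one row per patient (see COHORT_COLUMNS).

    Draws whose geometry is out of range (anteversion outside (-90, 90),
    inclination outside [0, 90], tilt outside (0, 180)) or whose projection
    is degenerate are redrawn; more than 10% redraws raises
    :class:`ParameterError`.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    redraws = 0
    max_redraws = max(5, int(np.ceil(0.10 * params.n_patients)))
    pid = 0
    while pid < params.n_patients:
        va = rng.normal(params.true_va_mean, params.true_va_sd)
        incl = rng.normal(params.inclination_mean, params.inclination_sd)
        pt_cl = rng.normal(params.pt_cl_mean, params.pt_cl_sd)
        pt_ct = rng.normal(params.pt_ct_mean, params.pt_ct_sd)
        pt_cl_meas = pt_cl + rng.normal(0.0, params.pt_noise_sd)
        try:
            va_cl = _noiseless_cl(va, incl, pt_cl, params.natural_tilt_deg)
            va_adj = _noiseless_cl(va, incl, pt_cl_meas, params.natural_tilt_deg)
        except (ParameterError, DegenerateMeasurementError):
            redraws += 1
            if redraws > max_redraws:
                raise ParameterError(
                    f"more than 10% of draws degenerate ({redraws}); "
                    "check cohort distributions"
                )
            continue
        va_cl += rng.normal(0.0, params.angle_noise_sd)
        va_ref = va + rng.normal(0.0, params.ct_noise_sd)
        va_adj += rng.normal(0.0, params.ct_noise_sd)
        rows.append(
            (
                pid, va, incl, pt_cl, pt_cl_meas, pt_ct,
                va_cl, va_ref, va_adj, model.correct(pt_cl_meas, va_cl),
            )
        )
        pid += 1
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    df.attrs["params"] = asdict(params)
    df.attrs["redraws"] = redraws
    return df


@dataclass(frozen=True)
class ValidationReport:
    """The three agreement comparisons, mirroring the clinical validation."""

    measured_vs_adjusted: ICCResult
    corrected_vs_reference: ICCResult
    measured_vs_reference: ICCResult

    def as_dict(self) -> dict:
        def pack(r: ICCResult) -> dict:
            return {
                "icc": r.icc, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "p": r.p_value,
            }

        return {
            "measured_vs_adjusted": pack(self.measured_vs_adjusted),
            "corrected_vs_reference": pack(self.corrected_vs_reference),
            "measured_vs_reference": pack(self.measured_vs_reference),
        }


def run_validation(cohort: pd.DataFrame) -> ValidationReport:
    """Compute the three absolute-agreement ICCs on a generated cohort."""
    if len(cohort) < 3:
        raise ParameterError("cohort must have at least 3 patients")

    def icc(col_a: str, col_b: str) -> ICCResult:
        m = cohort[[col_a, col_b]].to_numpy(dtype=float)
        return icc_two_way_random_absolute(m)

    return ValidationReport(
        measured_vs_adjusted=icc("va_cl_measured_deg", "va_ct_adjusted_deg"),
        corrected_vs_reference=icc("va_corrected_deg", "va_ct_reference_deg"),
        measured_vs_reference=icc("va_cl_measured_deg", "va_ct_reference_deg"),
    )
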