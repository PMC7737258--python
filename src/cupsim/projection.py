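"""Cross-table lateral projection and Woo-Morrey version measurement.

The radiographic setup: the patient is supine, the beam is horizontal at a
configurable angle to the body's long axis (45 deg for the standard
cross-table lateral film), and the film is perpendicular to the beam with its
in-plane vertical equal to the room vertical.  Projection is orthographic —
the simulation reproduces screenshots of a 3-D scene, so divergent-beam
magnification is deliberately absent.

On the film the circular cup rim appears as an ellipse.  The Woo-Morrey
version angle is the angle between the line along the rim (the ellipse's
major axis) and the line perpendicular to the horizontal plane (the film
vertical), signed so that anteversion is positive and retroversion negative,
reported in (-90, 90] with ties at +/-90 mapped to +90.

With the beam at 45 deg and the cup inclined at 45 deg the measurement is
*exact* at natural pelvic tilt (the apparent angle equals the set
anteversion); away from natural tilt it is distorted, which is precisely the
effect the downstream correction formula removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMeasurementError, ParameterError
from .geometry import (
    CupOrientation,
    PelvisPose,
    RimPointSet,
    apply_pelvic_tilt,
    make_rim,
)

__all__ = [
    "BeamConfig",
    "ProjectedRim",
    "EllipseGeometry",
    "project",
    "fit_ellipse",
    "measure_va",
    "simulate_cl_measurement",
]

#: relative axis-ratio threshold below which the projected rim is treated as
#: a circle and the version angle as undefined
_CIRCULAR_TOL = 1e-9


@dataclass(frozen=True)
class BeamConfig:
    """Horizontal beam geometry of the cross-table lateral film.

    ``beam_to_long_axis_deg`` is the angle between the beam and the
    longitudinal axis, in (0, 180); the standard technique uses 45.  ``side``
    mirrors the whole setup across the sagittal plane for left-hip films.
    The film plane is perpendicular to the beam and contains the vertical
    axis; its 2-D basis is (u, v) with v the room vertical.
    """

    beam_to_long_axis_deg: float = 45.0
    side: str = "right"

    def __post_init__(self) -> None:
        if not 0.0 < self.beam_to_long_axis_deg < 180.0:
            raise ParameterError(
                "beam_to_long_axis_deg must be in (0, 180), got "
                f"{self.beam_to_long_axis_deg}"
            )
        if self.side not in ("right", "left"):
            raise ParameterError(f"side must be 'right' or 'left', got {self.side!r}")

    @property
    def mirror_sign(self) -> float:
        return 1.0 if self.side == "right" else -1.0

    def direction(self) -> np.ndarray:
        """Unit beam direction (horizontal, from source toward the film)."""
        b = np.radians(self.beam_to_long_axis_deg)
        return np.array([self.mirror_sign * np.sin(b), np.cos(b), 0.0])

    def film_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal film basis (u, v); v is the vertical axis."""
        d = self.direction()
        v = np.array([0.0, 0.0, 1.0])
        u = np.cross(d, v)
        u /= np.linalg.norm(u)
        return u, v


@dataclass(frozen=True)
class ProjectedRim:
    """Rim sample projected onto the film, in the film's (u, v) basis (mm)."""

    points: np.ndarray  # (n, 2)
    beam: BeamConfig
    source: RimPointSet | None = None

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class EllipseGeometry:
    """Centre, semi-axes and major-axis direction of a film ellipse.

    ``major_axis`` is a unit 2-D vector; it and its negation are equivalent,
    and the stored representative has a non-negative v component.
    """

    center: np.ndarray
    semi_major: float
    semi_minor: float
    major_axis: np.ndarray

    @property
    def axis_ratio(self) -> float:
        return self.semi_minor / self.semi_major if self.semi_major > 0 else 1.0


def project(rim: RimPointSet, beam: BeamConfig | None = None) -> ProjectedRim:
    """Orthographically project the rim along the beam onto the film.

    Each 3-D point maps to ``(p . u, p . v)``; the second film coordinate is
    the vertical axis, so "up" on the film is "up" in the room.
    """
    if beam is None:
        beam = BeamConfig(side=rim.side)
    u, v = beam.film_basis()
    pts = np.column_stack((rim.points @ u, rim.points @ v))
    return ProjectedRim(points=pts, beam=beam, source=rim)


def fit_ellipse(proj: ProjectedRim) -> EllipseGeometry:
    """Recover the exact ellipse parameters by second-moment decomposition.

    For a full period of equally spaced circle samples the covariance of the
    projected points is exactly ``M M^T / 2`` with ``M`` the 2x3 plane-to-film
    map restricted to the rim plane, so its eigen-decomposition yields the
    true semi-axes (sqrt of twice the eigenvalues) and axis directions up to
    float rounding, independently of the sample count.

    Collinear input (edge-on rim) is a valid degenerate ellipse with
    ``semi_minor == 0``; coincident points are rejected.
    """
    pts = proj.points
    if pts.shape[0] < 8:
        raise ParameterError("ellipse fit requires at least 8 points")
    c = pts.mean(axis=0)
    q = pts - c
    cov = q.T @ q / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    semi_minor, semi_major = np.sqrt(2.0 * evals)
    if semi_major <= 0.0:
        raise ParameterError("all projected points coincide; no ellipse")
    major = evecs[:, 1]
    if major[1] < 0 or (major[1] == 0 and major[0] < 0):
        major = -major
    return EllipseGeometry(
        center=c, semi_major=float(semi_major), semi_minor=float(semi_minor),
        major_axis=major,
    )


def measure_va(proj: ProjectedRim) -> float:
    """Woo-Morrey version angle of the projected rim, in degrees.

    The angle between the ellipse major axis and the film vertical, signed so
    anteversion is positive, in (-90, 90].  A circular projection (axis ratio
    within ``1e-9`` of 1) has no defined rim line and raises
    :class:`DegenerateMeasurementError`.
    """
    ell = fit_ellipse(proj)
    if 1.0 - ell.axis_ratio < _CIRCULAR_TOL:
        raise DegenerateMeasurementError(
            "projected rim is circular; version angle undefined"
        )
    mu, mv = ell.major_axis
    angle = float(np.degrees(np.arctan2(-proj.beam.mirror_sign * mu, mv)))
    if angle == -90.0:  # tie at the range boundary: report +90
        angle = 90.0
    return angle


def simulate_cl_measurement(
    cup: CupOrientation,
    pose: PelvisPose,
    beam: BeamConfig | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    n_points: int = 256,
) -> float:
    """Full chain: rim -> pelvic tilt -> projection -> Woo-Morrey angle.

    Composes :func:`make_rim`, :func:`apply_pelvic_tilt`, :func:`project` and
    :func:`measure_va`, then adds Gaussian observer noise with standard
    deviation ``noise_sd`` degrees (0 = noiseless geometry).  ``rng`` may be
    a seed or a Generator; a fixed seed reproduces the call exactly.
    """
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if beam is None:
        beam = BeamConfig(side=cup.side)
    rim = apply_pelvic_tilt(make_rim(cup, n_points=n_points), pose)
    angle = measure_va(project(rim, beam))
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        angle += gen.normal(0.0, noise_sd)
    return angle
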