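"""Cup-rim geometry in a fixed patient coordinate frame.

The patient lies supine on the examination table.  The frame is right-handed:

* **x** — transverse axis, toward the patient's left (lateral+),
* **y** — longitudinal axis, toward the head (cranial+),
* **z** — vertical axis, away from the table (anterior+).

The acetabular cup opening is modelled as a circle of radius ``radius_mm``
whose plane normal is fixed by the *radiographic* anteversion/inclination
angles (Murray's definitions, taken relative to the coronal plane of the
pelvis at its natural supine tilt).  For a right-sided cup the outward
acetabular axis is

    n(A, I) = (cos A sin I,  -cos A cos I,  sin A)

so that anteversion ``A`` is the angle between the axis and the coronal
(table) plane, and inclination ``I`` is the angle between the coronal-plane
projection of the axis and the longitudinal axis.  A left-sided cup is the
mirror image across the sagittal plane (x -> -x).

Pelvic tilt is the sagittal-plane angle between the first-sacral-midpoint to
pubic-symphysis line and the vertical; its natural supine value is 60 deg.
Changing the tilt rotates the whole pelvis (and therefore the implanted cup)
about the transverse axis through the cup centre.  The rotation sign is fixed
so that *increasing* pelvic tilt *decreases* the downstream measured version
angle:

    posterior tilt (PT > 60 deg) rolls the cup opening away from the beam,
    foreshortening the apparent anteversion on the film.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParameterError

__all__ = [
    "CupOrientation",
    "PelvisPose",
    "RimPointSet",
    "rim_plane_normal",
    "make_rim",
    "apply_pelvic_tilt",
]

_SIDES = ("right", "left")


@dataclass(frozen=True)
class CupOrientation:
    """Radiographic orientation of the acetabular component.

    Parameters
    ----------
    anteversion_deg:
        Radiographic anteversion in degrees, in (-90, 90).  Positive values
        are anteversion, negative retroversion.
    inclination_deg:
        Radiographic inclination in degrees, in [0, 90].
    radius_mm:
        Rim radius in millimetres (> 0).  Under orthographic projection the
        radius never affects a measured angle; it is carried for geometry
        output only.
    side:
        ``"right"`` or ``"left"`` hip.  Left is the sagittal mirror of right.
    """

    anteversion_deg: float
    inclination_deg: float
    radius_mm: float = 24.0
    side: str = "right"

    def __post_init__(self) -> None:
        if not -90.0 < self.anteversion_deg < 90.0:
            raise ParameterError(
                f"anteversion_deg must be in (-90, 90), got {self.anteversion_deg}"
            )
        if not 0.0 <= self.inclination_deg <= 90.0:
            raise ParameterError(
                f"inclination_deg must be in [0, 90], got {self.inclination_deg}"
            )
        if not self.radius_mm > 0:
            raise ParameterError(f"radius_mm must be > 0, got {self.radius_mm}")
        if self.side not in _SIDES:
            raise ParameterError(f"side must be one of {_SIDES}, got {self.side!r}")


@dataclass(frozen=True)
class PelvisPose:
    """Sagittal pelvic tilt.

    ``pelvic_tilt_deg`` is the angle between the sacro-pubic line and the
    vertical (degrees); ``natural_tilt_deg`` is the reference value at which
    the cup angles are defined (60 deg for the natural supine pelvis).  Only
    the difference ``tilt_delta_deg`` enters any computation.
    """

    pelvic_tilt_deg: float
    natural_tilt_deg: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pelvic_tilt_deg < 180.0:
            raise ParameterError(
                f"pelvic_tilt_deg must be in (0, 180), got {self.pelvic_tilt_deg}"
            )

    @property
    def tilt_delta_deg(self) -> float:
        return self.pelvic_tilt_deg - self.natural_tilt_deg


@dataclass(frozen=True)
class RimPointSet:
    """Ordered 3-D sample of the cup-rim circle.

    ``points`` has shape ``(n_points, 3)`` in millimetres; ``center`` is the
    rim centre and ``radius_mm`` the common distance of every point from it.
    """

    points: np.ndarray
    center: np.ndarray
    radius_mm: float
    side: str = "right"

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def plane_normal(self) -> np.ndarray:
        """Unit normal of the best-fit (here: exact) rim plane.

        Oriented consistently with the stored point ordering (right-hand
        rule); for a right-sided rim from :func:`make_rim` this is the
        outward acetabular axis.
        """
        q = self.points - self.center
        # smallest principal axis of the centred points
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        n = vt[-1]
        ref = np.cross(q[0], q[1])
        if np.dot(n, ref) < 0:
            n = -n
        # rim points are ordered counter-clockwise about the outward axis
        return n

    def validate(self, tol: float = 1e-9) -> None:
        """Raise if the set is not an equidistant, coplanar circle sample."""
        q = self.points - self.center
        r = np.linalg.norm(q, axis=1)
        if not np.allclose(r, self.radius_mm, rtol=tol, atol=tol * self.radius_mm):
            raise ParameterError("rim points are not equidistant from the centre")
        n = self.plane_normal()
        if np.max(np.abs(q @ n)) > tol * self.radius_mm:
            raise ParameterError("rim points are not coplanar")


def rim_plane_normal(cup: CupOrientation) -> np.ndarray:
    """Outward unit normal of the rim plane (the acetabular axis)."""
    a = np.radians(cup.anteversion_deg)
    i = np.radians(cup.inclination_deg)
    n = np.array([np.cos(a) * np.sin(i), -np.cos(a) * np.cos(i), np.sin(a)])
    if cup.side == "left":
        n = n * np.array([-1.0, 1.0, 1.0])
    return n


def make_rim(cup: CupOrientation, n_points: int = 256) -> RimPointSet:
    """Sample the cup-rim circle with ``n_points`` equally spaced points.

    The rim is centred at the origin (the rotation/projection pipeline is
    translation-invariant for angles).  A left cup is produced by mirroring
    the equivalent right cup across the sagittal plane, so the two point
    sets are exact mirror images.
    """
    if n_points < 8:
        raise ParameterError(f"n_points must be >= 8, got {n_points}")
    right = replace(cup, side="right")
    n = rim_plane_normal(right)
    # in-plane basis; rim plane never contains z unless inclination is 90
    seed = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(n, seed)) > 1.0 - 1e-12:
        seed = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(n, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    pts = cup.radius_mm * (np.outer(np.cos(t), e1) + np.outer(np.sin(t), e2))
    if cup.side == "left":
        pts = pts * np.array([-1.0, 1.0, 1.0])
    return RimPointSet(
        points=pts, center=np.zeros(3), radius_mm=cup.radius_mm, side=cup.side
    )


def apply_pelvic_tilt(rim: RimPointSet, pose: PelvisPose) -> RimPointSet:
    """Rigidly rotate the rim about the transverse axis through its centre.

    The rotation angle is ``pelvic_tilt_deg - natural_tilt_deg`` about +x
    (right-hand rule), which makes the measured version angle fall as the
    pelvic tilt rises, matching the observed direction of the tilt effect.
    """
    rot = Rotation.from_euler("x", pose.tilt_delta_deg, degrees=True)
    pts = rot.apply(rim.points - rim.center) + rim.center
    return RimPointSet(
        points=pts, center=rim.center.copy(), radius_mm=rim.radius_mm, side=rim.side
    )
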