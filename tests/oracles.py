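"""Independent oracles used by the test suite.

Everything here is derived from first principles (closed forms, explicit
loops, generic conic algebra) and never calls into the package's own
pipeline, so agreement between the two routes is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def radiographic_normal(anteversion_deg: float, inclination_deg: float) -> np.ndarray:
    """Closed-form acetabular axis from the radiographic angle definitions.

    Derived directly from the definitions: anteversion A is the angle
    between the axis and the coronal plane (sin A = anterior component),
    inclination I the angle between the coronal-plane projection of the
    axis and the longitudinal axis, the axis pointing laterally (+x) and
    caudally (-y) for a right cup.
    """
    a, i = np.radians([anteversion_deg, inclination_deg])
    return np.array(
        [np.cos(a) * np.sin(i), -np.cos(a) * np.cos(i), np.sin(a)]
    )


def beam_direction(beta_deg: float = 45.0) -> np.ndarray:
    b = np.radians(beta_deg)
    return np.array([np.sin(b), np.cos(b), 0.0])


def film_operator(beta_deg: float = 45.0) -> np.ndarray:
    """Explicit 2x3 orthographic projection operator onto the film basis."""
    d = beam_direction(beta_deg)
    v = np.array([0.0, 0.0, 1.0])
    u = np.cross(d, v)
    u /= np.linalg.norm(u)
    return np.vstack([u, v])


def tilted_normal(
    anteversion_deg: float,
    inclination_deg: float,
    pelvic_tilt_deg: float,
    natural_tilt_deg: float = 60.0,
) -> np.ndarray:
    """Rim normal after the sagittal tilt rotation about +x."""
    n = radiographic_normal(anteversion_deg, inclination_deg)
    d = np.radians(pelvic_tilt_deg - natural_tilt_deg)
    c, s = np.cos(d), np.sin(d)
    return np.array([n[0], n[1] * c - n[2] * s, n[1] * s + n[2] * c])


def measured_va_closed_form(
    anteversion_deg: float,
    inclination_deg: float,
    pelvic_tilt_deg: float = 60.0,
    beta_deg: float = 45.0,
    natural_tilt_deg: float = 60.0,
) -> float:
    """Woo-Morrey angle without any point sampling or ellipse fitting.

    Under orthographic projection the image ellipse's minor axis lies along
    the film projection of the rim-plane normal, so the major axis's angle
    to the film vertical equals the angle of the projected normal to the
    film horizontal.
    """
    n = tilted_normal(
        anteversion_deg, inclination_deg, pelvic_tilt_deg, natural_tilt_deg
    )
    u, v = film_operator(beta_deg)
    return float(np.degrees(np.arctan2(n @ v, n @ u)))


def ellipse_axes_closed_form(
    radius: float,
    anteversion_deg: float,
    inclination_deg: float,
    pelvic_tilt_deg: float = 60.0,
    beta_deg: float = 45.0,
) -> tuple[float, float]:
    """Exact semi-axes of the projected rim: (r, r |n . d|).

    Equivalently the singular values of the plane-to-film map times the
    radius; a diameter perpendicular to the beam/normal plane projects at
    full length, everything else is foreshortened by the normal-beam cosine.
    """
    n = tilted_normal(anteversion_deg, inclination_deg, pelvic_tilt_deg)
    d = beam_direction(beta_deg)
    return radius, radius * abs(float(n @ d))


def plane_to_film_singular_values(
    normal: np.ndarray, beta_deg: float = 45.0
) -> np.ndarray:
    """Singular values of the 2x2 map from rim-plane to film coordinates."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    seed = np.array([0.0, 0.0, 1.0])
    if abs(n @ seed) > 1 - 1e-12:
        seed = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(n, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    m = film_operator(beta_deg) @ np.column_stack([e1, e2])
    return np.linalg.svd(m, compute_uv=False)


def fit_conic_ellipse(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic conic fit: returns (semi_major, semi_minor, angle_deg).

    Solves the general conic a x^2 + b xy + c y^2 + d x + e y + f = 0 as the
    smallest singular vector of the design matrix, then extracts the ellipse
    axes from the quadratic form.  ``angle_deg`` is the major-axis angle from
    the +v (vertical) axis in (-90, 90].
    """
    x, y = points[:, 0], points[:, 1]
    design = np.column_stack([x**2, x * y, y**2, x, y, np.ones_like(x)])
    _, _, vt = np.linalg.svd(design, full_matrices=False)
    a, b, c, d, e, f = vt[-1]
    m = np.array([[a, b / 2], [b / 2, c]])
    # centre from gradient = 0
    ctr = np.linalg.solve(2 * m, -np.array([d, e]))
    const = a * ctr[0] ** 2 + b * ctr[0] * ctr[1] + c * ctr[1] ** 2 \
        + d * ctr[0] + e * ctr[1] + f
    evals, evecs = np.linalg.eigh(m / -const)
    axes = 1.0 / np.sqrt(evals)  # descending eval -> ascending axis
    major_vec = evecs[:, 0]  # smallest eigenvalue -> longest axis
    ang = np.degrees(np.arctan2(major_vec[0], major_vec[1]))
    ang = (ang + 90.0) % 180.0 - 90.0
    if ang == -90.0:
        ang = 90.0
    return float(axes[0]), float(axes[1]), float(ang)


def icc21_bruteforce(x: np.ndarray) -> float:
    """ICC(2,1) assembled from explicit sum-of-squares loops."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += x[i, j]
    grand /= n * k
    ss_rows = 0.0
    for i in range(n):
        mean_i = sum(x[i, j] for j in range(k)) / k
        ss_rows += k * (mean_i - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        mean_j = sum(x[i, j] for i in range(n)) / n
        ss_cols += n * (mean_j - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (x[i, j] - grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def column_intercepts_bruteforce(table_df, common_slope=None) -> dict[float, float]:
    """Per-actual-VA-column y-intercepts via explicit normal equations."""
    out: dict[float, float] = {}
    for va in sorted(table_df["actual_va_deg"].unique()):
        sub = table_df[table_df["actual_va_deg"] == va]
        pt = sub["pelvic_tilt_deg"].to_numpy(float)
        m = sub["measured_va_deg"].to_numpy(float)
        if common_slope is None:
            sxx = ((pt - pt.mean()) ** 2).sum()
            sxy = ((pt - pt.mean()) * (m - m.mean())).sum()
            slope = sxy / sxx
        else:
            slope = common_slope
        out[float(va)] = float(m.mean() - slope * pt.mean())
    return out
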