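"""Differential geometry and surface fitting for corneal height fields.

All elevation maps are single-valued height fields h(x, y) in mm, positive
toward the instrument (the apex sits at h = 0 and the surface falls away
toward the periphery).  Curvature is reported in keratometric diopters,
D = 337.5 * sqrt(k1 * k2), the root-Gaussian curvature under the standard
keratometric index n = 1.3375; a sphere of radius R mm maps to 337.5 / R D.

Derivatives are estimated by Gaussian-weighted local biquadratic fits over
physical-distance neighborhoods, precomputed per grid as sparse linear
operators, which keeps the estimator well conditioned at the apex (where
index-space neighborhoods of a polar grid degenerate) and at the rim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .scan import PolarGrid, ScalarMap, DomainError

__all__ = [
    "ZernikeSpectrum",
    "ReferenceSurface",
    "NumericalError",
    "FitError",
    "conic_sagitta",
    "asphotoric_sagitta",
    "reference_elevation",
    "gaussian_curvature_map",
    "axial_principal_meridians",
    "zernike_nm_pairs",
    "zernike_basis",
    "fit_zernike",
    "reconstruct_zernike",
    "fit_reference_asphotoric",
    "deviation_map",
]

KERATOMETRIC_INDEX = 337.5  # (1.3375 - 1) * 1000, diopters per 1/mm

#: physiologic asphericity of the reference surfaces (fixed, never fitted)
Q_ANTERIOR = -0.2
Q_POSTERIOR = -0.3


class NumericalError(RuntimeError):
    """Non-finite derivatives or curvature at a grid node."""


class FitError(RuntimeError):
    """Surface fit failed to converge."""


# ---------------------------------------------------------------------------
# conicoid / aspho-toric sagitta


def conic_sagitta(c: float, Q: float, r: np.ndarray) -> np.ndarray:
    """Sagitta of a conicoid with apical curvature c (1/mm) and asphericity Q.

    z(r) = c r^2 / (1 + sqrt(1 - (1+Q) c^2 r^2)), measured away from the
    apex plane (posterior-positive).
    """
    r = np.asarray(r, dtype=float)
    arg = 1.0 - (1.0 + Q) * (c * r) ** 2
    arg = np.maximum(arg, 1e-9)
    return c * r**2 / (1.0 + np.sqrt(arg))


def asphotoric_sagitta(
    c_flat: float, c_steep: float, axis_deg: float, Q: float,
    r: np.ndarray, theta_rad: np.ndarray,
) -> np.ndarray:
    """Aspho-toric sagitta with meridional apical curvature
    c(theta) = c_flat + (c_steep - c_flat) * sin^2(theta - axis)."""
    c = c_flat + (c_steep - c_flat) * np.sin(theta_rad - np.deg2rad(axis_deg)) ** 2
    arg = 1.0 - (1.0 + Q) * (c * r) ** 2
    arg = np.maximum(arg, 1e-9)
    return c * r**2 / (1.0 + np.sqrt(arg))


# ---------------------------------------------------------------------------
# derivative operators


_DERIV_CACHE: dict[PolarGrid, dict[str, sparse.csr_matrix]] = {}


def _node_coordinates(grid: PolarGrid) -> tuple[np.ndarray, np.ndarray]:
    """Flattened node coordinates, apex first: shape (1 + n_rings*n_meridians,)."""
    x, y = grid.mesh_cartesian()
    return (
        np.concatenate(([0.0], x.ravel())),
        np.concatenate(([0.0], y.ravel())),
    )


def derivative_operators(grid: PolarGrid) -> dict[str, sparse.csr_matrix]:
    """Sparse operators mapping flattened heights to zx, zy, zxx, zxy, zyy.

    Each row is the derivative-extraction row of a Gaussian-weighted
    biquadratic least-squares fit over nodes within ~2.2 ring spacings.
    """
    cached = _DERIV_CACHE.get(grid)
    if cached is not None:
        return cached

    xs, ys = _node_coordinates(grid)
    n = xs.size
    h = 2.2 * grid.ring_spacing
    tree = cKDTree(np.column_stack([xs, ys]))
    neighbor_lists = tree.query_ball_point(np.column_stack([xs, ys]), r=h)

    rows = {k: [] for k in ("zx", "zy", "zxx", "zxy", "zyy")}
    cols = {k: [] for k in rows}
    data = {k: [] for k in rows}
    extract = {"zx": (1, 1.0), "zy": (2, 1.0), "zxx": (3, 2.0), "zxy": (4, 1.0), "zyy": (5, 2.0)}

    for i in range(n):
        idx = np.asarray(neighbor_lists[i], dtype=int)
        dx = xs[idx] - xs[i]
        dy = ys[idx] - ys[i]
        d2 = dx**2 + dy**2
        w = np.exp(-d2 / h**2)
        A = np.column_stack([np.ones_like(dx), dx, dy, dx**2, dx * dy, dy**2])
        Aw = A * w[:, None]
        # M = (A^T W A)^{-1} A^T W, rows give fit coefficients as linear
        # functionals of the neighborhood heights
        M = np.linalg.solve(A.T @ Aw + 1e-12 * np.eye(6), Aw.T)
        for key, (row_idx, scale) in extract.items():
            rows[key].append(np.full(idx.size, i))
            cols[key].append(idx)
            data[key].append(scale * M[row_idx])

    ops = {}
    for key in rows:
        ops[key] = sparse.csr_matrix(
            (
                np.concatenate(data[key]),
                (np.concatenate(rows[key]), np.concatenate(cols[key])),
            ),
            shape=(n, n),
        )
    _DERIV_CACHE[grid] = ops
    return ops


def _flatten_map(smap: ScalarMap) -> np.ndarray:
    return np.concatenate(([smap.apex], smap.values.ravel()))


def gaussian_curvature_map(elevation: ScalarMap, side: str) -> ScalarMap:
    """Root-Gaussian curvature of a height field, in keratometric diopters.

    Principal curvatures come from the first/second fundamental forms of the
    height field; the returned value is 337.5 * sign(K) * sqrt(|K|) with
    K = k1*k2 the Gaussian curvature (sign-preserving so saddle-shaped
    irregular regions remain informative; physiologic corneas have K > 0).
    """
    if side not in ("anterior", "posterior"):
        raise ValueError(f"side must be anterior or posterior, got {side!r}")
    ops = derivative_operators(elevation.grid)
    z = _flatten_map(elevation)
    zx = ops["zx"] @ z
    zy = ops["zy"] @ z
    zxx = ops["zxx"] @ z
    zxy = ops["zxy"] @ z
    zyy = ops["zyy"] @ z
    denom = (1.0 + zx**2 + zy**2) ** 2
    K = (zxx * zyy - zxy**2) / denom  # 1/mm^2
    if not np.all(np.isfinite(K)):
        bad = int(np.argmax(~np.isfinite(K)))
        raise NumericalError(f"non-finite curvature at flattened node {bad}")
    D = KERATOMETRIC_INDEX * np.sign(K) * np.sqrt(np.abs(K))
    g = elevation.grid
    return ScalarMap(
        grid=g,
        values=D[1:].reshape(g.n_rings, g.n_meridians),
        apex=float(D[0]),
        kind="curvature",
        side=side,
    )


# ---------------------------------------------------------------------------
# axial radii / principal meridians


def axial_principal_meridians(
    elevation: ScalarMap, zone_diameter: float = 3.0
) -> tuple[float, float, float]:
    """Flat/steep mean axial radii (mm) and flat axis (deg) over a central zone.

    The axial radius at a node is the distance along the surface normal to
    the optical axis, R_a = r * sqrt(1 + z_r^2) / |z_r| (the standard axial
    power definition); per-meridian means over the zone are fitted with a
    cos 2theta model.  For a sphere of radius R every meridian returns R.
    """
    g = elevation.grid
    if zone_diameter / 2.0 > g.max_radius + 1e-9:
        raise DomainError("zone extends beyond map support")
    radii = np.concatenate(([0.0], g.radii))
    zone_mask = (radii > 0) & (radii <= zone_diameter / 2.0 + 1e-12)
    if not np.any(zone_mask):
        raise DomainError("zone contains no rings")

    prof = np.vstack(
        [np.full(g.n_meridians, elevation.apex), elevation.values]
    )  # (n_rings+1, n_meridians), r = radii
    # remove piston and tilt over the zone: tilt carries no curvature but
    # breaks the axial-radius definition near the vertex
    t_all = np.deg2rad(g.angles_deg)
    rz = radii[zone_mask]
    zone_rows = prof[zone_mask]
    xs = (rz[:, None] * np.cos(t_all)[None, :]).ravel()
    ys = (rz[:, None] * np.sin(t_all)[None, :]).ravel()
    P = np.column_stack([np.ones_like(xs), xs, ys])
    coef_plane, *_ = np.linalg.lstsq(P, zone_rows.ravel(), rcond=None)
    x_full = radii[:, None] * np.cos(t_all)[None, :]
    y_full = radii[:, None] * np.sin(t_all)[None, :]
    prof = prof - (coef_plane[0] + coef_plane[1] * x_full + coef_plane[2] * y_full)
    dzdr = np.gradient(prof, radii, axis=0)
    zr = np.abs(dzdr[zone_mask])  # (n_zone, n_meridians)
    r_in = radii[zone_mask][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        R_a = r_in * np.sqrt(1.0 + zr**2) / zr
    if not np.all(np.isfinite(R_a)) or np.any(R_a <= 0) or np.any(R_a > 1e3):
        raise NumericalError(
            "degenerate axial radii (surface is flat or vertical within the zone)"
        )
    mer_mean = R_a.mean(axis=0)  # per-meridian mean axial radius

    t = np.deg2rad(g.angles_deg)
    A = np.column_stack([np.ones_like(t), np.cos(2 * t), np.sin(2 * t)])
    coef, *_ = np.linalg.lstsq(A, mer_mean, rcond=None)
    a0, b, c = coef
    amp = math.hypot(b, c)
    if amp < 1e-9:
        return float(a0), float(a0), 0.0
    # R(theta) = a0 + amp * cos(2 theta - phi); flat (largest R) at theta = phi/2
    phi = math.atan2(c, b)
    axis = math.degrees(phi / 2.0) % 180.0
    return float(a0 + amp), float(a0 - amp), float(axis)


# ---------------------------------------------------------------------------
# Zernike decomposition


def zernike_nm_pairs(max_order: int) -> list[tuple[int, int]]:
    """ANSI-ordered (n, m) pairs for all n <= max_order."""
    return [(n, m) for n in range(max_order + 1) for m in range(-n, n + 1, 2)]


def _zernike_radial(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - m_abs) // 2 + 1):
        coef = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)
            )
        )
        out = out + coef * rho ** (n - 2 * k)
    return out


def zernike_basis(nm_pairs, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Orthonormal Zernike basis over the unit disc, shape (npoints, ncoef)."""
    cols = []
    for n, m in nm_pairs:
        norm = math.sqrt(2.0 * (n + 1) / (1.0 + (1.0 if m == 0 else 0.0)))
        R = _zernike_radial(n, abs(m), rho)
        if m > 0:
            cols.append(norm * R * np.cos(m * theta))
        elif m < 0:
            cols.append(norm * R * np.sin(-m * theta))
        else:
            cols.append(norm * R)
    return np.column_stack(cols)


@dataclass
class ZernikeSpectrum:
    """Orthonormal Zernike coefficients (um) of an elevation over a disc."""

    max_order: int
    coefficients: np.ndarray  # um, ANSI order
    pupil_radius: float  # mm
    normalization: str = "orthonormal"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expected = (self.max_order + 1) * (self.max_order + 2) // 2
        if self.coefficients.size != expected:
            raise ValueError(
                f"expected {expected} coefficients for order {self.max_order}, "
                f"got {self.coefficients.size}"
            )

    @property
    def nm_pairs(self) -> list[tuple[int, int]]:
        return zernike_nm_pairs(self.max_order)


_ZERNIKE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _zernike_design(grid: PolarGrid, max_order: int, pupil_radius: float):
    key = (grid, max_order, round(pupil_radius, 9))
    hit = _ZERNIKE_CACHE.get(key)
    if hit is not None:
        return hit
    r, t = grid.mesh_polar()
    rr = np.concatenate(([0.0], r.ravel()))
    tt = np.concatenate(([0.0], t.ravel()))
    w = np.concatenate(([0.0], grid.area_weights().ravel()))
    mask = rr <= pupil_radius + 1e-12
    nm = zernike_nm_pairs(max_order)
    A = zernike_basis(nm, rr[mask] / pupil_radius, tt[mask])
    if mask.sum() < len(nm):
        raise FitError(
            f"grid too coarse for Zernike order {max_order}; lower the order"
        )
    sw = np.sqrt(np.maximum(w[mask], 1e-12))
    Aw = A * sw[:, None]
    # weighted pseudo-inverse, cached: coeffs = P @ (sw * values)
    P = np.linalg.pinv(Aw)
    if np.linalg.matrix_rank(Aw) < len(nm):
        raise FitError(
            f"rank-deficient Zernike design at order {max_order}; lower the order"
        )
    _ZERNIKE_CACHE[key] = (P, (mask, sw))
    return P, (mask, sw)


def fit_zernike(
    elevation: ScalarMap, max_order: int = 8, pupil_radius: float | None = None
) -> ZernikeSpectrum:
    """Least-squares orthonormal Zernike fit of an elevation map (result in um)."""
    g = elevation.grid
    if pupil_radius is None:
        pupil_radius = g.max_radius
    if pupil_radius > g.max_radius + 1e-9:
        raise DomainError("pupil_radius exceeds map support")
    if max_order < 4:
        raise ValueError("max_order must be >= 4")
    P, (mask, sw) = _zernike_design(g, max_order, pupil_radius)
    z_um = _flatten_map(elevation)[mask] * 1000.0
    coeffs = P @ (sw * z_um)
    return ZernikeSpectrum(max_order=max_order, coefficients=coeffs, pupil_radius=pupil_radius)


def reconstruct_zernike(spec: ZernikeSpectrum, grid: PolarGrid) -> ScalarMap:
    """Evaluate a spectrum back onto a grid as an elevation map (mm).

    Outside the fitted pupil the basis is extrapolated (rho > 1); intended
    for projection-property checks on the fitted zone.
    """
    r, t = grid.mesh_polar()
    rr = np.concatenate(([0.0], r.ravel()))
    tt = np.concatenate(([0.0], t.ravel()))
    A = zernike_basis(spec.nm_pairs, rr / spec.pupil_radius, tt)
    z = (A @ spec.coefficients) / 1000.0
    return ScalarMap(
        grid=grid,
        values=z[1:].reshape(grid.n_rings, grid.n_meridians),
        apex=float(z[0]),
        kind="elevation",
    )


# ---------------------------------------------------------------------------
# best-fit aspho-toric reference surface


@dataclass
class ReferenceSurface:
    """Best-fit aspho-toric reference: apical radii, flat axis, fixed Q."""

    apical_radius_flat: float  # mm
    apical_radius_steep: float  # mm
    axis: float  # degrees in [0, 180)
    asphericity_q: float
    fit_zone_diameter: float = 8.0
    fit_rms_residual: float = 0.0  # um

    def __post_init__(self) -> None:
        if not (4.0 <= self.apical_radius_steep <= self.apical_radius_flat <= 12.0):
            raise FitError(
                "apical radii out of physiologic range [4, 12] mm: "
                f"flat {self.apical_radius_flat:.3f}, steep {self.apical_radius_steep:.3f}"
            )


def reference_elevation(ref: ReferenceSurface, grid: PolarGrid) -> ScalarMap:
    """Reference surface as an elevation height field (mm) on a grid."""
    r, t = grid.mesh_polar()
    sag = asphotoric_sagitta(
        1.0 / ref.apical_radius_flat,
        1.0 / ref.apical_radius_steep,
        ref.axis,
        ref.asphericity_q,
        r,
        t,
    )
    return ScalarMap(grid=grid, values=-sag, apex=0.0, kind="elevation")


def fit_reference_asphotoric(
    elevation: ScalarMap, Q: float, zone_diameter: float = 8.0
) -> ReferenceSurface:
    """Fit the aspho-toric family (Q fixed) to an elevation over a central zone.

    The meridional apical curvature is parametrized as
    c(theta) = u0 + u1 cos 2theta + u2 sin 2theta (equivalent to
    c_flat + (c_steep - c_flat) sin^2(theta - axis)), which is smooth in the
    parameters; Levenberg-Marquardt iterations start from the closed-form
    best-fit sphere.  Deterministic.
    """
    g = elevation.grid
    r, t = g.mesh_polar()
    w = g.area_weights()
    mask = r <= zone_diameter / 2.0 + 1e-12
    if not np.any(mask):
        raise DomainError("fit zone contains no grid nodes")
    rr = r[mask]
    tt = t[mask]
    sw = np.sqrt(w[mask])
    h = elevation.values[mask]  # mm, apex excluded (zero area weight anyway)

    # closed-form spherical init: h ~ -c r^2/2
    q2 = rr**2 / 2.0
    c0 = float(-np.sum(sw**2 * h * q2) / np.sum(sw**2 * q2**2))
    c0 = min(max(c0, 1.0 / 12.0), 1.0 / 4.0)

    def residuals(u):
        c = u[0] + u[1] * np.cos(2 * tt) + u[2] * np.sin(2 * tt)
        arg = np.maximum(1.0 - (1.0 + Q) * (c * rr) ** 2, 1e-9)
        model = -(c * rr**2 / (1.0 + np.sqrt(arg)))
        return sw * (h - model) * 1000.0  # um, area-weighted

    sol = least_squares(
        residuals,
        x0=np.array([c0, 0.0, 0.0]),
        method="lm",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=800,
    )
    if not sol.success:
        rms = float(np.sqrt(np.sum(sol.fun**2) / np.sum(sw**2)))
        raise FitError(f"aspho-toric fit did not converge (residual RMS {rms:.3g} um)")
    u0, u1, u2 = sol.x
    amp = math.hypot(u1, u2)
    c_flat = u0 - amp
    c_steep = u0 + amp
    if amp < 1e-12:
        axis = 0.0
    else:
        # flat meridian where c(theta) is minimal: cos(2 theta - phi) = -1
        phi = math.atan2(u2, u1)
        axis = math.degrees((phi + math.pi) / 2.0) % 180.0
    rms = float(np.sqrt(np.sum(sol.fun**2) / np.sum(sw**2)))
    return ReferenceSurface(
        apical_radius_flat=1.0 / c_flat,
        apical_radius_steep=1.0 / c_steep,
        axis=axis,
        asphericity_q=Q,
        fit_zone_diameter=zone_diameter,
        fit_rms_residual=rms,
    )


def deviation_map(elevation: ScalarMap, ref: ReferenceSurface) -> ScalarMap:
    """Node-wise elevation minus reference sagitta, in um (kind=deviation)."""
    ref_map = reference_elevation(ref, elevation.grid)
    return ScalarMap(
        grid=elevation.grid,
        values=(elevation.values - ref_map.values) * 1000.0,
        apex=(elevation.apex - ref_map.apex) * 1000.0,
        kind="deviation",
    )
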