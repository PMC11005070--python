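"""Corneal scan data model, on-disk scan format, and zone sampling utilities.

Maps live on a shared polar grid: ``n_rings`` radial samples at radii
``r_k = (k+1) * max_radius / n_rings`` crossed with ``n_meridians`` angular
samples at ``theta_j = j * 360 / n_meridians`` degrees, plus one apex sample
at r = 0.  Coordinates are right-handed with y superior-positive and angles
counterclockwise from +x; elevation is positive toward the instrument.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PolarGrid",
    "ScalarMap",
    "CornealScan",
    "CLASS_ORDER",
    "CLASS_NAMES",
    "FormatError",
    "ConsistencyError",
    "DomainError",
    "read_scan",
    "write_scan",
    "sample_zone_mean",
    "sample_annulus_mean",
    "sample_point",
    "mirror_scan",
]

#: Fixed diagnostic class order used everywhere (confusion matrices, MLP outputs).
CLASS_ORDER = ("Abn", "Kcn", "MyPO", "Normal", "SKcn")

CLASS_NAMES = {
    "Abn": "Abnormal",
    "Kcn": "Keratoconus",
    "MyPO": "Myopic post-op",
    "Normal": "Normal",
    "SKcn": "Keratoconus suspect",
}

MAP_KINDS = ("elevation", "thickness", "curvature", "deviation")

#: corneal thickness must equal epithelial + stromal thickness within this (um)
ADDITIVITY_TOL_UM = 1.0


class FormatError(ValueError):
    """Scan file does not follow the documented dialect."""


class ConsistencyError(ValueError):
    """Maps within a scan disagree (grids, additivity, laterality)."""


class DomainError(ValueError):
    """A sampling zone extends beyond the map support."""


@dataclass(frozen=True)
class PolarGrid:
    """Polar sampling grid shared by all maps of a scan."""

    n_rings: int = 31
    n_meridians: int = 256
    max_radius: float = 4.0

    def __post_init__(self) -> None:
        if self.n_rings < 16:
            raise ValueError(f"n_rings must be >= 16, got {self.n_rings}")
        if self.n_meridians < 32 or self.n_meridians % 4 != 0:
            raise ValueError(
                f"n_meridians must be >= 32 and divisible by 4, got {self.n_meridians}"
            )
        if not self.max_radius > 0:
            raise ValueError("max_radius must be positive")

    @property
    def radii(self) -> np.ndarray:
        """Ring radii in mm, shape (n_rings,)."""
        return (np.arange(self.n_rings) + 1.0) * self.max_radius / self.n_rings

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_meridians) * 360.0 / self.n_meridians

    @property
    def ring_spacing(self) -> float:
        return self.max_radius / self.n_rings

    def mesh_polar(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, theta_rad) meshes of shape (n_rings, n_meridians)."""
        r = np.repeat(self.radii[:, None], self.n_meridians, axis=1)
        t = np.repeat(np.deg2rad(self.angles_deg)[None, :], self.n_rings, axis=0)
        return r, t

    def mesh_cartesian(self) -> tuple[np.ndarray, np.ndarray]:
        r, t = self.mesh_polar()
        return r * np.cos(t), r * np.sin(t)

    def area_weights(self) -> np.ndarray:
        """Polar area element per node (proportional to r), shape (n_rings, n_meridians)."""
        r, _ = self.mesh_polar()
        return r * self.ring_spacing * (2.0 * np.pi / self.n_meridians)


@dataclass
class ScalarMap:
    """One scalar field over a polar grid plus the apex sample.

    Units are mm for elevation, um for thickness and deviation, diopters for
    curvature.  ``side`` distinguishes anterior/posterior curvature maps.
    """

    grid: PolarGrid
    values: np.ndarray  # shape (n_rings, n_meridians)
    apex: float
    kind: str
    side: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rings, self.grid.n_meridians):
            raise ConsistencyError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_rings}, {self.grid.n_meridians})"
            )
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)) or not np.isfinite(self.apex):
            raise ConsistencyError("map contains non-finite values")
        if self.kind == "thickness" and (self.apex <= 0 or np.any(self.values <= 0)):
            raise ConsistencyError("thickness values must be positive")

    def copy(self) -> "ScalarMap":
        return replace(self, values=self.values.copy())


@dataclass
class CornealScan:
    """All five maps of one eye on a common grid."""

    anterior_elevation: ScalarMap
    posterior_elevation: ScalarMap
    corneal_thickness: ScalarMap
    epithelial_thickness: ScalarMap
    stromal_thickness: ScalarMap
    laterality: str
    scan_id: str = ""

    _MAP_FIELDS = (
        "anterior_elevation",
        "posterior_elevation",
        "corneal_thickness",
        "epithelial_thickness",
        "stromal_thickness",
    )

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ConsistencyError(f"laterality must be OD or OS, got {self.laterality!r}")
        grid = self.anterior_elevation.grid
        for name in self._MAP_FIELDS:
            m = getattr(self, name)
            if m.grid != grid:
                raise ConsistencyError(f"{name} is on a different grid")
        diff = (
            self.corneal_thickness.values
            - self.epithelial_thickness.values
            - self.stromal_thickness.values
        )
        diff_apex = (
            self.corneal_thickness.apex
            - self.epithelial_thickness.apex
            - self.stromal_thickness.apex
        )
        if np.max(np.abs(diff)) > ADDITIVITY_TOL_UM or abs(diff_apex) > ADDITIVITY_TOL_UM:
            raise ConsistencyError(
                "corneal thickness != epithelial + stromal beyond "
                f"{ADDITIVITY_TOL_UM} um (max |diff| = {np.max(np.abs(diff)):.3f})"
            )

    @property
    def grid(self) -> PolarGrid:
        return self.anterior_elevation.grid


# ---------------------------------------------------------------------------
# on-disk dialect: [META] + five CSV blocks, apex value line first in each


_SECTION_TO_FIELD = {
    "ANTERIOR_ELEVATION_MM": ("anterior_elevation", "elevation"),
    "POSTERIOR_ELEVATION_MM": ("posterior_elevation", "elevation"),
    "CORNEAL_THICKNESS_UM": ("corneal_thickness", "thickness"),
    "EPITHELIAL_THICKNESS_UM": ("epithelial_thickness", "thickness"),
    "STROMAL_THICKNESS_UM": ("stromal_thickness", "thickness"),
}


def write_scan(scan: CornealScan, path) -> None:
    """Write a scan in the sectioned UTF-8 text dialect (9 significant digits)."""
    buf = io.StringIO()
    g = scan.grid
    buf.write("[META]\n")
    buf.write(f"scan_id={scan.scan_id}\n")
    buf.write(f"laterality={scan.laterality}\n")
    buf.write(f"n_rings={g.n_rings}\n")
    buf.write(f"n_meridians={g.n_meridians}\n")
    buf.write(f"max_radius_mm={g.max_radius:.9g}\n")
    for section, (fname, _) in _SECTION_TO_FIELD.items():
        m: ScalarMap = getattr(scan, fname)
        buf.write(f"[{section}]\n")
        buf.write(f"{m.apex:.9g}\n")
        for row in m.values:
            buf.write(",".join(f"{v:.9g}" for v in row) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_scan(path) -> CornealScan:
    """Read a scan file written by :func:`write_scan`.

    Raises :class:`FormatError` for missing/garbled sections and
    :class:`ConsistencyError` when maps disagree.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    sections: dict[str, list[str]] = {}
    current = None
    for ln in lines:
        if not ln.strip():
            continue
        if ln.startswith("[") and ln.endswith("]"):
            current = ln[1:-1]
            if current in sections:
                raise FormatError(f"duplicate section [{current}]")
            sections[current] = []
        elif current is None:
            raise FormatError("content before first section header")
        else:
            sections[current].append(ln)

    if "META" not in sections:
        raise FormatError("missing section [META]")
    meta = {}
    for ln in sections["META"]:
        if "=" not in ln:
            raise FormatError(f"bad META line: {ln!r}")
        k, v = ln.split("=", 1)
        meta[k.strip()] = v.strip()
    try:
        grid = PolarGrid(
            n_rings=int(meta["n_rings"]),
            n_meridians=int(meta["n_meridians"]),
            max_radius=float(meta["max_radius_mm"]),
        )
        laterality = meta["laterality"]
        scan_id = meta.get("scan_id", "")
    except KeyError as exc:
        raise FormatError(f"missing META key {exc}") from exc

    maps = {}
    for section, (fname, kind) in _SECTION_TO_FIELD.items():
        if section not in sections:
            raise FormatError(f"missing map section [{section}]")
        body = sections[section]
        if len(body) != grid.n_rings + 1:
            raise FormatError(
                f"section [{section}] has {len(body)} data lines, "
                f"expected apex + {grid.n_rings} rows"
            )
        try:
            apex = float(body[0])
            values = np.array(
                [[float(v) for v in row.split(",")] for row in body[1:]], dtype=float
            )
        except ValueError as exc:
            raise FormatError(f"non-numeric value in section [{section}]: {exc}") from exc
        if values.shape[1] != grid.n_meridians:
            raise FormatError(
                f"section [{section}] rows have {values.shape[1]} columns, "
                f"expected {grid.n_meridians}"
            )
        maps[fname] = ScalarMap(grid=grid, values=values, apex=apex, kind=kind)

    return CornealScan(laterality=laterality, scan_id=scan_id, **maps)


# ---------------------------------------------------------------------------
# zone sampling


def _zone_tolerance(grid: PolarGrid) -> float:
    return 0.5 * grid.ring_spacing


def sample_zone_mean(
    smap: ScalarMap,
    center: tuple[float, float],
    radius: float,
    *,
    clip: bool = False,
) -> float:
    """Area-weighted mean over the disc of ``radius`` around ``center`` (mm).

    With ``clip=False`` (the default contract) the disc must lie inside the
    map support; with ``clip=True`` the mean is taken over the in-support
    part of the disc (used by the symmetry indexes whose zones graze the rim).
    """
    cx, cy = center
    g = smap.grid
    if radius <= 0:
        raise DomainError("zone radius must be positive")
    if not clip and np.hypot(cx, cy) + radius > g.max_radius + _zone_tolerance(g):
        raise DomainError(
            f"zone (center {center}, radius {radius}) extends beyond "
            f"map support of radius {g.max_radius}"
        )
    # apex, when inside the disc, carries zero polar area weight and is skipped
    x, y = g.mesh_cartesian()
    mask = (x - cx) ** 2 + (y - cy) ** 2 <= radius**2
    if not np.any(mask):
        raise DomainError("zone contains no grid nodes")
    w = g.area_weights()[mask]
    return float(np.sum(w * smap.values[mask]) / np.sum(w))


def sample_annulus_mean(smap: ScalarMap, r_inner: float, r_outer: float) -> float:
    """Area-weighted mean over nodes with r_inner < r <= r_outer (vertex-centered)."""
    g = smap.grid
    if not (0 <= r_inner < r_outer <= g.max_radius + _zone_tolerance(g)):
        raise DomainError(
            f"invalid annulus radii ({r_inner}, {r_outer}) for support {g.max_radius}"
        )
    r, _ = g.mesh_polar()
    mask = (r > r_inner) & (r <= r_outer)
    if not np.any(mask):
        raise DomainError("annulus contains no grid nodes")
    w = g.area_weights()[mask]
    return float(np.sum(w * smap.values[mask]) / np.sum(w))


def sample_point(smap: ScalarMap, x: float, y: float) -> float:
    """Bilinear (radius x angle) interpolation of the map at a cartesian point."""
    g = smap.grid
    r = float(np.hypot(x, y))
    if r > g.max_radius + 1e-12:
        raise DomainError(f"point ({x}, {y}) outside support radius {g.max_radius}")
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    dr = g.ring_spacing
    dtheta = 360.0 / g.n_meridians
    # radial position: apex sits at index -1, ring k at radius (k+1)*dr
    fr = r / dr - 1.0
    k0 = int(np.floor(fr))
    tr = fr - k0
    jf = theta / dtheta
    j0 = int(np.floor(jf)) % g.n_meridians
    j1 = (j0 + 1) % g.n_meridians
    tj = jf - np.floor(jf)

    def ring_value(k: int, j: int) -> float:
        if k < 0:
            return smap.apex
        k = min(k, g.n_rings - 1)
        return float(smap.values[k, j])

    v00 = ring_value(k0, j0)
    v01 = ring_value(k0, j1)
    v10 = ring_value(k0 + 1, j0)
    v11 = ring_value(k0 + 1, j1)
    v0 = v00 * (1 - tj) + v01 * tj
    v1 = v10 * (1 - tj) + v11 * tj
    return float(v0 * (1 - tr) + v1 * tr)


def _mirror_map(smap: ScalarMap) -> ScalarMap:
    """Mirror a map about the vertical (y) axis: theta -> 180 - theta."""
    n = smap.grid.n_meridians
    j = np.arange(n)
    src = (n // 2 - j) % n
    return replace(smap, values=smap.values[:, src].copy())


def canonical_scan(scan: CornealScan) -> CornealScan:
    """Return the scan in the canonical OD frame (OS scans are mirrored).

    Index computation runs in this frame so that nasal/temporal geometry is
    comparable across eyes and every index is exactly laterality-equivariant.
    """
    return scan if scan.laterality == "OD" else mirror_scan(scan)


def mirror_scan(scan: CornealScan) -> CornealScan:
    """Mirror a scan about the vertical axis and flip laterality (OD <-> OS)."""
    return CornealScan(
        anterior_elevation=_mirror_map(scan.anterior_elevation),
        posterior_elevation=_mirror_map(scan.posterior_elevation),
        corneal_thickness=_mirror_map(scan.corneal_thickness),
        epithelial_thickness=_mirror_map(scan.epithelial_thickness),
        stromal_thickness=_mirror_map(scan.stromal_thickness),
        laterality="OS" if scan.laterality == "OD" else "OD",
        scan_id=scan.scan_id,
    )
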