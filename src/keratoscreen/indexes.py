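"""The 19 scalar screening indexes computed from a corneal scan.

Index summary (abnormal direction for keratoconus in parentheses):

* ``SI_F`` / ``SI_B`` (+): inferior-minus-superior mean curvature of two
  1.5 mm discs centered 3 mm from the vertex on the 81/261 (OD) or 99/279
  (OS) degree axis.
* ``CSI_F`` / ``CSI_B`` (+): central 1.5 mm disc mean curvature minus the
  1.5-3 mm annulus mean.
* ``EI_F`` / ``EI_B`` (+): linear-plus-quadratic functional of the Zernike
  coefficients with weights trained to separate normal from keratoconus.
* ``RMS_F`` / ``RMS_B`` (+): RMS deviation (um) from the best-fit
  aspho-toric reference (Q = -0.2 anterior, -0.3 posterior, 8 mm zone).
* ``SI_THK`` (-): same two-disc geometry on corneal thickness (inferior
  thinning makes it negative).
* ``pTI`` / ``pEpiTI`` (+): max excess of the percentage thickness increase
  profile over the normative 95th-percentile profile.
* ``Thk_Min`` (-): minimum corneal thickness (um) in the 8 mm zone.
* ``KMax_F`` / ``KMax_B`` (+): maximum of the curvature map.
* ``DZMax_F`` / ``DZMax_B`` (+): signed maximum of the deviation map.
* ``NPtsR`` (-): mean distance of the seven notable points (thickness
  minima, curvature maxima, deviation maxima) from their barycenter; a
  coherent cone pulls them together.
* ``KAvg_F`` / ``KAvg_B`` (+): mean keratometric power of the two principal
  meridians over the central 3 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.linear_model import LogisticRegression

from .scan import (
    CornealScan,
    ScalarMap,
    DomainError,
    sample_zone_mean,
    sample_annulus_mean,
)
from .geometry import (
    Q_ANTERIOR,
    Q_POSTERIOR,
    KERATOMETRIC_INDEX,
    ZernikeSpectrum,
    gaussian_curvature_map,
    axial_principal_meridians,
    fit_zernike,
    fit_reference_asphotoric,
    deviation_map,
)

__all__ = [
    "INDEX_NAMES",
    "ABNORMAL_DIRECTION",
    "IndexVector",
    "NotablePoints",
    "EIWeights",
    "Profile",
    "symmetry_index",
    "center_surrounding_index",
    "ectatic_index",
    "train_ei_weights",
    "rms_vs_reference",
    "dz_max",
    "thickness_min",
    "thickness_symmetry_index",
    "pct_thickness_increase_profile",
    "pti_index",
    "epi_pti_index",
    "k_max",
    "k_avg",
    "nps_spread",
    "compute_index_vector",
]

INDEX_NAMES = (
    "SI_F", "SI_B", "CSI_F", "CSI_B", "EI_F", "EI_B", "RMS_F", "RMS_B",
    "SI_THK", "pTI", "pEpiTI", "Thk_Min", "KMax_F", "KMax_B",
    "DZMax_F", "DZMax_B", "NPtsR", "KAvg_F", "KAvg_B",
)

#: +1 when larger values are more abnormal for keratoconus, -1 when smaller are
ABNORMAL_DIRECTION = {
    "SI_F": 1, "SI_B": 1, "CSI_F": 1, "CSI_B": 1, "EI_F": 1, "EI_B": 1,
    "RMS_F": 1, "RMS_B": 1, "SI_THK": -1, "pTI": 1, "pEpiTI": 1,
    "Thk_Min": -1, "KMax_F": 1, "KMax_B": 1, "DZMax_F": 1, "DZMax_B": 1,
    "NPtsR": -1, "KAvg_F": 1, "KAvg_B": 1,
}

#: symmetry-index zone geometry (radius of each disc / distance of centers
#: from the vertex, mm); the discs graze the 8 mm rim and are clipped to it
SI_ZONE_RADIUS = 1.5
SI_CENTER_DISTANCE = 3.0

#: laterality-dependent hemisphere axes, degrees (inferior, superior)
SI_AXES = {"OD": (261.0, 81.0), "OS": (279.0, 99.0)}

PTI_STEP = 0.1
PTI_MAX_D = 3.0


@dataclass
class NotablePoints:
    """Cartesian locations (mm) of the seven cone-coherence landmarks."""

    p_epi_thk_min: tuple[float, float]
    p_str_thk_min: tuple[float, float]
    p_thk_min: tuple[float, float]
    p_kmax_f: tuple[float, float]
    p_kmax_b: tuple[float, float]
    p_dzmax_f: tuple[float, float]
    p_dzmax_b: tuple[float, float]

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.p_epi_thk_min, self.p_str_thk_min, self.p_thk_min,
                self.p_kmax_f, self.p_kmax_b, self.p_dzmax_f, self.p_dzmax_b,
            ],
            dtype=float,
        )


@dataclass
class IndexVector:
    """The 19 named screening indexes for one eye, in fixed order."""

    SI_F: float
    SI_B: float
    CSI_F: float
    CSI_B: float
    EI_F: float
    EI_B: float
    RMS_F: float
    RMS_B: float
    SI_THK: float
    pTI: float
    pEpiTI: float
    Thk_Min: float
    KMax_F: float
    KMax_B: float
    DZMax_F: float
    DZMax_B: float
    NPtsR: float
    KAvg_F: float
    KAvg_B: float
    scan_id: str = ""
    laterality: str = ""
    notable_points: NotablePoints | None = None

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            bad = INDEX_NAMES[int(np.argmax(~np.isfinite(arr)))]
            raise ValueError(f"index {bad} is non-finite")
        if self.Thk_Min <= 0:
            raise ValueError("Thk_Min must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in INDEX_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in INDEX_NAMES}


@dataclass
class EIWeights:
    """Weights of the ectatic-index functional EI = b + sum_nm a1 c + a2 c^2."""

    nm_pairs: list
    alpha1: np.ndarray
    alpha2: np.ndarray
    intercept: float
    side: str
    version: str = "1"

    def __post_init__(self) -> None:
        self.alpha1 = np.asarray(self.alpha1, dtype=float)
        self.alpha2 = np.asarray(self.alpha2, dtype=float)
        if not (self.alpha1.size == self.alpha2.size == len(self.nm_pairs)):
            raise ValueError("weight arrays must match nm_pairs")
        if not (np.all(np.isfinite(self.alpha1)) and np.all(np.isfinite(self.alpha2))):
            raise ValueError("non-finite EI weights")

    def to_jsonable(self) -> dict:
        return {
            "nm_pairs": [list(p) for p in self.nm_pairs],
            "alpha1": self.alpha1.tolist(),
            "alpha2": self.alpha2.tolist(),
            "intercept": self.intercept,
            "side": self.side,
            "version": self.version,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "EIWeights":
        return cls(
            nm_pairs=[tuple(p) for p in d["nm_pairs"]],
            alpha1=np.array(d["alpha1"]),
            alpha2=np.array(d["alpha2"]),
            intercept=float(d["intercept"]),
            side=d["side"],
            version=d.get("version", "1"),
        )


@dataclass
class Profile:
    """A radial profile: annulus distance d (mm) -> percentage thickness increase."""

    d: np.ndarray
    values: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.d.shape != self.values.shape:
            raise ValueError("profile d and values must align")


# ---------------------------------------------------------------------------
# curvature-type indexes


def _si_zone_centers(laterality: str) -> tuple[tuple[float, float], tuple[float, float]]:
    try:
        inf_deg, sup_deg = SI_AXES[laterality]
    except KeyError:
        raise ValueError(f"laterality must be OD or OS, got {laterality!r}")
    to_xy = lambda a: (
        SI_CENTER_DISTANCE * math.cos(math.radians(a)),
        SI_CENTER_DISTANCE * math.sin(math.radians(a)),
    )
    return to_xy(inf_deg), to_xy(sup_deg)


def symmetry_index(curv: ScalarMap, laterality: str) -> float:
    """Inferior-zone mean minus superior-zone mean of a curvature map (D)."""
    inf_c, sup_c = _si_zone_centers(laterality)
    inf_mean = sample_zone_mean(curv, inf_c, SI_ZONE_RADIUS, clip=True)
    sup_mean = sample_zone_mean(curv, sup_c, SI_ZONE_RADIUS, clip=True)
    return inf_mean - sup_mean


def center_surrounding_index(curv: ScalarMap) -> float:
    """Central 1.5 mm disc mean minus 1.5-3.0 mm annulus mean (D)."""
    central = sample_annulus_mean(curv, 0.0, 1.5)
    surround = sample_annulus_mean(curv, 1.5, 3.0)
    return central - surround


def ectatic_index(spec: ZernikeSpectrum, w: EIWeights) -> float:
    """EI = intercept + sum_nm alpha1 c_nm + alpha2 c_nm^2 (dimensionless)."""
    if list(spec.nm_pairs) != list(w.nm_pairs):
        raise ValueError("spectrum and weights have mismatched (n, m) support")
    c = spec.coefficients
    return float(w.intercept + w.alpha1 @ c + w.alpha2 @ (c**2))


def train_ei_weights(
    spectra: list[ZernikeSpectrum],
    labels: list[str],
    side: str,
    C: float = 50.0,
) -> EIWeights:
    """Fit EI weights by regularized logistic discrimination of Normal vs Kcn.

    Features are (c_nm, c_nm^2); standardization is folded back into the
    weights so the stored alphas act on raw coefficients.  ``C`` is the total
    inverse-regularization budget, applied per sample (C/n), so duplicating
    the training set leaves the optimum unchanged.  Deterministic given data
    order.
    """
    labs = np.asarray(labels)
    classes = set(labs.tolist())
    if classes != {"Normal", "Kcn"}:
        raise ValueError(f"need both Normal and Kcn labels, got {sorted(classes)}")
    nm = list(spectra[0].nm_pairs)
    Cmat = np.vstack([s.coefficients for s in spectra])
    X = np.hstack([Cmat, Cmat**2])
    y = (labs == "Kcn").astype(int)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xs = (X - mu) / sd
    clf = LogisticRegression(C=C / len(labs), solver="lbfgs", max_iter=5000, tol=1e-10)
    clf.fit(Xs, y)
    w = clf.coef_[0] / sd
    b = float(clf.intercept_[0] - np.sum(clf.coef_[0] * mu / sd))
    k = len(nm)
    return EIWeights(nm_pairs=nm, alpha1=w[:k], alpha2=w[k:], intercept=b, side=side)


# ---------------------------------------------------------------------------
# elevation-type indexes


def _weighted_rms(smap: ScalarMap) -> float:
    w = smap.grid.area_weights()
    return float(np.sqrt(np.sum(w * smap.values**2) / np.sum(w)))


def rms_vs_reference(dev: ScalarMap) -> float:
    """Area-weighted RMS (um) of a deviation map over its support."""
    if dev.kind != "deviation":
        raise ValueError("rms_vs_reference expects a deviation map")
    return _weighted_rms(dev)


def _extremum(smap: ScalarMap, mode: str) -> tuple[float, tuple[float, float]]:
    """Extreme value and its cartesian location; apex included.

    Ties are broken by smallest radius, then smallest angle index (the apex,
    at radius 0, wins any tie it is part of).
    """
    vals = smap.values
    best = float(np.max(vals)) if mode == "max" else float(np.min(vals))
    if (mode == "max" and smap.apex >= best) or (mode == "min" and smap.apex <= best):
        return float(smap.apex), (0.0, 0.0)
    hits = np.argwhere(vals == best)
    # rows are ring index (radius order); argwhere is already lexicographic
    k, j = hits[0]
    r = smap.grid.radii[k]
    a = math.radians(smap.grid.angles_deg[j])
    return best, (r * math.cos(a), r * math.sin(a))


def dz_max(dev: ScalarMap) -> tuple[float, tuple[float, float]]:
    """Signed maximum (um) of a deviation map and its location."""
    if dev.kind != "deviation":
        raise ValueError("dz_max expects a deviation map")
    return _extremum(dev, "max")


def thickness_min(thk: ScalarMap) -> tuple[float, tuple[float, float]]:
    """Minimum thickness (um) in the mapped zone and its location."""
    if thk.kind != "thickness":
        raise ValueError("thickness_min expects a thickness map")
    return _extremum(thk, "min")


def thickness_symmetry_index(thk: ScalarMap, laterality: str) -> float:
    """Inferior minus superior mean thickness (um); negative for inferior thinning."""
    return symmetry_index(thk, laterality)


def k_max(curv: ScalarMap) -> tuple[float, tuple[float, float]]:
    """Maximum of a curvature map (D) and its location."""
    if curv.kind != "curvature":
        raise ValueError("k_max expects a curvature map")
    return _extremum(curv, "max")


def k_avg(elevation: ScalarMap, zone_diameter: float = 3.0) -> float:
    """Mean keratometric power (D) of the two principal meridians, central 3 mm."""
    rf, rs, _ = axial_principal_meridians(elevation, zone_diameter)
    return 0.5 * KERATOMETRIC_INDEX * (1.0 / rf + 1.0 / rs)


# ---------------------------------------------------------------------------
# thickness-progression indexes


def pct_thickness_increase_profile(
    thk: ScalarMap, center: tuple[float, float] | None = None
) -> Profile:
    """Percentage thickness increase vs annulus distance from the thinnest point.

    CT(d) is the mean thickness over the annulus band (d - 0.05, d + 0.05] mm
    around the thinnest point (clipped to the map support), for
    d = 0.1 ... 3.0 mm; PTI(d) = 100 * (CT(d) - CT_min) / CT_min.
    """
    g = thk.grid
    if center is None:
        ct_min, center = thickness_min(thk)
    else:
        from .scan import sample_point

        ct_min = sample_point(thk, *center)
    cx, cy = center
    truncated = g.max_radius - math.hypot(cx, cy) < 0.5
    x, y = g.mesh_cartesian()
    dist = np.hypot(x - cx, y - cy)
    w = g.area_weights()
    ds = np.round(np.arange(PTI_STEP, PTI_MAX_D + PTI_STEP / 2, PTI_STEP), 10)
    values = np.full(ds.size, np.nan)
    for i, d in enumerate(ds):
        band = (dist > d - PTI_STEP / 2) & (dist <= d + PTI_STEP / 2)
        if not np.any(band):
            continue
        ct = np.sum(w[band] * thk.values[band]) / np.sum(w[band])
        values[i] = 100.0 * (ct - ct_min) / ct_min
    return Profile(d=ds, values=values, truncated=truncated)


def pti_index(profile: Profile, normative_p95: Profile) -> float:
    """Max over d of PTI_subject(d) - PTI_p95(d); positive = abnormally fast."""
    if profile.d.shape != normative_p95.d.shape or not np.allclose(
        profile.d, normative_p95.d
    ):
        raise ValueError("profiles are on different d-grids")
    diff = profile.values - normative_p95.values
    valid = np.isfinite(diff)
    if not np.any(valid):
        raise ValueError("no overlapping valid annuli between profiles")
    return float(np.max(diff[valid]))


def epi_pti_index(epi_thk: ScalarMap, normative_epi_p95: Profile) -> float:
    """The %TI machinery applied to the epithelial map (centered on its minimum)."""
    return pti_index(pct_thickness_increase_profile(epi_thk), normative_epi_p95)


# ---------------------------------------------------------------------------
# notable points


def nps_spread(points: NotablePoints) -> float:
    """Mean Euclidean distance (mm) of the seven notable points from their barycenter."""
    arr = points.as_array()
    centroid = arr.mean(axis=0)
    return float(np.mean(np.linalg.norm(arr - centroid, axis=1)))


# ---------------------------------------------------------------------------
# orchestration


def compute_index_vector(
    scan: CornealScan,
    ei_w_f: EIWeights,
    ei_w_b: EIWeights,
    normative: "NormativeModel",
) -> IndexVector:
    """Compute all 19 indexes (and the notable points) for one scan."""
    from .evaluation import NormativeModel  # circular-import guard
    from .scan import canonical_scan

    assert isinstance(normative, NormativeModel)
    orig_lat = scan.laterality
    scan = canonical_scan(scan)  # OS eyes are mirrored into the OD frame
    lat = scan.laterality
    try:
        curv_f = gaussian_curvature_map(scan.anterior_elevation, "anterior")
        curv_b = gaussian_curvature_map(scan.posterior_elevation, "posterior")
        ref_f = fit_reference_asphotoric(scan.anterior_elevation, Q_ANTERIOR, 8.0)
        ref_b = fit_reference_asphotoric(scan.posterior_elevation, Q_POSTERIOR, 8.0)
        dev_f = deviation_map(scan.anterior_elevation, ref_f)
        dev_b = deviation_map(scan.posterior_elevation, ref_b)
        spec_f = fit_zernike(scan.anterior_elevation)
        spec_b = fit_zernike(scan.posterior_elevation)

        kmax_f, p_kmax_f = k_max(curv_f)
        kmax_b, p_kmax_b = k_max(curv_b)
        dzmax_f, p_dzmax_f = dz_max(dev_f)
        dzmax_b, p_dzmax_b = dz_max(dev_b)
        thk_min, p_thk_min = thickness_min(scan.corneal_thickness)
        _, p_epi_min = thickness_min(scan.epithelial_thickness)
        _, p_str_min = thickness_min(scan.stromal_thickness)
        points = NotablePoints(
            p_epi_thk_min=p_epi_min,
            p_str_thk_min=p_str_min,
            p_thk_min=p_thk_min,
            p_kmax_f=p_kmax_f,
            p_kmax_b=p_kmax_b,
            p_dzmax_f=p_dzmax_f,
            p_dzmax_b=p_dzmax_b,
        )

        return IndexVector(
            SI_F=symmetry_index(curv_f, lat),
            SI_B=symmetry_index(curv_b, lat),
            CSI_F=center_surrounding_index(curv_f),
            CSI_B=center_surrounding_index(curv_b),
            EI_F=ectatic_index(spec_f, ei_w_f),
            EI_B=ectatic_index(spec_b, ei_w_b),
            RMS_F=rms_vs_reference(dev_f),
            RMS_B=rms_vs_reference(dev_b),
            SI_THK=thickness_symmetry_index(scan.corneal_thickness, lat),
            pTI=pti_index(
                pct_thickness_increase_profile(scan.corneal_thickness),
                normative.pti_p95,
            ),
            pEpiTI=epi_pti_index(scan.epithelial_thickness, normative.epi_pti_p95),
            Thk_Min=thk_min,
            KMax_F=kmax_f,
            KMax_B=kmax_b,
            DZMax_F=dzmax_f,
            DZMax_B=dzmax_b,
            NPtsR=nps_spread(points),
            KAvg_F=k_avg(scan.anterior_elevation),
            KAvg_B=k_avg(scan.posterior_elevation),
            scan_id=scan.scan_id,
            laterality=orig_lat,
            notable_points=points,
        )
    except (ValueError, RuntimeError, DomainError) as exc:
        raise type(exc)(f"[scan {scan.scan_id}] {exc}") from exc
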