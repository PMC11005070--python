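"""Synthetic cornea generator for five diagnostic phenotypes.

Each synthetic eye is built from an aspho-toric base shape (anterior and
posterior) plus phenotype-specific perturbations:

* ``Normal`` — base shape only.
* ``Kcn`` — an additive radial Gaussian protrusion (the cone) on both
  surfaces (posterior amplified x1.3, posterior-first ectasia), a co-located
  Gaussian corneal thinning crater, focal epithelial thinning over the cone
  apex with a compensatory annular thickening ring around it.
* ``SKcn`` — the same mechanism at roughly half the keratoconic effect
  sizes (an attenuated cone, not a distinct mechanism).
* ``MyPO`` — a Munnerlyn-style paraboloid ablation of the anterior surface
  and thickness over a 6 mm optical zone (central flattening).
* ``Abn`` — band-limited random Zernike irregularity on the anterior
  surface and epithelium (scars / irregular corneas).

Gaussian measurement noise is added to every map (thickness maps get twice
the elevation noise, mirroring the coarser repeatability of pachymetry);
stromal thickness is corneal minus epithelial by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .scan import PolarGrid, ScalarMap, CornealScan, CLASS_ORDER, sample_point
from .geometry import asphotoric_sagitta, zernike_nm_pairs, zernike_basis

__all__ = [
    "PhenotypeParams",
    "TruncNormal",
    "ClassPriors",
    "default_priors",
    "generate_cornea",
    "generate_cohort",
    "is_value",
    "rule_based_label",
    "DEFAULT_CLASS_MIX",
]

#: study-like relative class frequencies (Abn, Kcn, MyPO, Normal, SKcn)
DEFAULT_CLASS_MIX = {"Abn": 669, "Kcn": 1616, "MyPO": 1519, "Normal": 2663, "SKcn": 210}


@dataclass
class PhenotypeParams:
    """All generator knobs for one synthetic eye (units in field names' docs).

    Radii in mm, thicknesses/heights/depths in um, angles in degrees.
    """

    base_radius_ant: float = 7.8
    base_radius_post: float = 6.4
    q_ant: float = -0.2
    q_post: float = -0.3
    toricity: float = 0.75  # D, anterior steep-minus-flat power
    axis: float = 0.0
    central_thickness: float = 545.0
    epithelial_thickness: float = 53.0
    cone_height: float = 0.0
    cone_width_sigma: float = 1.2  # mm
    cone_center_r: float = 1.2  # mm
    cone_center_theta: float = 270.0  # deg
    epi_thinning_depth: float = 0.0
    epi_annulus_gain: float = 0.0
    #: hemisphere-wide inferior steepening (vertical-coma signature of real
    #: cones), as um of coma-like elevation per um of cone height
    cone_coma_fraction: float = 0.5
    ablation_depth: float = 0.0  # MyPO only
    irregularity_rms: float = 0.0  # Abn only
    noise_sd: float = 0.5  # um, elevation maps (thickness maps get 2x)

    def validate(self) -> None:
        if not (6.5 <= self.base_radius_ant <= 9.5):
            raise ValueError(f"base_radius_ant {self.base_radius_ant} outside [6.5, 9.5]")
        if not (5.0 <= self.base_radius_post <= 9.5):
            raise ValueError(f"base_radius_post {self.base_radius_post} outside [5.0, 9.5]")
        if not (380.0 <= self.central_thickness <= 650.0):
            raise ValueError("central_thickness outside physiologic 380-650 um")
        if not (35.0 <= self.epithelial_thickness <= 75.0):
            raise ValueError("epithelial_thickness outside physiologic 35-75 um")
        for name in ("cone_height", "cone_width_sigma", "cone_center_r",
                     "epi_thinning_depth", "epi_annulus_gain", "cone_coma_fraction",
                     "ablation_depth", "irregularity_rms", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TruncNormal:
    """Truncated normal sampling helper (rejection; deterministic given rng)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(min(max(self.mean, self.lo), self.hi))
        for _ in range(1000):
            v = rng.normal(self.mean, self.sd)
            if self.lo <= v <= self.hi:
                return float(v)
        return float(min(max(self.mean, self.lo), self.hi))


@dataclass
class ClassPriors:
    """Per-class distributions over PhenotypeParams fields."""

    params: dict[str, dict[str, TruncNormal]]

    def sample(self, cls: str, rng: np.random.Generator) -> PhenotypeParams:
        spec = self.params[cls]
        kwargs = {name: dist.sample(rng) for name, dist in spec.items()}
        # uniform angular knobs
        kwargs["axis"] = float(rng.uniform(0.0, 180.0))
        if cls in ("Kcn", "SKcn"):
            kwargs["cone_center_theta"] = float(rng.normal(270.0, 20.0)) % 360.0
        p = PhenotypeParams(**kwargs)
        p.validate()
        return p


def default_priors() -> ClassPriors:
    """Default study conditions for the five phenotype classes."""
    normal_base = {
        "base_radius_ant": TruncNormal(7.8, 0.22, 7.2, 8.6),
        "base_radius_post": TruncNormal(6.4, 0.20, 5.8, 7.1),
        "toricity": TruncNormal(0.9, 0.6, 0.0, 3.0),
        "central_thickness": TruncNormal(545.0, 25.0, 480.0, 620.0),
        "epithelial_thickness": TruncNormal(53.0, 3.0, 44.0, 62.0),
        "noise_sd": TruncNormal(0.5, 0.0, 0.5, 0.5),
    }
    kcn = {
        **normal_base,
        "base_radius_ant": TruncNormal(7.5, 0.28, 6.8, 8.3),
        "base_radius_post": TruncNormal(6.2, 0.22, 5.6, 6.9),
        "central_thickness": TruncNormal(500.0, 28.0, 445.0, 575.0),
        "cone_height": TruncNormal(25.0, 8.0, 12.0, 50.0),
        "cone_width_sigma": TruncNormal(1.2, 0.2, 0.8, 1.8),
        "cone_center_r": TruncNormal(1.2, 0.35, 0.4, 2.0),
        "epi_thinning_depth": TruncNormal(8.0, 2.0, 3.0, 14.0),
        "epi_annulus_gain": TruncNormal(4.0, 1.5, 1.0, 8.0),
    }
    # attenuated keratoconus: cone_height and epi_thinning_depth at half the
    # keratoconic means, everything else near normal
    skcn = {
        **normal_base,
        "base_radius_ant": TruncNormal(7.7, 0.22, 7.1, 8.4),
        "central_thickness": TruncNormal(525.0, 25.0, 465.0, 600.0),
        "cone_height": TruncNormal(12.5, 2.5, 6.0, 19.0),
        "cone_width_sigma": TruncNormal(1.2, 0.2, 0.8, 1.8),
        "cone_center_r": TruncNormal(1.2, 0.35, 0.4, 2.0),
        "epi_thinning_depth": TruncNormal(4.0, 1.2, 1.0, 8.0),
        "epi_annulus_gain": TruncNormal(2.0, 0.8, 0.5, 4.0),
    }
    mypo = {
        **normal_base,
        "base_radius_ant": TruncNormal(7.8, 0.22, 7.2, 8.6),
        "central_thickness": TruncNormal(545.0, 25.0, 480.0, 620.0),
        "ablation_depth": TruncNormal(55.0, 25.0, 15.0, 120.0),
    }
    abn = {
        **normal_base,
        "irregularity_rms": TruncNormal(8.0, 3.0, 3.0, 20.0),
    }
    return ClassPriors(
        params={"Abn": abn, "Kcn": kcn, "MyPO": mypo, "Normal": normal_base, "SKcn": skcn}
    )


# ---------------------------------------------------------------------------
# map construction

#: peripheral corneal thickening coefficient, um per mm^2 (545 um center ->
#: ~640 um at the 4 mm rim, the usual central-to-peripheral gradient)
PERIPHERAL_THK_GAIN = 6.0
#: mild peripheral epithelial thinning, um per mm^2
PERIPHERAL_EPI_SLOPE = -0.12


def _cone_bump(grid: PolarGrid, params: PhenotypeParams) -> tuple[np.ndarray, float]:
    """Unit-amplitude Gaussian bump at the cone center; (rings x mer, apex)."""
    x, y = grid.mesh_cartesian()
    cx = params.cone_center_r * math.cos(math.radians(params.cone_center_theta))
    cy = params.cone_center_r * math.sin(math.radians(params.cone_center_theta))
    d2 = (x - cx) ** 2 + (y - cy) ** 2
    s2 = 2.0 * params.cone_width_sigma**2
    return np.exp(-d2 / s2), math.exp(-(cx**2 + cy**2) / s2)


def _ablation_profile(grid: PolarGrid, depth_um: float, zone_radius: float = 3.0):
    """Munnerlyn-style paraboloid removal: depth * (1 - (r/zone)^2), clipped at 0."""
    r, _ = grid.mesh_polar()
    prof = depth_um * np.maximum(1.0 - (r / zone_radius) ** 2, 0.0)
    return prof, depth_um  # apex value = full depth


def _irregularity(
    grid: PolarGrid, rms_um: float, rng: np.random.Generator, max_order: int = 8
):
    """Band-limited random surface: Zernike orders 2..max_order scaled to a target RMS."""
    nm = [p for p in zernike_nm_pairs(max_order) if p[0] >= 2]
    coeffs = rng.normal(0.0, 1.0, size=len(nm)) / np.array([n for n, _ in nm])
    coeffs *= rms_um / max(np.sqrt(np.sum(coeffs**2)), 1e-12)  # orthonormal basis
    r, t = grid.mesh_polar()
    rr = np.concatenate(([0.0], r.ravel()))
    tt = np.concatenate(([0.0], t.ravel()))
    vals = zernike_basis(nm, rr / grid.max_radius, tt) @ coeffs
    return vals[1:].reshape(grid.n_rings, grid.n_meridians), float(vals[0])


def generate_cornea(
    cls: str,
    params: PhenotypeParams,
    rng: np.random.Generator,
    grid: PolarGrid | None = None,
    laterality: str | None = None,
    scan_id: str = "",
) -> CornealScan:
    """Generate one synthetic scan of the given diagnostic class."""
    if cls not in CLASS_ORDER:
        raise ValueError(f"unknown class {cls!r}")
    params.validate()
    if grid is None:
        grid = PolarGrid()
    if laterality is None:
        laterality = "OD" if rng.random() < 0.5 else "OS"
    r, t = grid.mesh_polar()

    c_f = 1.0 / params.base_radius_ant
    c_s = c_f + params.toricity / 337.5
    ant = -asphotoric_sagitta(c_f, c_s, params.axis, params.q_ant, r, t)
    ant_apex = 0.0
    cpf = 1.0 / params.base_radius_post
    cps = cpf + 1.2 * params.toricity / 337.5
    post = -asphotoric_sagitta(cpf, cps, params.axis, params.q_post, r, t)
    post_apex = 0.0

    thk = params.central_thickness + PERIPHERAL_THK_GAIN * r**2
    thk_apex = params.central_thickness
    epi = params.epithelial_thickness + PERIPHERAL_EPI_SLOPE * r**2
    epi_apex = params.epithelial_thickness

    if cls in ("Kcn", "SKcn") and params.cone_height > 0:
        bump, bump_apex = _cone_bump(grid, params)
        h_mm = params.cone_height / 1000.0
        ant = ant + h_mm * bump
        ant_apex += h_mm * bump_apex
        post = post + 1.3 * h_mm * bump
        post_apex += 1.3 * h_mm * bump_apex
        # corneal thinning crater scales with the cone height (focal thinning)
        crater = 2.2 * params.cone_height
        thk = thk - crater * bump
        thk_apex -= crater * bump_apex
        epi = epi - params.epi_thinning_depth * bump
        epi_apex -= params.epi_thinning_depth * bump_apex
        if params.epi_annulus_gain > 0:
            # compensatory annular thickening around the cone
            x, y = grid.mesh_cartesian()
            cx = params.cone_center_r * math.cos(math.radians(params.cone_center_theta))
            cy = params.cone_center_r * math.sin(math.radians(params.cone_center_theta))
            d = np.hypot(x - cx, y - cy)
            ring_r = 1.8 * params.cone_width_sigma
            ring_w = 0.8 * params.cone_width_sigma
            ring = np.exp(-((d - ring_r) ** 2) / (2.0 * ring_w**2))
            epi = epi + params.epi_annulus_gain * ring
            d0 = math.hypot(cx, cy)
            epi_apex += params.epi_annulus_gain * math.exp(
                -((d0 - ring_r) ** 2) / (2.0 * ring_w**2)
            )

    if cls in ("Kcn", "SKcn") and params.cone_height > 0 and params.cone_coma_fraction > 0:
        # localized bumps alone flatten the mid-periphery around the cone; real
        # cones steepen the whole inferior hemisphere, which a coma-like term
        # (3 rho^3 - 2 rho) * cos(theta - theta_cone) reproduces
        coma_mm = params.cone_coma_fraction * params.cone_height / 1000.0
        rho = r / grid.max_radius
        m = np.cos(t - math.radians(params.cone_center_theta))
        # elevation is instrument-positive, so steepening = more negative
        # radial second derivative on the cone side
        steep = -coma_mm * (3.0 * rho**3 - 2.0 * rho) * m
        ant = ant + steep
        post = post + 1.3 * steep  # vanishes at the apex (rho = 0)

    if cls == "MyPO" and params.ablation_depth > 0:
        prof, prof_apex = _ablation_profile(grid, params.ablation_depth)
        ant = ant - prof / 1000.0
        ant_apex -= prof_apex / 1000.0
        thk = thk - prof
        thk_apex -= prof_apex

    if cls == "Abn" and params.irregularity_rms > 0:
        irr, irr_apex = _irregularity(grid, params.irregularity_rms, rng)
        ant = ant + irr / 1000.0
        ant_apex += irr_apex / 1000.0
        epi_irr, epi_irr_apex = _irregularity(grid, 0.5 * params.irregularity_rms, rng)
        epi = epi + epi_irr
        epi_apex += epi_irr_apex

    # elevation measurement error is spatially smooth (surface reconstruction
    # error), so it is modeled as a band-limited random surface at the target
    # RMS; pachymetry error is node-independent at twice the elevation RMS
    shape = ant.shape
    if params.noise_sd > 0:
        n_ant, n_ant_apex = _irregularity(grid, params.noise_sd, rng, max_order=10)
        n_post, n_post_apex = _irregularity(grid, params.noise_sd, rng, max_order=10)
        ant = ant + n_ant / 1000.0
        ant_apex += n_ant_apex / 1000.0
        post = post + n_post / 1000.0
        post_apex += n_post_apex / 1000.0
        thk = thk + rng.normal(0.0, 2.0 * params.noise_sd, shape)
        epi = epi + rng.normal(0.0, 2.0 * params.noise_sd, shape)
        thk_apex += float(rng.normal(0.0, 2.0 * params.noise_sd))
        epi_apex += float(rng.normal(0.0, 2.0 * params.noise_sd))

    # epithelium never erodes below a physiologic floor, even over scars
    epi = np.maximum(epi, 20.0)
    epi_apex = max(epi_apex, 20.0)

    stroma = thk - epi
    stroma_apex = thk_apex - epi_apex
    if np.any(stroma <= 0) or stroma_apex <= 0:
        raise ValueError("generated stromal thickness is non-positive; check params")

    return CornealScan(
        anterior_elevation=ScalarMap(grid, ant, ant_apex, "elevation"),
        posterior_elevation=ScalarMap(grid, post, post_apex, "elevation"),
        corneal_thickness=ScalarMap(grid, thk, thk_apex, "thickness"),
        epithelial_thickness=ScalarMap(grid, epi, epi_apex, "thickness"),
        stromal_thickness=ScalarMap(grid, stroma, stroma_apex, "thickness"),
        laterality=laterality,
        scan_id=scan_id,
    )


def generate_cohort(
    n_per_class: dict[str, int],
    priors: ClassPriors | None = None,
    seed: int = 0,
    grid: PolarGrid | None = None,
) -> list[tuple[CornealScan, str]]:
    """Labeled cohort of synthetic scans; fully determined by one seed."""
    if priors is None:
        priors = default_priors()
    rng = np.random.default_rng(seed)
    cohort = []
    for cls in CLASS_ORDER:
        for i in range(int(n_per_class.get(cls, 0))):
            params = priors.sample(cls, rng)
            scan = generate_cornea(
                cls, params, rng, grid=grid, scan_id=f"{cls}-{i:04d}"
            )
            cohort.append((scan, cls))
    return cohort


# ---------------------------------------------------------------------------
# rule-based diagnostic criteria (ground-truth cross-check)

IS_RING_RADIUS = 3.0
IS_INFERIOR_DEG = (210.0, 240.0, 270.0, 300.0, 330.0)
IS_SUPERIOR_DEG = (30.0, 60.0, 90.0, 120.0, 150.0)


def is_value(curv: ScalarMap, laterality: str = "OD") -> float:
    """Inferior-superior keratometric difference on the 3 mm-radius ring (D).

    Mean curvature at five inferior points minus five superior points at 30
    degree spacing (the classic I-S convention).  The point sets are mirror
    symmetric about the vertical axis, so OD/OS give equal values by
    construction; laterality is accepted for interface symmetry.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be OD or OS")

    def ring_mean(angles):
        vals = []
        for a in angles:
            x = IS_RING_RADIUS * math.cos(math.radians(a))
            y = IS_RING_RADIUS * math.sin(math.radians(a))
            vals.append(sample_point(curv, x, y))
        return float(np.mean(vals))

    return ring_mean(IS_INFERIOR_DEG) - ring_mean(IS_SUPERIOR_DEG)


#: default normality cutoffs for the rule-based labeler, matched to the
#: default normal priors: p5 of central thickness N(545, 25) and of
#: epithelial thickness N(53, 3)
RULE_THK_P5_UM = 504.0
RULE_EPI_P5_UM = 48.0
RULE_IS_THRESHOLD_D = 1.4
RULE_CENTRAL_K_D = 47.2


def rule_based_label(
    scan: CornealScan,
    thk_p5: float = RULE_THK_P5_UM,
    epi_p5: float = RULE_EPI_P5_UM,
) -> tuple[str, dict[str, bool]]:
    """Quantitative keratoconus criteria; Kcn when at least two fire.

    Criteria: I-S > 1.4 D; central K (mean anterior curvature over the
    central 3 mm) > 47.2 D; focal corneal thinning (minimum below the normal
    5th percentile, off-center or co-located with the curvature maximum);
    focal epithelial thinning over the cone apex.
    """
    from .scan import sample_annulus_mean
    from .geometry import gaussian_curvature_map
    from .indexes import thickness_min, k_max

    curv_f = gaussian_curvature_map(scan.anterior_elevation, "anterior")
    i_s = is_value(curv_f, scan.laterality)
    central_k = sample_annulus_mean(curv_f, 0.0, 1.5)
    kmax, p_kmax = k_max(curv_f)
    thk_min, p_thk = thickness_min(scan.corneal_thickness)
    epi_min, p_epi = thickness_min(scan.epithelial_thickness)

    off_center = math.hypot(*p_thk) > 0.5
    near_kmax = math.hypot(p_thk[0] - p_kmax[0], p_thk[1] - p_kmax[1]) <= 1.0
    epi_near_kmax = math.hypot(p_epi[0] - p_kmax[0], p_epi[1] - p_kmax[1]) <= 1.0

    report = {
        "is_gt_1.4": i_s > RULE_IS_THRESHOLD_D,
        "central_k_gt_47.2": central_k > RULE_CENTRAL_K_D,
        "focal_corneal_thinning": thk_min < thk_p5 and (off_center or near_kmax),
        "focal_epithelial_thinning": epi_min < epi_p5 and epi_near_kmax,
    }
    label = "Kcn" if sum(report.values()) >= 2 else "not-Kcn"
    return label, report
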