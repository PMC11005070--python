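"""Shared fixtures: grids, analytic surfaces, matched phenotype pairs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from keratoscreen.scan import PolarGrid, ScalarMap, CornealScan
from keratoscreen.geometry import conic_sagitta, asphotoric_sagitta
from keratoscreen.simulate import default_priors, generate_cornea

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid() -> PolarGrid:
    return PolarGrid()


@pytest.fixture(scope="session")
def coarse_grid() -> PolarGrid:
    return PolarGrid(n_rings=16, n_meridians=64)


def sphere_elevation(grid: PolarGrid, R: float) -> ScalarMap:
    r, _ = grid.mesh_polar()
    return ScalarMap(grid, -(R - np.sqrt(R**2 - r**2)), 0.0, "elevation")


def conicoid_elevation(grid: PolarGrid, R0: float, Q: float) -> ScalarMap:
    r, _ = grid.mesh_polar()
    return ScalarMap(grid, -conic_sagitta(1.0 / R0, Q, r), 0.0, "elevation")


def toric_elevation(
    grid: PolarGrid, r_flat: float, r_steep: float, axis: float, Q: float = 0.0
) -> ScalarMap:
    r, t = grid.mesh_polar()
    sag = asphotoric_sagitta(1.0 / r_flat, 1.0 / r_steep, axis, Q, r, t)
    return ScalarMap(grid, -sag, 0.0, "elevation")


def uniform_scan(
    grid: PolarGrid,
    cct: float = 540.0,
    epi: float = 50.0,
    laterality: str = "OD",
    scan_id: str = "uniform",
) -> CornealScan:
    """Ideal conicoid normal eye with flat thickness maps."""
    ant = conicoid_elevation(grid, 7.8, -0.2)
    post = conicoid_elevation(grid, 6.4, -0.3)
    ones = np.ones((grid.n_rings, grid.n_meridians))
    return CornealScan(
        anterior_elevation=ant,
        posterior_elevation=post,
        corneal_thickness=ScalarMap(grid, cct * ones, cct, "thickness"),
        epithelial_thickness=ScalarMap(grid, epi * ones, epi, "thickness"),
        stromal_thickness=ScalarMap(grid, (cct - epi) * ones, cct - epi, "thickness"),
        laterality=laterality,
        scan_id=scan_id,
    )


@pytest.fixture(scope="session")
def matched_pair(grid):
    """A keratoconic eye and the identical eye with the cone removed."""
    pri = default_priors()
    rng = np.random.default_rng(2024)
    pk = pri.sample("Kcn", rng)
    scan_k = generate_cornea("Kcn", pk, np.random.default_rng(99), grid=grid, laterality="OD")
    pn = dataclasses.replace(
        pk, cone_height=0.0, epi_thinning_depth=0.0, epi_annulus_gain=0.0
    )
    scan_n = generate_cornea("Normal", pn, np.random.default_rng(99), grid=grid, laterality="OD")
    return scan_n, scan_k


@pytest.fixture(scope="session")
def small_cohort(grid):
    """22 Normal + 22 Kcn eyes, used by EI-weight and AUC checks."""
    from keratoscreen.simulate import generate_cohort

    return generate_cohort({"Normal": 22, "Kcn": 22}, seed=303, grid=grid)


@pytest.fixture(scope="session")
def trained_ei(small_cohort):
    from keratoscreen.geometry import fit_zernike
    from keratoscreen.indexes import train_ei_weights
    from keratoscreen.scan import canonical_scan

    spec_f, spec_b, labels = [], [], []
    for scan, cls in small_cohort:
        c = canonical_scan(scan)
        spec_f.append(fit_zernike(c.anterior_elevation))
        spec_b.append(fit_zernike(c.posterior_elevation))
        labels.append(cls)
    return (
        train_ei_weights(spec_f, labels, "anterior"),
        train_ei_weights(spec_b, labels, "posterior"),
        spec_f,
        labels,
    )


@pytest.fixture(scope="session")
def normative_from_pair(matched_pair):
    """Minimal normative model built from the matched normal eye."""
    from keratoscreen.evaluation import NormativeModel, percentile_profile
    from keratoscreen.indexes import INDEX_NAMES, pct_thickness_increase_profile

    scan_n, _ = matched_pair
    zero = {n: {"p1": 0.0, "p5": 0.0, "p95": 0.0, "p99": 0.0} for n in INDEX_NAMES}
    pti = [pct_thickness_increase_profile(scan_n.corneal_thickness)]
    epi = [pct_thickness_increase_profile(scan_n.epithelial_thickness)]
    return NormativeModel(
        percentiles=zero,
        pti_p95=percentile_profile(pti, 95.0),
        epi_pti_p95=percentile_profile(epi, 95.0),
    )
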