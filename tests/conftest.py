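import numpy as np
import pytest

from ezar import LayerSurfaces, PhenotypeParams, ScanGeometry


@pytest.fixture
def small_geometry() -> ScanGeometry:
    """Desk-scale macular cube: 32 B-scans of 128x128 over 6 x 6 mm."""
    return ScanGeometry(
        n_bscans=32,
        n_ascans=128,
        n_depth=128,
        lateral_scale=6000 / 128,
        bscan_spacing=6000 / 32,
        fovea_bscan=16,
        fovea_ascan=64,
    )


@pytest.fixture
def quiet_params() -> PhenotypeParams:
    """Pathology-free phenotype (no drusen, patches, or GA; no speckle)."""
    return PhenotypeParams(
        n_drusen=0,
        n_attenuation_patches=0,
        n_ga_lesions=0,
        speckle_sigma=0.0,
    )


def make_surfaces(
    n_bscans: int,
    n_ascans: int,
    ez_rpe_um: np.ndarray | float,
    rpe_bm_um: np.ndarray | float,
    axial_scale: float = 4.0,
    bm_row: float = 100.0,
    ez_absent=None,
    rpe_absent=None,
) -> LayerSurfaces:
    """Flat surfaces with prescribed pair thicknesses (µm) per column."""
    shape = (n_bscans, n_ascans)
    t_ez = np.broadcast_to(np.asarray(ez_rpe_um, dtype=float), shape)
    t_rpe = np.broadcast_to(np.asarray(rpe_bm_um, dtype=float), shape)
    bm = np.full(shape, bm_row)
    rpe = bm - t_rpe / axial_scale
    ez = rpe - t_ez / axial_scale
    onl = ez - 5.0
    if ez_absent is not None:
        ez = np.where(ez_absent, np.nan, ez)
    if rpe_absent is not None:
        rpe = np.where(rpe_absent, np.nan, rpe)
    return LayerSurfaces(onl=onl, ez=ez, rpe=rpe, bm=bm)


@pytest.fixture
def flat_surfaces_factory():
    return make_surfaces
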