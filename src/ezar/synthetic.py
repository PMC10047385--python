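"""Seeded synthetic SD-OCT volumes with AMD-like outer-retinal pathology.

The generator emulates a 6 x 6 mm macular cube: a smooth Bruch's membrane,
an RPE band elevated by Gaussian drusen, an EZ band whose distance to the
RPE shrinks inside radially decaying attenuation patches, and elliptical
geographic-atrophy (GA) lesions where EZ and RPE are absent and the choroid
shows hypertransmission.  B-scans are rendered as bright Gaussian bands over
a dim background with multiplicative speckle.

Ground truth is always produced by running the rule module on the generated
surfaces — the generator never hand-labels pathology — so generator and
rules cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BScanMask,
    EnFaceMap,
    LayerSurfaces,
    OCTVolume,
    ScanGeometry,
    ValidationError,
)
from .rules import (
    RuleThresholds,
    derive_at_risk_columns,
    detect_ga_columns,
    render_training_mask,
)
from .core import thickness_map

__all__ = [
    "PhenotypeParams",
    "GroundTruth",
    "generate_surfaces",
    "render_volume",
    "generate_labeled_volume",
]

Range = tuple[float, float]


@dataclass(frozen=True)
class PhenotypeParams:
    """Pathology mix of one synthetic eye.

    Counts are numbers of lesions; ranges are (low, high) in µm unless
    noted.  ``attenuation_depth`` is the fraction of the baseline EZ-RPE
    thickness removed at a patch center (1.0 collapses the EZ fully).
    """

    n_drusen: int = 8
    druse_height: Range = (20.0, 60.0)
    druse_radius: Range = (100.0, 300.0)
    n_attenuation_patches: int = 6
    attenuation_depth: Range = (0.8, 1.0)
    patch_radius: Range = (400.0, 900.0)
    n_ga_lesions: int = 1
    ga_radius: Range = (300.0, 700.0)
    baseline_ez_rpe: float = 35.0
    baseline_rpe_bm: float = 25.0
    speckle_sigma: float = 0.25
    hypertransmission_gain: float = 2.0
    onl_offset: float = 80.0  # µm, EZ to ONL boundary
    placement_margin: float = 500.0  # µm kept clear of the field edge
    foveal_pit: bool = True
    pit_depth: float = 60.0  # µm, downward shift of all surfaces at fovea
    pit_sigma: float = 400.0  # µm, lateral extent of the pit
    # Optional explicit en-face centers in µm (bscan axis, ascan axis); the
    # i-th lesion uses the i-th entry, any further lesions stay random.
    druse_centers: tuple = ()
    patch_centers: tuple = ()
    ga_centers: tuple = ()

    def __post_init__(self) -> None:
        for name in ("n_drusen", "n_attenuation_patches", "n_ga_lesions"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("druse_height", "druse_radius", "patch_radius", "ga_radius"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} range must be positive")
        lo, hi = self.attenuation_depth
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("attenuation_depth must lie in [0, 1]")
        if self.speckle_sigma < 0:
            raise ValidationError("speckle_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Rule-derived labels for one synthetic eye."""

    ga_columns: EnFaceMap
    at_risk_columns: EnFaceMap
    band_masks: list[BScanMask]


def _enface_um_grid(geometry: ScanGeometry) -> tuple[np.ndarray, np.ndarray]:
    y = np.arange(geometry.n_bscans)[:, None] * geometry.bscan_spacing
    x = np.arange(geometry.n_ascans)[None, :] * geometry.lateral_scale
    return y, x


def _uniform_center(rng, geometry: ScanGeometry, margin: float):
    y_max = (geometry.n_bscans - 1) * geometry.bscan_spacing
    x_max = (geometry.n_ascans - 1) * geometry.lateral_scale
    m_y = min(margin, 0.4 * y_max)
    m_x = min(margin, 0.4 * x_max)
    return rng.uniform(m_y, y_max - m_y), rng.uniform(m_x, x_max - m_x)


def generate_surfaces(
    geometry: ScanGeometry,
    params: PhenotypeParams,
    seed: int,
) -> LayerSurfaces:
    """Generate ONL/EZ/RPE/BM surfaces for one eye.

    Deterministic in ``(geometry, params, seed)``.  Lesion parameters are
    drawn sequentially from per-component streams, so raising a lesion
    count keeps the already-drawn lesions identical (superset policy).
    """
    # Independent child streams so component counts do not perturb each other.
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_bm, rng_drusen, rng_patch, rng_ga = (
        np.random.default_rng(s) for s in streams
    )
    y, x = _enface_um_grid(geometry)
    ax = geometry.axial_scale

    # Bruch's membrane: base depth plus <=5 bounded low-frequency cosines.
    bm = np.full(geometry.enface_shape, 0.65 * geometry.n_depth)
    n_terms = int(rng_bm.integers(3, 6))
    for _ in range(n_terms):
        amp = rng_bm.uniform(0.2, 1.0) * 0.02 * geometry.n_depth
        fy = rng_bm.uniform(-1.5, 1.5) / max(geometry.fov_bscan_um, 1.0)
        fx = rng_bm.uniform(-1.5, 1.5) / max(geometry.fov_ascan_um, 1.0)
        phase = rng_bm.uniform(0, 2 * np.pi)
        bm = bm + amp * np.cos(2 * np.pi * (fy * y + fx * x) + phase)

    # Drusen elevate the RPE (and everything above it) away from BM.
    elevation_um = np.zeros(geometry.enface_shape)
    for i_d in range(params.n_drusen):
        cy, cx = _uniform_center(rng_drusen, geometry, params.placement_margin)
        if i_d < len(params.druse_centers):
            cy, cx = params.druse_centers[i_d]
        h = rng_drusen.uniform(*params.druse_height)
        r = rng_drusen.uniform(*params.druse_radius)
        sigma = r / 2.0
        d2 = (y - cy) ** 2 + (x - cx) ** 2
        elevation_um += h * np.exp(-d2 / (2 * sigma**2))

    # EZ-RPE thickness field, thinned inside attenuation patches.
    removal = np.zeros(geometry.enface_shape)
    for i_p in range(params.n_attenuation_patches):
        cy, cx = _uniform_center(rng_patch, geometry, params.placement_margin)
        if i_p < len(params.patch_centers):
            cy, cx = params.patch_centers[i_p]
        depth = rng_patch.uniform(*params.attenuation_depth)
        r = rng_patch.uniform(*params.patch_radius)
        sigma = r / 2.0
        d2 = (y - cy) ** 2 + (x - cx) ** 2
        removal += depth * np.exp(-d2 / (2 * sigma**2))
    t_um = params.baseline_ez_rpe * np.clip(1.0 - removal, 0.0, 1.0)

    # GA lesions: elliptical en-face regions of complete EZ+RPE absence.
    ga = np.zeros(geometry.enface_shape, dtype=bool)
    for i_g in range(params.n_ga_lesions):
        cy, cx = _uniform_center(rng_ga, geometry, params.placement_margin)
        if i_g < len(params.ga_centers):
            cy, cx = params.ga_centers[i_g]
        ra = rng_ga.uniform(*params.ga_radius)
        rb = rng_ga.uniform(*params.ga_radius)
        theta = rng_ga.uniform(0, np.pi)
        dy, dx = y - cy, x - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        ga |= (u / ra) ** 2 + (v / rb) ** 2 <= 1.0

    rpe = bm - (params.baseline_rpe_bm + elevation_um) / ax
    ez = rpe - t_um / ax
    onl = ez - params.onl_offset / ax

    if params.foveal_pit:
        d2 = (y - geometry.fovea_bscan * geometry.bscan_spacing) ** 2 + (
            x - geometry.fovea_ascan * geometry.lateral_scale
        ) ** 2
        pit = (params.pit_depth / ax) * np.exp(-d2 / (2 * params.pit_sigma**2))
        for surf in (onl, ez, rpe, bm):
            surf += pit

    ez = np.where(ga, np.nan, ez)
    rpe = np.where(ga, np.nan, rpe)

    surfaces = LayerSurfaces(onl=onl, ez=ez, rpe=rpe, bm=bm)
    try:
        surfaces.validate(geometry)
    except ValidationError as exc:
        raise ValidationError(
            f"generated surfaces violate invariants ({exc}); reduce lesion "
            f"heights or increase n_depth"
        ) from exc
    return surfaces


# Rendering constants: band amplitudes and vertical Gaussian width (px).
_BAND_AMPLITUDE = {"onl": 0.35, "ez": 0.50, "rpe": 0.55, "bm": 0.40}
_BAND_SIGMA_PX = 1.3
_BACKGROUND = 0.06
_CHOROID_EXTRA = 0.12


def render_volume(
    surfaces: LayerSurfaces,
    geometry: ScanGeometry,
    params: PhenotypeParams,
    seed: int,
) -> OCTVolume:
    """Render B-scans: Gaussian bright bands, choroid glow, speckle.

    Columns where EZ/RPE are absent leave no band; below-BM intensity there
    is multiplied by ``hypertransmission_gain`` (GA hypertransmission).
    """
    if surfaces.shape != geometry.enface_shape:
        raise ValidationError("surfaces do not match geometry")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    rows = np.arange(geometry.n_depth)[:, None, None]  # (depth, 1, 1)

    def band(surface: np.ndarray, amp: float) -> np.ndarray:
        s = surface[None, :, :]
        out = amp * np.exp(-((rows - s) ** 2) / (2 * _BAND_SIGMA_PX**2))
        return np.nan_to_num(out, nan=0.0)

    intensity = np.full(
        (geometry.n_depth, geometry.n_bscans, geometry.n_ascans), _BACKGROUND
    )
    below_bm = rows > surfaces.bm[None, :, :]
    intensity += _CHOROID_EXTRA * below_bm
    for name, amp in _BAND_AMPLITUDE.items():
        intensity += band(surfaces.layer(name), amp)

    ga_cols = np.isnan(surfaces.ez) & np.isnan(surfaces.rpe)
    if params.hypertransmission_gain != 1.0 and ga_cols.any():
        gain_region = below_bm & ga_cols[None, :, :]
        intensity = np.where(
            gain_region, intensity * params.hypertransmission_gain, intensity
        )

    if params.speckle_sigma > 0:
        g = rng.standard_normal(intensity.shape)
        intensity = intensity * np.maximum(0.0, 1.0 + params.speckle_sigma * g)

    stack = np.clip(np.transpose(intensity, (1, 0, 2)), 0.0, 1.0)
    return OCTVolume(geometry, stack)


def generate_labeled_volume(
    geometry: ScanGeometry,
    params: PhenotypeParams,
    seed: int,
    thr: RuleThresholds = RuleThresholds(),
) -> tuple[OCTVolume, LayerSurfaces, GroundTruth]:
    """Generate one eye: volume, surfaces, and rule-derived ground truth."""
    surfaces = generate_surfaces(geometry, params, seed)
    volume = render_volume(surfaces, geometry, params, seed)
    t_ez_rpe = thickness_map(surfaces, geometry, "EZ_RPE")
    t_rpe_bm = thickness_map(surfaces, geometry, "RPE_BM")
    ga = detect_ga_columns(
        t_ez_rpe, t_rpe_bm, thr, lateral_scale=geometry.lateral_scale
    )
    at_risk = derive_at_risk_columns(t_ez_rpe, ga, thr)
    masks = [
        render_training_mask(at_risk, surfaces, i, thr, geometry=geometry)
        for i in range(geometry.n_bscans)
    ]
    return volume, surfaces, GroundTruth(ga, at_risk, masks)
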