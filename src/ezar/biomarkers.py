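"""Eye/visit-level quantitative biomarkers.

Six features per eye and visit, all derived from the layer surfaces:

* ``pct_ez_at_risk`` — % of en-face columns flagged EZ At-Risk
* ``pct_partial_ez_atten`` — % with EZ-RPE thickness < 20 µm
* ``pct_total_ez_rpe_atten`` — % with EZ-RPE thickness of 0 µm
* ``pct_rpe_bm_atten`` — % with RPE-BM thickness of 0 µm
* ``mean_cs_ez_rpe`` — mean EZ-RPE thickness (µm) over the central subfield
* ``mean_cs_rpe_bm`` — mean RPE-BM thickness (µm) over the central subfield

plus the GA-derived labels: sub-foveal GA (a GA column on the foveal
B-scan), fovea-threatening GA (a GA column inside the 0.5 mm-radius central
subfield) and the GA lesion area in mm².  Percentage areas use all A-scan
columns of the en-face field as denominator so values compare across eyes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .core import (
    EnFaceMap,
    LayerSurfaces,
    MapKind,
    ScanGeometry,
    ValidationError,
    thickness_map,
)
from .rules import (
    RuleThresholds,
    attenuation_columns,
    derive_at_risk_columns,
    detect_ga_columns,
)

__all__ = [
    "BiomarkerRecord",
    "percentage_area",
    "central_subfield_mask",
    "mean_central_subfield_thickness",
    "ga_labels",
    "compute_record",
    "FEATURE_COLUMNS",
]

CENTRAL_SUBFIELD_RADIUS_UM = 500.0

#: The six predictive features, in the order they are modelled downstream.
FEATURE_COLUMNS = (
    "pct_ez_at_risk",
    "pct_partial_ez_atten",
    "pct_total_ez_rpe_atten",
    "pct_rpe_bm_atten",
    "mean_cs_ez_rpe",
    "mean_cs_rpe_bm",
)


@dataclass
class BiomarkerRecord:
    eye_id: str
    visit: str
    pct_ez_at_risk: float
    pct_partial_ez_atten: float
    pct_total_ez_rpe_atten: float
    pct_rpe_bm_atten: float
    mean_cs_ez_rpe: float
    mean_cs_rpe_bm: float
    sfga: bool
    fovea_threat: bool
    ga_area: float  # mm^2

    def __post_init__(self) -> None:
        for name in FEATURE_COLUMNS[:4]:
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name}={v} outside [0, 100]")
        if self.pct_total_ez_rpe_atten > self.pct_partial_ez_atten + 1e-9:
            raise ValidationError("total attenuation % exceeds partial %")
        if self.mean_cs_ez_rpe < 0 or self.mean_cs_rpe_bm < 0:
            raise ValidationError("central-subfield thickness < 0")
        if self.ga_area < 0:
            raise ValidationError("ga_area < 0")

    def to_dict(self) -> dict:
        return asdict(self)


def percentage_area(flags: EnFaceMap) -> float:
    """Percent of en-face columns flagged, at full floating precision."""
    if flags.kind is not MapKind.FLAG:
        raise ValidationError("percentage_area needs a flag map")
    n = flags.values.size
    if n == 0:
        raise ValidationError("empty en-face map")
    return 100.0 * float(np.count_nonzero(flags.values)) / n


def central_subfield_mask(geometry: ScanGeometry) -> EnFaceMap:
    """Columns within 0.5 mm of the fovea in the en-face plane."""
    i = np.arange(geometry.n_bscans)[:, None]
    j = np.arange(geometry.n_ascans)[None, :]
    d2 = ((i - geometry.fovea_bscan) * geometry.bscan_spacing) ** 2 + (
        (j - geometry.fovea_ascan) * geometry.lateral_scale
    ) ** 2
    return EnFaceMap(d2 <= CENTRAL_SUBFIELD_RADIUS_UM**2, MapKind.FLAG)


def mean_central_subfield_thickness(t: EnFaceMap, cs: EnFaceMap) -> float:
    """Arithmetic mean of a thickness map over the central-subfield columns."""
    t.check_same_grid(cs)
    if not cs.values.any():
        raise ValidationError("central subfield selects no columns")
    return float(t.values[cs.values].mean())


def ga_labels(
    ga: EnFaceMap, geometry: ScanGeometry
) -> tuple[bool, bool, float]:
    """(sfGA, fovea-threatening, GA area in mm²) from the GA flag map.

    sfGA: any GA column on the foveal B-scan itself.  Fovea-threatening:
    any GA column inside the 0.5 mm central subfield.  The two definitions
    are evaluated independently.
    """
    if ga.shape != geometry.enface_shape:
        raise ValidationError("GA map does not match geometry")
    sfga = bool(ga.values[geometry.fovea_bscan].any())
    cs = central_subfield_mask(geometry)
    fovea_threat = bool((ga.values & cs.values).any())
    area_mm2 = (
        float(np.count_nonzero(ga.values))
        * geometry.lateral_scale
        * geometry.bscan_spacing
        / 1e6
    )
    return sfga, fovea_threat, area_mm2


def compute_record(
    surfaces: LayerSurfaces,
    geometry: ScanGeometry,
    thr: RuleThresholds = RuleThresholds(),
    eye_id: str = "eye",
    visit: str = "0",
) -> BiomarkerRecord:
    """Chain the full rule pipeline into one eye/visit biomarker row."""
    surfaces.validate(geometry)
    t_ez_rpe = thickness_map(surfaces, geometry, "EZ_RPE")
    t_rpe_bm = thickness_map(surfaces, geometry, "RPE_BM")
    ga = detect_ga_columns(
        t_ez_rpe, t_rpe_bm, thr, lateral_scale=geometry.lateral_scale
    )
    at_risk = derive_at_risk_columns(t_ez_rpe, ga, thr)
    partial = attenuation_columns(t_ez_rpe, "partial_ez", thr)
    total_ez = attenuation_columns(t_ez_rpe, "total_ez_rpe", thr)
    total_rpe = attenuation_columns(t_rpe_bm, "total_rpe_bm", thr)
    cs = central_subfield_mask(geometry)
    sfga, fovea_threat, ga_area = ga_labels(ga, geometry)
    return BiomarkerRecord(
        eye_id=eye_id,
        visit=visit,
        pct_ez_at_risk=percentage_area(at_risk),
        pct_partial_ez_atten=percentage_area(partial),
        pct_total_ez_rpe_atten=percentage_area(total_ez),
        pct_rpe_bm_atten=percentage_area(total_rpe),
        mean_cs_ez_rpe=mean_central_subfield_thickness(t_ez_rpe, cs),
        mean_cs_rpe_bm=mean_central_subfield_thickness(t_rpe_bm, cs),
        sfga=sfga,
        fovea_threat=fovea_threat,
        ga_area=ga_area,
    )


def bscan_percentage_area(flags: EnFaceMap, bscan: int) -> float:
    """Per-B-scan variant of percentage_area (that B-scan's columns only)."""
    row = flags.values[bscan]
    return 100.0 * float(np.count_nonzero(row)) / row.size
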