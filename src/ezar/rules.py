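"""Rule-based derivation of GA, EZ At-Risk, and attenuation maps.

The EZ At-Risk biomarker flags en-face columns whose EZ-RPE thickness has
thinned to <= 10 um but that have not yet progressed to geographic atrophy
(GA).  GA itself is operationalised at the segmentation level as confluence
of the EZ, RPE and BM surfaces: both the EZ-RPE and the RPE-BM thickness
collapse to 0.  For model training the flagged columns are rasterised into
a 10-pixel band centered on the EZ line of each B-scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BScanMask,
    EnFaceMap,
    LayerSurfaces,
    MapKind,
    ScanGeometry,
    ValidationError,
    round_half_up,
)

__all__ = [
    "RuleThresholds",
    "detect_ga_columns",
    "derive_at_risk_columns",
    "attenuation_columns",
    "render_training_mask",
]


@dataclass(frozen=True)
class RuleThresholds:
    """Thresholds of the column rules.

    at_risk_max
        Maximum EZ-RPE thickness (µm) for an at-risk column; inclusive.
    partial_max
        Partial-attenuation threshold (µm); strict (< 20 µm).
    total_tol
        Numeric tolerance (µm) below which a real-valued thickness counts
        as total attenuation (0 µm).
    ga_min_extent
        Minimum contiguous lateral width (µm) of a GA run within a B-scan;
        0 disables the filter.
    band_px
        Vertical thickness in pixels of the rasterised training band.
    """

    at_risk_max: float = 10.0
    partial_max: float = 20.0
    total_tol: float = 1e-6
    ga_min_extent: float = 0.0
    band_px: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.total_tol < self.at_risk_max < self.partial_max):
            raise ValidationError(
                "need 0 <= total_tol < at_risk_max < partial_max"
            )
        if self.band_px < 1:
            raise ValidationError("band_px must be >= 1")
        if self.ga_min_extent < 0:
            raise ValidationError("ga_min_extent must be >= 0")


def _require_same_grid(*maps: EnFaceMap) -> None:
    for m in maps[1:]:
        maps[0].check_same_grid(m)


def detect_ga_columns(
    t_ez_rpe: EnFaceMap,
    t_rpe_bm: EnFaceMap,
    thr: RuleThresholds = RuleThresholds(),
    lateral_scale: float | None = None,
) -> EnFaceMap:
    """Flag columns where both EZ-RPE and RPE-BM thickness are 0 (GA).

    If ``thr.ga_min_extent`` > 0, contiguous runs of flagged columns within
    a B-scan shorter than ``ga_min_extent / lateral_scale`` columns are
    cleared (``lateral_scale`` is then required).
    """
    _require_same_grid(t_ez_rpe, t_rpe_bm)
    ga = (t_ez_rpe.values <= thr.total_tol) & (
        t_rpe_bm.values <= thr.total_tol
    )
    if thr.ga_min_extent > 0:
        if lateral_scale is None:
            raise ValidationError(
                "lateral_scale required when ga_min_extent > 0"
            )
        min_cols = int(np.ceil(thr.ga_min_extent / lateral_scale))
        ga = _clear_short_runs(ga, min_cols)
    return EnFaceMap(ga, MapKind.FLAG)


def _clear_short_runs(flags: np.ndarray, min_cols: int) -> np.ndarray:
    out = flags.copy()
    for i in range(flags.shape[0]):
        row = flags[i]
        j = 0
        n = row.size
        while j < n:
            if row[j]:
                k = j
                while k < n and row[k]:
                    k += 1
                if k - j < min_cols:
                    out[i, j:k] = False
                j = k
            else:
                j += 1
    return out


def derive_at_risk_columns(
    t_ez_rpe: EnFaceMap,
    ga: EnFaceMap,
    thr: RuleThresholds = RuleThresholds(),
) -> EnFaceMap:
    """Flag EZ At-Risk columns: EZ-RPE thickness <= 10 µm, outside GA."""
    _require_same_grid(t_ez_rpe, ga)
    at_risk = (t_ez_rpe.values <= thr.at_risk_max) & ~ga.values
    return EnFaceMap(at_risk, MapKind.FLAG)


_ATTENUATION_KINDS = ("partial_ez", "total_ez_rpe", "total_rpe_bm")


def attenuation_columns(
    t: EnFaceMap,
    kind: str,
    thr: RuleThresholds = RuleThresholds(),
) -> EnFaceMap:
    """Flag attenuation columns on the appropriate pair's thickness map.

    ``partial_ez``: EZ-RPE thickness < 20 µm (strict; includes total
    attenuation, so the partial region is a superset of the total one).
    ``total_ez_rpe`` / ``total_rpe_bm``: thickness 0 µm within tolerance.
    The caller is responsible for passing the matching pair's map.
    """
    if kind not in _ATTENUATION_KINDS:
        raise ValidationError(f"kind must be one of {_ATTENUATION_KINDS}")
    if kind == "partial_ez":
        flags = t.values < thr.partial_max
    else:
        flags = t.values <= thr.total_tol
    return EnFaceMap(flags, MapKind.FLAG)


def render_training_mask(
    at_risk: EnFaceMap,
    surfaces: LayerSurfaces,
    bscan: int,
    thr: RuleThresholds = RuleThresholds(),
    n_depth: int | None = None,
    geometry: ScanGeometry | None = None,
) -> BScanMask:
    """Rasterise the flagged columns of one B-scan into a vertical band mask.

    Each flagged column gets ``band_px`` rows centered on the EZ line
    (``floor(band_px/2)`` above, ``ceil(band_px/2)`` below the half-up
    rounded row), clipped at the image borders.  At flagged columns where
    the EZ is absent the band centers on the RPE line instead.  There is no
    lateral dilation: the band's lateral extent is exactly the flagged
    columns.
    """
    if geometry is not None:
        n_depth = geometry.n_depth
    if n_depth is None:
        raise ValidationError("n_depth or geometry required")
    n_b, n_a = at_risk.shape
    if not (0 <= bscan < n_b):
        raise ValidationError(f"bscan index {bscan} out of range [0, {n_b})")
    if surfaces.shape != at_risk.shape:
        raise ValidationError("surfaces do not match the flag map grid")
    mask = np.zeros((n_depth, n_a), dtype=bool)
    flags = at_risk.values[bscan]
    ez = surfaces.ez[bscan]
    rpe = surfaces.rpe[bscan]
    half_lo = thr.band_px // 2
    half_hi = thr.band_px - half_lo
    for j in np.flatnonzero(flags):
        center = ez[j] if np.isfinite(ez[j]) else rpe[j]
        if not np.isfinite(center):
            raise ValidationError(
                f"no EZ or RPE row to center the band at column {j} of "
                f"B-scan {bscan}"
            )
        c = int(round_half_up(center))
        lo = max(c - half_lo, 0)
        hi = min(c + half_hi, n_depth)
        mask[lo:hi, j] = True
    return BScanMask(mask)
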