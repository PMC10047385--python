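"""Shared data model and coordinate conventions.

Conventions used throughout the package:

* All grids are 0-based.  Within a B-scan, row 0 is at the vitreous (top)
  and rows increase toward the choroid.
* The en-face frame is ``(bscan index, ascan index)``: element ``(i, j)``
  of any en-face product refers to A-scan column ``j`` of B-scan ``i``.
* Layer-surface rows are real-valued (sub-pixel); rasterisation rounds
  half-up to integer rows.
* All intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import numpy.typing as npt

__all__ = [
    "DeviceProfile",
    "ScanGeometry",
    "LayerSurfaces",
    "OCTVolume",
    "EnFaceMap",
    "BScanMask",
    "ValidationError",
    "FormatError",
    "thickness_map",
    "LAYERS",
]

#: Layer names in anatomical order, vitreous side first.
LAYERS = ("onl", "ez", "rpe", "bm")

#: Default axial sampling in µm per pixel (typical Spectralis optics).
DEFAULT_AXIAL_SCALE = 3.87


class ValidationError(ValueError):
    """Raised when data violates a structural invariant."""


class FormatError(ValueError):
    """Raised when an on-disk artifact cannot be parsed."""


class DeviceProfile(str, Enum):
    """Macular-cube acquisition presets (6 x 6 mm field of view)."""

    SPECTRALIS49 = "spectralis49"
    SPECTRALIS97 = "spectralis97"
    CIRRUS128 = "cirrus128"
    CUSTOM = "custom"


_PROFILE_NBSCANS = {
    DeviceProfile.SPECTRALIS49: 49,
    DeviceProfile.SPECTRALIS97: 97,
    DeviceProfile.CIRRUS128: 128,
}

#: Nominal en-face field of view of the macular-cube protocols, µm.
FIELD_OF_VIEW_UM = 6000.0


@dataclass(frozen=True)
class ScanGeometry:
    """Grid dimensions, physical scaling and fovea position of a volume.

    Parameters
    ----------
    n_bscans, n_ascans, n_depth
        Raster dimensions: number of B-scans, A-scan columns per B-scan,
        and depth rows per B-scan.
    axial_scale
        µm per pixel along depth (rows).
    lateral_scale
        µm per pixel along the A-scan (column) direction.
    bscan_spacing
        µm between adjacent B-scans.
    fovea_bscan, fovea_ascan
        En-face index of the foveal center.
    device_profile
        Acquisition preset; constrains ``n_bscans`` and the en-face field
        of view for the named devices.
    """

    n_bscans: int
    n_ascans: int
    n_depth: int
    axial_scale: float = DEFAULT_AXIAL_SCALE
    lateral_scale: float = FIELD_OF_VIEW_UM / 512
    bscan_spacing: float = FIELD_OF_VIEW_UM / 49
    fovea_bscan: int = 0
    fovea_ascan: int = 0
    device_profile: DeviceProfile = DeviceProfile.CUSTOM

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "device_profile", DeviceProfile(self.device_profile)
        )
        for name in ("n_bscans", "n_ascans", "n_depth"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("axial_scale", "lateral_scale", "bscan_spacing"):
            if not float(getattr(self, name)) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0 <= self.fovea_bscan < self.n_bscans):
            raise ValidationError("fovea_bscan outside grid")
        if not (0 <= self.fovea_ascan < self.n_ascans):
            raise ValidationError("fovea_ascan outside grid")
        profile = self.device_profile
        if profile in _PROFILE_NBSCANS:
            want = _PROFILE_NBSCANS[profile]
            if self.n_bscans != want:
                raise ValidationError(
                    f"profile {profile.value} requires n_bscans={want}, "
                    f"got {self.n_bscans}"
                )
            for fov in (self.fov_bscan_um, self.fov_ascan_um):
                if abs(fov - FIELD_OF_VIEW_UM) > 0.1 * FIELD_OF_VIEW_UM:
                    raise ValidationError(
                        f"profile {profile.value} implies a ~6 mm field of "
                        f"view; got {fov:.0f} um"
                    )

    @property
    def fov_bscan_um(self) -> float:
        """En-face extent across B-scans, µm."""
        return self.n_bscans * self.bscan_spacing

    @property
    def fov_ascan_um(self) -> float:
        """En-face extent along an A-scan row, µm."""
        return self.n_ascans * self.lateral_scale

    @property
    def enface_shape(self) -> tuple[int, int]:
        return (self.n_bscans, self.n_ascans)

    @property
    def bscan_shape(self) -> tuple[int, int]:
        return (self.n_depth, self.n_ascans)

    @classmethod
    def from_profile(
        cls,
        profile: DeviceProfile | str,
        n_ascans: int = 512,
        n_depth: int = 496,
        axial_scale: float = DEFAULT_AXIAL_SCALE,
        fovea_bscan: int | None = None,
        fovea_ascan: int | None = None,
    ) -> "ScanGeometry":
        """Build a 6 x 6 mm macular-cube geometry for a named device."""
        profile = DeviceProfile(profile)
        if profile is DeviceProfile.CUSTOM:
            raise ValidationError("from_profile needs a named device profile")
        n_bscans = _PROFILE_NBSCANS[profile]
        return cls(
            n_bscans=n_bscans,
            n_ascans=n_ascans,
            n_depth=n_depth,
            axial_scale=axial_scale,
            lateral_scale=FIELD_OF_VIEW_UM / n_ascans,
            bscan_spacing=FIELD_OF_VIEW_UM / n_bscans,
            fovea_bscan=fovea_bscan if fovea_bscan is not None else n_bscans // 2,
            fovea_ascan=fovea_ascan if fovea_ascan is not None else n_ascans // 2,
            device_profile=profile,
        )

    def to_dict(self) -> dict:
        return {
            "n_bscans": self.n_bscans,
            "n_ascans": self.n_ascans,
            "n_depth": self.n_depth,
            "axial_scale": self.axial_scale,
            "lateral_scale": self.lateral_scale,
            "bscan_spacing": self.bscan_spacing,
            "fovea_bscan": self.fovea_bscan,
            "fovea_ascan": self.fovea_ascan,
            "device_profile": self.device_profile.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**d)


def _as_surface_array(a, shape) -> npt.NDArray[np.float64]:
    arr = np.asarray(a, dtype=float)
    if arr.shape != shape:
        raise ValidationError(f"surface array shape {arr.shape} != {shape}")
    return arr


@dataclass
class LayerSurfaces:
    """Per-(B-scan, A-scan) row positions of the ONL, EZ, RPE and BM surfaces.

    Each attribute is an ``(n_bscans, n_ascans)`` float array of row
    positions; ``NaN`` is the absence sentinel (EZ and/or RPE may be absent
    where the band is atrophic; ONL and BM are always present).
    """

    onl: npt.NDArray[np.float64]
    ez: npt.NDArray[np.float64]
    rpe: npt.NDArray[np.float64]
    bm: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        shape = np.asarray(self.bm, dtype=float).shape
        if len(shape) != 2:
            raise ValidationError("surfaces must be 2-D (n_bscans, n_ascans)")
        for name in LAYERS:
            setattr(self, name, _as_surface_array(getattr(self, name), shape))

    @property
    def shape(self) -> tuple[int, int]:
        return self.bm.shape

    def layer(self, name: str) -> npt.NDArray[np.float64]:
        if name not in LAYERS:
            raise KeyError(f"unknown layer {name!r}")
        return getattr(self, name)

    def present(self, name: str) -> npt.NDArray[np.bool_]:
        """Boolean en-face map of where ``name``'s surface is present."""
        return ~np.isnan(self.layer(name))

    def validate(self, geometry: ScanGeometry | None = None) -> "LayerSurfaces":
        """Check ordering and range invariants; return self.

        Raises
        ------
        ValidationError
            If BM is absent anywhere, rows fall outside ``[0, n_depth)``
            (when a geometry is given), or the anatomical ordering
            ONL <= EZ <= RPE <= BM is violated at a column where the pair
            is present.
        """
        if np.isnan(self.bm).any():
            raise ValidationError("BM surface must be present at every column")
        if geometry is not None:
            if self.shape != geometry.enface_shape:
                raise ValidationError(
                    f"surfaces shape {self.shape} != geometry "
                    f"{geometry.enface_shape}"
                )
            for name in LAYERS:
                arr = self.layer(name)
                ok = np.isnan(arr) | ((arr >= 0) & (arr < geometry.n_depth))
                if not ok.all():
                    raise ValidationError(f"{name} rows outside [0, n_depth)")
        tol = 1e-9
        for upper, lower in zip(LAYERS[:-1], LAYERS[1:]):
            u, lo = self.layer(upper), self.layer(lower)
            both = ~np.isnan(u) & ~np.isnan(lo)
            bad = both & (u > lo + tol)
            if bad.any():
                coords = np.argwhere(bad)[:5].tolist()
                raise ValidationError(
                    f"row({upper}) > row({lower}) at (bscan, ascan) {coords}"
                )
        return self

    def copy(self) -> "LayerSurfaces":
        return LayerSurfaces(
            self.onl.copy(), self.ez.copy(), self.rpe.copy(), self.bm.copy()
        )


@dataclass
class OCTVolume:
    """A raster stack of grayscale B-scans with its acquisition geometry."""

    geometry: ScanGeometry
    bscans: npt.NDArray[np.float64]  # (n_bscans, n_depth, n_ascans) in [0,1]

    def __post_init__(self) -> None:
        self.bscans = np.asarray(self.bscans, dtype=float)
        want = (
            self.geometry.n_bscans,
            self.geometry.n_depth,
            self.geometry.n_ascans,
        )
        if self.bscans.shape != want:
            raise ValidationError(
                f"B-scan stack shape {self.bscans.shape} != geometry {want}"
            )
        if self.bscans.size and (
            self.bscans.min() < -1e-9 or self.bscans.max() > 1 + 1e-9
        ):
            raise ValidationError("intensities must lie in [0, 1]")


class MapKind(str, Enum):
    THICKNESS = "thickness"
    FLAG = "flag"


@dataclass
class EnFaceMap:
    """An ``(n_bscans, n_ascans)`` en-face grid of thicknesses (µm) or flags."""

    values: np.ndarray
    kind: MapKind = MapKind.THICKNESS

    def __post_init__(self) -> None:
        self.kind = MapKind(self.kind)
        if self.kind is MapKind.FLAG:
            self.values = np.asarray(self.values, dtype=bool)
        else:
            self.values = np.asarray(self.values, dtype=float)
            finite = np.isfinite(self.values)
            if (self.values[finite] < -1e-9).any():
                raise ValidationError("thickness values must be >= 0")
        if self.values.ndim != 2:
            raise ValidationError("en-face map must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def check_same_grid(self, other: "EnFaceMap") -> None:
        if self.shape != other.shape:
            raise ValidationError(
                f"en-face grids differ: {self.shape} vs {other.shape}"
            )


@dataclass
class BScanMask:
    """Boolean pixel mask over one B-scan (n_depth, n_ascans)."""

    pixels: npt.NDArray[np.bool_]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValidationError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


_PAIRS = {"EZ_RPE": ("ez", "rpe"), "RPE_BM": ("rpe", "bm")}


def thickness_map(
    surfaces: LayerSurfaces,
    geometry: ScanGeometry,
    pair: str,
) -> EnFaceMap:
    """En-face thickness of a surface pair, in µm.

    ``pair`` is ``"EZ_RPE"`` or ``"RPE_BM"``.  Per column the thickness is
    ``(row(lower) - row(upper)) * axial_scale``.  A column where the upper
    band is absent (and in the EZ-RPE case, where both are absent) has
    thickness 0: absence of a band is total attenuation of that band.

    Raises
    ------
    ValidationError
        If shapes are inconsistent or a present pair has a negative pixel
        difference beyond tolerance (corrupt surfaces).
    """
    if pair not in _PAIRS:
        raise ValidationError(f"pair must be one of {sorted(_PAIRS)}")
    if surfaces.shape != geometry.enface_shape:
        raise ValidationError("surfaces do not match geometry")
    upper_name, lower_name = _PAIRS[pair]
    upper = surfaces.layer(upper_name)
    lower = surfaces.layer(lower_name)
    diff_px = lower - upper
    both = ~np.isnan(upper) & ~np.isnan(lower)
    if (diff_px[both] < -1e-6).any():
        raise ValidationError(
            f"negative {pair} thickness: corrupt surface ordering"
        )
    t = np.zeros(surfaces.shape, dtype=float)
    t[both] = np.maximum(diff_px[both], 0.0) * geometry.axial_scale
    # Upper band absent (with or without the lower): total attenuation -> 0.
    return EnFaceMap(t, MapKind.THICKNESS)


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer with halves going up (toward +inf)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)
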