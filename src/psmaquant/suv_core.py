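"""Volume/mask data model, SUV conversion and geometric primitives.

Images are 3-D scalar grids in body-weight-normalised standardized uptake
value (SUVbw) units, index-ordered (x, y, z) with 0-based voxel indices.
Physical coordinates follow the voxel-centre convention::

    x_mm = origin + index * spacing

Masks must live on exactly the same grid as the image they annotate; no
resampling is performed anywhere in the package — a grid mismatch is an
error, never a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

logger = logging.getLogger("psmaquant")

#: default gallium-68 half-life in minutes, overridable per acquisition
GA68_HALF_LIFE_MIN = 67.71


class GridMismatchError(ValueError):
    """A mask or activity map does not share the grid of its image."""


@dataclass(frozen=True)
class SUVImage:
    """A 3-D PET volume in SUV(body-weight) units.

    Parameters
    ----------
    values
        Non-negative scalar grid, shape ``(nx, ny, nz)``.
    spacing
        Per-axis voxel edge length in mm, all > 0.
    origin
        Physical offset of voxel (0, 0, 0) in mm.
    frame_id
        Text label tying masks to this grid.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_id: str = "frame0"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError(f"SUV grid must be 3-D with >=1 voxel per axis, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("SUV values must be finite")
        if values.min() < 0:
            raise ValueError("SUV values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be three positive lengths, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel indices, voxel-centre convention."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class OrganMaskSet:
    """Named binary organ/exclusion masks aligned to one image grid.

    Typical names: ``bladder``, ``kidneys``, ``salivary_glands``, ``liver``,
    ``healthy_liver``, ``other_physiological``. ``liver`` marks the whole
    liver compartment (segmented with the relative threshold); the package
    treats every other mask as a physiological exclusion.
    """

    masks: Mapping[str, np.ndarray]
    frame_id: str = "frame0"

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, arr in self.masks.items():
            arr = np.asarray(arr)
            if arr.dtype != bool:
                uniq = np.unique(arr)
                if not np.all(np.isin(uniq, (0, 1))):
                    raise ValueError(f"mask '{name}' is not strictly binary (values {uniq[:5]}...)")
                arr = arr.astype(bool)
            if arr.ndim != 3:
                raise ValueError(f"mask '{name}' must be 3-D")
            clean[name] = arr
        object.__setattr__(self, "masks", clean)

    def validate_against(self, image: SUVImage) -> None:
        """Raise :class:`GridMismatchError` unless every mask shares the image grid."""
        if self.frame_id != image.frame_id:
            raise GridMismatchError(
                f"mask frame '{self.frame_id}' does not match image frame '{image.frame_id}'"
            )
        for name, arr in self.masks.items():
            if arr.shape != image.shape:
                raise GridMismatchError(
                    f"mask '{name}' shape {arr.shape} does not match image shape {image.shape}"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Injection/scan metadata needed to normalise an activity map to SUVbw."""

    injected_activity_mbq: float
    injection_time: datetime
    scan_time: datetime
    body_weight_kg: float
    half_life_min: float = GA68_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ValueError(f"injected activity must be positive, got {self.injected_activity_mbq} MBq")
        if self.body_weight_kg <= 0:
            raise ValueError(f"body weight must be positive, got {self.body_weight_kg} kg")
        if self.half_life_min <= 0:
            raise ValueError("isotope half-life must be positive")
        if self.scan_time < self.injection_time:
            raise ValueError("scan time precedes injection time")

    @property
    def elapsed_min(self) -> float:
        return (self.scan_time - self.injection_time).total_seconds() / 60.0

    def decay_corrected_activity_bq(self) -> float:
        """Injected activity decayed from injection to scan start, in Bq."""
        decay = 0.5 ** (self.elapsed_min / self.half_life_min)
        return self.injected_activity_mbq * 1e6 * decay


def to_suv(activity_map: np.ndarray, meta: AcquisitionMeta, *,
           spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
           origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
           frame_id: str = "frame0") -> SUVImage:
    """Convert an activity concentration map (Bq/mL) to body-weight SUV.

    SUV = concentration [Bq/mL] x body weight [g] / decay-corrected injected
    activity [Bq], with the injected activity corrected from injection time
    to scan start using the isotope half-life. The conversion is linear in
    the activity map.
    """
    activity = np.asarray(activity_map, dtype=np.float64)
    if activity.min() < 0:
        raise ValueError("activity map must be non-negative")
    suv = activity * (meta.body_weight_kg * 1e3) / meta.decay_corrected_activity_bq()
    return SUVImage(values=suv, spacing=spacing, origin=origin, frame_id=frame_id)


def voxel_volume_ml(image: SUVImage) -> float:
    """Volume of one voxel in mL (product of mm spacings / 1000)."""
    sx, sy, sz = image.spacing
    return sx * sy * sz / 1000.0


# ---------------------------------------------------------------------------
# NIfTI-1 and JSON-sidecar I/O
# ---------------------------------------------------------------------------

def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    affine = np.diag((*spacing, 1.0))
    affine[:3, 3] = origin
    return affine


def save_suv_nifti(image: SUVImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(image.values.astype(np.float32), _affine(image.spacing, image.origin)), str(path))


def load_suv_nifti(path: str | Path, frame_id: str | None = None) -> SUVImage:
    """Read an SUV volume; spacing from the header zooms, origin from the affine."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return SUVImage(values=np.asanyarray(img.dataobj, dtype=np.float64),
                    spacing=spacing, origin=origin,
                    frame_id=frame_id or Path(path).stem)


def save_mask_nifti(mask: np.ndarray, image: SUVImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(np.uint8), _affine(image.spacing, image.origin)), str(path))


def load_mask_set(paths: Mapping[str, str | Path], frame_id: str = "frame0") -> OrganMaskSet:
    masks = {name: np.asanyarray(nib.load(str(p)).dataobj) > 0 for name, p in paths.items()}
    return OrganMaskSet(masks=masks, frame_id=frame_id)


def load_acquisition_meta(path: str | Path) -> AcquisitionMeta:
    """Read acquisition metadata from a JSON sidecar.

    Expected keys: injected_activity_mbq, injection_time, scan_time
    (ISO-8601), body_weight_kg and optionally half_life_min.
    """
    with open(path) as fh:
        raw = json.load(fh)
    return AcquisitionMeta(
        injected_activity_mbq=float(raw["injected_activity_mbq"]),
        injection_time=datetime.fromisoformat(raw["injection_time"]),
        scan_time=datetime.fromisoformat(raw["scan_time"]),
        body_weight_kg=float(raw["body_weight_kg"]),
        half_life_min=float(raw.get("half_life_min", GA68_HALF_LIFE_MIN)),
    )
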