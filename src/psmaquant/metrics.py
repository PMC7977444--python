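"""Whole-body tumour-burden quantification: per-lesion and total MTV and TLP.

MTV (molecular tumour volume) is the segmented lesion volume in mL; TLP
(total lesion PSMA, the PSMA analogue of total lesion glycolysis) is the
sum over lesions of MTV x SUV_mean, expressed in mL x SUV to distinguish
it from MTV. Lesion-wise TLP is algebraically identical to the voxelwise
sum of SUV x voxel volume over all lesion voxels; tests exploit that
identity. All arithmetic is double precision; rounding happens only in the
export layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .suv_core import SUVImage, voxel_volume_ml

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import LesionSet

#: radius (mm) of the 1 mL sphere used for SUV_peak: (3*1000 / 4pi)^(1/3)
PEAK_SPHERE_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class LesionStats:
    mtv_ml: float
    suv_mean: float
    suv_max: float
    suv_peak: float
    centroid_mm: tuple[float, float, float]


@dataclass(frozen=True)
class BurdenSummary:
    """Whole-body totals over a lesion set."""

    tlp: float  # mL x SUV
    mtv: float  # mL
    n_lesions: int
    suv_max_global: float
    suv_peak_global: float


def suv_peak(image: SUVImage, hottest_index: tuple[int, int, int]) -> float:
    """Mean SUV in a 1 mL sphere centred at the given voxel.

    The sphere is voxelised by centre-inclusion (a voxel belongs to the
    sphere iff its centre lies within the radius) and clipped to the grid.
    """
    spacing = np.asarray(image.spacing)
    centre = np.asarray(hottest_index, dtype=np.float64)
    half = np.ceil(PEAK_SPHERE_RADIUS_MM / spacing).astype(int)
    lo = np.maximum(np.asarray(hottest_index) - half, 0)
    hi = np.minimum(np.asarray(hottest_index) + half + 1, image.shape)
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    offsets = np.stack([(g - c) * s for g, c, s in zip(grids, centre, spacing)])
    inside = np.sum(offsets**2, axis=0) <= PEAK_SPHERE_RADIUS_MM**2
    block = image.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return float(block[inside].mean())


def lesion_stats(voxel_indices: np.ndarray, image: SUVImage) -> LesionStats:
    """Per-lesion MTV and SUV statistics for a set of voxel indices.

    ``voxel_indices`` is an (n, 3) integer array of grid indices. SUV_mean
    is the arithmetic mean over the voxel set, SUV_max the maximum, and
    SUV_peak the 1 mL sphere mean centred at the lesion's hottest voxel.
    """
    idx = np.atleast_2d(np.asarray(voxel_indices, dtype=np.intp))
    if idx.size == 0:
        raise ValueError("lesion voxel set is empty")
    if idx.min() < 0 or np.any(idx >= np.asarray(image.shape)):
        raise ValueError("lesion voxel indices fall outside the image grid")
    suvs = image.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    hottest = tuple(int(i) for i in idx[int(np.argmax(suvs))])
    centroid = tuple(float(c) for c in image.index_to_physical(idx).mean(axis=0))
    return LesionStats(
        mtv_ml=len(idx) * voxel_volume_ml(image),
        suv_mean=float(suvs.mean()),
        suv_max=float(suvs.max()),
        suv_peak=suv_peak(image, hottest),
        centroid_mm=centroid,  # type: ignore[arg-type]
    )


def total_burden(lesions: "LesionSet | Iterable") -> BurdenSummary:
    """Whole-body burden: MTV = sum of lesion volumes, TLP = sum MTV_i x SUV_mean_i.

    An empty lesion set yields the all-zero summary (TLP = 0 iff MTV = 0).
    """
    items = list(getattr(lesions, "lesions", lesions))
    if not items:
        return BurdenSummary(tlp=0.0, mtv=0.0, n_lesions=0, suv_max_global=0.0, suv_peak_global=0.0)
    mtv = float(sum(l.mtv_ml for l in items))
    tlp = float(sum(l.mtv_ml * l.suv_mean for l in items))
    return BurdenSummary(
        tlp=tlp,
        mtv=mtv,
        n_lesions=len(items),
        suv_max_global=float(max(l.suv_max for l in items)),
        suv_peak_global=float(max(l.suv_peak for l in items)),
    )


def burden_to_frame(summary: BurdenSummary, patient_id: str, timepoint: str) -> pd.DataFrame:
    """One CSV-ready row per burden summary (TLP/MTV rounded to 1 d.p. for display)."""
    return pd.DataFrame([{
        "patient_id": patient_id,
        "timepoint": timepoint,
        "tlp": round(summary.tlp, 1),
        "mtv": round(summary.mtv, 1),
        "n_lesions": summary.n_lesions,
        "suv_max": round(summary.suv_max_global, 2),
        "suv_peak": round(summary.suv_peak_global, 2),
    }])
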