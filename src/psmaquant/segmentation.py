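"""SUV-threshold tumour segmentation with organ exclusion and liver rule.

Semi-automatic whole-body segmentation as used for PSMA-PET burden
quantification: voxels at or above a fixed SUV threshold (default 3.0)
outside caller-supplied physiological-organ masks are grouped into
connected components; liver lesions are segmented separately at
``liver_factor x SUV_mean(healthy liver)`` (default 1.5x) because the high
physiological hepatic background swamps the global threshold. The
threshold comparison is inclusive (SUV >= threshold).

Physiological exclusion is mask-based and caller-supplied, mirroring the
manual step of the clinical workflow; no automatic organ detection is
attempted. Longitudinal new-lesion detection is a centroid-distance
surrogate for expert reading, and a manual per-patient new-metastasis
flag always takes precedence downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import metrics
from .suv_core import OrganMaskSet, SUVImage, voxel_volume_ml

logger = logging.getLogger("psmaquant")

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

COMPARTMENTS = ("bone", "node", "liver", "other", "unspecified")


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable segmentation parameters.

    global_threshold
        Fixed SUV cut-off applied outside the liver (default 3.0).
    liver_factor
        Multiplier on healthy-liver SUV_mean for the liver compartment
        (default 1.5).
    connectivity
        Neighbourhood order for component labelling: 6, 18 or 26.
    min_voxels
        Components smaller than this are dropped (default 1: keep all).
    matching_radius_mm
        Centroid distance below which pre/post lesions are considered the
        same lesion when screening for new metastases (default 15 mm).
    """

    global_threshold: float = 3.0
    liver_factor: float = 1.5
    connectivity: int = 26
    min_voxels: int = 1
    matching_radius_mm: float = 15.0

    def __post_init__(self) -> None:
        if self.global_threshold <= 0:
            raise ValueError("global_threshold must be positive")
        if self.liver_factor <= 0:
            raise ValueError("liver_factor must be positive")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.matching_radius_mm <= 0:
            raise ValueError("matching_radius_mm must be positive")


@dataclass(frozen=True)
class Lesion:
    """One connected supra-threshold component with its burden statistics."""

    label: int
    voxel_indices: np.ndarray  # (n, 3) int
    mtv_ml: float
    suv_mean: float
    suv_max: float
    suv_peak: float
    centroid_mm: tuple[float, float, float]
    compartment: str = "unspecified"

    def __post_init__(self) -> None:
        idx = np.atleast_2d(np.asarray(self.voxel_indices, dtype=np.intp))
        if idx.size == 0:
            raise ValueError("lesion voxel set must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment '{self.compartment}'")
        if self.suv_mean > self.suv_max + 1e-12:
            raise ValueError("suv_mean cannot exceed suv_max")
        object.__setattr__(self, "voxel_indices", idx)

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)


@dataclass(frozen=True)
class LesionSet:
    lesions: tuple[Lesion, ...]
    frame_id: str
    config_used: SegmentationConfig

    def __post_init__(self) -> None:
        labels = [l.label for l in self.lesions]
        if len(set(labels)) != len(labels):
            raise ValueError("lesion labels must be unique")
        object.__setattr__(self, "lesions", tuple(self.lesions))

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)


def liver_threshold(image: SUVImage, healthy_liver: np.ndarray, factor: float = 1.5) -> float:
    """Relative liver threshold: ``factor x mean SUV over the healthy-liver mask``."""
    mask = np.asarray(healthy_liver, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("healthy_liver mask does not match the image grid")
    if not mask.any():
        raise ValueError("healthy_liver mask is empty; the relative liver threshold is undefined")
    return float(factor * image.values[mask].mean())


def _label_components(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    return ndimage.label(mask, structure=structure)


def _components_to_lesions(mask: np.ndarray, image: SUVImage, config: SegmentationConfig,
                           compartment: str, first_label: int) -> list[Lesion]:
    labelled, n = _label_components(mask, config.connectivity)
    lesions: list[Lesion] = []
    label = first_label
    for comp in range(1, n + 1):
        idx = np.argwhere(labelled == comp)
        if len(idx) < config.min_voxels:
            continue
        stats = metrics.lesion_stats(idx, image)
        lesions.append(Lesion(
            label=label, voxel_indices=idx, mtv_ml=stats.mtv_ml,
            suv_mean=stats.suv_mean, suv_max=stats.suv_max, suv_peak=stats.suv_peak,
            centroid_mm=stats.centroid_mm, compartment=compartment,
        ))
        label += 1
    return lesions


def segment_lesions(image: SUVImage, exclusions: OrganMaskSet | None = None,
                    config: SegmentationConfig | None = None) -> LesionSet:
    """Threshold-based whole-body lesion segmentation.

    Voxels with SUV >= ``global_threshold`` outside all exclusion masks and
    outside the liver are labelled into connected components; if a
    ``liver`` mask is supplied, liver voxels are thresholded separately at
    ``liver_factor x SUV_mean(healthy_liver)`` and appended as
    liver-compartment lesions. A ``liver`` mask without a ``healthy_liver``
    mask is rejected because the relative threshold is then undefined.
    """
    config = config or SegmentationConfig()
    liver_mask = None
    exclusion_union = np.zeros(image.shape, dtype=bool)
    if exclusions is not None:
        exclusions.validate_against(image)
        for name, mask in exclusions.masks.items():
            if name == "liver":
                liver_mask = mask
            elif name == "healthy_liver":
                continue  # reference region, not an exclusion
            else:
                exclusion_union |= mask
        if liver_mask is not None and "healthy_liver" not in exclusions:
            raise ValueError(
                "a liver mask requires a healthy_liver mask: the liver threshold "
                "1.5 x SUV_mean(healthy liver) is otherwise undefined"
            )

    body_mask = (image.values >= config.global_threshold) & ~exclusion_union
    if liver_mask is not None:
        body_mask &= ~liver_mask
    lesions = _components_to_lesions(body_mask, image, config, "unspecified", first_label=1)

    if liver_mask is not None:
        thr = liver_threshold(image, exclusions["healthy_liver"], config.liver_factor)
        liver_hot = (image.values >= thr) & liver_mask & ~exclusion_union
        lesions += _components_to_lesions(liver_hot, image, config, "liver",
                                          first_label=len(lesions) + 1)
        logger.debug("liver threshold %.3f SUV applied to %d liver voxels", thr, liver_mask.sum())

    return LesionSet(lesions=tuple(lesions), frame_id=image.frame_id, config_used=config)


@dataclass(frozen=True)
class MatchResult:
    """Greedy centroid pairing of two co-registered lesion sets."""

    pairs: tuple[tuple[int, int], ...]  # (pre label, post label)
    unmatched_pre: tuple[int, ...]
    unmatched_post: tuple[int, ...]  # candidate new metastases

    @property
    def has_new_candidates(self) -> bool:
        return len(self.unmatched_post) > 0


def match_lesions(pre: LesionSet, post: LesionSet,
                  config: SegmentationConfig | None = None) -> MatchResult:
    """Pair pre/post lesions by nearest centroid within ``matching_radius_mm``.

    Greedy over ascending centroid distance; each pre lesion pairs with at
    most one post lesion. Unmatched post lesions are returned as candidate
    new metastases. Both frames must be co-registered (same physical space).
    """
    config = config or (pre.config_used if pre.lesions else SegmentationConfig())
    candidates = []
    for a in pre:
        for b in post:
            d = float(np.linalg.norm(np.subtract(a.centroid_mm, b.centroid_mm)))
            if d <= config.matching_radius_mm:
                candidates.append((d, a.label, b.label))
    candidates.sort()
    used_pre: set[int] = set()
    used_post: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, la, lb in candidates:
        if la in used_pre or lb in used_post:
            continue
        pairs.append((la, lb))
        used_pre.add(la)
        used_post.add(lb)
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_pre=tuple(l.label for l in pre if l.label not in used_pre),
        unmatched_post=tuple(l.label for l in post if l.label not in used_post),
    )


def label_map(lesions: LesionSet, image: SUVImage) -> np.ndarray:
    """Integer label volume (0 = background) for NIfTI export."""
    out = np.zeros(image.shape, dtype=np.int32)
    for lesion in lesions:
        idx = lesion.voxel_indices
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = lesion.label
    return out


def lesions_to_frame(lesions: LesionSet, patient_id: str, timepoint: str) -> pd.DataFrame:
    """Per-lesion statistics table (the CSV twin of the label map)."""
    rows = [{
        "patient_id": patient_id,
        "timepoint": timepoint,
        "label": l.label,
        "compartment": l.compartment,
        "mtv_ml": round(l.mtv_ml, 3),
        "suv_mean": round(l.suv_mean, 3),
        "suv_max": round(l.suv_max, 3),
        "suv_peak": round(l.suv_peak, 3),
        "centroid_x_mm": round(l.centroid_mm[0], 2),
        "centroid_y_mm": round(l.centroid_mm[1], 2),
        "centroid_z_mm": round(l.centroid_mm[2], 2),
    } for l in lesions]
    columns = ["patient_id", "timepoint", "label", "compartment", "mtv_ml", "suv_mean",
               "suv_max", "suv_peak", "centroid_x_mm", "centroid_y_mm", "centroid_z_mm"]
    return pd.DataFrame(rows, columns=columns)
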