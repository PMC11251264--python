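"""Organoid instance segmentation and per-organoid intensity extraction.

The pipeline segments whole organoids (not nuclei or cells) from
multi-channel 3D stacks:

1. average the channels into a mean image;
2. build a *clipping mask* of saturated voxels (mean > 65000 on the 16-bit
   scale) and a full-resolution *organoid mask* (Gaussian sigma 5 voxels,
   Otsu threshold computed within the 0–99th percentile of the data);
3. down-sample the mean image in-plane by a factor 5 and build a low-res
   organoid mask (Gaussian sigma 1, percentile-clipped Otsu, removal of
   patches < 100 voxels, slice-wise 2D hole filling, 3D dilation by
   3 voxels, hole filling again);
4. seed via multiscale Laplacian-of-Gaussian blob detection on the
   anisotropy-aware Euclidean distance transform of the low-res mask, with
   a per-line size group setting the sigma range in micrometres;
5. dilate the seed centre points by 7 voxels and watershed-fill the
   negated distance transform within the mask;
6. post-process: drop instances < 5000 um^3, expand segments by 4 um,
   upsample to full resolution, intersect with the full-resolution mask,
   and drop any instance touching the saturation mask;
7. extract per-instance volume and per-channel mean intensities.

Everything is deterministic: there is no randomness in segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from skimage.feature import blob_log
from skimage.filters import threshold_otsu
from skimage.morphology import ball
from skimage.segmentation import expand_labels, watershed

from .stacks import LabelVolume, MultiChannelStack

__all__ = [
    "SegmentationConfig",
    "SIZE_GROUPS",
    "mean_image",
    "clipping_mask",
    "percentile_otsu",
    "fullres_mask",
    "downsample_inplane",
    "lowres_mask",
    "distance_transform",
    "detect_seeds",
    "watershed_segment",
    "postprocess",
    "segment_stack",
    "extract_records",
]

#: per-line organoid size groups: (min_sigma, max_sigma) for blob detection, um
SIZE_GROUPS: dict[str, tuple[float, float]] = {
    "small": (5.0, 9.0),
    "medium": (7.0, 11.0),
    "large": (9.0, 17.0),
}


@dataclass
class SegmentationConfig:
    """All tunables of the pipeline; defaults are the validated settings."""

    clip_threshold: float = 65000.0
    full_smooth_sigma_vox: float = 5.0
    low_smooth_sigma_vox: float = 1.0
    otsu_percentile_hi: float = 99.0
    downsample_factor_inplane: int = 5
    min_patch_vox: int = 100
    mask_dilation_vox: int = 3
    seed_dilation_vox: int = 7
    size_group: str = "medium"
    num_sigma: int = 10
    log_threshold: float = 1.0
    log_overlap: float = 0.5
    min_volume_um3: float = 5000.0
    upsample_expand_um: float = 4.0
    exclude_border_instances: bool = False
    #: override for (min_sigma, max_sigma) in um; None uses the size group
    sigma_range_um: tuple[float, float] | None = None

    def __post_init__(self):
        if self.sigma_range_um is None and self.size_group not in SIZE_GROUPS:
            raise ValueError(
                f"unknown size_group {self.size_group!r}; choose from {sorted(SIZE_GROUPS)}"
            )
        lo, hi = self.sigma_range()
        if not lo < hi:
            raise ValueError("min_sigma must be smaller than max_sigma")
        for name in (
            "full_smooth_sigma_vox",
            "low_smooth_sigma_vox",
            "downsample_factor_inplane",
            "min_patch_vox",
            "mask_dilation_vox",
            "seed_dilation_vox",
            "num_sigma",
            "min_volume_um3",
            "upsample_expand_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def sigma_range(self) -> tuple[float, float]:
        if self.sigma_range_um is not None:
            return tuple(float(v) for v in self.sigma_range_um)
        return SIZE_GROUPS[self.size_group]

    @classmethod
    def from_yaml(cls, path) -> "SegmentationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sigma_range_um" in data and data["sigma_range_um"] is not None:
            data["sigma_range_um"] = tuple(data["sigma_range_um"])
        return cls(**data)

    def replace(self, **kw) -> "SegmentationConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# elementary operations


def mean_image(stack: MultiChannelStack) -> np.ndarray:
    """Voxel-wise arithmetic mean over channels, floating point."""
    vals = np.asarray(stack.values)
    if vals.ndim != 4 or vals.shape[0] < 1:
        raise ValueError("stack must have at least one channel")
    return vals.mean(axis=0, dtype=np.float64)


def clipping_mask(mean: np.ndarray, threshold: float = 65000.0) -> np.ndarray:
    """Saturation mask: strictly above the clip threshold (I > 65000)."""
    return np.asarray(mean) > threshold


def percentile_otsu(values: np.ndarray, hi: float = 99.0, nbins: int = 256) -> float:
    """Otsu threshold computed on the data within the 0–``hi`` percentile.

    Clipping the top percentile first keeps rare saturated/debris voxels
    from stretching the histogram and displacing the threshold.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    cut = np.percentile(values, hi)
    sub = values[values <= cut]
    if sub.size < 2 or sub.min() == sub.max():
        raise ValueError("degenerate histogram: need >= 2 distinct values below the percentile cut")
    return float(threshold_otsu(sub, nbins=nbins))


def fullres_mask(mean: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Full-resolution organoid mask: Gaussian smooth, percentile-clipped Otsu."""
    sm = ndi.gaussian_filter(np.asarray(mean, dtype=np.float64), cfg.full_smooth_sigma_vox)
    return sm > percentile_otsu(sm, cfg.otsu_percentile_hi)


def downsample_inplane(volume: np.ndarray, factor: int = 5) -> np.ndarray:
    """Block-mean reduction over ``factor x factor`` in-plane windows.

    z is untouched; edge blocks are averaged over their partial window.
    Block means (rather than decimation) preserve mean-intensity semantics.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if factor == 1:
        return volume.copy()
    if volume.shape[1] < factor or volume.shape[2] < factor:
        raise ValueError("in-plane dimensions must be >= the downsampling factor")
    out = volume
    for axis in (1, 2):
        n = out.shape[axis]
        starts = np.arange(0, n, factor)
        sums = np.add.reduceat(out, starts, axis=axis)
        counts = np.diff(np.append(starts, n))
        shape = [1, 1, 1]
        shape[axis] = counts.size
        out = sums / counts.reshape(shape)
    return out


def downsampled_spacing(voxel_size_um, factor: int) -> tuple[float, float, float]:
    z, y, x = voxel_size_um
    return (z, y * factor, x * factor)


def _remove_small_patches(mask: np.ndarray, min_vox: int) -> np.ndarray:
    """Drop 26-connected components strictly smaller than ``min_vox`` voxels."""
    labeled, n = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return mask
    counts = np.bincount(labeled.ravel())
    keep = counts >= min_vox
    keep[0] = False
    return keep[labeled]


def _fill_holes_slicewise(mask: np.ndarray) -> np.ndarray:
    out = np.empty_like(mask)
    for z in range(mask.shape[0]):
        out[z] = ndi.binary_fill_holes(mask[z])
    return out


def lowres_mask(mean_lowres: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Low-resolution organoid mask with small-patch removal and hole filling.

    Order of operations: smooth (sigma 1) -> percentile-clipped Otsu ->
    remove connected components smaller than 100 voxels -> fill holes per
    z-slice -> 3D dilation by 3 voxels -> fill holes per z-slice again.
    Components use 26-connectivity in 3D; hole filling is 2D per slice so
    that cystic (hollow-lumen) organoids whose lumen opens axially are
    still filled.
    """
    sm = ndi.gaussian_filter(np.asarray(mean_lowres, dtype=np.float64), cfg.low_smooth_sigma_vox)
    mask = sm > percentile_otsu(sm, cfg.otsu_percentile_hi)
    mask = _remove_small_patches(mask, cfg.min_patch_vox)
    mask = _fill_holes_slicewise(mask)
    if cfg.mask_dilation_vox > 0:
        mask = ndi.binary_dilation(mask, structure=ball(cfg.mask_dilation_vox))
    mask = _fill_holes_slicewise(mask)
    return mask


def distance_transform(mask: np.ndarray, spacing) -> np.ndarray:
    """Anisotropy-aware Euclidean distance transform, micrometres.

    Each foreground voxel gets its distance to the nearest background voxel
    centre; background voxels are 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("all-false mask: distance transform undefined")
    return ndi.distance_transform_edt(mask, sampling=tuple(spacing))


def detect_seeds(edt: np.ndarray, cfg: SegmentationConfig, spacing) -> list[tuple[tuple[int, int, int], tuple[float, float, float]]]:
    """Multiscale LoG blob detection on the distance transform.

    The sigma range is specified in micrometres by the size group and
    converted per axis to voxels at the (low-res) spacing, so detection
    scales are isotropic in physical space despite anisotropic voxels.
    Returns ``(center_voxel, sigma_vox)`` pairs sorted by centre (z, y, x).
    """
    edt = np.asarray(edt, dtype=np.float64)
    if edt.max() == 0:
        return []
    lo_um, hi_um = cfg.sigma_range()
    spacing = np.asarray(spacing, dtype=float)
    min_sigma = lo_um / spacing
    max_sigma = hi_um / spacing
    blobs = blob_log(
        edt,
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=cfg.num_sigma,
        threshold=cfg.log_threshold,
        overlap=cfg.log_overlap,
        log_scale=False,
        threshold_rel=None,
    )
    seeds = [
        (tuple(int(round(c)) for c in b[:3]), tuple(float(s) for s in b[3:6]))
        for b in blobs
    ]
    seeds.sort(key=lambda s: s[0])
    return seeds


def watershed_segment(
    edt: np.ndarray,
    seeds: Iterable[tuple],
    mask: np.ndarray,
    cfg: SegmentationConfig,
) -> np.ndarray:
    """Seeded watershed of the negated distance transform within the mask.

    Seed centres are dilated by 7 voxels (nearest-seed wins on overlap) and
    uniquely labelled in (z, y, x) order of their centres, making label
    assignment deterministic.  Seeds falling outside the mask are dropped
    with a warning.  Every mask voxel reachable from a seed receives
    exactly one label.
    """
    mask = np.asarray(mask, dtype=bool)
    markers = np.zeros(mask.shape, dtype=np.int32)
    centers = sorted(tuple(s[0]) for s in seeds)
    next_label = 1
    for center in centers:
        if not all(0 <= c < n for c, n in zip(center, mask.shape)):
            warnings.warn(f"seed {center} outside volume; dropped")
            continue
        if not mask[center]:
            warnings.warn(f"seed {center} outside organoid mask; dropped")
            continue
        markers[center] = next_label
        next_label += 1
    if next_label == 1:
        return markers
    if cfg.seed_dilation_vox > 0:
        markers = expand_labels(markers, distance=cfg.seed_dilation_vox)
        markers[~mask] = 0
    return watershed(-np.asarray(edt, dtype=np.float64), markers=markers, mask=mask).astype(
        np.int32
    )


def postprocess(
    labels_lowres: np.ndarray,
    fullres_organoid_mask: np.ndarray,
    clip_mask: np.ndarray,
    cfg: SegmentationConfig,
    lowres_spacing,
    fullres_spacing,
) -> np.ndarray:
    """Filter, expand and upsample low-res instances to full resolution.

    Steps, in order: (1) remove instances with volume strictly below
    5000 um^3 (voxel count x voxel volume at low resolution); (2) expand
    the surviving segments by 4 um (nearest-segment assignment, ties to the
    nearest), upsample in-plane by nearest neighbour to the full-resolution
    grid and intersect with the full-resolution organoid mask; (3) remove
    any instance whose support touches the saturation (clipping) mask;
    relabel consecutively from 1.
    """
    labels = np.asarray(labels_lowres).astype(np.int32)
    lowres_spacing = tuple(float(v) for v in lowres_spacing)
    fullres_spacing = tuple(float(v) for v in fullres_spacing)

    # (1) strict minimum-volume filter at low resolution
    voxel_vol = float(np.prod(lowres_spacing))
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts * voxel_vol >= cfg.min_volume_um3]
    labels = np.where(np.isin(labels, keep), labels, 0)

    # (2) expand by 4 um in physical space, then nearest-neighbour upsample
    if cfg.upsample_expand_um > 0 and labels.any():
        labels = expand_labels(labels, distance=cfg.upsample_expand_um, spacing=lowres_spacing)
    full_shape = np.asarray(fullres_organoid_mask).shape
    factor = cfg.downsample_factor_inplane
    labels_full = np.repeat(np.repeat(labels, factor, axis=1), factor, axis=2)
    labels_full = labels_full[: full_shape[0], : full_shape[1], : full_shape[2]]
    pad = [(0, full_shape[i] - labels_full.shape[i]) for i in range(3)]
    if any(p[1] > 0 for p in pad):
        labels_full = np.pad(labels_full, pad, mode="edge")
    labels_full = np.where(np.asarray(fullres_organoid_mask, dtype=bool), labels_full, 0)

    # (3) saturation filter: drop instances overlapping the clipping mask
    saturated_ids = np.unique(labels_full[np.asarray(clip_mask, dtype=bool)])
    saturated_ids = saturated_ids[saturated_ids > 0]
    if saturated_ids.size:
        labels_full = np.where(np.isin(labels_full, saturated_ids), 0, labels_full)

    if cfg.exclude_border_instances:
        border_ids = np.unique(
            np.concatenate(
                [
                    labels_full[0].ravel(), labels_full[-1].ravel(),
                    labels_full[:, 0].ravel(), labels_full[:, -1].ravel(),
                    labels_full[:, :, 0].ravel(), labels_full[:, :, -1].ravel(),
                ]
            )
        )
        border_ids = border_ids[border_ids > 0]
        if border_ids.size:
            labels_full = np.where(np.isin(labels_full, border_ids), 0, labels_full)

    # relabel consecutively from 1, preserving original id order
    remaining = np.unique(labels_full[labels_full > 0])
    lut = np.zeros(int(labels_full.max()) + 1, dtype=np.int32)
    lut[remaining] = np.arange(1, remaining.size + 1, dtype=np.int32)
    return lut[labels_full]


# ---------------------------------------------------------------------------
# pipeline


def segment_stack(
    stack: MultiChannelStack,
    cfg: SegmentationConfig | None = None,
    return_intermediates: bool = False,
):
    """Run the full instance-segmentation pipeline on a multi-channel stack."""
    cfg = cfg or SegmentationConfig()
    mean = mean_image(stack)
    clip = clipping_mask(mean, cfg.clip_threshold)
    factor = cfg.downsample_factor_inplane
    lo_spacing = downsampled_spacing(stack.voxel_size_um, factor)
    try:
        full_mask = fullres_mask(mean, cfg)
        mean_lo = downsample_inplane(mean, factor)
        lo_mask = lowres_mask(mean_lo, cfg)
    except ValueError:
        # degenerate (flat) image: nothing to segment
        lo_mask = np.zeros([int(np.ceil(s / (factor if i else 1))) for i, s in enumerate(mean.shape)], dtype=bool)
        full_mask = np.zeros(mean.shape, dtype=bool)
    if not lo_mask.any():
        labels = np.zeros(mean.shape, dtype=np.int32)
        result = LabelVolume(labels, stack.voxel_size_um)
        if return_intermediates:
            return result, {
                "mean": mean, "clip_mask": clip, "fullres_mask": full_mask,
                "lowres_mask": lo_mask, "edt": None, "seeds": [],
                "labels_lowres": np.zeros(lo_mask.shape, dtype=np.int32),
            }
        return result

    edt = distance_transform(lo_mask, lo_spacing)
    seeds = detect_seeds(edt, cfg, lo_spacing)
    labels_lo = watershed_segment(edt, seeds, lo_mask, cfg)
    labels = postprocess(labels_lo, full_mask, clip, cfg, lo_spacing, stack.voxel_size_um)
    result = LabelVolume(labels, stack.voxel_size_um)
    if return_intermediates:
        return result, {
            "mean": mean, "clip_mask": clip, "fullres_mask": full_mask,
            "lowres_mask": lo_mask, "edt": edt, "seeds": seeds,
            "labels_lowres": labels_lo,
        }
    return result


def extract_records(
    labels: LabelVolume,
    stack: MultiChannelStack,
    line_id: str = "",
    day_id: str = "",
    clip_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per instance: volume (um^3) and per-channel mean intensity.

    ``saturated`` flags instances overlapping the clipping mask (recomputed
    from the stack when not supplied); after standard postprocessing these
    are already removed, so the flag is False for pipeline output.
    """
    lab = np.asarray(labels.labels)
    if lab.shape != stack.shape_zyx:
        raise ValueError("label volume and stack geometry differ")
    ids = labels.ids
    if clip_mask is None:
        clip_mask = clipping_mask(mean_image(stack))
    rows = []
    if ids.size:
        counts = ndi.sum_labels(np.ones_like(lab, dtype=np.int64), lab, index=ids)
        sat = ndi.maximum(clip_mask.astype(np.uint8), lab, index=ids)
        means = {
            name: ndi.mean(np.asarray(stack.values[c], dtype=np.float64), lab, index=ids)
            for c, name in enumerate(stack.channel_names)
        }
        for k, oid in enumerate(ids):
            row = {
                "organoid_id": int(oid),
                "line_id": line_id,
                "day_id": day_id,
                "volume_um3": float(counts[k]) * labels.voxel_volume_um3,
                "saturated": bool(sat[k]),
            }
            for name in stack.channel_names:
                row[name] = float(means[name][k])
            rows.append(row)
    cols = ["organoid_id", "line_id", "day_id", "volume_um3", "saturated"] + list(
        stack.channel_names
    )
    return pd.DataFrame(rows, columns=cols)
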