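"""In-memory containers for volumetric image data.

Axis convention is ``(z, y, x)`` throughout, with the channel (or spectral
bin) axis first for multi-channel data, i.e. ``(c, z, y, x)``.  Physical
voxel spacing is carried alongside the arrays as ``(z, y, x)`` micrometres;
the acquisition default is 0.415 x 0.415 um in-plane and 0.9 um axially,
digitised in 16 bits per voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_VOXEL_SIZE_UM = (0.9, 0.415, 0.415)
INTENSITY_MAX = 65535
N_LAMBDA_BINS = 32


def _validate_spacing(voxel_size_um) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size_um)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size_um must be 3 positive floats (z, y, x), got {voxel_size_um!r}")
    return vs


@dataclass
class MultiChannelStack:
    """A ``(channel, z, y, x)`` voxel grid on a 16-bit intensity scale."""

    values: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError(f"expected a (channel, z, y, x) array, got shape {self.values.shape}")
        if self.values.shape[0] < 1:
            raise ValueError("stack must have at least one channel")
        self.voxel_size_um = _validate_spacing(self.voxel_size_um)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match channel axis")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.values.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def to_ome_tiff(self, path) -> None:
        meta = {
            "axes": "CZYX",
            "PhysicalSizeZ": self.voxel_size_um[0],
            "PhysicalSizeY": self.voxel_size_um[1],
            "PhysicalSizeX": self.voxel_size_um[2],
            "Channel": {"Name": list(self.channel_names)},
        }
        tifffile.imwrite(
            path, np.asarray(self.values), metadata=meta, ome=True, photometric="minisblack"
        )

    @classmethod
    def from_ome_tiff(cls, path) -> "MultiChannelStack":
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            voxel, names = _read_ome_metadata(tf, arr)
        if arr.ndim == 3:
            arr = arr[None]
        return cls(arr, voxel, names or [])


@dataclass
class LambdaStack:
    """A 32-bin spectral image, ``(bin, z, y, x)``, emission bin axis first."""

    values: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    bin_centers_nm: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 4 or self.values.shape[0] != N_LAMBDA_BINS:
            raise ValueError(
                f"lambda stack must be ({N_LAMBDA_BINS}, z, y, x), got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("lambda stack values must be non-negative")
        self.voxel_size_um = _validate_spacing(self.voxel_size_um)
        if self.bin_centers_nm is not None:
            self.bin_centers_nm = np.asarray(self.bin_centers_nm, dtype=float)
            if self.bin_centers_nm.shape != (N_LAMBDA_BINS,):
                raise ValueError("bin_centers_nm must have 32 entries")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def to_ome_tiff(self, path) -> None:
        MultiChannelStack(
            self.values, self.voxel_size_um, [f"bin{i}" for i in range(self.n_bins)]
        ).to_ome_tiff(path)

    @classmethod
    def from_ome_tiff(cls, path) -> "LambdaStack":
        s = MultiChannelStack.from_ome_tiff(path)
        return cls(s.values, s.voxel_size_um)


@dataclass
class LabelVolume:
    """Integer instance mask: 0 is background, each positive id one organoid."""

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a (z, y, x) label array, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size_um = _validate_spacing(self.voxel_size_um)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    def volumes_um3(self) -> dict[int, float]:
        """Per-instance volume: voxel count times voxel volume."""
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        vv = self.voxel_volume_um3
        return {int(i): float(c) * vv for i, c in zip(ids, counts)}

    def to_ome_tiff(self, path) -> None:
        meta = {
            "axes": "ZYX",
            "PhysicalSizeZ": self.voxel_size_um[0],
            "PhysicalSizeY": self.voxel_size_um[1],
            "PhysicalSizeX": self.voxel_size_um[2],
        }
        tifffile.imwrite(
            path, np.asarray(self.labels), metadata=meta, ome=True, photometric="minisblack"
        )

    @classmethod
    def from_ome_tiff(cls, path) -> "LabelVolume":
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            voxel, _ = _read_ome_metadata(tf, arr)
        return cls(arr.astype(np.int32), voxel)

    def write_manifest(self, path, extra: dict | None = None) -> None:
        """JSON sidecar with instance ids and volumes."""
        manifest = {
            "voxel_size_um": list(self.voxel_size_um),
            "shape_zyx": list(self.labels.shape),
            "n_instances": int(self.ids.size),
            "volumes_um3": {str(k): v for k, v in self.volumes_um3().items()},
        }
        if extra:
            manifest.update(extra)
        Path(path).write_text(json.dumps(manifest, indent=2))


def _read_ome_metadata(tf, arr):
    """Best-effort recovery of voxel spacing and channel names from OME-XML."""
    voxel = list(DEFAULT_VOXEL_SIZE_UM)
    names = None
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is not None:
            for i, key in enumerate(("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX")):
                if px.get(key):
                    voxel[i] = float(px.get(key))
            chans = px.findall("ome:Channel", ns)
            got = [c.get("Name") for c in chans]
            if got and all(got):
                names = got
    except Exception:
        pass
    return tuple(voxel), names
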