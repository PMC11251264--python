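"""Ground-truth-bearing synthetic inputs for the screening pipeline.

Three generators mirror the three kinds of real input the platform consumes:

* :func:`generate_stack` — multi-channel confocal-like stacks of spherical
  (optionally ellipsoidal or hollow, cyst-like) organoids with a matching
  instance label volume, Gaussian/Poisson noise, debris speckles and
  saturated blobs;
* :func:`generate_screen_table` — biobank-style per-organoid intensity
  tables with line-level effects, day effects, healthy-control lines and
  optional intra-line mixture components (intra-tumoral heterogeneity);
* :func:`generate_lambda_stack` — 32-bin spectral stacks synthesised from
  known fluorophore abundances and a reference library, for unmixing
  round-trips.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stacks import (
    DEFAULT_VOXEL_SIZE_UM,
    INTENSITY_MAX,
    LabelVolume,
    LambdaStack,
    MultiChannelStack,
)

__all__ = [
    "GroundTruthOrganoid",
    "SceneSpec",
    "generate_stack",
    "random_scene",
    "generate_screen_table",
    "generate_lambda_stack",
]


@dataclass
class GroundTruthOrganoid:
    """A single simulated organoid: a (possibly hollow) sphere or ellipsoid.

    ``radius_um`` may be a scalar (sphere) or three semi-axes ``(z, y, x)``.
    ``shell_thickness_um``, if set, hollows out the interior leaving a shell
    of that thickness — breast-cancer organoids are frequently cystic, and
    the hollow case exercises the pipeline's slice-wise hole filling.
    """

    id: int
    center_um: tuple[float, float, float]
    radius_um: float | tuple[float, float, float]
    channel_intensity: np.ndarray
    line_id: str = ""
    shell_thickness_um: float | None = None

    def __post_init__(self):
        if self.id <= 0:
            raise ValueError("organoid id must be a positive integer")
        self.channel_intensity = np.atleast_1d(np.asarray(self.channel_intensity, dtype=float))
        if np.any(self.channel_intensity < 0) or np.any(self.channel_intensity > INTENSITY_MAX):
            raise ValueError("channel intensities must lie in [0, 65535]")
        if np.any(np.asarray(self.semi_axes_um) <= 0):
            raise ValueError("radius_um must be positive")

    @property
    def semi_axes_um(self) -> tuple[float, float, float]:
        r = self.radius_um
        if np.isscalar(r):
            return (float(r),) * 3
        return tuple(float(v) for v in r)

    @property
    def bounding_radius_um(self) -> float:
        return max(self.semi_axes_um)


@dataclass
class SceneSpec:
    """Full description of a synthetic scene; the generator's sole input."""

    shape_voxels: tuple[int, int, int]
    organoids: list[GroundTruthOrganoid] = field(default_factory=list)
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    background_level: float = 100.0
    gaussian_sd: float = 0.0
    poisson: bool = False
    saturation_fraction: float = 0.0
    n_debris: int = 0
    debris_radius_um: float = 3.0
    debris_intensity: float = 20000.0
    seed: int = 0

    def __post_init__(self):
        ids = [o.id for o in self.organoids]
        if len(ids) != len(set(ids)):
            raise ValueError("organoid ids must be unique within a scene")
        self.validate_disjoint()

    def validate_disjoint(self) -> None:
        """Reject scenes with overlapping organoids (conservative sphere test)."""
        orgs = self.organoids
        for i in range(len(orgs)):
            for j in range(i + 1, len(orgs)):
                a, b = orgs[i], orgs[j]
                d = np.linalg.norm(np.subtract(a.center_um, b.center_um))
                if d < a.bounding_radius_um + b.bounding_radius_um:
                    raise ValueError(
                        f"organoids {a.id} and {b.id} overlap: center distance "
                        f"{d:.2f} um < radius sum "
                        f"{a.bounding_radius_um + b.bounding_radius_um:.2f} um"
                    )


def _coordinate_axes(shape, spacing):
    # voxel i sits at physical coordinate i * spacing along each axis
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def _rasterize(organoid: GroundTruthOrganoid, shape, spacing):
    """Boolean interior of an organoid on the voxel grid (bounding-box local).

    Returns (slices, interior_mask) with the mask restricted to the box.
    """
    semi = organoid.semi_axes_um
    lo = [
        max(0, int(np.floor((c - a) / s)))
        for c, a, s in zip(organoid.center_um, semi, spacing)
    ]
    hi = [
        min(n, int(np.ceil((c + a) / s)) + 1)
        for c, a, s, n in zip(organoid.center_um, semi, spacing, shape)
    ]
    if any(l >= h for l, h in zip(lo, hi)):
        return None, None
    axes = [
        (np.arange(l, h) * s - c) / a
        for l, h, s, c, a in zip(lo, hi, spacing, organoid.center_um, semi)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    q = zz**2 + yy**2 + xx**2
    inside = q <= 1.0
    if organoid.shell_thickness_um is not None:
        t = organoid.shell_thickness_um
        inner = [max(a - t, 0.0) for a in semi]
        if all(v > 0 for v in inner):
            axes_in = [
                (np.arange(l, h) * s - c) / a
                for l, h, s, c, a in zip(lo, hi, spacing, organoid.center_um, inner)
            ]
            zz, yy, xx = np.meshgrid(*axes_in, indexing="ij", sparse=True)
            inside &= (zz**2 + yy**2 + xx**2) > 1.0
    return tuple(slice(l, h) for l, h in zip(lo, hi)), inside


def generate_stack(spec: SceneSpec) -> tuple[MultiChannelStack, LabelVolume]:
    """Render a scene into a multi-channel stack plus its ground-truth labels.

    Voxels inside an organoid take that organoid's per-channel intensity;
    everything else sits at the background level.  Optional Poisson shot
    noise, additive Gaussian noise, debris speckles and forced-saturation
    voxels are applied afterwards, and the result is clipped to the 16-bit
    range — clipping is what creates realistic saturation.  Debris and
    saturated voxels are *not* part of the ground-truth labels.
    """
    spec.validate_disjoint()
    shape = tuple(spec.shape_voxels)
    spacing = tuple(spec.voxel_size_um)
    n_channels = spec.organoids[0].channel_intensity.size if spec.organoids else 1

    labels = np.zeros(shape, dtype=np.int32)
    stack = np.full((n_channels,) + shape, float(spec.background_level), dtype=np.float64)

    for org in spec.organoids:
        if org.channel_intensity.size != n_channels:
            raise ValueError("all organoids must specify the same number of channels")
        sl, inside = _rasterize(org, shape, spacing)
        if sl is None or not inside.any():
            continue
        labels[sl][inside] = org.id
        for c in range(n_channels):
            stack[(c,) + sl][inside] = org.channel_intensity[c]

    rng = np.random.default_rng(spec.seed)

    # debris: bright sub-filter speckles, absent from the ground truth
    for _ in range(spec.n_debris):
        center = [rng.uniform(0, n * s) for n, s in zip(shape, spacing)]
        blob = GroundTruthOrganoid(
            id=1,
            center_um=tuple(center),
            radius_um=spec.debris_radius_um,
            channel_intensity=np.full(n_channels, spec.debris_intensity),
        )
        sl, inside = _rasterize(blob, shape, spacing)
        if sl is None:
            continue
        for c in range(n_channels):
            stack[(c,) + sl][inside] = spec.debris_intensity

    if spec.poisson:
        stack = rng.poisson(stack).astype(np.float64)
    if spec.gaussian_sd > 0:
        stack += rng.normal(0.0, spec.gaussian_sd, size=stack.shape)
    if spec.saturation_fraction > 0:
        n_vox = int(np.prod(shape))
        n_sat = int(round(spec.saturation_fraction * n_vox))
        flat = rng.choice(n_vox, size=n_sat, replace=False)
        idx = np.unravel_index(flat, shape)
        stack[(slice(None),) + idx] = INTENSITY_MAX

    stack = np.clip(np.rint(stack), 0, INTENSITY_MAX).astype(np.uint16)
    return (
        MultiChannelStack(stack, spacing),
        LabelVolume(labels, spacing),
    )


def random_scene(
    n_organoids: int,
    shape_voxels: tuple[int, int, int] = (64, 256, 256),
    radius_range_um: tuple[float, float] = (10.0, 13.0),
    n_channels: int = 3,
    intensity_range: tuple[float, float] = (5000.0, 20000.0),
    margin_um: float = 3.0,
    seed: int = 0,
    max_attempts: int = 10000,
    **scene_kwargs,
) -> SceneSpec:
    """Sample a scene of pairwise-disjoint spheres by rejection sampling.

    The default radius range 10–13 um sits inside the single-seed detection
    range of the "medium" size group while leaving dense scenes packable in
    a 106 x 106 x 58 um field of view.  Raises if ``max_attempts``
    placements fail — ground-truth identity must stay unambiguous, so
    overlap is never tolerated.
    """
    rng = np.random.default_rng(seed)
    spacing = scene_kwargs.get("voxel_size_um", DEFAULT_VOXEL_SIZE_UM)
    extent = [n * s for n, s in zip(shape_voxels, spacing)]
    organoids: list[GroundTruthOrganoid] = []
    attempts = 0
    while len(organoids) < n_organoids:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_organoids} disjoint organoids in "
                f"{max_attempts} attempts; enlarge the scene or shrink radii"
            )
        attempts += 1
        r = rng.uniform(*radius_range_um)
        center = [rng.uniform(r + margin_um, e - r - margin_um) for e in extent]
        if any(c <= 0 or not np.isfinite(c) for c in center) or any(
            e <= 2 * (r + margin_um) for e in extent
        ):
            raise ValueError("scene too small to contain the requested organoids plus margin")
        ok = all(
            np.linalg.norm(np.subtract(center, o.center_um))
            >= r + o.bounding_radius_um + margin_um
            for o in organoids
        )
        if not ok:
            continue
        organoids.append(
            GroundTruthOrganoid(
                id=len(organoids) + 1,
                center_um=tuple(center),
                radius_um=r,
                channel_intensity=rng.uniform(*intensity_range, size=n_channels),
            )
        )
    return SceneSpec(
        shape_voxels=tuple(shape_voxels), organoids=organoids, seed=int(seed), **scene_kwargs
    )


def generate_screen_table(
    n_lines: int | None = None,
    organoids_per_line: int = 100,
    probe_panel: list[str] | None = None,
    line_effects: dict[str, dict] | None = None,
    healthy_lines: list[str] | None = None,
    day_effects: dict[str, float] | None = None,
    lognormal_sigma: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a biobank-style per-organoid intensity table.

    ``line_effects`` maps line -> probe -> either a scalar expected mean
    intensity or a list of ``(fraction, mean)`` mixture components (the
    intra-line heterogeneity of cancer biobanks).  Intensities are lognormal
    with the given log-scale sigma, parameterised so the expectation equals
    the specified mean; ``sigma = 0`` gives exact constants.  ``day_effects``
    multiplies all probes of a day by a common factor, emulating day-to-day
    acquisition drift.  Healthy-control lines are ordinary lines listed in
    ``healthy_lines``; every returned row carries line, day and organoid ids
    plus a nominal volume.
    """
    if probe_panel is None:
        probe_panel = ["probeA"]
    if line_effects is None:
        if n_lines is None:
            raise ValueError("specify line_effects or n_lines")
        line_effects = {
            f"line{i + 1}": {p: 1000.0 for p in probe_panel} for i in range(n_lines)
        }
    if healthy_lines is None:
        healthy_lines = []
    for line, effects in line_effects.items():
        for probe in effects:
            if probe not in probe_panel:
                raise ValueError(f"unknown probe {probe!r} in line_effects[{line!r}]")
    if day_effects is None:
        day_effects = {"d1": 1.0}

    rng = np.random.default_rng(seed)
    rows = []
    organoid_id = 0
    for line in line_effects:
        for day, day_factor in day_effects.items():
            for _ in range(organoids_per_line):
                organoid_id += 1
                row = {
                    "organoid_id": organoid_id,
                    "line_id": line,
                    "day_id": day,
                    "volume_um3": float(rng.uniform(5000.0, 50000.0)),
                }
                for probe in probe_panel:
                    effect = line_effects[line].get(probe, 0.0)
                    if isinstance(effect, (list, tuple)):
                        fractions = np.array([f for f, _ in effect], dtype=float)
                        means = np.array([m for _, m in effect], dtype=float)
                        comp = rng.choice(len(means), p=fractions / fractions.sum())
                        mean = means[comp]
                    else:
                        mean = float(effect)
                    if lognormal_sigma > 0 and mean > 0:
                        # E[mean * exp(sigma Z - sigma^2/2)] == mean
                        val = mean * np.exp(
                            lognormal_sigma * rng.standard_normal()
                            - lognormal_sigma**2 / 2.0
                        )
                    else:
                        val = mean
                    row[probe] = day_factor * val
                rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["healthy_lines"] = list(healthy_lines)
    df.attrs["probe_panel"] = list(probe_panel)
    return df


def generate_lambda_stack(
    abundance: np.ndarray,
    library,
    gaussian_sd: float = 0.0,
    seed: int = 0,
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
) -> LambdaStack:
    """Synthesise a 32-bin spectral stack from per-voxel fluorophore abundances.

    ``abundance`` has shape ``(n_fluorophores, z, y, x)``; the noiseless
    stack is the per-voxel matrix product abundance x spectra.  Gaussian
    noise (truncated at zero) leaves the expectation approximately equal to
    that product.
    """
    abundance = np.asarray(abundance, dtype=float)
    if abundance.ndim != 4:
        raise ValueError("abundance must be (fluorophore, z, y, x)")
    if np.any(abundance < 0):
        raise ValueError("abundances must be non-negative")
    spectra = np.asarray(library.spectra, dtype=float)
    if spectra.shape[0] != abundance.shape[0]:
        raise ValueError(
            f"abundance has {abundance.shape[0]} fluorophores but library has "
            f"{spectra.shape[0]}"
        )
    values = np.einsum("fb,fzyx->bzyx", spectra, abundance)
    if gaussian_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, gaussian_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    return LambdaStack(values, voxel_size_um)
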