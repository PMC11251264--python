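"""Reference spectral libraries and linear unmixing of lambda stacks.

The microscope's online-fingerprinting stage is vendor software; this
module provides the equivalent desk-scale computation.  A reference library
is built from single-stain 32-bin acquisitions (unit-sum mean spectrum of
the brightest voxels), and mixed stacks are decomposed per voxel into
non-negative fluorophore abundances by least squares — the standard linear
unmixing formulation.  Because spectra are normalised to unit sum, the
recovered abundances carry intensity units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .stacks import N_LAMBDA_BINS, LambdaStack, MultiChannelStack

__all__ = ["SpectralLibrary", "build_library", "unmix"]

#: condition number above which a library is treated as rank deficient
DEFAULT_COND_THRESHOLD = 1e8


@dataclass
class SpectralLibrary:
    """Fluorophore x 32-bin emission reference matrix, rows unit-sum."""

    spectra: np.ndarray
    fluorophore_names: list[str]
    metadata: dict = field(default_factory=lambda: {"normalization": "unit_sum"})

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2 or self.spectra.shape[1] != N_LAMBDA_BINS:
            raise ValueError(f"spectra must be (n_fluorophores, {N_LAMBDA_BINS})")
        if np.any(self.spectra < 0):
            raise ValueError("spectra must be non-negative")
        sums = self.spectra.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("each spectrum must have positive total mass")
        self.spectra = self.spectra / sums[:, None]
        if len(self.fluorophore_names) != self.spectra.shape[0]:
            raise ValueError("one name per spectrum required")

    @property
    def n_fluorophores(self) -> int:
        return self.spectra.shape[0]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.spectra.T))

    def collinear_pair(self) -> tuple[str, str]:
        """Most nearly collinear pair of spectra (by cosine similarity)."""
        s = self.spectra / np.linalg.norm(self.spectra, axis=1, keepdims=True)
        cos = s @ s.T
        np.fill_diagonal(cos, -np.inf)
        i, j = np.unravel_index(np.argmax(cos), cos.shape)
        return self.fluorophore_names[i], self.fluorophore_names[j]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.spectra,
            index=pd.Index(self.fluorophore_names, name="fluorophore"),
            columns=[f"bin{i}" for i in range(N_LAMBDA_BINS)],
        )
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpectralLibrary":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(n) for n in df.index])

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "fluorophore_names": self.fluorophore_names,
                    "spectra": self.spectra.tolist(),
                    "metadata": self.metadata,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "SpectralLibrary":
        d = json.loads(Path(path).read_text())
        lib = cls(np.asarray(d["spectra"]), d["fluorophore_names"])
        lib.metadata.update(d.get("metadata", {}))
        return lib


def build_library(
    single_stain_stacks: list[LambdaStack],
    names: list[str],
    top_percentile: float = 1.0,
) -> SpectralLibrary:
    """Estimate one reference spectrum per fluorophore from single-stain stacks.

    Each spectrum is the unit-sum-normalised mean over the brightest voxels
    of that stain's stack — brightest by total across-bin intensity, keeping
    the top ``top_percentile`` percent (default 1%).  Restricting to bright
    voxels keeps the estimate dominated by genuine signal rather than
    background.
    """
    if len(single_stain_stacks) != len(names):
        raise ValueError("one stack per fluorophore name required")
    if not 0 < top_percentile <= 100:
        raise ValueError("top_percentile must be in (0, 100]")
    spectra = []
    for stack, name in zip(single_stain_stacks, names):
        vals = np.asarray(stack.values, dtype=float)
        total = vals.sum(axis=0)
        if total.max() <= 0:
            raise ValueError(f"no signal for fluorophore {name!r}: all-zero stack")
        cut = np.percentile(total, 100.0 - top_percentile)
        bright = total >= cut
        spectrum = vals[:, bright].mean(axis=1)
        spectra.append(spectrum)
    return SpectralLibrary(np.stack(spectra), list(names))


def unmix(
    stack: LambdaStack,
    library: SpectralLibrary,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
    return_residual: bool = False,
):
    """Decompose a lambda stack into non-negative fluorophore abundances.

    Per voxel, abundances minimise the squared spectral residual subject to
    non-negativity.  An unconstrained least-squares solve handles the bulk
    of voxels; the minority with active constraints are re-solved with NNLS.
    Output channel order follows the library order.  With
    ``return_residual=True`` also returns the per-voxel root-mean-square
    spectral residual as a diagnostic volume.
    """
    cond = library.condition_number()
    if not np.isfinite(cond) or cond > cond_threshold:
        a, b = library.collinear_pair()
        raise ValueError(
            f"spectral library is rank deficient (condition number {cond:.3g}); "
            f"most collinear fluorophore pair: {a!r} and {b!r}"
        )
    A = library.spectra.T  # (bins, fluorophores)
    vals = np.asarray(stack.values, dtype=float)
    nbins = vals.shape[0]
    spatial = vals.shape[1:]
    B = vals.reshape(nbins, -1)

    X, *_ = np.linalg.lstsq(A, B, rcond=None)
    neg = np.any(X < -1e-12, axis=0)
    if neg.any():
        for j in np.flatnonzero(neg):
            X[:, j], _ = nnls(A, B[:, j])
    X = np.clip(X, 0.0, None)

    out = MultiChannelStack(
        X.reshape((library.n_fluorophores,) + spatial),
        stack.voxel_size_um,
        list(library.fluorophore_names),
    )
    if return_residual:
        resid = np.sqrt(np.mean((A @ X - B) ** 2, axis=0)).reshape(spatial)
        return out, resid
    return out
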