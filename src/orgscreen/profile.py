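"""Heterogeneity profiling of per-organoid probe-binding patterns.

Day/probe-normalized intensities per organoid are embedded with UMAP and
partitioned with Leiden community detection on a k-nearest-neighbour graph
(resolution 0.40 for the breast-cancer screen, 0.45 for neuroblastoma).
Cluster proportions per donor line summarise inter-patient heterogeneity;
multiple occupied clusters within one line indicate intra-tumoral
heterogeneity in probe binding.

"Default parameters" are pinned explicitly so runs stay reproducible even
if library defaults drift: neighbourhood size 15, Euclidean metric on the
raw probe matrix (no PCA — panels have at most 7 probes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import ScreenTable

__all__ = [
    "ClusterAssignment",
    "RESOLUTION_BC",
    "RESOLUTION_NB",
    "build_matrix",
    "cluster",
    "cluster_proportions",
]

RESOLUTION_BC = 0.40
RESOLUTION_NB = 0.45
DEFAULT_N_NEIGHBORS = 15


@dataclass
class ClusterAssignment:
    """Per-organoid community labels from one clustering run."""

    labels: np.ndarray
    line_ids: np.ndarray
    organoid_ids: np.ndarray
    resolution: float
    seed: int
    embedding: np.ndarray | None = None

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "organoid_id": self.organoid_ids,
                "line_id": self.line_ids,
                "community": self.labels,
            }
        )


def build_matrix(table: ScreenTable):
    """AnnData with one row per organoid, one column per probe.

    Expects the table to be day/probe-normalized already.  Rows are ordered
    deterministically by (line_id, day_id, organoid_id) so the matrix is
    invariant to the input row order.
    """
    import anndata as ad

    df = table.df.sort_values(["line_id", "day_id", "organoid_id"], kind="mergesort")
    X = df[table.probe_panel].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("intensity matrix contains missing values")
    obs = df[["organoid_id", "line_id", "day_id"]].astype(
        {"line_id": str, "day_id": str}
    )
    obs.index = obs["organoid_id"].astype(str)
    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = list(table.probe_panel)
    return adata


def cluster(
    matrix,
    resolution: float = RESOLUTION_NB,
    seed: int = 0,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    compute_embedding: bool = True,
) -> ClusterAssignment:
    """Leiden communities (and optional UMAP embedding) of the probe matrix.

    Builds a k-nearest-neighbour graph directly on the probe columns
    (Euclidean), then runs Leiden at the given resolution.  Community
    labels are renumbered by descending community size for stable
    reporting.  A fixed seed gives identical labels.
    """
    import scanpy as sc

    if matrix.n_obs < n_neighbors:
        raise ValueError(
            f"need at least n_neighbors={n_neighbors} organoids, got {matrix.n_obs}"
        )
    adata = matrix.copy()
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, use_rep="X", random_state=seed)
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=seed,
        key_added="community",
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    raw = adata.obs["community"].astype(int).to_numpy()
    # stable renumbering: largest community first, ties by original label
    order = pd.Series(raw).value_counts().sort_values(ascending=False).index
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(v)] for v in raw], dtype=np.int64)

    embedding = None
    if compute_embedding:
        sc.tl.umap(adata, random_state=seed)
        embedding = np.asarray(adata.obsm["X_umap"], dtype=np.float64)

    return ClusterAssignment(
        labels=labels,
        line_ids=adata.obs["line_id"].to_numpy(),
        organoid_ids=adata.obs["organoid_id"].to_numpy(),
        resolution=float(resolution),
        seed=int(seed),
        embedding=embedding,
    )


def cluster_proportions(assignment: ClusterAssignment) -> pd.DataFrame:
    """Per-line community composition; fractions sum to 1 within each line."""
    df = assignment.to_frame()
    props = pd.crosstab(df["line_id"], df["community"], normalize="index")
    props.columns = [int(c) for c in props.columns]
    return props
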