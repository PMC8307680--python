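"""Unsupervised 2-D visualization of the global panel structure.

The batch-corrected log2 matrix is projected with UMAP purely descriptively
— no downstream decision consumes the coordinates.  The silhouette score of
the group labels in embedding space quantifies whether groups separate; a
heterogeneous cohort with subtle group effects is expected to show none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

DEFAULT_N_NEIGHBORS = 15
DEFAULT_MIN_DIST = 0.1


@dataclass
class EmbeddingResult:
    """2-D embedding with the group silhouette and the parameters used."""

    coordinates: pd.DataFrame  # sample_id x (umap1, umap2)
    groups: pd.Series
    silhouette: float
    params: dict

    def plot(self, path=None):
        """Scatter of the embedding coloured by group; optionally saved."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for g in pd.unique(self.groups):
            sub = self.coordinates[self.groups.to_numpy() == g]
            ax.scatter(sub["umap1"], sub["umap2"], s=12, label=str(g), alpha=0.7)
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        ax.legend(frameon=False)
        ax.set_title(f"group silhouette = {self.silhouette:.3f}")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def embed_2d(
    normalized_or_matrix,
    seed: int = 0,
    groups=None,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
) -> EmbeddingResult:
    """UMAP projection of the batch-corrected log2 matrix to 2-D.

    Accepts a :class:`~lipidsig.preprocess.NormalizedPanel` (uses its
    ``log2bc`` matrix and group labels) or a raw samples x features
    DataFrame plus ``groups``.  The seed fixes the embedding; a neighbour
    parameter exceeding the sample count is auto-reduced with a warning.
    """
    if groups is None:
        matrix = normalized_or_matrix.log2bc
        groups = normalized_or_matrix.groups
    else:
        matrix = normalized_or_matrix
        groups = pd.Series(np.asarray(groups, dtype=object), index=matrix.index)
    if matrix.isna().any().any():
        raise ValueError("embedding input must be complete")
    n = len(matrix)
    if n_neighbors >= n:
        n_neighbors = max(2, n - 1)
        warnings.warn(
            f"n_neighbors reduced to {n_neighbors} for {n} samples", stacklevel=2
        )
    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=seed, n_jobs=1,
    )
    coords = reducer.fit_transform(matrix.to_numpy(dtype=float))
    coordinates = pd.DataFrame(
        coords, index=matrix.index, columns=["umap1", "umap2"]
    )
    if len(pd.unique(groups)) > 1:
        sil = float(silhouette_score(coords, groups.to_numpy()))
    else:
        sil = np.nan
    return EmbeddingResult(
        coordinates=coordinates,
        groups=groups,
        silhouette=sil,
        params={"n_neighbors": n_neighbors, "min_dist": min_dist, "seed": seed},
    )
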