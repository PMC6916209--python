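"""Patient-similarity analysis: t-SNE projection and grid mortality rates.

Deep Features of all records are projected to 2-D with t-SNE, the plane is
split into g × g axis-aligned blocks (default 30 × 30 = 900) over the
embedding's bounding box, and each block's mortality rate is smoothed as

    H_ij = K_ij / (N_ij + F)

where K_ij counts dead records, N_ij all records in the block, and F
(default 5) is a smoothing constant that keeps a block holding a single
dead record from reporting a rate of 1.0 (it reports 1/6 instead).  F = 0
recovers the raw rate K/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE

DEFAULT_GRID = 30
DEFAULT_SMOOTHING = 5.0


@dataclass
class Embedding2D:
    """2-D embedding aligned with sample ids and death flags."""

    points: np.ndarray  # (n, 2)
    died: np.ndarray    # (n,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.died = np.asarray(self.died, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("embedding coordinates must be finite")


@dataclass
class MortalityGrid:
    """Per-block record counts, death counts and smoothed rates."""

    g: int
    F: float
    N: np.ndarray  # (g, g) record counts
    K: np.ndarray  # (g, g) death counts
    H: np.ndarray  # (g, g) smoothed rates


def project_2d(
    features: np.ndarray, seed: int = 0, perplexity: float = 30.0,
    died: np.ndarray | None = None,
) -> Embedding2D:
    """Seeded t-SNE projection of feature vectors to the plane."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"t-SNE needs n >= 3*perplexity ({3 * perplexity:.0f}); got n = {n}"
        )
    pts = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(features)
    if died is None:
        died = np.zeros(n, dtype=int)
    return Embedding2D(points=pts, died=died)


def grid_assign(embedding: Embedding2D, g: int = DEFAULT_GRID) -> np.ndarray:
    """Block index (i, j) per point over equal-width bins of the bounding box.

    Bins are right-open except the top edge, so max-coordinate points land
    in block g-1.  If all points coincide on an axis, that axis maps to 0.
    """
    if g < 1:
        raise ValueError("grid size must be >= 1")
    pts = embedding.points
    idx = np.zeros((pts.shape[0], 2), dtype=int)
    for ax in range(2):
        lo, hi = pts[:, ax].min(), pts[:, ax].max()
        if hi > lo:
            frac = (pts[:, ax] - lo) / (hi - lo)
            idx[:, ax] = np.minimum((frac * g).astype(int), g - 1)
    return idx


def mortality_grid(
    block_indices: np.ndarray, died: np.ndarray, g: int = DEFAULT_GRID,
    F: float = DEFAULT_SMOOTHING,
) -> MortalityGrid:
    """Smoothed mortality rate H = K/(N + F) for every block."""
    if F < 0:
        raise ValueError("smoothing factor must be >= 0")
    died = np.asarray(died, dtype=int)
    N = np.zeros((g, g), dtype=int)
    K = np.zeros((g, g), dtype=int)
    np.add.at(N, (block_indices[:, 0], block_indices[:, 1]), 1)
    np.add.at(K, (block_indices[:, 0], block_indices[:, 1]), died)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(N + F > 0, K / (N + F), 0.0)
    return MortalityGrid(g=g, F=F, N=N, K=K, H=H)


def grid_table(grid: MortalityGrid):
    """Tidy (i, j, N, K, H) table of the grid."""
    import pandas as pd

    ii, jj = np.meshgrid(np.arange(grid.g), np.arange(grid.g), indexing="ij")
    return pd.DataFrame(
        {"i": ii.ravel(), "j": jj.ravel(), "N": grid.N.ravel(),
         "K": grid.K.ravel(), "H": grid.H.ravel()}
    )


def render_heatmap(grid: MortalityGrid, path: str) -> None:
    """Static heatmap image; darker blocks have higher mortality."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(grid.H.T, origin="lower", cmap="Greys", vmin=0.0)
    fig.colorbar(im, ax=ax, label=f"mortality rate H = K/(N+{grid.F:g})")
    ax.set_xlabel("block i")
    ax.set_ylabel("block j")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
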