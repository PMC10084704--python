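"""Choosing which few experiments to run: t-SNE embedding + Kennard-Stone.

For a new reagent the few support reactions that will actually be measured
should cover the candidate space homogeneously.  Euclidean distance in the
raw high-dimensional descriptor space can misrepresent the intrinsic
geometry, so candidates are first embedded to low dimension with t-SNE and
Kennard-Stone maximin selection is then run on the embedded coordinates:
start from the farthest pair, then repeatedly add the candidate whose
minimum distance to the already-selected set is largest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE

from .reaction_data import ReactionDataset


@dataclass(frozen=True)
class EmbeddingConfig:
    """t-SNE settings: target dimension, neighborhood scale, optimizer steps.

    perplexity=None picks min(30, floor((N-1)/3)) at call time, which keeps
    the mandatory perplexity < N constraint satisfied for small groups.
    """

    out_dim: int = 2
    perplexity: float | None = None
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.out_dim < 1:
            raise ValueError("out_dim must be >= 1")


@dataclass(frozen=True)
class SelectionPlan:
    """Ordered experiment suggestions for one group.

    ``order`` holds dataset record indices in selection order;
    ``coords`` are the low-dimensional points the selection was made in.
    """

    group_value: str
    candidate_indices: np.ndarray
    order: np.ndarray
    coords: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """CSV-friendly table: group, rank, dataset_index, coordinates."""
        pos = {int(c): i for i, c in enumerate(self.candidate_indices)}
        rows = []
        for rank, idx in enumerate(self.order):
            c = self.coords[pos[int(idx)]]
            row = {"group": self.group_value, "rank": rank, "dataset_index": int(idx)}
            row.update({f"coord_{j}": float(v) for j, v in enumerate(c)})
            rows.append(row)
        return pd.DataFrame(rows)


def tsne_reduce(x: np.ndarray, config: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """Embed N points to ``config.out_dim`` dimensions with t-SNE.

    Deterministic for a fixed seed.  Requires N >= 4 (below that there is
    no neighborhood structure to preserve; callers should skip reduction).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("t-SNE needs at least 4 points; skip reduction instead")
    perp = config.perplexity
    if perp is None:
        perp = min(30.0, float((n - 1) // 3))
    if perp >= n:
        raise ValueError(f"perplexity {perp} must be < number of points {n}")
    emb = TSNE(
        n_components=config.out_dim,
        perplexity=perp,
        max_iter=config.iterations,
        init="pca",
        random_state=config.seed,
    ).fit_transform(x)
    return np.asarray(emb, dtype=float)


def kennard_stone(z: np.ndarray, n: int) -> np.ndarray:
    """Greedy maximin selection of ``n`` of the N rows of ``z``.

    The first two indices are the pair at maximal Euclidean distance (lower
    index emitted first); each later index maximizes the minimum distance
    to everything already selected.  All ties break to the lowest index,
    making the output deterministic even on duplicate points.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    big_n = z.shape[0]
    if not 2 <= n <= big_n:
        raise ValueError(f"need 2 <= n <= N, got n={n}, N={big_n}")
    if not np.all(np.isfinite(z)):
        raise ValueError("points must be finite")

    dist = cdist(z, z)
    # farthest pair; np.argmax returns the first (lowest flat index) maximum,
    # which in row-major order is the lexicographically smallest (i, j)
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    first, second = (i, j) if i < j else (j, i)
    selected = [int(first), int(second)]
    min_dist = np.minimum(dist[first], dist[second])
    min_dist[selected] = -np.inf
    while len(selected) < n:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf
    return np.asarray(selected, dtype=int)


def select_fewshot(
    dataset: ReactionDataset,
    group_value: str,
    n: int,
    embed_config: EmbeddingConfig = EmbeddingConfig(),
) -> SelectionPlan:
    """Plan the ``n`` most representative reactions of one group.

    Candidates are every reaction of the group; their feature vectors are
    embedded with t-SNE and ranked by Kennard-Stone.  Reduction is skipped
    (Kennard-Stone runs on the raw features) when the feature dimension is
    already <= out_dim or when the group has fewer than 4 candidates.
    Yields are never consulted.
    """
    candidates = dataset.indices_of_group(group_value)
    if candidates.size == 0:
        raise ValueError(f"group {group_value!r} has no reactions")
    if candidates.size < n:
        raise ValueError(
            f"group {group_value!r} has {candidates.size} candidates, "
            f"fewer than the requested {n}"
        )
    x = dataset.features[candidates]
    if x.shape[1] <= embed_config.out_dim or candidates.size < 4:
        coords = x.astype(float)
    else:
        coords = tsne_reduce(x, embed_config)
    local_order = kennard_stone(coords, n)
    return SelectionPlan(
        group_value=group_value,
        candidate_indices=candidates,
        order=candidates[local_order],
        coords=coords,
    )
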