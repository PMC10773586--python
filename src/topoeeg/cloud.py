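"""Point clouds from multichannel EEG windows via the folding construction.

A 2-s window of an n-channel recording is an ``n x W`` matrix.  One *fold*
splits every row at its midpoint and stacks both halves as separate rows,
doubling the number of points while halving their dimension: k folds turn
n channels into ``n * 2**k`` points of dimension ``W / 2**k``, conserving
the total sample count.  Each row is then treated as a point in Euclidean
space, and pairwise distances feed the Vietoris-Rips filtration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .recording import Segment

__all__ = [
    "PointCloud",
    "FiltrationConfig",
    "FoldError",
    "fold_segment",
    "fold_matrix",
    "distance_matrix",
    "save_cloud",
    "load_cloud",
]


class FoldError(ValueError):
    """Raised when a window cannot be folded the requested number of times."""


@dataclass
class PointCloud:
    """``P x D`` coordinate matrix with folding provenance.

    Invariant: ``P = n_channels * 2**n_folds`` and ``P * D`` equals the
    total sample count of the originating window.
    """

    points: np.ndarray
    n_channels: int
    n_folds: int
    source: str = "segment"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be a 2-D matrix")
        if self.points.shape[0] != self.n_channels * 2**self.n_folds:
            raise ValueError(
                f"expected {self.n_channels * 2**self.n_folds} points, "
                f"got {self.points.shape[0]}"
            )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dimension(self) -> int:
        return self.points.shape[1]


@dataclass
class FiltrationConfig:
    """Folding and Rips-filtration settings.

    ``eps_max_rule="max_pairwise"`` grows the filtration to the cloud
    diameter, which guarantees a single connected component at the final
    scale; a fixed numeric ``eps_max`` truncates earlier.  ``eps_grid``
    optionally lists thresholds at which Betti curves are reported.
    """

    n_folds: int = 3
    max_homology_dim: int = 1
    eps_max_rule: Union[Literal["max_pairwise"], float] = "max_pairwise"
    normalize: Literal["none", "zscore"] = "none"
    eps_grid: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.n_folds < 0:
            raise ValueError("n_folds must be >= 0")
        if self.max_homology_dim not in (0, 1):
            raise ValueError("max_homology_dim must be 0 or 1")
        if isinstance(self.eps_max_rule, (int, float)) and self.eps_max_rule <= 0:
            raise ValueError("fixed eps_max must be positive")
        if self.eps_grid is not None:
            grid = np.asarray(self.eps_grid, dtype=float)
            if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
                raise ValueError("eps_grid must be strictly increasing")
            self.eps_grid = grid.tolist()


def fold_matrix(rows: np.ndarray, n_folds: int) -> np.ndarray:
    """Apply the fold ``n_folds`` times to a ``R x C`` matrix.

    Each fold halves every row into its first- and second-half time slices
    and stacks all first halves (in row order) above all second halves.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise FoldError("input must be a 2-D matrix")
    if n_folds < 0:
        raise FoldError("n_folds must be >= 0")
    if rows.shape[1] % 2**n_folds != 0:
        raise FoldError(
            f"window of {rows.shape[1]} samples is not divisible by 2**{n_folds}"
            f" = {2**n_folds}"
        )
    out = rows
    for _ in range(n_folds):
        half = out.shape[1] // 2
        out = np.vstack([out[:, :half], out[:, half:]])
    return out


def fold_segment(
    segment: Segment, n_folds: int, normalize: Literal["none", "zscore"] = "none"
) -> PointCloud:
    """Convert a windowed EEG segment into a folded point cloud.

    With ``normalize="zscore"`` each channel is standardized before
    folding, removing amplitude information from the distances.
    """
    samples = segment.samples
    if normalize == "zscore":
        mu = samples.mean(axis=1, keepdims=True)
        sd = samples.std(axis=1, keepdims=True)
        samples = (samples - mu) / np.where(sd > 0, sd, 1.0)
    return PointCloud(
        points=fold_matrix(samples, n_folds),
        n_channels=segment.n_channels,
        n_folds=n_folds,
        source=f"{segment.subject_id}@{segment.start_time:g}s",
    )


def distance_matrix(cloud: PointCloud) -> np.ndarray:
    """Exact Euclidean pairwise distances (symmetric, zero diagonal)."""
    if cloud.n_points < 1:
        raise ValueError("cannot compute distances of an empty cloud")
    if cloud.n_points == 1:
        return np.zeros((1, 1))
    return squareform(pdist(cloud.points))


def save_cloud(cloud: PointCloud, path) -> None:
    """Write one point per row as plain text (debugging aid)."""
    header = f"n_channels={cloud.n_channels} n_folds={cloud.n_folds} source={cloud.source}"
    np.savetxt(path, cloud.points, header=header)


def load_cloud(path) -> PointCloud:
    with open(path) as fh:
        meta = fh.readline().lstrip("# ").split()
    kv = dict(item.split("=", 1) for item in meta)
    points = np.loadtxt(path, ndmin=2)
    return PointCloud(
        points=points,
        n_channels=int(kv["n_channels"]),
        n_folds=int(kv["n_folds"]),
        source=kv.get("source", "file"),
    )
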