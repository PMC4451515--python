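"""Leader-style conformational clustering within basins.

The algorithm is the single-pass leader scheme: the i-th conformation is
compared against the representatives of the existing clusters in founding
order and joins the FIRST one within the RMSD threshold (superposed RMSD,
0.1 nm by default); otherwise it founds a new cluster with itself as
representative.  The result is deterministic given the processing order but
not order-invariant -- the order is therefore explicit (`order="trajectory"`
or `order="random"` with a seed), and a nearest-representative variant is
available but is not the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .structure import rmsd


@dataclass
class Cluster:
    representative: int  # frame index of the founder
    members: list[int]  # frame indices, founder included

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float
    n_frames: int

    @property
    def populations(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters]) / self.n_frames

    def __len__(self) -> int:
        return len(self.clusters)

    def labels(self) -> np.ndarray:
        """Per-frame cluster index (clusters in size-sorted order)."""
        out = np.full(self.n_frames, -1, dtype=int)
        for k, c in enumerate(self.clusters):
            out[np.asarray(c.members)] = k
        return out


def _frame_coords(frames) -> list[np.ndarray]:
    if isinstance(frames, np.ndarray):
        return [frames[i] for i in range(frames.shape[0])]
    out = []
    for f in frames:
        if isinstance(f, np.ndarray):
            out.append(np.asarray(f, dtype=float))
        else:
            keep = np.asarray(f.elements, dtype=object) != "H"
            out.append(f.coords[keep])
    return out


def leader_cluster(
    frames,
    threshold: float = 0.1,
    order: str = "trajectory",
    seed: int = 0,
    nearest: bool = False,
    superpose: bool = True,
) -> ClusterSet:
    """Single-pass leader clustering of conformations by RMSD.

    Parameters
    ----------
    frames : list of StructureFrame or (n, N, 3) array
    threshold : RMSD threshold in nm (> 0)
    order : "trajectory" (the literal reading of the procedure) or
        "random" (permutation drawn from ``seed``), surfacing the known
        order-sensitivity of leader clustering
    nearest : join the nearest qualifying representative instead of the
        first qualifying one
    """
    coords = _frame_coords(frames)
    n = len(coords)
    if n == 0:
        raise EmptyInputError("no frames to cluster")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if order == "trajectory":
        processing = np.arange(n)
    elif order == "random":
        processing = np.random.default_rng(seed).permutation(n)
    else:
        raise ValueError(f"unknown order {order!r}")

    clusters: list[Cluster] = []
    for idx in processing:
        assigned = None
        best = np.inf
        for c in clusters:
            d = rmsd(coords[c.representative], coords[idx], superpose=superpose)
            if d <= threshold:
                if not nearest:
                    assigned = c
                    break
                if d < best:
                    best, assigned = d, c
        if assigned is None:
            clusters.append(Cluster(representative=int(idx), members=[int(idx)]))
        else:
            assigned.members.append(int(idx))

    # size-descending; Python's stable sort keeps founding order on ties
    clusters.sort(key=lambda c: -c.size)
    return ClusterSet(clusters, threshold, n)


def basin_representatives(
    frames,
    labels: np.ndarray,
    threshold: float = 0.1,
    skip_labels: tuple[str, ...] = ("transition",),
    **cluster_kwargs,
) -> dict[str, int]:
    """Representative frame per basin: the founder of its largest cluster.

    Ties between equally large clusters go to the earliest-founded cluster.
    Basins without frames are omitted with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    coords = _frame_coords(frames)
    if len(labels) != len(coords):
        raise ValueError("labels and frames lengths differ")
    out: dict[str, int] = {}
    for basin in pd.unique(labels):
        if basin in skip_labels:
            continue
        member_idx = np.nonzero(labels == basin)[0]
        if len(member_idx) == 0:
            warnings.warn(f"basin {basin!r} is empty; omitted", stacklevel=2)
            continue
        sub = leader_cluster(
            [coords[i] for i in member_idx], threshold, **cluster_kwargs
        )
        out[basin] = int(member_idx[sub.clusters[0].representative])
    return out


def cluster_populations(clusterset: ClusterSet, top_k: int | None = None) -> pd.DataFrame:
    """Relative populations of the largest clusters, descending."""
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    rows = [
        {
            "cluster": k,
            "representative_frame": c.representative,
            "size": c.size,
            "population": c.size / clusterset.n_frames,
        }
        for k, c in enumerate(clusterset.clusters)
    ]
    df = pd.DataFrame(rows)
    return df.head(top_k) if top_k is not None else df
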