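"""Interpretation analytics over the selected connection set.

Connection-level classification weights are aggregated to brain regions
(sum over incident connections) and networks (sum over member regions);
regions whose weight exceeds the mean + 2 SD of contributing regions are
flagged as important.  The network degree (ND) of a network counts its
selected between-network connections, and k-means over the connections x
subjects profile matrix splits the selected set into covarying patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .connectome import CANONICAL_NETWORKS, RoiAtlas


@dataclass
class ConnectionSet:
    """Selected connections (ROI pairs, i < j) with their mean weights."""

    connections: list[tuple[int, int]]
    weights: np.ndarray
    atlas: RoiAtlas

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.connections) != self.weights.size:
            raise ValueError("weights length must match connection count")
        R = self.atlas.n_rois
        seen = set()
        for i, j in self.connections:
            if not (0 <= i < j < R):
                raise ValueError(f"invalid connection ({i}, {j}) for R={R}")
            if (i, j) in seen:
                raise ValueError(f"duplicate connection ({i}, {j})")
            seen.add((i, j))

    def __len__(self) -> int:
        return len(self.connections)


def region_weights(cs: ConnectionSet, mode: str = "absolute") -> np.ndarray:
    """Per-ROI weight: sum of |w| (default) or w over incident connections.

    ROIs with no incident connection get 0 (non-contributing).
    """
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    if len(cs) == 0:
        raise ValueError("empty connection set")
    w = np.abs(cs.weights) if mode == "absolute" else cs.weights
    out = np.zeros(cs.atlas.n_rois)
    for (i, j), wc in zip(cs.connections, w):
        out[i] += wc
        out[j] += wc
    return out


def contributing_mask(cs: ConnectionSet) -> np.ndarray:
    """Boolean mask of ROIs incident to at least one selected connection."""
    mask = np.zeros(cs.atlas.n_rois, dtype=bool)
    for i, j in cs.connections:
        mask[i] = mask[j] = True
    return mask


def network_weights(region_weight: np.ndarray, atlas: RoiAtlas) -> dict[str, float]:
    """Per-network sum of member region weights."""
    if len(region_weight) != atlas.n_rois:
        raise ValueError("region weight length must equal atlas size")
    nets = atlas.network_of
    return {
        net: float(region_weight[nets == net].sum())
        for net in CANONICAL_NETWORKS
        if np.any(nets == net)
    }


def important_regions(
    region_weight: np.ndarray, contributing: np.ndarray
) -> list[int]:
    """ROIs whose weight exceeds mean + 2*SD of contributing regions.

    The SD is the sample (n-1) standard deviation over contributing ROIs
    only; the comparison is strict, so equal weights select nothing.
    Returned sorted by decreasing weight.
    """
    contributing = np.asarray(contributing, dtype=bool)
    if contributing.sum() < 2:
        raise ValueError("need >= 2 contributing regions (SD undefined)")
    w = np.asarray(region_weight, dtype=float)
    vals = w[contributing]
    threshold = vals.mean() + 2 * vals.std(ddof=1)
    idx = np.flatnonzero(contributing & (w > threshold))
    return sorted(idx.tolist(), key=lambda i: -w[i])


def network_degree(cs: ConnectionSet) -> dict[str, int]:
    """ND(N): number of selected connections with exactly one endpoint in N."""
    nets = cs.atlas.network_of
    nd = {net: 0 for net in CANONICAL_NETWORKS if np.any(nets == net)}
    for i, j in cs.connections:
        ni, nj = nets[i], nets[j]
        if ni != nj:
            nd[ni] += 1
            nd[nj] += 1
    return nd


def within_between_counts(cs: ConnectionSet) -> dict[str, tuple[int, int]]:
    """Per network: (within-network, between-network) selected-connection counts.

    A connection is within a network iff both endpoints belong to it; a
    between-network connection counts once for each of its two networks.
    """
    nets = cs.atlas.network_of
    counts = {net: [0, 0] for net in CANONICAL_NETWORKS if np.any(nets == net)}
    for i, j in cs.connections:
        ni, nj = nets[i], nets[j]
        if ni == nj:
            counts[ni][0] += 1
        else:
            counts[ni][1] += 1
            counts[nj][1] += 1
    return {net: (c[0], c[1]) for net, c in counts.items()}


def kmeans_patterns(
    profile: np.ndarray, k: int, seed: int, n_init: int = 100
) -> np.ndarray:
    """Cluster connections by their value profile across subjects.

    ``profile`` is (connections x subjects); Lloyd's algorithm with
    Euclidean distance, k-means++ seeding and the best of ``n_init``
    restarts by within-cluster sum of squares.  Deterministic given seed.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 2:
        raise ValueError("profile must be 2-D (connections x subjects)")
    if not 1 <= k <= profile.shape[0]:
        raise ValueError("k must be in [1, number of connections]")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=int(seed))
    return km.fit_predict(profile)


def silhouette_scan(
    profile: np.ndarray, seed: int, k_range: range = range(2, 9), n_init: int = 20
) -> dict[int, float]:
    """Mean silhouette score for each candidate k (diagnostic for choosing k)."""
    from sklearn.metrics import silhouette_score

    profile = np.asarray(profile, dtype=float)
    out = {}
    for k in k_range:
        if k >= profile.shape[0]:
            break
        labels = kmeans_patterns(profile, k, seed, n_init=n_init)
        out[k] = float(silhouette_score(profile, labels))
    return out
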