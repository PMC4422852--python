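"""Conformer-ensemble filtering, superposition and clustering.

Candidate structures from conformational sampling are filtered to a
±window (default ±3%) band around the experimentally derived CCS,
rigid-body superposed onto a common reference, and partitioned by
k-means on the flattened coordinates.  Cluster populations (percent of
the *filtered* ensemble) and centroid-nearest representative structures
are reported; downstream distance analysis runs on the representatives
of the most populated clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .ccs import Structure


@dataclass
class ConformerSet:
    """Structures paired with their computed CCS and the target window."""

    records: list[tuple[Structure, float]]
    target_ccs: float
    window: float = 0.03

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")

    def __len__(self) -> int:
        return len(self.records)


def filter_by_ccs(cset: ConformerSet) -> ConformerSet:
    """Retain structures with |ccs − target| / target ≤ window (inclusive)."""
    if cset.target_ccs <= 0:
        raise ValueError("target_ccs must be positive")
    kept = [
        (s, c)
        for s, c in cset.records
        if abs(c - cset.target_ccs) / cset.target_ccs <= cset.window
    ]
    return ConformerSet(kept, cset.target_ccs, cset.window)


def superpose(
    mobile: Structure,
    reference: Structure,
    atom_names: set[str] | None = None,
) -> tuple[Structure, float]:
    """Optimal least-squares rigid superposition (Kabsch, via SVD).

    Returns the transformed mobile structure and the minimum RMSD (Å)
    over the selected atoms (all atoms by default).
    """
    a = mobile.select(atom_names)
    b = reference.select(atom_names)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError(
            f"selections must match with >= 3 atoms (got {len(a)} vs {len(b)})"
        )
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    u, _, vt = np.linalg.svd((a - ca).T @ (b - cb))
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = mobile.transformed(rot, cb - rot @ ca)
    rmsd = float(np.sqrt(((moved.select(atom_names) - b) ** 2).sum(axis=1).mean()))
    return moved, rmsd


@dataclass
class Clustering:
    """k-means partition of a filtered conformer set."""

    labels: np.ndarray  # cluster id per retained structure
    k: int
    populations: np.ndarray  # percent of retained structures, per cluster
    representatives: list[str]  # structure label nearest each cluster mean
    inertia: float

    def __post_init__(self) -> None:
        assert abs(self.populations.sum() - 100.0) < 1e-6


def cluster(
    cset: ConformerSet,
    k: int,
    seed: int = 0,
    atom_names: set[str] | None = None,
) -> Clustering:
    """k-means on superposed, flattened coordinates of the retained set.

    Every structure is first superposed onto the first retained
    structure (over ``atom_names``; all atoms by default).  Populations
    are cluster sizes as percent of the retained ensemble; each
    cluster's representative is the member nearest its coordinate mean.
    """
    n = len(cset.records)
    if k < 1 or n < k:
        raise ValueError(f"need 1 <= k <= n structures (k={k}, n={n})")
    ref = cset.records[0][0]
    coords = np.stack(
        [superpose(s, ref, atom_names)[0].select(atom_names).ravel()
         for s, _ in cset.records]
    )
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=500)
    labels = km.fit_predict(coords)
    pops = np.array([100.0 * (labels == c).sum() / n for c in range(k)])
    reps = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(coords[members] - km.cluster_centers_[c], axis=1)
        reps.append(cset.records[members[np.argmin(d)]][0].label)
    return Clustering(labels, k, pops, reps, float(km.inertia_))


def top_clusters(clustering: Clustering, n: int) -> list[int]:
    """Ids of the ``n`` most populated clusters, ties broken by lower id."""
    if n > clustering.k:
        raise ValueError(f"asked for {n} of {clustering.k} clusters")
    order = sorted(
        range(clustering.k), key=lambda c: (-clustering.populations[c], c)
    )
    return order[:n]
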