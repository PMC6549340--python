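"""Fusion and multilevel K-means mining of temporal drug response profiles.

Each condition contributes four readouts: confluence change, morphology
change and object counts over ``n`` time points, plus one end-point
viability value.  The viability scalar is expanded to a constant
``n``-vector, every block is normalized by its own standard deviation
(constant blocks pass through unscaled), and the blocks are concatenated
into one profile of length ``N = 4n``.

Profiles are grouped by top-down hierarchical clustering with K-means++
at every level.  For each candidate K the clustering is repeated R times
with distinct seeded initializations and scored by the sum of squared
errors E_K (best of R).  K is selected by the relative SSE drop between
consecutive K,

    dE_{K-1->K} = (E_K - E_{K-1}) / E_{K-1} * 100,

as the smallest K whose drop exceeds the configured percentage (default
20%); if no transition drops enough the level stays unsplit.  Recursion
into each cluster continues until K* = 1, a minimum group size, or a
maximum depth.

Within each discovered group the combinations are reduced to their
*non-redundant representative set* — the subset-minimal members: the
lowest-order combinations such that every other member of the group
contains one of them.  A single drug representing a group of dozens of
higher-order combinations is direct evidence that the group's behavior is
a single-drug effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from combiscreen.design import Combination


@dataclass
class FusedProfile:
    condition: Combination | str
    x: np.ndarray


@dataclass
class ClusterNode:
    """One node of the multilevel cluster tree."""

    members: list[int]  # indices into the profile list
    centroid: np.ndarray
    depth: int
    selected_k: int = 1
    sse_trace: dict[int, float] = field(default_factory=dict)
    children: list["ClusterNode"] = field(default_factory=list)
    representatives: list[Combination] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["ClusterNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out


def fuse_profiles(
    delta_confluence: np.ndarray,
    delta_morphology: np.ndarray,
    counts: np.ndarray,
    viability: float,
    condition: Combination | str = "",
) -> FusedProfile:
    """Standardize and concatenate the four response blocks into one vector."""
    blocks = [
        np.asarray(delta_confluence, dtype=float),
        np.asarray(delta_morphology, dtype=float),
        np.asarray(counts, dtype=float),
    ]
    n = blocks[0].size
    if any(b.size != n for b in blocks):
        raise ValueError("temporal blocks must share length")
    if not np.isfinite(viability):
        raise ValueError("viability must be finite")
    blocks.append(np.full(n, float(viability)))
    scaled = []
    for b in blocks:
        sd = b.std(ddof=0)
        scaled.append(b / (sd if sd > 0 else 1.0))
    return FusedProfile(condition=condition, x=np.concatenate(scaled))


def kmeans_partition(
    X: np.ndarray, k: int, repeats: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-R K-means++ partition and its SSE.

    Runs Lloyd's algorithm with K-means++ initialization ``repeats`` times
    under distinct seeded initializations and keeps the run with minimal
    SSE.  Returns (labels, centroids, sse).
    """
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ValueError("K exceeds the number of profiles")
    if k == 1:
        centroid = X.mean(axis=0, keepdims=True)
        sse = float(((X - centroid) ** 2).sum())
        return np.zeros(X.shape[0], dtype=int), centroid, sse
    best = None
    for r in range(repeats):
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed + r)
        labels = km.fit_predict(X)
        if best is None or km.inertia_ < best[2]:
            best = (labels, km.cluster_centers_, float(km.inertia_))
    return best


def select_k(
    X: np.ndarray,
    k_values: range | list[int] = range(1, 11),
    repeats: int = 10,
    drop_pct: float = 20.0,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Select K by the relative SSE-drop rule.

    Returns the smallest K whose transition from K-1 reduces the best-of-R
    SSE by more than ``drop_pct`` percent, together with the SSE trace; if
    no transition qualifies, K = 1.  A perfect fit (SSE 0) at some K stops
    the scan there.
    """
    X = np.asarray(X, dtype=float)
    ks = sorted(k for k in k_values if 1 <= k <= X.shape[0])
    trace: dict[int, float] = {}
    prev_sse = None
    chosen = 1
    for k in ks:
        _, _, sse = kmeans_partition(X, k, repeats=repeats, seed=seed + 1000 * k)
        trace[k] = sse
        if prev_sse is not None:
            if prev_sse == 0:
                chosen = k - 1
                break
            drop = (sse - prev_sse) / prev_sse * 100.0
            if drop <= -drop_pct:
                chosen = k
                break
        prev_sse = sse
    return chosen, trace


def multilevel_cluster(
    profiles: list[FusedProfile],
    max_depth: int = 2,
    min_size: int = 8,
    k_values: range | list[int] = range(1, 11),
    repeats: int = 10,
    drop_pct: float = 20.0,
    seed: int = 0,
) -> ClusterNode:
    """Top-down hierarchical K-means clustering of fused profiles.

    Applies SSE-drop K selection at the root and recurses into every
    resulting cluster until K* = 1, the cluster falls below ``min_size``
    members, or ``max_depth`` levels have been built.  Every node stores
    its centroid (the prototypical response profile of the group) and its
    non-redundant representative combinations.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    X = np.vstack([p.x for p in profiles])

    def build(members: list[int], depth: int, node_seed: int) -> ClusterNode:
        sub = X[members]
        node = ClusterNode(
            members=members, centroid=sub.mean(axis=0), depth=depth
        )
        node.representatives = nonredundant_subset(
            [profiles[i].condition for i in members if isinstance(profiles[i].condition, Combination)]
        )
        if depth >= max_depth or len(members) < max(2, min_size):
            return node
        k, trace = select_k(
            sub, k_values=k_values, repeats=repeats, drop_pct=drop_pct, seed=node_seed
        )
        node.selected_k = k
        node.sse_trace = trace
        if k <= 1:
            return node
        labels, _, _ = kmeans_partition(sub, k, repeats=repeats, seed=node_seed + 1000 * k)
        for child_idx in range(k):
            child_members = [m for m, lab in zip(members, labels) if lab == child_idx]
            node.children.append(
                build(child_members, depth + 1, node_seed + 7919 * (child_idx + 1))
            )
        return node

    return build(list(range(len(profiles))), 0, seed)


def nonredundant_subset(group: list[Combination]) -> list[Combination]:
    """Subset-minimal combinations of a group (the minimal antichain).

    Iteratively takes the lowest-order remaining combination (lexicographic
    tie-break), keeps it, and removes every remaining combination that
    contains it.  The result is independent of input order: exactly those
    members that contain no other member as a subset.
    """
    remaining = sorted(set(group), key=lambda c: (c.order, c.members))
    representatives: list[Combination] = []
    while remaining:
        head = remaining.pop(0)
        representatives.append(head)
        remaining = [c for c in remaining if not c.contains(head)]
    return representatives


def group_report(
    tree: ClusterNode,
    profiles: list[FusedProfile],
    block_scales: np.ndarray | None = None,
) -> list[dict]:
    """Flat per-node summary of a cluster tree.

    Each entry reports the node path, member count, representative set and
    the four average response blocks, de-normalized back to original units
    when the per-block scales used in fusion are supplied.
    """
    n4 = profiles[0].x.size
    n = n4 // 4
    rows: list[dict] = []

    def walk(node: ClusterNode, path: str):
        centroid = node.centroid.copy()
        if block_scales is not None:
            for b in range(4):
                centroid[b * n : (b + 1) * n] *= block_scales[b]
        rows.append(
            {
                "path": path or "root",
                "depth": node.depth,
                "n_members": len(node.members),
                "members": [
                    profiles[i].condition.label()
                    if isinstance(profiles[i].condition, Combination)
                    else str(profiles[i].condition)
                    for i in node.members
                ],
                "representatives": [r.label() for r in node.representatives],
                "avg_delta_confluence": centroid[:n],
                "avg_delta_morphology": centroid[n : 2 * n],
                "avg_counts": centroid[2 * n : 3 * n],
                "avg_viability": centroid[3 * n :],
            }
        )
        for i, child in enumerate(node.children):
            walk(child, f"{path}/{i}" if path else str(i))

    walk(tree, "")
    return rows
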