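"""Dynamic hybrid tree cut: adaptive pruning of an average-linkage dendrogram.

Two phases, following the published dynamic hybrid scheme:

1. **Tree phase.** Merges are processed bottom-up, growing branches.
   Singletons (and branches too small or too loose to stand alone) are
   absorbed into the branch they merge with. When two *viable* branches meet
   — each with at least ``min_cluster_size`` members, a *core scatter* (mean
   of the lowest core merge heights) below a deep-split-dependent ceiling and
   a sufficient *gap* between the meeting height and its core scatter — both
   are finalized as separate clusters. Members that attached to a finalized
   branch above the core-scatter ceiling are released back to the background
   (they are stragglers, not core members). Merges above the cut height
   (default the 99th percentile of joining heights) are ignored, and any
   viable branch still active there is finalized. Deep split 0–4
   interpolates the core-scatter ceiling over (0.64, 0.73, 0.82, 0.91, 0.95)
   of the (reference, cut) height range, with the gap floor at 3/4 of the
   complement — the published parameterization.

2. **PAM-like phase.** Each unlabeled object joins the cluster with the
   smallest average dissimilarity, provided that distance beats its average
   dissimilarity to the remaining unlabeled background and stays below the
   core-scatter ceiling; ``pam_respects_dendro`` restricts candidates to
   clusters from the object's own below-cut branch of the dendrogram.
   Objects failing these stay unassigned (label 0).
"""

from __future__ import annotations

import numpy as np

_CORE_SCATTER_BY_DEEPSPLIT = (0.64, 0.73, 0.82, 0.91, 0.95)


class _Branch:
    __slots__ = ("leaves", "attach_heights", "merge_heights", "alive", "composite")

    def __init__(self, leaf: int | None = None):
        self.leaves: list[int] = [] if leaf is None else [leaf]
        self.attach_heights: list[float] = [] if leaf is None else [0.0]
        self.merge_heights: list[float] = []
        self.alive = True
        self.composite = False  # contains already-finalized clusters


def cut_tree_hybrid(
    Z: np.ndarray,
    dissimilarity: np.ndarray,
    min_cluster_size: int = 30,
    deep_split: int = 2,
    cut_height: float | None = None,
    pam_stage: bool = True,
    pam_respects_dendro: bool = True,
) -> np.ndarray:
    """Return integer cluster labels per leaf; 0 means unassigned.

    ``Z`` is a scipy linkage matrix over ``n`` objects; ``dissimilarity`` the
    matching square matrix (used by the PAM phase). Clusters are numbered
    1.. in decreasing size order.
    """
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    n = Z.shape[0] + 1
    labels = np.zeros(n, dtype=int)
    if n < min_cluster_size:
        return labels

    heights = Z[:, 2]
    if cut_height is None:
        cut_height = float(np.quantile(heights, 0.99))
    ref_height = float(np.quantile(heights, 0.05))
    span = max(cut_height - ref_height, 1e-12)
    frac = _CORE_SCATTER_BY_DEEPSPLIT[deep_split]
    max_core_scatter = ref_height + frac * span
    min_gap = (1 - frac) * 3 / 4 * span
    core_size = max(min_cluster_size - 1, 1)

    def scatter(b: _Branch) -> float:
        m = b.merge_heights
        k = min(core_size, len(m))
        return float(np.mean(m[:k])) if k else 0.0

    def viable(b: _Branch, h: float) -> bool:
        if b.composite or len(b.leaves) < min_cluster_size:
            return False
        s = scatter(b)
        return s <= max_core_scatter and (h - s) >= min_gap

    # node id -> branch; leaves are 0..n-1, internal nodes n..2n-2
    branch_of: dict[int, _Branch] = {}
    clusters: list[np.ndarray] = []
    component_root = np.arange(n)  # updated as merges happen (below cut only)

    def get_branch(idx: int) -> _Branch:
        return branch_of[idx] if idx >= n else _Branch(idx)

    def finalize(b: _Branch) -> None:
        members = np.array(b.leaves)
        attach = np.array(b.attach_heights)
        core = members[attach <= max_core_scatter]
        if len(core) >= min_cluster_size:
            clusters.append(core)
        b.alive = False

    for i in range(n - 1):
        h = float(heights[i])
        a, b_idx = int(Z[i, 0]), int(Z[i, 1])
        if h > cut_height:
            for idx in (a, b_idx):
                br = branch_of.get(idx)
                if br is not None and br.alive and viable(br, cut_height):
                    finalize(br)
            branch_of[i + n] = _Branch()  # dead placeholder
            branch_of[i + n].alive = False
            branch_of[i + n].composite = True
            continue
        ba, bb = get_branch(a), get_branch(b_idx)
        va, vb = viable(ba, h), viable(bb, h)
        if va and vb:
            finalize(ba)
            finalize(bb)
            merged = _Branch()
            merged.composite = True
            merged.leaves = ba.leaves + bb.leaves
            merged.attach_heights = ba.attach_heights + bb.attach_heights
        else:
            # absorb the smaller/non-viable side into the other branch
            big, small = (ba, bb) if len(ba.leaves) >= len(bb.leaves) else (bb, ba)
            if small.composite and not big.composite:
                big, small = small, big
            merged = big
            merged.leaves += small.leaves
            merged.attach_heights += [h] * len(small.leaves)
            if not merged.composite:
                merged.merge_heights = sorted(
                    merged.merge_heights + small.merge_heights + [h]
                )
        branch_of[i + n] = merged
        for leaf in merged.leaves:
            component_root[leaf] = i + n

    for br in branch_of.values():
        if br.alive and not br.composite and viable(br, cut_height):
            finalize(br)

    clusters.sort(key=lambda c: (-len(c), int(c.min())))
    for label, members in enumerate(clusters, start=1):
        labels[members] = label

    if pam_stage and clusters:
        labels = _pam_assign(
            labels,
            np.asarray(dissimilarity, float),
            max_dist=max_core_scatter,
            component=component_root if pam_respects_dendro else None,
        )
    return labels


def _pam_assign(
    labels: np.ndarray,
    dissimilarity: np.ndarray,
    max_dist: float,
    component: np.ndarray | None,
) -> np.ndarray:
    """Assign unlabeled objects to the nearest cluster by average
    dissimilarity when that beats the background and the distance ceiling."""
    new_labels = labels.copy()
    unassigned = np.flatnonzero(labels == 0)
    if len(unassigned) == 0:
        return new_labels
    cluster_ids = np.unique(labels[labels > 0])
    members = {c: np.flatnonzero(labels == c) for c in cluster_ids}
    comp_of_cluster = (
        {c: component[members[c][0]] for c in cluster_ids} if component is not None else {}
    )
    bg = unassigned
    for i in unassigned:
        others = bg[bg != i]
        d_bg = dissimilarity[i, others].mean() if len(others) else np.inf
        best_c, best_d = 0, np.inf
        for c in cluster_ids:
            if component is not None and component[i] != comp_of_cluster[c]:
                continue
            d = dissimilarity[i, members[c]].mean()
            if d < best_d:
                best_c, best_d = c, d
        if best_c and best_d < d_bg and best_d <= max_dist:
            new_labels[i] = best_c
    return new_labels
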