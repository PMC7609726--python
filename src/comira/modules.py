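"""Module detection on the TOM dissimilarity.

Average-linkage (UPGMA) hierarchical clustering of 1-TOM, a
deterministic dynamic branch cut with a minimum module size, module
eigengenes (first principal component of the standardized module
expression), and merging of modules whose eigengenes are highly
correlated.  Unassigned features collect in the reserved ``grey``
module.  Everything here is deterministic given the input — there is no
randomness in module detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InputError, NumericalError
from .io import GREY, ExpressionMatrix, ModuleAssignment

__all__ = [
    "Dendrogram",
    "EigengeneSet",
    "COLOR_PALETTE",
    "average_linkage",
    "dynamic_cut",
    "module_eigengene",
    "eigengene_set",
    "merge_close_modules",
    "assign_colors",
]

# canonical module color ordering (largest module first); grey is reserved
COLOR_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus leaf bookkeeping."""

    linkage: np.ndarray  # (n-1, 4): left, right, height, size
    feature_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        return hierarchy.leaves_list(self.linkage).tolist()

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "size"]
        )

    def to_newick(self) -> str:
        """Newick export for external tree viewers."""
        tree = hierarchy.to_tree(self.linkage)
        ids = self.feature_ids

        def rec(node) -> str:
            if node.is_leaf():
                return ids[node.id]
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({rec(node.left)}:{dl:.6g},{rec(node.right)}:{dr:.6g})"

        return rec(tree) + ";"


@dataclass
class EigengeneSet:
    """Per-module eigengenes (unit norm over samples) and variance explained."""

    data: pd.DataFrame  # samples x module colors
    variance_explained: dict[str, float]

    @property
    def colors(self) -> list[str]:
        return list(self.data.columns)


def average_linkage(diss: np.ndarray, feature_ids: list[str] | None = None) -> Dendrogram:
    """UPGMA tree of a square symmetric dissimilarity with zero diagonal."""
    diss = np.asarray(diss, dtype=float)
    if diss.ndim != 2 or diss.shape[0] != diss.shape[1]:
        raise InputError("dissimilarity must be square")
    if not np.allclose(diss, diss.T, atol=1e-10):
        raise InputError("dissimilarity must be symmetric")
    if feature_ids is None:
        feature_ids = [str(i) for i in range(diss.shape[0])]
    d = diss.copy()
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(z, list(feature_ids))


def _branches_at(dendro: Dendrogram, height: float) -> np.ndarray:
    return hierarchy.fcluster(dendro.linkage, t=height, criterion="distance")


def dynamic_cut(
    dendro: Dendrogram,
    diss: np.ndarray,
    min_size: int = 5,
    cut_quantile: float = 0.99,
    pam_stage: bool = True,
) -> ModuleAssignment:
    """Deterministic branch cut with minimum module size and a PAM-like
    rescue stage.

    The tree is cut just below the top of the merge-height range: the cut
    height is ``cut_quantile`` of the way from the lowest to the highest
    merge height.  Branches with at least ``min_size`` leaves become
    modules; leaves of smaller branches go to grey.  With ``pam_stage``,
    each grey leaf is reassigned to the module with the smallest average
    dissimilarity to its members, provided that average is below the
    grand mean of within-module dissimilarities — a guard that keeps
    genuinely unconnected features grey.
    """
    n = len(dendro.feature_ids)
    if min_size < 2:
        raise InputError("min_size must be >= 2")
    if min_size > n:
        warnings.warn("min_size exceeds the number of features; all grey")
        return ModuleAssignment(dendro.feature_ids, [GREY] * n)
    h = dendro.heights
    cut_height = float(h.min() + cut_quantile * (h.max() - h.min()))
    branches = _branches_at(dendro, cut_height)
    labels = _sized_branches_to_labels(branches, min_size)
    if pam_stage:
        labels = _pam_rescue(labels, np.asarray(diss, dtype=float))
    return ModuleAssignment(dendro.feature_ids, assign_module_colors(labels))


def _sized_branches_to_labels(branches: np.ndarray, min_size: int) -> np.ndarray:
    """Branch ids -> integer module labels (0 = grey), small branches dropped."""
    labels = np.zeros(branches.size, dtype=int)
    next_label = 1
    for b in np.unique(branches):  # ascending branch id: deterministic
        mask = branches == b
        if mask.sum() >= min_size:
            labels[mask] = next_label
            next_label += 1
    return labels


def _pam_rescue(labels: np.ndarray, diss: np.ndarray) -> np.ndarray:
    """Reassign grey leaves to the nearest module when close enough."""
    module_ids = [m for m in np.unique(labels) if m != 0]
    if not module_ids:
        return labels
    # grand mean of within-module dissimilarities, pooled over modules
    within = []
    for m in module_ids:
        idx = np.flatnonzero(labels == m)
        sub = diss[np.ix_(idx, idx)]
        within.append(sub[np.triu_indices_from(sub, k=1)])
    grand_mean = float(np.concatenate(within).mean())
    out = labels.copy()
    for i in np.flatnonzero(labels == 0):
        avg = [diss[i, labels == m].mean() for m in module_ids]
        j = int(np.argmin(avg))
        if avg[j] < grand_mean:
            out[i] = module_ids[j]
    return out


def assign_colors(sizes: list[int]) -> list[str]:
    """Canonical colors by decreasing size; ties broken by first-seen order."""
    order = sorted(range(len(sizes)), key=lambda i: (-sizes[i], i))
    colors = [""] * len(sizes)
    for rank, i in enumerate(order):
        if rank < len(COLOR_PALETTE):
            colors[i] = COLOR_PALETTE[rank]
        else:
            colors[i] = f"module{rank + 1}"
    return colors


def assign_module_colors(labels: np.ndarray) -> list[str]:
    """Integer labels (0 = grey) -> color names by decreasing module size."""
    module_ids = [m for m in np.unique(labels) if m != 0]
    sizes = [int((labels == m).sum()) for m in module_ids]
    colors = assign_colors(sizes)
    mapping = {m: c for m, c in zip(module_ids, colors)}
    mapping[0] = GREY
    return [mapping[m] for m in labels]


def module_eigengene(
    expr: ExpressionMatrix, members: list[str]
) -> tuple[pd.Series, float]:
    """First principal component of the standardized module expression.

    Features are standardized across samples; the eigengene is the first
    right-singular vector (unit norm, one value per sample), with sign
    aligned so its correlation with the mean standardized member profile
    is non-negative.  Returns (eigengene, variance explained).
    """
    if len(members) == 0:
        raise InputError("module has no members")
    if expr.n_samples < 3:
        raise InputError("eigengene needs at least 3 samples")
    x = expr.data.loc[list(members)].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [m for m, k in zip(members, keep) if not k]
        warnings.warn(f"dropping zero-variance members: {dropped[:5]}")
        x, sd = x[keep], sd[keep]
    if x.shape[0] == 0:
        raise NumericalError("all module members have zero variance")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    ve = float(s[0] ** 2 / np.sum(s ** 2))
    return pd.Series(e, index=expr.sample_ids), ve


def eigengene_set(expr: ExpressionMatrix, assignment: ModuleAssignment,
                  include_grey: bool = False) -> EigengeneSet:
    """Eigengenes for every (non-grey) module, columns ordered by size."""
    colors = assignment.module_colors
    if include_grey and GREY in assignment.labels:
        colors = colors + [GREY]
    data = {}
    ve = {}
    for color in colors:
        e, v = module_eigengene(expr, assignment.members(color))
        data[color] = e
        ve[color] = v
    return EigengeneSet(pd.DataFrame(data), ve)


def merge_close_modules(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    similarity_threshold: float = 0.75,
) -> tuple[ModuleAssignment, EigengeneSet]:
    """Merge modules whose eigengenes correlate above the threshold.

    Iterates: compute eigengenes, cluster them by average linkage on
    1 - cor, merge every group linked below 1 - threshold, recompute;
    stops when no pair merges.  Colors are reassigned by decreasing
    module size at the end.  Grey never participates.
    """
    if not assignment.module_colors:
        raise InputError("no non-grey modules to merge")
    labels = list(assignment.labels)
    while True:
        current = ModuleAssignment(assignment.feature_ids, labels)
        colors = current.module_colors
        if len(colors) <= 1:
            break
        es = eigengene_set(expr, current)
        me = es.data[colors].to_numpy()
        corr = np.corrcoef(me.T)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        dendro = average_linkage(d, colors)
        groups = hierarchy.fcluster(
            dendro.linkage, t=1.0 - similarity_threshold, criterion="distance"
        )
        if len(np.unique(groups)) == len(colors):
            break  # nothing merges: done
        # merge each group into its largest member's label
        sizes = current.sizes()
        for g in np.unique(groups):
            group_colors = [c for c, gg in zip(colors, groups) if gg == g]
            if len(group_colors) < 2:
                continue
            target = max(group_colors, key=lambda c: (sizes[c], -colors.index(c)))
            labels = [target if l in group_colors else l for l in labels]
    # relabel by decreasing size with canonical colors
    final = ModuleAssignment(assignment.feature_ids, labels)
    ordered = final.module_colors
    mapping = {old: new for old, new in
               zip(ordered, assign_colors([final.sizes()[c] for c in ordered]))}
    mapping[GREY] = GREY
    relabelled = ModuleAssignment(
        final.feature_ids, [mapping[l] for l in labels]
    )
    return relabelled, eigengene_set(expr, relabelled)
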