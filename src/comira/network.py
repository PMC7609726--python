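"""Weighted unsigned co-expression network construction.

The network substrate is the absolute Pearson correlation between
feature expression profiles (an *unsigned* network: anti-correlated
features are maximally connected).  The similarity is raised
elementwise to a soft-thresholding power beta, chosen as the smallest
power at which the connectivity distribution approximates a scale-free
(power-law) form, and the adjacency is then transformed into the
topological overlap measure (TOM), whose complement 1-TOM is the
clustering distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError, NumericalError
from .io import ExpressionMatrix

__all__ = [
    "SimilarityMatrix",
    "AdjacencyMatrix",
    "ScaleFreeFit",
    "TomMatrix",
    "similarity",
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom",
]

_SYM_TOL = 1e-12


def _check_square_symmetric(values: np.ndarray, what: str) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise InputError(f"{what} must be square, got shape {values.shape}")
    if not np.allclose(values, values.T, atol=_SYM_TOL, equal_nan=True):
        raise InputError(f"{what} must be symmetric")


@dataclass
class SimilarityMatrix:
    """|Pearson correlation| between feature pairs; unit diagonal."""

    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_square_symmetric(self.values, "similarity")
        if np.any(self.values < -_SYM_TOL) or np.any(self.values > 1 + _SYM_TOL):
            raise InputError("similarity entries must lie in [0, 1]")
        np.fill_diagonal(self.values, 1.0)


@dataclass
class AdjacencyMatrix:
    """similarity ** beta, elementwise; the weighted network."""

    feature_ids: list[str]
    values: np.ndarray
    beta: int

    def __post_init__(self) -> None:
        _check_square_symmetric(self.values, "adjacency")


@dataclass
class ScaleFreeFit:
    """Diagnostics of the scale-free topology fit at one power.

    ``r_squared`` is the signed fit index: the R-squared of the
    log10(frequency) ~ log10(connectivity) regression with the sign
    flipped so that a decreasing, power-law-like relationship scores
    positive.  NaN marks an invalid fit (fewer than 3 usable bins).
    """

    beta: int
    r_squared: float
    slope: float
    mean_connectivity: float

    @property
    def valid(self) -> bool:
        return np.isfinite(self.r_squared)


@dataclass
class TomMatrix:
    """Topological overlap; unit diagonal; 1 - values is the clustering distance."""

    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_square_symmetric(self.values, "TOM")
        np.fill_diagonal(self.values, 1.0)

    @property
    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


def similarity(expr: ExpressionMatrix, min_pairs: int = 3) -> SimilarityMatrix:
    """Unsigned similarity s_ij = |cor(x_i, x_j)| over pairwise-complete samples.

    Zero-variance features must be dropped beforehand
    (:meth:`ExpressionMatrix.drop_constant_features`); they are a hard
    error here because their correlation is undefined.
    """
    if expr.n_samples < 3:
        raise InputError("similarity needs at least 3 samples")
    const = expr.constant_features()
    if const:
        raise InputError(
            f"zero-variance features present (drop first): {const[:5]}"
        )
    x = expr.values
    if not np.isnan(x).any():
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(x)
    else:
        # pairwise-complete correlation; error if any pair has < min_pairs
        obs = (~np.isnan(x)).astype(float)
        n_pairs = obs @ obs.T
        if np.any(n_pairs < min_pairs):
            bad = np.argwhere(n_pairs < min_pairs)
            off = bad[bad[:, 0] != bad[:, 1]]
            i, j = (off[0] if off.size else bad[0])
            raise InputError(
                f"fewer than {min_pairs} complete sample pairs for features "
                f"({expr.feature_ids[i]!r}, {expr.feature_ids[j]!r})"
            )
        c = pd.DataFrame(x.T).corr(min_periods=min_pairs).to_numpy()
    s = np.abs(c)
    s = np.clip((s + s.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(expr.feature_ids, s)


def adjacency(sim: SimilarityMatrix, beta: int) -> AdjacencyMatrix:
    """Soft-threshold the similarity: a_ij = s_ij ** beta."""
    if int(beta) != beta or beta < 1:
        raise ConfigError(f"beta must be an integer >= 1, got {beta}")
    a = sim.values ** int(beta)
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(sim.feature_ids, a, int(beta))


def connectivity(adj: AdjacencyMatrix) -> np.ndarray:
    """Node connectivity k_i = sum_{j != i} a_ij (diagonal excluded)."""
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def scale_free_fit(adj: AdjacencyMatrix, n_bins: int = 10) -> ScaleFreeFit:
    """Signed scale-free topology fit index of the connectivity distribution.

    Connectivities are binned into ``n_bins`` equal-width bins; the log10
    of the per-bin frequency is regressed on the log10 of the per-bin
    mean connectivity over non-empty bins with positive mean.  Fewer
    than 3 usable bins marks the fit invalid (index NaN) rather than
    raising.
    """
    if adj.values.shape[0] < 10:
        raise InputError("scale-free fit needs at least 10 features")
    k = connectivity(adj)
    mean_k = float(k.mean())
    lo, hi = float(k.min()), float(k.max())
    if hi <= lo:  # regular graph: a single degenerate bin
        return ScaleFreeFit(adj.beta, float("nan"), float("nan"), mean_k)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        mk = float(k[mask].mean())
        if mk <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return ScaleFreeFit(adj.beta, float("nan"), float("nan"), mean_k)
    fit = stats.linregress(xs, ys)
    r2 = fit.rvalue ** 2
    signed = -np.sign(fit.slope) * r2
    return ScaleFreeFit(adj.beta, float(signed), float(fit.slope), mean_k)


def pick_soft_threshold(
    sim: SimilarityMatrix,
    candidate_betas=range(1, 21),
    target_r2: float = 0.80,
    n_bins: int = 10,
) -> tuple[int, list[ScaleFreeFit]]:
    """Choose the soft-thresholding power by the scale-free criterion.

    Returns the smallest candidate power whose signed fit index reaches
    ``target_r2`` plus the full diagnostic table.  If no candidate
    reaches the target, the power maximizing the index is returned with
    a warning.
    """
    candidates = list(candidate_betas)
    if not candidates:
        raise ConfigError("candidate beta list is empty")
    if candidates != sorted(candidates):
        raise ConfigError("candidate betas must be ascending")
    fits = [scale_free_fit(adjacency(sim, b), n_bins=n_bins) for b in candidates]
    for f in fits:
        if f.valid and f.r_squared >= target_r2:
            return f.beta, fits
    finite = [f for f in fits if f.valid]
    if not finite:
        raise NumericalError("scale-free fit invalid for every candidate power")
    best = max(finite, key=lambda f: f.r_squared)
    warnings.warn(
        f"no candidate power reached the scale-free fit target {target_r2}; "
        f"returning argmax beta={best.beta} (index {best.r_squared:.3f})"
    )
    return best.beta, fits


def fit_table(fits: list[ScaleFreeFit]) -> pd.DataFrame:
    """Diagnostic sweep as a tidy table (power, signed R^2, slope, mean k)."""
    return pd.DataFrame(
        {
            "beta": [f.beta for f in fits],
            "signed_r2": [f.r_squared for f in fits],
            "slope": [f.slope for f in fits],
            "mean_connectivity": [f.mean_connectivity for f in fits],
        }
    )


def tom(adj: AdjacencyMatrix) -> TomMatrix:
    """Topological overlap measure of a weighted network.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i the connectivity; TOM_ii = 1.
    The adjacency diagonal is treated as zero inside the formula.
    """
    a = adj.values.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # (A^2)_ij already excludes u == i and u == j terms (diag zero)
    denom = np.minimum.outer(k, k) + 1.0 - a
    if np.any(denom <= 0):
        raise NumericalError("non-positive TOM denominator; adjacency outside [0,1]?")
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return TomMatrix(adj.feature_ids, t)
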