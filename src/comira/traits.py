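"""Module-trait correlation and hub-candidate ranking.

Module eigengenes are correlated with each clinical trait (Pearson r
with a Student-t p-value); within a module of interest, each member's
gene significance (GS, correlation with the trait) and module
membership (MM, correlation with the eigengene) are tabulated and the
top candidates per correlation sign are ranked by GS p-value.

GS is stored signed — the ranking separates positively from negatively
trait-correlated features — with the absolute value available as a
view.  Survival enters here as a plain numeric trait (observed months);
censoring is handled only in the validation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, NumericalError
from .io import GREY, ExpressionMatrix, ModuleAssignment, TraitTable
from .modules import EigengeneSet

__all__ = [
    "CorrelationResult",
    "correlation_test",
    "module_trait_matrix",
    "gs_mm",
    "rank_candidates",
]


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n_used: int


def correlation_test(x, y, min_pairs: int = 3) -> CorrelationResult:
    """Pearson correlation with a two-sided Student-t p-value.

    Complete pairs only; t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom; r = +/-1 gives p = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < min_pairs:
        raise NumericalError(f"need at least {min_pairs} complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise NumericalError("zero variance in correlation input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:  # numerically perfect correlation
        return CorrelationResult(float(np.sign(r)), 0.0, n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r, float(p), n)


def module_trait_matrix(
    eigengenes: EigengeneSet,
    traits: TraitTable,
    adjust: bool = False,
) -> pd.DataFrame:
    """One row per (module, trait): r, p, n_used (pairwise-complete).

    With ``adjust``, a Benjamini-Hochberg column ``p_adj`` is appended
    across all (module, trait) tests — clearly labelled, since the raw
    per-correlation p < 0.05 rule invites false positives over many
    modules and traits.
    """
    shared = eigengenes.data.index.intersection(traits.data.index)
    if len(shared) < 3:
        raise InputError(
            f"only {len(shared)} shared samples between eigengenes and traits"
        )
    me = eigengenes.data.loc[shared]
    tr = traits.data.loc[shared]
    rows = []
    for module in me.columns:
        for trait in tr.columns:
            try:
                res = correlation_test(me[module], tr[trait])
            except NumericalError as exc:
                raise NumericalError(f"trait {trait!r}: {exc}") from exc
            rows.append(
                {"module": module, "trait": trait,
                 "r": res.r, "p": res.p, "n_used": res.n_used}
            )
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class GsMmTable:
    """Per-member gene significance and module membership for one module."""

    module: str
    trait: str
    data: pd.DataFrame  # index feature_id; gs_r, gs_p, mm_r, mm_p
    gs_mm_correlation: CorrelationResult | None  # across members; None if n<3

    @property
    def gs_abs(self) -> pd.Series:
        """Absolute gene significance (the paper-style GS view)."""
        return self.data["gs_r"].abs()


def gs_mm(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    eigengenes: EigengeneSet,
    trait: pd.Series | np.ndarray,
    module: str,
    trait_name: str = "trait",
) -> GsMmTable:
    """GS and MM tables for one module against one trait.

    Also computes the intramodular GS-MM correlation across members.
    The table is sorted by GS p-value ascending.
    """
    if module == GREY:
        raise InputError("grey is the unassigned bucket, not a module")
    members = assignment.members(module)
    if not members:
        raise InputError(f"no such module: {module!r}")
    trait = np.asarray(trait, dtype=float)
    me = eigengenes.data[module].to_numpy()
    rows = []
    for f in members:
        x = expr.data.loc[f].to_numpy(dtype=float)
        g = correlation_test(x, trait)
        m = correlation_test(x, me)
        rows.append({"feature_id": f, "gs_r": g.r, "gs_p": g.p,
                     "mm_r": m.r, "mm_p": m.p})
    table = pd.DataFrame(rows).set_index("feature_id")
    table = table.sort_values("gs_p", kind="mergesort")
    if len(members) >= 3:
        try:
            gm = correlation_test(table["gs_r"], table["mm_r"])
        except NumericalError:
            warnings.warn("GS-MM correlation degenerate (constant GS or MM)")
            gm = None
    else:
        warnings.warn("GS-MM correlation undefined for fewer than 3 members")
        gm = None
    return GsMmTable(module, trait_name, table, gm)


def rank_candidates(
    table: GsMmTable, k: int = 2
) -> tuple[list[str], list[str]]:
    """Top-k positively and top-k negatively trait-correlated members.

    Members are split by the sign of GS; within each sign they are
    ordered by GS p-value ascending, ties broken by |GS| descending and
    then feature id.  Zero GS counts as positive.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    df = table.data
    def top(sub: pd.DataFrame) -> list[str]:
        sub = sub.reset_index().copy()
        sub["_abs"] = sub["gs_r"].abs()
        sub = sub.sort_values(
            ["gs_p", "_abs", "feature_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        return list(sub["feature_id"][:k])

    pos = top(df[df["gs_r"] >= 0])
    neg = top(df[df["gs_r"] < 0])
    if len(pos) < k:
        warnings.warn(f"only {len(pos)} positively correlated members")
    if len(neg) < k:
        warnings.warn(f"only {len(neg)} negatively correlated members")
    return pos, neg
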