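"""Model/Results interface over the whole discovery pipeline.

`CoexpressionModel` holds the data and configuration;
:meth:`CoexpressionModel.fit` runs similarity -> soft-threshold ->
adjacency -> TOM -> clustering -> dynamic cut -> module merging ->
eigengenes -> module-trait correlation, and returns a
`CoexpressionResults` carrying every intermediate object, a
``summary()`` table and the hub-selection helpers (GS/MM tables,
candidate ranking).  Analysis is fully deterministic — randomness lives
only in the synthetic generators.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, modules, network, traits as traits_mod
from .errors import ConfigError, InputError
from .io import GREY, ExpressionMatrix, ModuleAssignment, TraitTable

__all__ = ["PipelineConfig", "CoexpressionModel", "CoexpressionResults"]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the discovery pipeline.

    Defaults follow the serum-miRNA study design this package grew out
    of: soft threshold chosen automatically against a scale-free fit
    target of 0.80, minimum module size 5, modules merged above 75%
    eigengene similarity, module selection at p < 0.05, top 2 candidates
    per correlation sign, OS bins at 12 and 24 months.
    """

    beta: int | None = None  # None = choose by scale-free criterion
    target_r2: float = 0.80
    candidate_betas: tuple[int, ...] = tuple(range(1, 21))
    min_module_size: int = 5
    cut_quantile: float = 0.99
    pam_stage: bool = True
    merge_similarity: float = 0.75
    module_p_cutoff: float = 0.05
    candidate_k: int = 2
    os_bins: tuple[float, float] = (12.0, 24.0)
    survival_trait: str = "survival"

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta < 1:
            raise ConfigError("beta must be >= 1")
        if not (0 < self.target_r2 <= 1):
            raise ConfigError("target_r2 must lie in (0, 1]")
        if self.min_module_size < 2:
            raise ConfigError("min_module_size must be >= 2")
        if not (0 < self.merge_similarity < 1):
            raise ConfigError("merge_similarity must lie in (0, 1)")
        if not (0 < self.module_p_cutoff <= 1):
            raise ConfigError("module_p_cutoff must lie in (0, 1]")
        if self.candidate_k < 1:
            raise ConfigError("candidate_k must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["candidate_betas"] = list(self.candidate_betas)
        d["os_bins"] = list(self.os_bins)
        return d


class CoexpressionModel:
    """Weighted unsigned co-expression network model of an expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Log-scale expression, features x samples.  Zero-variance
        features are dropped at construction.
    traits : TraitTable, optional
        Clinical traits, samples x traits; needed for module-trait
        correlation and hub selection.
    config : PipelineConfig, optional
    """

    def __init__(self, expr: ExpressionMatrix, traits: TraitTable | None = None,
                 config: PipelineConfig | None = None):
        self.expr = expr.drop_constant_features()
        self.traits = traits
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, expr_df: pd.DataFrame,
                       traits_df: pd.DataFrame | None = None,
                       **config_kwargs) -> "CoexpressionModel":
        """Build from raw DataFrames (expression features x samples)."""
        cfg = PipelineConfig(**config_kwargs) if config_kwargs else None
        return cls(
            ExpressionMatrix(expr_df),
            TraitTable(traits_df) if traits_df is not None else None,
            cfg,
        )

    def fit(self) -> "CoexpressionResults":
        cfg = self.config
        sim = network.similarity(self.expr)
        fits: list[network.ScaleFreeFit] = []
        if cfg.beta is None:
            beta, fits = network.pick_soft_threshold(
                sim, cfg.candidate_betas, cfg.target_r2
            )
        else:
            beta = cfg.beta
        adj = network.adjacency(sim, beta)
        tom = network.tom(adj)
        diss = tom.dissimilarity
        dendro = modules.average_linkage(diss, self.expr.feature_ids)
        raw = modules.dynamic_cut(
            dendro, diss, cfg.min_module_size, cfg.cut_quantile, cfg.pam_stage
        )
        if raw.module_colors:
            assignment, eigengenes = modules.merge_close_modules(
                self.expr, raw, cfg.merge_similarity
            )
        else:
            warnings.warn("no modules detected; everything is grey")
            assignment, eigengenes = raw, None
        module_trait = None
        if self.traits is not None and eigengenes is not None:
            module_trait = traits_mod.module_trait_matrix(eigengenes, self.traits)
        return CoexpressionResults(
            model=self,
            beta=beta,
            scale_free_fits=fits,
            similarity=sim,
            tom=tom,
            dendrogram=dendro,
            premerge_assignment=raw,
            assignment=assignment,
            eigengenes=eigengenes,
            module_trait=module_trait,
        )


@dataclass
class CoexpressionResults:
    """Everything the fitted network pipeline produced."""

    model: CoexpressionModel
    beta: int
    scale_free_fits: list
    similarity: "network.SimilarityMatrix"
    tom: "network.TomMatrix"
    dendrogram: "modules.Dendrogram"
    premerge_assignment: ModuleAssignment
    assignment: ModuleAssignment
    eigengenes: "modules.EigengeneSet | None"
    module_trait: pd.DataFrame | None

    # ------------------------------------------------------------------
    @property
    def module_sizes(self) -> dict[str, int]:
        return self.assignment.sizes()

    def significant_modules(self, trait: str | None = None) -> pd.DataFrame:
        """Module-trait rows below the configured p cut-off."""
        if self.module_trait is None:
            raise InputError("no trait table was supplied")
        mt = self.module_trait
        if trait is not None:
            mt = mt[mt["trait"] == trait]
        return mt[mt["p"] < self.model.config.module_p_cutoff]

    def select_module(self, trait: str) -> str:
        """Module with the smallest p against ``trait`` (the hub-step default)."""
        if self.module_trait is None:
            raise InputError("no trait table was supplied")
        mt = self.module_trait[self.module_trait["trait"] == trait]
        if mt.empty:
            raise InputError(f"no such trait: {trait!r}")
        return str(mt.loc[mt["p"].idxmin(), "module"])

    def gs_mm(self, trait: str, module: str | None = None) -> "traits_mod.GsMmTable":
        if self.model.traits is None or self.eigengenes is None:
            raise InputError("gs_mm needs traits and detected modules")
        if module is None:
            module = self.select_module(trait)
        shared = self.eigengenes.data.index
        tvec = self.model.traits.data.loc[shared, trait]
        return traits_mod.gs_mm(
            self.model.expr, self.assignment, self.eigengenes,
            tvec, module, trait_name=trait,
        )

    def rank_candidates(self, trait: str, module: str | None = None,
                        k: int | None = None):
        table = self.gs_mm(trait, module)
        return traits_mod.rank_candidates(
            table, k or self.model.config.candidate_k
        )

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary."""
        cfg = self.model.config
        lines = [
            "Weighted co-expression network analysis",
            "=" * 55,
            f"features: {self.model.expr.n_features}   "
            f"samples: {self.model.expr.n_samples}",
            f"soft threshold beta: {self.beta}"
            + ("" if cfg.beta is not None else
               f"  (auto, scale-free target {cfg.target_r2})"),
        ]
        if self.scale_free_fits:
            chosen = [f for f in self.scale_free_fits if f.beta == self.beta]
            if chosen and chosen[0].valid:
                lines.append(f"scale-free fit index: {chosen[0].r_squared:.3f}")
        sizes = self.module_sizes
        n_grey = sizes.get(GREY, 0)
        mods = self.assignment.module_colors
        lines += [
            f"modules before merging: {len(self.premerge_assignment.module_colors)}",
            f"modules after merging (>{cfg.merge_similarity:.0%} similarity): "
            f"{len(mods)}",
            f"grey (unassigned) features: {n_grey}",
            "module sizes: "
            + ", ".join(f"{c}={sizes[c]}" for c in mods),
        ]
        if self.module_trait is not None:
            sig = self.significant_modules()
            lines.append(
                f"module-trait correlations with p < {cfg.module_p_cutoff}: "
                f"{len(sig)}"
            )
            for _, row in sig.sort_values("p").head(8).iterrows():
                lines.append(
                    f"  {row['module']:<12} ~ {row['trait']:<12} "
                    f"r = {row['r']:+.2f}  p = {row['p']:.4f}"
                )
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        """Machine-readable summary; records every applied default so a
        run is reconstructible from the summary alone."""
        out = {
            "version": __version__,
            "config": self.model.config.to_dict(),
            "n_features": self.model.expr.n_features,
            "n_samples": self.model.expr.n_samples,
            "beta": self.beta,
            "n_modules": len(self.assignment.module_colors),
            "n_modules_premerge": len(self.premerge_assignment.module_colors),
            "module_sizes": self.module_sizes,
        }
        if self.module_trait is not None:
            out["module_trait"] = self.module_trait.to_dict(orient="records")
        return out

    def to_files(self, out_dir, seed: int | None = None) -> None:
        """Write assignment, eigengenes, fit table, dendrogram and summary."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_module_assignment(
            self.assignment, out_dir / "modules.tsv", seed=seed
        )
        if self.eigengenes is not None:
            io.write_eigengenes(
                self.eigengenes.data, out_dir / "eigengenes.tsv", seed=seed
            )
        if self.scale_free_fits:
            network.fit_table(self.scale_free_fits).to_csv(
                out_dir / "soft_threshold.tsv", sep="\t", index=False
            )
        self.dendrogram.merge_table().to_csv(
            out_dir / "dendrogram.tsv", sep="\t", index=False
        )
        (out_dir / "dendrogram.nwk").write_text(self.dendrogram.to_newick() + "\n")
        if self.module_trait is not None:
            self.module_trait.to_csv(
                out_dir / "module_trait.tsv", sep="\t", index=False
            )
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
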