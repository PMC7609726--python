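"""Tabular input/output with validation.

All artifacts are plain TSV/CSV.  Expression matrices are stored with
features as rows and samples as columns (the array-export convention);
trait tables with samples as rows.  Cq tables are long format, one row
per (sample, replicate).  Writers prepend a ``#`` comment line recording
the tool version and, when relevant, the seed, which readers skip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "ExpressionMatrix",
    "TraitTable",
    "QpcrTable",
    "SurvivalData",
    "ModuleAssignment",
    "read_expression",
    "write_expression",
    "read_traits",
    "write_traits",
    "read_qpcr",
    "write_qpcr",
    "read_survival",
    "write_survival",
    "read_module_assignment",
    "write_module_assignment",
    "write_eigengenes",
]

from . import __version__

GREY = "grey"


def _header_comment(seed: int | None = None) -> str:
    line = f"# comira v{__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise InputError(f"duplicate {what}: {dup}")


@dataclass
class ExpressionMatrix:
    """Log-scale expression, features x samples.

    Missing values are allowed (NaN); zero-variance features are flagged
    at construction so downstream network code can drop them.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "feature ids")
        _check_unique(self.data.columns, "sample ids")
        if self.data.shape[1] < 3:
            raise InputError(
                f"need at least 3 samples, got {self.data.shape[1]}"
            )
        if self.data.shape[0] < 2:
            raise InputError(
                f"need at least 2 features, got {self.data.shape[0]}"
            )
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def constant_features(self) -> list[str]:
        """Feature ids whose observed values have zero variance."""
        v = self.data.var(axis=1, ddof=1, skipna=True)
        return list(self.data.index[(v == 0) | v.isna()])

    def drop_constant_features(self) -> "ExpressionMatrix":
        bad = self.constant_features()
        if bad:
            warnings.warn(f"dropping {len(bad)} zero-variance features: {bad[:5]}...")
            return ExpressionMatrix(self.data.drop(index=bad))
        return self

    def subset(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(feature_ids)])


@dataclass
class TraitTable:
    """Clinical traits, samples x traits; ordinal scores encoded as numbers."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "trait names")
        self.data.index = self.data.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class QpcrTable:
    """Long-format qPCR table: one row per (sample, replicate).

    Columns: sample_id, replicate, target_cq, reference_cq,
    target_efficiency, reference_efficiency.  Efficiencies are fold per
    cycle in [1, 2]; absent efficiency columns default to 2.0 (perfect
    doubling, the classic 2^-ddCq assumption).
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "replicate", "target_cq", "reference_cq")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise InputError(f"qPCR table missing column {col!r}")
        for col in ("target_efficiency", "reference_efficiency"):
            if col not in self.data.columns:
                self.data[col] = 2.0
        eff = self.data[["target_efficiency", "reference_efficiency"]].to_numpy()
        if np.any((eff < 1.0) | (eff > 2.0)):
            raise InputError("amplification efficiencies must lie in [1, 2]")
        cq = self.data[["target_cq", "reference_cq"]].to_numpy()
        if np.any(cq <= 0):
            raise InputError("Cq values must be positive")

    def averaged(self) -> pd.DataFrame:
        """Arithmetic mean over replicates, one row per sample."""
        return (
            self.data.groupby("sample_id", sort=False)
            .agg(
                target_cq=("target_cq", "mean"),
                reference_cq=("reference_cq", "mean"),
                target_efficiency=("target_efficiency", "mean"),
                reference_efficiency=("reference_efficiency", "mean"),
            )
            .reset_index()
        )


@dataclass
class SurvivalData:
    """Per-patient follow-up: time (months, > 0), event flag, group label."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample_id", "time", "event"):
            if col not in self.data.columns:
                raise InputError(f"survival table missing column {col!r}")
        if "group" not in self.data.columns:
            self.data["group"] = ""
        if np.any(self.data["time"].to_numpy(dtype=float) <= 0):
            raise InputError("survival times must be positive")
        self.data["event"] = self.data["event"].astype(bool)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=bool)


@dataclass
class ModuleAssignment:
    """Module color per feature; ``grey`` is reserved for unassigned."""

    feature_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.labels):
            raise InputError("feature_ids and labels length mismatch")
        _check_unique(self.feature_ids, "feature ids")

    @property
    def module_colors(self) -> list[str]:
        """Non-grey module colors, by decreasing size then first-seen order."""
        sizes: dict[str, int] = {}
        order: dict[str, int] = {}
        for i, lab in enumerate(self.labels):
            if lab == GREY:
                continue
            sizes[lab] = sizes.get(lab, 0) + 1
            order.setdefault(lab, i)
        return sorted(sizes, key=lambda c: (-sizes[c], order[c]))

    def members(self, color: str) -> list[str]:
        return [f for f, l in zip(self.feature_ids, self.labels) if l == color]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.feature_ids, name="module")


# ---------------------------------------------------------------------------
# readers / writers


def _delimiter_for(path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path, delimiter, index_col=0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    return pd.read_csv(
        path, sep=_delimiter_for(path, delimiter), comment="#", index_col=index_col
    )


def _coerce_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    """Coerce every cell to float; a non-numeric cell is a hard error
    naming its row and column."""
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise InputError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    return out.astype(float)


def read_expression(path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix (first column feature ids, header samples)."""
    df = _read_table(path, delimiter)
    expr = ExpressionMatrix(_coerce_numeric(df, path))
    const = expr.constant_features()
    if const:
        warnings.warn(
            f"{len(const)} zero-variance feature(s) in {path}: {const[:5]}"
        )
    return expr


def write_expression(expr: ExpressionMatrix, path, delimiter=None, seed=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        expr.data.to_csv(fh, sep=_delimiter_for(path, delimiter))


def read_traits(path, delimiter=None) -> TraitTable:
    df = _read_table(path, delimiter)
    return TraitTable(_coerce_numeric(df, path))


def write_traits(traits: TraitTable, path, delimiter=None, seed=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        traits.data.to_csv(fh, sep=_delimiter_for(path, delimiter))


def read_qpcr(path, delimiter=None) -> QpcrTable:
    df = _read_table(path, delimiter, index_col=None)
    return QpcrTable(df)


def write_qpcr(table: QpcrTable, path, delimiter=None, seed=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        table.data.to_csv(fh, sep=_delimiter_for(path, delimiter), index=False)


def read_survival(path, delimiter=None) -> SurvivalData:
    df = _read_table(path, delimiter, index_col=None)
    return SurvivalData(df)


def write_survival(surv: SurvivalData, path, delimiter=None, seed=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        surv.data.to_csv(fh, sep=_delimiter_for(path, delimiter), index=False)


def read_module_assignment(path, delimiter=None) -> ModuleAssignment:
    df = _read_table(path, delimiter, index_col=None)
    if list(df.columns[:2]) != ["feature_id", "module"]:
        raise InputError(
            f"module assignment must have columns feature_id, module; got {list(df.columns)}"
        )
    return ModuleAssignment(
        [str(x) for x in df["feature_id"]], [str(x) for x in df["module"]]
    )


def write_module_assignment(assignment: ModuleAssignment, path, delimiter=None,
                            seed=None) -> None:
    """Two-column TSV (feature_id, module) in the assignment's feature order."""
    path = Path(path)
    df = pd.DataFrame(
        {"feature_id": assignment.feature_ids, "module": assignment.labels}
    )
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep=_delimiter_for(path, delimiter), index=False)


def write_eigengenes(eigengenes: pd.DataFrame, path, delimiter=None, seed=None) -> None:
    """Eigengene table, samples x modules."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        eigengenes.to_csv(fh, sep=_delimiter_for(path, delimiter))
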