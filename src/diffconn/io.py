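"""Reading and writing feature matrices, results, and correlation matrices.

Feature matrices are CSV/TSV with a header row of feature names and one row
per sample (a ``--transpose`` style flag covers features-as-rows files). An
optional group column with exactly two levels splits one file into the two
group matrices.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .association import AssociationError
from .corr_structures import CorrelationModel
from .significance import DCResult

__all__ = ["ParseError", "read_feature_matrix", "write_feature_matrix",
           "write_dc_result", "read_dc_result", "write_correlation_matrix",
           "read_correlation_matrix"]


class ParseError(ValueError):
    """Malformed input file."""


def _sep_for(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_feature_matrix(
    path: Union[str, Path],
    group_column: Optional[str] = None,
    transpose: bool = False,
    sep: Optional[str] = None,
):
    """Read a feature matrix; returns a DataFrame, or a pair when split.

    Non-numeric cells raise :class:`ParseError` naming every offending
    (row, column). With ``group_column`` the file must contain that column
    with exactly two levels, and a ``(group1, group2)`` pair of DataFrames is
    returned (in order of first appearance).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if df.columns.str.match(r"^Unnamed").any() or df.shape[1] == 0:
        raise ParseError(f"{path}: malformed or missing header row")
    if transpose:
        if group_column is not None:
            raise ParseError("group_column cannot be combined with transpose")
        df = df.set_index(df.columns[0]).T.reset_index(drop=True)
        df.columns.name = None

    groups = None
    if group_column is not None:
        if group_column not in df.columns:
            raise ParseError(f"{path}: group column {group_column!r} not found")
        groups = df[group_column]
        levels = pd.unique(groups)
        if len(levels) != 2:
            raise ParseError(
                f"{path}: group column must have exactly 2 levels, "
                f"found {len(levels)}: {list(levels)!r}")
        df = df.drop(columns=[group_column])

    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        rows, cols = np.where(bad.to_numpy())
        cells = [f"(row {i}, column {df.columns[j]!r})"
                 for i, j in zip(rows, cols)][:20]
        raise ParseError(f"{path}: non-numeric cells: {', '.join(cells)}")
    coerced = coerced.astype(float)

    if groups is None:
        return coerced
    levels = pd.unique(groups)
    g1 = coerced[groups == levels[0]].reset_index(drop=True)
    g2 = coerced[groups == levels[1]].reset_index(drop=True)
    return g1, g2


def write_feature_matrix(df: pd.DataFrame, path: Union[str, Path],
                         sep: Optional[str] = None) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path, sep), index=False)


def write_dc_result(result: DCResult, path: Union[str, Path]) -> None:
    """One row per feature: feature, chi_g1, chi_g2, delta_chi, p_value,
    significant. Full float precision so round trips are lossless."""
    result.to_frame().to_csv(Path(path), index=False)


def read_dc_result(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    required = ["feature", "chi_g1", "chi_g2", "delta_chi", "p_value",
                "significant"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def write_correlation_matrix(model: CorrelationModel,
                             path: Union[str, Path]) -> None:
    p = model.p
    names = [f"V{i + 1}" for i in range(p)]
    pd.DataFrame(model.matrix, index=names, columns=names).to_csv(Path(path))


def read_correlation_matrix(path: Union[str, Path]) -> np.ndarray:
    df = pd.read_csv(Path(path), index_col=0)
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ParseError(f"{path}: correlation matrix must be square")
    return m
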