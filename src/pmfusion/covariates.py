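"""Demographic/clinical covariate cleaning, encoding and screening.

Implements the tabular arm of the fusion pipeline: the 5%-missing
cleaning rule (columns before rows), categorical digitization with
lexicographic level codes, min-max scaling to [0,1] fitted on training
subjects, and a per-variable univariate screen (Welch t-test for numeric
columns, chi-square test of independence for categorical ones).  The
screen is a report: all surviving variables are carried into the
classifier regardless of p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyTableError, SingleClassError
from .types import FeatureView, as_labels

__all__ = [
    "CovariateTable",
    "clean_table",
    "encode_and_scale",
    "univariate_screen",
    "read_covariates",
]

log = logging.getLogger(__name__)

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass
class CovariateTable:
    """Typed covariate table keyed by subject id.

    ``data`` is indexed by unique subject ids; ``types`` declares every
    column as numeric or categorical.  Missing values are NaN (numeric) or
    NaN/empty (categorical).
    """

    data: pd.DataFrame
    types: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.data.index.is_unique:
            raise ValueError("subject ids must be unique")
        for col in self.data.columns:
            if col not in self.types:
                raise ValueError(f"column {col!r} has no declared type")
            if self.types[col] not in (NUMERIC, CATEGORICAL):
                raise ValueError(f"bad type for {col!r}: {self.types[col]!r}")

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    def column(self, name: str) -> pd.Series:
        return self.data[name]


def clean_table(
    t: CovariateTable, max_missing: float = 0.05, fit_subjects=None
) -> CovariateTable:
    """Drop over-missing columns, then over-missing rows, then impute.

    Columns whose missing fraction exceeds ``max_missing`` are removed
    first (retaining more subjects, the scarcer resource); then rows whose
    missing fraction over the surviving columns exceeds the threshold.
    Residual missing cells are imputed with the median (numeric) or mode
    (categorical) computed on ``fit_subjects`` (default: surviving rows).
    """
    df = t.data
    col_miss = df.isna().mean(axis=0)
    keep_cols = col_miss[col_miss <= max_missing].index
    dropped_cols = [c for c in df.columns if c not in set(keep_cols)]
    df = df[keep_cols]
    if df.shape[1] == 0:
        raise EmptyTableError("all columns exceeded the missing threshold")

    row_miss = df.isna().mean(axis=1)
    keep_rows = row_miss[row_miss <= max_missing].index
    dropped_rows = [r for r in df.index if r not in set(keep_rows)]
    df = df.loc[keep_rows].copy()
    if df.shape[0] == 0:
        raise EmptyTableError("all rows exceeded the missing threshold")
    if dropped_cols or dropped_rows:
        log.info(
            "cleaning removed %d columns %s and %d subjects",
            len(dropped_cols), dropped_cols, len(dropped_rows),
        )

    fit = df if fit_subjects is None else df.loc[
        [s for s in fit_subjects if s in df.index]
    ]
    for col in df.columns:
        if not df[col].isna().any():
            continue
        if t.types[col] == NUMERIC:
            fill = fit[col].median()
        else:
            modes = fit[col].mode()
            fill = sorted(modes)[0] if len(modes) else fit[col].dropna().iloc[0]
        df[col] = df[col].fillna(fill)
    return CovariateTable(data=df, types={c: t.types[c] for c in df.columns})


def encode_and_scale(t: CovariateTable, fit_subjects=None) -> FeatureView:
    """Digitize categoricals and min-max scale every column to [0,1].

    Categorical levels are coded by lexicographic order over the levels
    observed anywhere in the table; scaling min/max are fitted on
    ``fit_subjects`` only, and out-of-range values clip to [0,1] when the
    view is scaled.  Constant columns map to all zeros (with a warning).
    """
    df = t.data
    mat = np.empty((df.shape[0], df.shape[1]), dtype=float)
    for j, col in enumerate(df.columns):
        if t.types[col] == NUMERIC:
            mat[:, j] = pd.to_numeric(df[col]).to_numpy(dtype=float)
        else:
            levels = sorted(df[col].astype(str).unique())
            codes = {lev: i for i, lev in enumerate(levels)}
            mat[:, j] = [codes[v] for v in df[col].astype(str)]
        if np.nanstd(mat[:, j]) == 0:
            log.warning("column %r is constant; it scales to all zeros", col)

    view = FeatureView(
        source_id="D",
        subject_ids=list(df.index),
        matrix=mat,
        feature_names=list(df.columns),
    )
    if fit_subjects is not None:
        pos = {s: i for i, s in enumerate(df.index)}
        rows = [pos[s] for s in fit_subjects]
        view.fit_scaling(rows)
    else:
        view.fit_scaling()
    return view


def _welch_t(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float]:
    if np.std(x0) == 0 and np.std(x1) == 0:
        # degenerate: no within-class variation
        return (0.0, 1.0) if np.mean(x0) == np.mean(x1) else (np.inf, 0.0)
    res = stats.ttest_ind(x0, x1, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _chi2_merged(col: pd.Series, y: np.ndarray) -> tuple[float, float, bool]:
    """Chi-square on the level-by-class table; levels creating a zero
    row/column are merged into the rarest other level and flagged."""
    tab = pd.crosstab(col.astype(str), pd.Series(y, index=col.index))
    flagged = False
    while tab.shape[0] > 1 and (tab.sum(axis=1) == 0).any():
        zero = tab.sum(axis=1).idxmin()
        rest = tab.drop(index=zero)
        rarest = rest.sum(axis=1).idxmin()
        tab.loc[rarest] += tab.loc[zero]
        tab = tab.drop(index=zero)
        flagged = True
    if tab.shape[0] < 2:
        return 0.0, 1.0, True
    stat, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return float(stat), float(p), flagged


def univariate_screen(
    t: CovariateTable, y, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-variable association screen against the disease label.

    Numeric columns get a two-sample unequal-variance t-test, categorical
    columns a chi-square test of independence on the level-by-class
    contingency table.  Returns a report (variable, test, statistic,
    p_value, significant); no variable is dropped.
    """
    y = as_labels(y)
    if len(y) != t.data.shape[0]:
        raise ValueError("label length does not match table")
    rows = []
    for col in t.data.columns:
        if t.types[col] == NUMERIC:
            vals = pd.to_numeric(t.data[col]).to_numpy(dtype=float)
            stat, p = _welch_t(vals[y == -1], vals[y == 1])
            test, flagged = "t-test", False
        else:
            stat, p, flagged = _chi2_merged(t.data[col], y)
            test = "chi-square"
        rows.append(
            {
                "variable": col,
                "test": test,
                "statistic": stat,
                "p_value": p,
                "significant": p < alpha,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def read_covariates(csv_path, types_path) -> CovariateTable:
    """Read a covariate CSV (header + subject_id column) with a sidecar
    type declaration file of ``name,numeric|categorical`` lines."""
    types = {}
    with open(types_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, kind = line.replace("\t", ",").partition(",")
            types[name.strip()] = kind.strip()
    df = pd.read_csv(csv_path, index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if types.get(col) == CATEGORICAL:
            df[col] = df[col].astype("object")
            df.loc[df[col].astype(str).isin(["", "nan", "NA"]), col] = np.nan
    return CovariateTable(data=df, types=types)
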