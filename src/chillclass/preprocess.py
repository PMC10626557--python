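"""Normalization, outlier filtering, correlation screening and group stats.

The pipeline order is: 3σ outlier filtering on the raw derived-parameter
matrix (per temperature × day group by default), then column-wise min–max
normalization of the retained rows to [0, 1]. Filtering first keeps extreme
rows from compressing the normalized range of everything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chlf import FEATURE_NAMES, META_COLUMNS
from .errors import DomainError

__all__ = [
    "FeatureMatrix",
    "GroupSummary",
    "minmax_normalize",
    "inverse_normalize",
    "filter_outliers_3sigma",
    "pearson_matrix",
    "correlation_strength",
    "group_statistics",
]

STRENGTH_BINS = (
    (0.0, 0.2, "uncorrelated"),
    (0.2, 0.4, "weak"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "strong"),
    (0.8, 1.0, "extremely strong"),
)


@dataclass
class FeatureMatrix:
    """An N×p block of real-valued features plus aligned sample metadata.

    ``values`` carries the feature columns; ``sample_meta`` holds
    (plant_id, temperature_C, day) rows aligned by position.  After
    :func:`minmax_normalize`, ``ranges`` stores the per-column (min, max)
    so the transform can be inverted.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    ranges: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if len(self.values) != len(self.sample_meta):
            raise DomainError("values and sample_meta row counts differ")
        if self.values.isna().any().any():
            raise DomainError("feature matrix contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   feature_names: tuple[str, ...] = FEATURE_NAMES) -> "FeatureMatrix":
        """Split a tidy derived-parameter table into features + metadata."""
        return cls(
            values=frame[list(feature_names)].reset_index(drop=True).astype(float),
            sample_meta=frame[list(META_COLUMNS)].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.sample_meta.reset_index(drop=True),
             self.values.reset_index(drop=True)], axis=1
        )


@dataclass
class GroupSummary:
    """Per-feature, per-temperature summary plus across-group tests.

    ``table`` is tidy: one row per feature with mean/std per temperature
    group, Levene's p (mean-centered variant) and the one-way ANOVA F.
    ``degenerate`` flags features whose within-group variance is zero, for
    which F is reported as +inf.
    """

    table: pd.DataFrame
    degenerate: list[str] = field(default_factory=list)


def minmax_normalize(M: FeatureMatrix) -> FeatureMatrix:
    """Map each column linearly onto [0, 1]: Y = (X − Xmin)/(Xmax − Xmin).

    The per-column (Xmin, Xmax) pair is stored on the result for the
    inverse transform.  A constant column has no well-defined image and
    raises :class:`DomainError` naming the feature.
    """
    ranges: dict[str, tuple[float, float]] = {}
    out = {}
    for name in M.values.columns:
        col = M.values[name].to_numpy(dtype=float)
        lo, hi = float(col.min()), float(col.max())
        if hi == lo:
            raise DomainError(f"constant column cannot be normalized: {name}")
        ranges[name] = (lo, hi)
        out[name] = (col - lo) / (hi - lo)
    return FeatureMatrix(
        values=pd.DataFrame(out, columns=M.values.columns),
        sample_meta=M.sample_meta.reset_index(drop=True),
        ranges=ranges,
    )


def inverse_normalize(M: FeatureMatrix) -> FeatureMatrix:
    """Undo :func:`minmax_normalize` using the stored column ranges."""
    if M.ranges is None:
        raise DomainError("matrix has no stored normalization ranges")
    out = {}
    for name in M.values.columns:
        lo, hi = M.ranges[name]
        out[name] = M.values[name].to_numpy(dtype=float) * (hi - lo) + lo
    return FeatureMatrix(
        values=pd.DataFrame(out, columns=M.values.columns),
        sample_meta=M.sample_meta.reset_index(drop=True),
    )


def _loo_mean_std(col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # leave-one-out mean and sample (ddof=1) std for every position at once
    n = len(col)
    total, sq_total = col.sum(), (col ** 2).sum()
    mean = (total - col) / (n - 1)
    ss = (sq_total - col ** 2) - (n - 1) * mean ** 2
    var = ss / max(n - 2, 1)
    return mean, np.sqrt(np.clip(var, 0.0, None))


def filter_outliers_3sigma(
    M: FeatureMatrix,
    grouping: str = "group",
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Remove rows violating the 3σ rule on any feature.

    A row is flagged when one of its features lies more than three standard
    deviations from the mean of its group, the row itself excluded from the
    statistics (so a lone aberrant value in an otherwise constant group is
    caught).  ``grouping`` is ``"group"`` (per temperature × day, default)
    or ``"global"``.  Groups with fewer than 3 rows are passed through with
    a warning.  Returns the retained matrix and a table of removed rows
    with the feature that triggered removal.
    """
    if grouping not in ("group", "global"):
        raise DomainError(f"unknown grouping mode: {grouping!r}")
    meta = M.sample_meta.reset_index(drop=True)
    values = M.values.reset_index(drop=True)
    if grouping == "group":
        keys = list(zip(meta["temperature_C"], meta["day"]))
    else:
        keys = [0] * len(values)
    key_series = pd.Series(keys)

    drop_idx: list[int] = []
    trigger: dict[int, str] = {}
    for key, idx in key_series.groupby(key_series).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 3:
            warnings.warn(
                f"group {key} has fewer than 3 rows; passed through unfiltered",
                stacklevel=2,
            )
            continue
        for name in values.columns:
            col = values.loc[idx, name].to_numpy(dtype=float)
            mean, std = _loo_mean_std(col)
            bad = np.abs(col - mean) > 3.0 * std
            for local_i in np.nonzero(bad)[0]:
                row = int(idx[local_i])
                if row not in trigger:
                    trigger[row] = name
                    drop_idx.append(row)

    drop_idx.sort()
    removed = pd.concat(
        [meta.loc[drop_idx].reset_index(drop=True),
         pd.Series([trigger[i] for i in drop_idx], name="triggering_feature")],
        axis=1,
    )
    keep = values.index.difference(drop_idx)
    return (
        FeatureMatrix(
            values=values.loc[keep].reset_index(drop=True),
            sample_meta=meta.loc[keep].reset_index(drop=True),
        ),
        removed,
    )


def pearson_matrix(M: FeatureMatrix) -> pd.DataFrame:
    """Product-moment correlation for every feature pair (symmetric, unit
    diagonal).  Requires ≥ 3 samples and no constant column."""
    X = M.values.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise DomainError("pearson_matrix requires at least 3 samples")
    stds = X.std(axis=0)
    if np.any(stds == 0):
        bad = [n for n, s in zip(M.values.columns, stds) if s == 0]
        raise DomainError(f"correlation undefined for constant columns: {bad}")
    corr = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(corr, index=M.values.columns, columns=M.values.columns)


def correlation_strength(r: float) -> str:
    """Bin |r| into the five verbal strength categories.

    Bins are half-open on the left boundary except the top one:
    [0,0.2) uncorrelated, [0.2,0.4) weak, [0.4,0.6) moderate,
    [0.6,0.8) strong, [0.8,1.0] extremely strong.
    """
    a = abs(r)
    if a > 1.0:
        raise DomainError(f"|r| must be <= 1, got {r}")
    for lo, hi, label in STRENGTH_BINS:
        if lo <= a < hi:
            return label
    return STRENGTH_BINS[-1][2]  # a == 1.0


def group_statistics(M: FeatureMatrix, group_col: str = "temperature_C") -> GroupSummary:
    """Per-feature mean/std by group plus Levene's test (mean-centered) and
    one-way fixed-effects ANOVA across groups.

    Groups with zero within-group variance but distinct means make the
    ANOVA F diverge; such features are reported with F = +inf and flagged.
    """
    meta = M.sample_meta.reset_index(drop=True)
    groups = sorted(meta[group_col].unique())
    if len(groups) < 2:
        raise DomainError("group_statistics requires at least 2 groups")
    sizes = meta[group_col].value_counts()
    if (sizes < 2).any():
        raise DomainError("every group needs at least 2 rows")

    rows = []
    degenerate: list[str] = []
    for name in M.values.columns:
        samples = [
            M.values.loc[(meta[group_col] == g).to_numpy(), name].to_numpy(dtype=float)
            for g in groups
        ]
        row: dict[str, float | str] = {"feature": name}
        for g, s in zip(groups, samples):
            row[f"mean_{g}"] = float(np.mean(s))
            row[f"std_{g}"] = float(np.std(s, ddof=1))
        within_ss = sum(((s - s.mean()) ** 2).sum() for s in samples)
        if within_ss == 0:
            means = [s.mean() for s in samples]
            row["levene_p"] = np.nan
            row["anova_F"] = np.inf if len(set(means)) > 1 else 0.0
            degenerate.append(name)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, lev_p = stats.levene(*samples, center="mean")
                F, _ = stats.f_oneway(*samples)
            row["levene_p"] = float(lev_p)
            row["anova_F"] = float(F)
        rows.append(row)
    return GroupSummary(table=pd.DataFrame(rows), degenerate=degenerate)
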