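"""Two-group differential expression for microarray-style intensity matrices.

The analysis chain mirrors standard array practice: quantile normalization of
per-sample intensity distributions, per-feature one-way ANOVA between the two
age groups (young vs adult), Benjamini-Hochberg FDR adjustment, and threshold
classification into up / down / not-significant.

All statistics are computed on log2 intensities; ``log2fc`` is always the
adult mean minus the young mean, so "up" means higher in adult animals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

YOUNG = "young"
ADULT = "adult"

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "FilterSpec",
    "GENE_FILTER",
    "MIRNA_FILTER",
    "quantile_normalize",
    "log2_if_linear",
    "anova_per_feature",
    "bh_adjust",
    "classify_de",
]


class ValidationError(ValueError):
    """Raised when an input matrix or design violates the schema contract."""


@dataclass
class ExpressionMatrix:
    """Features x samples intensity grid with a two-group design.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, one column per sample id.
    design
        Series mapping sample id -> group label (``young`` / ``adult``).
    log2
        Whether ``values`` are on the log2 scale. Linear-scale matrices must
        pass through :func:`log2_if_linear` before testing.
    """

    values: pd.DataFrame
    design: pd.Series
    log2: bool = True

    def __post_init__(self) -> None:
        self.design = pd.Series(self.design)
        v = self.values
        if v.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        missing = [s for s in v.columns if s not in self.design.index]
        if missing:
            raise ValidationError(f"samples absent from design: {missing}")
        groups = self.design.loc[list(v.columns)]
        bad = sorted(set(groups) - {YOUNG, ADULT})
        if bad:
            raise ValidationError(f"unknown group labels: {bad}")
        counts = groups.value_counts()
        for g in (YOUNG, ADULT):
            if counts.get(g, 0) < 2:
                raise ValidationError(
                    f"group '{g}' has {counts.get(g, 0)} samples; need >= 2"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.design[s] == group]


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds used to call a feature differentially expressed.

    ``fc_threshold`` is a linear-scale fold change (>= 1); the classifier
    compares ``|log2fc|`` against ``log2(fc_threshold)``.
    """

    kind: str  # "gene" | "mirna"
    p_threshold: float
    use_adjusted: bool
    fc_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "mirna"):
            raise ValueError(f"kind must be 'gene' or 'mirna', got {self.kind!r}")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.fc_threshold < 1.0:
            raise ValueError("fc_threshold must be >= 1 (linear scale)")


#: Gene reporting filter: BH-adjusted p < 0.01, any nonzero fold change.
GENE_FILTER = FilterSpec(kind="gene", p_threshold=0.01, use_adjusted=True)
#: miRNA reporting filter: raw p < 0.001 and at least a 1.5-fold change.
MIRNA_FILTER = FilterSpec(
    kind="mirna", p_threshold=0.001, use_adjusted=False, fc_threshold=1.5
)


@dataclass
class DEResult:
    """Per-feature differential-expression table plus the derived DE sets.

    ``table`` columns: mean_young, mean_adult, log2fc, f_stat, p_raw, p_adj,
    direction (one of up/down/ns). ``up_features`` / ``down_features`` are
    present only after :func:`classify_de`.
    """

    table: pd.DataFrame
    filter_spec: FilterSpec | None = None
    up_features: set[str] = field(default_factory=set)
    down_features: set[str] = field(default_factory=set)


def quantile_normalize(m):
    """Force every sample onto the common reference intensity distribution.

    The reference is the vector of row means of the column-sorted matrix;
    each column's values are replaced by the reference value at their rank.
    Tied values within a column receive the mean of the reference values over
    the tied rank span, so ties stay tied.

    Accepts an :class:`ExpressionMatrix` (returned normalized, same design)
    or a bare features x samples DataFrame (returned as a DataFrame).
    """
    frame = m.values if isinstance(m, ExpressionMatrix) else m
    X = frame.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("expression matrix contains missing values")
    n_feat, n_samp = X.shape
    if n_samp < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samp):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sc = col[order]
        # group consecutive equal values; each tie block gets the mean of
        # the reference over the ranks it occupies
        change = np.r_[True, sc[1:] != sc[:-1]]
        gid = np.cumsum(change) - 1
        means = np.bincount(gid, weights=ref) / np.bincount(gid)
        out[order, j] = means[gid]
    values = pd.DataFrame(out, index=frame.index, columns=frame.columns)
    if isinstance(m, ExpressionMatrix):
        return ExpressionMatrix(values=values, design=m.design, log2=m.log2)
    return values


def log2_if_linear(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Return a log2-scale matrix; a no-op if ``m`` is already log2."""
    if m.log2:
        return m
    shifted = m.values.to_numpy(dtype=float) + offset
    if (shifted <= 0).any():
        raise ValidationError(
            "nonpositive intensities cannot be log-transformed; "
            "pass a positive offset"
        )
    values = pd.DataFrame(
        np.log2(shifted), index=m.values.index, columns=m.values.columns
    )
    return ExpressionMatrix(values=values, design=m.design, log2=True)


def anova_per_feature(m: ExpressionMatrix) -> DEResult:
    """One-way ANOVA of adult vs young per feature on a log2 matrix.

    With two groups the F statistic equals the square of the pooled-variance
    t statistic and the p-values coincide. Features that are constant within
    both groups get F=0, p=1 when the group means agree (no evidence) and
    p=0 when they differ (infinite evidence in the noiseless limit).
    """
    if not m.log2:
        raise ValidationError("ANOVA expects log2 intensities; run log2_if_linear")
    young = m.values[m.group_columns(YOUNG)].to_numpy(dtype=float)
    adult = m.values[m.group_columns(ADULT)].to_numpy(dtype=float)
    mean_y = young.mean(axis=1)
    mean_a = adult.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p_raw = stats.f_oneway(young, adult, axis=1)
    # degenerate rows: zero within-group variance in both groups
    ssw = ((young - mean_y[:, None]) ** 2).sum(axis=1) + (
        (adult - mean_a[:, None]) ** 2
    ).sum(axis=1)
    degenerate = ssw == 0.0
    equal_means = mean_y == mean_a
    f_stat = np.where(degenerate & equal_means, 0.0, f_stat)
    p_raw = np.where(degenerate & equal_means, 1.0, p_raw)
    f_stat = np.where(degenerate & ~equal_means, np.inf, f_stat)
    p_raw = np.where(degenerate & ~equal_means, 0.0, p_raw)
    table = pd.DataFrame(
        {
            "mean_young": mean_y,
            "mean_adult": mean_a,
            "log2fc": mean_a - mean_y,
            "f_stat": f_stat,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "direction": "ns",
        },
        index=m.values.index,
    )
    return DEResult(table=table)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_de(result: DEResult, spec: FilterSpec) -> DEResult:
    """Apply a :class:`FilterSpec` and fill in directions and DE sets.

    A feature is up (down) when its p criterion passes, ``|log2fc|`` clears
    ``log2(fc_threshold)``, and log2fc is strictly positive (negative).
    A passing p with log2fc exactly 0 stays ``ns`` (no direction assignable).
    """
    table = result.table.copy()
    pcol = table["p_adj"] if spec.use_adjusted else table["p_raw"]
    lfc = table["log2fc"]
    min_lfc = math.log2(spec.fc_threshold)
    passes = (pcol < spec.p_threshold) & (np.abs(lfc) >= min_lfc) & (lfc != 0)
    direction = np.where(passes & (lfc > 0), "up", np.where(passes, "down", "ns"))
    table["direction"] = direction
    up = set(table.index[table["direction"] == "up"])
    down = set(table.index[table["direction"] == "down"])
    return DEResult(
        table=table, filter_spec=spec, up_features=up, down_features=down
    )
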