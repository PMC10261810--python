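"""Group summaries, between-group hypothesis tests and regulatory checks.

Summaries reproduce the survey-table layout: per-congener and total
min/max/mean/SD per group (overall, by product type, or by brand), with the
total defined as the per-sample sum over the six congeners.

Group comparisons follow a normality-gated rule: Kolmogorov-Smirnov
normality per group (against a normal with moment-estimated parameters) at
alpha = 0.05; if every group passes, a parametric test is used (independent
t-test for two groups, one-way ANOVA otherwise), else the rank-based
analogue (Mann-Whitney / Kruskal-Wallis). Significance is declared at
p < 0.05.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .congeners import CONGENERS, EU_LIMIT_NG_G_FAT, Congener
from .distributions import MomentSpec
from .errors import DataError, SchemaError

__all__ = [
    "GroupSummary",
    "GroupTestResult",
    "total_ndl",
    "summarize",
    "summary_frame",
    "compare_groups",
    "check_regulatory_limit",
    "ALPHA",
]

ALPHA: float = 0.05

_LEVELS = ("overall", "product", "brand")


def _congener_matrix(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c.value for c in CONGENERS if c.value not in records.columns]
    if missing:
        raise SchemaError(f"records missing congener columns {missing}")
    return records[[c.value for c in CONGENERS]].astype(float)


def total_ndl(record: pd.Series | pd.DataFrame) -> float | pd.Series:
    """Per-sample sum of the six congener concentrations (ng/g fat)."""
    if isinstance(record, pd.Series):
        missing = [c.value for c in CONGENERS if c.value not in record.index]
        if missing:
            raise SchemaError(f"record missing congeners {missing}")
        return float(sum(record[c.value] for c in CONGENERS))
    return _congener_matrix(record).sum(axis=1)


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Min/max/mean/SD per congener and for the six-congener total, one group."""

    level: str  # "overall" | "product" | "brand"
    value: str  # group label ("all" for overall)
    n: int
    per_congener: dict[Congener, MomentSpec]
    total: MomentSpec


def _moments(x: np.ndarray) -> MomentSpec:
    return MomentSpec(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        minimum=float(x.min()),
        maximum=float(x.max()),
    )


def summarize(records: pd.DataFrame, level: str = "overall") -> list[GroupSummary]:
    """Group summaries at the requested level; groups with <2 records are
    skipped with a warning (an SD needs at least two observations)."""
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}, got {level!r}")
    mat = _congener_matrix(records)
    totals = mat.sum(axis=1)
    if level == "overall":
        groups = {"all": records.index}
    else:
        if level not in records.columns:
            raise SchemaError(f"records missing grouping column {level!r}")
        groups = {
            str(val): idx
            for val, idx in records.groupby(level, sort=True).groups.items()
        }
    out: list[GroupSummary] = []
    for label, idx in groups.items():
        if len(idx) < 2:
            warnings.warn(
                f"group {label!r} has {len(idx)} record(s); skipped", stacklevel=2
            )
            continue
        sub = mat.loc[idx]
        out.append(
            GroupSummary(
                level=level,
                value=label,
                n=len(idx),
                per_congener={c: _moments(sub[c.value].to_numpy()) for c in CONGENERS},
                total=_moments(totals.loc[idx].to_numpy()),
            )
        )
    return out


def summary_frame(summaries: Sequence[GroupSummary], decimals: int | None = 2) -> pd.DataFrame:
    """Survey-style table: rows congeners + Total, columns (group, statistic)."""
    rows = [c.value for c in CONGENERS] + ["Total"]
    cols: dict[tuple[str, str], list[float]] = {}
    for s in summaries:
        specs = [s.per_congener[c] for c in CONGENERS] + [s.total]
        cols[(s.value, "min")] = [sp.minimum for sp in specs]
        cols[(s.value, "max")] = [sp.maximum for sp in specs]
        cols[(s.value, "mean")] = [sp.mean for sp in specs]
        cols[(s.value, "sd")] = [sp.sd for sp in specs]
    frame = pd.DataFrame(cols, index=rows)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["group", "stat"])
    return frame.round(decimals) if decimals is not None else frame


@dataclasses.dataclass(frozen=True)
class GroupTestResult:
    """Outcome of one between-group comparison for one congener (or total)."""

    congener: str  # congener name or "total"
    factor: str
    test_name: str  # "anova" | "t_test" | "mann_whitney" | "kruskal_wallis"
    statistic: float
    p_value: float
    normality_p: dict[str, float]
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DataError(f"p-value outside [0, 1]: {self.p_value}")


def _normality_p(x: np.ndarray) -> float:
    """Plain KS test against a normal with moment-estimated parameters.

    A constant group has no normal fit; it is scored p = 0 so the pipeline
    falls through to the rank-based test.
    """
    sd = x.std(ddof=1)
    if sd == 0.0:
        return 0.0
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def compare_groups(
    records: pd.DataFrame,
    factor: str,
    congener: Congener | str = "total",
    alpha: float = ALPHA,
) -> GroupTestResult:
    """Normality-gated comparison of one congener (or the total) across groups.

    Requires >= 2 groups with >= 3 records each. Raises :class:`DataError`
    if the data are constant across all groups (no test is defined).
    """
    if factor not in ("product", "brand"):
        raise ValueError(f"factor must be 'product' or 'brand', got {factor!r}")
    if factor not in records.columns:
        raise SchemaError(f"records missing grouping column {factor!r}")
    name = congener.value if isinstance(congener, Congener) else str(congener)
    values = total_ndl(records) if name == "total" else _congener_matrix(records)[name]

    groups: dict[str, np.ndarray] = {
        str(lbl): values.loc[idx].to_numpy(dtype=float)
        for lbl, idx in records.groupby(factor, sort=True).groups.items()
    }
    if len(groups) < 2:
        raise DataError(f"need >= 2 groups for factor {factor!r}, got {len(groups)}")
    small = {k: v.size for k, v in groups.items() if v.size < 3}
    if small:
        raise DataError(f"groups with < 3 records: {small}")
    pooled = np.concatenate(list(groups.values()))
    if pooled.std() == 0.0:
        raise DataError("data constant across all groups; test undefined")

    normality = {k: _normality_p(v) for k, v in groups.items()}
    arrays = list(groups.values())
    if all(p > alpha for p in normality.values()):
        if len(arrays) == 2:
            test_name = "t_test"
            stat, p = sps.ttest_ind(*arrays)
        else:
            test_name = "anova"
            stat, p = sps.f_oneway(*arrays)
    else:
        if len(arrays) == 2:
            test_name = "mann_whitney"
            stat, p = sps.mannwhitneyu(*arrays, alternative="two-sided")
        else:
            test_name = "kruskal_wallis"
            stat, p = sps.kruskal(*arrays)
    return GroupTestResult(
        congener=name,
        factor=factor,
        test_name=test_name,
        statistic=float(stat),
        p_value=float(p),
        normality_p=normality,
        significant=bool(p < alpha),
    )


def check_regulatory_limit(
    summary: GroupSummary, limit: float = EU_LIMIT_NG_G_FAT
) -> tuple[bool, float]:
    """EU maximum-level check on the mean six-congener total.

    Returns (compliant, margin) with ``compliant`` true iff the mean total
    is strictly below the limit and ``margin = limit - mean``.
    """
    margin = limit - summary.total.mean
    return summary.total.mean < limit, margin
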