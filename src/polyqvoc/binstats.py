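"""Binned group-mean correlation and band comparison statistics.

The comparative analyses do not correlate species-level values directly:
species are first binned — either by fixed thresholds on a phenotype or
metric (e.g. characteristic call frequency in 10 kHz bins) or by rank into
equal-sized groups (e.g. 8 groups of 5 species ordered by relative cochlear
size) — and Pearson's r is computed over the per-bin means, optionally
after a log10 transform of one axis.  Ratio-band contrasts use a one-way
fixed-effects ANOVA followed by the Student-Newman-Keuls (SNK) stepdown on
ordered group means, with unbalanced groups handled via harmonic-mean n.

Built-in named schemes (exactly the published procedures):

=================  ============================================
``char_freq``      <=30 kHz, 30-90 kHz by 10, >90 kHz (8 bins)
``min_freq``       <=20 kHz, 20-80 kHz by 10, >80 kHz (8 bins)
``bandwidth``      <=5 kHz, 5-40 kHz by 5, >40 kHz (9 bins)
``ratio_10bin``    <=1, 1-5 by 0.5, >5 (10 bins)
``ratio_6bin``     <=3, 3-5 by 0.5, >5 (6 bins)
``cwbw_rank5``     rank groups of 5 by increasing value
=================  ============================================

Interval convention: the first bin is closed at its upper edge ("<=30"),
interior bins are left-open/right-closed, the last bin is open above.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BinningError, DegenerateDataError

THRESHOLD, RANK_EQUAL_SIZE = "THRESHOLD", "RANK_EQUAL_SIZE"
IDENTITY, LOG10 = "IDENTITY", "LOG10"


@dataclass(frozen=True)
class BinScheme:
    name: str
    mode: str = THRESHOLD
    edges: tuple[float, ...] = ()
    group_size: int = 0

    def __post_init__(self):
        if self.mode == THRESHOLD:
            if len(self.edges) < 1:
                raise ValueError("THRESHOLD scheme needs at least one edge")
            if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
                raise ValueError("edges must be strictly increasing")
        elif self.mode == RANK_EQUAL_SIZE:
            if self.group_size < 2:
                raise ValueError("RANK scheme needs group_size >= 2")
        else:
            raise ValueError(f"unknown bin mode {self.mode!r}")

    @property
    def n_bins(self) -> Optional[int]:
        return len(self.edges) + 1 if self.mode == THRESHOLD else None


def _by10(lo: float, hi: float, step: float) -> tuple[float, ...]:
    return tuple(np.round(np.arange(lo, hi + step / 2, step), 10))


SCHEMES: dict[str, BinScheme] = {
    "char_freq": BinScheme("char_freq", THRESHOLD, _by10(30, 90, 10)),
    "min_freq": BinScheme("min_freq", THRESHOLD, _by10(20, 80, 10)),
    "bandwidth": BinScheme("bandwidth", THRESHOLD, _by10(5, 40, 5)),
    "ratio_10bin": BinScheme("ratio_10bin", THRESHOLD, _by10(1, 5, 0.5)),
    "ratio_6bin": BinScheme("ratio_6bin", THRESHOLD, _by10(3, 5, 0.5)),
    "cwbw_rank5": BinScheme("cwbw_rank5", RANK_EQUAL_SIZE, group_size=5),
}


@dataclass(frozen=True)
class GroupSummary:
    bin_label: str
    n: int
    mean_x: float
    mean_y: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_groups: int
    p_value: float
    transform_x: str = IDENTITY
    transform_y: str = IDENTITY


@dataclass(frozen=True)
class GroupComparison:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    alpha: float
    #: pairwise (label_a, label_b) -> significant at alpha (SNK stepdown);
    #: empty when the omnibus test is not significant
    posthoc: dict[tuple[str, str], bool]


def assign_bins(
    values: Sequence[Optional[float]], scheme: BinScheme
) -> list[Optional[int]]:
    """Assign each non-missing value a 1-based bin label.

    THRESHOLD mode: value <= first edge -> bin 1; interior bins are
    left-open/right-closed; value > last edge -> last bin.  RANK mode sorts
    non-missing values ascending (stable on ties by input order) and chunks
    consecutive groups of ``group_size``; the non-missing count must divide
    evenly.
    """
    arr = [None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
           for v in values]
    labels: list[Optional[int]] = [None] * len(arr)
    if scheme.mode == THRESHOLD:
        edges = scheme.edges
        for i, v in enumerate(arr):
            if v is None:
                continue
            labels[i] = int(np.searchsorted(edges, v, side="left")) + 1
        return labels
    # RANK_EQUAL_SIZE
    present = [(v, i) for i, v in enumerate(arr) if v is not None]
    if len(present) % scheme.group_size != 0:
        raise BinningError(
            f"{len(present)} non-missing values are not divisible by "
            f"group_size {scheme.group_size}"
        )
    order = sorted(range(len(present)), key=lambda k: present[k][0])
    for rank, k in enumerate(order):
        labels[present[k][1]] = rank // scheme.group_size + 1
    return labels


def _transform(values: np.ndarray, how: str) -> np.ndarray:
    if how == IDENTITY:
        return values
    if how == LOG10:
        if np.any(values <= 0):
            raise ValueError("LOG10 transform requires strictly positive values")
        return np.log10(values)
    raise ValueError(f"unknown transform {how!r}")


def correlate_group_means(
    x: Sequence[Optional[float]],
    y: Sequence[Optional[float]],
    labels: Sequence[Optional[object]],
    transform_x: str = IDENTITY,
    transform_y: str = IDENTITY,
) -> tuple[CorrelationResult, list[GroupSummary]]:
    """Pearson correlation over per-bin means.

    Rows with a missing x, y or label are dropped; transforms apply per
    value *before* the group means; the two-sided p-value comes from the t
    distribution with n_groups - 2 degrees of freedom.
    """
    df = pd.DataFrame({"x": x, "y": y, "label": labels}).dropna()
    if df.empty or df["label"].nunique() < 2:
        raise DegenerateDataError("need at least 2 non-empty groups")
    df["x"] = _transform(df["x"].to_numpy(dtype=float), transform_x)
    df["y"] = _transform(df["y"].to_numpy(dtype=float), transform_y)
    grouped = df.groupby("label", sort=True).agg(
        n=("x", "size"), mean_x=("x", "mean"), mean_y=("y", "mean")
    )
    summaries = [
        GroupSummary(str(lbl), int(row.n), float(row.mean_x), float(row.mean_y))
        for lbl, row in grouped.iterrows()
    ]
    mx = grouped["mean_x"].to_numpy()
    my = grouped["mean_y"].to_numpy()
    if np.ptp(mx) == 0 or np.ptp(my) == 0:
        raise DegenerateDataError("degenerate_means: zero variance in group means")
    if len(mx) == 2:
        # two-point correlation is exactly +/-1; pearsonr still defines p
        r = 1.0 if (mx[1] - mx[0]) * (my[1] - my[0]) > 0 else -1.0
        p = 1.0
    else:
        r, p = stats.pearsonr(mx, my)
    result = CorrelationResult(
        r=float(r),
        n_groups=len(mx),
        p_value=float(p),
        transform_x=transform_x,
        transform_y=transform_y,
    )
    return result, summaries


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA from explicit sums of squares.

    Returns (F, df_between, df_within, p).
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, int(ns.sum()) - k
    if ss_within == 0:
        raise DegenerateDataError("degenerate_groups: zero within-group variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return f, df_b, df_w, p


@lru_cache(maxsize=4096)
def _q_crit(alpha: float, span: int, df: int) -> float:
    # studentized-range critical value; cached because ppf is expensive and
    # null simulations reuse the same (span, df) pairs thousands of times
    return float(stats.studentized_range.ppf(1 - alpha, span, df))


def snk_posthoc(
    groups: dict[str, np.ndarray], ms_within: float, df_within: int, alpha: float
) -> dict[tuple[str, str], bool]:
    """Student-Newman-Keuls stepdown on ordered group means.

    The studentized range statistic for a pair spanning p ordered means is
    q = (m_hi - m_lo) / sqrt(MSW / n_h), with n_h the harmonic mean of the
    two group sizes, referred to the studentized-range distribution with
    (p, df_within).  A pair contained in a non-significant wider range is
    declared non-significant without testing (the stepdown rule).
    """
    labels = sorted(groups, key=lambda g: groups[g].mean())
    means = {g: groups[g].mean() for g in labels}
    ns = {g: len(groups[g]) for g in labels}
    k = len(labels)
    result: dict[tuple[str, str], bool] = {}
    blocked: set[tuple[int, int]] = set()
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            a, b = labels[i], labels[j]
            key = (a, b) if a <= b else (b, a)
            if (i, j) in blocked:
                result[key] = False
                continue
            nh = 2.0 / (1.0 / ns[a] + 1.0 / ns[b])
            q_obs = (means[b] - means[a]) / np.sqrt(ms_within / nh)
            sig = q_obs > _q_crit(alpha, span, df_within)
            result[key] = bool(sig)
            if not sig:
                for ii in range(i, j + 1):
                    for jj in range(ii + 1, j + 1):
                        blocked.add((ii, jj))
    return result


def compare_groups(
    values: Sequence[float],
    labels: Sequence[object],
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA across labeled groups with SNK post hoc.

    The post hoc is computed only when the omnibus F test is significant at
    ``alpha``; otherwise ``posthoc`` is empty.
    """
    df = pd.DataFrame({"v": values, "label": labels}).dropna()
    groups = {
        str(lbl): sub["v"].to_numpy(dtype=float)
        for lbl, sub in df.groupby("label", sort=True)
    }
    if len(groups) < 2 or any(len(g) < 2 for g in groups.values()):
        raise DegenerateDataError("need >=2 groups each with >=2 values")
    f, df_b, df_w, p = anova_oneway(list(groups.values()))
    posthoc: dict[tuple[str, str], bool] = {}
    if p <= alpha:
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        posthoc = snk_posthoc(groups, ss_within / df_w, df_w, alpha)
    return GroupComparison(
        f_stat=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=float(p),
        alpha=alpha,
        posthoc=posthoc,
    )
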