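"""Device-comparison statistics for the preference survey and blind scans.

Four pieces, matching the study's analysis layer:

* per-category test for a device effect on preference ranks.  Because each
  rater ranks all devices, ranks within a rater are a constrained
  permutation (they always sum to n(n+1)/2), so groups are negatively
  correlated and a one-way ANOVA on pooled ranks is anti-conservative.
  The implementation therefore blocks on rater — a repeated-measures ANOVA
  on the ranks, which on rank data is the Iman–Davenport form of the
  Friedman test and holds its nominal size under the permutation null;
* paired Wilcoxon signed-rank between two devices' ranks across raters
  (Pratt handling of zero differences; exact null when available);
* descriptive summaries: rank mean/median/sd per device and category, and
  blind-scan pass success rates per device;
* per-device measurement-bias regression: ONSD error (manual measurement
  minus caliper mean) on device indicators with no intercept, so each
  coefficient is that device's expected bias in mm, with OLS standard
  errors and 95% CIs;
* a seeded Latin-square generator for counterbalancing evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phantom_io import AnnotationRecord, SurveyRecord

__all__ = [
    "RankSummary",
    "PassSummary",
    "rank_anova",
    "wilcoxon_paired",
    "summarize_ranks",
    "summarize_passes",
    "onsd_bias_regression",
    "latin_square",
]


@dataclass(frozen=True)
class RankSummary:
    device_id: str
    category: str
    mean_rank: float
    median_rank: float
    sd_rank: float


@dataclass(frozen=True)
class PassSummary:
    device_id: str
    mean_success_rate: float
    sd_success_rate: float


def _rank_table(records: Sequence[SurveyRecord], category: str) -> pd.DataFrame:
    """Rater × device rank matrix for one category; must be complete."""
    df = pd.DataFrame(
        [
            {"rater_id": r.rater_id, "device_id": r.device_id, "rank": r.rank}
            for r in records
            if r.category == category
        ]
    )
    if df.empty:
        raise ValueError(f"no records for category {category!r}")
    table = df.pivot(index="rater_id", columns="device_id", values="rank")
    if table.isna().any().any():
        raise ValueError(f"category {category!r}: incomplete rank permutations")
    return table


def rank_anova(records: Sequence[SurveyRecord], category: str) -> tuple[float, float]:
    """Test for a device effect on ranks within one survey category.

    Repeated-measures ANOVA on the rank matrix with rater as the blocking
    factor:  F = MS_device / MS_residual with (k−1) and (k−1)(n−1) degrees
    of freedom for k devices and n raters.  On within-rater ranks this is
    the Iman–Davenport statistic, whose size is close to nominal under the
    random-permutation null (a one-way layout is not, because each rater's
    ranks are negatively correlated).
    """
    table = _rank_table(records, category)
    n, k = table.shape
    if k < 2:
        raise ValueError("rank_anova needs at least 2 devices")
    if n < 2:
        raise ValueError("rank_anova needs at least 2 raters")
    R = table.to_numpy(dtype=float)
    grand = R.mean()
    ss_dev = n * ((R.mean(axis=0) - grand) ** 2).sum()
    ss_sub = k * ((R.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((R - grand) ** 2).sum()
    ss_err = ss_tot - ss_dev - ss_sub
    df_dev = k - 1
    df_err = (k - 1) * (n - 1)
    if ss_err <= 0:
        # perfect agreement across raters: no residual variance
        return float("inf"), 0.0
    F = (ss_dev / df_dev) / (ss_err / df_err)
    p = float(stats.f.sf(F, df_dev, df_err))
    return float(F), p


def wilcoxon_paired(
    records: Sequence[SurveyRecord],
    device_a: str,
    device_b: str,
    category: str,
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank on two devices' per-rater ranks.

    Zero differences are kept under the Pratt convention; the exact null
    distribution is used when the data admit it (no zeros, small n),
    otherwise the tie-corrected normal approximation with continuity
    correction.  All-zero differences yield p = 1 with a warning.  The
    result is symmetric in the two devices.
    """
    table = _rank_table(records, category)
    for d in (device_a, device_b):
        if d not in table.columns:
            raise ValueError(f"device {d!r} not ranked in category {category!r}")
    diffs = (table[device_a] - table[device_b]).to_numpy(dtype=float)
    if np.all(diffs == 0):
        warnings.warn(
            f"all rank differences between {device_a!r} and {device_b!r} are zero",
            stacklevel=2,
        )
        return 0.0, 1.0
    has_zeros = bool(np.any(diffs == 0))
    method = "approx" if (has_zeros or diffs.size > 25) else "auto"
    res = stats.wilcoxon(
        diffs, zero_method="pratt", correction=True, method=method
    )
    return float(res.statistic), float(res.pvalue)


def summarize_ranks(
    records: Sequence[SurveyRecord], ddof: int = 1
) -> pd.DataFrame:
    """Per-device, per-category rank mean/median/sd over raters.

    ``ddof=1`` (sample sd) by convention for survey summaries.
    """
    df = pd.DataFrame(
        [
            {
                "device_id": r.device_id,
                "category": r.category,
                "rank": r.rank,
            }
            for r in records
        ]
    )
    if df.empty:
        raise ValueError("no survey records")
    out = (
        df.groupby(["device_id", "category"])["rank"]
        .agg(
            mean_rank="mean",
            median_rank="median",
            sd_rank=lambda s: s.std(ddof=ddof),
        )
        .reset_index()
    )
    return out


def summarize_passes(annotations: Sequence[AnnotationRecord], ddof: int = 1) -> pd.DataFrame:
    """Per-device mean and sd of the per-video pass success rate.

    Videos with zero passes carry no rate and are excluded with a warning.
    """
    rows = []
    for a in annotations:
        if a.n_passes == 0:
            warnings.warn(f"video {a.video_id!r} has 0 passes; excluded", stacklevel=2)
            continue
        rows.append({"device_id": a.device_id, "rate": a.n_success / a.n_passes})
    if not rows:
        raise ValueError("no annotations with at least one pass")
    df = pd.DataFrame(rows)
    return (
        df.groupby("device_id")["rate"]
        .agg(mean_success_rate="mean", sd_success_rate=lambda s: s.std(ddof=ddof))
        .reset_index()
    )


def onsd_bias_regression(annotations: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Per-device expected ONSD measurement error, by OLS.

    Response: manual measurement minus the caliper mean (the average of the
    two physical axis measurements).  Design: one indicator column per
    device, no intercept, so each coefficient is that device's bias in mm.
    Returns a table with coefficient, std_error, t, p, ci_low, ci_high per
    device (95% CIs).
    """
    rows = [
        {
            "device_id": a.device_id,
            "error_mm": a.onsd_measured - a.caliper_mean,
        }
        for a in annotations
        if a.onsd_measured is not None
    ]
    if not rows:
        raise ValueError("no annotations with an ONSD measurement")
    df = pd.DataFrame(rows)
    counts = df["device_id"].value_counts()
    thin = counts[counts < 2]
    if not thin.empty:
        raise ValueError(f"devices with < 2 measurements: {sorted(thin.index)}")
    X = pd.get_dummies(df["device_id"], dtype=float)
    fit = sm.OLS(df["error_mm"].to_numpy(), X).fit()
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "device_id": X.columns,
            "coefficient": fit.params.to_numpy(),
            "std_error": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def latin_square(n: int, seed: int = 0) -> np.ndarray:
    """Seeded n×n Latin square for counterbalancing evaluation order.

    A cyclic square with independently permuted rows, columns and symbols;
    every symbol 0..n−1 appears exactly once per row and per column.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    base = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
    rows = rng.permutation(n)
    cols = rng.permutation(n)
    symbols = rng.permutation(n)
    return symbols[base[np.ix_(rows, cols)]]
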