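"""Two-group statistical comparison of progression speeds.

The comparison machinery mirrors the spreadsheet-style "two-sample assuming
unequal variances" t-test output: the Welch t statistic, the
Welch-Satterthwaite degrees of freedom, the one-tail p-value P(T <= t)
(upper-tail probability of |t|), and the two-tail critical value at alpha.

Also provided: the selector splitting a cohort into borderline (incipient
disease with fairly good function: DLco 70-85 % predicted, GAP-ILD 0-3) and
normal groups, and the per-band, per-metric speed-versus-DLco comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .progression import SpeedRecord


@dataclass(frozen=True)
class TTestResult:
    """Welch t-test output in the spreadsheet layout."""

    t_stat: float
    df: float
    p_one_tail: float
    t_crit_two_tail: float
    alpha: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class GroupSelector:
    """Thresholds defining the borderline (incipient DILD) group.

    DLco bounds are % predicted, inclusive on both ends; the interval is
    centred on the lower normal limit (80 %) to capture early impairment of
    the alveolar-capillary membrane.  GAP-ILD scores of 0-3 points keep only
    mildly affected cases.
    """

    dlco_low: float = 70.0
    dlco_high: float = 85.0
    gap_min: int = 0
    gap_max: int = 3

    def __post_init__(self) -> None:
        if self.dlco_low >= self.dlco_high:
            raise ValueError("dlco_low must be below dlco_high")


def welch_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = 0.05
) -> TTestResult:
    """Unequal-variance two-sample t-test.

    The t statistic is (mean_a - mean_b) / sqrt(var_a/n_a + var_b/n_b) with
    sample variances (ddof=1); degrees of freedom follow Welch-Satterthwaite.
    ``p_one_tail`` is the upper-tail probability of |t| under t(df) and
    ``t_crit_two_tail`` the (1 - alpha/2) quantile.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # degenerate but well-defined: no variance, no difference
            df = float(a.size + b.size - 2)
            return TTestResult(
                t_stat=0.0,
                df=df,
                p_one_tail=0.5,
                t_crit_two_tail=float(stats.t.ppf(1 - alpha / 2, df)),
                alpha=alpha,
                n_a=int(a.size),
                n_b=int(b.size),
            )
        raise ValueError("both samples have zero variance with unequal means")
    sa, sb = va / a.size, vb / b.size
    t_stat = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        (sa**2 / (a.size - 1)) + (sb**2 / (b.size - 1))
    )
    return TTestResult(
        t_stat=float(t_stat),
        df=float(df),
        p_one_tail=float(stats.t.sf(abs(t_stat), df)),
        t_crit_two_tail=float(stats.t.ppf(1 - alpha / 2, df)),
        alpha=alpha,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def select_groups(
    metadata: pd.DataFrame, selector: GroupSelector | None = None
) -> tuple[list[str], list[str]]:
    """Split cohort metadata into (borderline ids, normal ids).

    ``metadata`` needs columns subject_id, diagnosis, dlco_pct, gap_score.
    Borderline: diagnosis other than "normal" with DLco inside the selector
    interval (inclusive) and GAP score within [gap_min, gap_max].  Normal:
    rows whose diagnosis equals "normal" (case-insensitive).
    """
    if selector is None:
        selector = GroupSelector()
    required = {"subject_id", "diagnosis", "dlco_pct", "gap_score"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if metadata.empty:
        return [], []
    diag = metadata["diagnosis"].astype(str).str.lower()
    is_normal = diag == "normal"
    borderline = metadata[
        ~is_normal
        & metadata["dlco_pct"].between(selector.dlco_low, selector.dlco_high)
        & metadata["gap_score"].between(selector.gap_min, selector.gap_max)
    ]
    normal = metadata[is_normal]
    return (
        borderline["subject_id"].astype(str).tolist(),
        normal["subject_id"].astype(str).tolist(),
    )


def compare_metric_speeds(
    speeds: Sequence[SpeedRecord],
    reference: Sequence[float],
    band: str,
    metric: str,
    alpha: float = 0.05,
) -> TTestResult:
    """Welch t-test of one band/metric's speed values against reference values
    (typically the DLco relative-variation speeds of the same cohort)."""
    values = [r.v for r in speeds if r.band == band and r.metric_name == metric]
    if len(values) < 2:
        raise ValueError(f"fewer than 2 speed values for band {band!r} / {metric!r}")
    return welch_t_test(values, list(reference), alpha=alpha)


def comparison_table(
    speeds: Sequence[SpeedRecord],
    reference: Sequence[float],
    bands: Sequence[str],
    metrics: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spreadsheet-layout results table: one row per band x metric with the
    t statistic, one-tail p and two-tail critical value."""
    rows = []
    for band in bands:
        for metric in metrics:
            res = compare_metric_speeds(speeds, reference, band, metric, alpha=alpha)
            rows.append(
                {
                    "band": band,
                    "metric": metric,
                    "t_stat": res.t_stat,
                    "df": res.df,
                    "p_one_tail": res.p_one_tail,
                    "t_crit_two_tail": res.t_crit_two_tail,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                }
            )
    return pd.DataFrame(rows)


def two_group_table(
    values: pd.DataFrame,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Borderline-versus-normal comparison of metric values.

    ``values`` is long-format with columns subject_id, band, metric, value.
    Returns one row per band x metric comparing group A against group B.
    """
    required = {"subject_id", "band", "metric", "value"}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"values table missing columns: {sorted(missing)}")
    ids_a, ids_b = set(map(str, group_a_ids)), set(map(str, group_b_ids))
    rows = []
    for (band, metric), grp in values.groupby(["band", "metric"], sort=True):
        gsubj = grp["subject_id"].astype(str)
        a = grp.loc[gsubj.isin(ids_a), "value"].to_numpy(dtype=float)
        b = grp.loc[gsubj.isin(ids_b), "value"].to_numpy(dtype=float)
        res = welch_t_test(a, b, alpha=alpha)
        rows.append(
            {
                "band": band,
                "metric": metric,
                "t_stat": res.t_stat,
                "df": res.df,
                "p_one_tail": res.p_one_tail,
                "t_crit_two_tail": res.t_crit_two_tail,
                "n_a": res.n_a,
                "n_b": res.n_b,
            }
        )
    return pd.DataFrame(rows)
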