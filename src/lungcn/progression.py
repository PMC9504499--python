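"""Relative variation speed of network metrics between successive scans.

Progression is quantified as a normalized rate of change per year.  For a
metric value ``s`` at follow-up and ``s0`` at the reference (oldest) scan of
the same anatomical site, separated by ``t`` years:

    v = (s - s0) / (s0 * t)   when s0 != 0
    v = s / t                 otherwise

Elapsed time is the day count between acquisition dates divided by a
365-day year (a 360-day financial-style year is available as an option).
The speed is relative, so values are comparable across sites and patients;
its sign tracks the direction of change whenever s0 > 0.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .network import METRIC_NAMES, NetworkMetrics

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class TimepointRecord:
    """Per-band network metrics for one subject/site/date, plus optional
    functional parameters (e.g. DLco % predicted) measured at the same visit."""

    subject_id: str
    site_id: str
    date: _dt.date
    metrics: Mapping[str, NetworkMetrics]
    functional: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SpeedRecord:
    """Relative variation speed of one metric between t0 and a later scan."""

    subject_id: str
    site_id: str
    band: str
    metric_name: str
    v: float
    t_years: float
    s0: float
    s: float


def elapsed_years(
    date0: _dt.date, date1: _dt.date, days_per_year: float = DAYS_PER_YEAR
) -> float:
    """Calendar-day gap between two dates divided by a fixed-length year."""
    if date1 < date0:
        raise ValueError("date1 must not precede date0")
    return (date1 - date0).days / days_per_year


def relative_speed(s: float, s0: float, t_years: float) -> float:
    """Evaluate the piecewise speed formula.

    Branch selection uses exact equality ``s0 == 0``: the zero-reference
    branch is a genuine discontinuity of the definition, not a numerical
    guard.
    """
    if t_years <= 0:
        raise ValueError("t_years must be positive")
    if s0 != 0:
        return (s - s0) / (s0 * t_years)
    return s / t_years


def speed_table(
    records: Sequence[TimepointRecord],
    reference_policy: str = "first_scan",
    days_per_year: float = DAYS_PER_YEAR,
) -> list[SpeedRecord]:
    """Compute speeds for every later scan of each (subject, site) group.

    The reference is always the oldest scan of the group (``first_scan`` is
    the only policy).  One :class:`SpeedRecord` is emitted per later record,
    band and degree metric; functional parameters present at both timepoints
    (e.g. DLco) get speed records under band ``"functional"``.  Groups with a
    single timepoint are skipped with a warning.
    """
    if reference_policy != "first_scan":
        raise ValueError("only the 'first_scan' reference policy is supported")

    groups: dict[tuple[str, str], list[TimepointRecord]] = {}
    for rec in records:
        groups.setdefault((rec.subject_id, rec.site_id), []).append(rec)

    out: list[SpeedRecord] = []
    for (subject, site), group in sorted(groups.items()):
        group = sorted(group, key=lambda r: r.date)
        if len(group) < 2:
            logger.warning(
                "subject %s site %s: single timepoint, skipped", subject, site
            )
            continue
        dates = [r.date for r in group]
        if len(set(dates)) != len(dates):
            raise ValueError(f"subject {subject} site {site}: duplicate scan dates")
        ref = group[0]
        for later in group[1:]:
            t = elapsed_years(ref.date, later.date, days_per_year)
            for band in sorted(ref.metrics):
                if band not in later.metrics:
                    continue
                m0, m1 = ref.metrics[band].as_dict(), later.metrics[band].as_dict()
                for name in METRIC_NAMES:
                    out.append(
                        SpeedRecord(
                            subject_id=subject,
                            site_id=site,
                            band=band,
                            metric_name=name,
                            v=relative_speed(m1[name], m0[name], t),
                            t_years=t,
                            s0=float(m0[name]),
                            s=float(m1[name]),
                        )
                    )
            for name in sorted(ref.functional):
                if name not in later.functional:
                    continue
                s0, s = float(ref.functional[name]), float(later.functional[name])
                out.append(
                    SpeedRecord(
                        subject_id=subject,
                        site_id=site,
                        band="functional",
                        metric_name=name,
                        v=relative_speed(s, s0, t),
                        t_years=t,
                        s0=s0,
                        s=s,
                    )
                )
    return out


def speeds_to_frame(speeds: Sequence[SpeedRecord]) -> pd.DataFrame:
    """Speed records as a tidy DataFrame (one row per record)."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "site_id": r.site_id,
                "band": r.band,
                "metric": r.metric_name,
                "t_years": r.t_years,
                "s0": r.s0,
                "s": r.s,
                "v": r.v,
            }
            for r in speeds
        ],
        columns=["subject_id", "site_id", "band", "metric", "t_years", "s0", "s", "v"],
    )


def records_from_frame(df: pd.DataFrame) -> list[TimepointRecord]:
    """Assemble timepoint records from a long-format metrics table.

    Expected columns: subject_id, site_id, date, band, metric, value and
    optionally dlco_pct (constant within a subject/site/date group).
    """
    required = {"subject_id", "site_id", "date", "band", "metric", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    records = []
    for (subject, site, date), grp in df.groupby(
        ["subject_id", "site_id", "date"], sort=True
    ):
        metrics: dict[str, NetworkMetrics] = {}
        for band, bgrp in grp.groupby("band"):
            vals = dict(zip(bgrp["metric"], bgrp["value"]))
            metrics[str(band)] = NetworkMetrics(
                max_degree=int(vals.get("max_degree", 0)),
                total_count=int(vals.get("total_count", 0)),
                average_count=float(vals.get("average_count", 0.0)),
                node_count=int(vals.get("node_count", 0)),
            )
        functional = {}
        if "dlco_pct" in grp.columns:
            dlco = grp["dlco_pct"].dropna()
            if len(dlco):
                functional["dlco_pct"] = float(dlco.iloc[0])
        records.append(
            TimepointRecord(
                subject_id=str(subject),
                site_id=str(site),
                date=_parse_date(date),
                metrics=metrics,
                functional=functional,
            )
        )
    return records


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.date) and not isinstance(value, _dt.datetime):
        return value
    if isinstance(value, _dt.datetime):
        return value.date()
    return _dt.date.fromisoformat(str(value))
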