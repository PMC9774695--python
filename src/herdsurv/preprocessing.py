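"""Data cleaning and filtering rules for raw herd sensor files.

The cleaning pipeline turns raw daily sensor records (real or synthetic)
into the modelling dataset.  Rules, applied in this order:

1. 2-hourly rumination slots (if provided) are summed into daily minutes;
   a day with any missing slot is marked missing.
2. Survival time T = days from first calving to culling; cows without a
   culling date are right-censored at the dataset end date.
3. 3-SD outlier rule: per outcome, daily values more than 3 herd SDs from
   the herd mean are removed — unless a cow has >= 30 such days for that
   outcome, in which case they are all kept (sustained deviation is taken
   as real abnormal behaviour, e.g. disease, not recording error).  Herd
   mean/SD are computed once on the raw data (single pass).
4. Cows culled before 50 DIM are dropped (too little longitudinal signal).
5. Observations outside the 5-305 DIM window are dropped.
6. A cow is dropped when, for any outcome, she retains fewer than 90% of
   the possible daily observations in [5, min(T, 305)].

AFC (age at first calving) is coded low/medium/high against the herd
quartiles (Q1 and Q3 inclusive to 'medium'); season is 'warm' for April
through October, 'cold' otherwise.  No rule ever alters a value — rules
only remove rows/days or drop cows, and every removal is tallied in a
:class:`CleaningReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OUTCOME_COLS, HerdDataset, SurvivalRecord, logger

__all__ = [
    "CleaningReport",
    "HerdQuartiles",
    "aggregate_rumination",
    "compute_herd_stats",
    "remove_outliers",
    "compute_survival",
    "categorize_afc",
    "assign_season",
    "apply_cow_filters",
    "estimate_horizons",
    "preprocess",
]

MIN_DIM, MAX_DIM = 5, 305
MIN_SURVIVAL = 50
COMPLETENESS = 0.90
OUTLIER_SD = 3.0
OUTLIER_KEEP_COUNT = 30  # >= this many 3-SD days for one cow/outcome: keep all


@dataclass
class HerdQuartiles:
    """Herd-level summary statistics used by cleaning, coding and knots."""

    mean: dict[str, float]
    sd: dict[str, float]
    afc_q1: float
    afc_q2: float
    afc_q3: float
    dim_quartiles: tuple[float, float, float]

    def __post_init__(self):
        if not self.afc_q1 <= self.afc_q2 <= self.afc_q3:
            raise ValueError("AFC quartiles must be ordered")
        if any(s < 0 for s in self.sd.values()):
            raise ValueError("SDs must be non-negative")


@dataclass
class CleaningReport:
    """Audit trail of every cleaning rule."""

    n_input_cows: int = 0
    n_retained_cows: int = 0
    outlier_days_removed: dict = field(default_factory=dict)   # (cow_id, outcome) -> days
    outlier_days_kept: dict = field(default_factory=dict)      # >= 30-day exception hits
    cows_removed_t50: list = field(default_factory=list)
    cows_removed_completeness: list = field(default_factory=list)
    rows_outside_dim_window: int = 0
    completeness: dict = field(default_factory=dict)           # (cow_id, outcome) -> fraction

    def validate(self):
        removed = len(set(self.cows_removed_t50) | set(self.cows_removed_completeness))
        if self.n_retained_cows + removed != self.n_input_cows:
            raise AssertionError("cleaning report does not balance")

    def to_json(self, path):
        d = {
            "n_input_cows": self.n_input_cows,
            "n_retained_cows": self.n_retained_cows,
            "cows_removed_t50": list(self.cows_removed_t50),
            "cows_removed_completeness": list(self.cows_removed_completeness),
            "rows_outside_dim_window": self.rows_outside_dim_window,
            "outlier_days_removed": {f"{c}:{o}": v for (c, o), v in self.outlier_days_removed.items()},
            "outlier_days_kept": {f"{c}:{o}": v for (c, o), v in self.outlier_days_kept.items()},
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def aggregate_rumination(two_hourly: pd.DataFrame) -> pd.DataFrame:
    """Sum 2-hourly rumination slots into daily minutes.

    Input columns: ``cow_id, timestamp, minutes`` with 12 slots per full day.
    A day missing any slot is returned as NaN; a slot above 120 min is a
    validation error.
    """
    df = two_hourly.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if (df["minutes"] > 120).any() or (df["minutes"] < 0).any():
        bad = df.loc[(df["minutes"] > 120) | (df["minutes"] < 0)].iloc[0]
        raise ValueError(
            f"rumination slot out of [0, 120] min for cow {bad['cow_id']} at {bad['timestamp']}"
        )
    df["date"] = df["timestamp"].dt.normalize()
    g = df.groupby(["cow_id", "date"])["minutes"].agg(["sum", "count"]).reset_index()
    g["rum_min"] = np.where(g["count"] == 12, g["sum"], np.nan)
    return g[["cow_id", "date", "rum_min"]]


def compute_herd_stats(dataset: HerdDataset) -> HerdQuartiles:
    """Herd mean/SD per outcome and AFC/DIM quartiles (computed once, raw data)."""
    s = dataset.sensor
    mean = {c: float(np.nanmean(s[c])) for c in OUTCOME_COLS}
    sd = {c: float(np.nanstd(s[c], ddof=1)) for c in OUTCOME_COLS}
    afc = dataset.cows["afc_days"].to_numpy(dtype=float)
    q1, q2, q3 = (float(np.percentile(afc, q)) for q in (25, 50, 75))
    dq = tuple(float(np.percentile(s["dim"], q)) for q in (25, 50, 75))
    return HerdQuartiles(mean=mean, sd=sd, afc_q1=q1, afc_q2=q2, afc_q3=q3, dim_quartiles=dq)


def remove_outliers(
    dataset: HerdDataset, stats: HerdQuartiles, report: CleaningReport | None = None
) -> tuple[HerdDataset, CleaningReport]:
    """Apply the 3-SD rule with the 30-day exception, per cow and outcome."""
    if report is None:
        report = CleaningReport(n_input_cows=dataset.n_cows)
    out = dataset.copy()
    s = out.sensor
    for col in OUTCOME_COLS:
        vals = s[col].to_numpy(dtype=float)
        if stats.sd[col] == 0.0:
            if np.nanstd(vals) > 0:
                raise ValueError(f"herd SD for {col} is zero but data are not constant")
            continue
        flag = np.abs(vals - stats.mean[col]) > OUTLIER_SD * stats.sd[col]
        flag &= ~np.isnan(vals)
        if not flag.any():
            continue
        counts = s.loc[flag].groupby("cow_id").size()
        for cow, cnt in counts.items():
            key = (cow, col)
            if cnt >= OUTLIER_KEEP_COUNT:
                report.outlier_days_kept[key] = int(cnt)
            else:
                mask = flag & (s["cow_id"] == cow).to_numpy()
                vals[mask] = np.nan
                report.outlier_days_removed[key] = int(cnt)
        s[col] = vals
    return out, report


def compute_survival(calving1, culling, end_date) -> SurvivalRecord:
    """T = days from first calving to culling, or to the dataset end if censored."""
    calving1, end_date = pd.Timestamp(calving1), pd.Timestamp(end_date)
    if calving1 > end_date:
        raise ValueError("first calving after dataset end date")
    if culling is None or pd.isna(culling):
        return SurvivalRecord(T=int((end_date - calving1).days), event=0)
    culling = pd.Timestamp(culling)
    if culling <= calving1:
        raise ValueError("culling on or before first calving (T must be >= 1)")
    return SurvivalRecord(T=int((culling - calving1).days), event=1)


def categorize_afc(afc_days: float, quartiles: HerdQuartiles) -> str:
    """'low' below Q1, 'high' above Q3, 'medium' inside the closed IQR."""
    if afc_days < quartiles.afc_q1:
        return "low"
    if afc_days > quartiles.afc_q3:
        return "high"
    return "medium"


def assign_season(date) -> str:
    """'warm' for April through October (inclusive), 'cold' otherwise."""
    return "warm" if 4 <= pd.Timestamp(date).month <= 10 else "cold"


def _attach_survival(dataset: HerdDataset) -> pd.DataFrame:
    recs = []
    for row in dataset.cows.itertuples(index=False):
        r = compute_survival(row.calving1_date, row.culling_date, dataset.end_date)
        recs.append({"cow_id": row.cow_id, "T": r.T, "event": r.event})
    return pd.DataFrame(recs)


def apply_cow_filters(
    dataset: HerdDataset, report: CleaningReport | None = None
) -> tuple[HerdDataset, CleaningReport]:
    """Early-culling, DIM-window and completeness filters (in that order)."""
    if report is None:
        report = CleaningReport(n_input_cows=dataset.n_cows)
    out = dataset.copy()
    if out.survival is None:
        out.survival = _attach_survival(out)
    surv = out.survival.set_index("cow_id")

    early = surv.index[surv["T"] < MIN_SURVIVAL]
    report.cows_removed_t50 = sorted(early)

    s = out.sensor
    in_window = (s["dim"] >= MIN_DIM) & (s["dim"] <= MAX_DIM)
    report.rows_outside_dim_window = int((~in_window).sum())
    s = s.loc[in_window]

    keep_cows = []
    for cow, g in s.groupby("cow_id"):
        if cow in set(early):
            continue
        T = surv.loc[cow, "T"]
        denom = min(int(T), MAX_DIM) - (MIN_DIM - 1)
        ok = True
        for col in OUTCOME_COLS:
            frac = g[col].notna().sum() / denom
            report.completeness[(cow, col)] = float(frac)
            if frac < COMPLETENESS:
                ok = False
        if ok:
            keep_cows.append(cow)
        else:
            report.cows_removed_completeness.append(cow)
    # cows with zero in-window rows also fail completeness
    no_rows = set(out.cows["cow_id"]) - set(s["cow_id"]) - set(early)
    report.cows_removed_completeness = sorted(set(report.cows_removed_completeness) | no_rows)

    keep = sorted(keep_cows)
    if not keep:
        raise ValueError(
            "no cows left after filtering "
            f"(T<{MIN_SURVIVAL}: {len(report.cows_removed_t50)}, "
            f"completeness<{COMPLETENESS:.0%}: {len(report.cows_removed_completeness)})"
        )
    out.sensor = s.loc[s["cow_id"].isin(keep)].reset_index(drop=True)
    out.cows = out.cows.loc[out.cows["cow_id"].isin(keep)].reset_index(drop=True)
    out.survival = out.survival.loc[out.survival["cow_id"].isin(keep)].reset_index(drop=True)
    report.n_retained_cows = len(keep)
    report.validate()
    return out, report


def estimate_horizons(
    intervals=None, t1: int | None = None, t2: int | None = None
) -> tuple[int, int]:
    """Prediction horizons: the mean calving interval (and twice it).

    ``intervals`` is an iterable of observed first-to-second calving
    intervals in days; a configured ``t1`` (optionally with ``t2``)
    overrides it and is returned verbatim.
    """
    if t1 is not None:
        return int(t1), int(t2 if t2 is not None else 2 * t1)
    if intervals is None:
        raise ValueError("need observed calving intervals or configured horizons")
    intervals = np.asarray(list(intervals), dtype=float)
    if intervals.size == 0:
        raise ValueError("no calving intervals available")
    t1 = int(round(float(np.mean(intervals))))
    return t1, 2 * t1


def preprocess(
    dataset: HerdDataset,
) -> tuple[HerdDataset, CleaningReport, HerdQuartiles]:
    """Full cleaning pipeline; returns the modelling dataset, the audit
    report, and the herd statistics of the retained cows.

    AFC quartiles for category coding are computed on the post-filter herd.
    """
    report = CleaningReport(n_input_cows=dataset.n_cows)
    raw_stats = compute_herd_stats(dataset)
    cleaned, report = remove_outliers(dataset, raw_stats, report)
    cleaned.survival = _attach_survival(cleaned)
    filtered, report = apply_cow_filters(cleaned, report)
    quart = compute_herd_stats(filtered)
    filtered.cows = filtered.cows.assign(
        afc_cat=[categorize_afc(a, quart) for a in filtered.cows["afc_days"]]
    )
    logger.info(
        "preprocessing: %d -> %d cows (T<50: %d, completeness: %d); %d outlier days removed",
        report.n_input_cows,
        report.n_retained_cows,
        len(report.cows_removed_t50),
        len(report.cows_removed_completeness),
        sum(report.outlier_days_removed.values()),
    )
    return filtered, report, quart
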