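"""Cleaning and labelling rules that turn raw navigation logs into the
weekly modelling table.

Conventions: days are integer indices with day 0 = the Monday of week 0, so
day ``7*w`` is the Monday of week ``w`` (Monday = day-of-week 1).  A
patient-week row at Monday ``7*w`` has target = encounters in the half-open
window ``[7*w, 7*w + 7)`` — an encounter landing exactly on the next Monday
belongs to that next week's window.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

logger = logging.getLogger(__name__)

__all__ = [
    "drop_sparse_features",
    "map_insurance",
    "impute_numeric",
    "average_adi",
    "active_window",
    "build_weekly_rows",
    "label_target",
    "split_by_patient",
    "evaluate_proxies",
    "build_model_table",
    "INSURANCE_KEYWORDS",
]

DAYS_PER_WEEK = 7

# ---------------------------------------------------------------------------
# feature cleaning


def drop_sparse_features(table: pd.DataFrame, null_fraction_threshold: float = 0.8) -> pd.DataFrame:
    """Remove columns whose null fraction is >= the threshold (default 80%)."""
    if not (0.0 < null_fraction_threshold <= 1.0):
        raise ValueError("null_fraction_threshold must be in (0, 1]")
    frac = table.isna().mean()
    keep = [c for c in table.columns if frac[c] < null_fraction_threshold]
    return table[keep]


#: Keyword -> category mapping for raw insurance plan names.  Order matters:
#: the first matching keyword wins, and BC/BS is checked before generic
#: commercial carriers.
INSURANCE_KEYWORDS: tuple[tuple[str, str], ...] = (
    ("MEDICARE", "Medicare"),
    ("MEDICAID", "Medicaid"),
    ("SELF PAY", "Self-pay"),
    ("SELF-PAY", "Self-pay"),
    ("SELFPAY", "Self-pay"),
    ("UNINSURED", "Self-pay"),
    ("BCBS", "Blue Cross/Blue Shield"),
    ("BLUE CROSS", "Blue Cross/Blue Shield"),
    ("BLUE SHIELD", "Blue Cross/Blue Shield"),
    ("AETNA", "Commercial"),
    ("CIGNA", "Commercial"),
    ("UNITED", "Commercial"),
    ("HUMANA", "Commercial"),
    ("PPO", "Commercial"),
    ("HMO", "Commercial"),
)


def map_insurance(raw_plan) -> str:
    """Collapse a raw plan name into one of six categories.

    Missing or unmatched values map to ``"Others"``.
    """
    if raw_plan is None or (isinstance(raw_plan, float) and np.isnan(raw_plan)):
        return "Others"
    text = str(raw_plan).upper()
    if not text.strip():
        return "Others"
    for keyword, category in INSURANCE_KEYWORDS:
        if keyword in text:
            return category
    return "Others"


def map_insurance_series(raw: pd.Series) -> pd.Series:
    return raw.map(map_insurance)


def impute_numeric(
    train_table: pd.DataFrame,
    apply_table: pd.DataFrame,
    columns: Sequence[str] = ("adi", "rucc"),
) -> pd.DataFrame:
    """Replace nulls by the TRAINING-set column mean (no test leakage)."""
    out = apply_table.copy()
    for col in columns:
        train_vals = train_table[col]
        if train_vals.notna().sum() == 0:
            raise ValueError(f"column {col!r}: no non-null training values to impute from")
        out[col] = out[col].fillna(float(train_vals.mean()))
    return out


def average_adi(nine_digit_adis: Iterable[float]):
    """Mean ADI over the nine-digit zips in a five-digit zip; None if empty."""
    vals = [v for v in nine_digit_adis if v is not None and not np.isnan(v)]
    if not vals:
        return None
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# activity and weekly rows


def active_window(interactions: pd.DataFrame, tail_days: int = 90) -> pd.DataFrame:
    """Per-patient active window: first interaction to last + ``tail_days``.

    ``interactions`` needs columns ``patient_id`` and ``day``.  Patients with
    no interactions simply do not appear (excluded).
    """
    if len(interactions) == 0:
        raise ValueError("no interactions: no patients can be considered active")
    grouped = interactions.groupby("patient_id")["day"].agg(["min", "max"])
    return pd.DataFrame(
        {
            "patient_id": grouped.index.to_numpy(),
            "start_day": grouped["min"].to_numpy(),
            "end_day": grouped["max"].to_numpy() + tail_days,
        }
    ).reset_index(drop=True)


def build_weekly_rows(windows: pd.DataFrame, n_weeks: int) -> pd.DataFrame:
    """One row per patient per Monday on which the patient is active.

    ``windows`` is the output of :func:`active_window`.  Mondays are days
    ``0, 7, ..., 7*(n_weeks-1)``; a patient is active on a Monday iff it
    falls inside ``[start_day, end_day]``.
    """
    first_week = np.ceil(windows["start_day"].to_numpy() / DAYS_PER_WEEK).astype(int)
    last_week = np.minimum(
        windows["end_day"].to_numpy() // DAYS_PER_WEEK, n_weeks - 1
    ).astype(int)
    counts = np.maximum(last_week - first_week + 1, 0)
    pid = np.repeat(windows["patient_id"].to_numpy(), counts)
    week = np.concatenate(
        [np.arange(f, f + c) for f, c in zip(first_week, counts)]
    ) if counts.sum() else np.array([], dtype=int)
    return pd.DataFrame({"patient_id": pid, "week": week})


def label_target(
    weekly_rows: pd.DataFrame,
    encounter_log: pd.DataFrame,
    max_covered_day: int | None = None,
) -> pd.DataFrame:
    """Attach the next-week encounter count target to each Monday row.

    Target = encounters in ``[7w, 7w+7)``: an encounter on the next Monday
    belongs to the next week.  Rows whose target window runs past
    ``max_covered_day`` (default: the last logged day) are dropped — the
    trailing patient-weeks whose outcome is not yet observable.
    """
    if max_covered_day is None:
        max_covered_day = int(encounter_log["day"].max())
    rows = weekly_rows[weekly_rows["week"] * DAYS_PER_WEEK + 6 <= max_covered_day].copy()
    n_dropped = len(weekly_rows) - len(rows)
    if n_dropped:
        logger.info("label_target: dropped %d trailing rows without full follow-up", n_dropped)

    enc = encounter_log.copy()
    enc["week"] = enc["day"].to_numpy() // DAYS_PER_WEEK
    counts = enc.groupby(["patient_id", "week"]).size().rename("target")
    rows = rows.merge(counts, how="left", left_on=["patient_id", "week"], right_index=True)
    rows["target"] = rows["target"].fillna(0).astype(int)
    return rows


def split_by_patient(patient_ids, train_fraction: float = 0.8, seed: int = 0):
    """Random patient-level split; every patient lands wholly on one side."""
    ids = np.unique(np.asarray(patient_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    train = np.sort(ids[perm[:n_train]])
    test = np.sort(ids[perm[n_train:]])
    return train, test


# ---------------------------------------------------------------------------
# workload proxy evaluation


def _daily_proxy_values(log: pd.DataFrame) -> pd.DataFrame:
    """Per navigator-day values of the four candidate workload proxies."""
    df = log.copy()
    df["day"] = df["day"].astype(int)
    key = ["navigator_id", "day"]

    def sized(sub):
        if len(sub) == 0:
            return pd.Series(
                dtype=float, index=pd.MultiIndex.from_arrays([[], []], names=key)
            )
        return sub.groupby(key).size().astype(float)

    notct = sized(df[df["interaction_kind"] == "note_create"])
    notct2 = sized(df[df["interaction_kind"].isin(["note_create", "note_edit"])])
    enc = df[df["interaction_kind"] == "encounter"]
    # at most one encounter per patient per day
    enct = sized(enc.drop_duplicates(["navigator_id", "day", "patient_id"]))
    if "timestamp_hours" in df.columns:
        span = df.groupby(key)["timestamp_hours"].agg(lambda s: s.max() - s.min())
    else:
        span = pd.Series(dtype=float, index=pd.MultiIndex.from_arrays([[], []], names=key))
    out = pd.DataFrame({"notct": notct, "notct2": notct2, "enct": enct, "dur": span})
    return out.fillna(0.0).reset_index()


def evaluate_proxies(log: pd.DataFrame, panels: pd.DataFrame, days_per_month: int = 30) -> pd.DataFrame:
    """Rank candidate workload proxies by their correlation with panel size.

    ``log`` needs ``patient_id, navigator_id, day, interaction_kind`` (and
    optionally ``timestamp_hours`` for the ``dur`` span proxy); ``panels``
    gives ``navigator_id, month, panel_size``.  For each proxy, the average
    value per day over each navigator-month is paired with that month's
    panel size; the Pearson r per proxy is returned, highest first.  A
    constant series yields NaN (correlation undefined).
    """
    daily = _daily_proxy_values(log)
    daily["month"] = daily["day"] // days_per_month
    if daily["month"].nunique() < 2:
        raise ValueError("need at least 2 months of data to evaluate proxies")
    monthly = daily.groupby(["navigator_id", "month"])[["notct", "notct2", "enct", "dur"]].mean()
    merged = monthly.reset_index().merge(panels, on=["navigator_id", "month"], how="inner")
    if len(merged) < 2:
        raise ValueError("insufficient navigator-months matched with panel sizes")

    records = []
    for metric in ("notct", "notct2", "enct", "dur"):
        x = merged[metric].to_numpy(dtype=float)
        y = merged["panel_size"].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            r = np.nan
        else:
            r = float(_sps.pearsonr(x, y).statistic)
        records.append({"metric_name": metric, "pearson_r": r, "n_navigator_months": len(merged)})
    out = pd.DataFrame(records).sort_values("pearson_r", ascending=False, na_position="last")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# the full modelling table


def build_model_table(dataset) -> pd.DataFrame:
    """Assemble the weekly modelling table for a synthetic cohort.

    One row per active patient per Monday with static features (insurance
    mapped to six categories, ADI/RUCC imputed from *training-set* means),
    date-derived features, utilization trend features, and the next-week
    encounter-count target.  Trailing weeks without a populated target are
    dropped.
    """
    pats = dataset.patients
    windows = pd.DataFrame(
        {
            "patient_id": pats["patient_id"],
            "start_day": pats["enroll_day"],
            "end_day": pats["active_end_day"],
        }
    )
    rows = build_weekly_rows(windows, dataset.config.n_weeks)
    rows = label_target(
        rows, dataset.encounters, max_covered_day=dataset.config.n_weeks * DAYS_PER_WEEK
    )

    statics = pats.copy()
    statics["insurance"] = map_insurance_series(statics["insurance_raw"])
    train_mask = statics["patient_id"].isin(dataset.train_ids)
    statics = impute_numeric(statics[train_mask], statics, columns=("adi", "rucc"))
    keep = [
        "patient_id",
        "specialty_id",
        "enroll_day",
        "last_encounter_day",
        "age",
        "sex",
        "insurance",
        "adi",
        "rucc",
        "cancer_type",
        "days_diag_to_enroll",
    ]
    table = rows.merge(statics[keep], on="patient_id", how="left")

    monday = table["week"].to_numpy() * DAYS_PER_WEEK
    table["weeks_since_enrollment"] = (monday - table["enroll_day"].to_numpy()) // DAYS_PER_WEEK + 1
    table["days_since_diagnosis"] = monday - table["enroll_day"].to_numpy() + table.pop(
        "days_diag_to_enroll"
    ).to_numpy()

    # utilization history: encounter counts over trailing windows ending at the
    # row's Monday (inclusive), plus days since the most recent interaction
    enc = dataset.encounters
    ew = enc.copy()
    ew["week"] = ew["day"].to_numpy() // DAYS_PER_WEEK  # week whose window holds the day
    wk_counts = ew.groupby(["patient_id", "week"]).size().rename("cnt").reset_index()

    def trailing(n_weeks_back: int) -> np.ndarray:
        parts = []
        for lag in range(1, n_weeks_back + 1):
            shifted = wk_counts.copy()
            shifted["week"] = shifted["week"] + lag
            parts.append(shifted)
        allp = pd.concat(parts).groupby(["patient_id", "week"])["cnt"].sum()
        return (
            table.merge(
                allp.rename("v"), how="left", left_on=["patient_id", "week"], right_index=True
            )["v"]
            .fillna(0)
            .to_numpy(dtype=int)
        )

    util4 = trailing(4)
    util12 = trailing(12)
    table["util_1wk"] = trailing(1)
    table["util_4wk"] = util4
    table["util_12wk"] = util12
    table["util_trend_4wk"] = util4 - (trailing(8) - util4)

    last_enc_before = _last_interaction_before_monday(table, enc)
    table["days_since_last_interaction"] = monday - last_enc_before

    table["target"] = table["target"].astype(int)
    return table


def _last_interaction_before_monday(table: pd.DataFrame, enc: pd.DataFrame) -> np.ndarray:
    """Day of the most recent encounter on or before each row's Monday."""
    mondays = table["week"].to_numpy() * DAYS_PER_WEEK
    left = pd.DataFrame(
        {"patient_id": table["patient_id"].to_numpy(), "day": mondays}
    ).reset_index()
    right = enc.sort_values("day")[["patient_id", "day"]].rename(columns={"day": "enc_day"})
    merged = pd.merge_asof(
        left.sort_values("day"),
        right,
        left_on="day",
        right_on="enc_day",
        by="patient_id",
        direction="backward",
        allow_exact_matches=False,  # the Monday itself belongs to the target window
    ).sort_values("index")
    return merged["enc_day"].fillna(merged["day"]).to_numpy(dtype=int)
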