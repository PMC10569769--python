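"""Synthetic longitudinal cohort of navigated cancer patients.

The generator emulates the kind of data an oncology patient-navigation
program extracts from its EHR: patients arrive weekly into cancer
specialties, each is navigated through an *episode* of care during which
EHR encounters occur (at most one per patient per day — the ``enct``
workload proxy), and the patient remains *active* until 90 days after the
last encounter.  Per-patient 30-day encounter counts are zero-inflated and
right-skewed: the 90-day tail contributes whole months of zeros, and
gamma-distributed heterogeneity in weekly encounter rates produces a long
right tail.

Default calibration targets the marginal monthly-count profile of a real
navigation program: mean ~0.5 and SD ~1.1 encounters/patient/month, median
0, coefficient of variation ~220%, counts ranging 0-15 (a hard 15-per-30-day
truncation rule is enforced).

Covariates (age, ADI, RUCC, insurance, cancer subtype) are noisy monotone
functions of each patient's latent intensity; ``feature_signal_strength``
dials how informative they are.  At strength 0 the generator switches to a
degenerate memoryless mode (one shared constant rate, no episode structure)
in which no feature — including utilization history — carries information
about the next week's count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpecialtySpec",
    "EncounterModel",
    "CohortConfig",
    "LatentIntensity",
    "CohortDataset",
    "DEFAULT_ROSTER",
    "generate_cohort",
    "sample_weekly_encounters",
    "monthly_workload_stats",
    "describe_monthly_counts",
]

DAYS_PER_WEEK = 7
DAYS_PER_MONTH = 30


@dataclass(frozen=True)
class SpecialtySpec:
    """One cancer specialty: a fixed roster of navigators and an arrival rate."""

    specialty_id: str
    n_navigators: int
    arrival_rate: float  # new patients per week (Poisson mean)

    def __post_init__(self) -> None:
        if self.n_navigators < 2:
            raise ValueError("only specialties with >= 2 navigators are in scope")
        if self.arrival_rate <= 0:
            raise ValueError("arrival_rate must be > 0")


#: Default roster: 13 navigators across five specialties (2x2 + 3x3), with the
#: observed arrival rates of 13.4/week for two-navigator and 20.1/week for
#: three-navigator specialties.
DEFAULT_ROSTER: tuple[SpecialtySpec, ...] = (
    SpecialtySpec("breast", 3, 20.1),
    SpecialtySpec("gastrointestinal", 3, 20.1),
    SpecialtySpec("thoracic", 3, 20.1),
    SpecialtySpec("genitourinary", 2, 13.4),
    SpecialtySpec("hematology", 2, 13.4),
)


@dataclass(frozen=True)
class EncounterModel:
    """Parameters of the zero-inflated encounter-count process.

    ``rate_mean``/``rate_shape`` parametrise the gamma distribution of a
    patient's base weekly encounter rate during the navigation episode;
    ``episode_mean_weeks`` the mean episode length (gamma, shape 2);
    ``phase_boost``/``phase_tau_weeks`` an early-episode intensity boost
    (multiplier ``1 + boost * exp(-t/tau)``); ``monthly_cap`` the hard
    truncation of encounters per consecutive 30-day window.  Defaults were
    calibrated once so that 30-day aggregates reproduce the target monthly
    moments (see module docstring) and are not meant to be tuned per run.
    """

    episode_mean_weeks: float = 10.0
    engaged_fraction: float = 0.09
    rate_shape: float = 2.0
    rate_mean: float = 0.5
    low_rate: float = 0.012
    rate_cap: float = 2.5
    phase_boost: float = 1.5
    phase_tau_weeks: float = 4.0
    monthly_cap: int = 15
    max_episode_weeks: float = 52.0
    cadence_shape: float = 20.0


@dataclass(frozen=True)
class CohortConfig:
    n_weeks: int = 150
    specialties: tuple[SpecialtySpec, ...] = DEFAULT_ROSTER
    active_tail_days: int = 90
    encounter_model: EncounterModel = field(default_factory=EncounterModel)
    feature_signal_strength: float = 1.0
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.specialties) == 0:
            raise ValueError("at least one specialty is required")
        if not (0.0 <= self.feature_signal_strength <= 1.0):
            raise ValueError("feature_signal_strength must be in [0, 1]")
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        object.__setattr__(self, "specialties", tuple(self.specialties))


@dataclass(frozen=True)
class LatentIntensity:
    """A patient's latent workload driver: base weekly rate x phase profile."""

    patient_id: str
    base_rate: float
    phase_profile: tuple[float, ...]  # multiplier per week since enrollment; 0 after episode

    def weekly_rate(self, week: int) -> float:
        if week < 0:
            raise ValueError("week must be >= 0")
        if week >= len(self.phase_profile):
            return 0.0
        return self.base_rate * self.phase_profile[week]


@dataclass
class CohortDataset:
    """Everything the downstream pipeline consumes.

    ``patients`` has one row per patient (statics, enrollment day, active
    window); ``encounters`` one row per realized encounter (patient, day,
    with day 0 = the Monday of week 0); ``arrivals`` the per-specialty weekly
    arrival schedule.  ``latents`` holds the generative ground truth (base
    rates, episode lengths) for validation only — modelling code must not
    read it.
    """

    config: CohortConfig
    patients: pd.DataFrame
    encounters: pd.DataFrame
    arrivals: pd.DataFrame
    latents: pd.DataFrame
    train_ids: np.ndarray
    test_ids: np.ndarray

    @property
    def roster(self) -> dict[str, int]:
        return {s.specialty_id: s.n_navigators for s in self.config.specialties}


# ---------------------------------------------------------------------------
# categorical vocabularies

INSURANCE_CATEGORIES = (
    "Medicare",
    "Medicaid",
    "Self-pay",
    "Commercial",
    "Blue Cross/Blue Shield",
    "Others",
)

#: Raw plan strings emitted per category (what an EHR export looks like).
_RAW_PLANS = {
    "Medicare": ["MEDICARE PART A", "MEDICARE PART B", "MEDICARE ADVANTAGE HMO"],
    "Medicaid": ["MEDICAID IL", "MEDICAID MANAGED CARE"],
    "Self-pay": ["SELF PAY", "SELF-PAY UNINSURED"],
    "Commercial": ["AETNA PPO", "CIGNA OPEN ACCESS", "UNITEDHEALTHCARE CHOICE"],
    "Blue Cross/Blue Shield": ["BCBS OF IL PPO", "BLUE CROSS BLUE SHIELD HMO"],
    "Others": ["TRICARE", "WORKERS COMP", "VA CHAMPVA"],
}

_SUBTYPES = {
    "breast": (("ductal carcinoma", 0.6, 0.0), ("lobular carcinoma", 0.25, 0.3), ("inflammatory breast", 0.15, 1.0)),
    "gastrointestinal": (("colorectal", 0.55, 0.0), ("pancreatic", 0.2, 1.0), ("gastric", 0.25, 0.5)),
    "thoracic": (("nsclc", 0.6, 0.2), ("sclc", 0.2, 1.0), ("mesothelioma", 0.2, 0.8)),
    "genitourinary": (("prostate", 0.6, 0.0), ("bladder", 0.25, 0.5), ("renal", 0.15, 0.6)),
    "hematology": (("lymphoma", 0.45, 0.4), ("leukemia", 0.3, 1.0), ("myeloma", 0.25, 0.6)),
}
_DEFAULT_SUBTYPES = (("type_a", 0.5, 0.0), ("type_b", 0.3, 0.5), ("type_c", 0.2, 1.0))

_FEMALE_FRACTION = {"breast": 0.99, "gynecologic": 1.0}


# ---------------------------------------------------------------------------
# encounter sampling


def _phase_multiplier(weeks_since_enroll, model: EncounterModel):
    t = np.asarray(weeks_since_enroll, dtype=float)
    return 1.0 + model.phase_boost * np.exp(-t / model.phase_tau_weeks)


def sample_weekly_encounters(
    intensity: LatentIntensity,
    week: int,
    rng: np.random.Generator,
    cadence_shape: float = 8.0,
) -> int:
    """Draw one week's encounter count for a patient (at most one per day).

    Encounters follow the scheduled-cadence renewal process: gamma
    inter-visit gaps with mean ``7 / weekly_rate`` days, rounded to whole
    days with a 1-day minimum, counted over a 7-day window — so the weekly
    count is bounded by 7.  The 15-per-30-day truncation rule is applied at
    the cohort level, not here.
    """
    rate = intensity.weekly_rate(week)
    if rate <= 0:
        return 0
    mean_gap = DAYS_PER_WEEK / rate
    t = 0.0
    count = 0
    while True:
        t += max(1.0, round(rng.gamma(cadence_shape, mean_gap / cadence_shape)))
        if t >= DAYS_PER_WEEK:
            return count
        count += 1


def _draw_latents(n: int, model: EncounterModel, rng: np.random.Generator):
    """Latent intensity drivers: standard-normal z mapped to a base weekly rate.

    The rate distribution is zero-inflated gamma: the top ``engaged_fraction``
    of the latent driver z corresponds to patients in an engaged navigation
    phase (regular visits at a gamma-distributed weekly rate); the rest need
    little beyond the intake contact (``low_rate``).  Because engagement is a
    deterministic function of z, intake covariates carry signal about it.
    """
    z = rng.standard_normal(n)
    u = stats.norm.cdf(z)
    f = model.engaged_fraction
    base = np.full(n, model.low_rate)
    engaged = u > 1.0 - f
    v = (u[engaged] - (1.0 - f)) / f  # uniform within the engaged stratum
    lam = stats.gamma.ppf(v, a=model.rate_shape, scale=model.rate_mean / model.rate_shape)
    base[engaged] = np.minimum(lam, model.rate_cap)
    episode_weeks = np.clip(
        rng.gamma(2.0, model.episode_mean_weeks / 2.0, size=n), 1.0, model.max_episode_weeks
    )
    return z, base, episode_weeks


def _simulate_encounters(
    enroll_day: np.ndarray,
    base_rate: np.ndarray,
    episode_days: np.ndarray,
    model: EncounterModel,
    rng: np.random.Generator,
):
    """Scheduled-cadence encounter draws for all patients, vectorized.

    Navigation contact follows a visit schedule rather than a memoryless
    stream: after each encounter the gap to the next one is gamma-distributed
    with mean ``7 / weekly_rate`` days (shape ``cadence_shape``; larger =
    more regular), rounded to whole days with a 1-day minimum — so at most
    one encounter per patient per day by construction.  The enrollment day
    always carries an encounter (the intake contact); encounters stop at the
    episode end; within each consecutive 30-day window from enrollment,
    encounters beyond ``monthly_cap`` are dropped.  Returns (patient_index,
    day) pairs and each patient's last encounter day.
    """
    n = len(enroll_day)
    t = np.zeros(n)  # days since enrollment of the most recent encounter
    alive = np.arange(n)
    ev_patient: list[np.ndarray] = [np.arange(n)]
    ev_t: list[np.ndarray] = [np.zeros(n, dtype=int)]
    kappa = model.cadence_shape
    while alive.size:
        rate = base_rate[alive] * _phase_multiplier(t[alive] / DAYS_PER_WEEK, model)
        rate = np.clip(rate, 1e-9, None)
        mean_gap = DAYS_PER_WEEK / rate
        gap = np.maximum(np.round(rng.gamma(kappa, mean_gap / kappa)), 1.0)
        t[alive] = t[alive] + gap
        keep = t[alive] < episode_days[alive]
        alive = alive[keep]
        if alive.size:
            ev_patient.append(alive.copy())
            ev_t.append(t[alive].astype(int))

    idx_patient = np.concatenate(ev_patient)
    idx_t = np.concatenate(ev_t)
    order = np.lexsort((idx_t, idx_patient))
    idx_patient, idx_t = idx_patient[order], idx_t[order]

    # 15-per-30-day truncation rule
    window = idx_t // DAYS_PER_MONTH
    key = idx_patient * 10_000 + window  # episode <= 52 weeks -> window < 13
    start = np.r_[True, key[1:] != key[:-1]]
    pos = np.arange(len(key)) - np.maximum.accumulate(np.where(start, np.arange(len(key)), 0))
    keep = pos < model.monthly_cap
    idx_patient, idx_t = idx_patient[keep], idx_t[keep]

    last_t = np.zeros(n, dtype=int)
    np.maximum.at(last_t, idx_patient, idx_t)
    days = enroll_day[idx_patient] + idx_t
    return idx_patient, days, enroll_day + last_t


def _simulate_memoryless(
    enroll_day: np.ndarray,
    rate: float,
    tail_days: int,
    horizon_day: int,
    rng: np.random.Generator,
):
    """Signal-free mode: constant shared rate, activity self-terminated by a
    ``tail_days`` encounter gap.  Conditional on being active, the future count
    is independent of all history (memorylessness)."""
    p_day = 1.0 - math.exp(-rate / DAYS_PER_WEEK)
    idx_patient: list[int] = []
    days: list[int] = []
    last_days = np.zeros(len(enroll_day), dtype=int)
    for i, e0 in enumerate(enroll_day):
        day = int(e0)
        last = day
        idx_patient.append(i)
        days.append(day)
        while True:
            gap_draws = rng.random(tail_days) < p_day
            if not gap_draws.any():
                break
            day = last + 1 + int(gap_draws.argmax())
            if day > horizon_day + tail_days:
                break
            idx_patient.append(i)
            days.append(day)
            last = day
        last_days[i] = last
    return np.asarray(idx_patient), np.asarray(days), last_days


# ---------------------------------------------------------------------------
# covariates


def _correlated(z: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    return rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(len(z))


def _draw_covariates(
    z: np.ndarray, specialty: str, signal: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Statics as noisy monotone functions of the latent intensity driver.

    ``signal`` scales every feature's loading on z; at 0 all covariates are
    independent of the workload process.
    """
    n = len(z)
    zs = signal * z  # effective latent exposure; noise fills the rest

    w_adi = _correlated(zs, 0.80 * signal if signal > 0 else 0.0, rng) if signal > 0 else rng.standard_normal(n)
    adi = np.clip(np.round(52 + 24 * w_adi), 1, 100)
    w_rucc = _correlated(zs, 0.45 * signal, rng) if signal > 0 else rng.standard_normal(n)
    rucc = np.clip(np.round(3.3 + 2.1 * w_rucc), 1, 9)
    w_age = _correlated(zs, 0.30 * signal, rng) if signal > 0 else rng.standard_normal(n)
    age = np.clip(np.round(63 + 13 * w_age), 25, 94)

    female_frac = _FEMALE_FRACTION.get(specialty, 0.5)
    sex = np.where(rng.random(n) < female_frac, "F", "M")

    subtypes = _SUBTYPES.get(specialty, _DEFAULT_SUBTYPES)
    logits = np.log([p for _, p, _ in subtypes])[None, :] + 1.2 * zs[:, None] * np.array(
        [sev for _, _, sev in subtypes]
    )[None, :]
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    pick = (rng.random(n)[:, None] > cum).sum(axis=1)
    cancer_type = np.array([name for name, _, _ in subtypes])[pick]

    base_ins = np.array([0.36, 0.12, 0.04, 0.24, 0.18, 0.06])
    tilt = np.array([0.0, 0.5, 0.3, -0.2, -0.2, 0.0])  # Medicaid/self-pay lean high-need
    ins_logits = np.log(base_ins)[None, :] + 0.6 * zs[:, None] * tilt[None, :]
    ip = np.exp(ins_logits - ins_logits.max(axis=1, keepdims=True))
    ip /= ip.sum(axis=1, keepdims=True)
    ins_pick = (rng.random(n)[:, None] > np.cumsum(ip, axis=1)).sum(axis=1)
    ins_cat = np.array(INSURANCE_CATEGORIES)[ins_pick]
    raw_plan = np.array(
        [_RAW_PLANS[c][rng.integers(len(_RAW_PLANS[c]))] for c in ins_cat], dtype=object
    )

    # realistic missingness, to be handled by preprocessing
    adi = adi.astype(float)
    rucc = rucc.astype(float)
    adi[rng.random(n) < 0.05] = np.nan
    rucc[rng.random(n) < 0.03] = np.nan
    raw_plan[rng.random(n) < 0.02] = None

    days_diag_to_enroll = np.round(rng.exponential(21, size=n)).astype(int)

    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "insurance_raw": raw_plan,
            "adi": adi,
            "rucc": rucc,
            "cancer_type": cancer_type,
            "days_diag_to_enroll": days_diag_to_enroll,
        }
    )


# ---------------------------------------------------------------------------
# main generator


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Generate the full longitudinal cohort. Deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    model = config.encounter_model
    signal = config.feature_signal_strength
    horizon_day = config.n_weeks * DAYS_PER_WEEK

    arrivals_rows = []
    patient_frames = []
    latent_frames = []
    enc_frames = []
    pid_counter = 0

    for spec in config.specialties:
        counts = rng.poisson(spec.arrival_rate, size=config.n_weeks)
        arrivals_rows.append(
            pd.DataFrame(
                {
                    "specialty_id": spec.specialty_id,
                    "week": np.arange(config.n_weeks),
                    "n_new": counts,
                }
            )
        )
        n_pat = int(counts.sum())
        if n_pat == 0:
            continue
        arrival_week = np.repeat(np.arange(config.n_weeks), counts)
        pids = np.array([f"P{pid_counter + i:06d}" for i in range(n_pat)])
        pid_counter += n_pat
        # enrollment strictly after the arrival-week Monday so the intake
        # encounter falls in that Monday's (Mon, Mon+7] target window
        enroll_day = arrival_week * DAYS_PER_WEEK + rng.integers(1, 8, size=n_pat)

        if signal == 0.0:
            z = np.zeros(n_pat)
            base = np.full(n_pat, model.rate_mean)
            episode_weeks = np.full(n_pat, np.inf)
            idx_p, days, last_day = _simulate_memoryless(
                enroll_day, model.rate_mean, config.active_tail_days, horizon_day, rng
            )
        else:
            z, base, episode_weeks = _draw_latents(n_pat, model, rng)
            episode_days = np.maximum((episode_weeks * DAYS_PER_WEEK).astype(int), 1)
            idx_p, days, last_day = _simulate_encounters(
                enroll_day, base, episode_days, model, rng
            )

        cov = _draw_covariates(z, spec.specialty_id, signal, rng)
        pat = pd.DataFrame(
            {
                "patient_id": pids,
                "specialty_id": spec.specialty_id,
                "arrival_week": arrival_week,
                "enroll_day": enroll_day,
                "last_encounter_day": last_day,
                "active_end_day": last_day + config.active_tail_days,
            }
        )
        patient_frames.append(pd.concat([pat, cov], axis=1))
        latent_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pids,
                    "z": z,
                    "base_rate": base,
                    "episode_weeks": episode_weeks,
                }
            )
        )
        enc_frames.append(pd.DataFrame({"patient_id": pids[idx_p], "day": days}))

    patients = pd.concat(patient_frames, ignore_index=True)
    encounters = (
        pd.concat(enc_frames, ignore_index=True)
        .sort_values(["patient_id", "day"], kind="stable")
        .reset_index(drop=True)
    )
    arrivals = pd.concat(arrivals_rows, ignore_index=True)
    latents = pd.concat(latent_frames, ignore_index=True)

    # patient-level 80/20 split (local import avoids a cycle at module load)
    from .preprocessing import split_by_patient

    train_ids, test_ids = split_by_patient(
        patients["patient_id"].to_numpy(), train_fraction=config.train_fraction, seed=config.seed
    )
    return CohortDataset(
        config=config,
        patients=patients,
        encounters=encounters,
        arrivals=arrivals,
        latents=latents,
        train_ids=train_ids,
        test_ids=test_ids,
    )


# ---------------------------------------------------------------------------
# monthly workload statistics


def describe_monthly_counts(counts: Sequence[int]) -> dict:
    """Summary statistics of per-patient-month encounter counts.

    ``skew`` is Pearson's median skewness ``3*(mean - median)/sd`` — the
    statistic this package reports for the monthly workload profile;
    ``moment_skew`` is the adjusted Fisher-Pearson third-moment skewness,
    reported alongside for completeness.  With zero SD both are 0 by
    convention; a zero mean makes the CV undefined and raises.
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ValueError("no patient-months to summarise")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    median = float(np.median(arr))
    if sd == 0.0:
        skew = 0.0
        moment_skew = 0.0
    else:
        skew = 3.0 * (mean - median) / sd
        moment_skew = float(stats.skew(arr, bias=False))
    if mean == 0.0:
        raise ValueError("mean monthly count is 0: coefficient of variation undefined")
    return {
        "n_months": int(arr.size),
        "mean": mean,
        "sd": sd,
        "median": median,
        "cv_percent": 100.0 * sd / mean,
        "skew": skew,
        "moment_skew": moment_skew,
        "max": float(arr.max()),
    }


def monthly_encounter_counts(dataset: CohortDataset) -> np.ndarray:
    """Per-patient encounter counts over consecutive 30-day active windows.

    Windows run from each patient's first encounter; only windows fully
    inside the active period (through 90 days after the last encounter)
    are kept, so trailing partial windows are dropped.
    """
    pats = dataset.patients
    n_win = ((pats["active_end_day"] - pats["enroll_day"] + 1) // DAYS_PER_MONTH).to_numpy()
    if n_win.sum() == 0:
        raise ValueError("no complete patient-months in dataset")
    offsets = np.concatenate([[0], np.cumsum(n_win)])
    counts = np.zeros(int(n_win.sum()), dtype=int)

    enroll = pats.set_index("patient_id")["enroll_day"]
    win_index = pats.set_index("patient_id").assign(_row=np.arange(len(pats)))["_row"]

    enc = dataset.encounters
    row = win_index.loc[enc["patient_id"]].to_numpy()
    t = enc["day"].to_numpy() - enroll.loc[enc["patient_id"]].to_numpy()
    w = t // DAYS_PER_MONTH
    ok = w < n_win[row]
    np.add.at(counts, offsets[row[ok]] + w[ok], 1)
    return counts


def monthly_workload_stats(dataset: CohortDataset) -> dict:
    """Monthly workload profile of a cohort (see :func:`describe_monthly_counts`)."""
    return describe_monthly_counts(monthly_encounter_counts(dataset))
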