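"""Synthetic trial data with known ground truth.

Generates every input the analysis pipeline consumes — a per-patient
participant-flow ledger, a two-arm cohort table, and event-level
activity-monitor traces with participant log sheets — from explicit
specifications, plus "paper presets" that encode the pilot trial's printed
participant-flow counts and cohort mix.

The activity generator works on a one-minute lattice: each day is a sequence
of whole-minute bouts (sleep, sitting, standing, stepping at an integer
per-minute cadence), so a generated day tiles 24 h exactly and the true
number of brisk minutes per day is known exactly — the cadence of a stepping
bout never crosses the 100 steps/min threshold within a bout.  Night-time
bed exits are short (< 200 step) stepping bouts inside the sleep block,
which exercises the 200-step waking rule downstream.

Each participant gets an independent RNG stream derived from the master seed
and the participant index, so adding participants never perturbs existing
traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .accelerometry import ActivityEventSeries

__all__ = [
    "LedgerSpec",
    "CohortSpec",
    "AccelSpec",
    "SimulatedWeek",
    "paper_ledger_spec",
    "paper_ledger",
    "generate_ledger",
    "paper_cohort_spec",
    "generate_cohort",
    "paper_accel_specs",
    "generate_activity_series",
    "simulate_activity_study",
    "write_ledger_csv",
    "write_cohort_csv",
    "write_log_sheet_csv",
]

MINUTES_PER_DAY = 1440
_BASE_DATE = pd.Timestamp("2023-03-06")  # arbitrary Monday anchoring traces


# ---------------------------------------------------------------------------
# participant-flow ledger


@dataclass(frozen=True)
class LedgerSpec:
    """Aggregate participant-flow counts to realise as a per-patient ledger."""

    n_screened: int
    n_excluded_records: int
    n_sent_letter: int
    n_willing: int
    n_sent_pis: int
    n_consented: int
    n_randomised_intervention: int
    n_randomised_control: int
    n_followup_any: int
    n_first_call: int
    n_second_call: int
    n_app_downloaded: int
    n_app_question_asked: int
    n_app_still_using: int
    n_consent_linkage: int = 0
    n_online_help: int = 0
    n_withdrew_post_randomisation: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for k, v in asdict(self).items() if k.startswith("n_")):
            raise ValueError("all counts must be non-negative")
        n_rand = self.n_randomised_intervention + self.n_randomised_control
        chain = [
            ("n_screened", self.n_screened),
            ("n_sent_letter", self.n_sent_letter),
            ("n_willing", self.n_willing),
            ("n_sent_pis", self.n_sent_pis),
            ("n_consented", self.n_consented),
            ("n_randomised (total)", n_rand),
        ]
        for (up_name, up), (dn_name, dn) in zip(chain, chain[1:]):
            if dn > up:
                raise ValueError(
                    f"funnel monotonicity violated: {dn_name} ({dn}) > {up_name} ({up})"
                )
        if self.n_sent_letter + self.n_excluded_records > self.n_screened:
            raise ValueError("sent_letter + excluded_records exceeds screened")
        ni = self.n_randomised_intervention
        for name, v, cap_name, cap in [
            ("n_followup_any", self.n_followup_any, "randomised", n_rand),
            ("n_first_call", self.n_first_call, "intervention arm", ni),
            ("n_second_call", self.n_second_call, "first calls", self.n_first_call),
            ("n_app_downloaded", self.n_app_downloaded, "intervention arm", ni),
            ("n_app_question_asked", self.n_app_question_asked, "app downloads", self.n_app_downloaded),
            ("n_app_still_using", self.n_app_still_using, "asked app question", self.n_app_question_asked),
            ("n_consent_linkage", self.n_consent_linkage, "randomised", n_rand),
            ("n_online_help", self.n_online_help, "randomised", n_rand),
            ("n_withdrew_post_randomisation", self.n_withdrew_post_randomisation, "randomised", n_rand),
        ]:
            if v > cap:
                raise ValueError(f"{name} ({v}) exceeds {cap_name} ({cap})")


def paper_ledger_spec() -> LedgerSpec:
    """The pilot trial's published participant-flow counts as a spec."""
    return LedgerSpec(
        n_screened=1037,
        n_excluded_records=460,
        n_sent_letter=577,
        n_willing=369,
        n_sent_pis=148,
        n_consented=93,
        n_randomised_intervention=44,
        n_randomised_control=46,
        n_followup_any=87,
        n_first_call=43,
        n_second_call=39,
        n_app_downloaded=42,
        n_app_question_asked=39,
        n_app_still_using=33,
        n_consent_linkage=90,
        n_online_help=4,
        n_withdrew_post_randomisation=0,
        seed=20230306,
    )


def _pick(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    return rng.choice(pool, size=k, replace=False)


def generate_ledger(spec: LedgerSpec) -> pd.DataFrame:
    """Realise a per-patient ledger whose aggregates exactly equal the spec.

    Which specific patient carries each flag is assigned by seeded sampling
    (deterministic given ``spec.seed``); only the aggregate counts are
    contractual.  Flags are nested along the funnel, so every generated
    ledger satisfies funnel monotonicity by construction.
    """
    n = spec.n_screened
    rng = np.random.default_rng(spec.seed)
    ledger = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:04d}" for i in range(n)],
            "screened": True,
        }
    )
    for col in (
        "sent_letter", "willing", "sent_pis", "consented", "randomised",
        "followup_any", "first_call", "second_call", "app_downloaded",
        "app_question_asked", "app_still_using", "consent_linkage",
        "online_help", "withdrew_post_randomisation",
    ):
        ledger[col] = False
    ledger["arm"] = pd.Series([pd.NA] * n, dtype="string")

    idx = np.arange(n)
    letter = np.sort(_pick(rng, idx, spec.n_sent_letter))
    willing = np.sort(_pick(rng, letter, spec.n_willing))
    pis = np.sort(_pick(rng, willing, spec.n_sent_pis))
    consented = np.sort(_pick(rng, pis, spec.n_consented))
    n_rand = spec.n_randomised_intervention + spec.n_randomised_control
    randomised = np.sort(_pick(rng, consented, n_rand))
    interv = np.sort(_pick(rng, randomised, spec.n_randomised_intervention))
    control = np.setdiff1d(randomised, interv)

    ledger.loc[letter, "sent_letter"] = True
    ledger.loc[willing, "willing"] = True
    ledger.loc[pis, "sent_pis"] = True
    ledger.loc[consented, "consented"] = True
    ledger.loc[randomised, "randomised"] = True
    ledger.loc[interv, "arm"] = "intervention"
    ledger.loc[control, "arm"] = "control"

    for col, k, pool in (
        ("followup_any", spec.n_followup_any, randomised),
        ("consent_linkage", spec.n_consent_linkage, randomised),
        ("online_help", spec.n_online_help, randomised),
        ("withdrew_post_randomisation", spec.n_withdrew_post_randomisation, randomised),
        ("first_call", spec.n_first_call, interv),
        ("app_downloaded", spec.n_app_downloaded, interv),
    ):
        ledger.loc[np.sort(_pick(rng, pool, k)), col] = True
    second = _pick(rng, np.flatnonzero(ledger["first_call"]), spec.n_second_call)
    ledger.loc[np.sort(second), "second_call"] = True
    asked = _pick(rng, np.flatnonzero(ledger["app_downloaded"]), spec.n_app_question_asked)
    ledger.loc[np.sort(asked), "app_question_asked"] = True
    using = _pick(rng, np.flatnonzero(ledger["app_question_asked"]), spec.n_app_still_using)
    ledger.loc[np.sort(using), "app_still_using"] = True
    return ledger


def paper_ledger() -> pd.DataFrame:
    """Per-patient ledger reproducing the pilot trial's published counts."""
    return generate_ledger(paper_ledger_spec())


# ---------------------------------------------------------------------------
# cohort table


@dataclass(frozen=True)
class CohortSpec:
    """Distributional targets for a two-arm cohort table.

    Mixes are categorical probabilities and must each sum to one; baseline
    brisk walking is drawn lognormal matched to the given median and IQR.
    """

    n_per_arm: tuple[int, int] = (44, 46)  # (intervention, control)
    age_mean: float = 63.0
    age_sd: float = 11.0
    sex_mix: tuple[float, float] = (0.52, 0.48)  # (male, female)
    cancer_type_mix: tuple[float, float, float] = (0.40, 0.40, 0.20)
    stage_mix: tuple[float, ...] = (0.32, 0.33, 0.27, 0.08)
    eq5d_mean: float = 0.80
    eq5d_sd: float = 0.12
    baseline_brisk_median: float = 181.0
    baseline_brisk_iqr: tuple[float, float] = (116.0, 363.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_arm) <= 0:
            raise ValueError("n_per_arm must be positive")
        for name, mix in (
            ("sex_mix", self.sex_mix),
            ("cancer_type_mix", self.cancer_type_mix),
            ("stage_mix", self.stage_mix),
        ):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(mix)}")
            if min(mix) < 0:
                raise ValueError(f"{name} has negative entries")
        q1, q3 = self.baseline_brisk_iqr
        if not (0 < q1 <= self.baseline_brisk_median <= q3):
            raise ValueError("IQR must bracket the median and be positive")


def paper_cohort_spec() -> CohortSpec:
    """Cohort mix matching the pilot's baseline table (44/46 per arm,
    mean age 63, 40/40/20 breast/prostate/colorectal, stages 1-4)."""
    return CohortSpec(seed=20230306)


_SEXES = np.array(["male", "female"])
_CANCERS = np.array(["breast", "prostate", "colorectal"])


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per participant; empirical moments converge to the spec."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    q1, q3 = spec.baseline_brisk_iqr
    sigma = np.log(q3 / q1) / (2 * 0.6744897501960817)
    mu = np.log(spec.baseline_brisk_median)
    for arm, n in zip(("intervention", "control"), spec.n_per_arm):
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": [f"{arm[0].upper()}{i + 1:04d}" for i in range(n)],
                    "arm": arm,
                    "age": np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18, 100),
                    "sex": rng.choice(_SEXES, n, p=spec.sex_mix),
                    "cancer_type": rng.choice(_CANCERS, n, p=spec.cancer_type_mix),
                    "stage": rng.choice(
                        np.arange(1, len(spec.stage_mix) + 1), n, p=spec.stage_mix
                    ),
                    "eq5d": np.clip(rng.normal(spec.eq5d_mean, spec.eq5d_sd, n), 0.0, 1.0),
                    "baseline_brisk_min_week": rng.lognormal(mu, sigma, n),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# activity traces


@dataclass(frozen=True)
class AccelSpec:
    """Generative settings for one arm's 7-day, 24-h-wear activity traces.

    Cadences are integer steps/min per bout, truncated so brisk bouts stay
    strictly above and slow bouts strictly below the 100 steps/min
    threshold; daily totals tile 24 h exactly on wear-complete days.
    """

    n_days: int = 7
    sleep_start: str = "23:00"
    sleep_end: str = "07:00"
    bed_exit_prob: float = 0.3
    brisk_minutes_mean: float = 27.0
    brisk_minutes_sd: float = 12.0
    slow_minutes_mean: float = 55.0
    slow_minutes_sd: float = 15.0
    brisk_cadence_mean: float = 115.0
    brisk_cadence_sd: float = 8.0
    slow_cadence_mean: float = 75.0
    slow_cadence_sd: float = 12.0
    sitting_hours_mean: float = 10.0
    nonwear_day_prob: float = 0.0

    def __post_init__(self) -> None:
        if not (self.brisk_cadence_mean > 100 > self.slow_cadence_mean):
            raise ValueError("brisk cadence mean must exceed 100; slow must be below")
        if not (0 <= self.bed_exit_prob <= 1 and 0 <= self.nonwear_day_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")


def paper_accel_specs() -> dict[str, AccelSpec]:
    """Arm-level generative presets emulating the pilot's follow-up
    brisk-walking distributions (intervention ~39, control ~27 min/day,
    i.e. weekly medians in the high-200s vs high-100s of minutes)."""
    return {
        "intervention": AccelSpec(brisk_minutes_mean=39.0, brisk_minutes_sd=18.0),
        "control": AccelSpec(brisk_minutes_mean=27.0, brisk_minutes_sd=14.0),
    }


@dataclass
class SimulatedWeek:
    """A generated participant-week: trace, log sheet and hidden truth.

    ``truth`` has one row per day (brisk/slow minutes actually placed,
    posture hours, wear_complete); ``awake_truth`` is the per-minute wake
    ground truth (n_days x 1440) for label-agreement checks.
    """

    series: ActivityEventSeries
    log_sheet: pd.DataFrame
    truth: pd.DataFrame
    awake_truth: np.ndarray


def _clock_minutes(hhmm: str) -> int:
    h, m = hhmm.split(":")
    return int(h) * 60 + int(m)


def _participant_rng(master_seed: int, participant_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((master_seed, participant_index)))


def _truncnorm_int(rng, mean, sd, lo, hi) -> int:
    if sd == 0:
        return int(round(np.clip(mean, lo, hi)))
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return int(round(v))
    return int(round(np.clip(mean, lo, hi)))


def _chunk(rng, total: int, lo: int = 5, hi: int = 15) -> list[int]:
    """Split ``total`` minutes into bout lengths between lo and hi."""
    out = []
    left = total
    while left > 0:
        c = min(left, int(rng.integers(lo, hi + 1)))
        out.append(c)
        left -= c
    return out


# minute-class codes
_SLEEP, _SIT, _STAND, _STEP_BRISK, _STEP_SLOW, _BED_EXIT = range(6)


def _build_day(rng, spec: AccelSpec):
    """One day's minute classes + per-minute cadence, plus truth scalars."""
    cls = np.full(MINUTES_PER_DAY, _SIT, dtype=np.int8)
    cad = np.zeros(MINUTES_PER_DAY, dtype=np.int16)

    s0, s1 = _clock_minutes(spec.sleep_start), _clock_minutes(spec.sleep_end)
    night = np.zeros(MINUTES_PER_DAY, dtype=bool)
    if s0 > s1:  # crosses midnight
        night[s0:] = True
        night[:s1] = True
    else:
        night[s0:s1] = True
    cls[night] = _SLEEP

    if rng.random() < spec.bed_exit_prob:
        # keep the exit well inside the sleep block (5-min margin each side)
        night_ok = night.copy()
        for off in range(1, 8):
            night_ok &= np.roll(night, off) & np.roll(night, -off)
        inner = np.flatnonzero(night_ok)
        start = int(rng.choice(inner))
        dur = int(rng.integers(1, 3))
        cadence = int(rng.integers(30, 90))  # <200 steps in total, stays "sleep"
        cls[start : start + dur] = _BED_EXIT
        cad[start : start + dur] = cadence

    wake_idx = np.flatnonzero(~night)
    w = len(wake_idx)
    brisk = _truncnorm_int(rng, spec.brisk_minutes_mean, spec.brisk_minutes_sd, 0, int(0.4 * w))
    slow = _truncnorm_int(rng, spec.slow_minutes_mean, spec.slow_minutes_sd, 0, int(0.4 * w))

    bouts = [(_STEP_BRISK, c) for c in _chunk(rng, brisk)] + [
        (_STEP_SLOW, c) for c in _chunk(rng, slow)
    ]
    rng.shuffle(bouts)

    filler = w - brisk - slow
    sit_target = min(int(round(rng.normal(spec.sitting_hours_mean * 60, 20))), filler - 30)
    sit_target = max(sit_target, 0)

    # distribute stepping bouts over wake, then fill gaps with alternating
    # sitting/standing chunks; start and end of wake are standing so the
    # overnight sedentary run is bounded exactly at the bed/rise times
    n_gaps = len(bouts) + 1
    gap_sizes = np.full(n_gaps, filler // n_gaps)
    gap_sizes[: filler % n_gaps] += 1
    final_stand = int(min(10, gap_sizes[-1]))  # wake ends standing too
    gap_sizes[-1] -= final_stand
    sit_left = sit_target
    sequence: list[tuple[int, int]] = []  # (class or bout marker, minutes/cadence)
    for g in range(n_gaps):
        gap = int(gap_sizes[g])
        # alternate stand/sit within the gap, standing first
        while gap > 0:
            stand = min(gap, int(rng.integers(5, 21)))
            sequence.append((_STAND, stand))
            gap -= stand
            if gap <= 0:
                break
            sit = min(gap, int(rng.integers(20, 61)), sit_left if sit_left > 0 else gap)
            if sit <= 0:
                continue
            sequence.append((_SIT, sit))
            gap -= sit
            sit_left -= sit
        if g < len(bouts):
            kind, dur = bouts[g]
            if kind == _STEP_BRISK:
                c = _truncnorm_int(rng, spec.brisk_cadence_mean, spec.brisk_cadence_sd, 101, 140)
            else:
                c = _truncnorm_int(rng, spec.slow_cadence_mean, spec.slow_cadence_sd, 30, 99)
            sequence.append((kind, dur * 1000 + c))  # pack dur+cadence
    if final_stand:
        sequence.append((_STAND, final_stand))

    pos = 0
    for kind, payload in sequence:
        if kind in (_STEP_BRISK, _STEP_SLOW):
            dur, c = divmod(payload, 1000)
        else:
            dur, c = payload, 0
        span = wake_idx[pos : pos + dur]
        cls[span] = kind
        if c:
            cad[span] = c
        pos += dur

    truth = {
        "brisk_minutes": float(brisk),
        "slow_minutes": float(slow),
        "sitting_hours": float(np.sum(cls == _SIT)) / 60.0,
        "standing_hours": float(np.sum(cls == _STAND)) / 60.0,
        "sleep_hours": float(np.sum((cls == _SLEEP) | (cls == _BED_EXIT))) / 60.0,
    }
    return cls, cad, night, truth


def _minutes_to_events(day_start: pd.Timestamp, cls: np.ndarray, cad: np.ndarray) -> list[dict]:
    """Merge consecutive same-class/cadence minutes into bouts."""
    class_map = {
        _SLEEP: "sedentary",
        _SIT: "sedentary",
        _STAND: "standing",
        _STEP_BRISK: "stepping",
        _STEP_SLOW: "stepping",
        _BED_EXIT: "stepping",
    }
    events = []
    i = 0
    while i < MINUTES_PER_DAY:
        if cls[i] < 0:  # non-wear minute: no event emitted
            i += 1
            continue
        j = i
        while (
            j + 1 < MINUTES_PER_DAY
            and cls[j + 1] >= 0
            and class_map[cls[j + 1]] == class_map[cls[i]]
            and cad[j + 1] == cad[i]
        ):
            j += 1
        dur = (j - i + 1) * 60.0
        events.append(
            {
                "start": day_start + pd.Timedelta(minutes=i),
                "duration_s": dur,
                "activity_class": class_map[cls[i]],
                "steps": float(cad[i]) * (j - i + 1),
            }
        )
        i = j + 1
    return events


def generate_activity_series(
    participant_id: str,
    spec: AccelSpec,
    master_seed: int = 0,
    participant_index: int = 0,
    start_date: pd.Timestamp = _BASE_DATE,
) -> SimulatedWeek:
    """Generate one participant's week of events, log sheet and ground truth.

    Events tile each wear-complete day exactly (sum of durations = 86 400 s);
    a non-wear day, drawn with ``spec.nonwear_day_prob``, has an afternoon
    gap and is flagged ``wear_complete=False`` in the truth table.  The log
    sheet records the true bed/rise times.
    """
    rng = _participant_rng(master_seed, participant_index)
    all_events: list[dict] = []
    truth_rows = []
    log_rows = []
    awake_truth = np.zeros((spec.n_days, MINUTES_PER_DAY), dtype=bool)

    for d in range(spec.n_days):
        day_start = start_date + pd.Timedelta(days=d)
        cls, cad, night, truth = _build_day(rng, spec)
        awake_truth[d] = ~((cls == _SLEEP) | (cls == _BED_EXIT))
        wear_complete = True
        if rng.random() < spec.nonwear_day_prob:
            # afternoon removal: 13:00-17:00 missing from the record
            cls = cls.copy()
            cls[13 * 60 : 17 * 60] = -1
            wear_complete = False
        all_events.extend(_minutes_to_events(day_start, cls, cad))
        truth_rows.append({"date": day_start, "wear_complete": wear_complete, **truth})
        log_rows.append(
            {
                "participant_id": participant_id,
                "date": day_start.date().isoformat(),
                "wake_time": spec.sleep_end,
                "bed_time": spec.sleep_start,
                "removal_note": "" if wear_complete else "removed during afternoon",
            }
        )

    series = ActivityEventSeries(participant_id, pd.DataFrame(all_events))
    return SimulatedWeek(
        series=series,
        log_sheet=pd.DataFrame(log_rows),
        truth=pd.DataFrame(truth_rows),
        awake_truth=awake_truth,
    )


def simulate_activity_study(
    n_per_arm: dict[str, int],
    arm_specs: dict[str, AccelSpec] | None = None,
    master_seed: int = 0,
) -> dict[str, list[SimulatedWeek]]:
    """Generate traces for a two-arm study; per-arm lists of participant-weeks.

    Participant RNG streams are indexed globally (intervention first), so
    the same master seed always reproduces the same traces.
    """
    arm_specs = paper_accel_specs() if arm_specs is None else arm_specs
    out: dict[str, list[SimulatedWeek]] = {}
    index = 0
    for arm in sorted(n_per_arm):
        spec = arm_specs[arm]
        weeks = []
        for i in range(n_per_arm[arm]):
            pid = f"{arm[0].upper()}{i + 1:04d}"
            weeks.append(
                generate_activity_series(pid, spec, master_seed, participant_index=index)
            )
            index += 1
        out[arm] = weeks
    return out


# ---------------------------------------------------------------------------
# CSV writers (events CSV lives in accelerometry, which owns the dialect)


def write_ledger_csv(ledger: pd.DataFrame, path) -> None:
    ledger.to_csv(path, index=False)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def write_log_sheet_csv(log_sheets: list[pd.DataFrame], path) -> None:
    pd.concat(log_sheets, ignore_index=True).to_csv(path, index=False)
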