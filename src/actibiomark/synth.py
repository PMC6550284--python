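"""Synthetic actigraphy cohort generator.

Real minute-level actigraphy shows circadian periodicity (a ~1440-minute
cycle), near-zero activity during a sleep window, short-range positive
autocorrelation, and non-negative integer counts.  Mood-disorder patients
show lower overall activity and a flattened circadian amplitude.  The
generator produces cohorts with exactly this structure so the full feature
extraction and prediction pipeline can be exercised and calibrated without
any external recording.

Activity model for minute t (minute-of-day m = (t + start offset) mod 1440):

    x_t = round(max(0, g_t * (mu_g + s * 1[t >= T/2] + A_g * cos(2*pi*(m - phi)/1440) + e_t)))

where ``e_t`` is a stationary AR(1) noise process, ``g_t`` is a sleep gate
(1 while awake, ``sleep_activity_rate / mu_g`` inside the sleep window, so
sleep activity averages near the configured low rate), and ``s`` is a
subject-specific level shift applied to the second half of the recording.
Patients scale the mean and amplitude by their group ratios.

MADRS coupling: each patient's post score moves relative to the pre score in
proportion to that patient's standardized first-half/second-half activity
shift, so symptom change is recoverable from the actigraphy itself and the
regression task carries signal independent of the classification task.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.signal import lfilter

from .core import (GROUP_CONTROL, GROUP_PATIENT, VALID_GROUPS,
                   ActigraphySeries, Cohort, SubjectRecord)

#: fixed circadian period, minutes
DAY_MINUTES = 1440


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design being emulated: 23 patients vs 32
    controls, 19,299 minutes (~13.4 days) per subject, with patients at
    ~60% of control activity level and circadian amplitude.
    """

    n_patients: int = 23
    n_controls: int = 32
    n_minutes: int = 19_299
    seed: int = 0
    control_mean: float = 220.0          # counts/min while awake
    patient_mean_ratio: float = 0.6      # patient mean relative to control
    circadian_amplitude: float = 180.0   # counts, control group
    patient_amplitude_ratio: float = 0.6
    acrophase_minutes: float = 900.0     # minute-of-day of activity peak (15:00)
    ar_coefficient: float = 0.6          # AR(1) coefficient of the noise
    noise_sd: float = 80.0               # AR(1) innovation sd, counts
    sleep_window: Tuple[int, int] = (1380, 420)  # 23:00 -> 07:00, wrap-around
    sleep_activity_rate: float = 5.0     # mean counts/min while asleep
    level_shift_sd: float = 30.0         # sd of second-half level shift, counts
    madrs_pre_range: Tuple[float, float] = (18.0, 30.0)
    madrs_change_coupling: float = 4.0   # score units per standardized shift
    madrs_noise_sd: float = 2.0          # score units

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_minutes < 201:
            raise ValueError("n_minutes must be >= 201 (longest lag + 1 must fit)")
        if not (0 < self.patient_mean_ratio <= 1):
            raise ValueError("patient_mean_ratio must be in (0, 1]")
        if not (0 < self.patient_amplitude_ratio <= 1):
            raise ValueError("patient_amplitude_ratio must be in (0, 1]")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.control_mean <= 0 or self.circadian_amplitude < 0:
            raise ValueError("control_mean must be > 0 and amplitude >= 0")
        if self.noise_sd < 0 or self.sleep_activity_rate < 0 or self.level_shift_sd < 0:
            raise ValueError("noise_sd, sleep_activity_rate, level_shift_sd must be >= 0")
        lo, hi = self.madrs_pre_range
        if not lo <= hi:
            raise ValueError("madrs_pre_range must be ordered (low, high)")


def _subject_rng(config: SynthConfig, subject_seed: int, stream: int = 0) -> np.random.Generator:
    # stable hash of (master seed, subject seed, stream) -> independent stream
    return np.random.default_rng(np.random.SeedSequence([config.seed, subject_seed, stream]))


def sleep_mask(n_minutes: int, window: Tuple[int, int]) -> np.ndarray:
    """Boolean mask, True for minutes falling inside the (wrap-around) sleep window."""
    start, end = window
    minute_of_day = np.arange(n_minutes) % DAY_MINUTES
    if start <= end:
        return (minute_of_day >= start) & (minute_of_day < end)
    return (minute_of_day >= start) | (minute_of_day < end)


def _ar1_noise(n: int, coef: float, innovation_sd: float,
               rng: np.random.Generator) -> np.ndarray:
    if innovation_sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, innovation_sd, size=n)
    if coef == 0:
        return eps
    # stationary start so the first minutes are not systematically calmer
    eps[0] = rng.normal(0.0, innovation_sd / np.sqrt(1.0 - coef**2))
    return lfilter([1.0], [1.0, -coef], eps)


def halfwise_level_shift(values: np.ndarray) -> float:
    """Mean activity of the second half minus the first half of a recording.

    This is the within-subject activity shift that MADRS change is coupled
    to; computing it from the final (gated, rounded) series means the change
    score is exactly recoverable from the actigraphy itself.
    """
    values = np.asarray(values, dtype=float)
    half = values.size // 2
    return float(values[half:].mean() - values[:half].mean())


def _simulate_values(config: SynthConfig, group: str,
                     rng: np.random.Generator) -> Tuple[np.ndarray, float]:
    """Simulate one series; returns (values, injected second-half level shift)."""
    n = config.n_minutes
    if group == GROUP_PATIENT:
        mu = config.control_mean * config.patient_mean_ratio
        amp = config.circadian_amplitude * config.patient_amplitude_ratio
    else:
        mu = config.control_mean
        amp = config.circadian_amplitude

    minute_of_day = np.arange(n) % DAY_MINUTES
    template = mu + amp * np.cos(2.0 * np.pi * (minute_of_day - config.acrophase_minutes)
                                 / DAY_MINUTES)

    shift = float(rng.normal(0.0, config.level_shift_sd)) if config.level_shift_sd > 0 else 0.0
    signal = template + _ar1_noise(n, config.ar_coefficient, config.noise_sd, rng)
    signal[n // 2:] += shift

    gate = np.ones(n)
    gate[sleep_mask(n, config.sleep_window)] = config.sleep_activity_rate / mu
    values = np.round(np.maximum(0.0, gate * signal))
    return values, shift


def generate_subject(config: SynthConfig, group: str, subject_seed: int) -> SubjectRecord:
    """Simulate one subject's recording, deterministic in (config.seed, subject_seed).

    Patients receive placeholder MADRS scores (midpoint of the pre range);
    :func:`generate_cohort` overwrites them with the coupled pre/post pair,
    which needs the whole patient group to standardize the activity shift.
    """
    if group not in VALID_GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {VALID_GROUPS}")
    rng = _subject_rng(config, subject_seed)
    values, _ = _simulate_values(config, group, rng)
    series = ActigraphySeries(
        subject_id=f"{'condition' if group == GROUP_PATIENT else 'control'}_{subject_seed + 1}",
        start_time=np.datetime64("2003-05-07T12:00"),
        values=values,
    )
    if group == GROUP_PATIENT:
        mid = 0.5 * (config.madrs_pre_range[0] + config.madrs_pre_range[1])
        return SubjectRecord(series.subject_id, group, series,
                             madrs_pre=mid, madrs_post=mid)
    return SubjectRecord(series.subject_id, group, series)


def generate_cohort(config: SynthConfig) -> Cohort:
    """Simulate the full cohort with MADRS change coupled to the activity shift.

    Patients are indexed 0..n_patients-1 and controls continue the index
    range, so each subject's stream is a stable function of (master seed,
    subject index) and the cohort is reproducible under reordering.
    """
    records: List[SubjectRecord] = []
    shifts: List[float] = []

    for i in range(config.n_patients):
        rng = _subject_rng(config, i)
        values, _ = _simulate_values(config, GROUP_PATIENT, rng)
        series = ActigraphySeries(f"condition_{i + 1}",
                                  np.datetime64("2003-05-07T12:00"), values)
        records.append(SubjectRecord(series.subject_id, GROUP_PATIENT, series,
                                     madrs_pre=0.0, madrs_post=0.0))
        shifts.append(halfwise_level_shift(values))

    for j in range(config.n_controls):
        idx = config.n_patients + j
        rng = _subject_rng(config, idx)
        values, _ = _simulate_values(config, GROUP_CONTROL, rng)
        series = ActigraphySeries(f"control_{j + 1}",
                                  np.datetime64("2003-05-07T12:00"), values)
        records.append(SubjectRecord(series.subject_id, GROUP_CONTROL, series))

    if config.n_patients > 0:
        delta = np.asarray(shifts, dtype=float)
        sd = delta.std(ddof=1) if len(delta) > 1 else 0.0
        delta = (delta - delta.mean()) / sd if sd > 0 else np.zeros_like(delta)
        for i, rec in enumerate(records[:config.n_patients]):
            rng = _subject_rng(config, i, stream=1)
            lo, hi = config.madrs_pre_range
            pre = float(rng.uniform(lo, hi))
            noise = float(rng.normal(0.0, config.madrs_noise_sd)) if config.madrs_noise_sd > 0 else 0.0
            post = pre - config.madrs_change_coupling * delta[i] + noise
            records[i] = dataclasses.replace(rec, madrs_pre=pre, madrs_post=post)

    return Cohort(records=records, common_length=config.n_minutes)
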