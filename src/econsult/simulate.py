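"""Seeded synthetic practice rosters, event logs and survey responses.

The pilot's raw web logs were never released, so analytics is exercised
against a generator that reproduces their statistical structure: a panel
of GP practices with heterogeneous size, age, sex and deprivation
profiles; daily website visits as a Poisson process proportional to the
adult list size, with a mean-preserving upward trend across the window;
independent Bernoulli conversion of visits into submissions (~30%); a
categorical mix of submission types (32% specific conditions, 27%
administrative help, 24% new-problem and 17% existing-problem advice);
female-skewed (~67%) and young-adult-skewed (~64% aged 18-44) usage; and
a voluntary satisfaction survey with a ~6.5% response rate.

Everything is driven by one integer seed: identical (seed, config) gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BANDS",
    "BROAD_CLASSES",
    "EVENT_COLUMNS",
    "PracticeProfile",
    "GeneratorConfig",
    "generate_rosters",
    "generate_log",
    "generate_survey",
    "rosters_to_frame",
    "rosters_from_frame",
]

AGE_BANDS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65+")
YOUNG_BANDS = ("18-24", "25-34", "35-44")  # the 18-44 group
BROAD_CLASSES = (
    "specific_condition",
    "administrative_help",
    "general_advice_new",
    "general_advice_existing",
)
EVENT_COLUMNS = ("practice_id", "date", "kind", "category", "sex", "age_band")


@dataclass(frozen=True)
class PracticeProfile:
    """Roster summary for one practice.

    ``share_18_44``, ``share_18_64`` and ``share_65_plus`` are fractions
    of the total roll; ``adult_band_shares`` is the age distribution of
    the adult (18+) roll over the six reporting bands. SIMD shares are
    the fractions of the roll in deprivation quintiles 1-2 (most
    deprived) and 4-5 (least deprived).
    """

    practice_id: str
    list_size: int
    adult_list_size: int
    share_18_44: float
    share_18_64: float
    share_65_plus: float
    female_share: float
    simd_q1q2_share: float
    simd_q4q5_share: float
    adult_band_shares: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in (
            "share_18_44",
            "share_18_64",
            "share_65_plus",
            "female_share",
            "simd_q1q2_share",
            "simd_q4q5_share",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.share_18_64 + self.share_65_plus > 1.0 + 1e-9:
            raise ValueError("18-64 and 65+ shares exceed the total roll")
        if self.adult_list_size > self.list_size:
            raise ValueError("adult list cannot exceed the total list")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic pilot, with study-condition defaults.

    Rates and probabilities: 0.46 daily visits per 1000 adults with 30%
    conversion yields ~0.050 submissions per patient per year, the
    pilot's pooled mean. ``female_usage_odds`` (1.996) and the 1.641
    usage multiplier on the 18-44 bands are calibrated once (see
    ``scripts/calibrate_generator.py``) so the pooled submission shares
    under the default panel hit 67% female and 64% aged 18-44. ``simd_effect`` is a
    log-linear slope of practice visit rates on the most-deprived share;
    the default 0 encodes the pilot's null deprivation gradient.
    ``trend_growth`` g tilts the daily rate linearly from (1 - g/2) to
    (1 + g/2) across the window, preserving the mean.
    """

    seed: int = 0
    n_practices: int = 11
    list_size_range: tuple[int, int] = (3000, 12000)
    window_start: date = date(2017, 4, 17)
    window_end: date = date(2017, 8, 17)
    daily_visit_rate_per_1000: float = 0.46
    conversion_probability: float = 0.30
    urgent_divert_probability: float = 0.05
    unique_visit_probability: float = 0.80
    broad_class_mix: tuple[float, ...] = (0.32, 0.27, 0.24, 0.17)
    female_usage_odds: float = 1.996
    age_usage_multipliers: tuple[float, ...] = (1.641, 1.641, 1.641, 1.0, 1.0, 1.0)
    simd_effect: float = 0.0
    practice_rate_sigma: float = 0.5
    trend_growth: float = 0.8
    adult_fraction_mean: float = 0.84
    survey_response_probability: float = 0.065
    satisfaction_probability: float = 0.914
    recommend_probability: float = 0.915
    outlier_young_share_65_plus: float | None = 0.023
    outlier_old_share_65_plus: float | None = 0.281

    def __post_init__(self) -> None:
        for name in (
            "conversion_probability",
            "urgent_divert_probability",
            "unique_visit_probability",
            "survey_response_probability",
            "satisfaction_probability",
            "recommend_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if abs(sum(self.broad_class_mix) - 1.0) > 1e-9:
            raise ValueError("broad_class_mix must sum to 1")
        if len(self.broad_class_mix) != len(BROAD_CLASSES):
            raise ValueError("broad_class_mix must have one entry per broad class")
        if len(self.age_usage_multipliers) != len(AGE_BANDS):
            raise ValueError("age_usage_multipliers must have one entry per band")
        if self.window_end <= self.window_start:
            raise ValueError("window must be non-empty")
        if self.n_practices < 1:
            raise ValueError("need at least one practice")

    @property
    def window_days(self) -> pd.DatetimeIndex:
        return pd.date_range(self.window_start, self.window_end, inclusive="left")

    @property
    def window_months(self) -> float:
        return len(self.window_days) * 12.0 / 365.0


# Adult age-band distribution of a typical roll: 51% of adults aged 18-44,
# 65+ just under a quarter of adults (~20% of the total roll at 84% adult).
_BASE_ADULT_BANDS = np.array([0.13, 0.18, 0.20, 0.13, 0.122, 0.238])


def _profile_from_bands(
    pid: str,
    list_size: int,
    adult_fraction: float,
    bands: np.ndarray,
    female: float,
    q1q2: float,
    q4q5: float,
) -> PracticeProfile:
    adult = int(round(list_size * adult_fraction))
    young = float(bands[:3].sum()) * adult_fraction
    old = float(bands[5]) * adult_fraction
    return PracticeProfile(
        practice_id=pid,
        list_size=list_size,
        adult_list_size=adult,
        share_18_44=young,
        share_18_64=adult_fraction - old,
        share_65_plus=old,
        female_share=female,
        simd_q1q2_share=q1q2,
        simd_q4q5_share=q4q5,
        adult_band_shares=tuple(float(x) for x in bands),
    )


def generate_rosters(config: GeneratorConfig) -> list[PracticeProfile]:
    """Draw a heterogeneous panel of practice rosters.

    Age-band shares are Dirichlet-perturbed around a typical adult
    distribution; when the panel has at least three practices, the first
    is forced young-skewed and the second old-skewed (65+ shares of the
    total roll set exactly to the configured outlier values), emulating
    a student-area practice and a rural retirement-area practice.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    lo, hi = config.list_size_range
    profiles: list[PracticeProfile] = []
    for i in range(config.n_practices):
        pid = f"P{i + 1}"
        list_size = int(rng.integers(lo, hi + 1))
        adult_fraction = float(np.clip(rng.normal(config.adult_fraction_mean, 0.03), 0.7, 0.95))
        bands = rng.dirichlet(_BASE_ADULT_BANDS * 120)
        if i == 0 and config.n_practices >= 3 and config.outlier_young_share_65_plus is not None:
            bands = _force_old_share(bands, config.outlier_young_share_65_plus / adult_fraction)
        if i == 1 and config.n_practices >= 3 and config.outlier_old_share_65_plus is not None:
            bands = _force_old_share(bands, config.outlier_old_share_65_plus / adult_fraction)
        female = float(np.clip(rng.normal(0.504, 0.015), 0.45, 0.56))
        q1q2 = float(rng.uniform(0.10, 0.60))
        q4q5 = float(rng.uniform(0.05, min(0.60, 0.95 - q1q2)))
        profiles.append(
            _profile_from_bands(pid, list_size, adult_fraction, bands, female, q1q2, q4q5)
        )
    return profiles


def _force_old_share(bands: np.ndarray, old_adult_share: float) -> np.ndarray:
    """Rescale the under-65 bands so the 65+ adult share is exact."""
    out = bands.copy()
    out[:5] *= (1.0 - old_adult_share) / out[:5].sum()
    out[5] = old_adult_share
    return out


def _practice_rate_multipliers(config: GeneratorConfig, rosters: list[PracticeProfile]) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    log_mult = rng.normal(0.0, config.practice_rate_sigma, size=len(rosters))
    log_mult -= log_mult.mean()  # keep the panel mean rate on target
    q1q2 = np.array([r.simd_q1q2_share for r in rosters])
    log_mult += config.simd_effect * (q1q2 - q1q2.mean())
    return np.exp(log_mult)


def generate_log(config: GeneratorConfig, rosters: list[PracticeProfile]) -> pd.DataFrame:
    """Generate the event log for the panel over the observation window.

    Returns a DataFrame with columns practice_id, date (ISO 8601), kind
    (site_visit / unique_visit / urgent_divert / submission), category
    (broad service class, submissions only), sex and age_band
    (submissions only; 'unknown' elsewhere). Each website visit yields
    one site_visit row; a subset are additionally flagged as the day's
    unique visits or as urgent diversions; each visit independently
    converts into a submission carrying category and demographics.
    """
    days = config.window_days
    if len(days) == 0:
        raise ValueError("empty observation window")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    multipliers = _practice_rate_multipliers(config, rosters)
    t_frac = (np.arange(len(days)) + 0.5) / len(days)
    trend = 1.0 + config.trend_growth * (t_frac - 0.5)
    class_p = np.asarray(config.broad_class_mix)

    frames = []
    for roster, mult in zip(rosters, multipliers):
        lam = (
            config.daily_visit_rate_per_1000 * roster.adult_list_size / 1000.0 * mult * trend
        )
        visits_per_day = rng.poisson(lam)
        n_visits = int(visits_per_day.sum())
        if n_visits == 0:
            continue
        visit_dates = np.repeat(days.strftime("%Y-%m-%d"), visits_per_day)

        # submission demographics, conditional on the practice roster
        f = roster.female_share
        p_female = f * config.female_usage_odds / (f * config.female_usage_odds + 1.0 - f)
        band_w = np.asarray(roster.adult_band_shares) * np.asarray(config.age_usage_multipliers)
        band_w = band_w / band_w.sum()

        is_unique = rng.random(n_visits) < config.unique_visit_probability
        is_divert = rng.random(n_visits) < config.urgent_divert_probability
        is_submission = rng.random(n_visits) < config.conversion_probability

        parts = [
            pd.DataFrame(
                {
                    "practice_id": roster.practice_id,
                    "date": visit_dates,
                    "kind": "site_visit",
                    "category": "unknown",
                    "sex": "unknown",
                    "age_band": "unknown",
                }
            )
        ]
        for kind, mask in (("unique_visit", is_unique), ("urgent_divert", is_divert)):
            if mask.any():
                parts.append(
                    pd.DataFrame(
                        {
                            "practice_id": roster.practice_id,
                            "date": visit_dates[mask],
                            "kind": kind,
                            "category": "unknown",
                            "sex": "unknown",
                            "age_band": "unknown",
                        }
                    )
                )
        n_sub = int(is_submission.sum())
        if n_sub:
            parts.append(
                pd.DataFrame(
                    {
                        "practice_id": roster.practice_id,
                        "date": visit_dates[is_submission],
                        "kind": "submission",
                        "category": rng.choice(BROAD_CLASSES, size=n_sub, p=class_p),
                        "sex": np.where(rng.random(n_sub) < p_female, "female", "male"),
                        "age_band": rng.choice(AGE_BANDS, size=n_sub, p=band_w),
                    }
                )
            )
        frames.append(pd.concat(parts, ignore_index=True))
    if not frames:
        return pd.DataFrame(columns=list(EVENT_COLUMNS))
    log = pd.concat(frames, ignore_index=True)
    return log.sort_values(["practice_id", "date", "kind"], kind="stable").reset_index(
        drop=True
    )


def generate_survey(log: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Voluntary post-submission survey: response, satisfaction, recommend.

    Each submission responds independently with the configured response
    probability; responders are satisfied / likely to recommend with the
    configured probabilities. Returns one row of counts per practice.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    subs = log[log["kind"] == "submission"]
    if subs.empty:
        raise ValueError("log has no submissions to survey")
    rows = []
    for pid, grp in subs.groupby("practice_id", sort=True):
        n = len(grp)
        responded = int(rng.binomial(n, config.survey_response_probability))
        satisfied = int(rng.binomial(responded, config.satisfaction_probability))
        recommend = int(rng.binomial(responded, config.recommend_probability))
        rows.append(
            {
                "practice_id": pid,
                "submissions": n,
                "responses": responded,
                "satisfied": satisfied,
                "would_recommend": recommend,
            }
        )
    return pd.DataFrame(rows)


_ROSTER_COLUMNS = [
    "practice_id",
    "list_size",
    "adult_list_size",
    "share_18_44",
    "share_18_64",
    "share_65_plus",
    "female_share",
    "simd_q1q2_share",
    "simd_q4q5_share",
] + [f"adult_band_{b.replace('-', '_').replace('+', 'plus')}" for b in AGE_BANDS]


def rosters_to_frame(rosters: list[PracticeProfile]) -> pd.DataFrame:
    """Roster panel as a flat DataFrame (CSV-ready)."""
    rows = []
    for r in rosters:
        row = {
            "practice_id": r.practice_id,
            "list_size": r.list_size,
            "adult_list_size": r.adult_list_size,
            "share_18_44": r.share_18_44,
            "share_18_64": r.share_18_64,
            "share_65_plus": r.share_65_plus,
            "female_share": r.female_share,
            "simd_q1q2_share": r.simd_q1q2_share,
            "simd_q4q5_share": r.simd_q4q5_share,
        }
        for band, share in zip(AGE_BANDS, r.adult_band_shares):
            row[f"adult_band_{band.replace('-', '_').replace('+', 'plus')}"] = share
        rows.append(row)
    return pd.DataFrame(rows, columns=_ROSTER_COLUMNS)


def rosters_from_frame(frame: pd.DataFrame) -> list[PracticeProfile]:
    """Inverse of :func:`rosters_to_frame`."""
    band_cols = _ROSTER_COLUMNS[9:]
    out = []
    for _, row in frame.iterrows():
        bands = tuple(float(row[c]) for c in band_cols) if band_cols[0] in frame else ()
        out.append(
            PracticeProfile(
                practice_id=str(row["practice_id"]),
                list_size=int(row["list_size"]),
                adult_list_size=int(row["adult_list_size"]),
                share_18_44=float(row["share_18_44"]),
                share_18_64=float(row["share_18_64"]),
                share_65_plus=float(row["share_65_plus"]),
                female_share=float(row["female_share"]),
                simd_q1q2_share=float(row["simd_q1q2_share"]),
                simd_q4q5_share=float(row["simd_q4q5_share"]),
                adult_band_shares=bands,
            )
        )
    return out
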