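"""Usage metrics from web-triage event logs and practice rosters.

Works on the event-log schema produced by :mod:`econsult.simulate` (or any
CSV with the same columns): conversion of site visits into submissions,
annualised submission rates per 1000 adults, demographic and service-class
shares of submissions, the association between practice submission rates
and area deprivation, and survey proportion summaries with Wilson
intervals.

Demographics may be unknown (the trial-period logs carried none): shares
are computed over known values only, with unknown counts reported
alongside, never silently folded into denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .simulate import AGE_BANDS, BROAD_CLASSES, YOUNG_BANDS, PracticeProfile

__all__ = [
    "conversion_rate",
    "annualised_rate",
    "demographic_shares",
    "deprivation_association",
    "survey_summary",
    "ProportionSummary",
    "usage_metrics",
]


def _in_scope(log: pd.DataFrame, practice: str | None) -> pd.DataFrame:
    return log if practice is None else log[log["practice_id"] == practice]


def conversion_rate(log: pd.DataFrame, practice: str | None = None) -> float | None:
    """Submissions divided by site visits, pooled or for one practice.

    Returns None (missing) when there are no site visits in scope.
    """
    scoped = _in_scope(log, practice)
    visits = int((scoped["kind"] == "site_visit").sum())
    if visits == 0:
        return None
    submissions = int((scoped["kind"] == "submission").sum())
    return submissions / visits


def annualised_rate(
    log: pd.DataFrame, roster: PracticeProfile, window_months: float
) -> float:
    """Annualised submissions per 1000 adults for one practice.

    ``submissions * (12 / window_months) * 1000 / adult_list_size``; the
    observation window is expressed in months, matching how a few months
    of pilot data are scaled to a likely annual usage.
    """
    if window_months <= 0:
        raise ValueError("window_months must be positive")
    if roster.adult_list_size <= 0:
        raise ValueError("adult_list_size must be positive")
    scoped = _in_scope(log, roster.practice_id)
    submissions = int((scoped["kind"] == "submission").sum())
    return submissions * (12.0 / window_months) * 1000.0 / roster.adult_list_size


def demographic_shares(log: pd.DataFrame) -> dict:
    """Sex, age-band and service-class shares of submissions.

    Each block reports shares over known values and the count of
    unknowns. ``female_share`` is None when every record's sex is
    unknown; likewise for the age and class blocks.
    """
    subs = log[log["kind"] == "submission"]
    n = len(subs)

    sex_known = subs[subs["sex"].isin(["female", "male"])]
    female_share = (
        float((sex_known["sex"] == "female").mean()) if len(sex_known) else None
    )

    age_known = subs[subs["age_band"].isin(AGE_BANDS)]
    if len(age_known):
        age_counts = age_known["age_band"].value_counts()
        age_band_shares = {b: float(age_counts.get(b, 0)) / len(age_known) for b in AGE_BANDS}
        share_18_44 = sum(age_band_shares[b] for b in YOUNG_BANDS)
    else:
        age_band_shares = None
        share_18_44 = None

    cls_known = subs[subs["category"].isin(BROAD_CLASSES)]
    if len(cls_known):
        cls_counts = cls_known["category"].value_counts()
        category_shares = {
            c: float(cls_counts.get(c, 0)) / len(cls_known) for c in BROAD_CLASSES
        }
    else:
        category_shares = None

    return {
        "n_submissions": n,
        "female_share": female_share,
        "unknown_sex": int(n - len(sex_known)),
        "age_band_shares": age_band_shares,
        "share_18_44": share_18_44,
        "unknown_age": int(n - len(age_known)),
        "category_shares": category_shares,
        "unknown_category": int(n - len(cls_known)),
    }


def _permutation_pvalue(
    x: np.ndarray, y: np.ndarray, observed: float, rng: np.random.Generator, n_perm: int
) -> float:
    count = 0
    for _ in range(n_perm):
        rho = stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(rho) >= abs(observed) - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def deprivation_association(
    rates: dict[str, float],
    rosters: list[PracticeProfile],
    *,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Rank association of practice submission rates with deprivation.

    Spearman's rho of the annualised rate against the practice shares in
    SIMD quintiles 1-2 (most deprived) and 4-5 (least deprived), each
    with a seeded two-sided permutation p-value. The original analysis
    made this comparison visually; the statistic here quantifies the
    same question. Needs at least three practices; constant rates are
    flagged degenerate with rho reported as 0 by convention.

    Also returns a scatter-ready table (one row per practice).
    """
    roster_map = {r.practice_id: r for r in rosters}
    common = [pid for pid in rates if pid in roster_map]
    if len(common) < 3:
        raise ValueError(
            f"deprivation association needs >= 3 practices with both a rate and "
            f"a roster; got {len(common)}"
        )
    rate_arr = np.array([rates[p] for p in common], dtype=float)
    table = pd.DataFrame(
        {
            "practice_id": common,
            "rate": rate_arr,
            "simd_q1q2_share": [roster_map[p].simd_q1q2_share for p in common],
            "simd_q4q5_share": [roster_map[p].simd_q4q5_share for p in common],
        }
    )
    degenerate = bool(np.all(rate_arr == rate_arr[0]))
    out: dict = {"n_practices": len(common), "degenerate": degenerate, "table": table}
    rng = np.random.default_rng(seed)
    for key in ("simd_q1q2_share", "simd_q4q5_share"):
        x = table[key].to_numpy()
        if degenerate or np.all(x == x[0]):
            # rank correlation is undefined on a constant input; report 0
            out[key] = {"spearman_rho": 0.0, "p_value": 1.0}
            continue
        rho = float(stats.spearmanr(x, rate_arr).statistic)
        p = _permutation_pvalue(x, rate_arr, rho, rng, n_permutations)
        out[key] = {"spearman_rho": rho, "p_value": p}
    return out


@dataclass(frozen=True)
class ProportionSummary:
    """A proportion with its Wilson 95% interval.

    Wilson rather than Wald: survey denominators are small and the
    proportions near 1, where Wald intervals overshoot [0, 1].
    """

    name: str
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, name: str, numerator: int, denominator: int) -> "ProportionSummary":
        if denominator <= 0:
            raise ValueError("denominator must be positive")
        if not 0 <= numerator <= denominator:
            raise ValueError("numerator must be in [0, denominator]")
        low, high = proportion_confint(numerator, denominator, alpha=0.05, method="wilson")
        return cls(
            name=name,
            numerator=numerator,
            denominator=denominator,
            proportion=numerator / denominator,
            ci_low=float(low),
            ci_high=float(high),
        )


def survey_summary(
    responses: int,
    satisfied: int,
    would_recommend: int,
    submissions: int | None = None,
) -> dict[str, ProportionSummary]:
    """Satisfaction / recommendation proportions and the response rate.

    All as :class:`ProportionSummary` with Wilson 95% intervals; the
    response rate (responses over submissions) is included when the
    submission count is supplied.
    """
    out = {
        "satisfaction": ProportionSummary.from_counts("satisfaction", satisfied, responses),
        "recommend": ProportionSummary.from_counts("recommend", would_recommend, responses),
    }
    if submissions is not None:
        out["response_rate"] = ProportionSummary.from_counts(
            "response_rate", responses, submissions
        )
    return out


def usage_metrics(
    log: pd.DataFrame, rosters: list[PracticeProfile], window_months: float
) -> dict:
    """Per-practice and pooled usage metrics in one pass.

    Per practice: site visits, submissions, conversion and the
    annualised submission rate per 1000 adults. Pooled: totals, the
    overall conversion rate, demographic/service-class shares, and the
    deprivation association (when >= 3 practices have activity).
    """
    per_practice = []
    rates: dict[str, float] = {}
    for r in rosters:
        scoped = log[log["practice_id"] == r.practice_id]
        visits = int((scoped["kind"] == "site_visit").sum())
        subs = int((scoped["kind"] == "submission").sum())
        rate = annualised_rate(log, r, window_months)
        rates[r.practice_id] = rate
        per_practice.append(
            {
                "practice_id": r.practice_id,
                "site_visits": visits,
                "submissions": subs,
                "conversion_rate": subs / visits if visits else None,
                "annualised_submissions_per_1000_adults": rate,
            }
        )
    pooled = {
        "site_visits": int((log["kind"] == "site_visit").sum()),
        "submissions": int((log["kind"] == "submission").sum()),
        "conversion_rate": conversion_rate(log),
        **demographic_shares(log),
    }
    result = {"per_practice": pd.DataFrame(per_practice), "pooled": pooled}
    if len(rosters) >= 3:
        result["deprivation"] = deprivation_association(rates, rosters)
    return result
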