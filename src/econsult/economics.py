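"""Per-submission cost deltas versus conventional care, and break-even rates.

The comparator for a saved contact is one conventional pathway: a booking
call handled by administrative staff (3 min) plus a 10-minute face-to-face
GP appointment. If a fraction ``s`` of submissions replaces such a contact,
each submission *avoids* ``s`` times those minutes and *adds* the expected
admin/GP minutes of processing the submission itself. Valuing minutes at
the staff unit costs gives a per-submission saving (possibly negative),
and dividing the annual per-patient licence charge by the per-submission
saving gives the annual submissions per patient needed to break even.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import pandas as pd

from .timings import (
    ActivityTimings,
    CategoryMix,
    ExpectedResource,
    NoteUseModel,
    derive_per_type_resources,
    expected_resource,
    round_half_away,
)

__all__ = [
    "CostParameters",
    "SavingsBreakdown",
    "BreakevenResult",
    "savings_per_econsult",
    "breakeven_rate",
    "savings_table",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class CostParameters:
    """Staff unit costs and the service charge.

    Hourly rates (GBP/h) are national unit costs including overheads and
    are taken as configuration inputs: £95.08/h of GP time, £17.82/h of
    administrator time. The conventional comparator is a 3-minute booking
    call plus a 10-minute face-to-face appointment. The licence charge is
    £0.63 per registered patient per year.
    """

    gp_cost_per_hour: float = 95.08
    admin_cost_per_hour: float = 17.82
    conventional_booking_minutes: float = 3.0
    conventional_gp_minutes: float = 10.0
    annual_charge_per_patient: float = 0.63

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0):
                raise ValueError(f"cost parameter {f.name!r} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class SavingsBreakdown:
    """Per-submission cost saving in GBP, split by staff group.

    ``admin_saving`` is typically negative (a submission takes more admin
    time than the booking call it replaces); the GP saving usually more
    than offsets it at the appointment-replacement shares observed.
    """

    appointments_saved_fraction: float
    admin_saving: float
    gp_saving: float

    @property
    def total_saving(self) -> float:
        return self.admin_saving + self.gp_saving

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_away(self.admin_saving, ndigits),
            round_half_away(self.gp_saving, ndigits),
            round_half_away(self.total_saving, ndigits),
        )


@dataclass(frozen=True)
class BreakevenResult:
    """Annual submissions per patient at which savings cover the charge.

    Undefined (``defined`` False) when the per-submission saving is not
    positive — no finite submission rate recovers the charge.
    """

    submissions_per_patient_per_year: float | None

    @property
    def defined(self) -> bool:
        return self.submissions_per_patient_per_year is not None


def savings_per_econsult(
    expected: ExpectedResource, costs: CostParameters, s: float
) -> SavingsBreakdown:
    """Cost saving per submission when a fraction ``s`` replaces a contact.

    admin = (s * booking_min - expected_admin_min) * admin_rate / 60
    gp    = (s * appointment_min - expected_gp_min) * gp_rate / 60

    Rates are divided by 60 at full precision; pre-rounded per-minute
    rates do not reproduce the published money table.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"appointments-saved fraction must be in [0, 1], got {s!r}")
    admin = (
        (s * costs.conventional_booking_minutes - expected.admin_minutes_per_econsult)
        * costs.admin_cost_per_hour
        / 60.0
    )
    gp = (
        (s * costs.conventional_gp_minutes - expected.gp_minutes_per_econsult)
        * costs.gp_cost_per_hour
        / 60.0
    )
    return SavingsBreakdown(appointments_saved_fraction=s, admin_saving=admin, gp_saving=gp)


def breakeven_rate(savings: SavingsBreakdown, costs: CostParameters) -> BreakevenResult:
    """Annual submissions per patient needed to cover the licence charge.

    ``charge / total_saving`` when the saving is positive; undefined
    otherwise (reported as "no breakeven", never as infinity).
    """
    total = savings.total_saving
    if total <= 0.0:
        return BreakevenResult(submissions_per_patient_per_year=None)
    return BreakevenResult(
        submissions_per_patient_per_year=costs.annual_charge_per_patient / total
    )


DEFAULT_S_GRID = tuple(x / 100.0 for x in range(74, 59, -2))  # 74% down to 60%


def savings_table(
    expected: ExpectedResource,
    costs: CostParameters,
    s_values: "list[float] | tuple[float, ...]" = DEFAULT_S_GRID,
) -> pd.DataFrame:
    """Savings at each appointment-replacement share, one row per share.

    Columns hold both full-precision and display (1 dp, half away from
    zero) values; the display columns reproduce the published table.
    """
    if len(s_values) == 0:
        raise ValueError("s_values must be non-empty")
    rows = []
    for s in s_values:
        b = savings_per_econsult(expected, costs, s)
        a1, g1, t1 = b.rounded(1)
        rows.append(
            {
                "appointments_saved_pct": round_half_away(100 * s, 0),
                "admin_saving_gbp": b.admin_saving,
                "gp_saving_gbp": b.gp_saving,
                "total_saving_gbp": b.total_saving,
                "admin_saving_gbp_1dp": a1,
                "gp_saving_gbp_1dp": g1,
                "total_saving_gbp_1dp": t1,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_sweep(
    timings: ActivityTimings,
    perturbation: float,
    *,
    mix: CategoryMix | None = None,
    notes: NoteUseModel = NoteUseModel(),
    costs: CostParameters = CostParameters(),
    s: float = 0.73,
) -> pd.DataFrame:
    """Effect on the total saving of scaling administrative timings ±x.

    Administrative task estimates were the least certain inputs, so the
    full chain is recomputed with those timings scaled by (1 ± x), in two
    variants: scaling only the submission-side admin tasks (receive and
    close-off), and scaling all admin tasks including the conventional
    booking call. Either way the change is small relative to the GP cost
    component, which is the qualitative finding this sweep documents.

    Returns one row per (direction, variant) with the perturbed total
    saving and its change from baseline.
    """
    if not -1.0 < perturbation < 1.0:
        raise ValueError(f"perturbation must be in (-1, 1), got {perturbation!r}")
    mix = mix if mix is not None else CategoryMix()

    def total_for(t: ActivityTimings, c: CostParameters) -> float:
        exp = expected_resource(derive_per_type_resources(t, notes), mix)
        return savings_per_econsult(exp, c, s).total_saving

    base_total = total_for(timings, costs)
    rows = [
        {
            "scale": 1.0,
            "variant": "baseline",
            "total_saving_gbp": base_total,
            "delta_gbp": 0.0,
        }
    ]
    for direction in (+1, -1) if perturbation != 0 else ():
        factor = 1.0 + direction * perturbation
        scaled = replace(
            timings,
            receive_econsult=timings.receive_econsult * factor,
            close_off_with_contact=timings.close_off_with_contact * factor,
            close_off_no_contact=timings.close_off_no_contact * factor,
        )
        t_econ = total_for(scaled, costs)
        rows.append(
            {
                "scale": factor,
                "variant": "econsult_admin_only",
                "total_saving_gbp": t_econ,
                "delta_gbp": t_econ - base_total,
            }
        )
        scaled_all = replace(scaled, book_appointment=timings.book_appointment * factor)
        costs_all = replace(
            costs, conventional_booking_minutes=costs.conventional_booking_minutes * factor
        )
        t_all = total_for(scaled_all, costs_all)
        rows.append(
            {
                "scale": factor,
                "variant": "all_admin_tasks",
                "total_saving_gbp": t_all,
                "delta_gbp": t_all - base_total,
            }
        )
    return pd.DataFrame(rows)
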