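"""Activity timings and the expected staff time per electronic consultation.

An eConsult is a structured online submission to a GP practice. Each
submission lands in one of seven outcome categories (a details change, a
fit-note request, a prescription, a callback, a face-to-face appointment,
...), and each category consumes a different amount of administrative and
GP time, built up from elementary task timings: receiving the submission,
closing it off (with or without contacting the patient), checking the
patient's notes, and any follow-up contact.

This module represents the elementary timings, composes them into
per-category admin/GP minutes, and weights those by the observed category
mix to give the expected staff time per submission — the quantity the
economic model converts into money.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields

__all__ = [
    "ActivityTimings",
    "EConsultCategory",
    "CategoryMix",
    "NoteUseModel",
    "PerTypeResource",
    "ExpectedResource",
    "derive_per_type_resources",
    "expected_resource",
    "round_half_away",
]

_MIX_TOL = 1e-9


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention printed tables use).

    Python's built-in ``round`` is banker's rounding; the reference tables
    round 0.05 up in magnitude, so ties must move away from zero.
    """
    scale = 10.0**ndigits
    scaled = x * scale
    floor = int(scaled)
    frac = scaled - floor
    if frac >= 0.5 - 1e-12:
        floor += 1
    elif frac <= -0.5 + 1e-12:
        floor -= 1
    return floor / scale


class EConsultCategory(enum.Enum):
    """The seven outcome categories of a submission, in reporting order."""

    ADMIN_OTHER_DETAILS = "admin_other_details"
    ADMIN_FIT_NOTE = "admin_fit_note"
    GP_NO_ACTION = "gp_no_action"
    GP_PRESCRIPTION = "gp_prescription"
    OTHER_APPOINTMENT = "other_appointment"
    GP_PHONE_BACK = "gp_phone_back"
    GP_APPOINTMENT = "gp_appointment"

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    EConsultCategory.ADMIN_OTHER_DETAILS: "Admin: other & details change",
    EConsultCategory.ADMIN_FIT_NOTE: "Admin: fit note",
    EConsultCategory.GP_NO_ACTION: "GP no action (e.g. follow-up)",
    EConsultCategory.GP_PRESCRIPTION: "GP prescription",
    EConsultCategory.OTHER_APPOINTMENT: "Other appointment (e.g. bloods)",
    EConsultCategory.GP_PHONE_BACK: "GP phone back",
    EConsultCategory.GP_APPOINTMENT: "GP appointment",
}

#: Categories whose close-off involves contacting the patient, hence the
#: longer close-off timing. Only this assignment reproduces the published
#: per-category admin column from the elementary timings; the source tables
#: do not state it explicitly, so it is a documented inference.
CONTACT_CLOSE_OFF = frozenset(
    {
        EConsultCategory.ADMIN_FIT_NOTE,
        EConsultCategory.GP_PRESCRIPTION,
        EConsultCategory.OTHER_APPOINTMENT,
        EConsultCategory.GP_PHONE_BACK,
        EConsultCategory.GP_APPOINTMENT,
    }
)


@dataclass(frozen=True)
class ActivityTimings:
    """Elementary task timings in minutes.

    Defaults are the consensus estimates elicited from practice staff:
    3 min to book a conventional appointment, 3 min to receive a
    submission, 3/1.5 min to close off with/without patient contact,
    10-min face-to-face and 5-min telephone consultations, 2.5/5 min to
    process with minimal/detailed use of the patient's notes, 4 min for a
    sick note, and small increments for prescriptions (+1), other
    follow-ups (+0.5) and a change of details (0.5).
    """

    book_appointment: float = 3.0
    receive_econsult: float = 3.0
    close_off_with_contact: float = 3.0
    close_off_no_contact: float = 1.5
    face_to_face_appointment: float = 10.0
    telephone_consultation: float = 5.0
    process_minimal_notes: float = 2.5
    process_detailed_notes: float = 5.0
    sick_note: float = 4.0
    prescription_increment: float = 1.0
    other_followup_increment: float = 0.5
    change_of_details: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0):
                raise ValueError(f"timing {f.name!r} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class NoteUseModel:
    """Fraction of submissions needing detailed (vs minimal) note review.

    The expected note-check time is the mixture
    ``detailed_fraction * detailed + (1 - detailed_fraction) * minimal``;
    the default of one half reflects the elicitation consensus.
    """

    detailed_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.detailed_fraction <= 1.0:
            raise ValueError(
                f"detailed_fraction must be in [0, 1], got {self.detailed_fraction!r}"
            )

    def note_check_minutes(self, timings: ActivityTimings) -> float:
        d = self.detailed_fraction
        return d * timings.process_detailed_notes + (1 - d) * timings.process_minimal_notes


class CategoryMix:
    """Probability distribution over the seven outcome categories.

    The default is the observed mix from practice submission data:
    12% details changes, 15% fit notes, 10% no-action, 20% prescriptions,
    13% other appointments, 15% callbacks, 15% face-to-face appointments.
    """

    DEFAULT_SHARES = {
        EConsultCategory.ADMIN_OTHER_DETAILS: 0.12,
        EConsultCategory.ADMIN_FIT_NOTE: 0.15,
        EConsultCategory.GP_NO_ACTION: 0.10,
        EConsultCategory.GP_PRESCRIPTION: 0.20,
        EConsultCategory.OTHER_APPOINTMENT: 0.13,
        EConsultCategory.GP_PHONE_BACK: 0.15,
        EConsultCategory.GP_APPOINTMENT: 0.15,
    }

    def __init__(self, shares: dict[EConsultCategory, float] | None = None) -> None:
        if shares is None:
            shares = self.DEFAULT_SHARES
        missing = set(EConsultCategory) - set(shares)
        if missing:
            raise ValueError(f"mix missing categories: {sorted(c.value for c in missing)}")
        extra = set(shares) - set(EConsultCategory)
        if extra:
            raise ValueError(f"mix has unknown categories: {extra}")
        for c, p in shares.items():
            if p < 0:
                raise ValueError(f"share for {c.value} is negative: {p}")
        total = sum(shares.values())
        if abs(total - 1.0) > _MIX_TOL:
            raise ValueError(f"mix must sum to 1 (got {total!r})")
        self._shares = {c: float(shares[c]) for c in EConsultCategory}

    def __getitem__(self, category: EConsultCategory) -> float:
        return self._shares[category]

    def items(self):
        return self._shares.items()

    def as_dict(self) -> dict[EConsultCategory, float]:
        return dict(self._shares)

    @classmethod
    def point_mass(cls, category: EConsultCategory) -> "CategoryMix":
        return cls({c: (1.0 if c is category else 0.0) for c in EConsultCategory})

    @classmethod
    def from_labels(cls, shares: dict[str, float]) -> "CategoryMix":
        """Build a mix from ``{field_name: share}`` (e.g. parsed YAML)."""
        return cls({EConsultCategory(k): v for k, v in shares.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CategoryMix):
            return NotImplemented
        return self._shares == other._shares

    def __repr__(self) -> str:
        inner = ", ".join(f"{c.value}={p:.3g}" for c, p in self._shares.items())
        return f"CategoryMix({inner})"


@dataclass(frozen=True)
class CategoryResource:
    """Admin and GP minutes for a single category.

    ``gp_followup_minutes`` is the extra consultation time a callback or
    booked appointment adds on top of the initial assessment; it is kept
    separate so reports can print the published "base + follow-up" form.
    """

    admin_minutes: float
    gp_base_minutes: float
    gp_followup_minutes: float = 0.0

    @property
    def gp_minutes(self) -> float:
        return self.gp_base_minutes + self.gp_followup_minutes


class PerTypeResource:
    """Per-category admin/GP resource use (minutes)."""

    def __init__(self, resources: dict[EConsultCategory, CategoryResource]) -> None:
        missing = set(EConsultCategory) - set(resources)
        if missing:
            raise ValueError(f"resources missing categories: {missing}")
        for c, r in resources.items():
            if r.admin_minutes < 0 or r.gp_base_minutes < 0 or r.gp_followup_minutes < 0:
                raise ValueError(f"negative resource for {c.value}")
        self._resources = {c: resources[c] for c in EConsultCategory}

    def __getitem__(self, category: EConsultCategory) -> CategoryResource:
        return self._resources[category]

    def items(self):
        return self._resources.items()


@dataclass(frozen=True)
class ExpectedResource:
    """Mix-weighted expected staff minutes per submission, full precision.

    Rounding to one decimal place happens only at presentation: the
    downstream money table is only reproducible from the unrounded values.
    """

    admin_minutes_per_econsult: float
    gp_minutes_per_econsult: float

    def rounded(self, ndigits: int = 1) -> tuple[float, float]:
        return (
            round_half_away(self.admin_minutes_per_econsult, ndigits),
            round_half_away(self.gp_minutes_per_econsult, ndigits),
        )


def derive_per_type_resources(
    timings: ActivityTimings, notes: NoteUseModel = NoteUseModel()
) -> PerTypeResource:
    """Compose per-category admin and GP minutes from elementary timings.

    Admin time for every category is receive + close-off, with the longer
    with-contact close-off for categories whose outcome requires telling
    the patient something (fit note, prescription, other appointment,
    callback, appointment) and the short no-contact close-off otherwise.

    GP time is: a details change alone for the admin/details category; a
    sick note alone for fit notes; and a note check plus the category's
    increment or follow-up contact for the rest. The callback and
    appointment categories carry the follow-up contact (5-min call,
    10-min face-to-face) as a separate follow-up component.
    """
    nc = notes.note_check_minutes(timings)
    C = EConsultCategory

    def admin(c: EConsultCategory) -> float:
        close = (
            timings.close_off_with_contact
            if c in CONTACT_CLOSE_OFF
            else timings.close_off_no_contact
        )
        return timings.receive_econsult + close

    gp: dict[EConsultCategory, tuple[float, float]] = {
        C.ADMIN_OTHER_DETAILS: (timings.change_of_details, 0.0),
        C.ADMIN_FIT_NOTE: (timings.sick_note, 0.0),
        C.GP_NO_ACTION: (nc, 0.0),
        C.GP_PRESCRIPTION: (nc + timings.prescription_increment, 0.0),
        C.OTHER_APPOINTMENT: (nc + timings.other_followup_increment, 0.0),
        C.GP_PHONE_BACK: (nc, timings.telephone_consultation),
        C.GP_APPOINTMENT: (nc, timings.face_to_face_appointment),
    }
    return PerTypeResource(
        {
            c: CategoryResource(admin_minutes=admin(c), gp_base_minutes=b, gp_followup_minutes=f)
            for c, (b, f) in gp.items()
        }
    )


def expected_resource(per_type: PerTypeResource, mix: CategoryMix) -> ExpectedResource:
    """Probability-weighted expected admin and GP minutes per submission.

    Returns sums of ``p_c * t_c`` over the seven categories at full
    precision (5.67 admin / 5.9125 GP min under the defaults, printed as
    5.7 / 5.9).
    """
    admin = sum(p * per_type[c].admin_minutes for c, p in mix.items())
    gp = sum(p * per_type[c].gp_minutes for c, p in mix.items())
    return ExpectedResource(admin_minutes_per_econsult=admin, gp_minutes_per_econsult=gp)
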