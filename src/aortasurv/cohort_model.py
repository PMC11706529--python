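"""Patient records, eligibility cascade, and outcome derivation.

The cohort comprises adults discharged after elective (non-emergent) open or
endovascular repair of thoracic or abdominal aortic pathology (aneurysm,
Leriche syndrome, penetrating aortic ulcer). Primary outcomes are critical
events during surveillance: aortic events, reintervention, and death of any
cause. Aortic events are any new endoleak (types I–IV), a new or anastomotic
aneurysm, or diameter progression of at least 1 cm versus the immediate
postoperative baseline.

All times are months from discharge. Visit-detected events carry the visit
time; interval-censored onset is not back-imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

APPROACHES: tuple[str, ...] = ("open", "endovascular")
LEVELS: tuple[str, ...] = ("thoracic", "abdominal")
PATHOLOGIES: tuple[str, ...] = ("aneurysm", "leriche", "penetrating_aortic_ulcer")

ENDOLEAK_KINDS: tuple[str, ...] = (
    "endoleak_Ia",
    "endoleak_Ib",
    "endoleak_II",
    "endoleak_III",
    "endoleak_IV",
)
#: Event kinds qualifying as an aortic event (the composite's first arm).
AORTIC_EVENT_KINDS: tuple[str, ...] = ENDOLEAK_KINDS + ("new_aneurysm", "diameter_progression")
EVENT_KINDS: tuple[str, ...] = AORTIC_EVENT_KINDS + ("reintervention", "death")

#: "Diameter progression >= 1 cm": growth versus postoperative baseline, in mm.
DIAMETER_PROGRESSION_THRESHOLD_MM: float = 10.0

#: Exclusion criteria in the order the cascade applies them; a patient is
#: tallied under the first criterion that excludes them.
EXCLUSION_ORDER: tuple[str, ...] = (
    "age_under_18",
    "history_of_dissection",
    "planned_further_surgery",
    "emergent",
    "in_hospital_aortic_event",
    "insufficient_followup_imaging",
)


@dataclass(frozen=True)
class EventEntry:
    """One follow-up event: what happened and when (months from discharge)."""

    kind: str
    time_months: float
    diameter_delta_mm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not (self.time_months >= 0):
            raise ValueError(f"event time must be >= 0, got {self.time_months!r}")


@dataclass
class PatientRecord:
    """One subject: baseline covariates, eligibility flags, and event log."""

    patient_id: str
    approach: str
    level: str
    pathology: str
    age_years: float
    history_of_dissection: bool = False
    planned_further_surgery: bool = False
    emergent: bool = False
    in_hospital_aortic_event: bool = False
    n_followup_visits_with_cta: int = 0
    events: tuple[EventEntry, ...] = ()
    followup_end: float = 0.0
    #: Generating state trajectory, present only for synthetic cohorts; used
    #: as a parameter-recovery oracle, never by the estimators.
    true_states: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.pathology not in PATHOLOGIES:
            raise ValueError(f"unknown pathology {self.pathology!r}")
        self.events = tuple(self.events)
        deaths = [e for e in self.events if e.kind == "death"]
        if len(deaths) > 1:
            raise ValueError(f"patient {self.patient_id}: more than one death entry")
        if deaths:
            dt = deaths[0].time_months
            if any(e.time_months > dt for e in self.events):
                raise ValueError(f"patient {self.patient_id}: events recorded after death")
        if any(e.time_months > self.followup_end for e in self.events):
            raise ValueError(
                f"patient {self.patient_id}: event beyond follow-up end {self.followup_end}"
            )


@dataclass(frozen=True)
class OutcomeTimes:
    """Derived per-patient outcome times (months from discharge).

    ``primary_composite_time`` is the minimum of the component times present;
    ties are broken by severity death > reintervention > aortic_event.
    """

    censor_time: float
    aortic_event_time: float | None = None
    aortic_event_kind: str | None = None
    reintervention_time: float | None = None
    death_time: float | None = None
    primary_composite_time: float | None = None
    primary_composite_type: str | None = None


def derive_outcomes(p: PatientRecord) -> OutcomeTimes:
    """Derive outcome times from a patient's event log.

    The aortic-event time is the earliest among any endoleak, a new
    aneurysm, and diameter progression with delta >= 10 mm; sub-threshold
    progression entries are ignored. The result is invariant to the order of
    the event list.
    """
    aortic: list[EventEntry] = []
    reinterventions: list[float] = []
    death_time: float | None = None
    for e in p.events:
        if e.kind == "reintervention":
            reinterventions.append(e.time_months)
        elif e.kind == "death":
            death_time = e.time_months
        elif e.kind == "diameter_progression":
            if e.diameter_delta_mm is None:
                raise ValueError(
                    f"patient {p.patient_id}: diameter_progression event at "
                    f"{e.time_months} months lacks diameter_delta_mm"
                )
            if e.diameter_delta_mm >= DIAMETER_PROGRESSION_THRESHOLD_MM:
                aortic.append(e)
        else:  # endoleak subtypes, new aneurysm
            aortic.append(e)

    aortic_time: float | None = None
    aortic_kind: str | None = None
    if aortic:
        first = min(aortic, key=lambda e: (e.time_months, AORTIC_EVENT_KINDS.index(e.kind)))
        aortic_time, aortic_kind = first.time_months, first.kind
    reint_time = min(reinterventions) if reinterventions else None

    # severity order doubles as the tie-break for the composite
    components = [
        ("death", death_time),
        ("reintervention", reint_time),
        ("aortic_event", aortic_time),
    ]
    present = [(t, kind) for kind, t in components if t is not None]
    composite_time: float | None = None
    composite_type: str | None = None
    if present:
        composite_time = min(t for t, _ in present)
        composite_type = next(kind for t, kind in present if t == composite_time)

    return OutcomeTimes(
        censor_time=p.followup_end,
        aortic_event_time=aortic_time,
        aortic_event_kind=aortic_kind,
        reintervention_time=reint_time,
        death_time=death_time,
        primary_composite_time=composite_time,
        primary_composite_type=composite_type,
    )


def _exclusion_reason(p: PatientRecord) -> str | None:
    if p.age_years < 18:
        return "age_under_18"
    if p.history_of_dissection:
        return "history_of_dissection"
    if p.planned_further_surgery:
        return "planned_further_surgery"
    if p.emergent:
        return "emergent"
    if p.in_hospital_aortic_event:
        return "in_hospital_aortic_event"
    if p.n_followup_visits_with_cta < 2:
        return "insufficient_followup_imaging"
    return None


def apply_eligibility(
    cohort: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Apply the exclusion cascade; tally each patient under the first
    criterion that excludes them.

    Criteria, in fixed order: age < 18 years; history of aortic dissection;
    planned further aortic surgery; emergent surgery; in-hospital aortic
    event after the index procedure; fewer than two follow-up visits with
    CTA imaging. Idempotent: the eligible subset passes unchanged.
    """
    tally = {name: 0 for name in EXCLUSION_ORDER}
    eligible: list[PatientRecord] = []
    for p in cohort:
        reason = _exclusion_reason(p)
        if reason is None:
            eligible.append(p)
        else:
            tally[reason] += 1
    return eligible, tally
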