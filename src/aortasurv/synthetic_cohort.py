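"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The real surveillance data behind this kind of analysis are typically not
distributable, so every downstream stage (eligibility, outcome derivation,
Kaplan–Meier curves, Markov-chain estimation, NNH) is exercised on synthetic
cohorts generated here. The generator draws, per patient and 6-month
interval, an administrative-censoring Bernoulli followed by a categorical
transition among {stay, →C, →R, →D} with the configured per-interval
hazards, so the observed transition fractions are unbiased for the hazards
and parameter-recovery tests are sharp. Records carry the true generating
state trajectory as a recovery oracle.

Defaults emulate the shape of a real elective aortic-surgery cohort: 464
patients, one quarter endovascular, roughly 45% abdominal pathology overall,
front-loaded complication hazards (endovascular more so), detection only at
scheduled 6-month visits, no censoring across the first two visits and
markedly rising censoring after 18 months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort_model import EventEntry, PatientRecord
from .msm_markov import (
    N_STATES,
    STATE_INDEX,
    STATES,
    NonHomogeneousMCM,
    OccupancyTable,
    propagate_occupancy,
)

#: Hazard keys, one per allowed non-trivial transition.
TRANSITION_KEYS: tuple[str, ...] = ("H->C", "H->R", "H->D", "C->R", "C->D", "R->D")

_ORIGIN_OF = {k: k.split("->")[0] for k in TRANSITION_KEYS}

#: Aortic-event kind mix on entry to C, by approach. Endoleaks essentially
#: only occur after stent grafting; open-repair complications are new or
#: anastomotic aneurysms and diameter progression.
_AORTIC_KIND_MIX: dict[str, tuple[tuple[str, float], ...]] = {
    "endovascular": (
        ("endoleak_Ia", 0.10),
        ("endoleak_II", 0.55),
        ("endoleak_III", 0.05),
        ("new_aneurysm", 0.10),
        ("diameter_progression", 0.20),
    ),
    "open": (
        ("new_aneurysm", 0.60),
        ("diameter_progression", 0.40),
    ),
}


class ConfigurationError(ValueError):
    """Raised when a synthetic-cohort configuration violates its invariants."""


def _default_hazards() -> dict[str, tuple[float, ...]]:
    # Front-loaded complication and reintervention hazards with a flatter
    # death hazard, qualitatively matching surveillance experience after
    # elective aortic repair (most endoleaks surface at the first visits).
    return {
        "H->C": (0.026, 0.034, 0.012, 0.008, 0.006, 0.005),
        "H->R": (0.017, 0.020, 0.008, 0.006, 0.004, 0.003),
        "H->D": (0.005, 0.006, 0.007, 0.008, 0.009, 0.010),
        "C->R": (0.000, 0.080, 0.060, 0.050, 0.040, 0.040),
        "C->D": (0.000, 0.030, 0.030, 0.030, 0.030, 0.030),
        "R->D": (0.020, 0.020, 0.020, 0.020, 0.020, 0.020),
    }


def _default_censor() -> tuple[float, ...]:
    # Complete case over the first two visits; censoring rises markedly
    # beyond 18 months of follow-up.
    return (0.0, 0.0, 0.05, 0.15, 0.20, 0.25)


@dataclass
class SyntheticConfig:
    """Generating parameters for a synthetic surveillance cohort.

    ``hazards`` maps each allowed transition to its per-interval discrete
    probability; ``hazards_endovascular``, when given, overrides the hazards
    for the endovascular stratum (e.g. to emulate their higher early
    complication rate). ``detection`` is ``"visit"`` when events are only
    found at scheduled visits (times recorded at the interval end) or
    ``"exact"`` for continuously observed times.
    """

    n_patients: int = 464
    seed: int = 0
    frac_endovascular: float = 0.25
    frac_abdominal_given_approach: Mapping[str, float] = field(
        default_factory=lambda: {"open": 0.33, "endovascular": 0.81}
    )
    interval_length: float = 6.0
    horizon: float = 36.0
    hazards: Mapping[str, Sequence[float]] = field(default_factory=_default_hazards)
    hazards_endovascular: Mapping[str, Sequence[float]] | None = None
    censor_prob: Sequence[float] = field(default_factory=_default_censor)
    detection: str = "visit"

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.interval_length))

    def _hazard_array(self, hazards: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for key in TRANSITION_KEYS:
            if key not in hazards:
                raise ConfigurationError(f"missing hazard for transition {key}")
            arr = np.atleast_1d(np.asarray(hazards[key], dtype=float))
            if arr.size == 1:
                arr = np.full(self.n_steps, arr[0])
            if arr.size != self.n_steps:
                raise ConfigurationError(
                    f"hazard {key} has {arr.size} entries, expected {self.n_steps}"
                )
            out[key] = arr
        unknown = set(hazards) - set(TRANSITION_KEYS)
        if unknown:
            raise ConfigurationError(f"unknown transition keys: {sorted(unknown)}")
        return out

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.interval_length <= 0:
            raise ConfigurationError("interval_length must be positive")
        steps = self.horizon / self.interval_length
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ConfigurationError("horizon must be a positive multiple of interval_length")
        if not 0 <= self.frac_endovascular <= 1:
            raise ConfigurationError("frac_endovascular must lie in [0, 1]")
        for approach in ("open", "endovascular"):
            f = self.frac_abdominal_given_approach.get(approach)
            if f is None or not 0 <= f <= 1:
                raise ConfigurationError(
                    f"frac_abdominal_given_approach[{approach!r}] must lie in [0, 1]"
                )
        if self.detection not in ("visit", "exact"):
            raise ConfigurationError(f"detection must be 'visit' or 'exact', got {self.detection!r}")
        cens = np.asarray(self.censor_prob, dtype=float)
        if cens.size != self.n_steps:
            raise ConfigurationError(
                f"censor_prob has {cens.size} entries, expected {self.n_steps}"
            )
        for k, c in enumerate(cens, start=1):
            if not 0 <= c <= 1:
                raise ConfigurationError(f"censor_prob outside [0, 1] in interval {k}")
        hazard_sets = [("overall", self.hazards)]
        if self.hazards_endovascular is not None:
            hazard_sets.append(("endovascular", self.hazards_endovascular))
        for label, hz in hazard_sets:
            arrs = self._hazard_array(hz)
            for key, arr in arrs.items():
                for k, v in enumerate(arr, start=1):
                    if not 0 <= v <= 1:
                        raise ConfigurationError(
                            f"{label} hazard {key} outside [0, 1] in interval {k}"
                        )
            for origin in ("H", "C", "R"):
                keys = [k for k in TRANSITION_KEYS if _ORIGIN_OF[k] == origin]
                total = sum(arrs[k] for k in keys)
                bad = np.nonzero(total > 1 + 1e-12)[0]
                if bad.size:
                    raise ConfigurationError(
                        f"{label} outgoing hazards from {origin} "
                        f"({' + '.join(keys)}) sum to {total[bad[0]]:.4f} > 1 "
                        f"in interval {int(bad[0]) + 1}"
                    )


def generating_model(config: SyntheticConfig, *, endovascular: bool = False) -> NonHomogeneousMCM:
    """Transition matrices implied by the configured hazards (no censoring)."""
    config.validate()
    hz = config.hazards
    if endovascular and config.hazards_endovascular is not None:
        hz = config.hazards_endovascular
    arrs = config._hazard_array(hz)
    matrices = []
    for k in range(config.n_steps):
        m = np.zeros((N_STATES, N_STATES))
        hc, hr, hd = arrs["H->C"][k], arrs["H->R"][k], arrs["H->D"][k]
        cr, cd = arrs["C->R"][k], arrs["C->D"][k]
        rd = arrs["R->D"][k]
        m[0] = [1 - hc - hr - hd, hc, hr, hd]
        m[1] = [0.0, 1 - cr - cd, cr, cd]
        m[2] = [0.0, 0.0, 1 - rd, rd]
        m[3] = [0.0, 0.0, 0.0, 1.0]
        matrices.append(m)
    return NonHomogeneousMCM(interval_length=config.interval_length, matrices=tuple(matrices))


def true_occupancy(config: SyntheticConfig) -> OccupancyTable:
    """Exact occupancy implied by the generating hazards, ignoring censoring.

    With stratum-specific hazards the cohort occupancy is the mixture of the
    per-stratum occupancies weighted by the approach fractions (occupancy is
    linear in the initial mixture even though the mixture itself is not a
    Markov chain).
    """
    config.validate()
    occ_open = propagate_occupancy(generating_model(config, endovascular=False))
    if config.hazards_endovascular is None:
        return occ_open
    occ_endo = propagate_occupancy(generating_model(config, endovascular=True))
    f = config.frac_endovascular
    mixed = (1 - f) * occ_open.probs + f * occ_endo.probs
    return OccupancyTable(
        interval_length=config.interval_length, probs=mixed, provenance="exact"
    )


def _draw_categorical(rng: np.random.Generator, items: Sequence[tuple[str, float]]) -> str:
    u = rng.random()
    acc = 0.0
    for name, w in items:
        acc += w
        if u < acc:
            return name
    return items[-1][0]


def _draw_baseline(rng: np.random.Generator, config: SyntheticConfig) -> tuple[str, str, str, float]:
    approach = "endovascular" if rng.random() < config.frac_endovascular else "open"
    level = (
        "abdominal"
        if rng.random() < config.frac_abdominal_given_approach[approach]
        else "thoracic"
    )
    if approach == "endovascular":
        pathology = _draw_categorical(
            rng, (("aneurysm", 0.79), ("penetrating_aortic_ulcer", 0.21))
        )
        age = rng.normal(74.0, 8.0)
    else:
        pathology = _draw_categorical(
            rng, (("aneurysm", 0.94), ("leriche", 0.03), ("penetrating_aortic_ulcer", 0.03))
        )
        age = rng.normal(65.0, 11.0)
    return approach, level, pathology, float(np.clip(age, 18.0, 95.0))


def generate_cohort(config: SyntheticConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` synthetic patient records.

    Every patient starts healthy at discharge. Each patient uses a dedicated
    random substream keyed by ``(seed, patient index)``, so the same
    (config, seed) pair reproduces the identical cohort and cohorts are
    stable under reordering. A censor draw ends follow-up at the interval
    start (the interval's transition is never observed); a death ends
    follow-up at the death time with the remaining trajectory pinned at D.
    """
    config.validate()
    L = config.interval_length
    n_steps = config.n_steps
    cens = np.asarray(config.censor_prob, dtype=float)
    arrs_open = config._hazard_array(config.hazards)
    arrs_endo = (
        config._hazard_array(config.hazards_endovascular)
        if config.hazards_endovascular is not None
        else arrs_open
    )

    cohort: list[PatientRecord] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        approach, level, pathology, age = _draw_baseline(rng, config)
        arrs = arrs_endo if approach == "endovascular" else arrs_open

        state = STATE_INDEX["H"]
        states: list[str] = ["H"]
        events: list[EventEntry] = []
        followup_end = config.horizon
        died = False
        for k in range(1, n_steps + 1):
            ts, tk = (k - 1) * L, k * L
            if rng.random() < cens[k - 1]:
                followup_end = ts
                break
            origin = STATES[state]
            if origin == "H":
                moves = (("C", arrs["H->C"][k - 1]), ("R", arrs["H->R"][k - 1]),
                         ("D", arrs["H->D"][k - 1]))
            elif origin == "C":
                moves = (("R", arrs["C->R"][k - 1]), ("D", arrs["C->D"][k - 1]))
            else:  # R
                moves = (("D", arrs["R->D"][k - 1]),)
            u = rng.random()
            dest = origin
            acc = 0.0
            for name, w in moves:
                acc += w
                if u < acc:
                    dest = name
                    break
            if dest != origin:
                if config.detection == "visit":
                    t_event = tk
                else:
                    t_event = ts + L * (1.0 - rng.random())  # uniform in (ts, tk]
                if dest == "C":
                    kind = _draw_categorical(rng, _AORTIC_KIND_MIX[approach])
                    delta = None
                    if kind == "diameter_progression":
                        delta = 10.0 + float(rng.exponential(5.0))
                    events.append(EventEntry(kind=kind, time_months=t_event,
                                             diameter_delta_mm=delta))
                elif dest == "R":
                    events.append(EventEntry(kind="reintervention", time_months=t_event))
                else:
                    events.append(EventEntry(kind="death", time_months=t_event))
                    followup_end = t_event
                    died = True
            state = STATE_INDEX[dest]
            states.append(dest)
            if died:
                states.extend(["D"] * (n_steps - k))
                break

        # imaging-availability criterion: boundaries observed with CTA; death
        # ascertainment needs no imaging, so deceased patients keep the
        # 2-visit minimum and the cascade does not drop early deaths
        visits = int(math.floor(followup_end / L + 1e-9))
        if died:
            visits = max(visits, 2)

        cohort.append(
            PatientRecord(
                patient_id=f"SYN{i:05d}",
                approach=approach,
                level=level,
                pathology=pathology,
                age_years=round(age, 1),
                n_followup_visits_with_cta=visits,
                events=tuple(events),
                followup_end=followup_end,
                true_states=tuple(states),
            )
        )
    return cohort
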