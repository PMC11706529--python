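"""From-scratch Kaplan–Meier product-limit estimation with risk tables.

S(t) = prod over event times u <= t of (1 - d_u / n_u), with d_u events and
n_u subjects at risk just before u. Ties between events and censorings at
the same time are resolved events-first (the censored subjects are still at
risk at that time). 95% confidence bands use Greenwood's variance on the
log(-log) (complementary log-log) scale, so the bands stay inside [0, 1].

Curves can be computed per outcome and stratified by surgical approach or
anatomical level, together with number-at-risk / cumulative-event tables on
a 6-month grid — the layout of the usual surveillance follow-up figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort_model import (
    DIAMETER_PROGRESSION_THRESHOLD_MM,
    ENDOLEAK_KINDS,
    PatientRecord,
    derive_outcomes,
)

#: Valid stratification factors for km_by_strata.
STRATA_FACTORS: tuple[str, ...] = ("none", "approach", "level")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate on the observed time grid with bookkeeping."""

    outcome_label: str
    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n_censor: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    strata_label: str | None = None

    @property
    def n_subjects(self) -> int:
        return int(self.n_risk[0])

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (1 before the first time)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "n_censor": self.n_censor,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )
        df.insert(0, "outcome", self.outcome_label)
        df.insert(1, "stratum", self.strata_label if self.strata_label is not None else "all")
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def km_estimate(
    durations: Sequence[float],
    event_observed: Sequence[bool],
    *,
    outcome_label: str = "",
    strata_label: str | None = None,
    alpha: float = 0.05,
) -> KMCurve:
    """Kaplan–Meier product-limit estimate with Greenwood log(-log) bands."""
    t = np.asarray(durations, dtype=float)
    e = np.asarray(event_observed, dtype=bool)
    if t.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    if t.shape != e.shape:
        raise ValueError("durations and event_observed must have equal length")
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("durations must be finite and non-negative")

    uniq = np.unique(t)
    if uniq[0] > 0:
        times = np.concatenate(([0.0], uniq))
    else:
        times = uniq
    # events-first tie convention: subjects censored at u are at risk at u
    n_risk = (t[None, :] >= times[:, None]).sum(axis=1)
    d = np.array([(e & (t == u)).sum() for u in times])
    c = np.array([((~e) & (t == u)).sum() for u in times])

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_risk > 0, d / np.maximum(n_risk, 1), 0.0)
        survival = np.cumprod(1.0 - frac)
        # Greenwood variance accumulated on the event times only
        term = np.zeros_like(survival)
        has_events = d > 0
        saturated = has_events & (d == n_risk)
        partial = has_events & ~saturated
        term[partial] = d[partial] / (n_risk[partial] * (n_risk[partial] - d[partial]))
        term[saturated] = np.inf
        cumvar = np.cumsum(term)

        z = norm.ppf(1 - alpha / 2)
        ci_low = np.empty_like(survival)
        ci_high = np.empty_like(survival)
        interior = (survival > 0) & (survival < 1) & np.isfinite(cumvar)
        logS = np.log(survival[interior])
        se = np.sqrt(cumvar[interior]) / np.abs(logS)
        ci_low[interior] = survival[interior] ** np.exp(z * se)
        ci_high[interior] = survival[interior] ** np.exp(-z * se)
        ci_low[survival >= 1] = 1.0
        ci_high[survival >= 1] = 1.0
        dead_band = (survival <= 0) | ~np.isfinite(cumvar)
        ci_low[dead_band] = 0.0
        ci_high[dead_band] = np.where(survival[dead_band] > 0, survival[dead_band], 0.0)

    return KMCurve(
        outcome_label=outcome_label,
        times=times,
        n_risk=n_risk.astype(int),
        n_event=d.astype(int),
        n_censor=c.astype(int),
        survival=survival,
        ci_low=ci_low,
        ci_high=ci_high,
        strata_label=strata_label,
    )


# ---------------------------------------------------------------------------
# outcome selectors: PatientRecord -> (duration, event observed)


def _first_time_of_kinds(p: PatientRecord, kinds: Sequence[str]) -> float | None:
    times = [
        ev.time_months
        for ev in p.events
        if ev.kind in kinds
        and not (
            ev.kind == "diameter_progression"
            and (ev.diameter_delta_mm is None
                 or ev.diameter_delta_mm < DIAMETER_PROGRESSION_THRESHOLD_MM)
        )
    ]
    return min(times) if times else None


def _from_time(p: PatientRecord, t: float | None) -> tuple[float, bool]:
    return (t, True) if t is not None else (p.followup_end, False)


def _sel_primary(p: PatientRecord) -> tuple[float, bool]:
    return _from_time(p, derive_outcomes(p).primary_composite_time)


def _sel_death(p: PatientRecord) -> tuple[float, bool]:
    return _from_time(p, derive_outcomes(p).death_time)


def _sel_aortic(p: PatientRecord) -> tuple[float, bool]:
    return _from_time(p, derive_outcomes(p).aortic_event_time)


def _sel_reintervention(p: PatientRecord) -> tuple[float, bool]:
    return _from_time(p, derive_outcomes(p).reintervention_time)


OUTCOME_SELECTORS: dict[str, Callable[[PatientRecord], tuple[float, bool]]] = {
    "primary_composite": _sel_primary,
    "death": _sel_death,
    "aortic_event": _sel_aortic,
    "reintervention": _sel_reintervention,
    "endoleak": lambda p: _from_time(p, _first_time_of_kinds(p, ENDOLEAK_KINDS)),
    "new_aneurysm": lambda p: _from_time(p, _first_time_of_kinds(p, ("new_aneurysm",))),
    "diameter_progression": lambda p: _from_time(
        p, _first_time_of_kinds(p, ("diameter_progression",))
    ),
}


def _split_strata(
    cohort: Sequence[PatientRecord], strata: str
) -> list[tuple[str | None, list[PatientRecord]]]:
    if strata == "none":
        return [(None, list(cohort))]
    if strata == "approach":
        keys = ("open", "endovascular")
        return [(k, [p for p in cohort if p.approach == k]) for k in keys]
    if strata == "level":
        keys = ("thoracic", "abdominal")
        return [(k, [p for p in cohort if p.level == k]) for k in keys]
    raise ValueError(f"unknown stratum {strata!r}; choose one of {STRATA_FACTORS}")


def km_by_strata(
    cohort: Sequence[PatientRecord],
    outcome_selector: str
    | Mapping[str, Callable[[PatientRecord], tuple[float, bool]]]
    | None = None,
    strata: str = "none",
    *,
    grid_interval: float = 6.0,
    alpha: float = 0.05,
) -> tuple[list[KMCurve], pd.DataFrame]:
    """One KM curve per outcome per stratum, plus a 6-month-grid risk table.

    ``outcome_selector`` may be an outcome name, a mapping label -> selector
    callable, or None for the full standard set (primary composite, death,
    aortic events, reintervention, endoleak, new aneurysm, diameter
    progression). The grid table carries number at risk, cumulative events,
    cumulative censorings, and the survival estimate at each grid time.
    """
    if outcome_selector is None:
        selectors = dict(OUTCOME_SELECTORS)
    elif isinstance(outcome_selector, str):
        if outcome_selector not in OUTCOME_SELECTORS:
            raise ValueError(
                f"unknown outcome {outcome_selector!r}; "
                f"choose one of {sorted(OUTCOME_SELECTORS)}"
            )
        selectors = {outcome_selector: OUTCOME_SELECTORS[outcome_selector]}
    else:
        selectors = dict(outcome_selector)

    groups = _split_strata(cohort, strata)
    curves: list[KMCurve] = []
    for label, fn in selectors.items():
        for stratum, patients in groups:
            if not patients:
                continue
            pairs = [fn(p) for p in patients]
            curves.append(
                km_estimate(
                    [t for t, _ in pairs],
                    [ev for _, ev in pairs],
                    outcome_label=label,
                    strata_label=stratum,
                    alpha=alpha,
                )
            )
    grid = km_grid_table(curves, grid_interval=grid_interval)
    return curves, grid


def km_grid_table(curves: Iterable[KMCurve], *, grid_interval: float = 6.0) -> pd.DataFrame:
    """At-risk / cumulative-event summaries of KM curves at grid times."""
    rows = []
    for curve in curves:
        horizon = float(curve.times[-1])
        n_grid = int(np.floor(horizon / grid_interval + 1e-9))
        for g in range(n_grid + 1):
            t = g * grid_interval
            cum_events = int(curve.n_event[curve.times <= t].sum())
            cum_censored = int(curve.n_censor[curve.times <= t].sum())
            rows.append(
                {
                    "outcome": curve.outcome_label,
                    "stratum": curve.strata_label if curve.strata_label is not None else "all",
                    "months": t,
                    "n_risk": curve.n_subjects - cum_events - cum_censored,
                    "cum_events": cum_events,
                    "cum_censored": cum_censored,
                    "survival": curve.survival_at(t),
                }
            )
    return pd.DataFrame(rows)


def curves_to_frame(curves: Iterable[KMCurve]) -> pd.DataFrame:
    """Concatenate curves into one long-format frame for CSV export."""
    frames = [c.to_frame() for c in curves]
    if not frames:
        return pd.DataFrame(
            columns=["outcome", "stratum", "time", "n_risk", "n_event",
                     "n_censor", "survival", "ci_low", "ci_high"]
        )
    return pd.concat(frames, ignore_index=True)
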