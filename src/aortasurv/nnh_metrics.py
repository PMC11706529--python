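"""Number needed to harm (NNH) for skipped surveillance visits.

NNH is defined here as the reciprocal of the cumulative harm-state occupancy
at the skipped-visit time: the absolute risk that a patient attending that
visit would be found in one of the chosen harm states (complication C,
reintervention indication R, death D). This equates the missed-visit excess
risk with the full occupancy at the visit — a deliberate worst-case reading
in which every harmful finding at the skipped visit goes unnoticed and
unresolved. Every report carries this assumption explicitly.

Both the two-decimal reciprocal (e.g. 59.88) and the ceiling patient count
(60: the number of whole patients who must skip the visit for one harm to be
missed) are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .msm_markov import STATES, NonHomogeneousMCM, OccupancyTable, propagate_occupancy

#: States a skipped visit can fail to detect; H is by definition not a harm.
HARM_STATES: tuple[str, ...] = ("C", "R", "D")

ASSUMPTION_NOTE = (
    "worst-case: every patient occupying a harm state at the skipped visit "
    "is assumed to go unnoticed and unresolved"
)


class NoHarmError(ValueError):
    """Raised when the harm-state occupancy is zero and NNH is undefined."""


@dataclass(frozen=True)
class NNHResult:
    """Absolute risk at a skipped visit over a harm-state set, and its reciprocal."""

    harm_states: frozenset[str]
    at_step: int
    months: float
    absolute_risk: float
    nnh: float
    nnh_ceiling: int
    subgroup_label: str | None = None
    assumption_note: str = ASSUMPTION_NOTE

    @property
    def nnh_rounded(self) -> float:
        """Two-decimal reciprocal for reporting (e.g. 59.88)."""
        return round(self.nnh, 2)

    def to_row(self) -> dict:
        return {
            "harm_states": "+".join(s for s in STATES if s in self.harm_states),
            "months": self.months,
            "absolute_risk": self.absolute_risk,
            "nnh": self.nnh_rounded,
            "nnh_ceiling": self.nnh_ceiling,
            "subgroup": self.subgroup_label if self.subgroup_label is not None else "all",
            "assumption_note": self.assumption_note,
        }


def nnh(
    occupancy: OccupancyTable,
    harm_states: Iterable[str],
    at_step: int,
    *,
    subgroup_label: str | None = None,
) -> NNHResult:
    """NNH at interval boundary ``at_step`` over the given harm states.

    absolute_risk is the summed occupancy of the harm states at that step;
    nnh is its exact reciprocal (nnh * absolute_risk == 1 before rounding).
    Zero harm occupancy raises :class:`NoHarmError` rather than returning
    infinity.
    """
    harm = frozenset(harm_states)
    if not harm:
        raise ValueError("harm_states must be non-empty")
    unknown = harm - set(HARM_STATES)
    if unknown:
        raise ValueError(
            f"invalid harm states {sorted(unknown)}; allowed: {HARM_STATES} (H is never a harm)"
        )
    if not 0 <= at_step <= occupancy.n_steps:
        raise ValueError(
            f"at_step {at_step} outside the occupancy table (0..{occupancy.n_steps})"
        )
    risk = sum(occupancy.occupancy(s, at_step) for s in harm)
    if risk == 0:
        raise NoHarmError(
            f"no harm-state occupancy at step {at_step}; NNH undefined"
        )
    return NNHResult(
        harm_states=harm,
        at_step=at_step,
        months=at_step * occupancy.interval_length,
        absolute_risk=risk,
        nnh=1.0 / risk,
        nnh_ceiling=math.ceil(1.0 / risk),
        subgroup_label=subgroup_label,
    )


def compare_subgroup_nnh(
    models: Mapping[str, NonHomogeneousMCM] | Sequence[tuple[str, NonHomogeneousMCM]],
    harm_states: Iterable[str],
    at_step: int,
    *,
    initial: Sequence[float] | None = None,
) -> dict[str, NNHResult]:
    """Propagate each labelled subgroup model and compute its NNH.

    ``models`` is a mapping or a sequence of (label, model) pairs; duplicate
    labels are an error. Results are keyed by subgroup label.
    """
    if isinstance(models, Mapping):
        pairs = list(models.items())
    else:
        pairs = list(models)
    labels = [label for label, _ in pairs]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate subgroup labels: {dupes}")
    out: dict[str, NNHResult] = {}
    for label, model in pairs:
        occ = propagate_occupancy(model, initial)
        out[label] = nnh(occ, harm_states, at_step, subgroup_label=label)
    return out


def nnh_report_frame(results: Iterable[NNHResult]) -> pd.DataFrame:
    """Long-format NNH report for CSV export."""
    rows = [r.to_row() for r in results]
    return pd.DataFrame(
        rows,
        columns=["harm_states", "months", "absolute_risk", "nnh", "nnh_ceiling",
                 "subgroup", "assumption_note"],
    )
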