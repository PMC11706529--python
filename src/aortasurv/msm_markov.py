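"""Discrete-time non-homogeneous Markov chain over {H, C, R, D}.

Follow-up after elective aortic surgery is discretized into fixed-length
intervals (6 months by default, matching the standard first-visit schedule).
At each interval boundary a patient occupies exactly one of four mutually
exclusive states:

* ``H`` — healthy: no aortic event, no reintervention, alive;
* ``C`` — complication: at least one aortic event (endoleak, new/anastomotic
  aneurysm, or qualifying diameter progression) but no reintervention yet;
* ``R`` — reintervened: received an aortic reintervention, alive;
* ``D`` — dead (any cause).

Severity is monotone: patients never move back toward ``H`` and ``D`` is
absorbing, so the allowed transition graph is upper-triangular in the state
order above. Because event and reintervention rates visibly change over
follow-up, one transition matrix is estimated *per interval* (a
non-homogeneous chain) rather than a single time-constant matrix.

This module owns the state space, the interval-count sufficient statistics,
the maximum-likelihood per-interval transition estimator, exact occupancy
propagation, Monte-Carlo cohort simulation, and the CSV interchange formats
for matrices and occupancy tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_model import OutcomeTimes

logger = logging.getLogger(__name__)

#: Model states in severity order.
STATES: tuple[str, ...] = ("H", "C", "R", "D")
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}
N_STATES: int = len(STATES)

#: Allowed (origin, destination) pairs: severity never decreases, D absorbs.
ALLOWED_TRANSITIONS: frozenset[tuple[str, str]] = frozenset(
    (a, b) for i, a in enumerate(STATES) for j, b in enumerate(STATES) if j >= i
)

#: Boolean mask of allowed cells in STATES order (upper triangular).
ALLOWED_MASK: np.ndarray = np.triu(np.ones((N_STATES, N_STATES), dtype=bool))
ALLOWED_MASK.setflags(write=False)

_ROW_SUM_ATOL = 1e-12
_OCCUPANCY_ATOL = 1e-9


def validate_transition_matrix(matrix: np.ndarray, *, atol: float = _ROW_SUM_ATOL) -> np.ndarray:
    """Check that ``matrix`` is a valid 4x4 transition matrix.

    Rows must sum to 1 within ``atol``, all entries must lie in [0, 1], and
    structurally disallowed cells (toward lower severity) must be exactly 0.
    Returns the matrix as a read-only float array.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (N_STATES, N_STATES):
        raise ValueError(f"transition matrix must be {N_STATES}x{N_STATES}, got {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("transition matrix contains non-finite entries")
    if np.any(m < -atol) or np.any(m > 1 + atol):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if np.any(m[~ALLOWED_MASK] != 0.0):
        bad = np.argwhere((~ALLOWED_MASK) & (m != 0.0))[0]
        raise ValueError(
            f"disallowed transition {STATES[bad[0]]}->{STATES[bad[1]]} has nonzero probability"
        )
    rowsum = m.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > atol):
        bad_row = int(np.argmax(np.abs(rowsum - 1.0)))
        raise ValueError(
            f"row {STATES[bad_row]} sums to {rowsum[bad_row]!r}, not 1 within {atol}"
        )
    out = m.copy()
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class NonHomogeneousMCM:
    """Ordered per-interval transition matrices sharing one state space.

    ``matrices[k]`` governs movement across interval ``k+1``, i.e. from the
    boundary at ``k * interval_length`` months to the next one.
    """

    interval_length: float
    matrices: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if self.interval_length <= 0:
            raise ValueError("interval_length must be positive")
        if len(self.matrices) == 0:
            raise ValueError("model needs at least one transition matrix")
        object.__setattr__(
            self, "matrices", tuple(validate_transition_matrix(m) for m in self.matrices)
        )

    @property
    def n_steps(self) -> int:
        return len(self.matrices)

    @property
    def horizon(self) -> float:
        return self.n_steps * self.interval_length

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per (interval, origin) with destination columns."""
        rows = []
        for k, m in enumerate(self.matrices, start=1):
            for i, origin in enumerate(STATES):
                rows.append(
                    {"interval": k, "origin": origin, **{s: m[i, j] for j, s in enumerate(STATES)}}
                )
        return pd.DataFrame(rows, columns=["interval", "origin", *STATES])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, interval_length: float = 6.0) -> "NonHomogeneousMCM":
        required = {"interval", "origin", *STATES}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"transition-matrix table missing columns: {sorted(missing)}")
        matrices = []
        for k, grp in frame.groupby("interval", sort=True):
            m = np.zeros((N_STATES, N_STATES))
            seen = set()
            for _, row in grp.iterrows():
                origin = row["origin"]
                if origin not in STATE_INDEX:
                    raise ValueError(f"interval {k}: unknown origin state {origin!r}")
                seen.add(origin)
                m[STATE_INDEX[origin]] = [float(row[s]) for s in STATES]
            if seen != set(STATES):
                raise ValueError(f"interval {k}: missing origin rows {sorted(set(STATES) - seen)}")
            matrices.append(m)
        return cls(interval_length=interval_length, matrices=tuple(matrices))

    @classmethod
    def from_csv(cls, path, *, interval_length: float = 6.0) -> "NonHomogeneousMCM":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"), interval_length=interval_length)


@dataclass(frozen=True)
class OccupancyTable:
    """State occupancy (probability or relative frequency) per interval boundary.

    Row ``k`` of ``probs`` is the distribution over STATES at ``k *
    interval_length`` months. ``provenance`` is ``"exact"`` for matrix-product
    propagation and ``"simulated"`` for Monte-Carlo relative frequencies, in
    which case ``n`` and ``seed`` record the simulation settings.
    """

    interval_length: float
    probs: np.ndarray
    provenance: str = "exact"
    n: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != N_STATES:
            raise ValueError(f"occupancy must be (steps+1) x {N_STATES}, got {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("occupancy values must lie in [0, 1]")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > _OCCUPANCY_ATOL):
            raise ValueError("each occupancy row must sum to 1")
        d = p[:, STATE_INDEX["D"]]
        h = p[:, STATE_INDEX["H"]]
        if np.any(np.diff(d) < -_OCCUPANCY_ATOL):
            raise ValueError("death occupancy must be non-decreasing")
        if np.any(np.diff(h) > _OCCUPANCY_ATOL):
            raise ValueError("healthy occupancy must be non-increasing")
        if self.provenance not in ("exact", "simulated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "simulated" and (self.n is None or self.n < 1):
            raise ValueError("simulated occupancy requires n >= 1")
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    @property
    def n_steps(self) -> int:
        return self.probs.shape[0] - 1

    @property
    def months(self) -> np.ndarray:
        return np.arange(self.probs.shape[0]) * self.interval_length

    def occupancy(self, state: str, step: int) -> float:
        """Occupancy of ``state`` at interval boundary ``step``."""
        return float(self.probs[step, STATE_INDEX[state]])

    def row(self, step: int) -> dict[str, float]:
        return {s: float(self.probs[step, i]) for i, s in enumerate(STATES)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(STATES))
        df.insert(0, "months", self.months)
        df.insert(0, "step", np.arange(self.probs.shape[0]))
        df["provenance"] = self.provenance
        df["n"] = self.n
        df["seed"] = self.seed
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, interval_length: float = 6.0) -> "OccupancyTable":
        missing = {"step", *STATES} - set(frame.columns)
        if missing:
            raise ValueError(f"occupancy table missing columns: {sorted(missing)}")
        frame = frame.sort_values("step")
        provenance = str(frame["provenance"].iloc[0]) if "provenance" in frame else "exact"
        n = None
        seed = None
        if "n" in frame and pd.notna(frame["n"].iloc[0]):
            n = int(frame["n"].iloc[0])
        if "seed" in frame and pd.notna(frame["seed"].iloc[0]):
            seed = int(frame["seed"].iloc[0])
        return cls(
            interval_length=interval_length,
            probs=frame[list(STATES)].to_numpy(dtype=float),
            provenance=provenance,
            n=n,
            seed=seed,
        )

    @classmethod
    def from_csv(cls, path, *, interval_length: float = 6.0) -> "OccupancyTable":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"), interval_length=interval_length)


@dataclass
class IntervalCounts:
    """Sufficient statistics for one interval of the transition estimator.

    ``transitions[i, j]`` counts patients observed in state ``i`` at the
    interval start and state ``j`` at its end (diagonal = stayers).
    ``n_censored[i]`` counts patients in state ``i`` at the interval start
    whose follow-up ended strictly inside the interval; they contribute to
    ``n_at_risk`` but not to any transition.
    """

    interval: int
    n_at_risk: np.ndarray = field(default_factory=lambda: np.zeros(N_STATES, dtype=int))
    n_censored: np.ndarray = field(default_factory=lambda: np.zeros(N_STATES, dtype=int))
    transitions: np.ndarray = field(
        default_factory=lambda: np.zeros((N_STATES, N_STATES), dtype=int)
    )

    def validate(self) -> None:
        if self.interval < 1:
            raise ValueError("interval index is 1-based")
        for name, arr in (("n_at_risk", self.n_at_risk), ("n_censored", self.n_censored)):
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"negative count in {name} for interval {self.interval}")
        if np.any(self.transitions < 0):
            raise ValueError(f"negative transition count in interval {self.interval}")
        if np.any(self.transitions[~ALLOWED_MASK] != 0):
            raise ValueError(f"interval {self.interval}: counts in a disallowed transition cell")
        out = self.transitions.sum(axis=1) + self.n_censored
        if np.any(out > self.n_at_risk):
            raise ValueError(
                f"interval {self.interval}: destination counts plus censored exceed n_at_risk"
            )

    def to_row_dicts(self) -> list[dict]:
        rows = []
        for i, origin in enumerate(STATES):
            rows.append(
                {
                    "interval": self.interval,
                    "origin": origin,
                    "n_at_risk": int(self.n_at_risk[i]),
                    "n_censored": int(self.n_censored[i]),
                    **{f"to_{s}": int(self.transitions[i, j]) for j, s in enumerate(STATES)},
                }
            )
        return rows


def interval_counts_frame(counts: Sequence[IntervalCounts]) -> pd.DataFrame:
    rows: list[dict] = []
    for c in counts:
        rows.extend(c.to_row_dicts())
    return pd.DataFrame(rows)


def _state_at(outcome: "OutcomeTimes", t: float) -> int:
    """Severity-ordered state implied by an outcome record at boundary time t.

    Worst state wins when several component times fall at or before t
    (D > R > C), which also lands a same-interval complication-plus-
    reintervention patient directly in R.
    """
    if outcome.death_time is not None and outcome.death_time <= t:
        return STATE_INDEX["D"]
    if outcome.reintervention_time is not None and outcome.reintervention_time <= t:
        return STATE_INDEX["R"]
    if outcome.aortic_event_time is not None and outcome.aortic_event_time <= t:
        return STATE_INDEX["C"]
    return STATE_INDEX["H"]


def discretize(
    outcomes: Iterable["OutcomeTimes"],
    interval_length: float = 6.0,
    horizon: float = 36.0,
) -> list[IntervalCounts]:
    """Tabulate per-interval transition counts from derived outcome times.

    Intervals are half-open on the left, ``(t, t + interval_length]``: an
    event at exactly 6.0 months belongs to the first interval, so "at 6
    months" summaries include the 6-month visit findings. A patient censored
    strictly inside an interval joins that interval's risk set as censored
    (no transition observed) and is absent thereafter; a death inside the
    interval is a fully observed transition to D regardless of when imaging
    follow-up stopped.
    """
    if interval_length <= 0:
        raise ValueError("interval_length must be positive")
    n_steps_f = horizon / interval_length
    n_steps = int(round(n_steps_f))
    if n_steps < 1 or abs(n_steps_f - n_steps) > 1e-9:
        raise ValueError(
            f"horizon ({horizon}) must be a positive multiple of interval_length ({interval_length})"
        )
    counts = [IntervalCounts(interval=k) for k in range(1, n_steps + 1)]
    d_idx = STATE_INDEX["D"]
    for o in outcomes:
        ct = o.censor_time
        dt = o.death_time
        for k in range(1, n_steps + 1):
            ts = (k - 1) * interval_length
            tk = k * interval_length
            c = counts[k - 1]
            if dt is not None and dt <= ts:
                # already absorbed: complete observation, trivial D->D
                c.n_at_risk[d_idx] += 1
                c.transitions[d_idx, d_idx] += 1
                continue
            origin = _state_at(o, ts)
            if dt is not None and dt <= tk:
                c.n_at_risk[origin] += 1
                c.transitions[origin, d_idx] += 1
            elif ct >= tk:
                c.n_at_risk[origin] += 1
                c.transitions[origin, _state_at(o, tk)] += 1
            elif ct > ts:
                c.n_at_risk[origin] += 1
                c.n_censored[origin] += 1
            else:
                break  # follow-up ended at or before this interval's start
    return counts


def counts_from_trajectories(
    trajectories: Iterable[Sequence[str] | Sequence[int]],
    n_steps: int,
) -> list[IntervalCounts]:
    """Interval counts by direct counting of stored state trajectories.

    Each trajectory lists the occupied state at boundaries 0..m (m <= n_steps);
    a trajectory shorter than the horizon is treated as censored at its last
    recorded boundary and contributes no further observations.
    """
    counts = [IntervalCounts(interval=k) for k in range(1, n_steps + 1)]
    for traj in trajectories:
        idx = [STATE_INDEX[s] if isinstance(s, str) else int(s) for s in traj]
        for k in range(1, min(len(idx) - 1, n_steps) + 1):
            c = counts[k - 1]
            c.n_at_risk[idx[k - 1]] += 1
            c.transitions[idx[k - 1], idx[k]] += 1
    return counts


def estimate_transition_matrices(
    counts: Sequence[IntervalCounts],
    interval_length: float = 6.0,
) -> NonHomogeneousMCM:
    """Per-interval maximum-likelihood transition matrices from counts.

    For each interval and origin, p(origin->dest) = transitions / (n_at_risk
    − n_censored_in_interval); the diagonal receives the remainder. An origin
    with an empty effective risk set yields the identity row (no information,
    no movement) with a logged warning.
    """
    matrices = []
    for c in counts:
        c.validate()
        m = np.zeros((N_STATES, N_STATES))
        for i in range(N_STATES):
            n_eff = int(c.n_at_risk[i]) - int(c.n_censored[i])
            if n_eff <= 0:
                m[i, i] = 1.0
                if c.n_at_risk[i] == 0:
                    logger.warning(
                        "interval %d: empty risk set for state %s; using identity row",
                        c.interval,
                        STATES[i],
                    )
                continue
            off = 0.0
            for j in range(N_STATES):
                if j == i or not ALLOWED_MASK[i, j]:
                    continue
                p = c.transitions[i, j] / n_eff
                m[i, j] = p
                off += p
            m[i, i] = 1.0 - off
        matrices.append(m)
    return NonHomogeneousMCM(interval_length=interval_length, matrices=tuple(matrices))


def propagate_occupancy(
    model: NonHomogeneousMCM,
    initial: Sequence[float] | None = None,
) -> OccupancyTable:
    """Exact state occupancy at every boundary by left-multiplying the chain.

    ``initial`` defaults to everyone healthy at discharge, (1, 0, 0, 0).
    """
    if initial is None:
        init = np.zeros(N_STATES)
        init[STATE_INDEX["H"]] = 1.0
    else:
        init = np.asarray(initial, dtype=float)
    if init.shape != (N_STATES,):
        raise ValueError(f"initial distribution must have length {N_STATES}")
    if np.any(init < 0) or abs(init.sum() - 1.0) > _OCCUPANCY_ATOL:
        raise ValueError("initial distribution must be non-negative and sum to 1")
    probs = np.empty((model.n_steps + 1, N_STATES))
    probs[0] = init
    for k, m in enumerate(model.matrices, start=1):
        probs[k] = probs[k - 1] @ m
    return OccupancyTable(
        interval_length=model.interval_length, probs=probs, provenance="exact"
    )


def simulate_cohort(
    model: NonHomogeneousMCM,
    n: int,
    seed: int,
    initial_state: str = "H",
) -> tuple[np.ndarray, OccupancyTable]:
    """Simulate ``n`` independent patient trajectories through the chain.

    Returns the (n, n_steps+1) integer state-trajectory array and the
    occupancy table of exact relative frequencies per boundary.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_steps = model.n_steps
    traj = np.empty((n, n_steps + 1), dtype=np.int8)
    traj[:, 0] = STATE_INDEX[initial_state]
    for k, m in enumerate(model.matrices, start=1):
        cum = np.cumsum(m, axis=1)
        u = rng.random(n)
        # next state = first cumulative cell exceeding the uniform draw
        traj[:, k] = (u[:, None] > cum[traj[:, k - 1]]).sum(axis=1)
    freqs = np.empty((n_steps + 1, N_STATES))
    for k in range(n_steps + 1):
        freqs[k] = np.bincount(traj[:, k], minlength=N_STATES) / n
    table = OccupancyTable(
        interval_length=model.interval_length,
        probs=freqs,
        provenance="simulated",
        n=n,
        seed=seed,
    )
    return traj, table
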