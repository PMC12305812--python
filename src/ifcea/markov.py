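"""Markov state-transition model over anaemia severity.

Four ordered states (none < mild < moderate < severe) evolve in
six-month cycles under a row-stochastic 4x4 transition matrix, one
matrix per study arm (IFC vs non-IFC). By default transitions are
restricted to adjacent severity states within a cycle (a birth-death
chain), the conservative reading of severity shifting "one step at a
time" over six months; the restriction is configurable.

Transition probabilities are parameterised through per-cycle rates via
the standard exponential conversion p = 1 - exp(-rate * t), so that
intervention effects expressed as relative risks act multiplicatively
on rates rather than probabilities.

Because the source transition equations are not published, the chain is
calibrated: worsening rates are fixed at configured values and a scalar
multiplier on the recovery rates is solved by bisection so that the
projected anaemia prevalence at the final cycle matches a target; the
intervention arm is then derived by a relative risk on worsening rates,
itself calibrated to the intervention arm's target end prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import N_STATES, STATE_NAMES

__all__ = [
    "TransitionMatrix",
    "TrajectorySpec",
    "StateTrajectory",
    "TransitionShape",
    "CalibrationResult",
    "CalibrationError",
    "rate_to_probability",
    "probability_to_rate",
    "apply_relative_risk",
    "simulate_cohort_fractions",
    "simulate_individuals",
    "prevalence",
    "calibrate_transitions",
    "calibrate_relative_risk",
]

_ROW_TOL = 1e-9


class CalibrationError(RuntimeError):
    """Raised when a calibration target is unreachable within the bracket."""


def rate_to_probability(rate: float, t: float = 1.0) -> float:
    """Convert an event rate into a transition probability over time ``t``.

    Uses the constant-hazard relation ``p = 1 - exp(-rate * t)``.
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if t <= 0:
        raise ValueError(f"t must be positive, got {t}")
    return -np.expm1(-rate * t)


def probability_to_rate(p: float, t: float = 1.0) -> float:
    """Inverse of :func:`rate_to_probability`: ``rate = -ln(1-p)/t``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if t <= 0:
        raise ValueError(f"t must be positive, got {t}")
    if p == 1.0:
        raise ValueError("p = 1 corresponds to an infinite rate")
    return -np.log1p(-p) / t


@dataclass
class TransitionMatrix:
    """Row-stochastic 4x4 one-cycle transition matrix for one arm."""

    p: np.ndarray
    arm: str = ""
    adjacency_restricted: bool = True

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.p.shape != (N_STATES, N_STATES):
            raise ValueError(f"transition matrix must be 4x4, got {self.p.shape}")
        if np.any(self.p < -_ROW_TOL) or np.any(self.p > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = self.p.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _ROW_TOL):
            raise ValueError(f"rows must sum to 1 within {_ROW_TOL}, got {rows}")
        if self.adjacency_restricted:
            for i in range(N_STATES):
                for j in range(N_STATES):
                    if abs(i - j) > 1 and self.p[i, j] != 0.0:
                        raise ValueError(
                            f"non-adjacent transition p[{i}][{j}] must be 0 "
                            "under the adjacency restriction"
                        )

    @classmethod
    def from_rates(
        cls,
        worsening_rates,
        recovery_rates,
        arm: str = "",
        cycle_time: float = 1.0,
    ) -> "TransitionMatrix":
        """Build an adjacent-state matrix from per-cycle rates.

        ``worsening_rates[i]`` is the rate of moving from state i to i+1;
        ``recovery_rates[i]`` the rate from state i+1 to i (i = 0, 1, 2).
        """
        w = np.asarray(worsening_rates, dtype=float)
        r = np.asarray(recovery_rates, dtype=float)
        if w.shape != (3,) or r.shape != (3,):
            raise ValueError("need 3 worsening and 3 recovery rates")
        if np.any(w < 0) or np.any(r < 0):
            raise ValueError("rates must be non-negative")
        p = np.zeros((N_STATES, N_STATES))
        for i in range(N_STATES):
            up = rate_to_probability(w[i], cycle_time) if i < 3 else 0.0
            down = rate_to_probability(r[i - 1], cycle_time) if i > 0 else 0.0
            if up + down > 1.0:
                raise ValueError(
                    f"state {i}: competing transition mass {up + down:.4f} > 1; "
                    "reduce rates or cycle length"
                )
            if i < 3:
                p[i, i + 1] = up
            if i > 0:
                p[i, i - 1] = down
            p[i, i] = 1.0 - up - down
        return cls(p=p, arm=arm, adjacency_restricted=True)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.p, index=STATE_NAMES, columns=STATE_NAMES).to_csv(path)

    @classmethod
    def from_csv(cls, path, arm: str = "", adjacency_restricted: bool = True):
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(
            p=df.to_numpy(dtype=float), arm=arm, adjacency_restricted=adjacency_restricted
        )


@dataclass(frozen=True)
class TrajectorySpec:
    """Projection horizon: number of cycles, cycle length and mode."""

    n_cycles: int = 20
    cycle_days: float = 182.5
    mode: str = "cohort_fractions"  # or "individual_microsim"

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.cycle_days <= 0:
            raise ValueError("cycle_days must be positive")
        if self.mode not in ("cohort_fractions", "individual_microsim"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def horizon_days(self) -> float:
        return self.n_cycles * self.cycle_days


@dataclass
class StateTrajectory:
    """State occupancy fractions at cycles t = 1..n_cycles for one arm."""

    occupancy: np.ndarray  # (n_cycles, 4)
    arm: str = ""
    init: np.ndarray | None = None
    cycle_days: float = 182.5

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.ndim != 2 or self.occupancy.shape[1] != N_STATES:
            raise ValueError("occupancy must be (n_cycles, 4)")
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("each timepoint's occupancy must sum to 1")
        if np.any(self.occupancy < -1e-12) or np.any(self.occupancy > 1 + 1e-12):
            raise ValueError("occupancy fractions must lie in [0, 1]")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def prevalence_series(self) -> np.ndarray:
        """Anaemia prevalence (1 - fraction without anaemia) per cycle."""
        return 1.0 - self.occupancy[:, 0]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy, columns=STATE_NAMES)
        df.insert(0, "cycle", np.arange(1, self.n_cycles + 1))
        df["prevalence"] = self.prevalence_series()
        df["arm"] = self.arm
        return df


def prevalence(occupancy) -> float:
    """Anaemia prevalence of an occupancy 4-vector: 1 - P(no anaemia)."""
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (N_STATES,):
        raise ValueError("occupancy must be a 4-vector")
    if abs(occ.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy must sum to 1")
    return float(1.0 - occ[0])


def apply_relative_risk(m: TransitionMatrix, rr: float) -> TransitionMatrix:
    """Scale worsening-transition rates by a relative risk.

    Each probability of moving toward higher severity is converted to a
    rate, multiplied by ``rr``, and converted back; improving transitions
    are untouched and the diagonal re-absorbs the difference so rows
    still sum to 1.
    """
    if rr < 0:
        raise ValueError(f"relative risk must be non-negative, got {rr}")
    p = m.p.copy()
    for i in range(N_STATES):
        for j in range(N_STATES):
            if j <= i or p[i, j] == 0.0:
                continue
            if p[i, j] >= 1.0:
                p[i, j] = 0.0 if rr == 0.0 else 1.0 - (1.0 - p[i, j]) ** rr
            else:
                # 1-(1-p)^rr == 1-exp(-rr * (-ln(1-p)))
                p[i, j] = -np.expm1(rr * np.log1p(-p[i, j]))
    for i in range(N_STATES):
        off = p[i].sum() - p[i, i]
        if off > 1.0 + _ROW_TOL:
            raise ValueError(
                f"relative risk {rr} makes row {i} off-diagonal mass {off:.4f} > 1"
            )
        p[i, i] = 1.0 - off
    return TransitionMatrix(
        p=p, arm=m.arm, adjacency_restricted=m.adjacency_restricted
    )


def simulate_cohort_fractions(
    init, m: TransitionMatrix, spec: TrajectorySpec | None = None
) -> StateTrajectory:
    """Deterministically project occupancy: occupancy[t] = init @ m^t."""
    if spec is None:
        spec = TrajectorySpec()
    init = np.asarray(init, dtype=float)
    if init.shape != (N_STATES,):
        raise ValueError(f"init must be a 4-vector, got shape {init.shape}")
    if abs(init.sum() - 1.0) > 1e-9:
        raise ValueError("init occupancy must sum to 1")
    occ = np.empty((spec.n_cycles, N_STATES))
    cur = init
    for t in range(spec.n_cycles):
        cur = cur @ m.p
        occ[t] = cur
    return StateTrajectory(
        occupancy=occ, arm=m.arm, init=init, cycle_days=spec.cycle_days
    )


def simulate_individuals(
    states0: np.ndarray,
    m: TransitionMatrix,
    spec: TrajectorySpec | None = None,
    seed: int = 0,
) -> StateTrajectory:
    """Stochastic microsimulation of individual state paths.

    Each child's next state is sampled from its current state's matrix
    row every cycle; returns empirical occupancy fractions per cycle.
    Children are independent chains, so per-cycle state counts are
    exactly binomial around the deterministic projection.
    """
    if spec is None:
        spec = TrajectorySpec()
    rng = np.random.default_rng(seed)
    states = np.asarray(states0, dtype=np.int64).copy()
    if states.ndim != 1 or len(states) == 0:
        raise ValueError("states0 must be a non-empty 1-d integer array")
    if states.min() < 0 or states.max() >= N_STATES:
        raise ValueError("states0 contains out-of-range state codes")
    n = len(states)
    cum = np.cumsum(m.p, axis=1)
    occ = np.empty((spec.n_cycles, N_STATES))
    for t in range(spec.n_cycles):
        u = rng.random(n)
        states = (u[:, None] > cum[states]).sum(axis=1)
        occ[t] = np.bincount(states, minlength=N_STATES) / n
    return StateTrajectory(
        occupancy=occ, arm=m.arm, init=None, cycle_days=spec.cycle_days
    )


@dataclass(frozen=True)
class TransitionShape:
    """Fixed structural rates used by calibration.

    ``worsening_rates`` are per-cycle rates toward higher severity and
    stay fixed; ``recovery_rates`` give the shape of recovery whose
    overall level is solved for. ``anaemic_mix`` splits anaemic mass
    across (mild, moderate, severe) when building an initial occupancy
    from a scalar prevalence; defaults to the survey's conditional mix.
    """

    worsening_rates: tuple = (0.15, 0.20, 0.01)
    recovery_rates: tuple = (0.30, 0.30, 0.50)
    anaemic_mix: tuple = (410 / 1002, 574 / 1002, 18 / 1002)
    arm: str = ""

    def init_occupancy(self, start_prev: float) -> np.ndarray:
        mix = np.asarray(self.anaemic_mix, dtype=float)
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("anaemic_mix must sum to 1")
        return np.concatenate([[1.0 - start_prev], start_prev * mix])


@dataclass
class CalibrationResult:
    """A calibrated matrix plus how it was found."""

    matrix: TransitionMatrix
    multiplier: float
    achieved_end_prevalence: float
    target_end_prevalence: float
    iterations: int
    converged: bool
    bracket: tuple = (0.0, 0.0)

    def __str__(self):
        return (
            f"CalibrationResult(arm={self.matrix.arm!r}, "
            f"multiplier={self.multiplier:.6g}, "
            f"end_prev={self.achieved_end_prevalence:.6f} "
            f"-> target {self.target_end_prevalence:.6f}, "
            f"iters={self.iterations}, converged={self.converged})"
        )


_PREV_TOL = 1e-4
_MULT_TOL = 1e-6
_MAX_MULT = 1e6


def _end_prevalence(init, w, r, n_cycles) -> float:
    m = TransitionMatrix.from_rates(w, r)
    occ = init
    for _ in range(n_cycles):
        occ = occ @ m.p
    return 1.0 - occ[0]


def calibrate_transitions(
    start_prev: float,
    end_prev: float,
    n_cycles: int = 20,
    shape: TransitionShape | None = None,
) -> CalibrationResult:
    """Solve for a recovery-rate multiplier hitting a target end prevalence.

    With worsening rates fixed at ``shape.worsening_rates``, bisects a
    scalar multiplier k on ``shape.recovery_rates`` (monotone: larger k
    means faster recovery, hence lower end prevalence) until the
    projected prevalence after ``n_cycles`` matches ``end_prev`` within
    1e-4; the multiplier bracket is narrowed to 1e-6.

    Raises
    ------
    CalibrationError
        If the target lies outside what any multiplier in [0, 1e6] can
        reach; the message reports the bracket endpoints.
    """
    if not (0.0 < start_prev < 1.0) or not (0.0 < end_prev < 1.0):
        raise ValueError("start_prev and end_prev must lie strictly in (0, 1)")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if shape is None:
        shape = TransitionShape()
    init = shape.init_occupancy(start_prev)
    w = np.asarray(shape.worsening_rates, dtype=float)
    r = np.asarray(shape.recovery_rates, dtype=float)

    def f(k: float) -> float:
        return _end_prevalence(init, w, k * r, n_cycles)

    f0 = f(0.0)
    if abs(f0 - end_prev) <= _PREV_TOL:
        m = TransitionMatrix.from_rates(w, 0.0 * r, arm=shape.arm)
        return CalibrationResult(m, 0.0, f0, end_prev, 0, True, (0.0, 0.0))
    if f0 < end_prev:
        raise CalibrationError(
            f"target end prevalence {end_prev} exceeds the maximum reachable "
            f"{f0:.6f} at zero recovery (bracket [0, 0])"
        )

    lo, hi = 0.0, 1.0
    it = 0
    while f(hi) > end_prev:
        lo, hi = hi, hi * 2.0
        it += 1
        if hi > _MAX_MULT:
            raise CalibrationError(
                f"target end prevalence {end_prev} unreachable: prevalence is "
                f"{f(_MAX_MULT):.6f} at multiplier {_MAX_MULT} "
                f"(bracket [{lo}, {hi}])"
            )
    while hi - lo > _MULT_TOL:
        mid = 0.5 * (lo + hi)
        it += 1
        if f(mid) > end_prev:
            lo = mid
        else:
            hi = mid
    k = 0.5 * (lo + hi)
    achieved = f(k)
    converged = abs(achieved - end_prev) <= _PREV_TOL
    if not converged:
        raise CalibrationError(
            f"bisection converged on multiplier {k:.6g} but end prevalence "
            f"{achieved:.6f} misses target {end_prev} by more than {_PREV_TOL} "
            f"(bracket [{lo:.6g}, {hi:.6g}])"
        )
    m = TransitionMatrix.from_rates(w, k * r, arm=shape.arm)
    return CalibrationResult(m, k, achieved, end_prev, it, converged, (lo, hi))


def calibrate_relative_risk(
    base: TransitionMatrix,
    init,
    end_prev: float,
    n_cycles: int = 20,
    arm: str = "IFC",
) -> tuple[TransitionMatrix, float]:
    """Find the worsening relative risk taking ``base`` to a lower target.

    Bisects rr in (0, 1] (extended upward if the target exceeds the base
    arm's end prevalence) so that ``apply_relative_risk(base, rr)``
    projected from ``init`` reaches ``end_prev`` at cycle ``n_cycles``.
    """
    init = np.asarray(init, dtype=float)

    def f(rr: float) -> float:
        m = apply_relative_risk(base, rr)
        occ = init
        for _ in range(n_cycles):
            occ = occ @ m.p
        return 1.0 - occ[0]

    lo, hi = 0.0, 1.0
    if f(hi) < end_prev:  # target above base arm: rr > 1 needed
        while f(hi) < end_prev:
            lo, hi = hi, hi * 2.0
            if hi > 1e3:
                raise CalibrationError(
                    f"end prevalence {end_prev} unreachable by relative risk "
                    f"(bracket [{lo}, {hi}])"
                )
    if f(1e-12) > end_prev:
        raise CalibrationError(
            f"end prevalence {end_prev} below the minimum reachable "
            f"{f(1e-12):.6f} even as the relative risk vanishes"
        )
    while hi - lo > _MULT_TOL:
        mid = 0.5 * (lo + hi)
        if f(mid) > end_prev:
            hi = mid
        else:
            lo = mid
    rr = 0.5 * (lo + hi)
    achieved = f(rr)
    if abs(achieved - end_prev) > _PREV_TOL:
        raise CalibrationError(
            f"relative-risk bisection missed target {end_prev}: achieved "
            f"{achieved:.6f} at rr={rr:.6g}"
        )
    m = apply_relative_risk(base, rr)
    m.arm = arm
    return m, rr
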