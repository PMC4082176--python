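"""Core dynamics of the illness-death chain and its equilibrium.

The population is split into healthy (w), mentally ill (x), other-cause
deaths (y) and suicides (z).  Two one-year step operators are provided:

``step_no_replacement``
    The closed system: deaths accumulate, and the living population
    w + x decays exponentially whenever any death probability is positive.

``step_with_replacement``
    Each year's deaths are replaced by healthy newborns the following
    year, so y and z are *annual flows* (that year's deaths) rather than
    cumulative stocks and the bookkeeping total w + x + y + z stays at the
    fixed population size Q0.  This system has a unique stationary state,
    available in closed form.

With S = p12 + p32 + p42 (total annual exit probability from the ill
state), the stationary state is proportional to::

    (w, x, y, z)  ∝  (S,  p21,  p31·S + p32·p21,  p41·S + p42·p21)

with normalizer R = (1 + p31 + p41)·S + p21·(1 + p32 + p42), so the
stationary fractions are the components divided by R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .parameters import (
    HONG_KONG_2012,
    HONG_KONG_INITIAL_ILL,
    HONG_KONG_Q0,
    TransitionParameters,
)


class DegenerateChainError(ValueError):
    """The closed-form equilibrium is indeterminate (no exit from the ill
    state, so the printed formula does not define the stationary state)."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested tolerance."""


@dataclass(frozen=True)
class PopulationState:
    """Compartment tallies for one year.

    ``y`` and ``z`` are the deaths *occurring in* year ``n`` under the
    replacement dynamics (annual flows); under the no-replacement dynamics
    they are cumulative stocks.
    """

    w: float
    x: float
    y: float = 0.0
    z: float = 0.0
    n: int = 0

    def __post_init__(self) -> None:
        for name in ("w", "x", "y", "z"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative compartment count: {name}={getattr(self, name)!r}")

    @property
    def total(self) -> float:
        return self.w + self.x + self.y + self.z

    @property
    def living(self) -> float:
        return self.w + self.x

    def fractions(self) -> tuple[float, float, float, float]:
        t = self.total
        return (self.w / t, self.x / t, self.y / t, self.z / t)


def step_with_replacement(
    state: PopulationState, params: TransitionParameters
) -> PopulationState:
    """Advance one year with deaths replaced by healthy newborns.

    Last year's deaths (y, z) re-enter the healthy compartment, so the
    total w + x + y + z is conserved exactly.
    """
    p = params.validate()
    w, x = state.w, state.x
    return PopulationState(
        w=(1.0 - p.p21 - p.p31 - p.p41) * w + p.p12 * x + state.y + state.z,
        x=p.p21 * w + (1.0 - p.p12 - p.p32 - p.p42) * x,
        y=p.p31 * w + p.p32 * x,
        z=p.p41 * w + p.p42 * x,
        n=state.n + 1,
    )


def step_no_replacement(
    state: PopulationState, params: TransitionParameters
) -> PopulationState:
    """Advance one year in the closed system: deaths accumulate."""
    p = params.validate()
    w, x = state.w, state.x
    return PopulationState(
        w=(1.0 - p.p21 - p.p31 - p.p41) * w + p.p12 * x,
        x=p.p21 * w + (1.0 - p.p12 - p.p32 - p.p42) * x,
        y=state.y + p.p31 * w + p.p32 * x,
        z=state.z + p.p41 * w + p.p42 * x,
        n=state.n + 1,
    )


@dataclass(frozen=True)
class EquilibriumResult:
    """Stationary state of the replacement dynamics.

    Fractions are per-compartment shares of the total population Q0; the
    derived rates re-express them in the units conventionally reported
    (suicides per 100,000, other-cause deaths per 1,000, ill share in %).
    """

    w_frac: float
    x_frac: float
    y_frac: float
    z_frac: float
    R: float
    Q0: float
    params: TransitionParameters

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (self.w_frac, self.x_frac, self.y_frac, self.z_frac)

    @property
    def counts(self) -> tuple[float, float, float, float]:
        return tuple(f * self.Q0 for f in self.fractions)  # type: ignore[return-value]

    @property
    def z_count(self) -> float:
        """Annual number of suicides at equilibrium."""
        return self.z_frac * self.Q0

    @property
    def suicide_rate_per_100k(self) -> float:
        return self.z_frac * 100_000.0

    @property
    def other_cause_death_rate_per_1k(self) -> float:
        return self.y_frac * 1_000.0

    @property
    def mentally_ill_percent(self) -> float:
        return self.x_frac * 100.0

    def to_state(self, n: int = 0) -> PopulationState:
        w, x, y, z = self.counts
        return PopulationState(w=w, x=x, y=y, z=z, n=n)

    def summary(self) -> str:
        lines = [
            "Illness-death model equilibrium (with replacement)",
            "=" * 50,
            f"  Q0 (total population)        {self.Q0:,.0f}",
            f"  normalizer R                 {self.R:.6f}",
            "",
            f"  healthy        w = {self.w_frac:.4g} * Q0  ({self.w_frac * self.Q0:,.0f})",
            f"  mentally ill   x = {self.x_frac:.4g} * Q0  ({self.x_frac * self.Q0:,.0f})",
            f"  other deaths   y = {self.y_frac:.4g} * Q0  ({self.y_frac * self.Q0:,.0f}/yr)",
            f"  suicides       z = {self.z_frac:.4g} * Q0  ({self.z_frac * self.Q0:,.0f}/yr)",
            "",
            f"  suicide rate                 {self.suicide_rate_per_100k:.1f} per 100,000",
            f"  other-cause death rate       {self.other_cause_death_rate_per_1k:.2f} per 1,000",
            f"  mentally ill                 {self.mentally_ill_percent:.1f} %",
        ]
        return "\n".join(lines)


def equilibrium_closed_form(
    params: TransitionParameters, Q0: float = HONG_KONG_Q0
) -> EquilibriumResult:
    """Closed-form stationary state of the replacement dynamics.

    Raises
    ------
    DegenerateChainError
        If S = p12 + p32 + p42 = 0 (the ill state traps the living and the
        closed form does not determine the equilibrium).
    """
    p = params.validate()
    S = p.ill_exit
    if S == 0.0:
        raise DegenerateChainError(
            "degenerate chain: p12 + p32 + p42 = 0, the mentally ill state "
            "has no exit and the closed-form equilibrium is indeterminate"
        )
    R = (1.0 + p.p31 + p.p41) * S + p.p21 * (1.0 + p.p32 + p.p42)
    return EquilibriumResult(
        w_frac=S / R,
        x_frac=p.p21 / R,
        y_frac=(p.p31 * S + p.p32 * p.p21) / R,
        z_frac=(p.p41 * S + p.p42 * p.p21) / R,
        R=R,
        Q0=Q0,
        params=p,
    )


@dataclass(frozen=True)
class IterationResult:
    """Outcome of power iteration of the yearly map."""

    fractions: tuple[float, float, float, float]
    years_to_converge: int
    residual: float  # max abs per-compartment change at the last step, / Q0
    Q0: float
    trajectory: Sequence[PopulationState] | None = field(default=None, repr=False)

    def trajectory_frame(self) -> pd.DataFrame:
        """Trajectory as a tidy table with columns year, w, x, y, z."""
        if self.trajectory is None:
            raise ValueError("trajectory was not stored (keep_trajectory=False)")
        return pd.DataFrame(
            {
                "year": [s.n for s in self.trajectory],
                "w": [s.w for s in self.trajectory],
                "x": [s.x for s in self.trajectory],
                "y": [s.y for s in self.trajectory],
                "z": [s.z for s in self.trajectory],
            }
        )


def iterate_to_equilibrium(
    initial: PopulationState,
    params: TransitionParameters,
    tol: float = 1e-10,
    max_years: int = 100_000,
    keep_trajectory: bool = True,
) -> IterationResult:
    """Iterate the replacement map until the state stops moving.

    Stops when the maximum absolute per-compartment change in one step
    falls below ``tol * Q0``; the returned fractions then agree with the
    closed form to a comparable tolerance.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_years < 1:
        raise ValueError("max_years must be at least 1")
    p = params.validate()
    Q0 = initial.total
    w, x, y, z = initial.w, initial.x, initial.y, initial.z
    stay_w = 1.0 - p.p21 - p.p31 - p.p41
    stay_x = 1.0 - p.p12 - p.p32 - p.p42
    trajectory: list[PopulationState] | None = [initial] if keep_trajectory else None
    threshold = tol * Q0
    residual = float("inf")
    for year in range(1, max_years + 1):
        w1 = stay_w * w + p.p12 * x + y + z
        x1 = p.p21 * w + stay_x * x
        y1 = p.p31 * w + p.p32 * x
        z1 = p.p41 * w + p.p42 * x
        residual = max(abs(w1 - w), abs(x1 - x), abs(y1 - y), abs(z1 - z))
        w, x, y, z = w1, x1, y1, z1
        if trajectory is not None:
            trajectory.append(PopulationState(w=w, x=x, y=y, z=z, n=initial.n + year))
        if residual < threshold:
            return IterationResult(
                fractions=(w / Q0, x / Q0, y / Q0, z / Q0),
                years_to_converge=year,
                residual=residual / Q0,
                Q0=Q0,
                trajectory=trajectory,
            )
    raise ConvergenceError(
        f"no convergence after {max_years} years "
        f"(final residual {residual / Q0:.3e} of Q0, tolerance {tol:.3e})"
    )


class IllnessDeathModel:
    """Four-state illness-death chain with death replacement.

    The central modelling object: construct from a parameter set and a
    population size, then query the closed-form equilibrium, iterate the
    yearly dynamics, run the sensitivity analysis, or simulate a stochastic
    cohort realization.

    Parameters
    ----------
    params
        Annual transition probabilities (defaults to the Hong Kong 2012
        estimates).
    Q0
        Fixed total population size maintained by replacement.
    """

    def __init__(
        self,
        params: TransitionParameters = HONG_KONG_2012,
        Q0: float = HONG_KONG_Q0,
    ) -> None:
        if Q0 <= 0:
            raise ValueError("Q0 must be positive")
        self.params = params.validate()
        self.Q0 = float(Q0)

    @classmethod
    def from_tallies(cls, tallies, Q0: float | None = None) -> "IllnessDeathModel":
        """Build a model from simulated cohort tallies by re-estimating the
        six transition probabilities (see :func:`rosemarkov.cohort.estimate_parameters`)."""
        from .cohort import estimate_parameters

        estimates = estimate_parameters(tallies)
        return cls(estimates.to_params(), Q0 if Q0 is not None else tallies.Q0)

    def initial_state(self, initial_ill: float | None = None) -> PopulationState:
        """Default starting point: the prevalent ill stock, everyone else
        healthy, no deaths yet.  ``initial_ill`` defaults to the Hong Kong
        150,000 scaled to Q0."""
        if initial_ill is None:
            initial_ill = self.Q0 * HONG_KONG_INITIAL_ILL / HONG_KONG_Q0
        if initial_ill > self.Q0:
            raise ValueError("initial_ill cannot exceed Q0")
        return PopulationState(w=self.Q0 - initial_ill, x=initial_ill, y=0.0, z=0.0, n=0)

    def equilibrium(self) -> EquilibriumResult:
        return equilibrium_closed_form(self.params, self.Q0)

    def iterate(
        self,
        initial: PopulationState | None = None,
        tol: float = 1e-10,
        max_years: int = 100_000,
        keep_trajectory: bool = True,
    ) -> IterationResult:
        if initial is None:
            initial = self.initial_state()
        return iterate_to_equilibrium(
            initial, self.params, tol=tol, max_years=max_years,
            keep_trajectory=keep_trajectory,
        )

    def trajectory(
        self,
        initial: PopulationState | None = None,
        tol: float = 1e-10,
        max_years: int = 100_000,
    ) -> pd.DataFrame:
        """Year-by-year compartment counts until convergence, as a table."""
        return self.iterate(initial, tol=tol, max_years=max_years).trajectory_frame()

    def sensitivity(self, which: str = "p41", dp: float = 1e-5):
        """First-order sensitivity of the equilibrium suicide count
        (see :func:`rosemarkov.sensitivity.sensitivity_report`)."""
        from .sensitivity import sensitivity_report

        return sensitivity_report(self.params, self.Q0, which=which, dp=dp)

    def simulate(self, years: int, seed: int, initial_ill: int | None = None):
        """Stochastic cohort realization of the replacement dynamics
        (see :func:`rosemarkov.cohort.simulate_cohort`)."""
        from .cohort import simulate_cohort

        return simulate_cohort(
            self.params, int(round(self.Q0)), years, seed, initial_ill=initial_ill
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"IllnessDeathModel(params={self.params!r}, Q0={self.Q0:,.0f})"
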