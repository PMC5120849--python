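"""Markov-chain stand-age dynamics under rotational prescribed burning.

The landscape is tracked as area proportions over stand-age classes
1..A_max (years since last fire).  Under a rotation interval of R years,
stands younger than 8 years are never burned; each eligible stand
(age >= 8) burns in a given year with probability p = 1/(R - 7).  The
value 7 counts the ineligible ages 1-7, and is the unique choice for
which the stationary annual burned area is exactly 1/R.

The chain has a closed-form stationary distribution: a flat 1/R share in
each of ages 1-7 and a geometric tail with ratio (1 - p) from age 8
upward.  Ages at the truncation point A_max pool into an absorbing top
class; biomass curves are age-capped well below the default A_max = 200,
so the truncation does not affect carbon quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RotationPlan",
    "AgeDistribution",
    "stable_age_distribution",
    "advance_one_year",
    "simulate_transient",
    "transition_matrix",
]

MIN_BURN_AGE = 8
DEFAULT_A_MAX = 200


@dataclass(frozen=True)
class RotationPlan:
    """A prescribed-burning rotation of R years (8 <= R <= 50).

    The annual burn probability for eligible stands is
    ``p = 1/(R - 7)``; at R = 8 every eligible stand burns (p = 1).
    """

    R: int
    min_burn_age: int = MIN_BURN_AGE

    def __post_init__(self) -> None:
        if not (8 <= self.R <= 50):
            raise ValueError(f"rotation interval must be in [8, 50], got {self.R}")
        if self.min_burn_age != MIN_BURN_AGE:
            raise ValueError("min_burn_age is fixed at 8 years")

    @property
    def p(self) -> float:
        """Annual burn probability of an eligible (age >= 8) stand."""
        return 1.0 / (self.R - (self.min_burn_age - 1))


@dataclass(frozen=True)
class AgeDistribution:
    """Landscape area proportions over stand-age classes 1..A_max.

    ``proportions[k - 1]`` is the share of area at age k.  Proportions
    are non-negative and sum to one.
    """

    proportions: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", pi)
        if pi.ndim != 1 or pi.size < MIN_BURN_AGE:
            raise ValueError("need age classes at least up to the minimum burn age")
        if np.any(pi < -1e-12):
            raise ValueError("proportions must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {pi.sum()!r}")

    @property
    def a_max(self) -> int:
        return int(self.proportions.size)

    @property
    def ages(self) -> np.ndarray:
        """Stand ages 1..A_max matching ``proportions``."""
        return np.arange(1, self.a_max + 1)

    def proportion(self, age: int) -> float:
        return float(self.proportions[age - 1])

    @classmethod
    def point_mass(cls, age: int, a_max: int = DEFAULT_A_MAX) -> "AgeDistribution":
        pi = np.zeros(a_max)
        pi[age - 1] = 1.0
        return cls(pi)

    @classmethod
    def post_wildfire(cls, a_max: int = DEFAULT_A_MAX) -> "AgeDistribution":
        """All area freshly burned: the whole landscape in age class 1."""
        return cls.point_mass(1, a_max)


def stable_age_distribution(plan: RotationPlan,
                            a_max: int = DEFAULT_A_MAX) -> AgeDistribution:
    """Stationary age structure of the burning chain (closed form).

    pi_k = 1/R for k = 1..7 and pi_k = (1/R) (1-p)^(k-8) for k >= 8;
    the geometric mass beyond A_max is pooled into the top class.  This
    equals the dominant eigenvector of :func:`transition_matrix` and is
    a fixed point of :func:`advance_one_year`.
    """
    if a_max < MIN_BURN_AGE:
        raise ValueError("a_max must be at least the minimum burn age")
    R, p = plan.R, plan.p
    pi = np.zeros(a_max)
    pi[: MIN_BURN_AGE - 1] = 1.0 / R
    k = np.arange(MIN_BURN_AGE, a_max)  # ages 8..A_max-1
    pi[MIN_BURN_AGE - 1: a_max - 1] = (1.0 / R) * (1.0 - p) ** (k - MIN_BURN_AGE)
    pi[a_max - 1] = (1.0 / R) * (1.0 - p) ** (a_max - MIN_BURN_AGE) / p
    return AgeDistribution(pi)


def advance_one_year(state: AgeDistribution,
                     plan: RotationPlan) -> tuple[AgeDistribution, np.ndarray]:
    """One annual step of the chain.

    A fraction p of each eligible class (age >= 8, at its pre-step age)
    burns and re-enters age 1; everything else ages by one year, with
    the top class absorbing its survivors.  Returns the next state and
    the burned area by (pre-step) age class, aligned with ``state.ages``.
    Total area is conserved exactly.
    """
    pi = state.proportions
    a_max = state.a_max
    burned = np.zeros(a_max)
    burned[MIN_BURN_AGE - 1:] = plan.p * pi[MIN_BURN_AGE - 1:]
    survivors = pi - burned
    nxt = np.zeros(a_max)
    nxt[0] = burned.sum()
    nxt[1:] = survivors[:-1]
    nxt[-1] += survivors[-1]  # absorbing top class
    return AgeDistribution(nxt), burned


@dataclass(frozen=True)
class TransientTrace:
    """Year-by-year record of a transient simulation."""

    states: list[AgeDistribution] = field(default_factory=list)
    burned: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def final_state(self) -> AgeDistribution | None:
        return self.states[-1] if self.states else None

    def burned_fraction(self) -> np.ndarray:
        """Total area burned per simulated year."""
        return np.array([b.sum() for b in self.burned])

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: year, age_class, proportion, burned_fraction."""
        rows = []
        for year, (state, burned) in enumerate(zip(self.states, self.burned), 1):
            rows.append(pd.DataFrame({
                "year": year,
                "age_class": state.ages,
                "proportion": state.proportions,
                "burned_fraction": burned,
            }))
        if not rows:
            return pd.DataFrame(
                columns=["year", "age_class", "proportion", "burned_fraction"])
        return pd.concat(rows, ignore_index=True)


def simulate_transient(initial: AgeDistribution, plan: RotationPlan,
                       n_years: int) -> TransientTrace:
    """Run ``n_years`` annual steps from ``initial``.

    As ``n_years`` grows the state converges to
    :func:`stable_age_distribution` (the chain is ergodic up to the
    absorbing truncation class).
    """
    if n_years < 0:
        raise ValueError("n_years must be non-negative")
    states: list[AgeDistribution] = []
    burned: list[np.ndarray] = []
    state = initial
    for _ in range(n_years):
        state, b = advance_one_year(state, plan)
        states.append(state)
        burned.append(b)
    return TransientTrace(states, burned)


def transition_matrix(plan: RotationPlan, a_max: int = DEFAULT_A_MAX) -> np.ndarray:
    """Column-stochastic transition matrix of the age chain.

    ``M[i, j]`` is the share of age-class j+1 area that is at age i+1
    one year later.  Built explicitly as an independent cross-check of
    the closed-form stationary distribution.
    """
    p = plan.p
    M = np.zeros((a_max, a_max))
    for j in range(a_max):  # age j+1
        age = j + 1
        burn = p if age >= MIN_BURN_AGE else 0.0
        M[0, j] += burn
        target = min(j + 1, a_max - 1)
        M[target, j] += 1.0 - burn
    return M
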