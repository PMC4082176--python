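"""Stochastic cohort microsimulation and transition-probability recovery.

The deterministic yearly map is the expectation of a simple individual-level
mechanism: each year, every healthy person independently stays healthy, is
diagnosed, dies of another cause or dies by suicide with probabilities
(1 - p21 - p31 - p41, p21, p31, p41), and likewise for the mentally ill with
(1 - p12 - p32 - p42, p12, p32, p42).  Aggregated over a compartment this is
one multinomial draw per compartment-year.  All of a year's deaths re-enter
the healthy compartment the following year, so the population of the living
plus the current year's dead stays at Q0.

The simulator records only per-year event tallies (not individual
histories); :func:`estimate_parameters` closes the loop by re-estimating the
six transition probabilities from those tallies as pooled binomial
proportions with exact person-year denominators, which is how such annual
transition rates are estimated from service registers in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    HONG_KONG_INITIAL_ILL,
    HONG_KONG_Q0,
    PARAM_NAMES,
    TransitionParameters,
)

#: Tally column -> (source-exposure column, parameter it estimates)
FLOW_COLUMNS: dict[str, tuple[str, str]] = {
    "healthy_to_ill": ("n_healthy_start", "p21"),
    "healthy_to_death_other": ("n_healthy_start", "p31"),
    "healthy_to_suicide": ("n_healthy_start", "p41"),
    "ill_to_recovered": ("n_ill_start", "p12"),
    "ill_to_death_other": ("n_ill_start", "p32"),
    "ill_to_suicide": ("n_ill_start", "p42"),
}

#: Default number of initial years discarded when summarizing long-run
#: compartment shares (transient from the out-of-equilibrium start).
DEFAULT_BURN_IN = 50


@dataclass(frozen=True)
class CohortTallies:
    """Per-year transition event counts from one simulated cohort.

    ``table`` has one row per simulated year with the start-of-year
    compartment sizes, the six event counts, and the number of replacement
    newborns that entered the healthy compartment at the start of the year
    (equal to the previous year's deaths).
    """

    table: pd.DataFrame
    Q0: int
    seed: int
    years: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def ill_share(self, burn_in: int = DEFAULT_BURN_IN) -> pd.Series:
        """Start-of-year mentally ill share of Q0, after discarding the
        first ``burn_in`` transient years."""
        tab = self.table.iloc[burn_in:]
        return tab["n_ill_start"] / self.Q0

    def suicides_per_year(self, burn_in: int = DEFAULT_BURN_IN) -> pd.Series:
        tab = self.table.iloc[burn_in:]
        return tab["healthy_to_suicide"] + tab["ill_to_suicide"]


def simulate_cohort(
    params: TransitionParameters,
    Q0: int = HONG_KONG_Q0,
    years: int = 200,
    seed: int = 0,
    initial_ill: int | None = None,
) -> CohortTallies:
    """Simulate ``years`` one-year transition rounds of a closed population.

    Each compartment-year is one multinomial draw over its four outcomes;
    deaths in year n re-enter as healthy newborns at the start of year n+1.
    The same seed always reproduces the same tallies (per-year substreams
    are spawned deterministically from it).
    """
    p = params.validate()
    if Q0 < 1:
        raise ValueError("Q0 must be at least 1")
    if years < 1:
        raise ValueError("years must be at least 1")
    if initial_ill is None:
        initial_ill = int(round(Q0 * HONG_KONG_INITIAL_ILL / HONG_KONG_Q0))
    if not (0 <= initial_ill <= Q0):
        raise ValueError("initial_ill must lie in [0, Q0]")

    probs_healthy = np.array([1.0 - p.p21 - p.p31 - p.p41, p.p21, p.p31, p.p41])
    probs_ill = np.array([1.0 - p.p12 - p.p32 - p.p42, p.p12, p.p32, p.p42])

    w, x = Q0 - initial_ill, initial_ill
    replacements = 0
    records = []
    streams = np.random.SeedSequence(seed).spawn(years)
    for year in range(years):
        rng = np.random.default_rng(streams[year])
        h_stay, h_ill, h_dother, h_suic = rng.multinomial(w, probs_healthy)
        i_stay, i_rec, i_dother, i_suic = rng.multinomial(x, probs_ill)
        records.append(
            {
                "year": year,
                "n_healthy_start": w,
                "n_ill_start": x,
                "healthy_to_ill": int(h_ill),
                "healthy_to_death_other": int(h_dother),
                "healthy_to_suicide": int(h_suic),
                "ill_to_recovered": int(i_rec),
                "ill_to_death_other": int(i_dother),
                "ill_to_suicide": int(i_suic),
                "replacements": replacements,
            }
        )
        deaths = int(h_dother + h_suic + i_dother + i_suic)
        w = int(h_stay + i_rec) + deaths  # deaths replaced by healthy newborns
        x = int(i_stay + h_ill)
        replacements = deaths
    return CohortTallies(
        table=pd.DataFrame.from_records(records), Q0=Q0, seed=seed, years=years
    )


@dataclass(frozen=True)
class EstimatedParameters:
    """Pooled binomial estimates of the six transition probabilities.

    For each flow, p_hat = (total events) / (total start-of-year count of
    the source compartment), with standard error
    sqrt(p_hat * (1 - p_hat) / exposure).
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    exposures: dict[str, float]  # person-years at risk per parameter
    events: dict[str, int]

    def to_params(self) -> TransitionParameters:
        return TransitionParameters.from_mapping(self.estimates)

    def summary(self) -> str:
        frame = self.summary_frame()
        return "Recovered transition probabilities\n" + frame.to_string(index=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(PARAM_NAMES),
                "estimate": [self.estimates[k] for k in PARAM_NAMES],
                "std_error": [self.standard_errors[k] for k in PARAM_NAMES],
                "events": [self.events[k] for k in PARAM_NAMES],
                "exposure": [self.exposures[k] for k in PARAM_NAMES],
            }
        )


def estimate_parameters(tallies: CohortTallies) -> EstimatedParameters:
    """Re-estimate the six annual transition probabilities from tallies.

    Raises
    ------
    ValueError
        If a source compartment accumulates zero person-years of exposure
        (the corresponding probabilities are then undefined, not zero).
    """
    tab = tallies.table
    if len(tab) < 1:
        raise ValueError("need at least one year of tallies")
    estimates: dict[str, float] = {}
    ses: dict[str, float] = {}
    exposures: dict[str, float] = {}
    events: dict[str, int] = {}
    for flow, (exposure_col, name) in FLOW_COLUMNS.items():
        exposure = float(tab[exposure_col].sum())
        if exposure == 0:
            raise ValueError(
                f"zero exposure: no person-years at risk in {exposure_col}, "
                f"{name} is undefined"
            )
        k = int(tab[flow].sum())
        p_hat = k / exposure
        estimates[name] = p_hat
        ses[name] = float(np.sqrt(p_hat * (1.0 - p_hat) / exposure))
        exposures[name] = exposure
        events[name] = k
    return EstimatedParameters(
        estimates=estimates, standard_errors=ses, exposures=exposures, events=events
    )
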