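"""Cohort Markov model for the diagnostic testing strategies.

A cohort of symptomatic, undiagnosed children enters in the pre-test state
at cycle 0.  The first-line test resolves at the transition out of cycle 0;
under a two-tier strategy patients left undiagnosed wait
``second_line_delay`` cycles (accruing odyssey costs) and then receive the
second-line test.  Diagnosis states split by whether the result changes
clinical management.  Diagnosed, diagnosed-with-change, and undiagnosed
(no further testing) are absorbing; there is no death state, so cohort
fractions persist for the whole horizon.

Costs accrue per annual cycle and are discounted at ``discount_rate``:

- one-off test costs at the cycle each test is administered;
- the annual diagnostic-odyssey cost while a patient is pre-test or
  awaiting a second-line test — and, when the pathway ends with an
  inconclusive conventional (SOC) workup, for a further
  ``post_soc_odyssey_years`` cycles, reflecting continued sequential
  testing after a failed standard workup;
- annual post-test costs (with/without diagnosis) from the cycle after the
  final test, for pathways containing a genome-wide test;
- optionally (robustness analysis) one-off management-change costs on entry
  to the diagnosed-with-changed-management state;
- optionally the annual pathway care cost for the whole cohort.

Effectiveness is the discounted number of diagnoses: first-line diagnoses
are realised at cycle 0 (undiscounted), second-line diagnoses
``second_line_delay`` cycles later.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterSet, TestingStrategy, TestKind

__all__ = [
    "HealthState",
    "MarkovTrace",
    "CohortResult",
    "transition_row",
    "run_cohort",
    "accumulate",
    "base_case",
]


class HealthState(IntEnum):
    """Markov states; the three terminal states are absorbing."""

    PRE_TEST = 0
    AWAIT_SECOND = 1
    DX_CHANGED = 2
    DX_UNCHANGED = 3
    UNDIAGNOSED = 4


_N_STATES = len(HealthState)
_ABSORBING = (HealthState.DX_CHANGED, HealthState.DX_UNCHANGED, HealthState.UNDIAGNOSED)


@dataclass(frozen=True)
class MarkovTrace:
    """Per-cycle state occupancy of a unit cohort under one strategy.

    ``occupancy[c]`` is the state distribution at the start of cycle ``c``
    (``c`` = 0..n_cycles); transitions happen at the end of each cycle, so
    annual costs for cycle ``c`` accrue against ``occupancy[c]``.
    ``new_diagnoses[c]`` is the fraction newly diagnosed at the transition
    out of cycle ``c``.
    """

    strategy: TestingStrategy
    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    new_diagnoses: np.ndarray  # (n_cycles,)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def diagnosed_fraction(self, cycle: int = -1) -> float:
        row = self.occupancy[cycle]
        return float(row[HealthState.DX_CHANGED] + row[HealthState.DX_UNCHANGED])

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cycle, state, fraction) view of the occupancy matrix."""
        n = self.occupancy.shape[0]
        return pd.DataFrame(
            {
                "cycle": np.repeat(np.arange(n), _N_STATES),
                "state": [s.name for _ in range(n) for s in HealthState],
                "fraction": self.occupancy.ravel(),
            }
        )


@dataclass(frozen=True)
class CohortResult:
    """Discounted totals and per-cycle cost components for one strategy."""

    strategy: TestingStrategy
    disc_cost: float
    disc_diagnoses: float
    per_cycle: pd.DataFrame  # columns: cycle, component, cost

    def component_totals(self) -> pd.Series:
        return self.per_cycle.groupby("component")["cost"].sum()


def _second_test_cycle(strategy: TestingStrategy, params: ParameterSet) -> int | None:
    return params.second_line_delay if strategy.is_two_tier else None


def transition_row(
    state: HealthState,
    cycle: int,
    strategy: TestingStrategy,
    params: ParameterSet,
) -> np.ndarray:
    """One row of the transition matrix at a given cycle.

    Testing transitions: from PRE_TEST at cycle 0 with first-line test *t*,
    the cohort splits into diagnosed-with-change (yield*p_change),
    diagnosed-without-change (yield*(1-p_change)) and the undiagnosed
    remainder, which moves to AWAIT_SECOND under a two-tier strategy and to
    the absorbing UNDIAGNOSED state otherwise.  AWAIT_SECOND splits the same
    way with the second-line test at its testing cycle.  All other rows are
    identity.
    """
    row = np.zeros(_N_STATES)
    if state in _ABSORBING:
        row[state] = 1.0
        return row

    def split(kind: TestKind, remainder_state: HealthState) -> None:
        y = params.diagnostic_yield[kind]
        p = params.p_change[kind]
        if not (0.0 <= y <= 1.0 and 0.0 <= p <= 1.0):
            raise ValueError(f"probabilities out of range for {kind.value}: y={y}, p={p}")
        row[HealthState.DX_CHANGED] = y * p
        row[HealthState.DX_UNCHANGED] = y * (1.0 - p)
        row[remainder_state] = 1.0 - y

    if state is HealthState.PRE_TEST:
        if cycle == 0:
            remainder = (
                HealthState.AWAIT_SECOND if strategy.is_two_tier else HealthState.UNDIAGNOSED
            )
            split(strategy.first_line, remainder)
        else:
            row[state] = 1.0
    elif state is HealthState.AWAIT_SECOND:
        if not strategy.is_two_tier:
            raise ValueError(f"AWAIT_SECOND is unreachable under strategy {strategy.name!r}")
        if cycle == _second_test_cycle(strategy, params):
            split(strategy.second_line, HealthState.UNDIAGNOSED)
        else:
            row[state] = 1.0
    return row


def _transition_matrix(
    cycle: int, strategy: TestingStrategy, params: ParameterSet
) -> np.ndarray:
    rows = []
    for s in HealthState:
        if s is HealthState.AWAIT_SECOND and not strategy.is_two_tier:
            r = np.zeros(_N_STATES)
            r[s] = 1.0
            rows.append(r)
        else:
            rows.append(transition_row(s, cycle, strategy, params))
    return np.vstack(rows)


def run_cohort(strategy: TestingStrategy, params: ParameterSet) -> MarkovTrace:
    """Propagate a unit cohort from 100% PRE_TEST through ``n_cycles`` cycles."""
    n = params.n_cycles
    if strategy.is_two_tier and params.second_line_delay >= n:
        raise ValueError(
            f"second_line_delay ({params.second_line_delay}) must be < n_cycles ({n}) "
            "for a two-tier strategy"
        )
    occ = np.zeros((n + 1, _N_STATES))
    occ[0, HealthState.PRE_TEST] = 1.0
    new_dx = np.zeros(n)
    event_cycles = {0, _second_test_cycle(strategy, params)}
    dx_idx = [HealthState.DX_CHANGED, HealthState.DX_UNCHANGED]
    for c in range(n):
        if c in event_cycles:
            occ[c + 1] = occ[c] @ _transition_matrix(c, strategy, params)
        else:  # all occupied states map to themselves away from testing cycles
            occ[c + 1] = occ[c]
        new_dx[c] = occ[c + 1, dx_idx].sum() - occ[c, dx_idx].sum()
    return MarkovTrace(strategy=strategy, occupancy=occ, new_diagnoses=new_dx)


def _cost_components(
    trace: MarkovTrace, strategy: TestingStrategy, params: ParameterSet
) -> dict[str, np.ndarray]:
    """Per-cycle discounted cost components for a unit cohort."""
    n = params.n_cycles
    occ = trace.occupancy
    disc = (1.0 + params.discount_rate) ** -np.arange(n)
    t2 = _second_test_cycle(strategy, params)

    components: dict[str, np.ndarray] = {}

    # one-off testing costs at each test's administration cycle
    testing = np.zeros(n)
    testing[0] = params.test_cost[strategy.first_line] * occ[0, HealthState.PRE_TEST]
    if t2 is not None:
        testing[t2] += params.test_cost[strategy.second_line] * occ[t2, HealthState.AWAIT_SECOND]
    components["testing"] = testing * disc

    # annual diagnostic-odyssey cost while unresolved (pre-test / awaiting
    # second test); after an inconclusive conventional workup the odyssey
    # persists post_soc_odyssey_years further cycles
    unresolved = occ[:n, HealthState.PRE_TEST] + occ[:n, HealthState.AWAIT_SECOND]
    odyssey = params.odyssey_cost * unresolved.copy()
    if strategy.final_line is TestKind.SOC:
        t_final = 0
        undx = occ[t_final + 1, HealthState.UNDIAGNOSED]
        for c in range(t_final + 1, min(t_final + 1 + params.post_soc_odyssey_years, n)):
            odyssey[c] += params.odyssey_cost * undx
    components["odyssey"] = odyssey * disc

    # annual post-test costs (with / without diagnosis), genome-wide pathways
    # only, from the cycle after the final test
    post = np.zeros(n)
    if strategy.uses_ngs:
        t_final = t2 if t2 is not None else 0
        for c in range(t_final + 1, n):
            dx = occ[c, HealthState.DX_CHANGED] + occ[c, HealthState.DX_UNCHANGED]
            post[c] = (
                params.post_test_dx * dx
                + params.post_test_undx * occ[c, HealthState.UNDIAGNOSED]
            )
    components["post_test"] = post * disc

    # annual pathway care cost for the whole (immortal) cohort, optional
    care = np.zeros(n)
    if params.include_care_costs:
        for c in range(n):
            kind = strategy.first_line if (t2 is None or c < t2) else strategy.second_line
            care[c] = params.care_cost[kind] * occ[c].sum()
    components["care"] = care * disc

    # one-off management-change costs on entry to DX_CHANGED, optional
    change = np.zeros(n)
    if params.include_change_costs:
        inflow = np.diff(occ[:, HealthState.DX_CHANGED])
        change[0] = params.change_cost[strategy.first_line] * inflow[0]
        if t2 is not None:
            change[t2] += params.change_cost[strategy.second_line] * inflow[t2]
    components["management_change"] = change * disc
    return components


def accumulate(
    trace: MarkovTrace, strategy: TestingStrategy, params: ParameterSet
) -> CohortResult:
    """Accumulate discounted costs and diagnoses over a cohort trace."""
    if trace.strategy != strategy:
        raise ValueError(
            f"trace was produced under {trace.strategy.name!r}, not {strategy.name!r}"
        )
    n = params.n_cycles
    size = params.cohort_size
    disc = (1.0 + params.discount_rate) ** -np.arange(n)
    components = _cost_components(trace, strategy, params)
    per_cycle = pd.DataFrame(
        {
            "cycle": np.tile(np.arange(n), len(components)),
            "component": np.repeat(list(components), n),
            "cost": np.concatenate([v * size for v in components.values()]),
        }
    )
    disc_cost = float(sum(v.sum() for v in components.values()) * size)
    disc_dx = float((trace.new_diagnoses * disc).sum() * size)
    return CohortResult(
        strategy=strategy, disc_cost=disc_cost, disc_diagnoses=disc_dx, per_cycle=per_cycle
    )


def evaluate(strategy: TestingStrategy, params: ParameterSet) -> tuple[float, float]:
    """(disc_cost, disc_diagnoses) without the per-cycle breakdown frame.

    Same arithmetic as :func:`accumulate`; used in hot loops (PSA)."""
    trace = run_cohort(strategy, params)
    n = params.n_cycles
    disc = (1.0 + params.discount_rate) ** -np.arange(n)
    components = _cost_components(trace, strategy, params)
    cost = float(sum(v.sum() for v in components.values()) * params.cohort_size)
    dx = float((trace.new_diagnoses * disc).sum() * params.cohort_size)
    return cost, dx


def base_case(
    strategies: Sequence[TestingStrategy], params: ParameterSet
) -> list[CohortResult]:
    """Deterministic evaluation of each strategy at the given parameters."""
    return [accumulate(run_cohort(s, params), s, params) for s in strategies]


def outcomes(
    strategies: Sequence[TestingStrategy], params: ParameterSet
) -> dict[str, tuple[float, float]]:
    """Convenience map strategy name -> (disc_cost, disc_diagnoses)."""
    return {
        r.strategy.name: (r.disc_cost, r.disc_diagnoses)
        for r in base_case(strategies, params)
    }
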