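"""Independent patient-level microsimulation oracle.

Simulates individual patients under the same clinical rules as the cohort
engine — first-line test at cycle 0, optional second-line test after the
waiting delay, per-test diagnosis and management-change Bernoulli draws,
and the same cost-accrual rules — but as per-patient Monte Carlo with no
shared trace arithmetic, so it can serve as an external check on the
cohort Markov model.
"""

from __future__ import annotations

import numpy as np

from genecea.markov import HealthState
from genecea.parameters import ParameterSet, TestingStrategy, TestKind


def microsimulate(
    strategy: TestingStrategy, params: ParameterSet, n_patients: int, seed: int
):
    """Simulate ``n_patients`` individual patients.

    Returns a dict with per-patient ``cost`` (discounted EUR), ``dx``
    (discounted diagnosis indicator), and ``final_state`` (HealthState
    codes), all at cohort_size 1.
    """
    rng = np.random.default_rng(seed)
    r = params.discount_rate
    nc = params.n_cycles
    delay = params.second_line_delay

    def d(t: int) -> float:
        return (1.0 + r) ** -t

    first, second = strategy.first_line, strategy.second_line
    y1, p1 = params.diagnostic_yield[first], params.p_change[first]
    dx1 = rng.random(n_patients) < y1
    chg1 = np.zeros(n_patients, bool)
    chg1[dx1] = rng.random(int(dx1.sum())) < p1

    second_tested = np.zeros(n_patients, bool)
    dx2 = np.zeros(n_patients, bool)
    chg2 = np.zeros(n_patients, bool)
    if strategy.is_two_tier:
        second_tested = ~dx1
        y2, p2 = params.diagnostic_yield[second], params.p_change[second]
        dx2[second_tested] = rng.random(int(second_tested.sum())) < y2
        chg2[dx2] = rng.random(int(dx2.sum())) < p2

    diagnosed = dx1 | dx2
    changed = chg1 | chg2
    cost = np.zeros(n_patients)

    # test costs
    cost += params.test_cost[first] * d(0)
    if strategy.is_two_tier:
        cost[second_tested] += params.test_cost[second] * d(delay)

    # odyssey: everyone during cycle 0; those awaiting a second test during
    # cycles 1..delay; one extra stretch for undiagnosed after a final SOC test
    cost += params.odyssey_cost * d(0)
    if strategy.is_two_tier:
        for c in range(1, delay + 1):
            cost[second_tested] += params.odyssey_cost * d(c)
    if strategy.final_line is TestKind.SOC:
        for c in range(1, min(1 + params.post_soc_odyssey_years, nc)):
            cost[~diagnosed] += params.odyssey_cost * d(c)

    # annual post-test costs for genome-wide pathways
    if strategy.uses_ngs:
        tf = delay if strategy.is_two_tier else 0
        tail = sum(d(c) for c in range(tf + 1, nc))
        cost[diagnosed] += params.post_test_dx * tail
        cost[~diagnosed] += params.post_test_undx * tail

    if params.include_care_costs:
        for c in range(nc):
            kind = first if (not strategy.is_two_tier or c < delay) else second
            cost += params.care_cost[kind] * d(c)

    if params.include_change_costs:
        cost[chg1] += params.change_cost[first] * d(0)
        if strategy.is_two_tier:
            cost[chg2] += params.change_cost[second] * d(delay)

    dx_value = np.zeros(n_patients)
    dx_value[dx1] = d(0)
    dx_value[dx2] = d(delay)

    final_state = np.full(n_patients, int(HealthState.UNDIAGNOSED))
    final_state[diagnosed & ~changed] = int(HealthState.DX_UNCHANGED)
    final_state[diagnosed & changed] = int(HealthState.DX_CHANGED)
    return {"cost": cost, "dx": dx_value, "final_state": final_state}
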