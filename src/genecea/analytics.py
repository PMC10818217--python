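"""Economic outputs: ICER, net monetary benefit, cost-effectiveness plane,
acceptability curves and frontier, expected incremental benefit, and value
of information.

Conventions
-----------
- The reference strategy defaults to first-line WGS; incremental quantities
  are reference minus comparator (ΔC = C_ref − C_comp, ΔE = E_ref − E_comp).
- NMB(λ) = λ·ΔE − ΔC at willingness-to-pay λ (euros per diagnosis).
- The acceptability frontier picks, at each λ, the strategy with the highest
  *expected* NMB and reports that strategy's probability of being optimal.
- EVPI is computed per patient (outcomes divided by the cohort scale);
  population EVPI multiplies by the discounted affected population over an
  uptake horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import eur_to_usd
from .psa import PsaDraws

__all__ = [
    "icer",
    "nmb",
    "IncrementalResult",
    "incremental_table",
    "quadrant_proportions",
    "ceac",
    "ceaf",
    "CeacCurve",
    "eib",
    "evpi",
    "population_evpi",
    "evpi_curve",
    "evppi",
    "credible_interval",
]


def icer(delta_cost: float, delta_effect: float) -> float | None:
    """Incremental cost-effectiveness ratio ΔC/ΔE; ``None`` when ΔE = 0.

    Negative values are returned raw; interpret ΔE > 0 with ΔC < 0 as the
    reference dominating (cheaper and more effective).
    """
    if delta_effect == 0:
        return None
    return delta_cost / delta_effect


def nmb(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """Incremental net monetary benefit λ·ΔE − ΔC."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * delta_effect - delta_cost


@dataclass(frozen=True)
class IncrementalResult:
    """One pairwise comparison of the reference against a comparator."""

    reference: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    nmb: float
    wtp: float
    dominant: bool  # reference cheaper and more effective
    icer_ci: tuple[float, float] | None = None
    excluded_fraction: float = 0.0  # draws with ΔE <= 0 dropped from the ICER CI


def incremental_table(
    costs: Mapping[str, float],
    effects: Mapping[str, float],
    reference: str = "WGS",
    wtp: float = 30_000.0,
    psa: PsaDraws | None = None,
    ci_level: float = 0.95,
    eur_usd: float | None = None,
) -> pd.DataFrame:
    """Pairwise incremental comparisons of every strategy against the reference.

    ``costs``/``effects`` are deterministic (base-case) values per strategy;
    when ``psa`` is given, percentile credible intervals for the ICER are
    added, restricted to draws with ΔE > 0 (the excluded fraction is
    reported).  Pass ``eur_usd`` to add USD twins of the monetary columns.
    """
    if reference not in costs:
        raise ValueError(f"reference strategy {reference!r} not among results")
    rows = []
    for name in costs:
        if name == reference:
            continue
        dc = costs[reference] - costs[name]
        de = effects[reference] - effects[name]
        r = IncrementalResult(
            reference=reference,
            comparator=name,
            delta_cost=dc,
            delta_effect=de,
            icer=icer(dc, de),
            nmb=nmb(dc, de, wtp),
            wtp=wtp,
            dominant=(dc < 0 and de > 0),
        )
        row = {
            "comparator": r.comparator,
            "delta_cost": r.delta_cost,
            "delta_effect": r.delta_effect,
            "icer": np.nan if r.icer is None else r.icer,
            "nmb": r.nmb,
            "dominant": r.dominant,
        }
        if psa is not None:
            dc_d = psa.costs[reference] - psa.costs[name]
            de_d = psa.effects[reference] - psa.effects[name]
            keep = de_d > 0
            row["icer_excluded_fraction"] = float(1.0 - keep.mean())
            if keep.sum() >= 2:
                lo, hi = credible_interval(dc_d[keep] / de_d[keep], ci_level)
                row["icer_lo"], row["icer_hi"] = lo, hi
            else:
                row["icer_lo"] = row["icer_hi"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("comparator")
    if eur_usd is not None:
        for col in ("delta_cost", "icer", "nmb"):
            df[f"{col}_usd"] = df[col].apply(lambda v: eur_to_usd(v, eur_usd))
    return df


def _deltas(psa: PsaDraws, reference: str, comparator: str) -> tuple[np.ndarray, np.ndarray]:
    for name in (reference, comparator):
        if name not in psa.costs:
            raise ValueError(f"strategy {name!r} not present in the PSA draws")
    dc = psa.costs[reference] - psa.costs[comparator]
    de = psa.effects[reference] - psa.effects[comparator]
    return dc, de


def quadrant_proportions(
    psa: PsaDraws, reference: str, comparator: str
) -> dict[str, float]:
    """Fractions of PSA draws per cost-effectiveness-plane quadrant.

    Quadrants are (ΔE, ΔC) sign combinations: NE = more effective & more
    costly, SE = more effective & cheaper, NW/SW their western mirrors.
    Zero increments count on the positive (east/north) side.
    """
    dc, de = _deltas(psa, reference, comparator)
    east, north = de >= 0, dc >= 0
    n = len(dc)
    return {
        "NE": float((east & north).sum() / n),
        "NW": float((~east & north).sum() / n),
        "SE": float((east & ~north).sum() / n),
        "SW": float((~east & ~north).sum() / n),
    }


@dataclass(frozen=True)
class CeacCurve:
    """Acceptability curves over a WTP grid.

    ``pairwise`` columns give P(reference beats comparator); ``optimal``
    columns give P(strategy has the maximum NMB), summing to 1 per row.
    """

    wtp: np.ndarray
    pairwise: pd.DataFrame  # one column per comparator
    optimal: pd.DataFrame  # one column per strategy
    reference: str


def _nmb_matrix(psa: PsaDraws, wtp: float) -> np.ndarray:
    """(strategy, draw) per-draw NMB against a zero-cost do-nothing origin."""
    return np.vstack(
        [wtp * psa.effects[name] - psa.costs[name] for name in psa.strategies]
    )


def ceac(psa: PsaDraws, wtp_grid: Sequence[float], reference: str = "WGS") -> CeacCurve:
    """Cost-effectiveness acceptability curves across PSA draws.

    Pairwise: the fraction of draws in which the reference's NMB exceeds the
    comparator's.  Multi-strategy: the fraction of draws in which each
    strategy attains the maximum NMB, with exact ties split equally.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    names = psa.strategies
    if reference not in names:
        raise ValueError(f"reference strategy {reference!r} not present")
    n = psa.n_draws
    pair = {c: np.empty(grid.size) for c in names if c != reference}
    opt = {c: np.empty(grid.size) for c in names}
    for j, w in enumerate(grid):
        nmbs = _nmb_matrix(psa, w)
        ref_row = nmbs[names.index(reference)]
        for c in pair:
            pair[c][j] = float((ref_row > nmbs[names.index(c)]).mean())
        best = nmbs.max(axis=0)
        is_best = nmbs == best[None, :]
        weights = is_best / is_best.sum(axis=0, keepdims=True)  # split ties
        for i, c in enumerate(names):
            opt[c][j] = float(weights[i].sum() / n)
    return CeacCurve(
        wtp=grid,
        pairwise=pd.DataFrame(pair, index=grid),
        optimal=pd.DataFrame(opt, index=grid),
        reference=reference,
    )


def ceaf(curve: CeacCurve, psa: PsaDraws) -> pd.DataFrame:
    """Cost-effectiveness acceptability frontier.

    At each WTP the frontier strategy maximises the *expected* NMB over the
    PSA draws; the frontier reports that strategy's probability of being
    optimal (which need not be the maximal probability).
    """
    names = psa.strategies
    mean_e = np.array([psa.effects[c].mean() for c in names])
    mean_c = np.array([psa.costs[c].mean() for c in names])
    rows = []
    for j, w in enumerate(curve.wtp):
        exp_nmb = w * mean_e - mean_c
        best = names[int(np.argmax(exp_nmb))]
        rows.append(
            {
                "wtp": w,
                "strategy": best,
                "probability": float(curve.optimal.iloc[j][best]),
                "expected_nmb": float(exp_nmb.max()),
            }
        )
    return pd.DataFrame(rows)


def eib(psa: PsaDraws, reference: str, comparator: str, wtp: float) -> float:
    """Expected incremental benefit: mean over draws of the pairwise NMB."""
    dc, de = _deltas(psa, reference, comparator)
    return float(np.mean(wtp * de - dc))


def _per_person_nmb(psa: PsaDraws, wtp: float) -> np.ndarray:
    return _nmb_matrix(psa, wtp) / psa.cohort_size


def evpi(psa: PsaDraws, wtp: float) -> float:
    """Per-patient expected value of perfect information at one WTP.

    EVPI = E[max_s NMB_s] − max_s E[NMB_s]; non-negative by Jensen.
    """
    nmbs = _per_person_nmb(psa, wtp)
    return float(nmbs.max(axis=0).mean() - nmbs.mean(axis=1).max())


def population_evpi(
    per_person: float,
    population: float,
    horizon_years: int,
    discount_rate: float = 0.03,
) -> float:
    """Scale per-patient EVPI by the discounted affected population.

    ``population`` patients face the decision each year over
    ``horizon_years`` years; year t is discounted by (1+r)^-t.
    """
    disc = (1.0 + discount_rate) ** -np.arange(horizon_years)
    return float(per_person * population * disc.sum())


def evpi_curve(
    psa: PsaDraws,
    wtp_grid: Sequence[float],
    population: float | None = None,
    horizon_years: int = 10,
    discount_rate: float = 0.03,
) -> pd.DataFrame:
    """Per-patient (and optionally population) EVPI across the WTP grid."""
    rows = []
    for w in wtp_grid:
        pp = evpi(psa, float(w))
        row = {"wtp": float(w), "evpi_per_person": pp}
        if population is not None:
            row["evpi_population"] = population_evpi(
                pp, population, horizon_years, discount_rate
            )
        rows.append(row)
    return pd.DataFrame(rows)


def evppi(psa: PsaDraws, parameter_name: str, wtp: float, n_bins: int = 50) -> float:
    """Single-parameter expected value of partially perfect information.

    Single-loop binning estimator: draws are partitioned into ``n_bins``
    equal-count bins by the parameter's value; learning the parameter lets
    the decision maker pick the best strategy per bin, so EVPPI is the mean
    of bin-wise maxima of the within-bin mean NMBs minus the overall best
    expected NMB.  Returns 0 for a constant parameter.
    """
    if parameter_name not in psa.parameters.columns:
        raise ValueError(f"unknown parameter {parameter_name!r}")
    x = psa.parameters[parameter_name].to_numpy(float)
    if np.ptp(x) == 0.0:
        return 0.0
    nmbs = _per_person_nmb(psa, wtp)
    order = np.argsort(x, kind="stable")
    bins = np.array_split(order, min(n_bins, len(x)))
    overall_best = nmbs.mean(axis=1).max()
    weighted = 0.0
    for idx in bins:
        weighted += nmbs[:, idx].mean(axis=1).max() * len(idx)
    return float(weighted / len(x) - overall_best)


def credible_interval(samples: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Equal-tail empirical percentile interval."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
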