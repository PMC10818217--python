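"""Probabilistic sensitivity analysis: multi-chain Gibbs sampling of the
parameter priors and per-draw evaluation of the Markov model.

The joint prior factorises over parameters, so each component's full
conditional equals its marginal prior and a systematic-scan Gibbs sweep
reduces to independent draws.  The sweep structure is kept — parameters are
updated in a fixed order within each chain, chains carry independent RNG
streams, and chain membership is recorded per draw — so that standard MCMC
diagnostics (effective sample size, split potential-scale-reduction) can be
computed and verified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import markov
from .parameters import (
    PARAM_NAMES,
    CohortData,
    ParameterSet,
    PriorSet,
    RunSettings,
    TestingStrategy,
)

__all__ = ["PsaDraws", "ConvergenceReport", "sample_chain", "run_psa", "diagnostics"]


@dataclass(frozen=True)
class PsaDraws:
    """Sampled parameter sets and the model outcomes they induce.

    ``parameters`` has one row per draw and one column per flattened scalar
    parameter; ``costs``/``effects`` map strategy name to per-draw vectors of
    discounted cost and discounted diagnoses.  The same row index across
    strategies shares one parameter draw (common random parameters).
    ``cohort_size`` records the cohort scale of the outcome vectors so
    analytics can normalise to per-patient quantities.
    """

    parameters: pd.DataFrame
    costs: Mapping[str, np.ndarray]
    effects: Mapping[str, np.ndarray]
    chain_id: np.ndarray
    seed: int
    cohort_size: float = 1.0

    @property
    def n_draws(self) -> int:
        return len(self.parameters)

    @property
    def strategies(self) -> list[str]:
        return list(self.costs)

    def to_frame(self) -> pd.DataFrame:
        """One row per draw: chain, parameters, then per-strategy outcomes."""
        df = self.parameters.copy()
        df.insert(0, "chain", self.chain_id)
        for name in self.costs:
            df[f"cost::{name}"] = self.costs[name]
            df[f"effect::{name}"] = self.effects[name]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_frame(df: pd.DataFrame, seed: int = 0, cohort_size: float = 1.0) -> "PsaDraws":
        cost_cols = [c for c in df.columns if c.startswith("cost::")]
        names = [c.split("::", 1)[1] for c in cost_cols]
        missing = [n for n in names if f"effect::{n}" not in df.columns]
        if missing or not names:
            raise ValueError(
                "PSA table must contain paired 'cost::<strategy>'/'effect::<strategy>' "
                f"columns; missing effects for {missing}" if names else
                "PSA table contains no 'cost::<strategy>' columns"
            )
        param_cols = [c for c in df.columns if c in PARAM_NAMES]
        return PsaDraws(
            parameters=df[param_cols].reset_index(drop=True),
            costs={n: df[f"cost::{n}"].to_numpy(float) for n in names},
            effects={n: df[f"effect::{n}"].to_numpy(float) for n in names},
            chain_id=df["chain"].to_numpy(int) if "chain" in df else np.zeros(len(df), int),
            seed=seed,
            cohort_size=cohort_size,
        )

    @staticmethod
    def from_csv(path, seed: int = 0, cohort_size: float = 1.0) -> "PsaDraws":
        return PsaDraws.from_frame(pd.read_csv(path), seed=seed, cohort_size=cohort_size)


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter MCMC diagnostics."""

    table: pd.DataFrame  # index: parameter; columns: ess, rhat, mcse_mean
    n_chains: int

    @property
    def rhat_available(self) -> bool:
        return self.n_chains >= 2


def _chain_rng(seed: int, chain: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(chain,)))


def sample_chain(
    priors: PriorSet,
    base: ParameterSet,
    n: int,
    seed: int,
    chain: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` parameter vectors for one chain.

    One Gibbs sweep updates every scalar in the fixed ``PARAM_NAMES`` order
    from its full conditional (here: its prior, as the components are
    mutually independent); the sweep is vectorised across iterations, which
    leaves the sampled chain distributionally unchanged.  Deterministic
    given (seed, chain).
    """
    if n < 1:
        raise ValueError(f"chain length must be >= 1, got {n}")
    rng = _chain_rng(seed, chain)
    cols = {
        name: np.asarray(priors.spec_for(name, base).sample(rng, size=n), dtype=float)
        for name in PARAM_NAMES
    }
    return pd.DataFrame(cols)


def run_psa(
    strategies: Sequence[TestingStrategy],
    priors: PriorSet,
    base: ParameterSet,
    settings: RunSettings,
    cohort_data: CohortData | None = None,  # noqa: ARG001 (yield priors are prebuilt)
) -> PsaDraws:
    """Sample the prior and evaluate the Markov model for every draw.

    Draws are split as evenly as possible over ``settings.n_chains``
    independent chains; every strategy is evaluated on the same parameter
    draw.  Outcomes are at ``base.cohort_size`` scale.
    """
    n_total = settings.n_draws
    n_chains = settings.n_chains
    per_chain = [n_total // n_chains] * n_chains
    for i in range(n_total % n_chains):
        per_chain[i] += 1
    frames, chain_ids = [], []
    for c, n in enumerate(per_chain):
        if n == 0:
            continue
        frames.append(sample_chain(priors, base, n, settings.seed, chain=c))
        chain_ids.append(np.full(n, c, dtype=int))
    params_df = pd.concat(frames, ignore_index=True)
    chain_id = np.concatenate(chain_ids)

    costs = {s.name: np.empty(n_total) for s in strategies}
    effects = {s.name: np.empty(n_total) for s in strategies}
    records = params_df.to_dict("records")
    for i, row in enumerate(records):
        try:
            pset = base.with_flat(row)
            for s in strategies:
                costs[s.name][i], effects[s.name][i] = markov.evaluate(s, pset)
        except Exception as exc:
            raise RuntimeError(f"model evaluation failed at draw {i}: {exc}") from exc
    for s in strategies:
        if not (np.isfinite(costs[s.name]).all() and np.isfinite(effects[s.name]).all()):
            raise RuntimeError(f"non-finite outcomes for strategy {s.name!r}")
    return PsaDraws(
        parameters=params_df,
        costs=costs,
        effects=effects,
        chain_id=chain_id,
        seed=settings.seed,
        cohort_size=base.cohort_size,
    )


def diagnostics(draws: PsaDraws, min_draws_per_chain: int = 100) -> ConvergenceReport:
    """Effective sample size, split-R̂ and Monte-Carlo SE per parameter.

    Requires at least two chains for R̂ (flagged NaN otherwise) and
    ``min_draws_per_chain`` draws in each chain.  Constant (fixed-prior)
    parameters are reported with zero MCSE and NaN diagnostics.
    """
    import arviz as az

    chains = np.unique(draws.chain_id)
    counts = [int((draws.chain_id == c).sum()) for c in chains]
    if min(counts) < min_draws_per_chain:
        raise ValueError(
            f"need >= {min_draws_per_chain} draws per chain, got {min(counts)}"
        )
    n_keep = min(counts)  # truncate to equal length for split diagnostics
    multi = len(chains) >= 2
    rows = []
    for name in draws.parameters.columns:
        x = draws.parameters[name].to_numpy(float)
        mat = np.vstack([x[draws.chain_id == c][:n_keep] for c in chains])
        if np.ptp(mat) == 0.0:  # fixed-prior parameter: no sampling variability
            rows.append(
                {"parameter": name, "ess": np.nan, "rhat": np.nan, "mcse_mean": 0.0}
            )
            continue
        ess = float(az.ess(mat))
        rhat = float(az.rhat(mat)) if multi else np.nan
        mcse = float(mat.std(ddof=1) / np.sqrt(ess)) if ess > 0 else np.nan
        rows.append({"parameter": name, "ess": ess, "rhat": rhat, "mcse_mean": mcse})
    table = pd.DataFrame(rows).set_index("parameter")
    return ConvergenceReport(table=table, n_chains=len(chains))
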