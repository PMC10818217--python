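"""Model parameters, prior distributions, and configuration handling.

The economic model compares diagnostic testing strategies for children with
suspected genetic disorders.  Every tunable quantity of the decision model —
diagnostic yields, management-change probabilities, and the cost inputs —
lives in a :class:`ParameterSet`.  Uncertainty about each scalar is expressed
through a :class:`DistributionSpec` (beta, log-normal, uniform, or fixed),
collected in a :class:`PriorSet` for the probabilistic sensitivity analysis.

Diagnostic-yield priors are conjugate beta posteriors built from hospital
cohort counts (patients tested / patients diagnosed per test); cost priors
are log-normal distributions specified through the limits of a 95% interval;
the one-off management-change costs use vague uniform priors.
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "TestKind",
    "TestingStrategy",
    "STRATEGIES",
    "DistributionSpec",
    "ParameterSet",
    "PriorSet",
    "CohortData",
    "RunSettings",
    "ConfigError",
    "load_config",
    "config_to_dict",
    "default_config_dict",
    "beta_from_cohort",
    "lognormal_from_ci",
    "uniform_around",
    "eur_to_usd",
    "default_priors",
    "PARAM_NAMES",
]

#: z-quantile bounding the central 95% of a standard normal.
_Z975 = float(stats.norm.ppf(0.975))


class ConfigError(ValueError):
    """Raised for missing or out-of-range configuration values."""


class TestKind(str, Enum):
    """The three diagnostic test pathways."""

    SOC = "soc"  # standard of care: conventional genetic tests
    WES = "wes"  # whole-exome sequencing
    WGS = "wgs"  # whole-genome sequencing


@dataclass(frozen=True)
class TestingStrategy:
    """A testing strategy: a first-line test, optionally followed by a
    second-line test for patients left undiagnosed.

    Only standard of care may be followed by a second-line test; the
    genome-wide tests are terminal.
    """

    name: str
    first_line: TestKind
    second_line: TestKind | None = None

    def __post_init__(self) -> None:
        if self.second_line is not None and self.first_line is not TestKind.SOC:
            raise ValueError(
                "second_line testing is only defined after a first-line SOC workup"
            )

    @property
    def is_two_tier(self) -> bool:
        return self.second_line is not None

    @property
    def final_line(self) -> TestKind:
        return self.second_line if self.second_line is not None else self.first_line

    @property
    def uses_ngs(self) -> bool:
        """Whether the pathway contains a genome-wide (WES/WGS) test."""
        return self.first_line is not TestKind.SOC or self.second_line is not None


#: The five strategies compared in the analysis.
STRATEGIES: dict[str, TestingStrategy] = {
    s.name: s
    for s in (
        TestingStrategy("SOC", TestKind.SOC),
        TestingStrategy("WES", TestKind.WES),
        TestingStrategy("WGS", TestKind.WGS),
        TestingStrategy("WES after SOC", TestKind.SOC, TestKind.WES),
        TestingStrategy("WGS after SOC", TestKind.SOC, TestKind.WGS),
    )
}


@dataclass(frozen=True)
class DistributionSpec:
    """A univariate prior: one of ``beta``, ``lognormal``, ``uniform``, ``fixed``.

    ``params`` holds the family-specific hyperparameters:

    - beta: ``alpha`` > 0, ``beta`` > 0
    - lognormal: ``mu`` (log-scale location), ``sigma`` >= 0 (log-scale spread)
    - uniform: ``lower`` <= ``upper``
    - fixed: ``value``
    """

    family: str
    params: tuple[tuple[str, float], ...]

    @staticmethod
    def beta(alpha: float, beta: float) -> "DistributionSpec":
        if not (alpha > 0 and beta > 0):
            raise ValueError(f"beta hyperparameters must be positive, got ({alpha}, {beta})")
        return DistributionSpec("beta", (("alpha", float(alpha)), ("beta", float(beta))))

    @staticmethod
    def lognormal(mu: float, sigma: float) -> "DistributionSpec":
        if sigma < 0:
            raise ValueError(f"lognormal sigma must be >= 0, got {sigma}")
        return DistributionSpec("lognormal", (("mu", float(mu)), ("sigma", float(sigma))))

    @staticmethod
    def uniform(lower: float, upper: float) -> "DistributionSpec":
        if lower > upper:
            raise ValueError(f"uniform requires lower <= upper, got ({lower}, {upper})")
        return DistributionSpec("uniform", (("lower", float(lower)), ("upper", float(upper))))

    @staticmethod
    def fixed(value: float) -> "DistributionSpec":
        return DistributionSpec("fixed", (("value", float(value)),))

    @property
    def p(self) -> dict[str, float]:
        return dict(self.params)

    def mean(self) -> float:
        p = self.p
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "lognormal":
            return math.exp(p["mu"] + 0.5 * p["sigma"] ** 2)
        if self.family == "uniform":
            return 0.5 * (p["lower"] + p["upper"])
        if self.family == "fixed":
            return p["value"]
        raise ConfigError(f"unsupported distribution family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        p = self.p
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size=size)
        if self.family == "lognormal":
            if p["sigma"] == 0.0:  # degenerate; rng.lognormal handles it but be explicit
                val = math.exp(p["mu"])
                return val if size is None else np.full(size, val)
            return rng.lognormal(p["mu"], p["sigma"], size=size)
        if self.family == "uniform":
            return rng.uniform(p["lower"], p["upper"], size=size)
        if self.family == "fixed":
            return p["value"] if size is None else np.full(size, p["value"])
        raise ConfigError(f"unsupported distribution family {self.family!r}")

    def quantile(self, q: float) -> float:
        p = self.p
        if self.family == "beta":
            return float(stats.beta.ppf(q, p["alpha"], p["beta"]))
        if self.family == "lognormal":
            return float(stats.lognorm.ppf(q, p["sigma"], scale=math.exp(p["mu"])))
        if self.family == "uniform":
            return p["lower"] + q * (p["upper"] - p["lower"])
        if self.family == "fixed":
            return p["value"]
        raise ConfigError(f"unsupported distribution family {self.family!r}")


# ---------------------------------------------------------------------------
# Prior constructors


def beta_from_cohort(
    n_diagnosed: int, n_tested: int, prior_alpha: float = 1.0, prior_beta: float = 1.0
) -> DistributionSpec:
    """Conjugate beta update of a diagnostic-yield prior from cohort counts.

    ``n_diagnosed`` successes out of ``n_tested`` binomial trials update a
    Beta(prior_alpha, prior_beta) prior to
    Beta(prior_alpha + x, prior_beta + n - x).
    """
    if n_diagnosed < 0 or n_tested < 0 or n_diagnosed > n_tested:
        raise ValueError(
            f"need 0 <= n_diagnosed <= n_tested, got ({n_diagnosed}, {n_tested})"
        )
    return DistributionSpec.beta(prior_alpha + n_diagnosed, prior_beta + n_tested - n_diagnosed)


def lognormal_from_ci(lower95: float, upper95: float) -> DistributionSpec:
    """Log-normal prior from the lower/upper limits of its central 95% interval.

    The log of a log-normal variate is normal, so the log-limits sit at
    mu -/+ z*sigma with z the 97.5% normal quantile; inverting gives mu and
    sigma exactly.  The returned spec's 2.5th/97.5th percentiles reproduce
    the inputs.
    """
    if lower95 <= 0 or upper95 <= 0:
        raise ValueError(f"interval limits must be positive, got ({lower95}, {upper95})")
    if lower95 > upper95:
        raise ValueError(f"need lower95 <= upper95, got ({lower95}, {upper95})")
    mu = 0.5 * (math.log(lower95) + math.log(upper95))
    sigma = (math.log(upper95) - math.log(lower95)) / (2.0 * _Z975)
    return DistributionSpec.lognormal(mu, sigma)


def uniform_around(base: float, half_width_fraction: float) -> DistributionSpec:
    """Vague uniform prior centred on ``base`` spanning ±``half_width_fraction``."""
    if base < 0:
        raise ValueError(f"base must be >= 0, got {base}")
    if not (0.0 <= half_width_fraction <= 1.0):
        raise ValueError(
            f"half_width_fraction must be in [0, 1], got {half_width_fraction}"
        )
    return DistributionSpec.uniform(
        base * (1.0 - half_width_fraction), base * (1.0 + half_width_fraction)
    )


def eur_to_usd(amount: float, factor: float = 1.0875) -> float:
    """Convert euros to US dollars at a fixed factor (€1 = $``factor``)."""
    if factor <= 0:
        raise ValueError(f"conversion factor must be positive, got {factor}")
    return amount * factor


# ---------------------------------------------------------------------------
# Parameter containers

_KINDS = (TestKind.SOC, TestKind.WES, TestKind.WGS)

#: Flattened scalar parameter names, in sampling (sweep) order.
PARAM_NAMES: tuple[str, ...] = (
    "yield_soc",
    "yield_wes",
    "yield_wgs",
    "p_change_soc",
    "p_change_wes",
    "p_change_wgs",
    "care_cost_soc",
    "care_cost_wes",
    "care_cost_wgs",
    "test_cost_soc",
    "test_cost_wes",
    "test_cost_wgs",
    "change_cost_soc",
    "change_cost_wes",
    "change_cost_wgs",
    "post_test_dx",
    "post_test_undx",
    "odyssey_cost",
)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must lie in [0, 1], got {value}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ConfigError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class ParameterSet:
    """One full joint assignment of all decision-model parameters (EUR, years)."""

    diagnostic_yield: Mapping[TestKind, float]
    p_change: Mapping[TestKind, float]
    care_cost: Mapping[TestKind, float]
    test_cost: Mapping[TestKind, float]
    change_cost: Mapping[TestKind, float]
    post_test_dx: float = 92.0
    post_test_undx: float = 162.0
    odyssey_cost: float = 2375.0
    discount_rate: float = 0.03
    n_cycles: int = 60
    cohort_size: float = 1.0
    second_line_delay: int = 1
    post_soc_odyssey_years: int = 1
    include_change_costs: bool = False
    include_care_costs: bool = False

    def __post_init__(self) -> None:
        for mapping, label in (
            (self.diagnostic_yield, "yield"),
            (self.p_change, "p_change"),
        ):
            for k in _KINDS:
                if k not in mapping:
                    raise ConfigError(f"{label} is missing an entry for {k.value}")
                _check_prob(f"{label}[{k.value}]", mapping[k])
        for mapping, label in (
            (self.care_cost, "care_cost"),
            (self.test_cost, "test_cost"),
            (self.change_cost, "change_cost"),
        ):
            for k in _KINDS:
                if k not in mapping:
                    raise ConfigError(f"{label} is missing an entry for {k.value}")
                _check_nonneg(f"{label}[{k.value}]", mapping[k])
        for name in ("post_test_dx", "post_test_undx", "odyssey_cost"):
            _check_nonneg(name, getattr(self, name))
        if not (0.0 <= self.discount_rate < 1.0):
            raise ConfigError(
                f"discount_rate must lie in [0, 1), got {self.discount_rate}"
            )
        if self.n_cycles < 1:
            raise ConfigError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.cohort_size < 1:
            raise ConfigError(f"cohort_size must be >= 1, got {self.cohort_size}")
        if self.second_line_delay < 1:
            raise ConfigError(
                f"second_line_delay must be >= 1, got {self.second_line_delay}"
            )
        if self.post_soc_odyssey_years < 0:
            raise ConfigError(
                f"post_soc_odyssey_years must be >= 0, got {self.post_soc_odyssey_years}"
            )

    # -- flat scalar view (used by the PSA sampler) --------------------------

    def to_flat(self) -> dict[str, float]:
        flat: dict[str, float] = {}
        for k in _KINDS:
            flat[f"yield_{k.value}"] = float(self.diagnostic_yield[k])
            flat[f"p_change_{k.value}"] = float(self.p_change[k])
            flat[f"care_cost_{k.value}"] = float(self.care_cost[k])
            flat[f"test_cost_{k.value}"] = float(self.test_cost[k])
            flat[f"change_cost_{k.value}"] = float(self.change_cost[k])
        flat["post_test_dx"] = float(self.post_test_dx)
        flat["post_test_undx"] = float(self.post_test_undx)
        flat["odyssey_cost"] = float(self.odyssey_cost)
        return flat

    def with_flat(self, values: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with the given flattened scalars replaced."""
        flat = self.to_flat()
        unknown = set(values) - set(flat)
        if unknown:
            raise ConfigError(f"unknown parameter names: {sorted(unknown)}")
        flat.update(values)

        def kind_map(prefix: str) -> dict[TestKind, float]:
            return {k: flat[f"{prefix}_{k.value}"] for k in _KINDS}

        return replace(
            self,
            diagnostic_yield=kind_map("yield"),
            p_change=kind_map("p_change"),
            care_cost=kind_map("care_cost"),
            test_cost=kind_map("test_cost"),
            change_cost=kind_map("change_cost"),
            post_test_dx=flat["post_test_dx"],
            post_test_undx=flat["post_test_undx"],
            odyssey_cost=flat["odyssey_cost"],
        )


@dataclass(frozen=True)
class CohortData:
    """Hospital cohort counts per test kind: patients tested and diagnosed."""

    n_tested: Mapping[TestKind, int]
    n_diagnosed: Mapping[TestKind, int]

    def __post_init__(self) -> None:
        for k in _KINDS:
            if k not in self.n_tested or k not in self.n_diagnosed:
                raise ConfigError(f"cohort data missing counts for {k.value}")
            n, x = self.n_tested[k], self.n_diagnosed[k]
            if n < 0 or x < 0 or x > n:
                raise ConfigError(
                    f"cohort[{k.value}] needs 0 <= n_diagnosed <= n_tested, got ({x}, {n})"
                )

    @staticmethod
    def from_yields(
        yields: Mapping[TestKind, float], n_tested: Mapping[TestKind, int]
    ) -> "CohortData":
        """Reconstruct diagnosis counts as round(yield * n_tested)."""
        return CohortData(
            n_tested=dict(n_tested),
            n_diagnosed={k: int(round(yields[k] * n_tested[k])) for k in _KINDS},
        )


@dataclass(frozen=True)
class PriorSet:
    """Map from each flattened parameter name to its prior.

    Names without an explicit spec default to a point mass at the base value.
    """

    specs: Mapping[str, DistributionSpec]

    def __post_init__(self) -> None:
        unknown = set(self.specs) - set(PARAM_NAMES)
        if unknown:
            raise ConfigError(f"priors given for unknown parameters: {sorted(unknown)}")

    def spec_for(self, name: str, base: ParameterSet) -> DistributionSpec:
        if name in self.specs:
            return self.specs[name]
        return DistributionSpec.fixed(base.to_flat()[name])

    def means(self, base: ParameterSet) -> dict[str, float]:
        return {n: self.spec_for(n, base).mean() for n in PARAM_NAMES}


def default_priors(
    params: ParameterSet,
    cohort: CohortData,
    cost_ci_fraction: float = 0.2,
    change_cost_half_width: float = 0.5,
    p_change_ess: float = 100.0,
    cost_ci_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> PriorSet:
    """Build the default prior set from base parameters and cohort counts.

    - yields: conjugate Beta(1 + x, 1 + n - x) posteriors from the cohorts;
    - management-change probabilities: method-of-moments betas at an
      effective sample size of ``p_change_ess`` (literature-sourced point
      estimates without counts);
    - costs: log-normal, specified through 95% limits at
      base*(1 ± cost_ci_fraction) unless explicit limits are supplied;
    - management-change costs: vague uniforms at ±``change_cost_half_width``.
    """
    overrides = dict(cost_ci_overrides or {})
    specs: dict[str, DistributionSpec] = {}
    for k in _KINDS:
        specs[f"yield_{k.value}"] = beta_from_cohort(
            cohort.n_diagnosed[k], cohort.n_tested[k]
        )
        m = params.p_change[k]
        if 0.0 < m < 1.0 and p_change_ess > 0:
            specs[f"p_change_{k.value}"] = DistributionSpec.beta(
                m * p_change_ess, (1.0 - m) * p_change_ess
            )
        else:
            specs[f"p_change_{k.value}"] = DistributionSpec.fixed(m)
        specs[f"change_cost_{k.value}"] = uniform_around(
            params.change_cost[k], change_cost_half_width
        )

    def cost_prior(name: str, base: float) -> DistributionSpec:
        if name in overrides:
            lo, hi = overrides[name]
            return lognormal_from_ci(lo, hi)
        if base == 0 or cost_ci_fraction == 0:
            return DistributionSpec.fixed(base)
        return lognormal_from_ci(
            base * (1.0 - cost_ci_fraction), base * (1.0 + cost_ci_fraction)
        )

    for k in _KINDS:
        specs[f"care_cost_{k.value}"] = cost_prior(
            f"care_cost_{k.value}", params.care_cost[k]
        )
        specs[f"test_cost_{k.value}"] = cost_prior(
            f"test_cost_{k.value}", params.test_cost[k]
        )
    specs["post_test_dx"] = cost_prior("post_test_dx", params.post_test_dx)
    specs["post_test_undx"] = cost_prior("post_test_undx", params.post_test_undx)
    specs["odyssey_cost"] = cost_prior("odyssey_cost", params.odyssey_cost)
    return PriorSet(specs)


@dataclass(frozen=True)
class RunSettings:
    """Run-level settings: WTP grid, PSA size, currency, decision thresholds."""

    wtp_grid: tuple[float, ...] = tuple(float(w) for w in range(0, 50100, 100))
    n_draws: int = 100_000
    n_chains: int = 4
    seed: int = 0
    eur_usd: float = 1.0875
    threshold_band: tuple[float, float] = (30_000.0, 50_000.0)
    evpi_population: float = 10_000.0
    evpi_horizon_years: int = 10

    def __post_init__(self) -> None:
        grid = np.asarray(self.wtp_grid, dtype=float)
        if grid.size == 0:
            raise ConfigError("wtp_grid must be non-empty")
        if np.any(grid < 0) or np.any(np.diff(grid) < 0):
            raise ConfigError("wtp_grid must be sorted ascending and non-negative")
        if self.n_draws < 1:
            raise ConfigError(f"n_draws must be >= 1, got {self.n_draws}")
        if self.n_chains < 1:
            raise ConfigError(f"n_chains must be >= 1, got {self.n_chains}")
        if self.eur_usd <= 0:
            raise ConfigError(f"eur_usd must be positive, got {self.eur_usd}")
        if self.evpi_population < 0 or self.evpi_horizon_years < 0:
            raise ConfigError("population EVPI settings must be non-negative")


# ---------------------------------------------------------------------------
# Configuration document handling


def _default_config_path():
    return resources.files("genecea").joinpath("data/default_config.yaml")


def default_config_dict() -> dict:
    """The packaged default configuration (base-case parameter landscape)."""
    with _default_config_path().open("r") as fh:
        return yaml.safe_load(fh)


def _deep_merge(base: dict, over: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in over.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val) if isinstance(val, (dict, list)) else val
    return out


def _kind_map(section: Mapping, field_name: str) -> dict[TestKind, float]:
    try:
        sub = section[field_name]
    except KeyError:
        raise ConfigError(f"missing required field {field_name!r}") from None
    out = {}
    for k in _KINDS:
        if k.value not in sub:
            raise ConfigError(f"{field_name} is missing an entry for {k.value!r}")
        out[k] = sub[k.value]
    return out


def load_config(
    source: str | Path | io.TextIOBase | Mapping | None = None,
) -> tuple[ParameterSet, PriorSet, CohortData, RunSettings]:
    """Parse a YAML/JSON configuration document into validated model objects.

    ``source`` may be a path, an open text stream, a mapping, or ``None``
    for the packaged defaults.  User documents are merged over the defaults,
    so partial configurations are valid; the defaults reproduce the base-case
    parameter table exactly.
    """
    if source is None:
        doc: Mapping = {}
    elif isinstance(source, Mapping):
        doc = source
    elif isinstance(source, (str, Path)):
        with open(source, "r") as fh:
            doc = yaml.safe_load(fh) or {}
    else:
        doc = yaml.safe_load(source) or {}
    if not isinstance(doc, Mapping):
        raise ConfigError("configuration document must be a mapping")

    merged = _deep_merge(default_config_dict(), doc)
    known = {"parameters", "cohort", "priors", "run"}
    unknown = set(merged) - known
    if unknown:
        raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")

    p = merged["parameters"]
    try:
        params = ParameterSet(
            diagnostic_yield=_kind_map(p, "diagnostic_yield"),
            p_change=_kind_map(p, "p_change"),
            care_cost=_kind_map(p, "care_cost"),
            test_cost=_kind_map(p, "test_cost"),
            change_cost=_kind_map(p, "change_cost"),
            post_test_dx=p["post_test_dx"],
            post_test_undx=p["post_test_undx"],
            odyssey_cost=p["odyssey_cost"],
            discount_rate=p["discount_rate"],
            n_cycles=p["n_cycles"],
            cohort_size=p["cohort_size"],
            second_line_delay=p["second_line_delay"],
            post_soc_odyssey_years=p["post_soc_odyssey_years"],
            include_change_costs=p["include_change_costs"],
            include_care_costs=p["include_care_costs"],
        )
    except KeyError as exc:
        raise ConfigError(f"missing required field {exc.args[0]!r} in parameters") from None

    c = merged["cohort"]
    cohort = CohortData(
        n_tested={k: int(c["n_tested"][k.value]) for k in _KINDS},
        n_diagnosed={k: int(c["n_diagnosed"][k.value]) for k in _KINDS},
    )

    pr = merged["priors"]
    overrides: dict[str, tuple[float, float]] = {}
    for name, lim in (pr.get("cost_ci_overrides") or {}).items():
        if name not in PARAM_NAMES:
            raise ConfigError(f"cost_ci_overrides names unknown parameter {name!r}")
        overrides[name] = (float(lim[0]), float(lim[1]))
    priors = default_priors(
        params,
        cohort,
        cost_ci_fraction=pr["cost_ci_fraction"],
        change_cost_half_width=pr["change_cost_half_width"],
        p_change_ess=pr["p_change_ess"],
        cost_ci_overrides=overrides,
    )

    r = merged["run"]
    grid = tuple(
        float(w)
        for w in np.arange(r["wtp_min"], r["wtp_max"] + 0.5 * r["wtp_step"], r["wtp_step"])
    )
    settings = RunSettings(
        wtp_grid=grid,
        n_draws=int(r["n_draws"]),
        n_chains=int(r["n_chains"]),
        seed=int(r["seed"]),
        eur_usd=float(r["eur_usd"]),
        threshold_band=tuple(float(x) for x in r["threshold_band"]),
        evpi_population=float(r["evpi_population"]),
        evpi_horizon_years=int(r["evpi_horizon_years"]),
    )
    return params, priors, cohort, settings


def config_to_dict(params: ParameterSet, cohort: CohortData, settings: RunSettings) -> dict:
    """Serialize model objects back into a configuration mapping.

    Only sections derived from the objects are emitted; prior construction
    settings keep their defaults.  ``load_config(config_to_dict(...))``
    round-trips to identical objects.
    """
    grid = np.asarray(settings.wtp_grid)
    step = float(grid[1] - grid[0]) if grid.size > 1 else 100.0
    return {
        "parameters": {
            "diagnostic_yield": {k.value: float(params.diagnostic_yield[k]) for k in _KINDS},
            "p_change": {k.value: float(params.p_change[k]) for k in _KINDS},
            "care_cost": {k.value: float(params.care_cost[k]) for k in _KINDS},
            "test_cost": {k.value: float(params.test_cost[k]) for k in _KINDS},
            "change_cost": {k.value: float(params.change_cost[k]) for k in _KINDS},
            "post_test_dx": float(params.post_test_dx),
            "post_test_undx": float(params.post_test_undx),
            "odyssey_cost": float(params.odyssey_cost),
            "discount_rate": float(params.discount_rate),
            "n_cycles": int(params.n_cycles),
            "cohort_size": float(params.cohort_size),
            "second_line_delay": int(params.second_line_delay),
            "post_soc_odyssey_years": int(params.post_soc_odyssey_years),
            "include_change_costs": bool(params.include_change_costs),
            "include_care_costs": bool(params.include_care_costs),
        },
        "cohort": {
            "n_tested": {k.value: int(cohort.n_tested[k]) for k in _KINDS},
            "n_diagnosed": {k.value: int(cohort.n_diagnosed[k]) for k in _KINDS},
        },
        "run": {
            "wtp_min": float(grid[0]),
            "wtp_max": float(grid[-1]),
            "wtp_step": step,
            "n_draws": int(settings.n_draws),
            "n_chains": int(settings.n_chains),
            "seed": int(settings.seed),
            "eur_usd": float(settings.eur_usd),
            "threshold_band": [float(x) for x in settings.threshold_band],
            "evpi_population": float(settings.evpi_population),
            "evpi_horizon_years": int(settings.evpi_horizon_years),
        },
    }
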