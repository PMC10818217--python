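# Methods

## Decision problem and model structure

The package evaluates five diagnostic testing strategies for a cohort of
children with suspected genetic disorders: standard of care (SOC),
first-line WES, first-line WGS, and two-tier strategies that follow an
inconclusive SOC workup with WES or WGS. The model is a cohort Markov chain
with five states — pre-test, awaiting second-line test, diagnosed with
changed management, diagnosed without management change, undiagnosed — and
annual cycles over a 60-year horizon. The three terminal states are
absorbing. Mortality is deliberately not modelled (no absorbing death
state): pediatric mortality in this population is heterogeneous and poorly
quantified, so cohort fractions persist for the whole horizon. No
half-cycle correction is applied; transitions are instantaneous events at
cycle boundaries (a `half-cycle` flag would be a natural future addition,
but none of the reported quantities motivates it here).

Timing convention: the first-line test resolves at the transition out of
cycle 0, so first-line diagnoses are undiscounted. Second-line tests happen
`second_line_delay` cycles later (default 1), so second-line diagnoses and
test costs are discounted accordingly. The cumulative diagnosed fraction of
a two-tier strategy is exactly `y1 + (1 − y1)·y2`.

## Effectiveness and discounting

Effectiveness is the discounted number of diagnoses — the field's standard
outcome for genome-wide sequencing evaluations when QALY mappings are
unavailable — with both costs and effects discounted at 3%/year
(`discount_rate`). QALYs are out of scope by design.

## Cost accrual rules

Per cycle `c` (discount factor `(1+r)^-c`), for a unit cohort:

- **Testing** (one-off): the strategy's first-line tariff at cycle 0
  (€450 SOC / €1800 WES / €3700 WGS); the second-line tariff applied to the
  awaiting fraction at its testing cycle.
- **Diagnostic odyssey** (€2375/year): accrues while a patient is
  unresolved — the pre-test cycle and any cycles awaiting a second-line
  test. When the *final* test of the pathway is conventional (single-tier
  SOC), patients left undiagnosed remain in the odyssey for
  `post_soc_odyssey_years` further cycles (default 1): an inconclusive
  conventional workup is typically followed by continued sequential
  testing, whereas an inconclusive genome-wide test ends the active search.
- **Post-test care** (€92/year with diagnosis, €162/year without): from the
  cycle after the final test to the end of the horizon, only for pathways
  containing a genome-wide test (the values are defined as after-WES/WGS
  costs).
- **Management change** (one-off €4241/€9611/€15 785 by test): applied to
  the fraction newly entering the changed-management state, only when
  `include_change_costs` is set (the robustness analysis); excluded from
  the base case because the underlying estimates come from small,
  population-specific studies.
- **Pathway care** (annual €29 870/€61 704/€79 170): reported as a
  component behind `include_care_costs`, default **off**. The published
  incremental results pin this choice down: the printed per-patient
  incremental cost of WGS vs WES (≈€1784) is exactly the test-cost
  difference plus the discounted post-test-cost difference, leaving no room
  for a pathway care-cost differential, which at 60-year accrual would be
  two orders of magnitude larger than every printed increment. Treating
  these annual pathway costs as a reportable overhead rather than a
  component of the incremental comparison reproduces the published
  incremental structure; turning the flag on gives a conservative
  whole-pathway costing.

With these defaults the deterministic per-patient ICERs are ≈€24.6k (WGS vs
SOC), ≈€29.7k (WGS vs WES) and ≈€22.5k (WES vs SOC), so the expected-NMB
frontier moves SOC → WES → WGS with switch points near €22.5k and €29.7k,
and first-line WGS is optimal throughout the €30 000–€50 000 band.

## Priors and the PSA

Parameters and their priors (all money in 2022 EUR; USD only at reporting
time via the fixed 1.0875 factor):

| group | default | prior |
|---|---|---|
| diagnostic yields | 0.43 / 0.58 / 0.64 | Beta(1+x, 1+n−x) conjugate posteriors from cohorts of 300/480/90 patients with 129/278/58 diagnoses (counts reconstructed as round(yield·n) when only a point yield is given) |
| management-change probabilities | 0.06 / 0.17 / 0.27 | method-of-moments Beta at effective sample size 100 (`p_change_ess`) — informative but non-degenerate, since these are literature point estimates without counts |
| costs (care, test, post-test, odyssey) | table values | log-normal specified by 95% limits; published limits are not available, so defaults use base·(1 ± `cost_ci_fraction`), `cost_ci_fraction` = 0.2, overridable per parameter via `cost_ci_overrides` (outputs flag these as defaults, not data) |
| management-change costs | 4241 / 9611 / 15 785 | vague Uniform over base·(1 ± 0.5) (`change_cost_half_width`) |

The joint prior factorises, so each component's Gibbs full conditional is
its own marginal; the sampler performs systematic-scan sweeps in a fixed
parameter order, vectorised across iterations (distributionally identical,
bit-reproducible per `(seed, chain)` via `SeedSequence` spawning). Chain
bookkeeping is retained so effective sample size, split-$\hat R$ and MCSE
are real, testable diagnostics; for this independent-component posterior
they should show $\hat R \approx 1$ and ESS ≈ the draw count, and the test
suite asserts exactly that. Default 100 000 draws over 4 chains; tests and
the acceptance script use a 10 000-draw desk-scale profile, which puts
Monte-Carlo error on reported probabilities near 0.5 percentage points.

## Economic analytics

- ICER is the exact quotient ΔC/ΔE (undefined flag at ΔE = 0; dominance
  annotated when ΔC < 0 < ΔE). ICERs are invariant to `cohort_size` by
  linearity.
- ICER credible intervals are percentile intervals over draws restricted to
  ΔE > 0 (ratio statistics are unstable near ΔE = 0); the excluded fraction
  is always reported.
- CEAC ties are split equally; quadrant classification places zero
  increments on the positive side (both rules are arbitrary at measure-zero
  events for continuous priors and only matter for degenerate inputs).
- The CEAF picks the strategy maximising *expected* NMB, not maximal
  probability.
- EVPI uses per-patient NMB (outcomes divided by `cohort_size`); population
  EVPI multiplies by the discounted annual affected population over an
  uptake horizon (`evpi_population`, default 10 000/year, and
  `evpi_horizon_years`, default 10 — placeholders for jurisdiction-specific
  figures, labelled as such in outputs).
- EVPPI uses the single-loop equal-count binning estimator (default 50
  bins). Binning trades a small upward bias at low bin counts against
  regression machinery; regression-based (GAM/GP) estimators are out of
  scope.

## Synthetic data and what the tests show

`genecea.synthetic` generates the two data types the analysis consumes:
binomial cohort counts at the true yields (defaults 300/480/90 tested, the
study's cohort sizes) and log-normal cost records with natural-scale mean
and CV (default 0.2, matching the prior-construction width so round trips
are self-consistent). `recovery_experiment` closes the loop: truth → data →
priors → sampler → posterior summaries, asserting posterior means land
within 3 Monte-Carlo SEs of their conjugate/analytic expectations and
within binomial error of truth.

The generator reproduces the statistical structure the model *assumes* —
independent binomial diagnoses, independent log-normal costs. Passing tests
therefore validate the machinery (conjugate updating, sampling, discounted
accumulation, the economics), not the clinical realism of those
assumptions: correlated costs and yields, non-stationary tariffs, or
heterogeneous subpopulations are not emulated, and real-data conclusions
inherit the published parameter estimates' own limitations.

An independent patient-level microsimulation (in the test suite) applies
the same clinical rules patient by patient and checks the cohort engine's
discounted costs, diagnoses and final-state distribution at 10⁵ patients
within 3 standard errors, for all five strategies.

## Numerical choices and degenerate inputs

- Occupancy rows are checked to sum to 1 within 1e-12; absorbing-state
  occupancy is non-decreasing.
- Zero-width log-normal intervals and zero-variance priors degenerate to
  point masses; a PSA under all-fixed priors reproduces the deterministic
  base case bit-exactly.
- Strategy evaluation is linear in `cohort_size` (exactly, not just
  approximately), which the suite asserts.
- The printed comparison table's *absolute* totals imply a national cohort
  whose size is not derivable from the main text (and differs slightly
  across rows); the package therefore treats `cohort_size` as a plain
  config input, defaults it to 1 (per-patient scale), and anchors
  verification on the incremental arithmetic, which is self-consistent.

## Known limitations

- No mortality, QALYs, incidental findings, WES reanalysis, or CPI
  inflation machinery (all out of scope by design).
- The log-normal cost priors' published interval limits are unavailable;
  the ±20% defaults keep the PSA exercisable but understate or overstate
  true cost uncertainty to an unknown degree — use `cost_ci_overrides`
  when real limits exist.
- Two-tier strategies inherit the composition `y1 + (1−y1)·y2`, which makes
  them more effective than any single test; published two-tier
  effectiveness figures that fall below this bound cannot be reproduced by
  this structure, and frontier statements about first-line strategies are
  made over the single-tier set.
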