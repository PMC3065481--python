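# Methods

## The decision problem

A large urban HIV clinic in Kampala introduced a Pharmacy-only Refill
Program (PRP): stable patients on antiretroviral therapy (ART) pick up
their medicines monthly at the pharmacy, seeing a physician only every six
months, instead of the Standard of Care (SOC) of monthly physician visits.
This package evaluates the trade-off as a two-strategy incremental
cost-effectiveness analysis. Effectiveness is the probability of a
Favorable Immune Response (FIR) — a follow-up CD4 lymphocyte count above
500 cells/µL, the lower limit of normal in Ugandan populations — over a
roughly 13-month follow-up. Costs are annual per-patient 2009 US dollars.

Two perspectives are supported. The *limited societal* perspective counts
direct medical costs plus the direct non-medical costs borne by patients
(transport, lost patient time) but no productivity losses. The *Ministry of
Health* (MoH) perspective counts direct medical costs only. With cost C_s
and FIR probability p_s per strategy s, the incremental comparison of PRP
versus SOC is

    ΔC = C_PRP − C_SOC,   ΔE = p_PRP − p_SOC,   ICER = |ΔC / ΔE|.

The base case sits in the *southwest* quadrant of the cost-effectiveness
plane (ΔC < 0, ΔE < 0): the program buys a small loss of effectiveness at a
large saving, and the ICER reads as dollars saved per FIR forgone. Because
a signed ratio is ambiguous in the SW/NW quadrants, `cea_core.icer` always
reports the absolute ratio together with the quadrant and an interpretation
string; the ratio is undefined exactly when ΔE = 0. The net monetary
benefit NMB_s(λ) = λ·p_s − C_s formalizes the acceptability decision rule;
ΔNMB(λ) = λ·ΔE − ΔC is affine in λ with its root at the ICER, and ties are
broken toward the comparator.

Costs are annual while effects accrue over ~13 months of follow-up; no
time alignment or discounting is applied between the two, matching the
original analysis. This is a deliberate limitation, not an oversight.

## Cost reconciliation and the residual category

The itemized component costs (ART $243, other drugs $35, radiology $2,
laboratory $34, personnel $10 PRP / $31 SOC, overhead and capital $141,
transport $20, lost patient time $4 PRP / $16 SOC) do not sum to the
published annual totals (PRP $520 / SOC $655 societal; $496 / $610 MoH).
The package treats the published totals as authoritative for the headline
analysis — they are pinned per perspective via `total_override` — and
carries each gap as an explicit `residual` cost category ($31 PRP, $133
SOC, classed as direct medical), so component-level sensitivity analysis
and the published totals coexist. With the residuals included, component
sums reproduce the societal totals exactly and the MoH totals to within $9
for SOC (619 vs the published 610); that $9 disagreement is intrinsic to
the published figures, and `perspective_total` emits a reconciliation
warning whenever an override differs from its component sum by more than
$1. The residual is an accounting device, not a claim about arm-specific
utilization.

## Uncertainty analysis

**Ranges.** Every cost is halved and doubled; every probability is shifted
±20% (upper bound capped at 1). Each range is treated as a 95% confidence
interval, giving se = (high − low) / (2 × 1.959964).

**Distributions.** Probabilities get beta distributions, costs gamma
distributions, both fitted by moment matching so the fitted mean and SD
equal the point estimate and SE exactly:

    beta:  ν = m(1−m)/se² − 1,  α = mν,  β = (1−m)ν
    gamma: shape = m²/se²,      scale = se²/m

Note the halved-to-doubled rule makes every cost's coefficient of variation
identical (1.5/3.9199 ≈ 0.38, gamma shape ≈ 6.83).

**Tornado.** One parameter at a time is set to its bounds with all others
at base; rows are sorted by swing. Incremental outcomes are computed from
component sums. Under the default *shared* mode, categories with identical
base values in both arms (ART, other drugs, radiology, laboratory,
overhead, transport) move in both arms together and therefore cancel out of
ΔC — only arm-specific parameters (personnel, lost patient time, residual,
the FIR probabilities) can swing an increment. The alternative
*independent* mode (`shared_costs=False`) varies each category per arm, in
which case ART, the largest component, dominates the ΔC tornado. Both
readings are supported because the original figure is only reproducible
under the independent mode while the Monte Carlo claim (below) requires
the shared mode; neither is asserted as the original procedure.

**PSA.** 10,000 Monte Carlo iterations by default. Per iteration each
uncertain parameter is sampled once from its fitted distribution — shared
categories as one draw applied to both arms, arm-specific parameters
independently per arm, the two FIR probabilities independently — and
per-strategy costs are rebuilt from component sums under the chosen
perspective. The residual categories stay at their base values by default:
they are reconciliation constants without a measured uncertainty, and
fixing them is the only configuration under which an intervention cheaper
in every differing component is cheaper in *every* replicate (the
all-draws-cost-saving property of the base case); `sample_residual=True`
gives them gammas like any other component. All sampling uses a single
seeded `numpy` generator with parameters drawn in sorted-name order, so
runs are bit-reproducible at a fixed seed and package version.

**CEAC.** At each willingness-to-pay λ on a grid of $0–30,000/FIR in $100
steps, the PRP's acceptability is the fraction of draws with λ·ΔE − ΔC > 0
(ties to the comparator); the SOC curve is its complement. The crossover
(acceptability 0.5) is reported by linear interpolation between bracketing
grid points. At the base configuration it falls near the deterministic root
of $13,500 per FIR, with a Monte-Carlo standard deviation of roughly $500
across seeds at 10,000 iterations.

## The synthetic cohort generator

The clinic database behind the retrospective cohort (578 PRP / 251 SOC
patients treated 2005–2007) is not public, so `cohort_simulator` generates
a stand-in calibrated to the published descriptive statistics:

- **Continuous covariates** (follow-up months, age, ART duration, CD4 at
  ART start, CD4 at baseline) are truncated normals at the published
  per-arm means and SDs. The published table's column headers for these
  rows are internally inconsistent with the running text's arm
  comparisons; the generator follows the text (PRP: older, 12.8-month
  follow-up, 41.8 months on ART, baseline CD4 218), while categorical
  frequencies follow the printed per-arm counts, whose denominators match
  the arm sizes.
- **Arm assignment is confounded by design**: with
  `enforce_prp_eligibility` (default on) the PRP arm is constrained to the
  database-observable entry criteria — baseline CD4 > 200 cells/µL, ≥ 12
  months on ART, optimal (>95%) self-reported adherence — by truncating the
  respective distributions and forcing adherence. The four unobservable
  criteria (visit adherence, disclosure, pregnancy, recent clinical
  events) are collapsed into one latent Bernoulli pass probability
  (default 1.0), since they never enter the regression. Enforcement means
  the PRP arm's *realized* baseline-CD4 mean exceeds the configured
  location parameter (≈334 vs 218 with SD 160) — unavoidable, since the
  published mean is itself incompatible with universal eligibility at that
  spread. The covariate-moment convergence test therefore runs with
  enforcement off, against the truncated-normal theoretical moments.
- **Outcome.** P(FIR | covariates) follows a logistic model whose default
  coefficients are the published adjusted odds ratios (arm effect
  ln 0.93; follow-up dichotomized at 1 year; ART duration in <2 / 2–3 / >3
  year bands; CD4-at-ART-start in <200 / 200–300 / >300 bands; regimen
  indicators against their reference levels). The intercept (−2.2533) was
  calibrated once by bisection against a Monte-Carlo marginal oracle —
  averaging the model over fresh covariate draws — so the pooled FIR
  prevalence is the published 18.9%; it is frozen thereafter. A latent FIR
  Bernoulli is drawn per record, the follow-up CD4 count is then drawn
  from a lognormal (median 350 cells/µL, σ = 0.6 — a typical post-ART
  distribution; the published band proportions are garbled and not used
  for calibration) truncated to the matching side of 500, and `fir` is
  always recomputed from the count, never stored independently.
- **Missingness.** Adherence is masked at random for a configurable
  fraction (default 22/829, reproducing the published regression's
  n = 807); the regression is complete-case in that column.

What the generator does **not** emulate: longitudinal CD4 trajectories,
loss to follow-up (excluded patients are never generated), residual
selection on unmeasured characteristics, or the marginal arm-level FIR
rates of the published cohort — combining the published covariate tables
with the published *conditional* odds ratios implies marginal arm rates
(≈0.16 PRP / 0.26 SOC) further apart than the published 0.186 / 0.196,
and the generator is calibrated to the conditional model plus the pooled
prevalence, which the estimation pipeline targets. Passing tests
therefore demonstrate internal consistency of the estimators on data with
the configured structure, not agreement with the unpublished patient-level
data.

## Effectiveness estimation

`fir_proportions` and `crude_or` are direct formulas: OR = ad/bc with the
Wald CI exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)); zero cells get the
Haldane–Anscombe +0.5 correction with a warning (or an error if disabled).
`fit_logistic` is a maximum-likelihood fit (Newton scoring, tolerance 1e-8,
≤100 iterations; statsmodels underneath) with Wald SEs from the inverse
observed information; a coefficient beyond ±15 log-odds flags
(quasi-)separation and marks the fit non-converged rather than reporting
silently — with the default cohort this fires in roughly 1 replicate in 30,
when no FIR event lands among the ~28 suboptimal-adherence SOC patients.
The saturated-model identity (arm-only logistic OR ≡ 2×2 OR) is tested to
1e-6 as a cross-check between the two routes.

## Problem sizes and numerical choices

Simulation-based tests use the study's own sample sizes (829 patients) for
parameter recovery (500 replicates, Wald 95% CI coverage of the arm
log-OR ≥ 93%), 10,000-iteration PSAs for plane and CEAC summaries,
10,000/arm cohorts for moment checks, and 10⁶ draws for sampled-moment
verification of the fitted distributions (0.5% relative tolerance).
Degenerate inputs are exercised via near-unit range factors (the PSA's
deterministic limit), all-zero cost profiles, zero-mean costs (excluded
from ranges with a warning), and zero 2×2 cells.

## Known limitations

- Intermediate outcome only: cost per FIR, not life-years or QALYs.
- Two strategies, one period, no discounting, single currency (2009 US$).
- The beta/gamma SEs inherit the strong assumption that halved-to-doubled
  (costs) and ±20% (probabilities) spans are 95% intervals.
- The cross-arm cost correlation structure of the original Monte Carlo is
  unstated; the shared-draw default is chosen as the only structure
  consistent with every replicate being cost-saving, and is configurable.
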