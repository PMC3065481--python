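# refill-cea

Cost-effectiveness analysis of a **Pharmacy-only Refill Program (PRP)** —
monthly ART pick-up at the pharmacy, a form of task-shifting — against the
**Standard of Care (SOC)** of monthly physician visits, for a large urban
HIV/AIDS clinic. The package is aimed at health economists and
implementation researchers who want the full evaluation pipeline as tested,
reusable code: a synthetic retrospective cohort stage, effectiveness
estimation, deterministic incremental cost-effectiveness, and one-way plus
probabilistic sensitivity analysis.

Effectiveness is the probability of a **Favorable Immune Response (FIR)**,
a follow-up CD4 count > 500 cells/µL. With annual per-patient cost `C_s`
and FIR probability `p_s` per strategy,

```
ΔC = C_PRP − C_SOC      ΔE = p_PRP − p_SOC      ICER = |ΔC/ΔE|
```

reported with its cost-effectiveness-plane quadrant (the base case lies in
the southwest: cheaper and very slightly less effective, so the ICER reads
as dollars saved per FIR forgone). Uncertainty is handled the standard way:
one-way ranges (costs halved/doubled, probabilities ±20%) read as 95%
confidence intervals, moment-matched beta (probabilities) and gamma (costs)
distributions, 10,000-iteration Monte Carlo simulation, and
cost-effectiveness acceptability curves (CEAC) from the net-monetary-benefit
rule `NMB_s(λ) = λ·p_s − C_s`. See `docs/methods.md` for the model's
assumptions and design choices.

## Worked example

The published base-case parameter set ships with the package
(`refill_cea/data/paper_params.yaml`). Deterministic analysis:

```
$ refill-cea cea --out results
societal: SOC $655 vs PRP $520/person-year; dC -135, dE -0.010; ICER $13,500 per FIR (SW)
     moh: SOC $610 vs PRP $496/person-year; dC -114, dE -0.010; ICER $11,400 per FIR (SW)
```

Read: from the limited societal perspective the refill program saves $135
per patient-year while giving up 0.010 in FIR probability — one FIR forgone
per $13,500 saved ($11,400 from the Ministry-of-Health perspective, which
excludes patient transport and lost time). Probabilistic sensitivity
analysis and the acceptability curve:

```
$ refill-cea psa --out results --seed 0
quadrant fractions: SE 0.356, SW 0.644
mean dC -135.2, mean dE -0.0102, fraction cost-saving 1.0000

$ refill-cea ceac --out results --seed 0
curves cross at a willingness to pay of $13,108 per FIR
```

Every Monte Carlo replicate is cost-saving (all draws below the cost axis),
about a third land in the southeast quadrant where the program is also more
effective, and the program stays the preferred strategy until a decision
maker values a FIR at roughly $13,000 — near the deterministic ICER, with a
Monte-Carlo spread of a few hundred dollars across seeds.

The same pieces are available as a library:

```python
from refill_cea import paper_model, incremental, icer, Perspective

model = paper_model()
dc, de = incremental(model, Perspective.LIMITED_SOCIETAL)
print(icer(dc, de).icer)   # 13499.999999999987
```

`refill-cea all --out results --seed 0` chains every stage — synthetic
cohort, effectiveness (crude/adjusted odds ratios via logistic regression),
CEA, tornado, PSA, CEAC — and writes CSV/JSON artifacts plus a manifest.
The patient-level stage runs on a synthetic cohort generated to match the
published descriptive statistics (the clinic database is not public), so
its odds ratios vary by seed around the configured arm effect of 0.93.

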