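# sahcue

A pre-trial cost-utility engine for therapies that aim to reduce cerebral
infarction in aneurysmal subarachnoid hemorrhage (aSAH) patients.

Before committing to a phase-3 trial, investigators and payers want to know
whether a candidate drug *could* be cost-effective given (1) its price per
patient and (2) the infarction reduction it might plausibly deliver. `sahcue`
answers that question with a decision-analytic cohort model: 100 hypothetical
aSAH patients are split at admission into an infarction stratum (base rate
35%) and a no-infarction stratum, each stratum's functional status
(independent mRS 0–2 / dependent mRS 3–5 / dead) evolves through a simple
Markov state-transition model over 30 years, and costs (acute admission,
disability-band care, nursing-home care) and point-in-time QALYs are
accumulated at 1-, 5- and 30-year horizons.

For an intervention costing *C* per patient that shifts the infarction
proportion from the base case to a counterfactual saving *S* dollars and
gaining *G* QALYs over *n* patients, the incremental cost-utility ratio is

```
ICER = (n·C − S) / G        [USD per QALY gained]
```

classified against willingness-to-pay tiers of <\$50,000, <\$100,000 and
<\$150,000 per QALY (strict `<`; a negative ICER with positive QALY gain is
*dominant*, i.e. cost-saving). One-way deterministic sensitivity sweeps
(nursing-home cost, intervention cost, QALY gain, long-term care cost of
independent patients) produce a tornado ordering of parameter influence.
A drug-costing module prices real candidate regimens — cilostazol,
nimodipine, 25% IV albumin (whole-bag dispensing), clazosentan, and their
combinations — from NADAC/AWP unit costs and dosing rules.

Intended users: neurocritical-care trialists, health-economics analysts, and
anyone running threshold analyses ("how much infarction reduction would a
\$15,000 drug need?").

## Worked example

```
$ sahcue scenarios --out scenarios.csv
scenario p=0.35 horizon=1y mode=anchor cost=13,777,940 qaly=56.9 (shipped defaults)
scenario p=0.35 horizon=5y mode=anchor cost=21,833,504 qaly=56.1 (shipped defaults)
...
scenario p=0.20 horizon=30y mode=anchor cost=61,177,403 qaly=20.2 (shipped defaults)
```

The base case (35% infarction) costs \$13,777,940 for the 100-patient cohort
in its first year, with a cohort utility of 56.9 QALYs measured
cross-sectionally at the 1-year point. Reducing the infarction proportion to
20% lowers the 1-year cost to \$13,012,653 and raises utility to 60.8 — a
saving of \$765,287 and a gain of 3.9 QALYs, which is what an intervention
delivering a 15-point reduction would buy.

```python
>>> from sahcue import default_config, evaluate_intervention
>>> cfg = default_config()
>>> r = evaluate_intervention(cfg, horizon=5, reduction=0.15, cost_per_patient=5000)
>>> round(r.icer), r.wtp_class
(-230905, 'dominant')
```

A \$5,000-per-patient drug achieving a 15-point reduction is dominant at the
5-year horizon: it saves more (\$1,261,986) than it costs (\$500,000) while
gaining 3.3 QALYs. The same grid shows a \$15,000 drug (clazosentan-like
pricing) is cost-effective only at 5 years with a 15% reduction
(\$72,125/QALY, under the <\$100k tier), and a \$20,000 drug clears no tier
anywhere.

```
$ sahcue drugcost --regimen cilostazol-200+albumin-1+nimodipine
cilostazol-200+albumin-1+nimodipine   unit $57.09   per day $460.30   course $725.28

$ sahcue tornado --out tornado.csv
tornado nh_cost: anchor -146,576 -> [-104,231, -188,921] span 84,690 (shipped defaults)
tornado intervention_cost: anchor -230,905 -> [-261,208, -200,602] span 60,606 (shipped defaults)
tornado longterm_cost_mrs02: anchor -146,576 -> [-171,429, -121,723] span 49,706 (shipped defaults)
tornado qaly_gain: anchor -230,905 -> [-256,561, -209,913] span 46,647 (shipped defaults)
```

The tornado confirms nursing-home cost is the dominant uncertainty; varying
the QALY gain by ±10% moves the anchor ICER by +\$20,991 / −\$25,656, and
±20% on the intervention price moves it by ±\$30,303.

Other commands: `sahcue icer-grid` (full grid + ICER-vs-cost plot series),
`sahcue fixtures` (default + seeded perturbed configs). All commands accept
`--config PATH`; see `fixtures/default.yaml` output for the full commented
parameter ledger.

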