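# catgrm

Tools for developing **computerized adaptive tests (CAT)** from ordinal
Likert questionnaires, in the tradition of PROMIS-style mood scales: you
start from a pool of 5-point items measuring a single construct
(depression, anxiety, positive affect, ...), screen the pool against the
assumptions of item response theory, calibrate a graded response model,
and simulate how well a short adaptive test reproduces the full-scale
score.

## Who this is for

Psychometricians and clinical researchers who want a scriptable,
fully-synthetic-testable pipeline for polytomous IRT scale development:
every stage runs on generated data, so the whole battery can be
exercised, unit-tested, and benchmarked without any proprietary response
data.

## The model

Items follow Samejima's graded response model (GRM). For an item with
discrimination *a* and ordered thresholds *b₁ < … < b₄*, the probability
of responding in category *k* or higher is logistic,

&nbsp;&nbsp;&nbsp;&nbsp;P\*ₖ(θ) = 1 / (1 + exp(−a(θ − bₖ))),

and category probabilities are adjacent differences of these boundary
curves. The latent trait θ is standard normal. Adaptive testing selects,
at each step, the unadministered item with maximum Fisher information at
the current trait estimate; the trait is re-estimated after every
response by posterior mode (MAP, "Bayesian mode estimation"), and the
session stops once the standard error of measurement drops to 0.32
(≈ reliability 0.90) after a minimum of three items, or when the item
budget is exhausted.

## The screening battery

Items are filtered, in order, by the standard cutoffs baked into
`RunConfig`:

| stage | rule |
|---|---|
| complete cases | respondents with any missing answer dropped |
| unused categories | items with an unobserved category dropped |
| item-remainder | Pearson r with the remainder score < 0.3 → dropped |
| unidimensionality | 1st principal component ≥ 20% of variance and 1st/2nd ratio ≥ 4, else iterative removal |
| local dependence | one-factor residual correlation > 0.2 → weaker pair member dropped |
| monotonicity | Loevinger scalability Hᵢ < 0.3 → dropped |
| never-modal category | calibrated items with a never-modal category dropped |
| item fit | S-X² (rest-score, Lord–Wingersky expected tables) p < 0.01 → dropped |
| DIF | per-item multigroup likelihood-ratio test, p < 0.01 → dropped |

Calibration is marginal maximum likelihood (Bock–Aitkin EM, 61-point
standard-normal quadrature). After selection the scale is recalibrated,
Cronbach's α computed, and a CAT simulation run against the full-bank
MAP scores (θ_true); accuracy is the Pearson correlation between the
adaptive estimates (θ_est) and θ_true.

## Worked example

```python
from catgrm import (CATConfig, RunConfig, SyntheticConfig,
                    generate_dataset, run_pipeline)

data, bank, theta = generate_dataset(SyntheticConfig(
    n_respondents=600, n_items=12, seed=0,
    threshold_spread=1.2, min_threshold_gap=1.2))
result = run_pipeline(data, RunConfig(em_tol=1e-3))
print(f"items retained: {len(result.calibration.bank)} of {data.n_items}")
print(f"alpha = {result.calibration.alpha:.3f}")
print(f"PCC(theta_est, theta_true) = {result.simulation.pcc:.3f}")
print(f"mean items administered = {result.simulation.mean_items:.2f}")
```

prints

```
items retained: 12 of 12
alpha = 0.898
PCC(theta_est, theta_true) = 0.940
mean items administered = 8.29
```

i.e. on this clean 12-item synthetic scale every item survives
screening, internal consistency is high, and an adaptive test averaging
about 8 items reproduces the full 12-item score with r ≈ 0.94. The same
pipeline is available from the shell:

```
catgrm simulate-data --n-respondents 600 --n-items 12 --seed 0 \
    --out responses.csv --meta meta.csv
catgrm run-all --data responses.csv --meta meta.csv --out report.json
```

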