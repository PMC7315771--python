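# catgrm

Polytomous item response theory (IRT) and computerized adaptive testing
(CAT) for ordinal self-report scales, built around the workflow used to
turn a large screening item pool into a short adaptive instrument:

1. **Item-bank construction and QC** — unidimensionality screening
   (first-factor loadings, eigenvalue ratio, variance share), marginal
   maximum likelihood calibration of the graded response model (GRM),
   generalized partial credit model (GPCM) and nominal response model
   (NRM) with AIC/BIC model selection, S-X² item-fit testing,
   differential item functioning (DIF) via ordinal logistic regression
   and McFadden pseudo-R² change, and a discrimination filter.
2. **A GRM CAT engine** — random first item, expected a posteriori (EAP)
   trait estimation over a Normal(0, 1) quadrature prior, maximum Fisher
   information item selection, and stopping on the information-based
   standard error `SE(θ) = 1/√I(θ)` or an item cap.
3. **Evaluation** — marginal reliability `1 − mean(SE²)`, correlation of
   adaptive with full-bank scores, sensitivity/specificity/Youden
   index/AUC against a diagnostic criterion, and a logistic
   diagnosis-probability curve with percentile ranks.

The package is aimed at psychometricians and clinical researchers who
want to prototype adaptive short forms of ordinal symptom scales and
quantify what precision is lost relative to administering the full bank.
It ships a calibrated 68-item GRM bank for separation anxiety screening
in adolescents (mixed 3/4/5-category items) as a packaged fixture, plus
a synthetic-respondent generator so the whole pipeline is testable
without any external data.

## The model

For an item with ordered categories `k = 0..m−1`, slope `a` and strictly
increasing thresholds `b_1 < … < b_{m−1}`, the GRM sets

```
P*(X ≥ k | θ) = 1 / (1 + exp(−a(θ − b_k))),   P*₀ = 1, P*_m = 0
P(X = k | θ)  = P*_k − P*_{k+1}
```

with item information `I_j(θ) = Σ_k (∂P_k/∂θ)² / P_k`, test information
`I(θ) = Σ_j I_j(θ)`, `SE(θ) = 1/√I(θ)`, and per-person reliability
`r_xx(θ) = 1 − 1/I(θ)` on a trait scale fixed to mean 0, SD 1.

## Worked example

Simulate 1000 respondents with θ ~ Normal(0, 1) on the packaged bank and
replay the adaptive test under each stopping rule:

```python
from catgrm import generate_respondents, load_packaged_bank, run_study, study_table

bank = load_packaged_bank()                      # 68 calibrated GRM items
respondents = generate_respondents(1000, bank, seed=1)
print(study_table(run_study(respondents, bank, seed=1)).round(3).to_string(index=False))
```

```
stopping_rule  mean_items  sd_items  mean_se  marginal_reliability  correlation_with_full
         none      68.000     0.000    0.211                 0.952                  1.000
       SE<0.3      17.193     2.439    0.325                 0.891                  0.972
       SE<0.4      11.125     4.104    0.397                 0.841                  0.945
       SE<0.5       7.551     3.530    0.479                 0.770                  0.916
```

Reading the `SE<0.3` row: stopping once the standard error of the trait
estimate drops below 0.3 (or at 20 items) needs about 17 of the 68 items
on average, keeps marginal reliability near 0.89, and its scores
correlate 0.97 with scoring the entire bank — the precision cost of a
75% shorter test is small. Relaxing the rule shortens the test further
at a steady cost in reliability and agreement with the full bank.

The same workflow is available from the shell:

```sh
catgrm --seed 1 simulate --n 1000 --out study.csv
catgrm --seed 1 generate --n 500 --out responses.csv
catgrm --seed 1 qc --responses responses.csv --out-bank bank_qc.csv --report qc.json
catgrm administer --interactive --se-threshold 0.3
```

## Layout

- `src/catgrm/models.py` — GRM/GPCM/NRM probabilities, likelihoods, information
- `src/catgrm/calibration.py` — MML-EM estimation, AIC/BIC comparison
- `src/catgrm/bank_qc.py` — unidimensionality, S-X², DIF, discrimination screen
- `src/catgrm/engine.py` — the adaptive administration loop
- `src/catgrm/simulation.py` — synthetic respondents, stopping-rule study
- `src/catgrm/evaluation.py` — reliability, screening metrics, diagnosis curve
- `src/catgrm/io.py`, `src/catgrm/cli.py` — formats, filters, configuration, CLI

See `docs/methods.md` for modeling assumptions, numerical choices, and
known limitations.
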