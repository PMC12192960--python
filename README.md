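# multicf

Multi-disease counterfactual recommendations over tabular risk models.

## The problem

A counterfactual explanation answers "what would this patient have to change
for the model to predict low risk?". With a single disease model this is a
one-objective search. But chronic-disease models overlap: a stroke model and
a diabetes model may share features such as age, average glucose level and
BMI, and a change that lowers one predicted risk can raise the other.
`multicf` treats the problem as *multi-objective recourse*: given one trained
probability model per disease, each on its own feature set `X_i`, it searches
the union `X_Δ = X_1 ∪ … ∪ X_n` for feature assignments that minimise **all**
predicted disease probabilities at once, subject to the patient's
constraints:

- *infeasible* features (age, gender, …) are pinned to constants
  `LB_δ = UB_δ = C_δ`;
- *feasible* continuous features move inside a window — either one the user
  supplies, or a default of ±10 % around the user's current value — always
  clipped to physiological default bounds `[LB_δ, UB_δ]`.

The search is an elitist non-dominated-sorting genetic algorithm (NSGA-II)
over a mixed continuous/binary/categorical genome: simulated binary crossover
and polynomial mutation for continuous genes, uniform exchange / re-draw for
discrete genes, binary crowded-comparison tournaments, and survival of the
best `N` of parents ∪ offspring by (front rank, crowding distance). The final
Pareto front is ranked for presentation by the penalty

```
L(x) = w₁·P_HS(x) + w₂·P_DM(x) + λ·max(0, P_HS(x) − P_DM(x))
```

(unit weights and λ = 1 by default; for n > 2 diseases the gap term
generalises to the sum of ordered pairwise positive gaps), and the lowest-
penalty solutions are returned as counterfactuals CF 1, CF 2, …

## Worked example

`examples/03_recommend.py` generates a synthetic two-disease cohort
(5,000 subjects, stroke-like and diabetes-like outcomes from known logistic
risk surfaces over a 15-feature union with 3 shared features), trains a
logistic model per disease, and searches with population 500 for 40
generations for a 32-year-old man who fixed his age, gender, marital status
and work type and anchored BMI at 20.10:

```
recommended feature values (one column per counterfactual):
                           CF 1          CF 2
age                      32.000        32.000
hypertension                 no            no
heart_disease                no            no
avg_glucose_level        50.000        50.000
bmi                      18.090        18.090
...
insulin                   0.007         0.034
diabetes_pedigree         0.080         0.080

CF 1: P(heart_stroke) = 0.004477, P(diabetes) = 0.027232, penalty = 0.031708
CF 2: P(heart_stroke) = 0.004477, P(diabetes) = 0.027233, penalty = 0.031710

convergence (per-generation minima):
 generation  min_heart_stroke  min_diabetes  min_penalty
          0          0.004661      0.043904     0.055758
         10          0.004481      0.028736     0.033622
         20          0.004477      0.027324     0.031801
         40          0.004477      0.027231     0.031708
```

Fixed features stay at their constants in every recommendation, the BMI
recommendation sits inside the ±10 % window [18.09, 22.11], and both
per-disease minima decrease monotonically — elitist selection can never lose
the best solution of a generation. The other examples cover the feature
union and bounds (`01`), the model zoo and metric table (`02`), the penalty
arithmetic (`04`) and the analytic oracles of the synthetic generator (`05`).

## Command line

The same pipeline is scriptable from a shell:

```bash
multicf generate-data --n 5000 --seed 1 --out data/
multicf train --config data/problem.yaml --data data/ --out models/
multicf recommend --config data/problem.yaml --models models/ \
    --out run/ --num-cf 2 --population-size 500 --max-generations 40 --seed 1
```

`recommend` writes `recommendations.csv` (feature × CF table), `pareto.csv`
(objective pairs with the minimum-penalty member flagged), `trace.csv`
(per-generation objective minima) and `provenance.json` (the fully resolved
configuration and seed, sufficient to replay the run).

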