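# surveycog

Infer cognitive-ability information from the way people answer ordinary
self-report questionnaires.

Standardized cognitive testing is expensive and burdensome, while rating-scale
questionnaires are everywhere. Completing a questionnaire is itself a
cognitively demanding task, and two robust regularities from intelligence
research should leave fingerprints in the answers if they carry ability
information: the **worst performance rule** (WPR — a person's *worst* trials
are the most ability-diagnostic) and the **task complexity hypothesis**
(TCH — performance on higher-information-load tasks correlates more strongly
with general ability). `surveycog` implements the full analysis chain needed
to test both on ordinal questionnaire data, plus a synthetic-data generator
that emulates the statistical structure the analyses assume, so the entire
pipeline is testable without restricted survey data.

## The model

For each multi-item scale a unidimensional graded response model (GRM) is
fitted by marginal maximum likelihood: the probability that person *i* picks
category *k* or higher on item *j* is

    P*_ijk = logistic(a_j (θ_i − b_jk)),   k = 2..m_j,

with discrimination `a_j > 0` and ordered thresholds `b_j1 < … < b_j,m−1`.
Person traits θ̂ are expected-a-posteriori (EAP) scores under a standard
normal prior. The **response error score** for an observed response `y` is

    error = | y − E(Y | θ̂) | / (m_j − 1),   E(Y | θ̂) = Σ_k k·P(Y = k | θ̂),

a number in [0, 1]: 0 when the answer is exactly the statistically expected
one, 1 when it is maximally deviant. Scores are computed only for
person × scale blocks with no missing responses.

*WPR analysis.* Each person's (cube-root transformed) error scores are sorted
into ten equal-count deciles; decile means are correlated with a cognitive
composite; the equality of the ten dependent correlations is tested by an
omnibus Wald test on Fisher-z scale with a delta-method covariance, followed
by pairwise contrasts.

*TCH analysis.* Item complexity is coded as ten binary indicators (word
count, familiar-word list, three precomputed clarity flags, and five lexicon
categories: conjunctions, negations, discrepancy, tentative, and
differentiation words), summed into a 0–10 composite. A cross-level
interaction mixed model regresses item-level errors on complexity with
person-level random intercepts and slopes, both moderated by ability
(`error_ij = γ00 + γ01·ability_i + γ10·c_j + γ11·ability_i·c_j + u_0i +
u_1i·c_j + r_ij`). A reparameterization with basis weights `(9−c)/9` and
`c/9` yields latent person error levels at the complexity extremes and their
correlations with ability — either the manifest 0–27 composite or a latent
factor measured by four cognitive subtests with a recall residual covariance.

## Worked example

```python
from surveycog import SimulationConfig, simulate_study, score_all_scales
from surveycog.wpr import per_person_deciles, DecileCorrelationAnalysis

study = simulate_study(SimulationConfig(n_persons=1500, rng_seed=21))
errors, thetas, fits = score_all_scales(study.responses, study.items)
print(float(errors["error"].median()))            # 0.1122

deciles = per_person_deciles(errors)              # cube-root transform + 10 bins
ability = study.cognition.set_index("person_id")["composite"]
res = DecileCorrelationAnalysis(deciles, ability).fit()
print(res.summary())
```

The median error score of 0.1122 says that a typical response sits about a
tenth of the scale away from the model-expected response; the distribution
is strongly right-skewed. On this seed the decile–ability correlations rise
in magnitude from −0.11 (smallest errors, decile 1) to −0.38/−0.36 in the
top two deciles, and the omnibus Wald test rejects equality decisively
(χ²(9) = 87.6, p ≈ 5 × 10⁻¹⁵ at n = 1500): the worst-performance-rule
pattern — a person's largest response errors carry the most information
about their ability. The task-complexity side:

```python
from surveycog.wpr import cube_root_transform
from surveycog.tch import ModeratedErrorModel

errors["terr"] = cube_root_transform(errors["error"])
long = (errors.merge(study.items[["item_id", "complexity"]], on="item_id")
              .merge(ability.rename("ability"), left_on="person_id",
                     right_index=True))
fit = ModeratedErrorModel(long, error_col="terr").fit()
print(fit.summary())
print(fit.simple_slopes())
```

prints a negative ability slope at complexity 0 (−0.0012, robust SE 0.0002),
a positive complexity slope (0.0077), and a negative `ability_x_complexity`
interaction (−0.0002, z ≈ −5.7) whose size implies the ability–error
association strengthens by about 16% per complexity point — the
task-complexity signature.

The same chain runs from the shell:

```bash
surveycog all --outdir run1 --seed 7       # simulate ... report
cat run1/report.md
```

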