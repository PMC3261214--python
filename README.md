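# epirt — item-response calibration of diagnostic codes in electronic patient records

Coded primary-care records register a clinical event (say, a first stroke)
with one or more diagnostic codes drawn from a large code set.  Which code
a practitioner picks carries information: some codes are vague
("CVA unspecified"), some are precise ("thrombosis of cavernous sinus"),
and practices differ systematically in their choices.  `epirt` treats the
codes as *psychometric items*: the presence of code *i* in patient *s*'s
record is a binary endorsement `X_si`, and the codes are calibrated with
logistic item-response (IRT) models so that each code gets a
**discrimination** and a **location** on a latent trait — interpretable as
the degree of confidence in the diagnosis.

It is written for epidemiologists and health-data researchers who work
with coded event tables (one row per patient, code and date, with a
practice identifier) and want to characterise, rather than merely count,
the codes that define a phenotype.

## The model

The two-parameter logistic (2PL) model gives the probability that the
record of subject *s* contains code *i* as

```
P(X_si = 1 | θ_s) = exp(α_i (θ_s − β_i)) / (1 + exp(α_i (θ_s − β_i)))
```

where `θ_s ~ N(0, 1)` is the subject's latent trait, `β_i` is the code's
location (the trait level at which endorsement probability is ½ — high for
rarely-used, specific codes) and `α_i` its discrimination.  The 1PL
variant shares a single slope across codes; the 3PL adds a lower asymptote
`γ_i`.  Estimation is **marginal maximum likelihood** via the Bock–Aitkin
EM algorithm on a fixed quadrature grid, with a few post-EM Newton polish
cycles, standard errors from the observed information of the marginal
likelihood, and EAP (expected-a-posteriori) trait scores.

Around the model sits the full pipeline:

* `epirt.records` — event CSV loading, same-date deduplication, first-event
  cohort/index-date construction, and the binary patient×code response
  matrix over a post-index endorsement window (default 30 days);
* `epirt.descriptives` — distribution of distinct codes per patient,
  relative code frequencies, and between-practice intraclass correlation
  (one-way ANOVA estimator) per code;
* `epirt.irt` — item screening (item-rest correlation below −0.15 excludes
  codes outside the measurable range), `CodeIRT` model / `CodeIRTResults`;
* `epirt.fitstats` — leave-one-out interval chi-square item-fit
  diagnostics, parametric-bootstrap reference distributions, and nested
  1PL/2PL/3PL likelihood-ratio comparisons;
* `epirt.synthetic` — a seeded generator of coded-event extracts with known
  latent structure, including a preset that emulates a national
  primary-care stroke extract;
* `epirt` CLI — `simulate`, `prepare`, `describe`, `fit`, `report`.

## Worked example

```python
import datetime as dt
from epirt import (CodeIRT, CohortConfig, paper_like_preset, generate,
                   records, descriptives)

cfg = paper_like_preset(n_patients=20_000, seed=1)
events, truth = generate(cfg)
events = records.deduplicate_same_date(events)
window = CohortConfig(dt.date(1997, 1, 1), dt.date(2006, 12, 31),
                      post_index_window_days=30)
cohort = records.build_cohort(events, window)
matrix = records.build_response_matrix(events, cohort, window)

print(descriptives.code_count_distribution(matrix).head(4).to_string(index=False))
print(descriptives.icc_table(matrix, top=3)[["code", "icc", "relative_frequency"]]
      .round(3).to_string(index=False))
res = CodeIRT(matrix, model="2pl").fit(criterion=1e-3, max_em=100, max_newton=10)
print(res.summary())
```

prints (abridged):

```
 distinct_codes  n_patients  percentage  display_percentage
              1       16374      81.870                  82
              2        2529      12.645                  13
              3         555       2.775                   3
              4         222       1.110                   1

code   icc  relative_frequency
c000 0.218               0.215
c001 0.165               0.153
c002 0.255               0.145

2PL item-response calibration (marginal maximum likelihood)
patients: 20000   items kept: 94   excluded: 7
-2 log-likelihood: 50123.32
EM cycles: 71   Newton cycles: 1   converged: True (last change 0.000763 vs criterion 0.001)

code  alpha  se_alpha     beta      se_beta  n_endorsed
c007  0.153     0.067   20.315        8.936         868
c008  2.951     0.140    2.181        0.040         490
c009  3.068     0.148    2.194        0.039         449
  ...
```

Reading the output: 82% of simulated patients carry exactly one distinct
code; the three commonest codes show substantial between-practice
variation (ICC up to ~0.26), reflecting practice-level preferences among
near-synonymous codes; those same frequent codes fail the item-rest
screen (7 excluded) because a record that contains one of them rarely
contains anything else — they sit outside the measurable range of the
trait.  Among the calibrated codes, rarer codes get higher locations and
larger standard errors, the characteristic pattern for codes far out on
the latent continuum.

The same run from the shell:

```
epirt simulate --seed 1 --out-dir run/sim
epirt prepare  --events run/sim/events.csv --out-dir run/mat
epirt describe --events run/sim/events.csv --matrix-dir run/mat --out-dir run/desc
epirt fit      --matrix-dir run/mat --out-dir run/fit2
epirt fit      --matrix-dir run/mat --model 1pl --out-dir run/fit1
epirt report   --matrix-dir run/mat --fit-dir run/fit1 --fit-dir run/fit2 --out-dir run/rep
```

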