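# episcore

Gene-expression-based prognostic risk scores for survival cohorts, built
from treatment-deregulated genes.

Multiple myeloma (and other tumors) respond transcriptionally to epigenetic
drugs — DNA-methyltransferase inhibitors such as decitabine and histone
deacetylase inhibitors such as quisinostat.  The genes a drug deregulates
*in vivo* in a murine model often carry prognostic information in human
patients.  `episcore` implements the full methodology for turning such a
treatment signature into a validated patient risk score:

1. **Differential expression** — SAM-style two-class permutation test on the
   treated-vs-vehicle experiment (d statistic with fudge factor s0, exact
   label enumeration for small designs, Benjamini–Hochberg FDR, fold-change
   filter `ratio ≥ 2`).
2. **Ortholog translation** — murine deregulated genes → human probe sets
   via an explicit many-to-many map; each probe set is screened
   independently.
3. **Per-probe survival cutpoints** — maximally selected log-rank
   statistics: for probe *g*, the cutpoint `c_g` maximizes the standardized
   log-rank statistic |Z(c)| over the 10th–90th percentile candidate range,
   with a selection-corrected p-value (survival-permutation null by default,
   improved-Bonferroni approximation optionally) and BH adjustment across
   probes.  Kept probes are labeled *good* (HR < 1) or *bad* (HR > 1) by the
   univariate Cox fit on the dichotomized marker.
4. **The ±β risk score** — for patient *i*,

   `score_i = Σ_g w_ig · β_g`, with `w_ig = +1` if the patient's signal for
   probe *g* is above `c_g` and `−1` otherwise, where `β_g = ln HR_g` is the
   training-cohort Cox coefficient.  A score-level cutpoint θ is selected by
   the same maxstat engine; patients with `score > θ` form the high-risk
   group.
5. **Validation and evaluation** — frozen-parameter stratification of
   independent cohorts (Kaplan–Meier, log-rank, median OS, uni/bi/
   multivariate Cox against clinical covariates), response-prediction
   contingency analysis (sensitivity/specificity, Fisher exact), Spearman
   correlation with ordinal proliferation classes, and Mann–Whitney
   comparisons across molecular subgroups.

A synthetic-data module generates every input the pipeline consumes —
two-arm expression experiments with planted fold changes, survival cohorts
with planted dichotomous hazard effects, response and subgroup labels —
with ground-truth tables, so the whole methodology is testable end to end
without any external download.  The published 25-probe decitabine (Mu-DM)
and 61-probe quisinostat (Mu-HA) score models ship as JSON
(`episcore.load_published_model`), carrying probe sets, gene symbols and
hazard ratios; their expression cutpoints were never published, so scoring
against them requires user-supplied cutpoints.

## Worked example

Train a score on a synthetic 400-patient cohort whose 20 probes all carry a
planted hazard effect (|β| = ln 3, ten protective and ten adverse), then
validate it on an independently generated cohort:

```python
import numpy as np
import episcore as ep

beta = float(np.log(3))
planted = {i: (0.5, beta if i < 10 else -beta) for i in range(20)}
spec = ep.CohortSimSpec(n_patients=400, n_probes=20,
                        planted_effects=planted, censor_rate=0.3, seed=611)
matrix, cohort, truth = ep.gen_survival_cohort(spec)

fitted = ep.PrognosticScoreModel(matrix, cohort, name="demo-DM", B=999).fit(seed=612)
print(fitted.summary())
```

```
demo-DM prognostic risk score
==============================================
probes screened            20
probes kept (FDR<=0.05)      18   good: 9   bad: 9
score range          [  -9.631,    9.631]
theta (score cutoff)       -0.740
training split       low 230 (57.5%) / high 170 (42.5%)
median OS            low not reached / high 4.5 mo
log-rank             chi2 = 269.11, p = 1.77e-60

             cutpoint    beta     hr    p_adj prognosis
probe_id
probe_00000     391.3  0.4603  1.585  0.03176       bad
probe_00001     232.9  0.4716  1.603    0.012       bad
...
```

The screen recovered 18 of the 20 planted probes with the correct
good/bad label.  Note the per-probe `beta` values are smaller than the
planted ln 3 ≈ 1.10: with twenty independent hazard effects acting at once,
each probe's *marginal* dichotomous effect is attenuated by the unobserved
heterogeneity the other nineteen create (see `docs/methods.md`).  The
low-risk group never reaches median overall survival while the high-risk
group's median is a few months — the pattern the score is designed to
expose.  Applying the frozen model to an independent cohort:

```python
vspec = ep.CohortSimSpec(n_patients=400, n_probes=20,
                         planted_effects=planted, censor_rate=0.3, seed=70001)
vmatrix, vcohort, _ = ep.gen_survival_cohort(vspec)
strat = fitted.validate(vmatrix, vcohort)
print(strat.summary_dict())
# {'model': 'demo-DM', 'theta': -0.740, 'n': 400, 'n_low': 230, 'n_high': 170,
#  'frac_low': 0.575, 'frac_high': 0.425, 'median_os_low': 'not reached',
#  'median_os_high': 7.13, 'logrank_chi2': 168.43, 'logrank_p': 1.63e-38, ...}
```

Nothing is re-estimated at validation: per-probe cutpoints, βs and θ are
all frozen from training.

## Command line

Every stage is also a subcommand of the `episcore` CLI:

```sh
episcore run --demo --out runs/demo          # full pipeline in a few seconds
episcore de --matrix X.tsv --pheno P.tsv --seed 1 --out de.tsv
episcore screen --matrix X.tsv --surv S.tsv --B 999 --seed 2 --out prognostic.tsv
episcore train --matrix X.tsv --surv S.tsv --name Mu-DM --seed 3 --out model.json
episcore score --model model.json --matrix Y.tsv --out scores.tsv
episcore validate --model model.json --matrix Y.tsv --surv S2.tsv --out strat.json
episcore evaluate --scores scores.tsv --pheno P.tsv --mode response --theta -0.74 --out eval.json
```

`episcore run --config cfg.yaml --out runs/x` drives the whole analysis from
a single YAML config; every stochastic stage must name an explicit seed and
each run directory records the config and its hash, so identical configs
reproduce bit-identically.

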