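# pathmed

Path-specific effects of a randomised treatment on a time-to-event outcome,
mediated by repeatedly measured post-baseline covariates, under time-varying
confounding.

## The problem

In many trials a treatment affects survival partly *through* an intermediate
biomarker that is re-measured at scheduled visits (say months 3 and 9), and
partly through other channels. Splitting the total effect into a mediated and
a non-mediated part is hard for a survival outcome because

* the mediator is measured repeatedly, and later measurements are confounded
  by post-baseline covariates that the treatment itself affects;
* patients die (or are censored) *between* visits, so later mediator values
  are undefined for part of the population and naive regression adjustment
  conditions on survival.

`pathmed` estimates the **path-specific survival curves** `S_{a,a*}(t)`: the
probability of surviving beyond `t` when every treatment arrow carries arm
`a` *except* the arrows pointing into the mediator assessments, which carry
arm `a*`. Three curves summarise the trial:

| curve      | treatment arrows | mediator arrows | meaning                     |
|------------|------------------|-----------------|-----------------------------|
| `S_{1,1}`  | treated          | treated         | ordinary treated survival   |
| `S_{1,0}`  | treated          | control         | treated, mediator path off  |
| `S_{0,0}`  | control          | control         | ordinary control survival   |

`S_{1,1}/S_{1,0}` is the **indirect** (mediated) effect, `S_{1,0}/S_{0,0}`
the **direct** effect, and `(S11−S10)/(S11−S00)` the mediated proportion.
Because *all* paths into the mediators are bundled into one channel, the
decomposition stays identified even when confounders are treatment-responsive
(no "recanting witness" problem).

## The estimator

A nested sequence of regressions, working backwards from the horizon `t`:

1. **Terminal step** — a Cox model for the hazard after the last visit
   preceding `t`, fitted in arm `a` on the patients still at risk, left
   truncated at that visit; predict interval survival to `t`.
2. **Mediator integration** — regress that prediction on the history
   *excluding* the current mediator, in arm `a*` (quasi-binomial logistic
   model, since the response is a fitted probability). This averages the
   current mediator out under arm `a*`.
3. **Confounder integration** — regress the result on the shorter history in
   arm `a`, and predict for the *larger* risk set of the previous visit:
   this averages the current confounders (and survival to the visit) under
   arm `a`.
4. **Visit survival** — multiply by the arm-`a` probability of surviving to
   the visit given the shorter history (another Cox step).

Repeat per visit; the estimate is the average of the final prediction over
all patients. A useful robustness property (tested): when `a = a*` the logit
steps only re-average their own fitted values, so the same-arm curves
`S_{1,1}` and `S_{0,0}` are nearly unaffected by misspecifying them — only
the crossed curve `S_{1,0}` relies on their correctness.

Inference is by nonparametric bootstrap of whole patients with percentile
intervals.

## Worked example

A two-visit synthetic trial (visits at months 3 and 9, 24-month horizon,
HbA1c-like mediator near 62 units). The treatment lowers the mediator by 10
units and the event log-hazard by 0.4; higher mediator values raise the
hazard, so part of the survival benefit is mediated:

```python
import pathmed as pm

cfg = pm.two_visit_config(n=10_000, mediator_effect=-10.0, direct_effect=-0.4)
ds = pm.simulate_trial(cfg, seed=1)
eff = pm.bootstrap_cis(ds, [6.0, 12.0, 18.0], B=200, seed=2, scale="ratio")
print(eff.to_frame().round(3))
```

Output (about one minute; `pie` = indirect survival ratio, `pde` = direct,
`mp` = mediated proportion):

```text
   t curve  estimate    lo    hi
 6.0   pie     1.008 1.003 1.017
12.0   pie     1.029 1.008 1.067
18.0   pie     1.057 1.020 1.120
 6.0   pde     1.024 1.010 1.037
12.0   pde     1.053 1.012 1.078
18.0   pde     1.072 1.015 1.118
 6.0    mp     0.263 0.084 0.613
12.0    mp     0.366 0.087 0.843
18.0    mp     0.456 0.155 0.871
```

with estimated curves at (6, 12, 18) months

```text
S11 = [0.958, 0.924, 0.890]
S10 = [0.950, 0.898, 0.842]
S00 = [0.927, 0.853, 0.785]
```

So by month 18 treatment improves survival from 0.785 to 0.890, and an
estimated 46% (CI 16–87%) of that gain flows through the mediator.

The same from the command line:

```bash
pathmed simulate --design two_visit --n 5000 --seed 1 --out trial.csv
pathmed estimate --data trial.csv --schema trial.csv.schema.yaml \
    --a 1 --astar 0 --grid 6,12,18 --out s10.csv
pathmed effects  --data trial.csv --schema trial.csv.schema.yaml \
    --grid 6,12,18 --B 200 --seed 2 --out effects.csv
pathmed validate   # deterministic ten-patient worked-example replay
```

`pathmed validate` prints

```text
frozen-replay S_(1,0)(5) = 0.8008 (reference 0.80): PASS
```

## Analytic special case

With a single mediator wave at `tau_1`, *additive* hazards and a normal
linear mediator model, the nested estimand integrates in closed form
(`pathmed.dynpath`): the direct survival ratio is `exp{−Λ1(t)}` and the
indirect one `exp{−[Λ2(t)−Λ2(tau_1)] α1}`. The package uses this as an exact
oracle for the general estimator, and quantifies how classical dynamic path
analysis — which ignores events occurring before the first mediator
assessment — overstates the indirect effect by the constant factor
`exp{−Λ2(tau_1) α1}`.

## Reproduction

Everything below is deterministic given the stated seeds.

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/   # ~1 min, 111 tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json  # ~30 s
```

`tests/test_acceptance.py` holds the headline checks: a deterministic replay
of a ten-patient worked example with frozen coefficients; agreement of the
same-arm curves with Kaplan–Meier; agreement with the additive-hazard closed
form and with a structural-simulation oracle (including under a shared
mediator frailty); the same-arm robustness property; and bootstrap
determinism plus null coverage. `scripts/acceptance.py` recomputes the main
quantities from scratch with all randomness derived from `--seed` and writes
them as JSON.

## Layout

```
src/pathmed/
  datamodel.py   dataset container, risk sets, history designs, long-CSV I/O
  hazard.py      Cox (Breslow ties + baseline), quasi-binomial logit
  gcomp.py       the nested sequential-regression estimator
  effects.py     effect contrasts and the patient bootstrap
  dynpath.py     additive-hazard closed forms
  simulate.py    structural simulator, oracle, reference designs, fixture
  cli.py         `pathmed` command-line interface
docs/methods.md  methods note: model, assumptions, defaults, limitations
```
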