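# weberkit

Psychophysics of magnitude discrimination for developmental-dyscalculia
research: estimate each child's Weber fraction (*w*) from two-alternative
discrimination data, simulate whole study cohorts with known ground
truth, and compare groups with the heteroscedasticity-aware statistics
such studies use.

It is written for researchers in numerical cognition who want the full
analysis chain — trial design, preprocessing, acuity estimation, group
comparison — as tested, reproducible code, validated end-to-end by
parameter recovery on synthetic observers rather than on any particular
dataset.

## The model

A magnitude *n* (a dot count, or a duration in ms) is represented
internally as a Gaussian N(*n*, *w·n*).  For a pair *n₁* > *n₂* the
predicted error rate is

    error = ½ · erfc( (n₁ − n₂) / (√2 · w · √(n₁² + n₂²)) )

which depends only on the ratio *n₁/n₂* — so numerosity and duration
tasks share one scale-free computation.  A participant's *w* is fitted
by Levenberg–Marquardt nonlinear least squares on mean accuracy per
ratio bin; fits with r² < 0.2 are flagged for exclusion.  Groups are
compared with a decision tree: Levene's test gates ANOVA/ANCOVA +
Tukey–Kramer versus Brown–Forsythe + Games–Howell, with a
homogeneity-of-slopes pretest before every ANCOVA, plus Mann–Whitney U
(with *r = z/√N*) for the skewed *w* distributions.  See
`docs/methods.md` for the full account.

## Worked example

Fit one 75-trial numerosity session (ratio bins 1:2, 3:4, 5:6, 7:8 with
19/19/19/18 trials) simulated from a true *w* of 0.35:

```python
import numpy as np
from weberkit import BinAccuracy, fit_weber
from weberkit.simulate import sample_choices

rng = np.random.default_rng(7)
bins = []
for r, n in {2.0: 19, 4/3: 19, 6/5: 19, 8/7: 18}.items():
    hits = int(sample_choices(np.full(n, 10*r), np.full(n, 10.0), 0.35, rng).sum())
    bins.append(BinAccuracy(ratio=r, n_trials=n, n_correct=hits))
print([f"{b.ratio:.3f}: {b.n_correct}/{b.n_trials}" for b in bins])
print(fit_weber(bins))
```

prints

```
['2.000: 18/19', '1.333: 13/19', '1.200: 14/19', '1.143: 10/18']
WeberEstimate(w=0.3174910601621154, r_squared=0.8306998950586868,
              converged=True, excluded=False, n_bins_used=4, degenerate_r2=False)
```

Accuracy falls from 95% at the easy 2:1 ratio toward chance at 8:7, and
the fitted *w* of 0.317 recovers the generating 0.35 to within the noise
of a single 75-trial session (r² = 0.83, so the session is kept).

## The analysis, step by step

Numbered drivers under `analysis/` run the full study pipeline on a
simulated cohort (DD n = 19, TA4 n = 32, TA2 n = 31, acuities
moment-matched to published group descriptives) and write their tables
under `results/`:

```sh
python analysis/01_simulate_cohort.py        # raw response tables
python analysis/02_preprocess.py             # RT trimming, exclusions
python analysis/03_fit_weber.py              # per-participant w
python analysis/04_group_comparisons.py      # Levene-gated ANOVA tree
python analysis/05_parameter_recovery.py     # recovery validation
python analysis/06_statistical_calibration.py  # type-I calibration
```

The same chain is available as a CLI (`weberkit run --seed 1 --out
bundle/`, plus `simulate`, `preprocess`, `fit`, `analyze`, `report`
subcommands) and as library calls (`weberkit.run_pipeline`).

## Layout

```
src/weberkit/
  model.py        erfc psychometric model, LM + grid Weber estimators
  tasks.py        the four task designs (seeded, exactly reproducible)
  simulate.py     synthetic observers: latent acuities, choices, RTs
  preprocess.py   trimming, exclusion and aggregation rules
  stats.py        Levene / ANOVA / Brown-Forsythe / ANCOVA / post-hocs /
                  Mann-Whitney / mixed ANOVA, and the decision tree
  pipeline.py     orchestration, tidy CSV/JSON I/O, report writer
  validation.py   recovery, calibration and end-to-end experiments
  config.py, cli.py
analysis/         numbered drivers over the package
tests/            pytest suite (unit, property and whole-package checks)
```
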