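# twostep

Computational toolkit for the **spatial two-step task for rats**: a task
simulator, the reinforcement-learning agents used to model choice on it,
Bayesian likelihood fitting with DIC model comparison, and
trajectory-derived measures of deliberation (vicarious trial and error)
and procedural automation (path stereotypy), together with the
mixed-model and rank-test battery used to analyze them.  Everything runs
on synthetic cohorts with known ground truth, so every estimator in the
package can be scored against the process that generated its input.

It is written for computational/behavioral neuroscientists who want to
simulate two-step behavior, do parameter- and model-recovery studies, or
reuse the deliberation metrics on their own position-tracking data.

## The task and the models

Each lap is two sequential left/right choices.  The first-stage choice
(state C1, options A/B) leads to one of two second-stage contexts — A
commonly (80%) to C2 and rarely (20%) to C3, reversed for B.  Each
second-stage choice ends at a feeder whose cost is a delay to food,
drifting across laps as a bounded Gaussian random walk on [1, 30] s
(SD 1 s/lap); reward is modelled as `maxDelay − delay`.

Three algorithms assign values Q(s, a):

* **model-free** — SARSA(λ): `Q(s,a) ← Q(s,a) + α_i δ_i` with
  `δ_i = r_i + Q(s', a') − Q(s,a)`, r₁ = 0, plus the end-of-trial
  eligibility update `Q(s₁,a₁) ← Q(s₁,a₁) + α₁ λ δ₂`;
* **model-based** — stage-1 values computed at decision time,
  `Q_MB(C1,a) = Σ_s' p(s'|C1,a) · max_{a'} Q(s',a')`, with the 0.8/0.2
  transition probabilities fixed;
* **constant-weight hybrid** — `Q_CW = w·Q_MB + (1−w)·Q_MF`, all
  parameters shared.

Choices are softmax with perseveration,
`P(a) ∝ exp(β_i [Q(s,a) + p·rep(a)])`; fitting is Bayesian
(Beta/Exponential/Normal priors, adaptive Metropolis MCMC) with
`DIC = D(θ̄) + 2 p_D` for model comparison.  Deliberation is measured by
`LogIdPhi = log ∫ |d/dt atan2(ẏ, ẋ)| dt` over a choice-point pass, and
automation by the inverse mean time-resampled distance between same-type
paths.  See `docs/methods.md` for the full account.

## Worked example

Fit all three algorithms to a cohort generated by a hybrid agent
(w = 0.65) and compare by DIC — `examples/03_fit_and_compare.py`:

```
mf      DIC    2080.0  p_D   5.6
mb      DIC    2170.2  p_D   4.3
hybrid  DIC    1115.7  p_D   5.2, posterior mean w = 0.64

algorithm         dic      p_d   delta_dic                   support
   hybrid 1115.700419 5.248824    0.000000               most likely
       mf 2080.013396 5.639279  964.312978 considerably less support
       mb 2170.213806 4.311348 1054.513387 considerably less support
```

The generating hybrid wins with DIC margins far above the
considerably-less-support threshold of 7, its posterior mean weight
(0.64) brackets the generating w = 0.65, and p_D sits near each
algorithm's free-parameter count (6, 4, 7).

Measuring deliberation from synthetic trajectories
(`examples/04_vte_and_stereotypy.py`):

```
LogIdPhi, non-VTE mode: 4.87 (log-degrees)
LogIdPhi, VTE mode:     6.54
fitted threshold:       6.05
classification accuracy vs injected ground truth: 100.0%
```

Laps with injected head sweeps separate cleanly from straight passes,
and the mixture-fit threshold recovers the injected labels.

Other examples: `01_simulate_task.py` (a learning agent earns a mean
delay of 10.0 s vs 16.0 s for a random chooser), `02_stay_probability.py`
(the stay-by-delay signature that separates model-free from model-based
choice), `05_mixed_models.py` (mixed-model recovery of a known
VTE-correlation structure).

A thin CLI wraps the same library:

```bash
twostep generate --preset hybrid --rats 7 --sessions 51 --out run/
twostep fit --data run/laps.tsv --algorithm hybrid --out run/
twostep report --out run/   # full generate -> fit -> compare -> analyze demo
```

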