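# csfbayes

Two-dimensional Bayesian estimation of the contrast sensitivity function
(CSF), with the four adaptive sampling strategies it is most often paired
with — interleaved weighted up-down staircases, the Ψ method, qCSF-style
expected-entropy minimization, and Fisher-information-gain (FIG)
D-optimal selection — plus a simulated-observer Monte-Carlo harness for
comparing them.

## Who this is for

Vision scientists and clinical researchers who measure contrast sensitivity
with 2AFC detection tasks.  The central point the package operationalizes:
2-D Bayesian inference over the full (spatial frequency, contrast) space can
be applied *after the fact* to trial data collected by **any** sampling
procedure — including plain staircases — and recovers most of the precision
of the modern 2-D adaptive methods.  Trial logs are plain CSV
(`trial,sf_cpd,contrast,response`), so data from other lab software can be
fed straight to the `infer` command.

## Model

Sensitivity follows the double-exponential CSF
`S(f) = M f^A exp(−f/F)` (peak at `f = A·F`), and the probability of
detecting contrast `c` at frequency `f` in a 2AFC task is logistic in log
contrast with threshold `1/S(f)`:

```
P(f, c) = γ + (1 − γ − δ) / (1 + exp(−β (ln c + ln M + A ln f − f/F)))
```

with guess rate γ = 1/2 and lapse rate δ.  Inference runs on a
[32, 32, 32, 8, 8] grid over (log₁₀M, log₁₀A, log₁₀F, log₁₀β, log₁₀δ) with
a weak normal prior on the CSF parameters and narrow priors on the nuisance
parameters β and δ; the estimate is the posterior mean per dimension.  See
`docs/methods.md` for the full account.

## Worked example

Simulate one 108-trial staircase session against the bundled "normal"
observer {M, A, F, β, δ} = {100, 0.8, 4, 4, 0.02}, then fit the CSF from
the resulting log:

```
$ cat cfg.json
{"observer": {"preset": "normal"}, "sampler": "staircase", "trials": 108}
$ csfbayes simulate --config cfg.json --seed 7 --out run/
wrote 108 trials to run/trials.csv
$ csfbayes infer --log run/trials.csv --out est.json
wrote estimates for 108 trials to est.json
```

`est.json` then contains the posterior-mean parameters and per-frequency
sensitivities (abridged):

```
"params": {"M": 93.2, "A": 0.253, "F": 9.67, "beta": 3.81, "gamma": 0.5, "delta": 0.0200}
"sensitivities": {"0.5": 74.3, "1": 84.1, "2": 90.3, "4": 87.5, "8": 69.0, "16": 35.9, "22.6": 19.8}
```

The estimated peak sensitivity (≈ 90 at 2–3 c/d) sits close to the
generating observer's true peak (113 at 3.2 c/d) after only 108 binary
trials sampled by a plain staircase; `M` is recovered well while the
low-frequency exponent `A` remains prior-dominated at this trial count —
the characteristic behavior analyzed in `docs/methods.md`.

The same library surface is importable directly:

```python
from csfbayes import run_experiment, rmse_db, preset

runs = [run_experiment("staircase", 108, preset("normal"), seed=s) for s in range(20)]
print(rmse_db(runs, "bayes"), rmse_db(runs, "native"))  # 4.31 vs 5.86 dB
```

(These 20 seeds happen to include two hard sessions whose high-frequency
tail collapses; at N = 300 the pooled values settle near 2.9 vs 5.0 dB —
the 2-D re-fit roughly halves the staircase's error.)

`csfbayes evaluate --config cfg.json --n 100 --out metrics/` drives the
full Monte-Carlo comparison (six method labels: `fig`, `qcsf`, `bayes-psi`,
`psi`, `bayes-stc`, `stc`) and writes tidy JSON/CSV metrics with bootstrap
standard errors.

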