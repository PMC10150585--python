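# phonlr

Likelihood-ratio evaluation of acoustic-phonetic speaker evidence, for
forensic-phonetics researchers and practitioners who work with
token-level acoustic measurements (formant frequencies, durations, f0
summaries) rather than raw audio.

## What it does

Given a tidy token table — one row per measured speech unit (vowel,
vowel-to-vowel interval, silent pause, or connected-speech chunk) with
speaker, speaking style and numeric features — `phonlr` answers the
forensic question: *how much more probable is the acoustic evidence if
the reference and questioned recordings come from the same speaker than
from different speakers?*

* **Scoring** — a two-level multivariate kernel-density model: tokens
  are Gaussian around speaker means with pooled within-speaker
  covariance **U**; the population of speaker means is an equal-weight
  kernel mixture g(θ) = (1/m) Σᵢ N(θ; x̄ᵢ, h²**C**) over the m
  background speakers, with bandwidth h = (4/((2p+1)m))^(1/(p+4)).
  The log₁₀ LR for token sets with means ȳₛ, ȳ_q is evaluated in closed
  form from
  LR = ∫N(ȳₛ;θ,U/n₁)N(ȳ_q;θ,U/n₂)g(θ)dθ / [∫N(ȳₛ;θ,U/n₁)g(θ)dθ ·
  ∫N(ȳ_q;θ,U/n₂)g(θ)dθ], with the background refitted for every trial on
  all speakers except those compared (leave-out cross-validation).
* **Calibration & fusion** — class-balanced logistic regression
  (effective target prior 0.5, ridge on weights) maps raw scores of one
  or several systems to calibrated log-LRs.
* **Validity metrics** — Cllr = ½[mean_ss log₂(1+1/LR) +
  mean_ds log₂(1+LR)] and EER via a midpoint-threshold sweep with
  interpolated FAR/FRR crossing.
* **Replication protocol** — balanced downsampling of every speaker to
  the minority count per unit type and style, repeated R times with
  fresh random selections; metrics reported as
  Average/Median/Minima/Maxima/SD.
* **Synthetic data** — a generator that emulates a 20-speaker, two-style
  (dialogue/interview) conversational corpus with nine parameters across
  temporal, melodic and spectral classes, imbalanced counts and a
  dialogue style shift + variance inflation, so the whole pipeline runs
  and is tested without any recordings.

See `docs/methods.md` for the model, estimators, conventions and the
generator's design rationale.

## Worked example

Generate a desk-scale synthetic corpus (10 speakers, two styles) and run
the mismatched-style condition — interview as reference, dialogue as
questioned — for four single parameters, the spectral pair, and a
multi-class fusion, with 5 downsampling replications:

```bash
phonlr generate --seed 1 --reduced --out-dir demo
phonlr run --tokens demo/tokens.csv --condition dialogue_vs_interview \
    --systems "F3,F4,f0_base,vowel_dur,F3+F4,F3+F4+f0_base+vowel_dur" \
    -R 5 --seed 1 --out-dir demo/run
```

which prints (and writes to `demo/run/summary.csv`):

```
                 F3     F4  f0_base  vowel_dur  F3+F4  F3+F4+f0_base+vowel_dur
cllr average  0.825  0.622    0.876      0.989  0.611                    0.479
     median   0.821  0.622    0.876      0.988  0.606                    0.484
     minima   0.817  0.615    0.867      0.984  0.598                    0.463
     maxima   0.841  0.636    0.884      0.994  0.632                    0.486
     sd       0.010  0.008    0.007      0.004  0.013                    0.010
eer  average  0.400  0.244    0.364      0.427  0.218                    0.113
     median   0.400  0.244    0.356      0.422  0.200                    0.111
     minima   0.378  0.244    0.333      0.400  0.200                    0.100
     maxima   0.422  0.244    0.400      0.467  0.267                    0.133
     sd       0.022  0.000    0.025      0.029  0.029                    0.012
```

Reading the numbers: Cllr runs from 0 (perfect) to 1 (uninformative) —
under style mismatch the single temporal parameter (vowel duration,
0.99) carries almost no speaker information and the single spectral
parameters degrade to 0.62–0.83, while fusing the two high formants
(0.61) and especially adding a melodic and a temporal parameter (0.48,
EER 0.11) recovers a usable system: combining parameters from different
acoustic-phonetic classes buys back what the mismatch destroyed.  The
minima–maxima rows show how much the random downsampling alone moves
each estimate.

The same pipeline is available as a library:

```python
from phonlr import generate_dataset, reduced_config, run_condition, summarize_condition

table, truth = generate_dataset(reduced_config(seed=1))
results = run_condition(table, "dialogue", ["F3", "f0_base", "F3+f0_base"],
                        R=20, base_seed=0)
print(summarize_condition(results).round(3))
```

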