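# pupilbias

Decision uncertainty, pupil-linked arousal and serial choice bias: an
analysis pipeline for two-alternative psychophysics with pupillometry.

## The problem

In sequential two-choice tasks, people's decisions are biased by their
recent history: some observers tend to repeat their previous choice,
others to alternate. Signal detection theory provides a graded,
single-trial readout of **decision uncertainty**: a decision variable
dv ~ N(μ, σ) is compared with a criterion c, the choice is sign(dv − c),
and the probability of being correct given dv is

    confidence = Φ(|dv − c| / σ),        uncertainty = 1 − confidence.

Uncertainty decreases with evidence strength on correct trials but
*increases* on errors; accuracy falls from ~100% to ~50% across
uncertainty levels without ever dropping below chance. Peri-decisional
pupil dilation tracks this uncertainty, and on the next trial
uncertainty-linked arousal changes how strongly history biases the choice.
This package implements the full analysis chain needed to measure those
effects, plus a synthetic-data generator so every stage can be validated
end to end against known ground truth.

## What's inside

| module | contents |
| --- | --- |
| `pupilbias.sdt` | SDT uncertainty model (σ = 2.723 from the group probit slope 0.367) and its three diagnostic signatures |
| `pupilbias.synthetic` | counterbalanced stimulus sequences (53-trial blocks, exactly 26 repeat / 26 alternate transitions), a generative history-biased observer with lapses and uncertainty-scaled pupil/RT, synthetic 1000-Hz eye recordings, RDK movies |
| `pupilbias.motion_energy` | opponent quadrature spatio-temporal filtering of dot movies → signed single-trial evidence |
| `pupilbias.pupil` | blink interpolation, event-response deconvolution, 0.01–10 Hz band-pass + z-score + 100 Hz resampling, epoching, 250-ms pre-feedback scalar responses, RT residualization |
| `pupilbias.behavior` | lapse-constrained logistic psychometric and cumulative Weibull fits, serial bias by previous-pupil/RT tertile, post-error slowing, pupil–evidence regressions |
| `pupilbias.history` | history-bias regression: 7 lags of past choices/stimuli on 3 exponential basis functions, pupil×history and RT×history interactions, EM fitting over a latent lapse state, permutation significance, block-bootstrap CIs, strategy-space transform, population analyses |
| `pupilbias.stats` | permutation tests, cluster-based permutation for time courses, repeated-measures ANOVA, JZS Bayes factors for ANOVA and correlations |
| `pupilbias.io`, `pupilbias.config`, `pupilbias.cli` | trial-table/eye-recording formats, YAML config, `pupilbias` command line |

## Worked example

```python
import numpy as np
from pupilbias import synthetic, history

# a choice repeater whose serial bias is damped after high-arousal trials
obs = synthetic.ObserverParams(
    kernel_choice=0.3 * np.exp(-np.arange(7)),       # lag-1 weight +0.3
    mod_pupil_choice=-0.25 * np.exp(-np.arange(7)),  # arousal damps it
    noise="logistic", lapse=0.03)

rng = np.random.default_rng(7)
import pandas as pd
trials = pd.concat([
    synthetic.simulate_observer(
        synthetic.generate_stimulus_sequence(10, "easy", seed=rng),
        obs, session=s, seed=rng)
    for s in range(1, 6)], ignore_index=True)        # 2500 trials

design = history.build_design(trials)                # 7 lags, 3 bases
fit = history.fit(design, seed=0)
print("lag-1 choice weight:       %+.3f" % fit.kernel_choice[0])
print("lag-1 pupil x choice:      %+.3f" % fit.mod_kernels["pupil"]["choice"][0])
print("evidence weight (1/sigma): %+.3f" % fit.weights["evidence"])
```

Output from this exact script:

```
lag-1 choice weight:       +0.359
lag-1 pupil x choice:      -0.311
evidence weight (1/sigma): +0.346
```

The fitted lag-1 choice weight recovers the generative repetition bias
(+0.3), the negative pupil×choice weight recovers the arousal-linked
damping (−0.25), and the evidence weight approximates 1/σ = 0.367 (the
lapse mixture is weakly identified at 2500 trials, which inflates the
estimates somewhat; they are consistent at larger n).

A CLI mirrors the pipeline stages:

```bash
pupilbias simulate --observers 2 --sessions 5 --blocks 10 --seed 1 --out data/
pupilbias rdk --coherence 30 --frames 45 --out movie.h5
pupilbias motion-energy --movie movie.h5 --direction 45 --out trace.csv
pupilbias preprocess --samples eye_samples.tsv --events eye_events.tsv \
    --trials trials.csv --out trials_pupil.csv
pupilbias fit-history --trials trials.csv --out fit.json
pupilbias stats bf-corr --r -0.634 --n 27      # -> 76.040
```

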