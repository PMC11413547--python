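# affsync

Affective synchrony and sentiment trajectories in online health communities.

`affsync` is a Python toolkit for researchers studying peer support in
online health communities (chronic pain forums and similar) who want to
quantify, from comment histories alone, (1) whether users *synchronize* the
sentiment of their language with the peers they interact with, and (2) how
a user's sentiment evolves over the course of their community
participation. It implements the full analysis chain — lexicon sentiment
scoring, bivariate Morlet wavelet synchrony against red-noise and shuffled
nulls, and mixed-effects growth-curve modelling — together with a
synthetic community generator with known ground truth, so every stage is
testable without access to any real (and typically privacy-restricted)
corpus.

## The statistics at the core

For each user, two chronological series are built over their interactions:
own-comment sentiment `x_t` and the sentiment `y_t` of the posts they
replied to. Sentiment is a *compound* score: the mean of two z-standardized
lexicon scorers (a rule-based valence scorer with negation/booster handling
and a positive/negative word-list tone scorer).

After a percentile (empirical CDF) transform, both series get a Morlet CWT
(ω₀ = 6), and synchrony is read off the cross-spectrum:

- **XWT common power** `|W^XY| = |W^X · conj(W^Y)|`, tested pointwise
  against the product of the two AR(1) red-noise spectra;
- **wavelet coherence** `R² = |S(W^XY/s)|² / (S(|W^X|²/s) S(|W^Y|²/s))`
  with the standard scale-dependent smoothing operator S (0.6-octave
  decorrelation width), tested against a Monte Carlo AR(1) null;
- **relative phase** `arg W^XY`, summarized as a circular mean over
  significant common-power regions (0° = in-phase, 180° = antiphase).

Per-user statistics are the COI-restricted fractions of significant points
(overall and within low [20–32], medium [10–20) and high (<10) interaction
period bands), compared against a *shuffled baseline* — the same pipeline
on order-destroyed data — with paired t tests and Cohen's d. Sentiment
trajectories are modelled on 100 proportional interaction windows with a
random-intercept mixed model: standardized window slope, synchrony and
tenure moderators (including the three-way interaction), ICC and
marginal/conditional R².

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a small coupled community, run the whole pipeline, and look at the
group tests:

```python
from affsync.pipeline import PipelineConfig, run_pipeline
from affsync.synthetic_data import SimulationConfig

cfg = PipelineConfig(
    source="simulate-series",           # analyze the numeric series directly
    simulation=SimulationConfig(
        n_users=30, n_interactions_range=(100, 300),
        coupling=0.4, oscillation_period=24.0, trend_slope=-0.1, seed=1,
    ),
    wtc_nsim=200, seed=1,
)
report = run_pipeline(cfg, outdir="affsync_out")
print(report["synchrony"]["paired_tests"]["common_power_frac"])
print(report["synchrony"]["rp_circular_mean_deg"])
print(report["trajectory"]["coefficients"]["window"])
```

With these settings this prints (numbers produced by this exact run):

```
{'t': 5.5747445536953215, 'df': 29, 'p': 5.143850424480101e-06, 'd_av': 1.5981180185520283, 'd_z': 1.0178044481293325}
-2.9917046645415923
{'beta': -0.04012729140995635, 'ci_low': -0.07709620317439339, 'ci_high': -0.0031583796455193144, 'p': 0.033386001939105146}
```

Read: with 40% of the peer oscillation mixed into each user's series, real
interactions show significantly more common power than the shuffled
baseline (mean fraction 0.094 vs 0.062, paired t(29) = 5.57, d_av = 1.60);
the mean relative phase of ≈ −3° says users and peers fluctuate in phase;
and the generator's negative tenure trend surfaces as a negative
standardized window slope (β = −0.040, 95% CI −0.077 to −0.003).

The same pipeline runs from the shell:

```bash
affsync simulate --n-users 20 --seed 7 --out corpus.jsonl
affsync ingest corpus.jsonl
affsync run --source simulate-series --outdir affsync_out --seed 7
```

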