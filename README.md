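# mcia — multi-component information accumulation

`mcia` models how people integrate two sources of perceptual evidence —
the top and bottom halves of a morphed face — when categorizing the face
as one of two family patriarchs. It is aimed at researchers in perceptual
decision making and psychophysics who want a complete, testable pipeline
for the *face-dilution* paradigm: stimulus design and staircase
calibration, a generative random-walk model, trial-level filtering and
deviation-score analysis, and weighted least-squares model fitting with
variant comparison. Because no participant data are published for this
paradigm, the package includes a first-class synthetic-data generator that
produces the full experiment from the model's own generative process, with
known ground truth.

## The model

Choice and response time arise from a biased random walk between absorbing
response thresholds at ±θ, starting midway. On each step the process
samples the top half (probability (1 − α)/2), the bottom half
((1 − α)/2), or the automatically integrated whole face (α). A source
moves the walk toward the correct threshold with probability δ (one of
δ_weak, δ_medium, δ_strong per the calibrated strength of that half); the
whole-face source combines the halves optimally by multiplying odds:

    odds(δ_whole) = δ_top/(1 − δ_top) · δ_bottom/(1 − δ_bottom)

Sampling halves in alternation instead *averages* their step
probabilities, pulling accuracy below the stronger half alone — the
dilution effect. The marginal step probability
p = α·δ_whole + (1 − α)(δ_top + δ_bottom)/2 feeds the gambler's-ruin
closed forms, with r = (1 − p)/p:

    P(correct) = 1 / (1 + r^θ)
    E[N] = (θ − 2θ·P(correct)) / (1 − 2p)        (θ² at p = ½)
    RT = τ + k·E[N]   (half faces: τ + h·k·E[N])

The attention parameter α is the theoretical crux: α = 1 forces additive
(optimal) integration, α = 0 forces averaging (dilution); the full model
lets together faces use α > 0 while split faces are pinned at α = 0.
See `docs/methods.md` for assumptions, variants and numerical choices.

## Worked example

```python
>>> from mcia import combine_optimal, derive_levels, McIAParams, predict_all
>>> combine_optimal(0.55, 0.75)        # odds-product whole-face evidence
0.7857142857142858
>>> (0.55 + 0.75) / 2                  # averaging the halves instead
0.65
>>> derive_levels(82.0)                # weak/strong morph % from medium 82%
(66.0, 94.0)
>>> table = predict_all(McIAParams())  # 17 condition predictions
>>> table.loc[[2, 9], ["condition", "format", "p_correct", "mean_rt_ms", "deviation_pred"]]
  condition    format  p_correct  mean_rt_ms  deviation_pred
2        ws  together   0.960440  896.499196       -0.019514
9        ws     split   0.921319  991.914908       -0.058635
```

A weak+strong face is categorized more accurately together (.96) than
split (.92), and the split face shows three times the dilution (deviation
−.059 vs −.020): with α = 0 the walk keeps averaging the weak half into
strong evidence.

The end-to-end pipeline lives in numbered scripts:

```
python analysis/01_calibrate.py           # staircase calibration demo
python analysis/02_simulate_experiment.py # 19 x 4 x 68 synthetic trials
python analysis/03_behavioral_analysis.py # filter, summarize, deviations
python analysis/04_fit_variants.py        # wSSE fits, 5 variants ranked
python analysis/05_parameter_recovery.py  # 20-replication recovery study
```

On the default seed the pipeline removes 13.4% of trials (the planted
~13% contamination plus the walk's natural slow tail), reports together
vs split mean accuracy .881 vs .826 and mean deviation −.043 vs −.097,
shows deviations falling as the strength gap grows (−.029 → −.045 →
−.054) and slower trials diluting more (−.088 vs −.050), and the variant
ranking puts the hybrid model first on data generated with
α_together = .30. The equivalent operations are also exposed on the
command line via `mcia calibrate|simulate|analyze|predict|fit|compare`.

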