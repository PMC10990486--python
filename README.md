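# binocombine

How do V1 neurons combine the two eyes' signals? Most neurons in the
superficial layers of primate primary visual cortex respond to both eyes
but with graded eye preferences, summarized by the ocular dominance index

    ODI = (R_i − R_c) / (R_i + R_c)

where R_c and R_i are the peak responses to contralateral and ipsilateral
stimulation (−1: fully contralateral, +1: fully ipsilateral, 0: balanced).
Under monocular stimulation, neurons preferring the stimulated eye respond
far more strongly than balanced neurons — yet under binocular stimulation
those differences largely disappear. `binocombine` implements the analysis
pipeline that quantifies this flattening and the divisive gain-control
model that explains it, together with a synthetic two-photon data generator
so that every stage is testable against known ground truth without any
recorded data.

## The model

With eye weights w_c = (ODI + 1)/2 and w_i = 1 − w_c:

    R_c = w_c^{m_c} · k                R_i = w_i^{m_i} · k
    R_b = (w_i^{m_i} k) / w_i^b  +  (w_c^{m_c} k) / w_c^b

`k` is a divisive gain constant shared between the eyes, `m_c`, `m_i` are
monocular nonlinearity exponents (empirically negative, near −1), and `b`
is the interocular suppression exponent: each eye's drive is divided by
the other eye's weight raised to `b`, then the two suppressed signals are
summed. With `b = 0` (other eye unstimulated) the binocular response
reduces exactly to R_c + R_i. Monocular neurons are strongly suppressed
and binocular neurons facilitated, producing a nearly flat binocular
response function across ocular dominance.

Fitting proceeds on population data: responses normalized by the
field-of-view median binocular response, neurons sorted by ODI into 60
equal-count bins, bin medians fit by least squares — the two monocular
curves jointly with shared `k`, then the binocular curve with `b` the only
free parameter. Goodness of fit is q = 1 − RMS(residual)/mean(data).

## What's in the package

| module | contents |
|---|---|
| `binocombine.synthetic_data` | stimulus design (12 orientations × 6 SFs × 3 sizes × 2 directions × 3 eye conditions), ground-truth populations, trialwise ΔF/F tables, rendered movies with calcium kernel + motion |
| `binocombine.roi_segmentation` | rigid motion correction (normalized cross-correlation), differential images (ΔF = F − F0), band-pass filtering, sequential ROI screening with overlap rules and roundness filter |
| `binocombine.tuning_analysis` | trial ΔF/F, Friedman screens, base-2 Gaussian orientation fits, difference-of-Gaussians SF fits, ODI |
| `binocombine.binocular_model` | model evaluation, normalization, ODI binning, two-stage fitting, fit-quality index, binocular-modulation regression, curve simulation |
| `binocombine.pipeline_cli` | `binocombine` command: `simulate`, `segment`, `tune`, `model`, `run`, `report` |

## Worked example

Run the table-backed demo pipeline (120 synthetic neurons, default
binocular-heavy ODI mixture, 5% trial noise) and print the summary:

```python
from binocombine.pipeline_cli import RunConfig, run_pipeline, make_report

run_pipeline(RunConfig(seed=7, n_neurons=120), "demo_out")
print(make_report("demo_out"))
```

which prints (numbers from this exact run):

```
# Pipeline run summary

seed: 7

## Filter cascade
- neurons_simulated: 120
- neurons_analyzed: 120
- neurons_tuned: 120
- neurons_binned: 120

## Combination model
- k = 0.4692
- m_c = -0.9981
- m_i = -0.9969
- b_supp = -0.9147
- fit quality q: contra 0.931, ipsi 0.972, binocular 0.991

## Binocular modulation
- regression: index = -0.924 * |ODI| + 0.114 (p = 5.51e-87)
```

Reading the output: the fitted exponents m_c, m_i ≈ −1 reproduce the
planted monocular nonlinearity (the generator's ground truth is −1); the
suppression exponent b ≈ −0.91 matches the planted −0.9, the regime in
which the binocular response function is nearly flat. `k` is the gain on
the *normalized* response scale (multiplying it by the normalization
constant stored in `model_fit.json` recovers the generative gain). The
negative modulation slope says binocular stimulation facilitates balanced
neurons (|ODI| ≈ 0, index ≈ +0.11) and suppresses monocular ones — the
population signature the model explains. The same pipeline runs from the
shell: `binocombine run --seed 7 --out demo_out`.

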