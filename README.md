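# afterimage

Quantitative models of complementary colour afterimages, and the
psychophysical analysis pipeline that discriminates them.

After fixating a coloured *inducer*, a neutral field appears tinged with an
illusory, complementary colour. Competing accounts of the adaptation behind
this place it at different stages of colour processing, and they make
different quantitative predictions about the afterimage's hue and chroma:

- **Cone adaptation** (first stage, divisive / Weber's law). The neutral
  probe's cone contrast under local adaptation to the inducer,
  `CC = (bgLMS − iLMS) / iLMS` per cone class, re-embedded under global
  adaptation to the background: `LMS_after = bgLMS·(1 + CC) = bgLMS²/iLMS`.
  Because the inducer sits in a denominator, predictions are *non-opponent*:
  hue deviates from the 180° direction, and chroma peaks three times around
  the hue circle, each peak driven by the least-adapted cone.
- **Cone-opponent adaptation** (second stage, subtractive). In DKL space,
  `DKL_after = bgDKL − k·iDKL = −k·iDKL` for a neutral background: hue is
  exactly the inducer's +180°, chroma proportional to inducer chroma.
- **Colour-appearance transforms** — CIELUV (u′v′ subtraction), CIELAB
  (white-substitution pseudo von Kries), CIECAM02/CAT02 — as
  corresponding-colour predictions with the inducer as adapting white.
- **Munsell and Hering opponency** — complementaries on the 100-step
  Munsell hue circle (via renotation-table interpolation in CIELAB) and
  between measured unique-hue prototypes.

The package provides exact, invertible colorimetry (xyY/XYZ, Stockman–Sharpe
cone excitations, CIELUV, CIELAB, gamut-scaled DKL) for a calibrated
monitor, the hue-circle stimulus sets of the matching and adjustment
paradigms, seed-deterministic synthetic observers, and the circular
statistics of the analysis: deviation-from-opponency curves, hue histograms
with noise-convolved model simulation, Pearson correlations with Fisher
confidence intervals, one-sample/paired t-tests with Cohen's d, and exact
binomial sign tests.

## Worked example

```python
import afterimage as ai
from afterimage.models import predict_cone_adaptation, predict_cone_opponent

monitor = ai.DEFAULT_MONITOR            # calibrated display (gamma 2.2)
ind = ai.InducerSpec("CIELUV", 60.0, 50.0)   # yellowish inducer, chroma 50

p = predict_cone_adaptation(ind, monitor)
q = predict_cone_opponent(ind, monitor)
print(f"cone:     hue {p.hue_azimuth:.1f} deg, chroma {p.chroma:.1f}")
print(f"opponent: hue {q.hue_azimuth:.1f} deg, chroma {q.chroma:.1f}")
```

```
cone:     hue 251.0 deg, chroma 34.6
opponent: hue 240.0 deg, chroma 24.4
```

Both models use the default partial adaptation strength (CIELUV chroma
27.0). The opponent prediction is exactly the inducer hue + 180°; the cone
model deviates from opponency by +11° here — the measurable signature that
separates the mechanisms.

A full simulated experiment, statsmodels-style:

```python
from afterimage import AfterimageExperiment, ObserverConfig
from afterimage.observer import simulate_exp2_adjustment

inducers = ai.make_hue_circle_set(5.0, 50.0, "CIELUV", monitor)  # 72 hues
sim = simulate_exp2_adjustment(
    inducers, ObserverConfig(truth_model="cone", sigma_hue=10.0,
                             n_participants=3, n_reps=2, seed=17), monitor)
results = AfterimageExperiment(sim, monitor).fit()
print(results.summary())
```

The summary table reports, per model, the mean absolute hue error, the
correlation of measured vs predicted deviation-from-opponency curves,
chroma profiles, and hue histograms, plus sign tests against the reference
model; `results.to_report()` exports the same as JSON and
`results.plot_deviation_curves()` draws the curves.

The same operations are available from the shell:

```
afterimage predict  --models cone,dkl --hues 0:355:5 --chroma 50 --out pred.csv
afterimage simulate --experiment 2a --truth cone --seed 1 --out sim.csv
afterimage analyze  --measurements sim.csv --out report.json
```

## Layout

- `afterimage.colorimetry` — colour spaces, monitor model, DKL plane
- `afterimage.stimuli` — inducer/comparison/chroma-series stimulus sets
- `afterimage.models` — the afterimage prediction models
- `afterimage.munsell` — renotation table I/O and Munsell opponency
- `afterimage.stats` — circular statistics and test machinery
- `afterimage.analysis` — `AfterimageExperiment` / `AfterimageResults`
- `afterimage.observer` — synthetic observers and model recovery
- `afterimage.io`, `afterimage.cli` — file formats, configuration, CLI

See `docs/methods.md` for the models, conventions, and design choices in
detail.
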