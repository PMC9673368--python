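# ovus

Ensemble-CNN classification of ovarian ultrasound-like images — benign vs
malignant — with ensemble Grad-CAM saliency and confidence-threshold
triage, built to run end to end on one CPU.

Distinguishing benign from malignant adnexal tumors on B-mode ultrasound is
a routine but error-prone clinical task; CNN ensembles with a
selective-prediction front end (defer low-confidence cases to a human
reader) are a natural automation. Clinical archives for this problem are
private, so `ovus` ships a synthetic phantom generator whose two classes
carry the standard sonographic cues — benign: smooth unilocular hypoechoic
cyst; malignant: irregular boundary with septations, papillary projections,
or a solid component — and everything downstream (augmentation, training,
ensembling, saliency, evaluation, triage) operates identically on phantoms
or on external images supplied through a manifest CSV.

## What it implements

* **`synthgen`** — labeled phantom rendering, balanced dataset generation,
  seeded 70/30 train/validation splitting, PNG + manifest I/O.
* **`augment`** — horizontal flip, +-30 deg rotation, and dataset doubling
  via multiplicative speckle copies: `out = clip(I + n*I, 0, 1)` with
  zero-mean `n`, Var(n) = 0.05.
* **`backbone`** — three small trainable CNN presets (residual x2,
  depthwise-separable x1) on a purpose-built numpy layer library with
  analytic backprop; fixed-epoch Adam training; softmax confidences over
  (benign, malignant).
* **`ensemble`** — majority vote, confidence sum (soft voting), and
  weighted confidence sum (x1.5 on the per-class best model); ties resolve
  to malignant; accuracy/time backbone selection.
* **`gradcam`** — per-model Grad-CAM and the ensemble map
  (normalize-then-average), plus colormap overlays.
* **`evaluate`** — ACC/SE/SP (both the as-printed and the conventional
  formula variants, always labeled), population-SD summaries, repeated
  random subsampling with full re-training per repetition, paired t-tests,
  and the accuracy/time trade-off curve.
* **`triage`** — retained-fraction curves, the 0.80-1.00 threshold sweep in
  1% steps, and operating-point reports (default threshold 0.86).
* **`pipeline` / CLI** — one config, one seed, full reproducibility.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
from ovus.pipeline import ExperimentConfig, run_experiment

cfg = ExperimentConfig(n_per_class=150, image_size=(64, 64), epochs=10,
                       learning_rate=1e-3, repetitions=2, base_seed=7,
                       triage_threshold=0.80, output_dir="ovus-output")
result = run_experiment(cfg)
print(result["summary"].summary_frame().round(2).to_string(index=False))
```

prints (about a minute on one CPU):

```
           model_or_strategy  acc_mean  acc_sd  se_mean  se_sd  sp_mean  sp_sd
       tiny-residual-18-like     78.33    8.33   100.00   0.00    70.44   6.92
       tiny-residual-50-like     78.89   12.22   100.00   0.00    72.36  11.32
tiny-separable-xception-like     73.33    3.33    78.12  15.62    77.85  10.61
               ensemble_vote     83.33    5.56   100.00   0.00    75.27   5.12
                ensemble_sum     77.22   10.56   100.00   0.00    69.94   8.90
           ensemble_weighted     77.78   11.11   100.00   0.00    70.72   9.68
```

Each row is the mean +- population SD over the 2 random-subsampling
repetitions of validation accuracy, SE and SP in percent (`as_printed`
metric mode: SE = TP/(TP+FP), SP = TN/(TN+FN); malignant is positive — see
`docs/methods.md` for why that mode is the default and how to switch). The
triage report on the pooled ensemble predictions,
`result["triage_report"].as_dict()`:

```json
{
  "threshold": 0.8, "n_total": 180, "n_excluded": 89,
  "n_retained_correct": 85, "n_retained_incorrect": 6,
  "retained_accuracy": 93.4065934065934,
  "baseline_accuracy": 77.22222222222223
}
```

reads: of 180 validation decisions, 89 fell below the 0.80 ensemble
confidence and would be deferred to a human reader; accuracy on the 91
auto-accepted decisions is 93.4% versus 77.2% with no triage — the
selective-prediction trade: fewer automated calls, better ones. The output
directory additionally contains per-repetition metrics, per-image decision
CSVs, t-tests, the 21-row triage sweep, and Grad-CAM heat maps/overlays for
one exemplar per class.

The same workflow is scriptable from the shell:

```bash
ovus simulate --n-per-class 100 --seed 1 --out data/
ovus run-all --seed 1 --out results/
ovus triage --decisions my_decisions.csv --threshold 0.86 --out triage/
```

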