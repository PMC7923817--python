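# hrvdoa

Depth-of-anaesthesia state classification from ECG-derived heart-rate
variability.

During general anaesthesia the autonomic nervous system shifts with the
depth of unconsciousness, and that shift is visible in heart-rate
variability (HRV): the beat-to-beat variation of the RR intervals of the
ECG. `hrvdoa` implements a pipeline for anaesthesia researchers and
physiological-signal engineers that distinguishes the three clinical states
— **I** induction, **II** maintenance, **III** recovery — from four HRV
features per analysis window:

* **HF** — high-frequency band power (≈0.15–0.40 Hz, ms²), from a discrete
  wavelet transform of the resampled RR tachogram;
* **LF** — low-frequency band power (≈0.04–0.15 Hz, ms²);
* **HF/LF** — their ratio;
* **SampEn** — sample entropy of the raw RR intervals,
  SampEn = −ln(A/B), where B and A count m- and (m+1)-length template pairs
  within tolerance r (Chebyshev distance, self-matches excluded; m = 2,
  r = 0.2·SD).

The features feed four classifiers trained against an expert assessment of
consciousness level (EACL, 0–100, averaged over five raters): multinomial
logistic regression, an RBF support-vector machine, a decision tree, and a
fully connected **4-10-17-1** deep network — one scalar output trained on
ordinal state codes {0, 0.5, 1} and decoded to the nearest code. Performance
is reported as per-state precision/recall and overall accuracy from the 3×3
confusion matrix, with pairwise chi-square comparisons between classifiers.

Clinical intra-operative ECG is not publicly available, so the package
includes a seeded synthetic cohort generator (state-dependent LF/HF
modulation of RR, PQRST ECG rendering with noise and artifacts, five-rater
EACL traces, event timelines) whose ground truth makes every stage testable.
See `docs/methods.md` for the model details and what passing tests do and do
not show.

## Worked example

End-to-end demo (3 short synthetic cases: simulate → filter ECG → detect R
peaks → filter RR → extract features → train all four models → evaluate):

```
$ hrvdoa run --seed 1 --out demo
run complete: 423 records (338 train / 85 test), manifest at demo/manifest.json

$ hrvdoa report --run demo
lr: accuracy 0.941 (n=85)
svm: accuracy 0.976 (n=85)
dt: accuracy 0.929 (n=85)
dnn: accuracy 0.965 (n=85)
model_a model_b  statistic        p  low_expected_cell
     lr     svm   1.340929 0.246870               True
     lr      dt   0.097198 0.755218              False
     lr     dnn   0.524691 0.468847               True
    svm      dt   2.098765 0.147418               True
    svm     dnn   0.206061 0.649873               True
     dt     dnn   1.055901 0.304152               True
```

Each of the 423 records is one 64 s window (4 s stride) with its HF, LF,
HF/LF and SampEn values, mean EACL and true state. The accuracies are the
fraction of test windows whose state each model recovers; the chi-square
table compares each model pair's correct/incorrect counts on the shared test
set (all pairs indistinguishable here — 85 test windows is a smoke-scale
demo). `demo/` also contains the feature table, per-state precision/recall
(`metrics.csv`), feature–EACL Pearson correlations, state-wise quartile
summaries, and a manifest with SHA-256 checksums: re-running with the same
seed reproduces identical outputs.

The stages are also available individually (`hrvdoa simulate | preprocess |
features | train | predict | evaluate`) and as library functions:

```python
import hrvdoa as h

config = h.SimConfig(n_cases=23, seed=0)          # the default cohort
case = h.simulate_case(config, 0, with_ecg=True)
rr = h.preprocess_ecg(case.ecg)                   # filter + detect + RR-clean
features = h.extract_features(rr, case.eacl, case.timeline)
```

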