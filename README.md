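# netorigin

Predicts the primary site — pancreas vs. small intestine — of
neuroendocrine-tumor liver metastases from patch embeddings of H&E-stained
slides, with a calibrated abstention ("uncertain") class that protects
against misclassifying tumors of other origins.

The pipeline has two steps:

1. **Binary patch classifier.** 100 patches per patient are sampled from
   annotated tumor regions (excluding artifacts), resized to 224×224,
   channel-standardized, embedded by a frozen feature extractor, and scored
   by an SVM (RBF or linear) or logistic regression with fixed default
   hyperparameters. Patient labels come from a majority vote over patch
   predictions.
2. **Abstention layer.** Each patient is reduced to the sum of their signed
   patch decision values. On a calibration split (40% of the binary-origin
   patients plus all `o` other-origin patients), lower/upper thresholds are
   chosen for each `i ∈ 0..o` such that exactly `i` other-origin sums fall
   inside the interval while the number of pancreas/SI sums inside is
   minimized; `c = i/o` is the confidence parameter. Patients whose sum
   falls inside the interval are labeled "uncertain".

Evaluation supports leave-one-out over a cohort (fresh 60/40 split, model
and thresholds per fold) and fixed-model external testing, with
sensitivity / specificity / PPV / NPV conventions in which abstentions count
against sensitivity and as correct rejections for specificity.

Pretrained histopathology extractors (ImageNet-ResNet50, MTDP, RetCCL) are
consumed only through an adapter interface; the bundled deterministic
`toy-stats` extractor (36 per-channel statistics) and the synthetic-cohort
simulator make every stage testable fully offline.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(quota conservation, artifact exclusion, round-trip identity, threshold
exactness/optimality against a brute-force oracle) and
`tests/test_acceptance.py` covering the acceptance criteria.

## CLI

```sh
# synthetic cohort (manifest.csv + embeddings.csv, optionally PNG tiles)
netorigin simulate --out cohort/ --n-pancreas 20 --n-si 20 --n-other 8 --seed 0

# patch coordinates from GeoJSON annotations
netorigin sample-patches --manifest m.csv --annotations dir/ \
    --patch-size 4096 --per-patient 100 --seed 0 --out coords.csv

# embeddings from PNG tiles (toy-stats extractor)
netorigin extract --tiles tiles/ --extractor toy-stats --out embeddings.csv

# train / calibrate / predict
netorigin train --embeddings e.csv --manifest m.csv --model svm_rbf --seed 0 --out model.joblib
netorigin calibrate --scores cal_scores.csv --confidence 0.875 --out thresholds.json
netorigin predict --model model.joblib --embeddings e.csv --thresholds thresholds.json --out pred.csv

# leave-one-out or external evaluation -> JSON report with confusion matrix,
# per-class metrics, thresholds, config echo and input fingerprints
netorigin evaluate --mode loo --embeddings e.csv --manifest m.csv \
    --confidence 0.875 --seed 0 --out report.json --predictions pred.csv
```

`evaluate` also accepts `--config run.yaml` (unknown keys rejected; CLI
flags override file values).

## Conventions worth knowing

- `positive_class` is fixed to small intestine: signed scores > 0 mean SI,
  < 0 pancreas, everywhere.
- The "signed distance" is the raw decision value (logit for logistic
  regression), not the geometric distance.
- Thresholds are a closed interval; confidence 0 degenerates to
  `lower = upper = 0` (pure binary classifier).
- Candidate threshold intervals are anchored to the decision boundary
  (contain 0); an unconstrained search is available via
  `contain_zero=False` / `--no-contain-zero`.
- For held-out classification the thresholds are padded to the midpoint
  toward the nearest excluded calibration sum (`padding="midpoint"`), which
  never changes any calibration count; `padding="none"` places them exactly
  at the extreme included other-origin sums.
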