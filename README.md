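# finmark

Headless automated morphometric landmarking for standardized organism
photographs. The pipeline covers the full workflow:

1. **Annotate** — landmark ground truth stored in the image/box/part XML
   dialect (`finmark.annotations`), with overlay rendering for visual
   confirmation.
2. **Train** — a gradient-boosted cascade-of-regression-trees shape
   predictor over pixel-intensity-difference features
   (`finmark.shape_model`), with its nine training hyperparameters tuned
   by a cross-validated study (`finmark.hpo`): each trial is scored by
   the mean 5-fold validation pixel deviation, and the final model is
   retrained on the full dataset with the best trial's configuration.
3. **Predict** — batch landmark placement on unseen images, exported as
   XML and overlay PNGs (`finmark.export`).
4. **Evaluate** — deviation arithmetic normalized by the image diagonal,
   and model-vs-observer comparison (`finmark.metrics`).
5. **Calibrate** — per-image scale-bar detection (Gaussian smoothing +
   hysteresis edge detection + probabilistic Hough transform) converting
   pixel distances to millimetres (`finmark.scalebar`).

A deterministic synthetic-fixture generator (`finmark.fixtures`) renders
fish-like images with analytically exact landmark ground truth and
optional scale bars, so the whole pipeline is testable offline.

## CLI

All commands are seeded and stateless; `finmark --help` lists everything.

```bash
# 1. generate a synthetic training set (or bring your own images + XML)
finmark fixtures --n 100 --seed 1 --out train_dir --with-scale-bar

# 2. hyperparameter study + final model
finmark train --xml train_dir/landmarks.xml --images train_dir \
    --trials 25 --folds 5 --sampler adaptive --seed 1 \
    --out model.bin --study-out study.json

# 3. predict on unseen images (with overlays for review)
finmark predict --model model.bin --images new_dir --out-xml pred.xml --overlay

# 4. accuracy against ground truth / a second annotation pass
finmark evaluate --truth truth.xml --pred pred.xml \
    --width 1800 --height 1200 --out report.json

# 5. per-image scale calibration and CSV export of measurements
finmark scalebar --images new_dir --bar-mm 10 --out calibration.csv
finmark export --pred pred.xml --pairs 0:1:standard_length \
    --calibration calibration.csv --out measurements.csv
```

A TOML config file can pre-populate any flag per subcommand:
`finmark --config finmark.toml train`.

## Library

```python
from finmark.fixtures import FixtureParams, generate_dataset
from finmark.hpo import run_study, finalize_model
from finmark.shape_model import mean_deviation

out_dir, dataset = generate_dataset(100, FixtureParams(seed=1), "train_dir")
study = run_study(dataset, n_trials=25, k=5, seed=1, image_root=out_dir)
model = finalize_model(dataset, study, seed=1, image_root=out_dir)
```

## Conventions

- Coordinates are integer pixels, origin at the upper-left corner, x
  rightward, y downward; landmark order is positional identity.
- Deviations are reported in pixels and as a percentage of the image
  diagonal `sqrt(width² + height²)`; printed pixel values round to the
  nearest integer, half away from zero.
- Training is CPU-only and deterministic given (data, hyperparameters,
  seed). Models serialize to one binary file plus a JSON sidecar with
  hyperparameters, seed, landmark count and training-set hash.
- The predictor is sensitive to rotation, flipping and scaling outside
  the training distribution; standardize input images.

## Tests

```bash
python -m pytest tests/            # full suite (~6 min on one CPU)
```

`tests/test_acceptance.py` holds the acceptance criteria: metric worked
examples, brute-force oracle equivalence, the parameter-search contract,
landmark recovery on fixtures (including the dataset-size trend), and
scale-bar recovery.

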