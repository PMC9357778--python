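# neuroseg

Segmentation and classification toolkit for noisy grayscale images,
built around three pieces:

- **`neuroseg.ifrfcm`** — noise-robust fuzzy C-means segmentation run over
  the gray-level *histogram* instead of individual pixels. The pipeline is
  morphological reconstruction (opening- then closing-by-reconstruction,
  which removes impulse noise), histogram-domain FCM with a spatial
  neighborhood penalty ("fuzzy factor"), an adaptive Wiener filter on the
  membership planes, and argmax defuzzification. Disabling those three
  extras recovers plain FCM, used as the baseline in the tests.
- **`neuroseg.texture`** — gray-level co-occurrence matrix (GLCM) features
  (contrast, dissimilarity, energy, homogeneity, entropy, correlation)
  over the whole image plus top/bottom and left/right halves, at four
  distance-1 offsets; 120 features by default.
- **`neuroseg.elm` / `neuroseg.pso`** — an extreme learning machine
  (random fixed hidden layer, output weights solved with the Moore-Penrose
  pseudoinverse) whose input weights and biases can be tuned by particle
  swarm optimization against validation error. Both the classical inertia
  PSO rule and an accelerated global-best rule are implemented, with
  injectable randomness for exact step-level testing.

Supporting modules: **`neuroseg.metrics`** (diseased/non-diseased confusion
counts, sensitivity, specificity, PPV, NPV, prevalence-weighted accuracy,
permutation-matched segmentation accuracy), **`neuroseg.synthetic`**
(seeded head-like phantoms with ground truth and Gaussian, salt-and-pepper
or speckle noise, so everything is testable without external data), and
**`neuroseg.io`** / **`neuroseg.cli`** (PNG/TIFF/NIfTI readers, lossless
CSV feature tables, JSON model serialization, end-to-end pipeline).

## CLI

All functionality is exposed through the `neuroseg` command:

```sh
neuroseg simulate --n 20 --size 128 --noise salt_pepper --level 0.05 \
    --seed 1 --outdir data/
neuroseg segment --input data/phantom_000.png --clusters 3 --fuzziness 2.0 \
    --radius 1 --wiener 3 --seed 42 --output out/
neuroseg features --input data/phantom_000.png --input data/phantom_001.png \
    --levels 8 --labels data/manifest.csv --output features.csv
neuroseg train --features features.csv --hidden 10 --optimizer pso \
    --particles 20 --iters 50 --seed 7 --model model.json
neuroseg predict --model model.json --features features.csv --output pred.csv
neuroseg evaluate --pred pred.csv --truth truth.csv --prevalence 0.53
neuroseg pipeline --outdir run/ --seed 7     # simulate → … → evaluate
```

Each segmentation writes a label-map PNG plus a JSON sidecar (centroids,
iteration count, objective trace, config echo); the pipeline writes a
manifest recording every derived seed and a config hash, so a rerun with
the same config is byte-identical.

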