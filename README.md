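# fsda

Supervised dimensionality reduction of pre-trained-network image features by
recursive Foley–Sammon discriminant analysis, fusion of the reduced features
with clinical variables, cross-validated classification, and a
projection-aware class activation map (CAM) that visualizes classifier
evidence through the reduced feature space.

## What it does

Binary Fisher analysis normally yields a single discriminant direction
because the between-class scatter has rank one. The Foley–Sammon recursion
extracts an ordered orthonormal set of directions, each maximizing the
Fisher criterion subject to orthogonality with its predecessors, so a
high-dimensional feature vector (e.g. 512 pooled conv activations) can be
reduced to L ≪ M dimensions without discarding discriminative structure.
The reduced features are concatenated with encoded clinical variables
(strategy 1) or with discriminant-reduced text embeddings (strategy 2) and
fed to an SVM or a single linear layer. For linear classifiers, the
image-block weights of the predicted class are back-projected through the
projection transpose onto the last-conv feature map, giving a spatial
relevance map.

Modules (under `src/fsda/`):

| module      | contents |
|-------------|----------|
| `core_da`   | class statistics, Fisher criterion, the direction recursion, projection, basis persistence |
| `fusion`    | clinical schema/encoder (z-score + one-hot), concatenation fusion, hashing text embedder |
| `evaluate`  | SVM / linear classifiers, six comparison arms (original/PCA/DA × ±clinical), stratified k-fold ACC/AUC reports |
| `cam`       | feature-map container, projection-aware CAM, interpolation, heat-map overlay |
| `backbone`  | frozen feature-extractor adapters (deterministic synthetic backbone ships; deep backbones are optional extras) |
| `synth`     | seeded generators for features, clinical tables and planted-blob feature maps |
| `config`/`cli` | YAML run configuration and the `fsda` command group |

## CLI

```bash
# generate a synthetic dataset (features + clinical table + schema)
fsda synth --out data/ --seed 1 --n-per-class 50 --n-features 512 --delta 4

# fit a 10-direction discriminant basis
fsda fit --features data/features.npz --out data/basis.npz -L 10

# run the cross-validated arm comparison from a config
fsda evaluate --config config.yaml

# compute a CAM for one feature map
fsda cam --feature-map fmap.npz --basis data/basis.npz \
         --classifier clf.npz --image img.png --out cam_out/
```

A minimal `config.yaml`:

```yaml
features_path: data/features.npz
clinical_path: data/clinical.csv
schema_path: data/schema.yaml
output_dir: run/
arms: [original, original+CV, PCA, PCA+CV, DA, DA+CV]
n_directions: 10
folds: 5
seed: 0
classifier: margin   # or: linear (required for CAM)
```

## Notes

- The within-scatter combination defaults to the cross-weighted form
  (`within_mode="as_printed"`); the classical pooled form is available via
  `within_mode="pooled"`. The two coincide for balanced classes.
- All solves against the within-scatter use a ridge-regularized Cholesky
  factorization (default ridge `1e-6·trace/M`), never an explicit inverse —
  necessary in the M ≥ N regime where the raw scatter is singular.
- When the recursion exhausts the discriminative subspace before L
  directions, the basis is truncated with a warning.
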