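# finnet

Fisher information networks (FIN): characterise and visualise cases by
similarity. From any probabilistic classifier's posteriors `p(c|x)` the
package derives a position-dependent Riemannian metric over feature space
(the data-space Fisher information matrix), approximates geodesic distances
over a nearest-neighbour graph by all-pairs shortest paths, embeds all
cases into a low-dimensional latent space by classical multidimensional
scaling, and projects unseen cases into that space for
"patient-like-me" neighbour analysis.

## What it computes

1. **Metric** — `FI(x) = Σ_c p(c|x) ∇ₓlog p(c|x) ∇ₓlog p(c|x)ᵀ`, a
   symmetric PSD matrix that is large where class membership is sensitive
   to small moves (`finnet.fisher`).
2. **Local distances** — `d(x, y) ≈ ∫₀¹ √(Δᵀ FI(x+tΔ) Δ) dt`, midpoint
   quadrature along the straight segment (`finnet.fisher`).
3. **Geodesics** — symmetrised Euclidean-kNN graph with FI edge weights,
   then Floyd–Warshall all-pairs shortest paths (`finnet.geodesic`).
4. **Network + embedding** — Gaussian kernel adjacency
   `A = exp(−D²/σ_G²)` with `σ_G` the mean same-predicted-label geodesic
   distance, and classical MDS coordinates (`finnet.embed`).
5. **Out-of-sample projection** — FI distances from a new case to its
   training anchors chained through the training geodesics, then solved
   into coordinates with the Gower out-of-sample formula
   (`finnet.project`).
6. **Retrieval & plots** — ranked nearest neighbours with labels, kernel
   similarities and pass-through metadata; latent-space scatter plots;
   row-normalised confusion tables (`finnet.report`).

The bundled classifier is a one-hidden-layer softmax MLP with analytic
input-gradients (`finnet.posterior`); any object implementing the
`PosteriorModel` contract can replace it. `finnet.datagen` generates
multi-class Gaussian-mixture features (class means on a regular simplex)
so the whole pipeline is testable without external data, and
`finnet.preprocess` provides variance-threshold PCA.

## CLI

Every stage reads/writes plain CSV/JSON artifacts:

```sh
finnet simulate --n 500 --classes 5 --dim 20 --sep 6 --sd 1 --seed 0 --out-prefix data/train
finnet simulate --n 50  --classes 5 --dim 20 --sep 6 --sd 1 --seed 1 --out-prefix data/test
finnet fit     --features data/train.csv --out-dir model --pca-var 0.9 --decay 0.001
finnet embed   --model-dir model --features data/train.csv --out-dir latent --knn 10 --steps 10
finnet project --model-dir model --embedding-dir latent --features data/test.csv --out latent/test.csv
finnet report  --embedding-dir latent --case-id case00003 --k 10 --metadata meta.csv
```

Case files are comma-separated with a header: `case_id`, feature columns,
and optionally `label`.

## Library example

```python
import numpy as np
from finnet import *

spec = SyntheticSpec(n_cases=500, n_classes=5, n_features=50, separation=6.0, seed=0)
X, y = generate_features(spec)
pca = fit_pca(X, variance_threshold=0.9)
Z = apply_pca(pca, X)
model = train_mlp(Z, y, MLPConfig(weight_decay=1e-3, seed=0))

seg = SegmentDistanceSpec(n_steps=10, ridge=1e-8)
graph = build_graph(Z, model, k=10, spec=seg)
D = all_pairs_geodesic(graph)                       # Floyd-Warshall
sigma = compute_sigma_g(D, model.predict_labels(Z)) # same-predicted-label mean
A = kernel_adjacency(D, sigma)
emb = mds_embed(D, m=2)

results = project_cases(model, Z, graph, D, emb, Z[:3], spec=seg)
rep = nearest_neighbours(D.matrix[0], k=10, true_labels=y, sigma_g=sigma, exclude_index=0)
```

## Notes on defaults

- PCA centres by the training mean and does not rescale (optional
  `standardise=True` flag); default variance threshold 0.90.
- MLP defaults: 30 hidden units, learning rate 0.01, momentum 0.9, weight
  decay 0.2 as an L2 coefficient. 0.2 is strong for an L2 penalty and
  markedly underfits; the end-to-end examples use `weight_decay=1e-3`.
- Segment quadrature default 10 midpoints; a ridge of 1e-8 is recommended
  for graph building so distances in posterior-flat regions stay positive.
- kNN graph default k=10 with Euclidean pre-screening; disconnected
  components are bridged by the cheapest FI edge and the additions logged.
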