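# edpc — noise-robust unsupervised domain adaptation via discriminative possibilistic clustering

`edpc` implements EDPC, an unsupervised domain-adaptation classifier for the
setting where a labeled *source* dataset and an unlabeled *target* dataset
share a feature space but not a distribution — the situation of, e.g.,
cross-subject EEG emotion recognition from differential-entropy features,
where every new subject is a new domain. The package is aimed at
researchers who want a transparent, closed-form-update alternative to
adversarial adaptation methods, plus a fully synthetic benchmark so every
algorithmic claim can be checked without any data download.

## The model

Classical subspace adaptation minimizes the Maximum Mean Discrepancy

```
MMD²(Xs, Xt) = ‖ 1/n Σᵢ Pᵀxᵢˢ − 1/m Σⱼ Pᵀxⱼᵗ ‖²
```

between projected domains, but the empirical means are fragile: a few
outliers or mislabeled samples shift them and the alignment with them. EDPC
relaxes the MMD into a **possibilistic one-center clustering** distance

```
PC(λ) = Σₖ λₖ² ‖ Pᵀxₖ − Pᵀμ ‖²,   μ = δ·μₛ + (1−δ)·μₜ,
```

where each sample carries its own typicality weight λₖ ∈ [0,1]. A fuzzy
entropy penalty `θ Σ (w ln w − w)` on the effective weights `w = λ²` gives
the closed form `w = exp(−J/θ)`: a sample whose cost J (classifier residual
plus distance to its blended class center) is large is automatically
down-weighted, so noise stops dragging the means. The full objective couples

* weighted intra-class attraction to blended global and per-class centers
  ("sames attract"),
* an inter-class repulsion term `−β Σ_c ‖projected mean of class c −
  projected mean of the rest‖²` ("opposites repel"),
* graph-Laplacian label propagation `α·tr(YᵀLY)` on a kNN affinity graph,
* an `ℓ₂,₁`-regularized least-squares decision matrix W (row-sparse feature
  selection),

under the orthogonality constraint `PᵀP = I`. Optimization is
block-coordinate descent with a closed form per block: memberships
(elementwise exponential), W (iteratively reweighted least squares), labels
(eigenvectors of `H = αL + Bᵀdiag(w)B`, discretized and refined by per-row
coordinate descent), and P (a small Sylvester-type solve followed by polar
projection). The objective trace is non-increasing by construction.

Prediction fuses a source-only head and a shared head,
`υ·f̃s + (1−υ)·f̃t` with υ = 0.9; the in-sample target labeling produced by
the optimization itself (the transductive output) is available as
`state.pseudo_labels`.

## Worked example

```python
import numpy as np
from edpc import SyntheticSpec, make_domain_pair, fit, predict

spec = SyntheticSpec(seed=0)          # shifted 3-class pair, d=20, N=300
pair, y_true = make_domain_pair(spec)

state = fit(pair)                     # default hyperparameters
labels, scores = predict(state, pair.Xt)

print(len(state.objective_trace) - 2)                  # 4  (iterations)
print(np.mean(state.pseudo_labels == y_true))          # 0.980
print(np.mean(labels == y_true))                       # 0.973
```

The generator draws three Gaussian class blobs in 20 dimensions and gives
the target copy a 30° rotation plus a translation of norm 2 — a covariate
shift with a shared label space. On this pair the fit converges in 4
iterations (objective −203140.9 → −211297.1, monotone), the transductive
target accuracy is 0.980 and the fused prediction reaches 0.973, while a
ridge classifier trained on the source alone scores 0.967. With injected
outliers the same fit assigns them a median typicality weight of roughly
0.6× that of clean samples (see `state.Lam[:, 0]`), which is what keeps the
centers — and hence the alignment — in place.

The same run from the shell:

```bash
edpc synth --out data/ --seed 0
edpc fit --source-x data/Xs.csv --source-y data/ys.csv \
         --target-x data/Xt.csv --target-truth data/yt_true.csv \
         --out run/
# target accuracy: 0.9733
```

`edpc grid` searches β, ρ over {1e−6 … 1e6} and the neighbor count k over
{3, 5, 10, 15, 17}, ranking by target accuracy when a truth file is given
and by the final objective value otherwise.

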