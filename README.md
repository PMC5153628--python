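# cosine-dti

One-class collaborative filtering for genome-scale virtual screening:
completes a sparse binary protein–chemical interaction matrix by **weighted,
imputed logistic matrix factorization with dual similarity regularization**,
and predicts targets for brand-new chemicals (the cold-start problem) via a
weighted-profile extension.

## Who this is for

Computational chemists and bioinformaticians who have (a) a binary
interaction matrix `R` (m targets × n chemicals, e.g. a ChEMBL/DrugBank
extract or one of the public gold-standard sets), (b) a protein–protein
similarity matrix `M` (normalized Smith–Waterman), and (c) a
chemical–chemical similarity matrix `N` (Tanimoto), and want a ranked list of
candidate targets for every chemical — including chemicals with no known
interactions at all.

## The model

Interaction probabilities are logistic in a low-rank factorization
`R ≈ σ(F Gᵀ)`, with `F ∈ ℝ^{m×r}`, `G ∈ ℝ^{n×r}`. Training minimizes

    L = Σ_ij w_ij [ log(1 + e^{f_i·g_j}) − (r_ij + q_ij) f_i·g_j ]
      + (λ_F/2)‖F‖²_Fro + (λ_G/2)‖G‖²_Fro
      + (λ_M/2) tr(Fᵀ(D_M − M)F) + (λ_N/2) tr(Gᵀ(D_N − N)G)

where `tr(Fᵀ(D_M − M)F) = ½ Σ_ij m_ij ‖f_i − f_j‖²` is the homophily penalty
on the target-similarity graph (and symmetrically for chemicals).
Minimization is by full-batch AdaGrad, run **twice**: pass 1 with per-cell
weights `w_ij = 6` on
verified interactions and 1 elsewhere; then weights are incremented on
confidently-predicted cells and targets are imputed from the pass-1
probabilities (`r+q = 1` where `p ≥ p_high`, else `max(r, p)`); pass 2
re-minimizes. The homophily terms are graph-Laplacian penalties tying the
latent vectors to the similarity graphs. A new chemical's latent row is the
blend `v·g_j + (1−v)·Σ_{topJ} n_jk g_k / Σ n_jk` over its J most similar
chemicals with interaction data. See `docs/methods.md` for the full account.

## Worked example

All three inputs are tab-delimited adjacency tables (header row of chemical
ids, first column of target ids — the layout of the public gold-standard
distributions). No download is needed to try the pipeline; the package ships
a generator with the statistical structure the model assumes:

```sh
cosine simulate --out fixture --seed 7 --m 30 --n 50 --rank 3 --density 0.1
cosine fit --interactions fixture/R.tsv --target-sim fixture/M.tsv \
           --chem-sim fixture/N.tsv --out model
cosine predict --model model --out scores.tsv
cosine eval --protocol cv5 --simulate 7 --out eval_out
```

The `eval` step prints (numbers from an actual run):

```json
{
  "protocol": "cv5",
  "auc":  {"mean": 0.9852, "sd": 0.0087},
  "aupr": {"mean": 0.9502, "sd": 0.0301}
}
```

i.e. over five chemical-wise cross-validation folds — each fold's chemicals
fully removed from training and re-scored via the cold-start profile — the
model ranks true interactions with mean ROC AUC 0.985 and mean area under
the precision–recall curve 0.950.

The same from Python, recovering deliberately hidden interactions:

```python
import numpy as np
from cosine import (SyntheticSpec, generate_fixture, hide_positives,
                    fit_cosine, predict_probability)
from cosine.evaluate import auc

fx = generate_fixture(SyntheticSpec(seed=0))          # 50 x 80, rank 3
masked, hidden = hide_positives(fx.data, 0.25, seed=100)
result = fit_cosine(masked, fx.M, fx.N)               # two-pass training
P = predict_probability(result.model)

labels = np.zeros_like(masked.R)
for i, j in hidden:
    labels[i, j] = 1
unobserved = masked.R == 0
print(f"recovery AUC: {auc(P[unobserved], labels[unobserved]):.3f}")
```

```
recovery AUC: 0.996
```

80 of the 320 known interactions were hidden before training; the fitted
model ranks them against the ~3,700 untested pairs with AUC 0.996.

## Layout

```
src/cosine/
  data_io.py      tab-delimited I/O, validation, alignment
  factor_model.py losses, probabilities, analytic gradients
  optimizer.py    AdaGrad + the two-pass training driver
  reweight.py     position-specific weights and imputation
  cold_start.py   weighted-profile rows for new entities
  evaluate.py     AUC/AUPR/Top-1/TPR@r%, CV/LOOCV/cold-start protocols
  synthetic.py    fixture generator, hiding/noise injection
  workflow.py     end-to-end runs, manifests, model checkpoints
  cli.py          the `cosine` command
```
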