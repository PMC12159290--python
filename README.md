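# scadapt

Domain-adaptive drug-response prediction for single cells.

Bulk RNA-seq panels (cell lines screened against drugs) carry response
labels; patient single-cell RNA-seq mostly does not.  `scadapt` transfers a
classifier trained on labeled bulk profiles to unlabeled single-cell data:

1. **Representation.**  A residual variational autoencoder (Res-VAE) is
   pretrained on an unlabeled reference corpus of transcriptome embeddings.
   Residual blocks are `linear → spectral norm (optional) → batch norm →
   Swish` with dimension-adaptive shortcuts; the variational layer uses the
   reparameterization trick `z = μ + ε · exp(½ log σ²)` and the β-weighted
   objective `L = β·REC + KLD` with β = 1000.
2. **Transfer.**  Bidirectional adaptive instance normalization (AdaIN)
   re-styles each feature to target per-feature moments,
   `AdaIN(x, y) = σ(y)·(x − μ(x))/σ(x) + μ(y)`: bulk → reference style at
   training time, patient cells → bulk style at inference time (the bulk
   statistics are frozen into the model bundle).  The raw-expression route
   instead minimizes the Gaussian-kernel MMD between bulk and single-cell
   latent batches alongside the bulk-only cross-entropy.
3. **Classification.**  A two-logit head (sensitivity / resistance) on the
   frozen stem; 130 head-only epochs then 20 joint fine-tuning epochs;
   SMOTE(k=5)/Tomek or VAE-posterior augmentation for label imbalance.
4. **Distillation.**  A raw-expression student Res-VAE trained with
   `L = β·REC + KLD + θ·COD`, where COD is one minus the cosine similarity
   between teacher and student latents for the same cell.
5. **Interpretation.**  Expectation-based integrated gradients per output
   head, with a baseline library (cohort mean, zero, random-k,
   random-mean) and a Spearman rank-robustness audit; top-ranked features
   feed a Cox proportional-hazards risk score, median stratification and a
   Kaplan–Meier / log-rank comparison.

Everything runs on CPU (numpy with hand-written backpropagation; exact
input gradients for the attribution path), and a synthetic two-domain
generator reproduces the statistical structure the method assumes, so the
whole pipeline is testable without any external download.

## Worked example

```python
import json
from scadapt.pipeline import run_pipeline

config = {
    "pipeline": "adain_embedding",
    "seed": 42,
    "data": {"synthetic": {}},          # default two-domain study conditions
    "vae": {"latent_dim": 8, "encoder_block_dims": [32], "epochs": 40},
    "classifier": {},                   # 150 epochs = 130 head-only + 20 joint
    "attribution": {"n_steps": 32, "top_k": 30},
    "survival": {"synthetic_n": 200},
}
manifest = run_pipeline(config, "demo_run")
print(json.dumps(manifest["metrics"], indent=1))
```

prints

```
{
 "auroc": 0.9293285714285713,
 "auprc": 0.8779243119112234,
 "f1": 0.7480769230769231,
 "mcc": 0.6769160920789191,
 "accuracy": 0.869,
 "precision": 0.884090909090909,
 "recall": 0.6483333333333333
}
```

i.e. the bulk-trained classifier, after AdaIN re-styling, ranks unlabeled
target cells by resistance with AUROC ≈ 0.93 although the target domain is
distorted by per-feature scale factors spanning orders of magnitude
(predicting the same cells *without* the transfer step drops the AUROC to
roughly 0.7).  The run directory also holds predictions, per-head
attributions, the top-30 feature signature and its survival stratification
(here log-rank p ≈ 2.4e-37 on patients simulated with hazards tied to the
top-ranked features), plus a manifest with seeds and artifact hashes.

The same `config` style drives the CLI:

```bash
scadapt simulate --out sim/                      # two-domain CSV fixtures
scadapt run --config config.json --out run/      # any of the three pipelines
scadapt attribute --model run/model --data sim/single_cell.csv --out attr/
```

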