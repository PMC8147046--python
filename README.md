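# hippofuse

Classification of Alzheimer's disease (AD) versus cognitively normal (CN)
subjects from paired left/right hippocampus segmentation masks, for
researchers studying structural-MRI biomarkers of neurodegeneration.

Convolutional networks are good at local visual texture but notoriously
weak at *global object shape* — and hippocampal shape change is exactly
what AD atrophy produces. hippofuse therefore fuses two feature families
before classification:

- **Deep visual features**: a two-stream lightweight 3D dense CNN (one
  stream per hippocampus; dense blocks with 8 and 16 filters, ~75k
  parameters) whose merged global-average-pooling output summarizes
  appearance;
- **Global shape features**: the Laplace–Beltrami (LB) spectrum of each
  hippocampal surface (Shape-DNA). With Δf = div(grad f) on the surface
  *M*, the ascending eigenvalues 0 = λ₀ < λ₁ ≤ λ₂ ≤ … are computed by
  linear FEM (cotangent stiffness, consistent mass) and normalized to
  ln(λₙ/λ₁), n = 1…30 per side — an isometry- and scale-invariant global
  shape descriptor.

Both vectors are z-scored (training statistics only), concatenated, and
classified by a small fully connected softmax head trained with SGD
(momentum 0.9, lr 1e−3, dropout 0.5, L2 2e−2). The evaluation harness runs
repeated stratified k-fold cross-validation comparing shape-only,
visual-only, and fused models with accuracy, sensitivity, specificity, ROC
and AUC, plus Gaussian class-separability indices (Bhattacharyya,
Jeffries–Matusita, divergence) and a seeded 2-D UMAP embedding.

Real clinical segmentations are access-controlled, so the package includes
a first-class synthetic generator: paired closed hippocampus-like shapes
(ellipsoid + smooth surface-bump field) with two controllable, independent
class signals — global atrophy (semi-axis shrinkage) and local surface
texture (bump density). See `docs/methods.md` for the full model
description and limitations.

## Worked example

```python
from hippofuse.experiments import run_desk_experiment

result = run_desk_experiment(seed=1)   # ~10 min on one CPU
for model, s in result.summary.items():
    print(f"{model:7s} acc={s['accuracy']:.3f} sens={s['sensitivity']:.3f} "
          f"spec={s['specificity']:.3f} auc={s['auc']:.3f}")
for model in ("visual", "fused"):
    i = result.indices[model]
    print(f"{model:7s} JM={i['jeffries_matusita']:.3f} "
          f"B={i['bhattacharyya']:.2f} D={i['divergence']:.1f}")
```

prints (seed 1):

```
shape   acc=0.770 sens=0.700 spec=0.840 auc=0.870
visual  acc=1.000 sens=1.000 spec=1.000 auc=1.000
fused   acc=1.000 sens=1.000 spec=1.000 auc=1.000
visual  JM=2.000 B=61.94 D=6417.5
fused   JM=2.000 B=127.94 D=15998.5
```

Reading this: the generator planted both a global signal (AD semi-axes
× 0.85) and a local one (more surface bumps in AD). The shape-only head
sees mainly the bump signal (its descriptor is scale-invariant), the CNN
sees mainly the volume signal, and the fused model is at least as good as
the best single family while its features separate the classes more widely
on the Bhattacharyya and divergence indices (Jeffries–Matusita saturates at
its cap of 2 for both feature sets here) — the qualitative behaviour the
fusion design predicts.

The same pipeline runs from the shell:

```bash
hippofuse generate --out data/ --n-per-class 100 --seed 1
hippofuse features --data data/ --k 30 --out shape.csv
hippofuse evaluate --data data/ --k 5 --repeats 10 --seed 7 --out report/
hippofuse separability --features shape.csv --out indices.json
hippofuse embed --features shape.csv --seed 0 --out embedding
```

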