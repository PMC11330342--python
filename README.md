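# miloc

Multi-label prediction of **miRNA subcellular localization** from
multi-source association evidence.

Many miRNAs act in several compartments at once — cytoplasm, exosome,
nucleolus, nucleus, extracellular vesicle, microvesicle, mitochondrion — and
assigning these compartments experimentally is slow and costly. `miloc`
predicts the localization *set* of each miRNA by fusing five feature types
built from heterogeneous sources:

| block | source | method | width |
|---|---|---|---|
| sequence | sequence-similarity network (Smith–Waterman, GIP back-fill) | node2vec | 64 |
| disease | miRNA–disease association network | node2vec + graph attention auto-encoder | 128 |
| drug | miRNA–drug association network | node2vec + graph attention auto-encoder | 128 |
| mRNA network | miRNA–mRNA association network | node2vec + graph attention auto-encoder | 128 |
| co-localization | target mRNAs' own compartment annotations | per-compartment target ratios | 4 |

The concatenated 452-D vector feeds a self-attention layer over the five
blocks and a fully-connected net (two ReLU hidden layers, 7 sigmoid outputs)
trained with binary cross-entropy. Key formulas, in standard notation:

* GIP kernel: `GM(m_i,m_j) = exp(−λ‖MD(m_i)−MD(m_j)‖²)`,
  `λ = n_m / Σ_k ‖MD(m_k)‖²`
* sequence similarity: `SW(m_i,m_j) = sp(m_i,m_j) / √(sp(m_i,m_i)·sp(m_j,m_j))`
* Wang functional similarity over the disease DAG (decay Δ = 0.5):
  semantic values `D_di(dt)`, `DS(di) = Σ_{dt∈A(di)} D_di(dt)`,
  `SS(di,dj) = Σ_{dt∈A(di)∩A(dj)} (D_di(dt)+D_dj(dt)) / (DS(di)+DS(dj))`,
  best-match averaging over disease sets for `mFS(m_i,m_j)`
* co-localization ratios: `R_c(m) = |M_c(m)| / |M(m)|` for the four mRNA
  compartments
* loss: `L = −Σ_i [y_i log ŷ_i + (1−y_i) log(1−ŷ_i)]`

Evaluation uses the set-based multi-label measures (aiming, coverage,
accuracy, absolute true, absolute false) plus per-label ROC-AUC and AUPR
under pooled 10-fold cross-validation. A synthetic-data module generates
complete input bundles with planted localization signal, so the whole
pipeline is testable without any download. See `docs/methods.md` for the
model details and design rationale.

## Worked example

```python
from miloc import PipelineConfig, benchmark_instance, featurize
from miloc.evaluate import cross_validate

ds = benchmark_instance()              # 300 synthetic miRNAs, signal 0.8
cfg = PipelineConfig(seed=7)
res = featurize(ds, cfg)               # ~3 min on one CPU
print(res.features.shape)
rep = cross_validate(res.features, ds.labels.values, cfg,
                     block_dims=res.bundle.block_dims())
print(f"average AUC  {rep.average_auc:.4f}")
print(f"aiming {rep.metrics.aiming:.4f}  coverage {rep.metrics.coverage:.4f}  "
      f"absolute_true {rep.metrics.absolute_true:.4f}")
```

prints

```
(300, 452)
average AUC  0.8216
aiming 0.8755  coverage 0.8473  absolute_true 0.4367
```

Each miRNA is described by 452 features (64+128+128+128+4). The average AUC
is the mean per-compartment ranking quality of out-of-fold scores: 0.82 means
the model recovers most of the localization signal planted in the benchmark's
association networks (a label-shuffled control sits at ≈0.5). Aiming and
coverage are precision- and recall-like set measures; absolute_true is the
fraction of miRNAs whose *entire* predicted label set is exact — the
strictest measure, so it is always the lowest.

The same pipeline is scriptable from a shell:

```bash
miloc simulate --out data/ --seed 7
miloc featurize --data data/ --out feats/ --seed 7
miloc evaluate --data data/ --features feats/ --out eval/ --seed 7
miloc ablate   --data data/ --features feats/ --out ablation.tsv --seed 7
```

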