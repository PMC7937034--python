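# funlink

Functional-interactome inference and **gene set linkage analysis (GSLA)**
for interpreting observed transcriptomic changes (OTCs) at the
biological-process level.

Enrichment-based annotation tools can only label a gene set with terms the
set itself is enriched in; they fail when a transcriptomic change *impacts*
a process without overlapping it. GSLA instead asks whether the changed
genes are densely wired, in a high-quality functional interactome, to the
genes of an established biological process. `funlink` provides both halves
of that system at desk scale:

1. **Interactome inference.** Per-gene-pair features are computed from six
   evidence categories (interologs, phylogenetic profiles, domain-domain
   interactions, subcellular colocalization, coexpression, shared
   annotation; 36 features, census 1/3/23/4/2/3), gated by ROC AUC > 0.6,
   and fed to a soft-margin Gaussian-kernel SVM trained on a filtered
   experimental gold standard (interactions reported by ≥ 2 studies or by
   a low-throughput experiment) against 100× randomly sampled negative
   pairs. Every gene pair is then scored; the margin-clipped decision
   value is the edge confidence.

2. **GSLA.** A query set *Q* and reference set *R* are linked when both
   hold:
   - **Q1**: inter-set density `d(Q,R) = |edges(Q,R)| / cross-pairs(Q,R)`
     exceeds 0.01, and
   - **Q2**: the add-one permutation p-value of `d(Q,R)` against
     degree-preserving double-edge-swap rewirings of the interactome is
     below 0.001 (`p = (1 + #{d_null ≥ d_obs}) / (1 + n_perm)`), so that
     hub-rich set compositions cannot fake a linkage.

Supporting modules solve the interactome-size equation
`N_int·sens + (N_all − N_int)·(1 − spec) = N_pred` for the true
interactome size, benchmark interactome quality by guilt-by-association
function prediction (hypergeometric neighbour enrichment swept into a
precision-recall curve), and generate fully synthetic planted-module
benchmark bundles so everything runs without any database download.

## Worked example

```python
import numpy as np
import funlink as fl

bundle = fl.generate(fl.FixtureConfig(seed=1))       # planted benchmark
pos = [g.pair for g in fl.filter_gold_positives(bundle.gold)]
neg = fl.sample_negatives(bundle.truth.genes, pos, 100, seed=1)
pairs = pos + sorted(neg)
labels = np.array([1] * len(pos) + [0] * len(neg))

fm = fl.compute_features(pairs, bundle.evidence)     # 36 evidence features
sel = fl.select_features(fl.feature_aucs(fm, labels))
res = fl.train(fl.LabeledPairSet(fm.subset(sel), labels),
               fl.TrainingConfig(sigma_grid=(0.25, 1, 4), c_grid=(1, 8, 64),
                                 seed=1))
print(res.summary())
```

```
Functional association SVM (RBF kernel)
=============================================
features            : 35
training pairs      : 6060
sigma (kernel width): 4
C (soft margin)     : 1
CV sensitivity      : 0.8167
CV specificity      : 0.9955
CV harmonic mean    : 0.8917
apparent sensitivity: 0.9500
apparent specificity: 1.0000
```

35 of the 36 features pass the AUC gate on this bundle, and the chosen
kernel width/soft margin give a cross-validated harmonic mean of
sensitivity and specificity of 0.89 at a 1:100 class imbalance. Scoring
held-out true edges against random non-edges with this model gives a
ranking ROC AUC of about 0.98 — the planted evidence signal is recovered.

Running GSLA on a planted module:

```python
mod1 = sorted(bundle.sets["module_01"].members)
query = fl.GeneSet("query", "", frozenset(mod1[:3]))
results = fl.gsla_run(bundle.truth, query, bundle.sets,
                      fl.GslaConfig(n_permutations=1999, seed=1))
print(results.summary().head(3)[["ref_set", "density", "p_value",
                                 "passes_q1", "passes_q2"]])
```

```
      ref_set   density  p_value  passes_q1  passes_q2
0   module_01  0.666667   0.0005       True       True
1  module_106  0.066667   0.0400       True      False
2   module_02  0.000000   1.0000      False      False
```

The module's own reference set tops the ranking at the minimal attainable
p-value `1/2000 = 0.0005 < 0.001`; a module that happens to share one edge
with the query passes the density screen but fails the permutation test,
and modules with no connecting edges fail Q1 and are not tested further.

The same workflow is scriptable end to end:

```bash
funlink run --out runs/demo --seed 1
funlink estimate-size --n-predict 88069 --n-genes 19711 \
        --sensitivity 0.3248 --specificity 0.9998
```

The second command solves the size equation at genome scale and prints an
estimated interactome size of ~1.52 × 10⁵ true interactions, i.e. roughly
one interaction per ~1280 gene pairs, of which the 88 069 predictions are
expected to cover about 32% at ~56% precision.

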