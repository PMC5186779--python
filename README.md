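# brainpred

Link prediction for resting-state functional brain networks.

Resting-state fMRI studies summarize each subject's brain as a binary
graph: ~90 anatomical regions, with an edge wherever the Pearson
correlation between two regional time series survives a sparsity
threshold.  A long-standing observation is that such functional edges are
partly predictable from geometry — close regions connect more ("distance
penalty") — and partly from local network topology: node pairs whose
neighbourhoods already look alike tend to be connected.  `brainpred`
implements and evaluates a family of prediction models that combine the
two, for methodologists comparing local-information indices and for
anyone who needs a tested reference implementation of the surrounding
pipeline (network construction, graph metrics, evaluation statistics).

## The model

For a node pair (i, j) with Euclidean centroid distance d_ij and a
local-information similarity s_ij, the connection score is

    P_ij = s_ij^gamma / d_ij        (default "penalty" form)
    P_ij = d_ij * s_ij^gamma        (optional "literal" form)

with the exponent gamma scanned over [0, 3] in steps of 0.1 (s^0 := 1, so
gamma = 0 is the pure distance model).  Seven similarity indices are
supported, all functions of the common-neighbour count and the two
degrees:

| index | s_ij |
|-------|------|
| CN    | \|Γ_i ∩ Γ_j\| |
| HDI   | CN / max(k_i, k_j) |
| HPI   | CN / min(k_i, k_j) |
| LHN-I | CN / (k_i·k_j) |
| PA    | k_i·k_j |
| RA    | Σ_{z∈Γ_i∩Γ_j} 1/k_z |
| SI    | 2·CN / (k_i + k_j) |

A prediction keeps the top-m scoring pairs, edge-matched to the real
network (m = round(S·n(n−1)/2) at sparsity S), and is scored two ways:

* **prediction power** = 10·log10(Pre_M / Pre_R) dB, where Pre_M is the
  fraction of real edges recovered and Pre_R the chance-level fraction
  (0 dB = random, 10·log10(n(n−1)/2 / m) dB = perfect);
* **energy** E = 1 / Σ re_p, the reciprocal summed relative error of
  eight topological properties (assortativity, clustering, path length,
  global/local efficiency, modularity, transitivity, and the truncated
  power-law degree-distribution fit), each summarized by its AUC over the
  5–40% sparsity grid.

Group-level comparisons use exact Wilcoxon signed-rank tests with
Benjamini–Hochberg FDR (q = 0.05), one-way ANOVA across models, and the
energy-vs-power Pearson correlation.

Because no subject data ship with the package, a synthetic-cohort
generator provides ground truth: spatially embedded modular small-world
networks (edge weight ∝ exp(−d/λ), boosted within modules) and regional
time series drawn from a multivariate normal whose covariance embeds the
planted adjacency.

## Worked example

```python
import brainpred as bp

cfg = bp.SyntheticConfig(n_regions=90, sparsity=0.15, seed=7)
truth, ts = bp.generate_subject(cfg)                 # planted network + fMRI-like series
corr = bp.pearson_correlation_matrix(bp.regress_confounds(ts))
net = bp.threshold_by_sparsity(corr, 0.15)           # binary network, 601 edges

model = bp.LinkPrediction(net, truth.coordinates, "CN")
print(model.fit().summary())
```

```
Link prediction fit
============================================
index             CN
distance mode     penalty
criterion         prediction_power
nodes / edges     90 / 601
best gamma        1.4
edges recovered   0.742
prediction power  6.942 dB
```

The fitted exponent 1.4 says the common-neighbour term materially
improves on pure distance; 74.2% of the real edges are recovered against
a 15% chance rate, i.e. the prediction is ~6.9 dB above random.

The same pipeline is scriptable end to end:

```
brainpred simulate --n-regions 90 --seed 42 --out subj/
brainpred construct --timeseries subj/timeseries.tsv --out nets/
brainpred predict --network net.tsv --coords subj/coordinates.tsv --index CN --out pred/
brainpred study --n-subjects 12 --seed 0 --out study/
```

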