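# coregnet

Co-regulation partnership networks and their scaling laws, for systems
biologists studying how regulators (transcription factors, kinases)
divide up control of a genome.

## The question

Regulators rarely act alone: two transcription factors are *partners*
when they control at least one common target gene. Given a directed
regulatory network, how does a regulator's number of partners `f` scale
with its number of targets `k`? Across curated networks from bacteria
to human, the answer is an **exponential saturation curve**

```
f(k) = a (1 - e^{-b k}),    a, b >= 0,
```

where `a` is the plateau (the limiting number of partners, empirically
around half the available regulators) and `b` the approach rate. In
bacteria only the initial, nearly linear part of the curve is visible
at the gene level, because operons shrink the effective target pool;
recounting targets as *operons* brings the saturating tail back.

`coregnet` implements the full analysis as a tested pipeline:

1. **Partnership construction** — project the bipartite regulator →
   target network onto regulator pairs sharing targets.
2. **Null-model filtering** — generate degree-preserving randomized
   networks (double edge swaps); score each pair by the co-regulation
   coefficient `CC = x/mu` (real shared count over null mean) or the
   z-score `(x - mu)/sigma`, and keep `CC > 1` edges by default.
3. **Scaling fits** — per-regulator (k, f) scatter, ordinary least
   squares for the linear law, bounded nonlinear least squares for the
   saturation law, preference by R²; log–log power-law diagnostics of
   the partnership degree distribution; operon recalibration; node and
   edge down-sampling controls.
4. **Explanatory models** — the closed-form random-target-acquisition
   curve `f(k) = m(1 - e^{-(n/N)k})` with its Monte-Carlo oracle, and a
   generative network-growth simulator (node addition, duplication with
   partial edge inheritance, TF→TG conversion, edge turnover).
5. **Synthetic data** — generators for heavy-tailed bipartite networks,
   operon-structured bacterial networks, and noisy saturation scatter,
   so every stage is testable without external downloads.

## Worked example

```python
from coregnet import PartnershipModel, SynthNetworkSpec, make_bipartite_network

net = make_bipartite_network(
    SynthNetworkSpec(157, 4410, "powerlaw", exponent=1.4, seed=0))
res = PartnershipModel(net, ensemble_size=100).fit(seed=100)
print(res.summary())
```

```
Partnership network analysis
============================================================
Network: synth-powerlaw
  regulators=157  targets=4377  interactions=16707
Null ensemble: size=100  swap_factor=10  seed=100
Edge filter: cc (threshold 1); 1174 partnership edges retained
------------------------------------------------------------
Partners f vs targets k (one point per regulator):
  linear:         f = 0.03192 k + 11.56   R^2 = 0.6082
  exp saturation: f = 54.55 (1 - exp(-0.01016 k))   R^2 = 0.8057
  preferred: exp_saturation (delta R^2 = +0.1975)
Degree-distribution power-law diagnostic: gamma = 0.675, R^2 = 0.597
```

Reading the output: of 157 regulators, partnerships that beat the
degree-preserving null (CC > 1) form a network of 1,174 edges. The
partners-vs-targets scatter is fit clearly better by the saturation
curve (R² 0.81 vs 0.61), with a plateau of ≈ 55 partners — roughly a
third of the regulator pool — and the weak power-law diagnostic on the
partnership degree distribution (R² 0.6 with a shallow exponent of
0.68) shows partnership degrees far more homogeneously distributed
than the heavy-tailed regulatory out-degrees that produced them.

The same analysis is scriptable from the shell:

```bash
coregnet synth -m 157 -n 4410 --law powerlaw --exponent 1.4 --seed 0 --out net.tsv
coregnet run net.tsv --ensemble-size 100 --seed 100 --out-dir run/
coregnet grow --iterations 10000 --seed 0 --out grown.tsv --audit-out audit.json
```

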