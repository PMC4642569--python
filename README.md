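# netkl

Network visualization, node ordering and coarse-graining as one
optimization problem: find the representation **B** of a weighted network
**A** that is hardest to tell apart from it, measured by the relative
entropy (Kullback–Leibler divergence)

```
D(A‖B) = Σ_{ij: a_ij>0} (a_ij/a_**) ln[ (a_ij/a_**) / (b_ij/b_**) ]   [nats]
```

where `a_** = Σ_ij a_ij` and `b_** = Σ_ij b_ij` normalize the raw
non-negative weights, so inputs never need to be normalized by hand.
Three families of representations share this single quality function:

* **Gaussian layouts** — every node i becomes an isotropic d-dimensional
  Gaussian with position `x_i`, width `σ_i` and norm `h_i`; the
  representation weight of a pair is the overlap integral
  `b_ij = h_i h_j [2π(σ_i²+σ_j²)]^(−d/2} exp(−‖x_i−x_j‖²/(2(σ_i²+σ_j²)))`.
  Minimizing D is a force-directed layout whose attractive and repulsive
  forces both derive from the one objective: an edge whose normalized
  overlap falls short of its normalized weight pulls its endpoints
  together, an over-represented pair pushes apart, and non-edges repel
  through the `b_**` normalization alone, so B stays as sparse as A.
  In d = 1 the layout is a seriation: it orders the nodes.
* **Degree-preserving coarse-graining** — groups of nodes are fused into
  degree-proportional averages at fixed node degrees. The divergence of
  the fused representation is exactly the mutual information lost,
  `D = I(A) − I(M)` for the reduced group matrix M, and minimizing it at
  fixed group count is equivalent to maximizing the Karrer–Newman
  degree-corrected stochastic block-model kernel
  `Σ_rs m_rs ln(m_rs/(κ_r κ_s))`. Greedy pairwise fusion builds a full
  dendrogram whose heights are cumulative information loss, ending at
  I(A).
* **Hierarchical layout** — the dendrogram replayed top-down guides the
  layout from one node to the full network; at every intermediate scale
  the coarse-graining divergence is a hard lower bound on the layout
  divergence.

Baselines are built in: the structureless product state
`b⁰_ij = a_i* a_*j / a_**` satisfies `D(A‖B⁰) = I(A)` exactly, so the
quality ratio η = D/I(A) runs from 100% (trivial representation) to 0
(perfect). Divergences can equivalently be quoted against the total
description length, η_S = D/S(A), the scale used for the layout
percentages below. Pinsker's inequality
`TV(A,B) ≤ sqrt(D/2)` guarantees that low-divergence representations have
few spurious connections.

## Worked example

```python
import netkl

A = netkl.karate_fixture()            # weighted 34-node karate club
info = netkl.summarize(A)
print(f"S = {info.entropy:.3f} nats, I = {info.mutual_information:.3f} nats")

# hierarchical coarse-graining and the two-community cut
cg = netkl.KLCoarseGraining(n_clusters=2).fit(A.values)
print(f"final dendrogram height = {cg.heights_[-1]:.3f} nats (= I)")
print(f"two-cluster divergence  = {cg.divergence_:.3f} nats")

# dendrogram-guided 2-D Gaussian layout with width/norm fine-tuning
emb = netkl.GaussianEmbedding(n_components=2, init="hierarchical",
                              n_restarts=4, random_state=0).fit(A)
print(f"layout D = {emb.divergence_:.4f} nats, "
      f"eta_S = {100 * emb.divergence_ / info.entropy:.2f}%")
```

prints

```
S = 4.969 nats, I = 1.455 nats
final dendrogram height = 1.455 nats (= I)
two-cluster divergence  = 1.078 nats
layout D = 0.1003 nats, eta_S = 2.02%
```

The dendrogram height reaching I(A) confirms that full fusion discards
every bit of row–column structure; the two-cluster cut keeps 1.455 − 1.078
≈ 0.38 nats of it and coincides with the split found by weighted
modularity maximization. The layout leaves about 2% of the description
length unexplained; each node's σ_i shows the residual uncertainty of its
position.

The same operations are available from the shell:

```bash
netkl info network.tsv
netkl layout network.tsv --dim 2 --seed 0 --svg layout.svg --coords xy.tsv
netkl order network.tsv --out ordering.txt
netkl coarsegrain network.tsv --cut 2 --newick tree.nwk --table merges.tsv
netkl hierlayout network.tsv --dim 2 --snapshots stages/
```

Inputs are TSV edge lists (`source  target  weight`), dense matrices, or
edge-by-node incidence matrices (hypergraphs/bipartite data) via
`A ~ HᵀH`.

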