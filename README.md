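# micronet

Network-based detection of subtle perturbations in time-series microbiomes.

Conventional alpha-diversity indices (Shannon, inverse Simpson, Chao1) are
largely blind to a *subtle* perturbation — for example, bioaugmenting an
anaerobic digester with a pregrown strain that never becomes abundant but
still rewires the community. `micronet` implements the alternative: compare
the community's *interaction network* before (control, "C") and after
(bioaugmentation, "B") the perturbation, and read the response off network
topology and motif structure instead of composition alone.

The pipeline, for a paired family-level 16S abundance time series:

1. **Abundance features.** Depth-normalize counts (rescale every sample to
   the minimum library size, discard taxa under one adjusted read
   everywhere), convert to relative abundances, and classify each taxon i by
   - abundance level from the presence-mean
     x̄ᵢ = Σₖ xᵢₖ / #{k : xᵢₖ > 0}: **H** (> 1%), **L** (0.1–1%), **R** (< 0.1%),
     with **nR** for rare taxa absent from some samples;
   - **core** status (present in every sample);
   - differential status by paired t-test on same-date samples:
     Diff_UP / Diff_DN (p < 0.05) or NDiff_UP / NDiff_DN.
2. **Co-occurrence patterns.** Pearson self-correlation r_CᵢBᵢ of a taxon's C
   versus B trajectory finds taxa with conserved dynamics; within-condition
   correlations r_CᵢCⱼ / r_BᵢBⱼ attach similar taxa. Average-linkage
   clustering under 1 − r distance, followed by an anchor/link significance
   filter, yields co-occurrence clusters tagged with ascent / descent /
   convex trajectory shapes and a before/after epoch per link.
3. **Ensemble gLV network inference.** Discrete-time generalized
   Lotka-Volterra dynamics, ln(xᵢ(k+1)/xᵢ(k))/Δt = bᵢ + Σⱼ aᵢⱼ xⱼ(k), fitted
   by ridge-regularized gradient matching on many random 90% taxon subsets
   (1000 networks by default). The coefficient aᵢⱼ is the directed influence
   j → i; an interaction is **reliable** when its sign is coherent in ≥ 90%
   of the fits observing the pair and an exact binomial test rejects a coin
   flip.
4. **Topological niche.** At each interaction-strength level S (top-500 …
   top-2000 edges, plus the full network), normalized indegree and
   betweenness centralities per taxon; the niche score
   Nicheᵢ = Σ_S (Centᵢ,S^B − Centᵢ,S^C) / maxⱼ |rawⱼ| ∈ [−1, 1]
   classifies each taxon as bioaug_niche (> 0.1 on both centralities),
   control_niche (< −0.1), none, or ambiguous.
5. **Motif analysis.** Exact census of connected induced 3-/4-node directed
   subgraphs (ESU enumeration), canonical identifiers given by the minimum
   row-major adjacency bitmask over node relabelings (the convention in
   which 36 = convergence, 98 = feedback cycle, 78 = reciprocal hub,
   74 = reciprocal dyad + in-edge), z-scores against a degree- and
   mutual-dyad-preserving edge-switching null, representativeness across
   strength levels, sub-motif containment, and the fraction of a 4-node
   motif's instances that carry a feedback loop of correlated taxa.

A fully ground-truth-annotated **synthetic community generator** emulates
the study shape (113 families, 7 paired dates, ~19,392 ± 982 reads/sample,
planted trajectory groups, planted ±3-sd differential shifts,
condition-specific rare taxa including a ~0.4% invader), so every stage is
testable end-to-end without external data.

## Worked example

```python
from micronet import PipelineConfig, run_pipeline
from micronet.config import Ensemble, MotifSettings

cfg = PipelineConfig(
    ensemble=Ensemble(n_networks=200),          # scaled-down ensemble
    motifs=MotifSettings(sizes=(3,), n_random=10),
    strength_grid=(500, 1000),
    seed=42,
)
res = run_pipeline(cfg)                          # synthetic study-shaped data
shared, c_only, b_only = res.partition
print(f"taxa: {res.table_c.n_taxa}   Venn: {len(shared)} shared / "
      f"{len(c_only)} control-only / {len(b_only)} bioaug-only")
print(f"reliable edges: C={sum(e.reliable for e in res.edges_c)} "
      f"B={sum(e.reliable for e in res.edges_b)}")
print(f"PC1+PC2 variance: {res.pca_variance[:2].sum():.2f}%")
print("niche classes:", res.niche["niche_class"].value_counts().to_dict())
```

prints

```
taxa: 113   Venn: 101 shared / 5 control-only / 7 bioaug-only
reliable edges: C=10456 B=10847
PC1+PC2 variance: 75.79%
niche classes: {'none': 102, 'bioaug_niche': 6, 'control_niche': 5}
```

The Venn partition recovers the planted condition-specific taxa exactly
(101 shared families, 12 specific); the perturbed and control samples
separate in the leading principal components; and eleven taxa shift their
topological niche between the two inferred networks while most of the
community is topologically unmoved — the signature of a subtle perturbation.

There is also a CLI (`micronet simulate | annotate | correlate |
infer-network | topology | motifs | run-all`), e.g.

```bash
micronet run-all --seed 42 --out-dir out/
```

which writes every stage artifact (annotations, clusters, edge lists, niche
scores, motif records, PCA report) as TSV/JSON with the config hash and
seed in each header.

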