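# bridgenet

Multilayer partial-correlation network analysis for cohort studies that
measure variables at several levels of organisation at once — typically
mental-health questionnaires, cognitive test scores and regional
gray-matter volumes (GMV).  The package estimates a single regularized
network over all variables, identifies the *bridge nodes* that connect the
layers, and quantifies how stable that identification is under resampling.

It is aimed at researchers in network psychometrics and clinical
neuroscience who want the full workflow — covariate residualization,
mixed-type correlation, penalized network estimation, bridge centrality,
bootstrap stability — as a tested, scriptable library rather than a chain
of one-off analysis scripts.

## The model

Variables are nodes of a Gaussian graphical model (GGM): the data are
treated as multivariate normal with precision matrix K, and a zero entry
K_ij = 0 means variables i and j are conditionally independent given all
others.  Edges carry the partial correlations

    w_ij = − K_ij / √(K_ii · K_jj).

K is estimated by the graphical LASSO (L1-penalized maximum likelihood)
over a descending penalty path, with the Extended Bayesian Information
Criterion selecting the penalty:

    EBIC(K) = −2·L + E·log n + 4·E·γ·log p,   L = (n/2)(log det K − tr(SK)),

where S is the input correlation matrix, E the number of nonzero edges,
p the number of nodes and γ = 0.5 by default.  Input correlations are
chosen per pair (Spearman when either variable is ordinal or non-normal,
Pearson otherwise), and every node is first residualized on its nuisance
covariates: age for all nodes, plus total intracranial volume and
acquisition site for GMV nodes.

Given a layer partition, the *bridge strength* of node i is
Σ_{j : layer(j) ≠ layer(i)} |w_ij| — its total interlayer connectivity.
Nodes strictly above the 80th percentile of the raw strengths are bridge
nodes.  Stability is measured by the case-dropping bootstrap: the
correlation-stability (CS) coefficient is the largest proportion of
participants that can be dropped while the subsample bridge strengths keep,
with 95% probability, a correlation of at least 0.70 with the full-sample
ones (CS ≥ 0.50 stable; 0.25–0.50 interpret with caution; < 0.25 not
interpretable).

A seeded synthetic-cohort generator produces multilayer data with known
ground truth (sparse multilayer precision matrix, ordinal questionnaire
nodes, age/TIV/site confounding), so the whole pipeline is testable end to
end without any restricted clinical data.

## Worked example

```python
import bridgenet as bn

# a three-layer cohort (4 mental-health, 6 cognition, 8 GMV nodes) with a
# planted 4-node bridge set and realistic confounding
truth = bn.make_planted_bridge_model(seed=7)
cohort = bn.sample_cohort(truth, n=457, seed=8)

res = bn.MultilayerGGM.from_cohort(cohort).fit()
print(res.summary())
```

```
================================================================
          Multilayer Gaussian Graphical Model Results
================================================================
No. participants:                  457
No. nodes:                          18
Layers:                            mental_health, cognition, gmv
EBIC gamma:                       0.50
Selected lambda:                0.0711
Edges (nonzero/possible):   51/153 (33.3%, medium)
Edge weights (all pairs):   mean 0.017 (SD 0.068), range [-0.19, 0.27]
----------------------------------------------------------------
             Bridge strength (80th-percentile rule)
----------------------------------------------------------------
  gmv1        gmv                1.022  *bridge*
  mh1         mental_health      0.593  *bridge*
  cog1        cognition          0.586  *bridge*
  cog2        cognition          0.579  *bridge*
  cog6        cognition          0.299
  ...
  threshold (80th pct)                 0.467
================================================================
```

The EBIC selected a penalty giving 51 of 153 possible edges (33.3%, a
"medium"-density network), and the four nodes designated as bridges —
`gmv1`, `mh1`, `cog1`, `cog2` — are exactly the four that were planted as
interlayer hubs in the generating model.  Ranked interlayer edges and the
bootstrap stability of the profile follow the same object:

```python
res.interlayer_edges().head(3)     # strongest cross-layer edges
stab = res.stability(n_boot=2000, seed=1)
res.cs()                           # CSCoefficient(cs=..., band=...)
```

The same workflow is available from the shell:

```bash
bridgenet simulate --layer-sizes 4,6,8 --n 457 --seed 7 \
    --out cohort.tsv --layers-out layers.yaml
bridgenet run --cohort cohort.tsv --layers layers.yaml --out-dir out/
```

which writes the weight matrix (CSV), edge list (TSV), GraphML, bridge
profile, Fruchterman–Reingold layout, bootstrap draws and a JSON report.

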