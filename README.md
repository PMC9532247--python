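# pollinet

Analysis of plant–pollinator interaction networks from flower-visitation
surveys: weighted bipartite webs, structural and specialization metrics,
connectance-preserving null models, multi-metric species-role ranking, and
comparison against published networks.

`pollinet` is aimed at community ecologists working with visitation
records of the form *site × date × habitat × plant × insect × visit
count*, as collected by hand-netting transect surveys and deposited in
interaction-web databases. It grew out of the analysis pattern of
national-scale flower-visitor datasets (notably the Irish one, whose
published summary tables ship with the package as reference data), but
every step runs on any survey table or interaction matrix in the standard
delimited formats.

## The statistics at its core

For a web with `P` plants, `A` visitors, visit counts `a_ij`, marginals
`A_i` (plants) and `B_j` (visitors), grand total `m` and `L` realized
links:

- **Connectance** `C = L / (P·A)` and **web asymmetry**
  `W = (A − P)/(A + P)` — positive when visitor species outnumber plants,
  the typical pattern in flower-visitor webs.
- **NODF** nestedness (0–100): mean percentage overlap of sparser rows
  (columns) within fuller ones, over all pairs with strictly decreasing
  fill.
- **H2′** network-level specialization: the two-dimensional Shannon
  entropy of `a_ij/m`, rescaled between the extreme entropies achievable
  by integer matrices with the observed marginals; 0 = interactions as
  proportional as the counts allow, 1 = maximally specialized. The
  extrema are computed exactly for small webs (convex-flow refinement for
  the maximum, vertex dynamic programming for the minimum) and by
  deterministic greedies beyond.
- **d′** species-level specialization: Kullback–Leibler divergence of a
  species' partner use from partner availability `q_j = B_j/m`, rescaled
  to [0,1]; **Δd′** = mean visitor d′ − mean plant d′.
- **vaznull** null model: randomized webs preserving dimensions, `m` and
  `L`, links placed with probability proportional to the product of the
  marginal frequencies; observed specialization is scored as
  `z = (obs − μ_null)/σ_null`.
- **Species roles**: weighted/unweighted degree, visitation rate (visits
  per mm² of floral display), node longevity (ISO-week activity span),
  betweenness/closeness centrality in the unweighted one-mode projection,
  and a leave-one-out functional-complementarity contribution — each
  min–max scaled to [0,1] and combined into top-*k* rankings,
  plant-family preference summaries and native/non-native permutation
  contrasts.
- **Good–Turing sample coverage** `Ĉ = 1 − (f1/n)·(n−1)f1/((n−1)f1+2f2)`
  from singleton and doubleton counts.

A synthetic-data module generates survey records with known ground truth
(log-log display–visitation slope β, non-native attractiveness deficit
δ < 1, guild-by-family preferences, phenology windows) so that every
estimator in the pipeline can be validated by parameter recovery.

## Worked example

```python
from pollinet import (CommunitySpec, generate_community, generate_surveys,
                      build_network, metric_report, null_ensemble,
                      species_role_table, top_k_union)

spec = CommunitySpec(n_plants=40, n_insects=20)
community = generate_community(spec, seed=7)
records = generate_surveys(community, n_sites=12, n_weeks=20, seed=8)

net = build_network(records)          # 38 plants x 20 visitors, m=730, L=265
report = metric_report(net)
print(report.connectance, report.nodf, report.asymmetry)
#  0.349  51.757  -0.310

ens = null_ensemble(net, n_reps=1000, seed=0)
print(ens.summary()["h2_prime"])
#  observed 0.231, null mean 0.144 +/- 0.009, z = 10.04

table = species_role_table(records)
print(top_k_union(table, k=5)["n_metrics"].sort_values(ascending=False).head(3))
#  Planta033 vulgaris    5
#  Planta012 vulgaris    4
#  Planta014 vulgaris    4
```

Reading: this simulated community is moderately connected (C ≈ 0.35),
nested (NODF ≈ 52), plant-biased (W ≈ −0.31), and significantly more
specialized than its connectance-preserving nulls (H2′ = 0.231 against a
null mean of 0.144, z ≈ 10). One plant ranks in the top five of all
seven role metrics — the "generalist core" species a restoration planting
would prioritize.

The same pipeline is available from the shell:

```bash
pollinet simulate --seed 5 --out surveys.csv
pollinet metrics surveys.csv --partition habitat_l1
pollinet nulls surveys.csv --n-reps 1000 --seed 5
pollinet rank surveys.csv --subgroup bee
pollinet compare --use-reference-table --focal Ireland
```

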