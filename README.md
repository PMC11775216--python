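# sdgspace

Network analytics for country-level sustainability indicator panels.

Given a country × indicator × year table of scores on a 0–100
percent-of-optimum scale (the layout used by the Sustainable Development
Report's SDG dashboards), `sdgspace` answers comparative questions that
raw scores hide: *which indicators is each country specialized in, how
are indicators related through co-specialization, and what do countries
gain and abandon as their overall performance rises?* It is aimed at
sustainability researchers and indicator-framework analysts who want the
product-space / economic-complexity toolkit applied to SDG-style score
panels, with a synthetic ground-truth generator so every stage is
testable without external data.

## The method

**Specialization.** For a complete year matrix `Score(c, i)` the
centered Balassa index (revealed comparative advantage) is

```
RCA[c,i] = (Score(c,i) / Σ_i Score(c,i)) / (Σ_c Score(c,i) / Σ_{c,i} Score(c,i)) − 1
```

so `RCA > 0` means country *c* devotes a larger share of its total score
to indicator *i* than the world does. The binary advantage matrix is
`M[c,i] = 1 iff RCA[c,i] > 0`; its row sums are *diversity*, its column
sums *ubiquity*.

**Sustainability indices.** The country sustainability index (CSI) and
goal sustainability index (GSI) are the ECI/PCI analogues on `M`: CSI is
the eigenvector of the second-largest eigenvalue of
`W = D⁻¹ M U⁻¹ Mᵀ` (D = diag(diversity), U = diag(ubiquity)), GSI the
ubiquity-normalized average of CSI over specialized countries. Both are
z-scored and sign-anchored so CSI correlates positively with raw scores.
The iterative method of reflections (alternating averaging over the
bipartite advantage graph, standardized each round) is provided as a
numerically verified cross-check.

**Indicator and country spaces.** Pairwise proximity is the cosine
similarity of binary advantage columns, `S[i,j] = co(i,j)/√(k_i·k_j)`;
the product of the two conditional co-specialization probabilities
(`co²/(k_i·k_j) = S²`) is kept as a diagnostic variant, and the
trade-off similarity is `1 − S`. The rendered space is the maximum
spanning tree (95 edges for 96 indicators) overlaid with every edge at
proximity ≥ 0.7, split into two communities by Girvan–Newman edge
removal and laid out with Kamada–Kawai. Transposing `M` yields the
country space.

**Trajectories and stages.** Countries are ranked by aggregate score and
grouped into overlapping rank windows (width 50, stride 1: 166 countries
→ 117 windows); per-window mean RCA traces how specialization evolves
along the development gradient. Quartile stages (Stage 1 "Primary" to
Stage 4 "Advanced") give per-stage RCA profiles, stage-to-stage deltas,
top/bottom-k specializations, a six-way GSI × environment grouping, a
four-area RCA × score classification, and *orphaned* indicators —
low-GSI indicators whose specialization is lost into negative territory
at the final stage transition.

## Worked example

```python
import sdgspace as s

spec = s.SyntheticSpec(n_countries=20, n_indicators=12, n_years=1,
                       noise_sd=3.0, seed=42)
panel, truth = s.generate_panel(spec)          # planted two-block panel
matrix = s.select_year(panel, 2000)            # complete 20 x 12 matrix
rca = s.compute_rca(matrix)
m = s.binarize_advantage(rca)
idx = s.eigen_indices(m, scores=matrix)
print("GSI > 0:", sorted(i for i in idx.gsi.index if idx.gsi[i] > 0))

p = s.proximity_matrix(m)
g = s.build_space_graph(p, threshold=0.7, node_scores=idx.gsi)
print("edges:", g.graph.number_of_edges(), "MST edges:", len(g.mst_edges))

ranking = s.rank_countries(matrix)
stages = s.assign_stages(ranking)
summary = s.stage_summary(rca, stages, k=3)
orphaned = s.identify_orphaned(summary, idx.gsi)
print("orphaned:", sorted(orphaned.loc[orphaned["orphaned"], "indicator"]))
```

prints

```
GSI > 0: ['I00', 'I01', 'I02', 'I03', 'I04', 'I05']
edges: 31 MST edges: 11
orphaned: ['I07', 'I08', 'I09']
```

The generator planted indicators I00–I05 as the block specialized by the
high-scoring countries: the GSI sign recovers that block exactly, the
12-node space keeps 11 tree edges plus 20 overlay edges, and the
orphaned set falls inside the low-GSI block (indicators whose mean RCA
drops below zero at the last stage transition).

The same pipeline is scriptable from a shell:

```
sdgspace synth --out scores.csv --countries 166 --indicators 96 --years 23
sdgspace run --scores scores.csv --out results/ --format csv --format graphml
sdgspace robustness --scores scores.csv --out robustness/
```

`run` writes per-year `rca.csv`, `indices.csv`, `space.graphml`,
`trajectories.csv`, `stages.csv`, `stage_deltas.csv`, `orphaned.csv`,
`quadrants.csv` and a `summary.json` with dropped entities, convergence
flags and community sizes. Real score panels are consumed as a long CSV
(`country_code, year, indicator, score`) via `--scores`.

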