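# triplenet

Resting-state fMRI connectivity analysis of the **triple-network model**:
the default mode network (DMN), central executive network (CEN) and
salience network (SN). The package is aimed at researchers who want to
quantify, per subject, how strongly eleven canonical triple-network
nodes interact — and then test whether a patient group differs from
controls in node-level, edge-level or network-level connectivity.

## The measure

Each of the 11 nodes (4 DMN, 4 CEN, 3 SN; 3 mm spheres at fixed MNI
coordinates) contributes one BOLD time series, obtained by discarding
the first 10 volumes, averaging over the sphere, removing the linear
trend and band-passing to 0.01–0.08 Hz. For nodes *i*, *j* with Pearson
correlation *c₍ᵢⱼ₎*, the edge weight is

```
η_ij = exp(−ξ·d_ij),   d_ij = (1 − c_ij) / (1 + c_ij),   ξ = 2
```

so η maps correlation monotonically onto (0, 1]: identical series give
η = 1, independent series give e⁻² ≈ 0.135. From the η graph over all
11 nodes the package computes

- the **node degree** Γᵢ = Σ₍ⱼ≠ᵢ₎ η᎐ᵢⱼ and its normalisation
  Γ̄ᵢ = Γᵢ / Σⱼ Γⱼ (Σ Γ̄ᵢ = 1 per subject),
- the **inter-network degree** Γ_MN = Σ₍ᵢ∈M₎ Σ₍ⱼ∈N₎ η᎐ᵢⱼ for each pair
  of networks,

and compares the two groups metric-by-metric with two-sample t-tests
(pooled by default, Welch by flag; uncorrected α = 0.05, optional
Benjamini–Hochberg). Nodes whose Γ̄ differs significantly get an
edgewise follow-up on every incident η.

Because clinical scans cannot ship with the code, a **synthetic cohort
simulator** generates two groups of BOLD-like node series with a
block-structured correlation target (higher within than between
networks), lag-1 autocorrelation and measurement noise, plus two
plantable effects: raised coupling on all edges of the right anterior
insula (rAI) and lowered DMN×CEN cross-correlation in the affected
group. Every stage of the pipeline is tested end to end against this
generator, including a NIfTI rendering/extraction round trip.

## Worked example

```python
from triplenet import (SimulationConfig, default_atlas, simulate_cohort,
                       analyze_cohort, compare_node_degrees,
                       compare_network_degrees)

atlas = default_atlas()                      # 11 nodes: 4 DMN, 4 CEN, 3 SN
cohort = simulate_cohort(atlas, SimulationConfig(seed=7))   # 16 + 16 subjects
conns, tables = analyze_cohort(cohort, atlas)
print(compare_node_degrees(tables).query("metric == 'rAI'"))
print(compare_network_degrees(tables))
```

With seed 7 this prints (abridged; `examples/group_comparison.py` runs
the full version):

```
metric   mean_a    mean_b          t         p  significant
   rAI 0.083343  0.145324 -33.146986 3.41e-25         True

  DMN-CEN: control 2.98+/-0.42 vs affected 0.91+/-0.27, p = 0.0000 *
  DMN-SN:  control 2.34+/-0.36 vs affected 3.14+/-0.33, p = 0.0000 *
  CEN-SN:  control 2.28+/-0.34 vs affected 2.92+/-0.26, p = 0.0000 *
```

Group *a* is the control group, so the negative t says the affected
group's normalised rAI degree (0.145 vs 0.083) is higher — the planted
insula hyper-coupling — while the DMN–CEN inter-network degree drops
from 2.98 to 0.91, the planted network decoupling. The other two
network pairs rise, a side effect of the raised rAI (an SN node)
coupling.

The same analysis runs from a shell:

```bash
triplenet run --mode simulate --seed 7 --out-dir out/
triplenet extract --manifest scans/manifest.tsv --out-dir series/   # real NIfTI data
triplenet connect --manifest series/manifest.tsv --out-dir conn/
triplenet compare --edges conn/edges.tsv --out-dir reports/
```

All reports are tab-separated tables; `run` additionally writes a
`run_metadata.json` that fully reproduces the run.

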