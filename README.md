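# peatmob

Amplicon OTU inference, bioindicator statistics and closed-vial CH₄
accounting for peat methanotroph (MOB) community studies.

Grazing by large herbivores reshapes high-latitude peatlands, and with them
the methane-oxidizing bacteria (MOB) that consume CH₄ before it reaches the
atmosphere. Quantifying that link takes two parallel measurements: community
profiling of the active MOB by *pmoA* transcript (and 16S rRNA V3–V4)
amplicon sequencing, and potential CH₄ oxidation rates from closed soil
microcosms. `peatmob` implements the complete computational path for both,
from raw paired reads to OTU tables, indicator statistics, ordination,
phylogeny and oxidation rates, together with seeded synthetic-data
generators that emulate every input with known ground truth.

## What it computes

**Sequence path** — read pairs are merged over their best 3′ overlap, reads
containing any 50-nt window with mean phred < 20 are discarded, primers are
trimmed under IUPAC degeneracy, sequences are dereplicated, chimeras are
removed by a two-parent crossover model (de novo and against a reference),
protein-coding amplicons are checked for an intact reading frame (length
divisible by 3, expected first/last codons, no in-frame stop), and OTUs are
built by single-linkage clustering at edit distance *d* = 1 (swarm style),
taxonomically assigned by best global affine-gap alignment against a
primer-trimmed, dereplicated reference database, then filtered by amplicon
length window and taxonomy.

**Statistics** — on relative-abundance matrices: OTUs below 0.001 relative
abundance per sample are treated as absent; matrices are log transformed
(x → log₂x + 1 for x > 0); treatment, sampling date, their interaction and
the CH₄ oxidation rate are tested by partial redundancy analysis (RDA)
conditioned on site, with sequential permutation tests of terms and axes
(p = (1 + #{F\* ≥ F}) / (1 + m)); bioindicator OTUs per treatment are found
with the IndVal statistic, IndVal = A·B with specificity
A<sub>jk</sub> = x̄<sub>jk</sub> / Σ<sub>k′</sub> x̄<sub>jk′</sub> and
fidelity B<sub>jk</sub> = occurrence frequency in group k, tested on 10 000
permutations at α = 0.001; group comparisons use the Kruskal–Wallis rank
sum test.

**Phylogeny** — Jukes–Cantor distances d = −(3/4)·ln(1 − 4p/3) with pairwise
deletion, neighbor-joining trees, and column-bootstrap bipartition support
(500 replicates by default) over a fixed alignment window (440 bp default).

**Gas accounting** — headspace CH₄ mass by the ideal gas law
(n = f·p·V / RT), pore-water CH₄ concentration adding the dissolved phase by
Henry's law (c = K_H·p_CH₄), and potential oxidation rates as the OLS slope
of headspace mass against time in a closed microcosm, scaled to
µg CH₄ g⁻¹ dry soil d⁻¹.

## Worked example

```python
import peatmob as pm

# 1 mL CH4 into a 175-mL bottle with 15 g peat and 34 mL added air
spec = pm.MicrocosmSpec(water_content=0.9)
print(f"headspace CH4: {spec.initial_ch4_fraction:.2%}")

series = pm.simulate_gas_series(pm.GasSimParams(consumption_rate=6.0, noise_sd=0.0), spec)
result = pm.oxidation_rate(series, spec)
print(f"rate: {result.rate:.1f} ug/g/d  (slope {result.slope:.1f} ug/h, R2 {result.r_squared:.3f})")

design = pm.CommunityDesign(
    dates=("summer2015",), replicates_per_cell=5,
    planted_bioindicators=(pm.PlantedIndicator(0, "grazed", 8.0),),
    seed=1)
counts, meta = pm.simulate_community_counts(design)
rel = pm.threshold_relative_abundance(pm.to_relative_abundance(counts))
iv = pm.indval(rel, meta["treatment"].tolist(), pm.StatsParams(n_permutations=10_000), seed=1)
print(iv[iv.bioindicator])
```

prints

```
headspace CH4: 0.51%
rate: 96.0 ug/g/d  (slope -6.0 ug/h, R2 1.000)
            group         A    B    indval       p  bioindicator
planted_0  grazed  0.888046  1.0  0.888046  0.0001          True
```

The 0.51 % headspace fraction is 1 mL CH₄ in 195 mL of gas volume; the
96 µg g⁻¹ d⁻¹ rate is the 6 µg/h consumption slope scaled by 24 h over
1.5 g dry soil; the planted 8-fold indicator is recovered at the
permutation floor p = 1/10 001 with no background OTU flagged.

A command-line front end mirrors the stages:
`peatmob process-reads | cluster | assign | stats | tree | gas`.

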