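# fluxomix

Constraint-based flux simulation and multi-omics statistics for fungal
fed-batch fermentations under oxygen limitation.

Industrial enzyme producers such as *Aspergillus niger* are grown in
fed-batch bioreactors where poor oxygen transfer into the viscous mycelial
broth pushes the culture into oxygen limitation, typically ~20 h into the
run. The limitation slows growth but raises product yield, and the
intracellular reasons — redistribution of central-carbon flux, redox
rebalancing, transcriptional reprogramming — are what this package lets you
analyse. It is aimed at quantitative physiologists and systems biologists
who have per-phase measured rates, metabolite pool sizes and RNA-seq time
courses and want a single tested pipeline from those tables to flux maps,
responsive-metabolite calls and enriched gene sets.

## What it computes

**Flux simulation.** A genome-scale (or toy) metabolic model is read from
SBML Level 3 + fbc or a plain TSV dialect, and each fermentation phase is
solved as the linear program

```
max/min  Z = cᵀ v
s.t.     S v = 0,   lb ≤ v ≤ ub
```

where `S` is the m × n stoichiometric matrix and `v` the reaction-rate
vector (mmol/gDCW/h). Measured biomass-specific rates — glucose uptake
`q_S`, oxygen uptake `q_O2`, product secretion `q_P`, by-product rates and
the maintenance demand `m_ATP` — are imposed as relative bound intervals on
the corresponding exchange reactions (uptake-negative convention). Growth
is maximized and the flux vector refined by **parsimonious FBA**: with the
optimum `Z*` pinned, every reaction is split into non-negative forward and
backward halves and `Σ|v|` is minimized. Predictions are validated by
comparing the growth rate μ and CO₂ evolution rate `q_CO2` with their
measured values, and reported per 100 mol glucose as relative fluxes.

**Metabolomics.** Pool-size tables (metabolites × samples, μmol/gDCW) are
imputed (half-minimum), autoscaled, and decomposed by PCA; the relation of
pools to `q_O2` is modelled by single-response NIPALS PLS and summarized by
the **variable importance in projection**,

```
VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ),
```

whose squared values average exactly 1 over the p metabolites; `VIP > 1`
flags oxygen-responsive pools.

**Transcriptomics.** Genes with little expression at two or more time
points are removed, standardized time profiles are soft-clustered by fuzzy
c-means (fuzzifier from a data-size heuristic), per-gene phase contrasts
use Welch t on log2(FPKM+1), and gene sets are scored in five directional
classes (distinct-directional up/down, mixed-directional up/down,
non-directional) against a size-matched gene-sampling permutation null,
with Benjamini–Hochberg control across sets. An exact hypergeometric
over-representation test covers simple gene-list enrichment.

**Synthetic data.** Every input above can be generated with known ground
truth: toy networks whose optima are enumerable (including a 19-reaction
central-carbon `core` model with an NADH-rich TCA lump, an NADH-poor
glyoxylate bypass, a polyol redox valve and a glucoamylase drain built from
the enzyme's amino-acid composition), a fed-batch scenario with an abrupt
oxygen switch at 20 h, pool tables with planted `q_O2`-tracking
metabolites, and expression matrices with planted temporal patterns and
gene sets.

## Worked example

```python
from fluxomix import (make_toy_model, FermentationScenario,
                      simulate_fermentation, simulate_phases,
                      validate_predictions)

model = make_toy_model("core")
scenario = FermentationScenario(noise_sd=0.05, tolerance=0.05, seed=1)
sim = simulate_fermentation(model, scenario)          # "measured" rates
results = simulate_phases(model, sim["phases"])       # constrained pFBA
report = validate_predictions(results, sim["measured"])

for r in results:
    rel = r.relative_fluxes
    print(f"t={r.constraints.time_h:5.1f} h  q_O2={r.constraints.q_O2:5.2f}  "
          f"mu={r.mu_predicted:.3f} 1/h  EMP={rel['EMP']:5.1f}  "
          f"TCA={rel['TCA']:5.1f}  GLX={rel['GLX']:5.1f}")
print(f"mean relative error in mu: {report['summary']['mean_rel_error_mu']:.3f}")
```

prints

```
t=  8.0 h  q_O2= 1.40  mu=0.150 1/h  EMP= 50.4  TCA= 28.1  GLX=  0.0
t= 16.0 h  q_O2= 1.37  mu=0.153 1/h  EMP= 50.7  TCA= 25.8  GLX=  3.6
t= 24.0 h  q_O2= 0.82  mu=0.075 1/h  EMP= 74.5  TCA=  0.3  GLX= 35.0
t= 36.0 h  q_O2= 0.79  mu=0.070 1/h  EMP= 75.4  TCA=  0.0  GLX= 35.5
t= 48.0 h  q_O2= 0.84  mu=0.080 1/h  EMP= 73.3  TCA=  0.0  GLX= 34.7
t= 60.0 h  q_O2= 0.81  mu=0.074 1/h  EMP= 74.2  TCA=  0.0  GLX= 35.1
t= 72.0 h  q_O2= 0.83  mu=0.076 1/h  EMP= 74.7  TCA=  1.5  GLX= 33.4
mean relative error in mu: 0.143
```

Columns are relative fluxes in mol per 100 mol glucose. When the culture
crosses the oxygen switch (20 h), `q_O2` halves and growth drops from
~0.15 to ~0.07 1/h; glycolytic throughput per glucose (`EMP`) rises from
~51 to ~75 because less hexose is drained into biomass carbohydrate and the
pentose-phosphate shunt, and acetyl-CoA catabolism swings from the
NADH-producing TCA lump to the glyoxylate bypass — the flux signature of
redox rebalancing under hypoxia. The 14% mean μ error reflects the 5%
multiplicative noise planted on the "measured" rates.

The same analyses run from the shell:

```
fluxomix synth --what all --seed 7 --out synthetic/
fluxomix simulate --model synthetic/model --phases synthetic/phases.tsv \
    --measured synthetic/measured.tsv --out flux_out/
fluxomix metabolome --pools synthetic/pools.tsv --phases synthetic/phases.tsv
fluxomix transcriptome --expr synthetic/expression.tsv \
    --samples synthetic/samples.tsv --gmt synthetic/sets.gmt --k 4
fluxomix all --config config.yaml
```

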