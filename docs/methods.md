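# Methods

This note records the models, defaults and numerical choices behind
`fluxomix`, what the synthetic generators do and do not emulate, and the
design decisions taken where the problem left room.

## Constraint-based flux model

Steady-state fluxes solve `max cᵀv` subject to `S v = 0` and `lb ≤ v ≤ ub`.
Default bounds are (0, 1000) mmol/gDCW/h for irreversible reactions and
(−1000, 1000) for reversible ones; exchange fluxes are negative for uptake
and positive for secretion, and measured uptake rates are entered as
positive magnitudes and negated internally. The LP is solved with HiGHS
via `scipy.optimize.linprog`; the contract is solver-agnostic (any engine
reproducing the objective to 1e−9 would do) and nothing downstream depends
on tie-breaking among degenerate optima — tests assert only
solver-independent quantities.

**Parsimonious FBA.** Stage 1 maximizes growth; stage 2 splits each
reaction into non-negative forward/backward parts, pins `cᵀv` to the stage-1
optimum within a relative slack of 1e−9, and minimizes the total flux sum.
Because the halves are never simultaneously active at the L1 optimum, the
reported `total_absolute_flux` equals `Σ|v|`. The pinning slack means the
recovered objective can sit up to one part in 10⁹ below the true optimum;
tests and the acceptance script treat 1e−8 relative as equality.

**Measured-rate constraints.** Each phase's `q_S`, `q_O2`, `q_P`,
by-product rates and `m_ATP` become relative bound intervals
`[q(1−tol), q(1+tol)]` (default `tol = 0.05`) rather than equalities;
equality constraints on noisy measurements routinely make the LP
infeasible. Whether the original analyses fixed or bounded these rates is
not documented, so both the tolerance and the fixed-band treatment of
`m_ATP` are configuration knobs. Phases are solved independently
(snapshot assumption) — the measured series is treated as a sequence of
pseudo-steady states, not integrated as dynamic FBA.

**Diagnostics.** `flux_variability` reports the min/max of each flux with
the objective held at its optimum. It exists because a single parsimonious
flux vector hides degeneracy; reactions with wide ranges should not be
over-interpreted.

**Validation.** `validate_predictions` compares predicted μ (biomass flux)
and `q_CO2` (CO₂ exchange magnitude) with measured values, reporting
absolute/relative errors per phase and their means.

## The `core` toy network

A 19-reaction lumped central-carbon model of an obligately aerobic,
glucoamylase-secreting fungus: glucose phosphorylation, upper glycolysis
(PFK + aldolase lump), lower glycolysis (GAPDH..PK lump, 2 ATP + 1 NADH
per triose), an oxidative pentose-phosphate cycle lump (12 NADPH + 6 CO₂
per hexose), pyruvate dehydrogenase, an oxidative TCA lump (4 NADH + 1 ATP
per acetyl-CoA), a glyoxylate bypass lump (1 NADH per 2 acetyl-CoA, to
C4), pyruvate carboxylase, oxidative phosphorylation at P/O 2, a polyol
redox valve (triose + NADH → glycerol), C4 overflow secretion, ATP
maintenance, a biomass drain and a glucoamylase drain.

Two choices matter for the qualitative behaviour:

* the biomass equation drains hexose phosphate heavily (3 mmol/gDCW,
  standing in for cell-wall glucan) so that when growth slows the freed
  hexose descends glycolysis, raising the EMP flux per 100 mol glucose;
* the redox valve sits on the triose pool, not the hexose pool. Fungi
  secrete both mannitol (hexose-derived) and glycerol (triose-derived)
  under oxygen limitation; with a hexose-level valve the overflow carbon
  would bypass aldolase and the EMP share would fall, so the glycerol
  placement is what lets the toy reproduce the observed EMP increase while
  staying biologically defensible.

The glucoamylase drain's precursor demand is the composition-weighted sum
over the enzyme's twenty amino acids (mass-percent table bundled in
`synthetic_data`, treated as molar fractions at toy precision), with each
amino acid mapped to its biosynthetic family's lumped precursors plus
4.3 ATP and 1.5 NADPH per residue for activation/polymerization and
reductive biosynthesis. `q_P` is carried in mmol residues/gDCW/h; a gram
basis would divide by a mean residue mass (~110 g/mol), exposed to the
caller rather than hard-coded.

Because the network's only ATP sinks are growth, product and maintenance,
its maximal `q_O2` at `q_S = 1` is ≈1.43 mmol/gDCW/h — real genome-scale
models admit higher uptake through futile cycling. Scenario rates are
generated from the model's own optima, so they are feasible by
construction.

## Fermentation scenario

Defaults: time grid 8–72 h, oxygen switch at 20 h, constant `q_S = 1`
mmol/gDCW/h (fed-batch at constant residual glucose), oxygen capacity 4.0
before and 0.8 after the switch (the aerobic cap is deliberately
non-binding), product drain 0.02 → 0.03 mmol residues/gDCW/h across the
switch (higher yield under limitation), maintenance 1.0 mmol ATP/gDCW/h.
The true flux vector per time point is the parsimonious optimum under that
schedule; emitted rates get multiplicative Gaussian noise
`q·(1 + sd·N(0,1))`, default sd 0.05 for rate tables (0 for closed-loop
identity checks). Noise-free closed loops recover μ and `q_CO2` exactly
because re-imposing a solution's own exchange rates is a tightening under
which that solution stays optimal.

The generator-derived error bound used in tests: optimal fluxes are
positively homogeneous in the bound vector, and the network's μ
sensitivity to any single rate group is below 2, so with noise sd ε and
tolerance ε the first-order bound on the mean relative μ error is
`2(ε+ε)`; at ε = 0.05 that is 0.20 (observed ≈0.09).

## Metabolomics statistics

Missing pools (<50% per metabolite) are imputed with half the metabolite's
minimum (limit-of-detection convention). Default scaling is autoscaling
(unit variance per metabolite), log-transform off, replicates kept as
separate samples; the published workflow states none of these, so all are
switches, and PLS-DA with dummy-coded phase labels is available next to
the primary continuous-`q_O2` PLS1 mode. PCA is the SVD of the
sample-centered matrix. PLS is single-response NIPALS, which per component
is non-iterative (weight = normalized covariance, then deflation); the
per-component explained response sum of squares `SS_a = q_a²·tᵃᵀtᵃ` feeds
the VIP formula, whose normalization identity `mean(VIP²) = 1` is asserted
to 1e−8 on every fit. Component count defaults to 2, with a leave-one-out
Q² selector available. Heatmap ordering is Euclidean complete-linkage with
rows/columns pre-sorted by id so distance ties resolve identically across
runs.

## Transcriptome statistics

The low-expression filter removes a gene when its replicate-mean FPKM is
below 1.0 at ≥2 time points; the threshold of 1 FPKM operationalizes
"little expression" and is logged in the outputs. Profiles are per-gene
z-scores of replicate-mean time courses. Fuzzy c-means uses Euclidean
distance, seeded center initialization from k distinct profiles,
memberships `u_ij ∝ (1/d_ij²)^(1/(m−1))`, and stops when the largest
center shift is below 1e−6 (300 iterations cap, `converged` flag exposed).
The fuzzifier heuristic `m(N, D)` gives ≈2.6–3.0 for 4-point profiles —
soft by design. Hard assignments therefore pass through a core-membership
cutoff, default 0.6: the winning cluster must carry more than twice the
membership of all others combined, and genes without coherent temporal
signal (membership near 1/k) are reported unassigned rather than forced
into a cluster. This mirrors the α-core convention of fuzzy time-course
clustering and is what makes hard assignments meaningful on z-scored
profiles, where a signal-free gene's shape is pure noise. k defaults to 20
for genome-scale runs (presentation parity) but is a knob; no automatic k
selection is attempted.

Gene-level statistics are Welch t on log2(FPKM+1) with log2 fold changes
on the +1-offset scale; with a single replicate only fold changes are
reported. The gene-set statistic is the mean gene-level t — signed for the
distinct-directional classes, absolute for the non-directional class and
for the up-/down-subsets in the mixed classes. The null resamples
size-matched gene sets without replacement (n_perm default 1999, add-one
empirical p). A gene-sampling null was chosen over sample permutation
because two replicates per phase make sample permutation degenerate.
Over-representation uses the exact hypergeometric tail; multiple testing
is Benjamini–Hochberg within each class. Transcription-factor reporting is
the generic `annotate_clusters` operation over a user-supplied gene list.

## Synthetic omics generators

Pools: informative metabolites are log-linear in the standardized
three-plateau `q_O2` profile (slope `effect`, default 1.0, alternating
sign so some pools fall and some accumulate under limitation) with
lognormal noise (log-sd 0.1); the default grid is 18–96 h with duplicate
sampling. Expression: four planted temporal shapes (up, down, transient,
flat) at amplitude 1.5 log2 units with lognormal noise (log-sd 0.2), four
time points with two replicates, planted low-expression genes for the
filter and planted gene sets (all-up, all-down, half/half mixed, null) for
the directional classes.

What the generators do **not** emulate: heteroscedastic count noise and
library-size effects in RNA-seq, correlated metabolite blocks and batch
effects, missing-not-at-random pools, biological replicate variance beyond
i.i.d. lognormal noise, or any kinetic (Monod/ODE) fermentation dynamics —
the scenario is a declarative flux schedule. Passing tests therefore
demonstrate correctness of the algorithms on data with the stated
structure, not robustness to every artefact of real instruments.

## Problem sizes and determinism

Test and acceptance runs use deliberately small instances — toy networks
of ≤19 reactions, 50-metabolite pool panels, 200-gene expression matrices,
2000-gene nulls with 1999 permutations — chosen so every check reruns in
seconds while keeping each statistical assertion comfortably powered.
Every stochastic step takes an explicit seed; identical configs produce
byte-identical outputs, and the pipeline manifest records the config,
seeds, package version and a SHA-256 per output file.

## Known limitations

* No ¹³C-MFA, thermodynamic constraints, gene-deletion analysis or dynamic
  FBA; no automatic selection of k or of the VIP threshold.
* The TSV model dialect is this package's own; SBML+fbc is the
  interchange format.
* Directional gene-set p-values are permutation-based and hence granular
  at 1/(n_perm+1); with the default 1999 permutations the smallest
  attainable p is 5e−4.
* The toy core network is a caricature for validating machinery and
  directions of change; its absolute fluxes and yields are not calibrated
  to any organism.
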