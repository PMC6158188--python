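"""Synthetic inputs for every pipeline stage.

No omics dataset is bundled; instead this module generates inputs whose
ground truth is known by construction, at the scale and structure of a
fed-batch fungal fermentation with an abrupt oxygen-limitation switch
near 20 h:

* toy metabolic networks (``chain``, ``diamond``, ``core``) whose optima
  are computable by hand or exhaustive vertex enumeration — the ``core``
  variant lumps glucose phosphorylation, EMP glycolysis, the oxidative PP
  shunt, pyruvate dehydrogenase, an NADH-rich TCA lump, an NADH-poor
  glyoxylate bypass, anaplerosis, oxidative phosphorylation, a polyol
  redox valve, ATP maintenance, biomass and a glucoamylase drain whose
  amino-acid demand follows the enzyme's composition;
* a declarative fermentation scenario emitting per-time-point measured
  rates (with multiplicative Gaussian noise) plus the true growth and CO2
  evolution rates for closed-loop validation;
* metabolite pool tables with metabolites planted to track q_O2;
* expression matrices with planted temporal patterns, low-expression genes
  and gene sets of known directionality.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gem_model import MetabolicModel, Metabolite, Reaction
from .flux_sim import ExchangeMap, PhaseConstraints, solve_pfba

__all__ = [
    "GLUCOAMYLASE_AA_PERCENT",
    "ToyNetworkSpec",
    "FermentationScenario",
    "make_toy_model",
    "make_random_toy_model",
    "simulate_fermentation",
    "make_synthetic_pools",
    "make_synthetic_expression",
    "default_qo2_profile",
]

# Amino-acid composition of glucoamylase (percent content per residue).
GLUCOAMYLASE_AA_PERCENT = {
    "Ala": 10.17, "Cys": 1.56, "Asp": 6.89, "Glu": 3.91, "Phe": 3.44,
    "Gly": 7.20, "His": 0.63, "Ile": 3.76, "Lys": 2.03, "Leu": 7.51,
    "Met": 0.47, "Asn": 3.91, "Pro": 3.44, "Gln": 2.66, "Arg": 3.13,
    "Ser": 13.77, "Thr": 11.58, "Val": 6.57, "Trp": 3.13, "Tyr": 4.23,
}

# Precursor demand per mole of amino acid, in the core toy's lumped
# currency (g6p / pyr / accoa / oaa), by biosynthetic family.
_AA_PRECURSORS = {
    "Ala": {"pyr": 1}, "Val": {"pyr": 2}, "Leu": {"pyr": 2, "accoa": 1},
    "Ser": {"pyr": 1}, "Gly": {"pyr": 0.5}, "Cys": {"pyr": 1},
    "Asp": {"oaa": 1}, "Asn": {"oaa": 1}, "Thr": {"oaa": 1},
    "Met": {"oaa": 1}, "Lys": {"oaa": 1, "pyr": 1}, "Ile": {"oaa": 1, "pyr": 1},
    "Glu": {"oaa": 1, "accoa": 1}, "Gln": {"oaa": 1, "accoa": 1},
    "Arg": {"oaa": 1, "accoa": 1}, "Pro": {"oaa": 1, "accoa": 1},
    "His": {"g6p": 1},
    "Phe": {"g6p": 1, "pyr": 1}, "Tyr": {"g6p": 1, "pyr": 1},
    "Trp": {"g6p": 1, "pyr": 1},
}

_ATP_PER_RESIDUE = 4.3      # polymerization + activation cost
_NADPH_PER_RESIDUE = 1.5    # reductive biosynthesis cost


@dataclass
class ToyNetworkSpec:
    variant: str = "core"      # chain | diamond | core
    seed: int = 0


def _glaA_precursor_demand() -> dict:
    """Per-residue precursor stoichiometry of the glucoamylase drain,
    weighted by the enzyme's amino-acid composition."""
    total = sum(GLUCOAMYLASE_AA_PERCENT.values())
    demand = {"g6p": 0.0, "pyr": 0.0, "accoa": 0.0, "oaa": 0.0}
    for aa, pct in GLUCOAMYLASE_AA_PERCENT.items():
        frac = pct / total
        for prec, coef in _AA_PRECURSORS[aa].items():
            demand[prec] += frac * coef
    return demand


def make_toy_model(spec: ToyNetworkSpec | str = "core") -> MetabolicModel:
    """Construct a toy metabolic model.

    ``chain``: uptake -> conversion -> secretion; the FBA optimum equals
    the uptake capacity.  ``diamond``: two alternative routes of equal
    yield (2 vs 3 reactions) between source and sink — a degenerate
    optimal face for exercising parsimonious FBA.  ``core``: a 19-reaction
    lumped central-carbon network of an aerobic fungus with a glucoamylase
    product drain; oxygen limitation provably reroutes acetyl-CoA from the
    NADH-rich TCA lump to the NADH-poor glyoxylate bypass.
    """
    if isinstance(spec, str):
        spec = ToyNetworkSpec(variant=spec)
    if spec.variant == "chain":
        return _chain_model()
    if spec.variant == "diamond":
        return _diamond_model()
    if spec.variant == "core":
        return _core_model()
    raise ValueError(f"unknown toy variant {spec.variant!r}")


def _chain_model() -> MetabolicModel:
    mets = [Metabolite("A[c]", compartment="c"), Metabolite("B[c]", compartment="c")]
    rxns = [
        Reaction("UPT", {"A[c]": 1.0}, 0.0, 10.0, name="uptake"),
        Reaction("CONV", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 1000.0, name="conversion"),
        Reaction("SEC", {"B[c]": -1.0}, 0.0, 1000.0, name="secretion"),
    ]
    m = MetabolicModel(
        id="toy_chain", metabolites=mets, reactions=rxns,
        objective={"SEC": 1.0}, compartments={"c": "cytosol"},
    )
    m.validate()
    return m


def _diamond_model() -> MetabolicModel:
    mets = [
        Metabolite(x, compartment="c")
        for x in ("X[c]", "M[c]", "N1[c]", "N2[c]", "Y[c]")
    ]
    rxns = [
        Reaction("UPT", {"X[c]": 1.0}, 0.0, 10.0),
        # short path: 2 reactions
        Reaction("P1A", {"X[c]": -1.0, "M[c]": 1.0}, 0.0, 1000.0),
        Reaction("P1B", {"M[c]": -1.0, "Y[c]": 1.0}, 0.0, 1000.0),
        # long path of equal yield: 3 reactions
        Reaction("P2A", {"X[c]": -1.0, "N1[c]": 1.0}, 0.0, 1000.0),
        Reaction("P2B", {"N1[c]": -1.0, "N2[c]": 1.0}, 0.0, 1000.0),
        Reaction("P2C", {"N2[c]": -1.0, "Y[c]": 1.0}, 0.0, 1000.0),
        Reaction("SEC", {"Y[c]": -1.0}, 0.0, 1000.0),
    ]
    m = MetabolicModel(
        id="toy_diamond", metabolites=mets, reactions=rxns,
        objective={"SEC": 1.0}, compartments={"c": "cytosol"},
    )
    m.validate()
    return m


def _core_model() -> MetabolicModel:
    e, c = "e", "c"
    mets = [
        Metabolite("glc[e]", "glucose", e), Metabolite("o2[e]", "oxygen", e),
        Metabolite("co2[e]", "carbon dioxide", e),
        Metabolite("glaA[e]", "glucoamylase (residue basis)", e),
        Metabolite("succ[e]", "succinate (overflow C4)", e),
        Metabolite("gol[e]", "glycerol (polyol overflow)", e),
        Metabolite("g6p[c]", "hexose 6-phosphate pool", c),
        Metabolite("t3p[c]", "triose 3-phosphate pool", c),
        Metabolite("pyr[c]", "pyruvate", c),
        Metabolite("accoa[c]", "acetyl-CoA", c),
        Metabolite("oaa[c]", "oxaloacetate/C4 pool", c),
        Metabolite("nadh[c]", "NADH", c), Metabolite("nadph[c]", "NADPH", c),
        Metabolite("atp[c]", "ATP", c),
    ]
    gd = _glaA_precursor_demand()
    # biomass demand, mmol per gDCW: heavy hexose-phosphate drain (cell-wall
    # glucan), growth-associated ATP 35
    biomass = {
        "g6p[c]": -3.0, "pyr[c]": -2.0, "accoa[c]": -1.5, "oaa[c]": -1.5,
        "nadph[c]": -6.0, "atp[c]": -35.0,
    }
    glaa = {
        "g6p[c]": -gd["g6p"], "pyr[c]": -gd["pyr"], "accoa[c]": -gd["accoa"],
        "oaa[c]": -gd["oaa"], "nadph[c]": -_NADPH_PER_RESIDUE,
        "atp[c]": -_ATP_PER_RESIDUE, "glaA[e]": 1.0,
    }
    rxns = [
        Reaction("EX_glc", {"glc[e]": -1.0}, -10.0, 0.0, name="glucose exchange"),
        Reaction("EX_o2", {"o2[e]": -1.0}, -1000.0, 0.0, name="oxygen exchange"),
        Reaction("EX_co2", {"co2[e]": -1.0}, 0.0, 1000.0, name="CO2 exchange"),
        Reaction("EX_glaA", {"glaA[e]": -1.0}, 0.0, 1000.0, name="product exchange"),
        Reaction("EX_succ", {"succ[e]": -1.0}, 0.0, 1000.0, name="C4 overflow exchange"),
        Reaction("EX_gol", {"gol[e]": -1.0}, 0.0, 1000.0, name="polyol exchange"),
        Reaction(
            "HXK", {"glc[e]": -1.0, "atp[c]": -1.0, "g6p[c]": 1.0},
            0.0, 1000.0, name="uptake + phosphorylation", subsystem="EMP",
        ),
        Reaction(
            "EMP",
            {"g6p[c]": -1.0, "atp[c]": -1.0, "t3p[c]": 2.0},
            0.0, 1000.0, name="upper glycolysis lump (PFK + aldolase)",
            subsystem="EMP",
        ),
        Reaction(
            "EMP_LOWER",
            {"t3p[c]": -1.0, "pyr[c]": 1.0, "atp[c]": 2.0, "nadh[c]": 1.0},
            0.0, 1000.0, name="lower glycolysis lump (GAPDH..PK)",
            subsystem="EMP",
        ),
        Reaction(
            "PPP", {"g6p[c]": -1.0, "nadph[c]": 12.0, "co2[e]": 6.0},
            0.0, 1000.0, name="oxidative PP shunt (cyclic lump)", subsystem="PPP",
        ),
        Reaction(
            "PDH",
            {"pyr[c]": -1.0, "accoa[c]": 1.0, "co2[e]": 1.0, "nadh[c]": 1.0},
            0.0, 1000.0, name="pyruvate dehydrogenase", subsystem="TCA",
        ),
        Reaction(
            "TCA",
            {"accoa[c]": -1.0, "co2[e]": 2.0, "nadh[c]": 4.0, "atp[c]": 1.0},
            0.0, 1000.0, name="oxidative TCA lump", subsystem="TCA",
        ),
        Reaction(
            "GLX", {"accoa[c]": -2.0, "oaa[c]": 1.0, "nadh[c]": 1.0},
            0.0, 1000.0, name="glyoxylate bypass lump", subsystem="glyoxylate",
        ),
        Reaction(
            "PYC",
            {"pyr[c]": -1.0, "atp[c]": -1.0, "co2[e]": -1.0, "oaa[c]": 1.0},
            0.0, 1000.0, name="pyruvate carboxylase", subsystem="anaplerosis",
        ),
        Reaction(
            "OXPHOS", {"nadh[c]": -1.0, "o2[e]": -0.5, "atp[c]": 2.0},
            0.0, 1000.0, name="oxidative phosphorylation (P/O 2)",
            subsystem="oxidative phosphorylation",
        ),
        Reaction(
            "POLYOL", {"t3p[c]": -1.0, "nadh[c]": -1.0, "gol[e]": 1.0},
            0.0, 1000.0, name="polyol redox valve (G3P dehydrogenase lump)",
            subsystem="overflow",
        ),
        Reaction(
            "SUCT", {"oaa[c]": -1.0, "succ[e]": 1.0},
            0.0, 1000.0, name="C4 overflow secretion", subsystem="overflow",
        ),
        Reaction("ATPM", {"atp[c]": -1.0}, 0.0, 1000.0, name="ATP maintenance"),
        Reaction("BIOMASS", biomass, 0.0, 1000.0, name="biomass drain"),
        Reaction("GLAA_SYN", glaa, 0.0, 1000.0, name="glucoamylase synthesis"),
    ]
    m = MetabolicModel(
        id="toy_core",
        metabolites=mets,
        reactions=rxns,
        objective={"BIOMASS": 1.0},
        biomass_reaction_id="BIOMASS",
        atp_maintenance_reaction_id="ATPM",
        compartments={"c": "cytosol", "e": "extracellular"},
    )
    m.validate()
    return m


def make_random_toy_model(seed: int, n_metabolites: int = 3, n_reactions: int = 7
                          ) -> MetabolicModel:
    """Random small network with finite bounds (hence a bounded LP) and the
    zero flux vector always feasible — fodder for vertex-enumeration
    oracle checks."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, n_metabolites + 1))
    n = int(rng.integers(m + 2, n_reactions + 1))
    mets = [Metabolite(f"M{i}[c]", compartment="c") for i in range(m)]
    rxns = []
    for j in range(n):
        k = int(rng.integers(1, m + 1))
        rows = rng.choice(m, size=k, replace=False)
        coefs = rng.choice([-2, -1, 1, 2], size=k)
        stoich = {f"M{i}[c]": float(cf) for i, cf in zip(rows, coefs)}
        lb = float(rng.choice([-5.0, -2.0, 0.0]))
        ub = float(rng.choice([0.0, 2.0, 5.0]))
        if lb > ub:
            lb, ub = ub, lb
        rxns.append(Reaction(f"R{j}", stoich, lb, ub))
    c_idx = rng.choice(n, size=max(1, n // 3), replace=False)
    objective = {f"R{j}": float(rng.choice([-1.0, 1.0])) for j in c_idx}
    model = MetabolicModel(
        id=f"random_{seed}", metabolites=mets, reactions=rxns,
        objective=objective, compartments={"c": "cytosol"},
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Fermentation scenario
# ---------------------------------------------------------------------------

@dataclass
class FermentationScenario:
    """Declarative flux schedule for a fed-batch run.

    Before ``switch_time_h`` the culture is aerobic (oxygen capacity
    ``o2_cap_aerobic``); afterwards the oxygen supply collapses to
    ``o2_cap_limited``.  Glucose uptake is held constant (fed-batch at
    constant residual glucose), the glucoamylase drain rises after the
    switch (higher product yield under limitation), and the maintenance
    demand is constant.  Rates in mmol/gDCW/h.
    """

    time_grid_h: tuple = (8.0, 16.0, 24.0, 36.0, 48.0, 60.0, 72.0)
    switch_time_h: float = 20.0
    q_S: float = 1.0
    o2_cap_aerobic: float = 4.0
    o2_cap_limited: float = 0.8
    q_P_aerobic: float = 0.02
    q_P_limited: float = 0.03
    m_ATP: float = 1.0
    noise_sd: float = 0.0
    tolerance: float = 0.05
    seed: int = 0

    def o2_cap(self, t: float) -> float:
        return self.o2_cap_aerobic if t < self.switch_time_h else self.o2_cap_limited

    def q_P_at(self, t: float) -> float:
        return self.q_P_aerobic if t < self.switch_time_h else self.q_P_limited


class GenerationError(RuntimeError):
    """The scenario's declared rates admit no feasible flux distribution."""


def simulate_fermentation(
    model: MetabolicModel,
    scenario: FermentationScenario,
    exchange_map: ExchangeMap | None = None,
    byproduct_exchanges: Sequence[str] = ("EX_succ", "EX_gol"),
) -> dict:
    """Emit measured-rate rows plus ground truth per time point.

    Per time point the true flux vector is the parsimonious-FBA optimum of
    the toy model with glucose uptake and the product drain pinned at the
    scenario's schedule, oxygen capped, and maintenance fixed.  Measured
    q_S, q_O2, q_P, by-product rates and m_ATP are read off that vector
    and perturbed with multiplicative Gaussian noise ``(1 + sd*N(0,1))``;
    the unperturbed mu and q_CO2 are kept aside for validation.

    Returns ``{"phases": [PhaseConstraints...], "measured": {t: {"mu", "qCO2"}},
    "true_fluxes": {t: flux dict}}``.
    """
    emap = exchange_map or ExchangeMap()
    rng = np.random.default_rng(scenario.seed)
    phases, measured, true_fluxes = [], {}, {}
    for t in scenario.time_grid_h:
        work = model.copy()
        glc = work.get_reaction(emap.glucose)
        glc.lower_bound = glc.upper_bound = -scenario.q_S
        o2 = work.get_reaction(emap.o2)
        o2.lower_bound, o2.upper_bound = -scenario.o2_cap(t), 0.0
        prod = work.get_reaction(emap.product)
        prod.lower_bound = prod.upper_bound = scenario.q_P_at(t)
        if work.atp_maintenance_reaction_id:
            atpm = work.get_reaction(work.atp_maintenance_reaction_id)
            atpm.lower_bound = atpm.upper_bound = scenario.m_ATP
        sol = solve_pfba(work)
        if not sol.optimal:
            raise GenerationError(
                f"scenario infeasible at t={t} h (status {sol.status})"
            )
        v = sol.fluxes

        def noisy(x: float) -> float:
            return float(x * (1.0 + scenario.noise_sd * rng.standard_normal()))

        byp = {
            ex: noisy(v[ex]) for ex in byproduct_exchanges
            if abs(v.get(ex, 0.0)) > 1e-9
        }
        phases.append(
            PhaseConstraints(
                time_h=t,
                q_S=noisy(-v[emap.glucose]),
                q_O2=noisy(-v[emap.o2]),
                q_P=noisy(v[emap.product]),
                q_byproducts=byp,
                m_ATP=noisy(scenario.m_ATP),
                tolerance=scenario.tolerance,
            )
        )
        measured[t] = {
            "mu": v[model.biomass_reaction_id],
            "qCO2": v[emap.co2],
        }
        true_fluxes[t] = v
    return {"phases": phases, "measured": measured, "true_fluxes": true_fluxes}


# ---------------------------------------------------------------------------
# Pool-size tables
# ---------------------------------------------------------------------------

def default_qo2_profile(times_h: Sequence[float], switch_time_h: float = 20.0
                        ) -> np.ndarray:
    """Three-plateau specific oxygen uptake profile (mmol/gDCW/h): aerobic,
    early oxygen limitation, late oxygen limitation."""
    out = []
    for t in times_h:
        if t < switch_time_h:
            out.append(4.0)
        elif t < 60.0:
            out.append(1.2)
        else:
            out.append(0.3)
    return np.array(out)


def make_synthetic_pools(
    n_metab: int = 50,
    n_informative: int = 5,
    times_h: Sequence[float] = (18.0, 24.0, 36.0, 48.0, 60.0, 72.0, 96.0),
    n_replicates: int = 2,
    effect: float = 1.0,
    noise_sd: float = 0.1,
    switch_time_h: float = 20.0,
    seed: int = 0,
):
    """Metabolite pool table with planted q_O2-tracking metabolites.

    Informative metabolites are log-linear in the standardized q_O2
    profile with slope ``effect`` (alternating sign, so some pools decay
    and some accumulate under limitation); the rest are lognormal noise
    around a constant baseline.  Noise is multiplicative lognormal with
    log-sd ``noise_sd``.  Returns ``(MetabolitePoolTable, truth)`` where
    truth holds the informative ids, the per-sample q_O2 and the
    three-plateau phase labels.
    """
    from .metabolomics_stats import MetabolitePoolTable

    if n_informative > n_metab:
        raise ValueError("n_informative exceeds n_metab")
    rng = np.random.default_rng(seed)
    qo2_t = default_qo2_profile(times_h, switch_time_h)
    z = (qo2_t - qo2_t.mean()) / qo2_t.std()
    sample_ids, time_col, rep_col, zs, qs = [], [], [], [], []
    for t, zt, qt in zip(times_h, z, qo2_t):
        for r in range(1, n_replicates + 1):
            sample_ids.append(f"t{t:g}_r{r}")
            time_col.append(t)
            rep_col.append(r)
            zs.append(zt)
            qs.append(qt)
    zs = np.array(zs)
    n_samples = len(sample_ids)

    mids = [f"met{i+1:03d}" for i in range(n_metab)]
    informative = mids[:n_informative]
    base = rng.uniform(np.log(0.05), np.log(20.0), size=n_metab)  # umol/gDCW
    log_vals = np.empty((n_metab, n_samples))
    for i in range(n_metab):
        if i < n_informative:
            sign = 1.0 if i % 2 == 0 else -1.0
            log_vals[i] = base[i] + sign * effect * zs
        else:
            log_vals[i] = base[i]
    log_vals += noise_sd * rng.standard_normal(log_vals.shape)
    values = pd.DataFrame(np.exp(log_vals), index=mids, columns=sample_ids)
    samples = pd.DataFrame(
        {"time_h": time_col, "replicate": rep_col}, index=sample_ids
    )
    table = MetabolitePoolTable(values=values, samples=samples)
    group = np.where(
        np.array(time_col) < switch_time_h, "aerobic",
        np.where(np.array(time_col) < 60.0, "early_limited", "late_limited"),
    )
    truth = {
        "informative": informative,
        "q_O2": dict(zip(sample_ids, qs)),
        "sample_group": dict(zip(sample_ids, group)),
        "effect": effect,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

DEFAULT_PATTERNS = {
    # standardized log2 shapes over the four sampling times
    "up": (-1.2, -0.4, 0.4, 1.2),
    "down": (1.2, 0.4, -0.4, -1.2),
    "transient": (-0.6, 1.5, -0.3, -0.6),
    "flat": (0.0, 0.0, 0.0, 0.0),
}


def make_synthetic_expression(
    n_genes_per_pattern: int = 50,
    patterns: Mapping[str, Sequence[float]] | None = None,
    times_h: Sequence[float] = (16.0, 24.0, 42.0, 66.0),
    n_replicates: int = 2,
    amplitude: float = 1.5,
    noise_sd: float = 0.2,
    n_low: int = 10,
    set_size: int = 20,
    seed: int = 0,
):
    """Expression matrix with planted temporal patterns and gene sets.

    Genes follow ``FPKM = 2^(base + amplitude*pattern(t) + eps)`` with
    ``eps ~ N(0, noise_sd)`` (lognormal noise, non-negative values).
    ``n_low`` extra genes sit below FPKM 1 at two time points to exercise
    the low-expression filter.  Planted gene sets: ``set_all_up`` (up
    genes), ``set_all_down`` (down), ``set_mixed`` (half up, half down),
    ``set_null`` (flat genes).  Phases: the first time point is labelled
    ``aerobic``, the rest ``limited``.

    Returns ``(ExpressionMatrix, sets, truth)``.
    """
    from .transcript_stats import ExpressionMatrix

    patterns = dict(patterns or DEFAULT_PATTERNS)
    D = len(times_h)
    for name, shape in patterns.items():
        if len(shape) != D:
            raise ValueError(f"pattern {name!r} has {len(shape)} values, need {D}")
    rng = np.random.default_rng(seed)

    sample_ids, time_col, rep_col, phase_col = [], [], [], []
    for t in times_h:
        for r in range(1, n_replicates + 1):
            sample_ids.append(f"t{t:g}_r{r}")
            time_col.append(t)
            rep_col.append(r)
            phase_col.append("aerobic" if t == times_h[0] else "limited")

    gene_ids, rows, pattern_of = [], [], {}
    for name, shape in patterns.items():
        shape = np.asarray(shape, dtype=float)
        for i in range(n_genes_per_pattern):
            gid = f"{name}_{i+1:03d}"
            base = rng.normal(5.0, 1.0)
            log2_tp = base + amplitude * shape
            log2_vals = np.repeat(log2_tp, n_replicates)
            log2_vals = log2_vals + noise_sd * rng.standard_normal(len(sample_ids))
            gene_ids.append(gid)
            rows.append(2.0 ** log2_vals)
            pattern_of[gid] = name
    low_ids = []
    for i in range(n_low):
        gid = f"low_{i+1:03d}"
        # below threshold at the first two time points, expressed later
        log2_tp = np.full(D, 3.0)
        log2_tp[:2] = -4.0
        log2_vals = np.repeat(log2_tp, n_replicates)
        log2_vals = log2_vals + noise_sd * rng.standard_normal(len(sample_ids))
        gene_ids.append(gid)
        rows.append(2.0 ** log2_vals)
        pattern_of[gid] = "low"
        low_ids.append(gid)

    values = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {"time_h": time_col, "replicate": rep_col, "phase": phase_col},
        index=sample_ids,
    )
    mat = ExpressionMatrix(values=values, samples=samples)

    def pick(pattern: str, k: int, offset: int = 0) -> list:
        pool = [g for g in gene_ids if pattern_of[g] == pattern]
        return pool[offset:offset + k]

    half = set_size // 2
    sets = {
        "set_all_up": pick("up", set_size),
        "set_all_down": pick("down", set_size),
        "set_mixed": pick("up", half, offset=set_size)
        + pick("down", half, offset=set_size),
        "set_null": pick("flat", set_size),
    }
    truth = {
        "pattern_of": pattern_of,
        "low_genes": low_ids,
        "n_patterns": len(patterns),
        "times_h": tuple(times_h),
    }
    return mat, sets, truth
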