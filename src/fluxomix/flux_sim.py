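"""Flux balance analysis and parsimonious FBA over a metabolic model.

The core problem is the linear program

    max/min  Z = c' v
    s.t.     S v = 0          (intracellular steady state)
             lb <= v <= ub    (reversibility, capacity, measured rates)

solved per fermentation phase with measured biomass-specific rates (q_S,
q_O2, q_P, by-product secretion, ATP maintenance) imposed as bound
intervals on the corresponding exchange reactions.  Parsimonious FBA keeps
the optimal objective fixed and minimizes the total absolute flux,
selecting the enzymatically economical flux distribution among the optima.

Sign convention: exchange fluxes are negative for uptake and positive for
secretion; measured uptake rates are supplied as positive magnitudes and
negated internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .gem_model import MetabolicModel, build_stoichiometric_matrix

__all__ = [
    "FBASolution",
    "PhaseConstraints",
    "ExchangeMap",
    "PhaseSimulationResult",
    "solve_fba",
    "solve_pfba",
    "apply_phase_constraints",
    "simulate_phases",
    "compute_relative_flux",
    "validate_predictions",
    "flux_variability",
    "ConstraintConfigurationError",
]

_LINPROG_OPTIONS = {"presolve": True}


class ConstraintConfigurationError(ValueError):
    """A measured rate refers to a reaction the model does not contain."""


@dataclass
class FBASolution:
    status: str                    # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict                   # reaction id -> rate, mmol/gDCW/h
    total_absolute_flux: float | None = None  # pFBA only

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class ExchangeMap:
    """Which model reactions carry the measured rates."""

    glucose: str = "EX_glc"
    o2: str = "EX_o2"
    co2: str = "EX_co2"
    product: str = "EX_glaA"


@dataclass
class PhaseConstraints:
    """Measured biomass-specific rates for one fermentation snapshot.

    Uptake rates (``q_S``, ``q_O2``) are positive magnitudes; secretion
    rates (``q_P``, by-products) positive as well.  ``tolerance`` is the
    relative half-width of the bound interval each rate is allowed to move
    within (0 gives equality constraints).
    """

    time_h: float
    q_S: float                 # glucose uptake, mmol/gDCW/h
    q_O2: float                # oxygen uptake, mmol/gDCW/h
    q_P: float = 0.0           # product secretion, mmol/gDCW/h
    q_byproducts: dict = field(default_factory=dict)  # exchange id -> rate
    m_ATP: float = 0.0         # maintenance, mmol ATP/gDCW/h
    tolerance: float = 0.05

    def __post_init__(self):
        if self.time_h < 0:
            raise ValueError("time_h must be non-negative")
        if not (0 <= self.tolerance < 1):
            raise ValueError("tolerance must lie in [0, 1)")
        for label, q in (("q_S", self.q_S), ("q_O2", self.q_O2)):
            if q < 0:
                raise ValueError(f"{label} is an uptake magnitude and must be >= 0")


@dataclass
class PhaseSimulationResult:
    constraints: PhaseConstraints
    solution: FBASolution
    mu_predicted: float | None            # 1/h, biomass reaction flux
    qCO2_predicted: float | None          # mmol/gDCW/h, CO2 exchange flux
    relative_fluxes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------

def _lp_arrays(model: MetabolicModel):
    smat = build_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    c = np.zeros(len(model.reactions))
    for i, r in enumerate(model.reactions):
        if r.id in model.objective:
            c[i] = model.objective[r.id]
    return smat, lb, ub, c


def _status_name(status_code: int) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(
        status_code, "infeasible"
    )


def solve_fba(model: MetabolicModel, sense: str = "max") -> FBASolution:
    """Solve max/min c'v subject to S v = 0 and lb <= v <= ub.

    The objective value is deterministic; with degenerate optima the flux
    vector is one optimal basic solution.
    """
    if not model.objective:
        raise ValueError("model objective is empty")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    smat, lb, ub, c = _lp_arrays(model)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=smat.values,
        b_eq=np.zeros(smat.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options=_LINPROG_OPTIONS,
    )
    status = _status_name(res.status)
    if status != "optimal":
        return FBASolution(status=status, objective_value=None, fluxes={})
    fluxes = dict(zip(smat.col_index, res.x))
    return FBASolution(
        status="optimal", objective_value=float(c @ res.x), fluxes=fluxes
    )


def solve_pfba(model: MetabolicModel, sense: str = "max") -> FBASolution:
    """Two-stage parsimonious FBA.

    Stage 1 finds the FBA optimum Z*; stage 2 splits every reaction into
    non-negative forward/backward halves, pins c'v to Z* and minimizes the
    total flux sum.  The returned ``total_absolute_flux`` is the minimal
    sum of |v| over the optimal face.
    """
    stage1 = solve_fba(model, sense=sense)
    if not stage1.optimal:
        return stage1
    z_star = stage1.objective_value

    smat, lb, ub, c = _lp_arrays(model)
    n = len(lb)
    # split v = f - b, f in [max(lb,0), max(ub,0)], b in [max(-ub,0), max(-lb,0)]
    f_lo, f_hi = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    b_lo, b_hi = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    S = smat.values
    A_eq = sparse.hstack([S, -S], format="csc")
    b_eq = np.zeros(S.shape[0])
    # pin the objective with a small absolute slack scaled to |Z*|
    slack = 1e-9 * max(1.0, abs(z_star))
    obj_row = sparse.csr_matrix(np.concatenate([c, -c])[None, :])
    A_ub = sparse.vstack([obj_row, -obj_row], format="csc")
    b_ub = np.array([z_star + slack, -(z_star - slack)])
    cost = np.ones(2 * n)
    res = linprog(
        cost,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(np.concatenate([f_lo, b_lo]), np.concatenate([f_hi, b_hi]))),
        method="highs",
        options=_LINPROG_OPTIONS,
    )
    if res.status != 0:
        raise RuntimeError(
            f"pFBA stage 2 unexpectedly {_status_name(res.status)} "
            f"(stage 1 was optimal; this indicates a numerical failure)"
        )
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(smat.col_index, v))
    return FBASolution(
        status="optimal",
        objective_value=float(c @ v),
        fluxes=fluxes,
        total_absolute_flux=float(res.fun),
    )


def flux_variability(
    model: MetabolicModel, fraction_of_optimum: float = 1.0
) -> dict:
    """Optimal-face width per reaction: min and max of each flux with the
    objective held at ``fraction_of_optimum`` times its optimum.

    Diagnostic for degeneracy — a reaction with a wide range is not pinned
    down by the optimum and its pFBA value should be read with care.
    """
    stage1 = solve_fba(model, sense="max")
    if not stage1.optimal:
        raise RuntimeError(f"FVA requires an optimal base solve, got {stage1.status}")
    z_star = stage1.objective_value
    smat, lb, ub, c = _lp_arrays(model)
    obj_row = sparse.csr_matrix(c[None, :])
    bound = fraction_of_optimum * z_star
    A_ub = -obj_row  # c'v >= bound
    b_ub = np.array([-bound + 1e-9 * max(1.0, abs(bound))])
    out = {}
    for j, rid in enumerate(smat.col_index):
        e = np.zeros(len(lb))
        e[j] = 1.0
        lohi = []
        for sgn in (1.0, -1.0):
            res = linprog(
                sgn * e,
                A_eq=smat.values,
                b_eq=np.zeros(smat.shape[0]),
                A_ub=A_ub,
                b_ub=b_ub,
                bounds=list(zip(lb, ub)),
                method="highs",
                options=_LINPROG_OPTIONS,
            )
            lohi.append(sgn * res.fun if res.status == 0 else np.nan)
        out[rid] = (lohi[0], lohi[1])
    return out


# ---------------------------------------------------------------------------
# Measured-rate constraints
# ---------------------------------------------------------------------------

def _band(value: float, tol: float) -> tuple:
    lo, hi = value * (1 - tol), value * (1 + tol)
    return (min(lo, hi), max(lo, hi))


def apply_phase_constraints(
    model: MetabolicModel,
    pc: PhaseConstraints,
    exchange_map: ExchangeMap | None = None,
) -> MetabolicModel:
    """Return a copy of the model with measured rates imposed as bounds.

    Glucose and O2 exchange get ``[-q(1+tol), -q(1-tol)]`` (uptake-negative
    convention); the product and each by-product exchange get
    ``[q(1-tol), q(1+tol)]``; the ATP maintenance flux is confined to
    ``[m_ATP(1-tol), m_ATP(1+tol)]``.  All other bounds are untouched.
    """
    emap = exchange_map or ExchangeMap()
    out = model.copy()
    rxn_ids = set(out.reaction_ids())
    tol = pc.tolerance

    assignments = {
        emap.glucose: ("q_S", _band(-pc.q_S, tol)),
        emap.o2: ("q_O2", _band(-pc.q_O2, tol)),
        emap.product: ("q_P", _band(pc.q_P, tol)),
    }
    for ex_id, rate in pc.q_byproducts.items():
        assignments[ex_id] = (f"by-product {ex_id}", _band(rate, tol))
    atpm = out.atp_maintenance_reaction_id
    if pc.m_ATP:
        if atpm is None:
            raise ConstraintConfigurationError(
                "m_ATP given but the model declares no ATP maintenance reaction"
            )
        assignments[atpm] = ("m_ATP", _band(pc.m_ATP, tol))

    for rid, (label, (lo, hi)) in assignments.items():
        if rid not in rxn_ids:
            raise ConstraintConfigurationError(
                f"rate {label} maps to reaction {rid!r}, absent from the model"
            )
        rxn = out.get_reaction(rid)
        rxn.lower_bound, rxn.upper_bound = lo, hi
    return out


def simulate_phases(
    model: MetabolicModel,
    phases: Sequence[PhaseConstraints],
    exchange_map: ExchangeMap | None = None,
    pfba: bool = True,
) -> list:
    """Snapshot simulation of each fermentation phase independently.

    Per phase: impose the measured rates, maximize growth (pFBA by
    default), and record the predicted specific growth rate, CO2 evolution
    rate and the fluxes relative to glucose uptake.  Infeasible phases are
    reported without aborting the batch.
    """
    emap = exchange_map or ExchangeMap()
    results = []
    for pc in phases:
        constrained = apply_phase_constraints(model, pc, emap)
        sol = solve_pfba(constrained) if pfba else solve_fba(constrained)
        if sol.optimal:
            mu = sol.fluxes.get(model.biomass_reaction_id)
            qco2 = sol.fluxes.get(emap.co2)
            try:
                rel = compute_relative_flux(sol, emap.glucose)
            except ValueError:
                rel = {}
        else:
            mu, qco2, rel = None, None, {}
        results.append(
            PhaseSimulationResult(
                constraints=pc,
                solution=sol,
                mu_predicted=mu,
                qCO2_predicted=qco2,
                relative_fluxes=rel,
            )
        )
    return results


def compute_relative_flux(
    sol: FBASolution, reference_reaction: str, min_reference: float = 1e-9
) -> dict:
    """Fluxes as mol per 100 mol of the reference flux (typically glucose
    uptake); the reference itself maps to +/-100."""
    if reference_reaction not in sol.fluxes:
        raise KeyError(reference_reaction)
    ref = abs(sol.fluxes[reference_reaction])
    if ref <= min_reference:
        raise ValueError(
            f"reference flux |v({reference_reaction})| = {ref:g} is near zero; "
            "report absolute fluxes instead"
        )
    return {rid: 100.0 * v / ref for rid, v in sol.fluxes.items()}


def validate_predictions(
    results: Sequence[PhaseSimulationResult],
    measured: Mapping[float, Mapping[str, float]],
) -> dict:
    """Compare predicted mu and q_CO2 against measured values per phase.

    ``measured`` maps time_h -> {"mu": ..., "qCO2": ...}.  Returns per-phase
    absolute/relative errors and a summary with the mean relative error per
    quantity.  CO2 secretion magnitude is compared (predicted exchange flux
    is positive for evolution under the secretion-positive convention).
    """
    result_times = [r.constraints.time_h for r in results]
    missing = sorted(set(measured) - set(result_times))
    extra = sorted(set(result_times) - set(measured))
    if missing or extra:
        raise KeyError(
            f"phase mismatch: measured-only times {missing}, "
            f"predicted-only times {extra}"
        )
    per_phase = {}
    rel_mu, rel_qco2 = [], []
    for r in results:
        t = r.constraints.time_h
        entry = {"status": r.solution.status}
        if r.solution.optimal:
            for key, pred in (("mu", r.mu_predicted), ("qCO2", abs(r.qCO2_predicted))):
                meas = measured[t][key]
                abs_err = abs(pred - meas)
                rel_err = abs_err / abs(meas) if meas != 0 else (
                    0.0 if abs_err == 0 else float("inf")
                )
                entry[f"{key}_predicted"] = pred
                entry[f"{key}_measured"] = meas
                entry[f"{key}_abs_error"] = abs_err
                entry[f"{key}_rel_error"] = rel_err
            rel_mu.append(entry["mu_rel_error"])
            rel_qco2.append(entry["qCO2_rel_error"])
        per_phase[t] = entry
    summary = {
        "n_phases": len(results),
        "n_optimal": sum(1 for r in results if r.solution.optimal),
        "mean_rel_error_mu": float(np.mean(rel_mu)) if rel_mu else float("nan"),
        "mean_rel_error_qCO2": float(np.mean(rel_qco2)) if rel_qco2 else float("nan"),
    }
    return {"per_phase": per_phase, "summary": summary}
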