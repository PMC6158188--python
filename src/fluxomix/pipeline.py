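"""Orchestration of the full analysis: flux simulation, metabolomics and
transcriptomics stages over one configuration, with a provenance manifest.

Stages are independent: the flux stage reads a metabolic model and a phase
table; the metabolomics stage a pool table; the transcriptomics stage an
expression matrix, sample sheet and GMT gene sets.  The "integration" is a
join on fermentation phase in the final summary, mirroring how flux
shifts, responsive metabolites and enriched gene sets are read side by
side.  All randomness is seeded through the config, so rerunning an
identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gem_model import read_model
from .flux_sim import (
    ExchangeMap,
    PhaseConstraints,
    simulate_phases,
    validate_predictions,
)
from .metabolomics_stats import (
    MetabolitePoolTable,
    read_pool_table,
    preprocess_pools,
    run_pca,
    fit_pls,
    compute_vip,
    heatmap_order,
)
from .transcript_stats import (
    ExpressionMatrix,
    filter_low_expression,
    standardize_profiles,
    estimate_fuzzifier,
    fuzzy_cmeans,
    differential_stats,
    gene_set_analysis,
    read_gmt,
)

logger = logging.getLogger("fluxomix")

__all__ = ["RunConfig", "run_pipeline", "load_config", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "fluxomix_out"
    # stage toggles
    run_flux: bool = True
    run_metabolome: bool = True
    run_transcriptome: bool = True
    # inputs
    model_path: str | None = None
    model_format: str | None = None
    phases_path: str | None = None
    measured_path: str | None = None          # optional mu/qCO2 per phase
    pools_path: str | None = None
    expression_path: str | None = None
    samples_path: str | None = None
    gmt_path: str | None = None
    qo2_column: str = "q_O2"
    # exchange mapping
    glucose_exchange: str = "EX_glc"
    o2_exchange: str = "EX_o2"
    co2_exchange: str = "EX_co2"
    product_exchange: str = "EX_glaA"
    # knobs
    tolerance: float = 0.05
    pfba: bool = True
    transform: str = "none"
    scale: str = "autoscale"
    n_pls_components: int = 2
    vip_threshold: float = 1.0
    fpkm_threshold: float = 1.0
    min_low_timepoints: int = 2
    k_clusters: int = 20
    fuzzifier: float | None = None
    phase_a: str = "aerobic"
    phase_b: str = "limited"
    n_perm: int = 1999
    seed: int = 7

    def validate(self) -> None:
        checks = []
        if self.run_flux:
            checks += [("model_path", self.model_path), ("phases_path", self.phases_path)]
        if self.run_metabolome:
            checks += [("pools_path", self.pools_path)]
        if self.run_transcriptome:
            checks += [
                ("expression_path", self.expression_path),
                ("samples_path", self.samples_path),
                ("gmt_path", self.gmt_path),
            ]
        missing = [name for name, p in checks if p is None]
        if missing:
            raise PipelineError(f"config lacks required paths: {missing}")
        absent = [p for _, p in checks if p is not None and not Path(p).exists()]
        if absent:
            raise PipelineError(f"input paths do not exist: {absent}")


def load_config(path) -> RunConfig:
    """Read a YAML/JSON config file into a RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise PipelineError(f"unknown config keys: {unknown}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def read_phase_table(path, tolerance: float) -> list:
    """Phase table TSV: time_h, q_S, q_O2, q_P, m_ATP, then one column per
    by-product exchange id."""
    df = pd.read_csv(path, sep="\t")
    fixed = {"time_h", "q_S", "q_O2", "q_P", "m_ATP", "tolerance"}
    byp_cols = [c for c in df.columns if c not in fixed]
    phases = []
    for _, row in df.iterrows():
        phases.append(
            PhaseConstraints(
                time_h=float(row["time_h"]),
                q_S=float(row["q_S"]),
                q_O2=float(row["q_O2"]),
                q_P=float(row.get("q_P", 0.0)),
                q_byproducts={
                    c: float(row[c]) for c in byp_cols if pd.notna(row[c])
                },
                m_ATP=float(row.get("m_ATP", 0.0)),
                tolerance=float(row["tolerance"]) if "tolerance" in df.columns
                else tolerance,
            )
        )
    return phases


def write_phase_table(phases, path) -> None:
    byp_ids = sorted({ex for pc in phases for ex in pc.q_byproducts})
    rows = []
    for pc in phases:
        row = {
            "time_h": pc.time_h, "q_S": pc.q_S, "q_O2": pc.q_O2,
            "q_P": pc.q_P, "m_ATP": pc.m_ATP, "tolerance": pc.tolerance,
        }
        for ex in byp_ids:
            row[ex] = pc.q_byproducts.get(ex, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _stage_flux(cfg: RunConfig, out: Path) -> dict:
    model = read_model(cfg.model_path, format=cfg.model_format)
    phases = read_phase_table(cfg.phases_path, cfg.tolerance)
    emap = ExchangeMap(
        glucose=cfg.glucose_exchange, o2=cfg.o2_exchange,
        co2=cfg.co2_exchange, product=cfg.product_exchange,
    )
    results = simulate_phases(model, phases, emap, pfba=cfg.pfba)
    rows = []
    for r in results:
        for rid in (r.solution.fluxes or {}):
            rows.append(
                {
                    "time_h": r.constraints.time_h,
                    "reaction": rid,
                    "flux": r.solution.fluxes[rid],
                    "relative_flux": r.relative_fluxes.get(rid, np.nan),
                }
            )
    pd.DataFrame(rows).to_csv(out / "fluxes.tsv", sep="\t", index=False)
    summary = {
        "phases": [
            {
                "time_h": r.constraints.time_h,
                "status": r.solution.status,
                "mu_predicted": r.mu_predicted,
                "qCO2_predicted": r.qCO2_predicted,
                "objective_value": r.solution.objective_value,
                "total_absolute_flux": r.solution.total_absolute_flux,
            }
            for r in results
        ]
    }
    if cfg.measured_path:
        meas_df = pd.read_csv(cfg.measured_path, sep="\t")
        measured = {
            float(row["time_h"]): {"mu": float(row["mu"]), "qCO2": float(row["qCO2"])}
            for _, row in meas_df.iterrows()
        }
        summary["validation"] = validate_predictions(results, measured)["summary"]
    with open(out / "flux_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    mu_by_phase = {
        r.constraints.time_h: r.mu_predicted for r in results if r.solution.optimal
    }
    rel_by_phase = {r.constraints.time_h: r.relative_fluxes for r in results}
    return {"mu": mu_by_phase, "relative_fluxes": rel_by_phase}


def _stage_metabolome(cfg: RunConfig, out: Path) -> dict:
    table = read_pool_table(cfg.pools_path)
    prep = preprocess_pools(table, transform=cfg.transform, scale=cfg.scale)
    pca = run_pca(prep)
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    # response: q_O2 per sample — from the sample sheet column when
    # present, otherwise interpolated over time from the phase table
    if cfg.qo2_column in prep.samples.columns:
        y = prep.samples[cfg.qo2_column].to_numpy(dtype=float)
    elif cfg.phases_path and Path(cfg.phases_path).exists():
        ph = pd.read_csv(cfg.phases_path, sep="\t").sort_values("time_h")
        y = np.interp(prep.time_h, ph["time_h"], ph[cfg.qo2_column])
    else:
        raise PipelineError(
            f"no {cfg.qo2_column!r} per sample: provide it in the pool sample "
            "sheet or supply a phase table to interpolate from"
        )
    pls = fit_pls(prep, y, n_components=cfg.n_pls_components)
    vip = compute_vip(pls, threshold=cfg.vip_threshold)
    vip_df = pd.DataFrame({"VIP": vip.vip, "selected": vip.selected})
    vip_df.sort_values("VIP", ascending=False).to_csv(out / "vip.tsv", sep="\t")
    order = heatmap_order(prep)
    with open(out / "heatmap_order.json", "w") as fh:
        json.dump(order, fh, indent=2)
    return {
        "n_metabolites": prep.values.shape[0],
        "n_vip_selected": vip.n_selected,
        "vip_selected": sorted(vip.vip[vip.selected].index),
        "explained_variance_pc1": float(pca.explained_variance_fraction[0]),
    }


def _stage_transcriptome(cfg: RunConfig, out: Path) -> dict:
    values = pd.read_csv(cfg.expression_path, sep="\t", index_col=0)
    samples = pd.read_csv(cfg.samples_path, sep="\t", index_col=0)
    mat = ExpressionMatrix(values=values, samples=samples.loc[values.columns])
    filtered = filter_low_expression(
        mat, fpkm_threshold=cfg.fpkm_threshold,
        min_low_timepoints=cfg.min_low_timepoints,
    )
    profiles = standardize_profiles(filtered)
    m = cfg.fuzzifier or estimate_fuzzifier(profiles)
    k = min(cfg.k_clusters, len(profiles) - 1)
    clustering = fuzzy_cmeans(profiles, k=k, m=m, seed=cfg.seed)
    clustering.memberships.round(6).to_csv(out / "cluster_memberships.tsv", sep="\t")
    clustering.assignment().to_csv(out / "cluster_assignment.tsv", sep="\t")
    stats = differential_stats(filtered, cfg.phase_a, cfg.phase_b)
    stats.table.round(8).to_csv(out / "gene_stats.tsv", sep="\t")
    sets = read_gmt(cfg.gmt_path)
    gsa = gene_set_analysis(stats, sets, n_perm=cfg.n_perm, seed=cfg.seed)
    gsa.table.round(8).to_csv(out / "gsa.tsv", sep="\t")
    return {
        "n_genes_input": mat.values.shape[0],
        "n_genes_kept": filtered.values.shape[0],
        "k": k,
        "fuzzifier": float(m),
        "converged": clustering.converged,
        "n_sets": len(gsa.table),
        "gsa_skipped": gsa.skipped,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages in order; write per-stage outputs, an
    integrative summary and a JSON manifest (config echo, seeds, package
    version, output hashes).  A stage failure is logged, dependent outputs
    are skipped, and partial outputs are preserved; the manifest records
    per-stage status."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.random.seed(cfg.seed % (2**32))
    stage_status: dict = {}
    stage_summaries: dict = {}
    runners = [
        ("flux", cfg.run_flux, _stage_flux),
        ("metabolome", cfg.run_metabolome, _stage_metabolome),
        ("transcriptome", cfg.run_transcriptome, _stage_transcriptome),
    ]
    failed = False
    for name, enabled, runner in runners:
        if not enabled:
            stage_status[name] = "disabled"
            continue
        try:
            logger.info("running stage %s", name)
            stage_summaries[name] = runner(cfg, out)
            stage_status[name] = "ok"
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.error("stage %s failed: %s", name, exc)
            stage_status[name] = f"failed: {exc}"
            failed = True

    # integrative summary: per-phase relative fluxes of headline pathways
    # alongside VIP metabolites and significant gene sets
    integ: dict = {"stages": stage_status}
    flux = stage_summaries.get("flux")
    if flux:
        integ["mu_by_phase"] = flux["mu"]
    if "metabolome" in stage_summaries:
        integ["vip_selected"] = stage_summaries["metabolome"]["vip_selected"]
    if "transcriptome" in stage_summaries:
        integ["transcriptome"] = {
            k: v for k, v in stage_summaries["transcriptome"].items()
            if k != "gsa_skipped"
        }
    with open(out / "integrative_summary.json", "w") as fh:
        json.dump(integ, fh, indent=2, sort_keys=True, default=str)

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "stages": stage_status,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if failed:
        raise PipelineError(
            "one or more stages failed: "
            + ", ".join(f"{k}={v}" for k, v in stage_status.items())
        )
    return {"status": stage_status, "summaries": stage_summaries, "out_dir": str(out)}
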