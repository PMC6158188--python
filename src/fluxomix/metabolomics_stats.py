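"""Statistics for intracellular metabolite pool-size tables.

A pool table holds metabolite concentrations (umol/gDCW) over fermentation
samples (time points x replicates).  The screening logic is: preprocess
(impute, transform, scale per metabolite), inspect sample structure by PCA,
regress pools on the specific oxygen uptake rate q_O2 by single-response
PLS (NIPALS), and flag metabolites whose variable importance in projection
(VIP) exceeds 1 as responsive to the oxygen shift.  The VIP of variable j
over A components with weights w_a and explained response sums of squares
SS_a is

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )

so that the mean of VIP^2 over the p variables is exactly 1; VIP > 1 marks
above-average influence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "MetabolitePoolTable",
    "PcaResult",
    "PlsModel",
    "VipResult",
    "preprocess_pools",
    "run_pca",
    "fit_pls",
    "fit_pls_da",
    "compute_vip",
    "choose_n_components",
    "heatmap_order",
    "read_pool_table",
    "write_pool_table",
]


@dataclass
class MetabolitePoolTable:
    """Metabolites x samples matrix with per-sample time/replicate labels."""

    values: pd.DataFrame               # index: metabolite ids, columns: sample ids
    samples: pd.DataFrame              # index: sample ids; columns time_h, replicate
    dropped: list = field(default_factory=list)  # metabolites removed upstream

    def __post_init__(self):
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample annotations do not match value columns")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 samples")
        if "time_h" not in self.samples.columns:
            raise ValueError("samples need a time_h annotation")

    @property
    def metabolite_ids(self) -> list:
        return list(self.values.index)

    @property
    def time_h(self) -> np.ndarray:
        return self.samples["time_h"].to_numpy(dtype=float)


def read_pool_table(path) -> MetabolitePoolTable:
    """Read the TSV layout with a two-row header (time_h, replicate)."""
    raw = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    samples = pd.DataFrame(
        {
            "time_h": [float(t) for t, _ in raw.columns],
            "replicate": [r for _, r in raw.columns],
        },
        index=[f"t{t}_r{r}" for t, r in raw.columns],
    )
    values = raw.copy()
    values.columns = samples.index
    return MetabolitePoolTable(values=values, samples=samples)


def write_pool_table(table: MetabolitePoolTable, path) -> None:
    out = table.values.copy()
    out.columns = pd.MultiIndex.from_arrays(
        [table.samples["time_h"].astype(str), table.samples["replicate"].astype(str)],
        names=["time_h", "replicate"],
    )
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_pools(
    table: MetabolitePoolTable,
    transform: str = "none",
    scale: str = "autoscale",
) -> MetabolitePoolTable:
    """Impute, optionally log-transform, center and scale per metabolite.

    Missing cells are imputed with half the metabolite's minimum observed
    value (a common limit-of-detection convention).  ``scale`` is
    ``autoscale`` (unit variance) or ``pareto`` (sqrt of the sd).
    Constant metabolites cannot be autoscaled and are dropped; their ids
    are recorded on the returned table.
    """
    if transform not in ("none", "log"):
        raise ValueError("transform must be 'none' or 'log'")
    if scale not in ("autoscale", "pareto"):
        raise ValueError("scale must be 'autoscale' or 'pareto'")
    values = table.values.astype(float).copy()
    missing_frac = values.isna().mean(axis=1)
    too_missing = missing_frac[missing_frac >= 0.5]
    if len(too_missing):
        raise ValueError(
            f"metabolites with >=50% missing values: {sorted(too_missing.index)}"
        )
    for mid in values.index[values.isna().any(axis=1)]:
        row = values.loc[mid]
        values.loc[mid] = row.fillna(row.min() / 2.0)
    if transform == "log":
        if (values <= 0).any().any():
            raise ValueError("log transform requires strictly positive pools")
        values = np.log(values)
    sd = values.std(axis=1, ddof=1)
    constant = sorted(values.index[sd == 0])
    values = values.drop(index=constant)
    sd = sd.drop(index=constant)
    centered = values.sub(values.mean(axis=1), axis=0)
    denom = sd if scale == "autoscale" else np.sqrt(sd)
    scaled = centered.div(denom, axis=0)
    return MetabolitePoolTable(
        values=scaled,
        samples=table.samples.copy(),
        dropped=list(table.dropped) + constant,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # metabolites x components
    explained_variance_fraction: np.ndarray


def run_pca(table: MetabolitePoolTable, n_components: int | None = None) -> PcaResult:
    """PCA of the samples-by-metabolites matrix via SVD.

    The table is expected preprocessed (rows centered); sample means are
    removed before decomposition so scores are centered per component.
    """
    X = table.values.to_numpy(dtype=float).T   # samples x metabolites
    if np.isnan(X).any():
        raise ValueError("PCA requires a table without missing values")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = rank if n_components is None else min(n_components, rank)
    comps = [f"PC{i+1}" for i in range(k)]
    scores = pd.DataFrame(
        U[:, :k] * s[:k], index=table.values.columns, columns=comps
    )
    loadings = pd.DataFrame(Vt[:k].T, index=table.values.index, columns=comps)
    total_var = float(np.sum(s**2))
    explained = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=explained,
    )


# ---------------------------------------------------------------------------
# PLS (NIPALS, single response) and VIP
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    n_components: int
    weights: pd.DataFrame        # metabolites x components (w_a, unit norm)
    scores: pd.DataFrame         # samples x components (t_a)
    x_loadings: pd.DataFrame     # metabolites x components (p_a)
    y_loadings: np.ndarray       # q_a per component
    ss_explained: np.ndarray     # SS_a = q_a^2 t_a't_a per component
    variable_ids: list
    y_mean: float


@dataclass
class VipResult:
    vip: pd.Series               # metabolite -> VIP score
    selected: pd.Series          # metabolite -> VIP > 1 flag

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def fit_pls(
    table: MetabolitePoolTable,
    y: Sequence[float],
    n_components: int = 2,
) -> PlsModel:
    """Single-response PLS regression of y (e.g. q_O2 per sample) on the
    pool table, by the NIPALS algorithm with deflation per component.

    For one response NIPALS is non-iterative per component: the weight
    vector is the normalized covariance X'y, the score t = Xw, loadings
    p = X't/t't and q = y't/t't, after which X and y are deflated by the
    rank-one fit.
    """
    X = table.values.to_numpy(dtype=float).T.copy()  # samples x metabolites
    y = np.asarray(y, dtype=float).copy()
    if y.shape[0] != X.shape[0]:
        raise ValueError("y must have one value per sample")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    y_mean = float(y.mean())
    yc = y - y_mean
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0, keepdims=True)))
    A = min(n_components, max(rank, 1))
    p = X.shape[1]
    W = np.zeros((p, A))
    T = np.zeros((X.shape[0], A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    ss = np.zeros(A)
    for a in range(A):
        w = X.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            A = a
            break
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            A = a
            break
        pa = X.T @ t / tt
        qa = float(yc @ t) / tt
        X = X - np.outer(t, pa)
        yc = yc - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
        ss[a] = qa**2 * tt
    comps = [f"C{i+1}" for i in range(A)]
    ids = list(table.values.index)
    return PlsModel(
        n_components=A,
        weights=pd.DataFrame(W[:, :A], index=ids, columns=comps),
        scores=pd.DataFrame(T[:, :A], index=table.values.columns, columns=comps),
        x_loadings=pd.DataFrame(P[:, :A], index=ids, columns=comps),
        y_loadings=q[:A],
        ss_explained=ss[:A],
        variable_ids=ids,
        y_mean=y_mean,
    )


def predict_pls(model: PlsModel, table: MetabolitePoolTable) -> np.ndarray:
    """Predict the response for new samples from a fitted PLS model."""
    X = table.values.loc[model.variable_ids].to_numpy(dtype=float).T.copy()
    yhat = np.full(X.shape[0], model.y_mean)
    for a in range(model.n_components):
        w = model.weights.iloc[:, a].to_numpy()
        p = model.x_loadings.iloc[:, a].to_numpy()
        t = X @ w
        yhat += model.y_loadings[a] * t
        X = X - np.outer(t, p)
    return yhat


def fit_pls_da(
    table: MetabolitePoolTable,
    labels: Sequence[str],
    n_components: int = 2,
) -> dict:
    """Discriminant variant: PLS against dummy-coded class labels.

    Two classes are coded +1/-1 and fitted with a single model; with more
    classes one one-vs-rest model is fitted per class.  Returns a mapping
    class label -> PlsModel (a single entry keyed by the positive class
    for the two-class case).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != table.values.shape[1]:
        raise ValueError("need one label per sample")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if len(classes) == 2:
        y = np.where(labels == classes[1], 1.0, -1.0)
        return {classes[1]: fit_pls(table, y, n_components)}
    return {
        cls: fit_pls(table, np.where(labels == cls, 1.0, -1.0), n_components)
        for cls in classes
    }


def choose_n_components(
    table: MetabolitePoolTable, y: Sequence[float], max_components: int = 5
) -> int:
    """Pick the PLS component count maximizing leave-one-out Q^2."""
    y = np.asarray(y, dtype=float)
    n = table.values.shape[1]
    best_a, best_q2 = 1, -np.inf
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    for A in range(1, max_components + 1):
        press = 0.0
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            sub = MetabolitePoolTable(
                values=table.values.iloc[:, keep],
                samples=table.samples.iloc[keep],
            )
            mdl = fit_pls(sub, y[keep], n_components=A)
            held = MetabolitePoolTable(
                values=table.values.iloc[:, [i, i]],
                samples=table.samples.iloc[[i, i]],
            )
            press += (predict_pls(mdl, held)[0] - y[i]) ** 2
        q2 = 1.0 - press / ss_tot
        if q2 > best_q2 + 1e-12:
            best_a, best_q2 = A, q2
    return best_a


def compute_vip(model: PlsModel, threshold: float = 1.0) -> VipResult:
    """VIP scores and the VIP > threshold selection flags."""
    ss = model.ss_explained
    if not np.any(ss > 0):
        raise ValueError("no explained response variance; VIP undefined")
    W = model.weights.to_numpy()
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn**2 @ ss) / ss.sum())
    vip_s = pd.Series(vip, index=model.variable_ids, name="VIP")
    return VipResult(vip=vip_s, selected=vip_s > threshold)


# ---------------------------------------------------------------------------
# Heatmap ordering
# ---------------------------------------------------------------------------

def heatmap_order(table: MetabolitePoolTable) -> dict:
    """Hierarchical-clustering leaf orders (Euclidean distance, complete
    linkage) for metabolites (rows) and samples (columns).

    Rows/columns are pre-sorted by id before linkage so that distance ties
    resolve identically across runs.
    """
    def leaves(matrix: np.ndarray, labels: list) -> list:
        order = np.argsort(np.asarray(labels, dtype=object))
        matrix = matrix[order]
        labels = [labels[i] for i in order]
        if len(labels) == 1:
            return list(labels)
        Z = hierarchy.linkage(pdist(matrix, metric="euclidean"), method="complete")
        return [labels[i] for i in hierarchy.leaves_list(Z)]

    X = table.values.to_numpy(dtype=float)
    return {
        "rows": leaves(X, list(table.values.index)),
        "columns": leaves(X.T, list(table.values.columns)),
    }
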