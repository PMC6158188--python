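"""Time-course transcriptome statistics.

Implements the expression arm of the analysis: removal of genes with little
or no expression at multiple time points, fuzzy c-means clustering of
standardized temporal profiles (soft memberships with fuzzifier m), a
data-driven fuzzifier heuristic, per-gene two-phase differential statistics
(Welch t on log2(FPKM+1)), directional gene-set analysis with a
gene-sampling permutation null in five directionality classes, exact
hypergeometric over-representation analysis, and Benjamini-Hochberg
adjustment.

The five gene-set classes follow the directional enrichment convention:
*non-directional* scores magnitude only (mean |t|); *distinct-directional*
scores the signed mean t, once per tail; *mixed-directional* scores the
up-regulated and down-regulated subsets of a set separately, so a set that
splits coherently both ways can be significant in both mixed classes while
staying invisible to the distinct classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "FuzzyClustering",
    "GeneLevelStats",
    "GeneSetResult",
    "filter_low_expression",
    "standardize_profiles",
    "estimate_fuzzifier",
    "fuzzy_cmeans",
    "differential_stats",
    "gene_set_analysis",
    "ora_hypergeometric",
    "bh_adjust",
    "annotate_clusters",
    "read_gmt",
    "write_gmt",
]

GSA_CLASSES = (
    "distinct_up",
    "distinct_down",
    "mixed_up",
    "mixed_down",
    "non_directional",
)


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix with sample time/replicate/phase labels."""

    values: pd.DataFrame           # index gene ids, columns sample ids
    samples: pd.DataFrame          # index sample ids; time_h, replicate, phase

    def __post_init__(self):
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample annotations do not match value columns")
        if (self.values < 0).any().any():
            raise ValueError("FPKM values must be non-negative")
        if self.samples["time_h"].nunique() < 2:
            raise ValueError("need at least 2 time points")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    def timepoint_means(self) -> pd.DataFrame:
        """Collapse replicates: genes x time points, mean FPKM."""
        groups = self.values.T.groupby(self.samples["time_h"]).mean().T
        return groups[sorted(groups.columns)]


def filter_low_expression(
    mat: ExpressionMatrix,
    fpkm_threshold: float = 1.0,
    min_low_timepoints: int = 2,
) -> ExpressionMatrix:
    """Drop genes with little or no expression at several time points.

    A gene is removed iff its replicate-mean FPKM falls below
    ``fpkm_threshold`` at ``min_low_timepoints`` or more time points.
    """
    if fpkm_threshold < 0:
        raise ValueError("fpkm_threshold must be non-negative")
    means = mat.timepoint_means()
    n_low = (means < fpkm_threshold).sum(axis=1)
    keep = n_low < min_low_timepoints
    return ExpressionMatrix(
        values=mat.values.loc[keep], samples=mat.samples.copy()
    )


def standardize_profiles(mat: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene z-score of the replicate-mean time profile (genes x time
    points, mean 0 sd 1 per row).  Zero-variance genes are dropped."""
    means = mat.timepoint_means()
    sd = means.std(axis=1, ddof=0)
    means = means.loc[sd > 0]
    sd = sd[sd > 0]
    return means.sub(means.mean(axis=1), axis=0).div(sd, axis=0)


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------

@dataclass
class FuzzyClustering:
    k: int
    m: float
    memberships: pd.DataFrame        # genes x k, rows sum to 1
    centers: np.ndarray              # k x time points
    converged: bool
    n_iter: int
    objective: float

    def assignment(self, min_membership: float = 0.6) -> pd.Series:
        """Hard cluster per gene (argmax membership); genes whose best
        membership falls below ``min_membership`` are reported unassigned
        (-1).  The default 0.6 demands a >2:1 dominance of the best cluster
        over all others combined, so genes without coherent temporal signal
        (membership near 1/k) stay out of the core clusters."""
        best = self.memberships.to_numpy().argmax(axis=1)
        top = self.memberships.to_numpy().max(axis=1)
        out = np.where(top >= min_membership, best, -1)
        return pd.Series(out, index=self.memberships.index, name="cluster")


def estimate_fuzzifier(profiles: pd.DataFrame) -> float:
    """Data-size heuristic for the fuzzy c-means fuzzifier m.

    With N genes and D time points,

        m = 1 + (1418/N + 22.05) D^-2
              + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)

    which approaches 1 (hard clustering) for long profiles and stays
    comfortably above 1 for the short time courses typical of fermentation
    sampling.
    """
    N, D = profiles.shape
    if N < 2 or D < 2:
        raise ValueError("need at least 2 genes and 2 time points")
    return float(
        1.0
        + (1418.0 / N + 22.05) * D**-2.0
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    )


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    k: int,
    m: float | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> FuzzyClustering:
    """Fuzzy c-means of standardized profiles with Euclidean distance.

    Alternates membership and center updates (u_ij proportional to
    (1/d_ij^2)^(1/(m-1)); centers are membership^m-weighted means) until
    the largest center shift drops below ``tol``.  Centers are initialized
    from k distinct profiles drawn with the seeded generator, so runs are
    reproducible given the seed.
    """
    X = profiles.to_numpy(dtype=float)
    n, d = X.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of profiles ({n})")
    if m is None:
        m = estimate_fuzzifier(profiles)
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    u = np.zeros((n, k))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = np.maximum(
            ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), 0.0
        )
        zero = d2 < 1e-30
        u = np.zeros_like(d2)
        any_zero = zero.any(axis=1)
        # membership: u_ij = 1 / sum_l (d_ij/d_il)^(2/(m-1))
        dist_pow = d2[~any_zero] ** (1.0 / (m - 1.0))
        u[~any_zero] = (1.0 / dist_pow) / (1.0 / dist_pow).sum(
            axis=1, keepdims=True
        )
        if any_zero.any():
            rows = np.where(any_zero)[0]
            for i in rows:
                hits = np.where(zero[i])[0]
                u[i, hits] = 1.0 / len(hits)
        um = u**m
        new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            converged = True
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    objective = float((u**m * d2).sum())
    memberships = pd.DataFrame(
        u, index=profiles.index, columns=[f"cluster_{j+1}" for j in range(k)]
    )
    return FuzzyClustering(
        k=k,
        m=float(m),
        memberships=memberships,
        centers=centers,
        converged=converged,
        n_iter=it,
        objective=objective,
    )


def fcm_objective(X: np.ndarray, u: np.ndarray, centers: np.ndarray, m: float) -> float:
    """Fuzzy c-means objective sum_ij u_ij^m d_ij^2 (exposed for tests)."""
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float((u**m * d2).sum())


def annotate_clusters(
    clustering: FuzzyClustering,
    gene_list: Sequence[str],
    min_membership: float = 0.0,
) -> pd.DataFrame:
    """Cross a hard cluster assignment with an annotation gene list (for
    example transcription factors): per cluster, the member count and which
    annotated genes it contains."""
    assign = clustering.assignment(min_membership)
    marked = set(gene_list)
    rows = []
    for cl in range(clustering.k):
        members = assign.index[assign == cl]
        hits = sorted(marked & set(members))
        rows.append(
            {
                "cluster": cl + 1,
                "n_genes": len(members),
                "n_annotated": len(hits),
                "annotated_genes": ";".join(hits),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# Differential statistics
# ---------------------------------------------------------------------------

@dataclass
class GeneLevelStats:
    table: pd.DataFrame     # index gene ids; log2fc, t, p, direction
    phase_a: str
    phase_b: str

    @property
    def t(self) -> pd.Series:
        return self.table["t"]


def differential_stats(
    mat: ExpressionMatrix, phase_a, phase_b
) -> GeneLevelStats:
    """Per-gene phase-B-vs-phase-A statistics.

    ``phase_a``/``phase_b`` select samples by the ``phase`` annotation (or
    by ``time_h`` when numeric).  The fold change is
    log2((mean_B + 1)/(mean_A + 1)) on FPKM; the t statistic is a Welch
    two-sample t on log2(FPKM + 1) across replicates.  With a single
    replicate in either phase only the fold change is reported and p is NaN.
    """
    def pick(label):
        if isinstance(label, (int, float)) and not isinstance(label, bool):
            cols = mat.samples.index[mat.samples["time_h"] == float(label)]
        elif "phase" in mat.samples.columns:
            cols = mat.samples.index[mat.samples["phase"] == label]
        else:
            raise KeyError("samples carry no 'phase' annotation")
        if len(cols) == 0:
            raise KeyError(f"no samples for phase {label!r}")
        return cols

    cols_a, cols_b = pick(phase_a), pick(phase_b)
    A = mat.values[cols_a].to_numpy(dtype=float)
    B = mat.values[cols_b].to_numpy(dtype=float)
    log2fc = np.log2(B.mean(axis=1) + 1.0) - np.log2(A.mean(axis=1) + 1.0)
    if A.shape[1] >= 2 and B.shape[1] >= 2:
        la, lb = np.log2(A + 1.0), np.log2(B + 1.0)
        with warnings.catch_warnings():
            # zero-variance genes trigger a precision warning; they are
            # mapped to t=0, p=1 below
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        # degenerate genes (zero variance in both phases, equal means)
        t = np.where(np.isnan(t), 0.0, t)
        p = np.where(np.isnan(p), 1.0, p)
    else:
        t = np.where(log2fc == 0, 0.0, np.sign(log2fc))
        p = np.full(A.shape[0], np.nan)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "direction": np.sign(log2fc).astype(int),
        },
        index=mat.values.index,
    )
    return GeneLevelStats(table=table, phase_a=str(phase_a), phase_b=str(phase_b))


# ---------------------------------------------------------------------------
# Directional gene-set analysis
# ---------------------------------------------------------------------------

@dataclass
class GeneSetResult:
    table: pd.DataFrame       # index set ids; size + p_/q_ per class
    n_perm: int
    skipped: list = field(default_factory=list)


def _empirical_p(null: np.ndarray, observed: float, tail: str) -> float:
    if tail == "ge":
        hits = int(np.sum(null >= observed))
    else:
        hits = int(np.sum(null <= observed))
    return (1.0 + hits) / (null.size + 1.0)


def gene_set_analysis(
    gene_stats: GeneLevelStats,
    sets: Mapping[str, Sequence[str]],
    n_perm: int = 1999,
    seed: int = 0,
    min_coverage: float = 0.8,
) -> GeneSetResult:
    """Directional gene-set analysis with a gene-sampling null.

    The set statistic is the mean of the member genes' t values (signed for
    the distinct-directional classes, absolute for the non-directional
    class, and absolute over the up-/down-subset for the mixed classes).
    The null resamples size-matched gene subsets without replacement from
    all scored genes, ``n_perm`` times; empirical p-values use the
    add-one estimator (1 + #{null at least as extreme})/(n_perm + 1).
    Sets whose genes are not covered by the statistics at ``min_coverage``
    or that are empty after mapping are skipped with a notice.
    """
    t_all = gene_stats.t.dropna()
    gene_index = {g: i for i, g in enumerate(t_all.index)}
    t_arr = t_all.to_numpy(dtype=float)
    abs_arr = np.abs(t_arr)
    rng = np.random.default_rng(seed)
    n_genes = t_arr.size

    mapped = {}
    skipped = []
    for sid, members in sets.items():
        idx = np.array([gene_index[g] for g in members if g in gene_index], dtype=int)
        total = len(set(members))
        if total == 0 or idx.size == 0:
            skipped.append((sid, "empty after mapping"))
            continue
        if idx.size / total < min_coverage:
            skipped.append(
                (sid, f"coverage {idx.size}/{total} below {min_coverage:.0%}")
            )
            continue
        mapped[sid] = idx

    # one permutation pool per distinct set size: rows of sampled indices
    sizes = sorted({idx.size for idx in mapped.values()})
    null_signed, null_abs = {}, {}
    for size in sizes:
        samples = np.empty((n_perm, size), dtype=int)
        for r in range(n_perm):
            samples[r] = rng.choice(n_genes, size=size, replace=False)
        null_signed[size] = t_arr[samples].mean(axis=1)
        null_abs[size] = abs_arr[samples].mean(axis=1)

    rows = []
    for sid, idx in mapped.items():
        size = idx.size
        t_set = t_arr[idx]
        mean_t = float(t_set.mean())
        mean_abs = float(np.abs(t_set).mean())
        row = {"size": size, "mean_t": mean_t, "mean_abs_t": mean_abs}
        row["p_distinct_up"] = _empirical_p(null_signed[size], mean_t, "ge")
        row["p_distinct_down"] = _empirical_p(null_signed[size], mean_t, "le")
        row["p_non_directional"] = _empirical_p(null_abs[size], mean_abs, "ge")
        for direction, mask_key in (("up", t_set > 0), ("down", t_set < 0)):
            subset = t_set[mask_key]
            if subset.size == 0:
                row[f"p_mixed_{direction}"] = 1.0
                continue
            stat = float(np.abs(subset).mean())
            if subset.size not in null_abs:
                samples = np.empty((n_perm, subset.size), dtype=int)
                for r in range(n_perm):
                    samples[r] = rng.choice(n_genes, size=subset.size, replace=False)
                null_abs[subset.size] = abs_arr[samples].mean(axis=1)
            row[f"p_mixed_{direction}"] = _empirical_p(
                null_abs[subset.size], stat, "ge"
            )
        rows.append((sid, row))

    table = pd.DataFrame({sid: row for sid, row in rows}).T
    if len(table):
        table["size"] = table["size"].astype(int)
        for cls in GSA_CLASSES:
            table[f"q_{cls}"] = bh_adjust(table[f"p_{cls}"].to_numpy())
    return GeneSetResult(table=table, n_perm=n_perm, skipped=skipped)


def ora_hypergeometric(
    selected: Sequence[str],
    universe: Sequence[str],
    sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    p = P(X >= overlap) where X counts selected genes falling in the set
    when |selected| genes are drawn from the universe without replacement.
    """
    universe_set = set(universe)
    offenders = sorted(set(selected) - universe_set)
    if offenders:
        raise ValueError(f"selected genes outside the universe: {offenders}")
    N = len(universe_set)
    n_sel = len(set(selected))
    sel_set = set(selected)
    rows = []
    for sid, members in sets.items():
        in_universe = set(members) & universe_set
        K = len(in_universe)
        overlap = len(in_universe & sel_set)
        if K == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, N, K, n_sel))
        rows.append(
            {"set": sid, "set_size": K, "overlap": overlap, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read gene sets from GMT (set id, description, then member genes)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for sid, members in sets.items():
            fh.write("\t".join([sid, description or sid, *members]) + "\n")
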