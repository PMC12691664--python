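"""Weighted gene co-expression network analysis and clique-centrality hubs.

Pearson correlation -> soft threshold chosen by scale-free topology fit ->
unsigned adjacency |r|^beta -> topological overlap (TOM) -> average-linkage
clustering of 1 - TOM with a static height cut -> module eigengenes (first
principal component across samples) -> module-to-time-point assignment by
indicator correlation.  Hub genes within a module are ranked by maximal
clique centrality, MCC(v) = sum over maximal cliques C containing v of
(|C| - 1)!, computed from an exact Bron-Kerbosch enumeration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InputError, SelectionError
from .preprocess import ZMatrix

DEFAULT_SOFT_POWERS = tuple(range(1, 13))


def pearson_matrix(Z: ZMatrix) -> pd.DataFrame:
    """Gene x gene Pearson correlations; constant genes get r = 0 (flagged)."""
    if Z.values.shape[1] < 3:
        raise InputError("correlation needs at least 3 samples")
    vals = Z.values.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals)
    const = sd == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant genes; correlations set to 0",
                      stacklevel=2)
        r[const, :] = 0.0
        r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=Z.gene_ids, columns=Z.gene_ids)


def adjacency_from_correlation(
    C: pd.DataFrame, beta: int, signed: bool = False
) -> pd.DataFrame:
    """Soft-thresholded adjacency: |r|^beta (or ((1+r)/2)^beta when signed)."""
    r = C.to_numpy(dtype=float)
    a = ((1 + r) / 2) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=C.index, columns=C.columns)


@dataclass
class SoftThresholdResult:
    beta: int
    fit_table: pd.DataFrame  # per candidate: power, r2, slope, mean_k
    fallback: bool


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10(freq) ~ log10(mean k) over connectivity bins."""
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    res = stats.linregress(xs, ys)
    return float(res.rvalue ** 2), float(res.slope)


def pick_soft_threshold(
    C: pd.DataFrame,
    candidates=DEFAULT_SOFT_POWERS,
    r2_target: float = 0.8,
    signed: bool = False,
) -> SoftThresholdResult:
    """Smallest power whose connectivity distribution fits a scale-free law
    (R^2 >= target with negative slope); falls back to beta = 6 with a
    warning when no candidate qualifies."""
    candidates = list(candidates)
    if not candidates or min(candidates) < 1:
        raise InputError("candidate powers must be >= 1")
    rows = []
    chosen = None
    for beta in candidates:
        a = adjacency_from_correlation(C, beta, signed=signed).to_numpy()
        k = a.sum(axis=1)
        if np.allclose(k, 0):
            raise SelectionError(f"degenerate network at power {beta}: all k = 0")
        r2, slope = _scale_free_fit(k)
        rows.append({"power": beta, "r2": r2, "slope": slope, "mean_k": k.mean()})
        if chosen is None and r2 >= r2_target and slope < 0:
            chosen = beta
    fallback = chosen is None
    if fallback:
        chosen = 6
        warnings.warn(
            f"no candidate power reached scale-free R^2 >= {r2_target}; using beta = 6",
            stacklevel=2)
    return SoftThresholdResult(beta=chosen, fit_table=pd.DataFrame(rows),
                               fallback=fallback)


def tom_from_adjacency(A: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    with l_ij = sum_{u != i,j} a_iu a_uj; diagonal set to 1."""
    a = A.to_numpy(dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise InputError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a  # diagonal of a is 0, so cross-terms u=i, u=j vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=A.index, columns=A.columns)


@dataclass
class ModuleSet:
    """Module detection output plus eigengene and time-point tables."""

    assignment: pd.Series                       # gene -> "M1".. or "unassigned"
    eigengenes: pd.DataFrame | None = None      # modules x samples, unit norm
    var_explained: pd.Series | None = None
    tp_correlation: pd.DataFrame | None = None  # (module, timepoint) -> r, p
    tp_assignment: pd.Series | None = None      # module -> timepoint or NaN

    def genes_of(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    def modules(self) -> list[str]:
        return [m for m in self.assignment.unique() if m != "unassigned"]

    def genes_by_timepoint(self) -> dict[str, set[str]]:
        """Time point -> genes of modules assigned to it."""
        out: dict[str, set[str]] = {}
        if self.tp_assignment is None:
            return out
        for module, tp in self.tp_assignment.items():
            if isinstance(tp, str):
                out.setdefault(tp, set()).update(self.genes_of(module))
        return out


def detect_modules(
    tom: pd.DataFrame,
    cut_height: float = 0.97,
    min_size: int = 20,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_size`` become "unassigned"; surviving modules
    are labeled M1, M2, ... in decreasing size (ties by first gene index),
    making labels deterministic.
    """
    genes = list(tom.index)
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    Zlink = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(Zlink, t=cut_height, criterion="distance")
    assignment = pd.Series("unassigned", index=genes, dtype=object)
    sizes = pd.Series(flat).value_counts()
    order = sorted(
        (cl for cl in sizes.index if sizes[cl] >= min_size),
        key=lambda cl: (-sizes[cl], int(np.argmax(flat == cl))),
    )
    for rank, cl in enumerate(order, start=1):
        assignment.iloc[np.nonzero(flat == cl)[0]] = f"M{rank}"
    return ModuleSet(assignment=assignment)


def module_eigengene(Z: ZMatrix, module_genes) -> tuple[pd.Series, float]:
    """First principal component of the module across samples.

    Unit norm, sign aligned so its correlation with the module's mean
    profile is non-negative; also returns the variance-explained fraction.
    """
    genes = list(module_genes)
    if len(genes) < 2:
        raise InputError("eigengene needs a module of >= 2 genes")
    sub = Z.values.loc[genes].to_numpy(dtype=float)
    if np.allclose(sub.std(axis=1), 0):
        raise SelectionError("module of constant genes has no eigengene")
    centered = sub - sub.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    mean_profile = centered.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=Z.sample_ids), var_explained


def module_timepoint_assign(
    eigengenes: pd.DataFrame,
    timepoints: pd.Series,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Correlate each eigengene with each time point's one-hot indicator.

    Returns the (module, timepoint) r/p table and the per-module assignment:
    the time point with the largest positive r having p < alpha, else NaN.
    """
    counts = timepoints.value_counts()
    thin = [tp for tp, c in counts.items() if c < 2]
    if thin:
        raise InputError(f"time points with < 2 samples: {thin}")
    tps = list(dict.fromkeys(timepoints))
    rows = []
    assign = {}
    for module in eigengenes.index:
        e = eigengenes.loc[module, timepoints.index].to_numpy(dtype=float)
        best_tp, best_r = None, 0.0
        for tp in tps:
            ind = (timepoints == tp).to_numpy(dtype=float)
            res = stats.pearsonr(e, ind)
            rows.append({"module": module, "timepoint": tp,
                         "r": float(res.statistic), "p": float(res.pvalue)})
            if res.statistic > best_r and res.pvalue < alpha:
                best_tp, best_r = tp, float(res.statistic)
        assign[module] = best_tp if best_tp is not None else np.nan
    table = pd.DataFrame(rows)
    return table, pd.Series(assign, name="timepoint")


def build_modules(
    Z: ZMatrix,
    tom: pd.DataFrame,
    cut_height: float = 0.97,
    min_size: int = 20,
) -> ModuleSet:
    """Detect modules then attach eigengenes and time-point assignments."""
    ms = detect_modules(tom, cut_height=cut_height, min_size=min_size)
    mods = ms.modules()
    if not mods:
        return ms
    eig_rows, ve = {}, {}
    for m in mods:
        eig, var = module_eigengene(Z, ms.genes_of(m))
        eig_rows[m] = eig
        ve[m] = var
    eigengenes = pd.DataFrame(eig_rows).T
    table, assign = module_timepoint_assign(eigengenes, Z.meta["timepoint"])
    ms.eigengenes = eigengenes
    ms.var_explained = pd.Series(ve, name="var_explained")
    ms.tp_correlation = table
    ms.tp_assignment = assign
    return ms


# ---------------------------------------------------------------------------
# Maximal clique centrality (MCC)
# ---------------------------------------------------------------------------

@dataclass
class MccTable:
    scores: pd.Series                   # node -> MCC (int)
    maximal_cliques: list[list[str]] = field(default_factory=list)

    def top(self, n: int = 10) -> pd.Series:
        ranked = self.scores.sort_values(ascending=False, kind="stable")
        # deterministic tie-break by node id within equal scores
        ranked = self.scores.loc[
            sorted(self.scores.index, key=lambda v: (-self.scores[v], str(v)))]
        return ranked.head(n)


def mcc_scores(
    matrix: pd.DataFrame,
    edge_threshold: float = 0.75,
    max_nodes: int = 2000,
) -> MccTable:
    """Maximal clique centrality from exact clique enumeration.

    Edges are pairs with |value| >= edge_threshold; maximal cliques come from
    Bron-Kerbosch with pivoting; MCC(v) = sum over maximal cliques C
    containing v of (|C| - 1)!.  Isolated vertices score 0.
    """
    nodes = list(matrix.index)
    if len(nodes) > max_nodes:
        raise InputError(
            f"{len(nodes)} nodes exceeds the clique-enumeration guard ({max_nodes})")
    vals = matrix.to_numpy(dtype=float)
    G = nx.Graph()
    G.add_nodes_from(nodes)
    ii, jj = np.nonzero(np.triu(np.abs(vals) >= edge_threshold, k=1))
    G.add_edges_from((nodes[i], nodes[j]) for i, j in zip(ii, jj))
    scores = {v: 0 for v in nodes}
    cliques = []
    for clique in nx.find_cliques(G):
        if len(clique) < 2:
            continue  # isolated vertices score 0 by convention
        cliques.append(sorted(clique))
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return MccTable(scores=pd.Series(scores, name="mcc"), maximal_cliques=cliques)
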