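"""Diel-variable expression: four-state ANOVA, BH correction, day/night
partition by hierarchical clustering, and per-contrast log2 fold changes.

The test asks whether a gene's normalized expression differs across the four
diel states (MidDark, Pre-Dawn, MidLight, Pre-Dusk) sampled during the two
core entrainment cycles; significant genes (BH-adjusted p < alpha) are split
into "day" and "night" sets by cutting a complete-linkage Euclidean
dendrogram of their z-scores into two clusters and labeling each cluster by
its light-vs-dark mean z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import DesignError, InputError
from .preprocess import ExpressionMatrix, ZMatrix, timepoint_means, zscore_by_gene
from .simdata import ANOVA_STATES, CORE_STATE_OF_TIMEPOINT


def core_state_map(meta: pd.DataFrame) -> pd.Series:
    """Sample -> diel state for core-cycle samples; other samples dropped."""
    tp = meta["timepoint"]
    keep = tp.isin(CORE_STATE_OF_TIMEPOINT)
    return tp[keep].map(CORE_STATE_OF_TIMEPOINT)


def anova_four_state(
    X: ExpressionMatrix,
    states: pd.Series | None = None,
    collapse_replicates: bool = False,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of the four diel states, per gene.

    ``states`` maps sample id -> state; by default it is derived from the
    matrix metadata (both occurrences of each core time point pooled, each
    replicate an independent observation).  ``collapse_replicates`` averages
    replicates within each time point first, leaving n = 2 per state.
    Returns a DataFrame with F, p, and the four state means; all-constant
    genes get F = 0, p = 1 by convention.
    """
    if states is None:
        states = core_state_map(X.meta)
    bad = set(states.unique()) - set(ANOVA_STATES)
    if bad:
        raise DesignError(f"unexpected states: {sorted(bad)}")
    samples = list(states.index)
    sub = X.values[samples]
    if collapse_replicates:
        tp = X.meta.loc[samples, "timepoint"]
        sub = sub.T.groupby(tp, sort=False).mean().T
        states = pd.Series({t: CORE_STATE_OF_TIMEPOINT[t] for t in sub.columns})
    groups = []
    for state in ANOVA_STATES:
        cols = states.index[states == state]
        if len(cols) < 2:
            raise DesignError(f"state {state!r} has {len(cols)} observations (<2)")
        groups.append(sub[list(cols)].to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows handled below
        with np.errstate(invalid="ignore", divide="ignore"):
            F, p = stats.f_oneway(*groups, axis=1)
    F = np.asarray(F, dtype=float)
    p = np.asarray(p, dtype=float)
    flat = sub.to_numpy().std(axis=1) == 0
    F[flat] = 0.0
    p[flat] = 1.0
    out = pd.DataFrame({"F": F, "p": p}, index=sub.index)
    for state, g in zip(ANOVA_STATES, groups):
        out[f"mean_{state}"] = g.mean(axis=1)
    return out


def anova_group_means(X: ExpressionMatrix, state: str) -> pd.Series:
    """Per-gene mean of one diel state over its core-cycle samples."""
    states = core_state_map(X.meta)
    cols = list(states.index[states == state])
    return X.values[cols].mean(axis=1)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i} m * p(j) / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise InputError("bh_adjust expects a 1-D array")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    def cut(self, k: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return walk(tree) + ";"


def hclust_complete(rows, labels: list[str] | None = None) -> Dendrogram:
    """Complete-linkage agglomerative clustering with Euclidean distances."""
    if isinstance(rows, pd.DataFrame):
        labels = labels or list(rows.index)
        rows = rows.to_numpy(dtype=float)
    rows = np.asarray(rows, dtype=float)
    if rows.shape[0] < 2:
        raise InputError("clustering needs at least 2 rows")
    if not np.isfinite(rows).all():
        raise InputError("non-finite values in clustering input")
    if labels is None:
        labels = [str(i) for i in range(rows.shape[0])]
    Z = hierarchy.linkage(rows, method="complete", metric="euclidean")
    return Dendrogram(linkage=Z, labels=list(labels))


def partition_day_night(
    dendrogram: Dendrogram,
    Z: ZMatrix,
    phases: pd.Series | None = None,
) -> pd.Series:
    """Cut the significant-gene dendrogram into two clusters and label them.

    A cluster is "day" when its genes' mean z over light-phase samples
    exceeds their mean over dark-phase samples, else "night"; if both
    clusters lean the same way, the stronger lean keeps the label and the
    other takes the opposite (with a warning), so both labels are used.
    """
    if len(dendrogram.labels) < 2:
        warnings.warn("fewer than 2 significant genes; day/night partition skipped",
                      stacklevel=2)
        return pd.Series(dtype=object)
    if phases is None:
        phases = Z.meta["phase"]
    flat = dendrogram.cut(2)
    light_cols = [s for s in Z.sample_ids if phases[s] == "light"]
    dark_cols = [s for s in Z.sample_ids if phases[s] == "dark"]
    lean = {}
    for cl in (1, 2):
        genes = flat.index[flat == cl]
        sub = Z.values.loc[genes]
        lean[cl] = sub[light_cols].to_numpy().mean() - sub[dark_cols].to_numpy().mean()
    labels = {cl: ("day" if v > 0 else "night") for cl, v in lean.items()}
    if labels[1] == labels[2]:
        warnings.warn("both clusters lean the same way; weaker cluster relabeled",
                      stacklevel=2)
        stronger = max(lean, key=lambda c: abs(lean[c]))
        weaker = 3 - stronger
        labels[weaker] = "night" if labels[stronger] == "day" else "day"
    return flat.map(labels).rename("day_night")


def log2_fold_change(
    tp_means: pd.DataFrame,
    contrast: tuple[str, str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2((mean_A + pc) / (mean_B + pc)) per gene for a time-point contrast."""
    a, b = contrast
    for tp in (a, b):
        if tp not in tp_means.columns:
            raise DesignError(f"time point {tp!r} not in design")
    if pseudocount <= 0:
        raise InputError("pseudocount must be > 0")
    fc = np.log2((tp_means[a] + pseudocount) / (tp_means[b] + pseudocount))
    return fc.rename(f"log2fc_{a}_vs_{b}")


@dataclass
class ConsensusSets:
    day: set[str]
    night: set[str]
    conflicts: set[str]


def consensus_gene_sets(
    anova_day: set[str],
    anova_night: set[str],
    module_tp_sets: dict[str, set[str]],
    phase_of_timepoint: dict[str, str],
    Z: ZMatrix,
) -> ConsensusSets:
    """Union ANOVA day/night genes with time-point-assigned module genes.

    Day = ANOVA day genes plus genes in modules assigned to light time
    points; night analogous.  A gene landing in both unions is resolved to
    the side with the larger |mean z difference| (light vs dark samples)
    and reported in ``conflicts``.
    """
    day = set(anova_day)
    night = set(anova_night)
    for tp, genes in module_tp_sets.items():
        phase = phase_of_timepoint.get(tp)
        if phase == "light":
            day |= set(genes)
        elif phase == "dark":
            night |= set(genes)
        else:
            raise DesignError(f"time point {tp!r} has no declared phase")
    conflicts = day & night
    if conflicts:
        phases = Z.meta["phase"]
        light_cols = [s for s in Z.sample_ids if phases[s] == "light"]
        dark_cols = [s for s in Z.sample_ids if phases[s] == "dark"]
        for gene in sorted(conflicts):
            if gene not in Z.values.index:
                day.discard(gene)  # unresolvable without expression; drop from day
                continue
            diff = (Z.values.loc[gene, light_cols].mean()
                    - Z.values.loc[gene, dark_cols].mean())
            if diff > 0:
                night.discard(gene)
            else:
                day.discard(gene)
    return ConsensusSets(day=day, night=night, conflicts=conflicts)


def diel_gene_table(
    X_norm: ExpressionMatrix,
    alpha: float = 0.05,
    contrasts: tuple[tuple[str, str], ...] = (
        ("MidDark1", "MidLight1"), ("MidDark2", "MidLight2")),
    pseudocount: float = 1.0,
    collapse_replicates: bool = False,
    log_scale: bool = True,
) -> tuple[pd.DataFrame, Dendrogram | None]:
    """Full diel-statistics stage on a normalized, filtered matrix.

    Runs the four-state ANOVA on the core-cycle samples, BH-adjusts, labels
    significant genes day/night via the z-score dendrogram, and attaches
    per-contrast log2 fold changes.  Returns the per-gene table and the
    dendrogram of significant genes (None when fewer than 2).

    By default the ANOVA runs on log2(normalized + 1): counts are strongly
    heteroscedastic (variance grows with the squared mean under negative
    binomial noise, so high-expression states dominate the pooled error),
    and the log transform stabilizes the per-observation variance the F
    test assumes.  ``log_scale=False`` tests the normalized counts as-is.
    """
    X_test = X_norm
    if log_scale:
        X_test = ExpressionMatrix(np.log2(X_norm.values + 1.0), X_norm.meta)
    res = anova_four_state(X_test, collapse_replicates=collapse_replicates)
    for state in ANOVA_STATES:  # report means on the normalized-count scale
        res[f"mean_{state}"] = anova_group_means(X_norm, state)
    res["q"] = bh_adjust(res["p"].to_numpy())
    core_samples = [s for s in X_norm.sample_ids
                    if X_norm.meta.loc[s, "timepoint"] in CORE_STATE_OF_TIMEPOINT]
    Zcore = zscore_by_gene(X_norm.subset_samples(core_samples))
    sig = res.index[res["q"] < alpha]
    res["label"] = "none"
    dend = None
    if len(sig) >= 2:
        dend = hclust_complete(Zcore.values.loc[sig])
        labels = partition_day_night(dend, Zcore.subset_genes(sig))
        res.loc[labels.index, "label"] = labels
    tp_means = timepoint_means(X_norm)
    for contrast in contrasts:
        fc = log2_fold_change(tp_means, contrast, pseudocount)
        res[fc.name] = fc
    return res, dend
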