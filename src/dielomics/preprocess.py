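"""Count-matrix containers and the normalize -> filter -> z-score stage.

The pipeline operates on a gene x sample expression matrix with per-sample
metadata (time point, replicate, light/dark phase).  Counts are upper-quartile
normalized, genes with consistently low expression (every time-point mean
below a threshold) are removed, and retained genes are z-scored per gene
before any clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, InputError, NormalizationError

logger = logging.getLogger(__name__)

PHASES = ("light", "dark")
META_COLUMNS = ("timepoint", "replicate", "phase")


def _validate_matrix(values: pd.DataFrame, meta: pd.DataFrame, nonneg: bool) -> None:
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate gene ids: {dups}")
    if values.columns.has_duplicates:
        dups = values.columns[values.columns.duplicated()].unique().tolist()
        raise InputError(f"duplicate sample ids: {dups}")
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise InputError("expression values must be finite")
    if nonneg and (values.to_numpy(dtype=float) < 0).any():
        raise InputError("expression values must be non-negative")
    if list(meta.index) != list(values.columns):
        raise InputError("sample metadata index must match matrix columns (same order)")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise InputError(f"sample metadata missing columns: {missing}")
    bad_phase = set(meta["phase"]) - set(PHASES)
    if bad_phase:
        raise InputError(f"unknown phases in metadata: {sorted(bad_phase)}")


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values plus sample metadata.

    ``values``: DataFrame indexed by gene id, columns = sample ids.
    ``meta``: DataFrame indexed by sample id with columns
    ``timepoint``, ``replicate``, ``phase`` (phase in {"light", "dark"}).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_matrix(self.values, self.meta, nonneg=True)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def timepoint_order(self) -> list[str]:
        """Time points in design order (order of first appearance in metadata)."""
        return list(dict.fromkeys(self.meta["timepoint"]))

    def phase_of_sample(self) -> pd.Series:
        return self.meta["phase"]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.meta)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.values[samples], self.meta.loc[samples])


@dataclass
class ZMatrix:
    """Per-gene z-scored expression; same layout as :class:`ExpressionMatrix`."""

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_matrix(self.values, self.meta, nonneg=False)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def timepoint_order(self) -> list[str]:
        return list(dict.fromkeys(self.meta["timepoint"]))

    def subset_genes(self, genes) -> "ZMatrix":
        return ZMatrix(self.values.loc[list(genes)], self.meta)

    def subset_samples(self, samples) -> "ZMatrix":
        samples = list(samples)
        return ZMatrix(self.values[samples], self.meta.loc[samples])


def upper_quartile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample by ``f_s = m / UQ_s``.

    ``UQ_s`` is the 75th percentile (linear interpolation) of the sample's
    *nonzero* values and ``m`` the arithmetic mean of the per-sample UQs, so
    the transform is idempotent and scale-equivariant.
    """
    vals = X.values.to_numpy(dtype=float)
    uq = np.empty(vals.shape[1])
    for j, sample in enumerate(X.sample_ids):
        col = vals[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise NormalizationError(f"sample {sample!r} has no nonzero counts")
        uq[j] = np.percentile(nz, 75)
    m = uq.mean()
    scaled = vals * (m / uq)[np.newaxis, :]
    out = pd.DataFrame(scaled, index=X.values.index, columns=X.values.columns)
    return ExpressionMatrix(out, X.meta)


def timepoint_means(X: ExpressionMatrix | ZMatrix) -> pd.DataFrame:
    """Mean over replicates per time point; columns follow design order."""
    order = X.timepoint_order
    counts = X.meta["timepoint"].value_counts()
    empty = [tp for tp in order if counts.get(tp, 0) == 0]
    if empty:
        raise DesignError(f"time points without samples: {empty}")
    grouped = X.values.T.groupby(X.meta["timepoint"], sort=False).mean().T
    return grouped[order]


@dataclass
class FilterResult:
    matrix: ExpressionMatrix
    n_retained: int
    n_removed: int
    removed_genes: list[str] = field(default_factory=list)


def filter_low_expression(X: ExpressionMatrix, threshold: float = 10.0) -> FilterResult:
    """Drop genes whose replicate-averaged expression is below ``threshold``
    in *all* time points; a gene with any time-point mean >= threshold stays."""
    tp_means = timepoint_means(X)
    keep = (tp_means >= threshold).any(axis=1)
    removed = [g for g, k in keep.items() if not k]
    retained = keep.sum()
    if retained == 0:
        warnings.warn("no genes survive the low-expression filter", stacklevel=2)
        logger.warning("low-expression filter removed every gene")
    logger.info("low-expression filter: retained %d, removed %d genes",
                retained, len(removed))
    return FilterResult(
        matrix=ExpressionMatrix(X.values.loc[keep[keep].index], X.meta),
        n_retained=int(retained),
        n_removed=len(removed),
        removed_genes=removed,
    )


def zscore_by_gene(X: ExpressionMatrix) -> ZMatrix:
    """Per-gene centering and scaling (sd with n-1); constant rows map to 0."""
    if X.values.shape[1] < 2:
        raise DesignError("z-scoring needs at least 2 samples")
    vals = X.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return ZMatrix(pd.DataFrame(z, index=X.values.index, columns=X.values.columns),
                   X.meta)


def sample_spearman(X: ExpressionMatrix | ZMatrix) -> pd.DataFrame:
    """Sample x sample Spearman correlation (average ranks for ties)."""
    if X.values.shape[0] < 3:
        raise DesignError("Spearman QC needs at least 3 genes")
    rho = stats.spearmanr(X.values.to_numpy(dtype=float), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return pd.DataFrame(rho, index=X.sample_ids, columns=X.sample_ids)
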