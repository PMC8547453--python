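"""Per-data-type preparation of feature-by-sample matrices.

Every matrix is a pandas DataFrame with features in rows and samples in
columns.  Three kinds flow through the pipeline: ``continuous_log`` (log
analyte abundances: metabolites, proteins, SRM light/heavy ratios),
``ordinal`` (food-frequency scores 0-8) and ``count`` (sequencing counts of
taxa or gene clusters).  This module turns raw measurements into model-ready
matrices: batch/QC scaling and minimum-value imputation for metabolites,
missingness filtering for proteins, longitudinal log ratios for SRM panels,
KO-term aggregation, median-of-ratios ("poscounts") size factors for counts,
and seeded rarefaction for gene richness.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "normalize_metabolites",
    "prepare_proteins",
    "srm_log_ratios",
    "aggregate_gene_clusters",
    "poscounts_size_factors",
    "rarefied_richness",
    "MetaboliteNormalizer",
    "ProteinPreparer",
    "PoscountsNormalizer",
    "UNANNOTATED",
]

#: reserved term under which unannotated ORFs pool
UNANNOTATED = "unannotated"


def _as_float_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.astype(float)
    if (out.to_numpy() < 0)[~np.isnan(out.to_numpy())].any():
        raise ValueError("raw abundances must be >= 0 or missing")
    return out


def normalize_metabolites(
    raw: pd.DataFrame,
    batch: Mapping[str, str],
    qc_samples: Iterable[str],
    log_base: float | None = None,
) -> pd.DataFrame:
    """Batch-median and QC scaling, minimum imputation, log transform.

    Per batch and metabolite the raw values are divided by the within-batch
    median over study samples (so each metabolite's batch median becomes 1)
    and then by the mean of the scaled values in that batch's quality-control
    samples, removing residual between-batch shifts.  Missing cells are then
    imputed as the minimum observed normalized value of the metabolite over
    the whole cohort, and everything is log transformed (natural log by
    default).  QC samples are dropped from the output.

    Parameters
    ----------
    raw:
        Metabolite x sample matrix, values >= 0 or NaN.
    batch:
        Sample -> batch label for every column.
    qc_samples:
        Columns that are quality-control pools (each batch needs >= 1).
    log_base:
        Base of the final log transform; ``None`` = natural log.
    """
    raw = _as_float_frame(raw)
    qc = set(qc_samples)
    missing_batch = [s for s in raw.columns if s not in batch]
    if missing_batch:
        raise ValueError(f"samples without batch label: {missing_batch}")
    study_cols = [c for c in raw.columns if c not in qc]

    normalized = pd.DataFrame(index=raw.index, columns=study_cols, dtype=float)
    for b in sorted({batch[c] for c in raw.columns}):
        cols = [c for c in raw.columns if batch[c] == b]
        qc_cols = [c for c in cols if c in qc]
        if not qc_cols:
            raise ValueError(f"batch {b!r} contains no quality-control samples")
        st_cols = [c for c in cols if c not in qc]
        med = raw[st_cols].median(axis=1)
        scaled = raw[cols].div(med, axis=0)
        qc_mean = scaled[qc_cols].mean(axis=1)
        normalized[st_cols] = scaled[st_cols].div(qc_mean, axis=0)

    all_missing = normalized.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} metabolite(s) missing in all samples"
        )
        normalized = normalized[~all_missing]

    minima = normalized.min(axis=1)
    normalized = normalized.apply(lambda row: row.fillna(minima[row.name]), axis=1)
    logged = np.log(normalized)
    if log_base is not None:
        logged = logged / np.log(log_base)
    return logged


def prepare_proteins(
    raw: pd.DataFrame,
    max_missing_fraction: float = 0.05,
    log_base: float | None = None,
) -> pd.DataFrame:
    """Drop high-missingness proteins, impute the rest, log transform.

    A protein is kept only when its fraction of missing samples is below
    ``max_missing_fraction`` (the "< 5% missing" rule); remaining missing
    cells are imputed as the protein's minimum observed value.
    """
    raw = _as_float_frame(raw)
    frac_missing = raw.isna().mean(axis=1)
    kept = raw[frac_missing < max_missing_fraction].copy()
    minima = kept.min(axis=1)
    kept = kept.apply(lambda row: row.fillna(minima[row.name]), axis=1)
    logged = np.log(kept)
    if log_base is not None:
        logged = logged / np.log(log_base)
    return logged


def srm_log_ratios(
    baseline: pd.DataFrame, followup: pd.DataFrame
) -> pd.DataFrame:
    """Within-subject change in log protein abundance.

    ``delta = log(followup) - log(baseline)`` per protein and subject; both
    matrices must share features and samples and contain positive
    light/heavy ratios.
    """
    if not baseline.index.equals(followup.index) or not baseline.columns.equals(
        followup.columns
    ):
        raise ValueError("baseline and followup must share features and samples")
    for name, df in (("baseline", baseline), ("followup", followup)):
        vals = df.astype(float)
        bad = (vals <= 0) | vals.isna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-positive {name} ratio at feature "
                f"{df.index[r]!r}, sample {df.columns[c]!r}"
            )
    return np.log(followup.astype(float)) - np.log(baseline.astype(float))


def aggregate_gene_clusters(
    orf_counts: pd.DataFrame, orf_to_term: Mapping[str, str]
) -> pd.DataFrame:
    """Sum ORF counts into annotation-term gene clusters.

    ORFs absent from ``orf_to_term`` pool under the reserved
    :data:`UNANNOTATED` row, which keeps library sizes intact while letting
    cluster-level analyses drop it.  Per sample, the column sums of the
    output equal those of the input.
    """
    counts = orf_counts.astype(np.int64)
    terms = pd.Series(
        [orf_to_term.get(orf, UNANNOTATED) for orf in counts.index],
        index=counts.index,
    )
    if (terms != UNANNOTATED).sum() == 0:
        warnings.warn("no annotated ORFs: cluster table is empty")
    out = counts.groupby(terms).sum()
    out.index.name = orf_counts.index.name or "feature_id"
    return out


def poscounts_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors tolerant of zeros ("poscounts").

    Per feature i the reference is ``g_i = exp(sum_j log c_ij over c_ij > 0
    / n_samples)`` (zeros excluded from the sum but the denominator counts
    all samples); per sample j the factor is the median over features with
    ``g_i > 0`` and ``c_ij > 0`` of ``c_ij / g_i``.  Factors are divided by
    their geometric mean so they multiply to 1, fixing the scale the
    median-of-ratios construction leaves free.
    """
    arr = counts.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    if (arr.sum(axis=0) == 0).any():
        bad = counts.columns[arr.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    n_samples = arr.shape[1]
    with np.errstate(divide="ignore"):
        logs = np.where(arr > 0, np.log(arr), 0.0)
    g = np.exp(logs.sum(axis=1) / n_samples)
    factors = np.empty(n_samples)
    for j in range(n_samples):
        mask = (g > 0) & (arr[:, j] > 0)
        if not mask.any():
            raise ValueError(
                f"sample {counts.columns[j]!r} shares no positive feature with "
                "the reference"
            )
        factors[j] = np.median(arr[mask, j] / g[mask])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def rarefied_richness(
    cluster_counts: pd.DataFrame,
    depth: int = 100_000,
    seed: int | np.random.Generator = 0,
    exclude: Iterable[str] = (UNANNOTATED,),
) -> pd.Series:
    """Observed distinct gene clusters after downsampling to a common depth.

    Each sample's assigned-cluster reads are subsampled without replacement
    (multivariate hypergeometric draw) to ``depth`` reads and the number of
    clusters still observed is counted.  Deterministic given ``seed``.
    Samples with fewer than ``depth`` assigned reads are excluded with a
    warning.  Rows named in ``exclude`` (the unannotated pool by default) do
    not count as assigned clusters.
    """
    rng = np.random.default_rng(seed)
    counts = cluster_counts.drop(
        index=[t for t in exclude if t in cluster_counts.index]
    ).astype(np.int64)
    richness: dict[str, int] = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has only {total} assigned reads "
                f"(< depth {depth}); excluded from richness"
            )
            continue
        sub = rng.multivariate_hypergeometric(col, depth)
        richness[sample] = int((sub > 0).sum())
    return pd.Series(richness, name="richness", dtype=int)


class MetaboliteNormalizer(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`normalize_metabolites`."""

    def __init__(
        self,
        batch: Mapping[str, str] | None = None,
        qc_samples: Iterable[str] = (),
        log_base: float | None = None,
    ) -> None:
        self.batch = batch
        self.qc_samples = qc_samples
        self.log_base = log_base

    def fit(self, X: pd.DataFrame, y: None = None) -> "MetaboliteNormalizer":
        self.feature_ids_ = X.index
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        batch = self.batch if self.batch is not None else {c: "batch1" for c in X.columns}
        return normalize_metabolites(X, batch, self.qc_samples, self.log_base)


class ProteinPreparer(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`prepare_proteins`."""

    def __init__(
        self, max_missing_fraction: float = 0.05, log_base: float | None = None
    ) -> None:
        self.max_missing_fraction = max_missing_fraction
        self.log_base = log_base

    def fit(self, X: pd.DataFrame, y: None = None) -> "ProteinPreparer":
        frac = X.astype(float).isna().mean(axis=1)
        self.kept_features_ = X.index[frac < self.max_missing_fraction]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return prepare_proteins(X, self.max_missing_fraction, self.log_base)


class PoscountsNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios count normalizer; ``fit`` learns size factors.

    ``transform`` divides each sample's counts by its size factor, yielding
    library-size-corrected (generally non-integer) abundances.
    """

    def fit(self, X: pd.DataFrame, y: None = None) -> "PoscountsNormalizer":
        self.size_factors_ = poscounts_size_factors(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.div(self.size_factors_, axis=1)
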