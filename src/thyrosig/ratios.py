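"""Log2 tumor/normal-pool ratios and qRT-PCR delta-Ct normalization.

The microarray side expresses every tumor sample relative to the mean of the
normal-pool samples on the log2 scale (arithmetic mean of log2 intensities,
i.e. geometric mean of raw intensities). The qPCR side converts cycle
thresholds to log2 expression ratios via the ΔΔCt method with two reference
genes and an assumed amplification efficiency of 2 per cycle.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import ConfigurationError, DataError

__all__ = ["LogRatioTransformer", "log_ratio", "qpcr_log_ratio"]


class LogRatioTransformer(TransformerMixin, BaseEstimator):
    """Center log2 expression profiles on a normal-reference pool.

    sklearn-style transformer over arrays of shape (n_samples, n_features):
    ``fit`` learns the per-feature mean of the reference (normal pool)
    samples; ``transform`` subtracts it, yielding log2(tumor / pool) ratios.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=1)
        self.n_features_in_ = X.shape[1]
        self.reference_mean_ = X.mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_mean_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X - self.reference_mean_


def log_ratio(matrix: pd.DataFrame, sheet: pd.Series) -> pd.DataFrame:
    """Convert a log2 intensity matrix into log2 tumor/pool ratios.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Probes x samples log2 intensities; must contain at least one sample
        labelled NORMAL in the sheet and at least one tumor sample.
    sheet : pandas.Series
        sample_id -> group label; NORMAL samples form the reference pool.

    Returns
    -------
    pandas.DataFrame
        Probes x tumor-samples matrix of log2 ratios: each tumor value minus
        the probe's mean over the NORMAL samples. NORMAL columns are dropped;
        tumor column order is preserved.
    """
    missing = [s for s in matrix.columns if s not in sheet.index]
    if missing:
        raise DataError(f"samples missing from sample sheet: {missing}")
    groups = sheet.loc[matrix.columns]
    normal_cols = list(matrix.columns[(groups == "NORMAL").to_numpy()])
    tumor_cols = list(matrix.columns[(groups != "NORMAL").to_numpy()])
    if not normal_cols:
        raise ConfigurationError("no NORMAL samples to form the reference pool")
    if not tumor_cols:
        raise ConfigurationError("no tumor samples in the matrix")
    tr = LogRatioTransformer().fit(matrix[normal_cols].to_numpy().T)
    ratios = tr.transform(matrix[tumor_cols].to_numpy().T).T
    return pd.DataFrame(ratios, index=matrix.index, columns=tumor_cols)


def _delta_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, sample) ΔCt = Ct_target - mean(Ct_ref1, Ct_ref2).

    Replicate rows (technical triplicates) are averaged per Ct column first.
    """
    agg = table.groupby(["gene", "sample"], sort=False)[
        ["ct_target", "ct_ref1", "ct_ref2"]
    ].mean()
    dct = agg["ct_target"] - (agg["ct_ref1"] + agg["ct_ref2"]) / 2.0
    return dct.rename("delta_ct").reset_index()


def qpcr_log_ratio(
    tumor: pd.DataFrame, normal_reference: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """qRT-PCR log2 expression ratios of tumor samples versus normal tissue.

    With amplification efficiency 2 per cycle, expression is proportional to
    2^(-ΔCt), so the log2 ratio of a tumor sample to the normal reference is
    -(ΔCt_tumor - mean ΔCt_normal), computed per gene.

    Returns
    -------
    per_sample : pandas.DataFrame
        Genes x tumor-samples log2 ratios.
    mean : pandas.Series
        Per-gene mean over tumor samples.
    """
    genes_t = set(tumor["gene"])
    genes_n = set(normal_reference["gene"])
    if genes_t != genes_n:
        raise DataError(
            "tumor and normal qPCR tables must cover the same genes; "
            f"difference: {sorted(genes_t ^ genes_n)}"
        )
    dct_t = _delta_ct(tumor)
    dct_n = _delta_ct(normal_reference).groupby("gene", sort=False)["delta_ct"].mean()
    per_sample = dct_t.pivot(index="gene", columns="sample", values="delta_ct")
    # preserve first-appearance order of genes and samples from the tumor table
    gene_order = list(dict.fromkeys(tumor["gene"]))
    sample_order = list(dict.fromkeys(tumor["sample"]))
    per_sample = per_sample.reindex(index=gene_order, columns=sample_order)
    ratios = -(per_sample.sub(dct_n, axis=0))
    ratios.columns.name = None
    ratios.index.name = "gene"
    return ratios, ratios.mean(axis=1).rename("mean_log2_ratio")
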