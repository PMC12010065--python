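"""PCA embedding of the neuron feature table and pairwise separability.

Undefined cells (burst/oscillation metrics of neurons lacking the phenomenon)
are imputed as 0 and the binary phenomenon flags are kept as features, so the
*absence* of a phenomenon is encoded explicitly rather than discarded.
Features are z-scored before PCA; constant features are dropped with a
warning. Pairwise separability of two gene populations on the first two PCs
is quantified with the Calinski-Harabasz score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .features import FLAGS, METRICS

logger = logging.getLogger("pallidyn")


@dataclass
class Embedding:
    scores: pd.DataFrame            # neurons x PCs, with gene labels
    loadings: pd.DataFrame          # features x PCs (orthonormal eigenvectors)
    correlation_loadings: pd.DataFrame  # eigenvectors scaled by singular values: corr(feature, PC)
    explained_variance_ratio: np.ndarray
    feature_names: list[str]


_ID_COLUMNS = ("unit_id", "patient_id", "gene", "discharge", "duration_s")


def design_matrix(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Numeric design matrix: continuous metrics with NaN -> 0 plus 0/1 flags.

    Defaults to the canonical metric/flag registry; a table without those
    columns (e.g. an external feature table) falls back to all numeric and
    boolean columns except identifiers.
    """
    if features is None:
        features = [f for f in METRICS + FLAGS if f in table.columns]
        if not features:
            features = [c for c in table.columns
                        if c not in _ID_COLUMNS and (table[c].dtype == bool or
                                                     pd.api.types.is_numeric_dtype(table[c]))]
    X = pd.DataFrame(index=table.index)
    for f in features:
        if f not in table.columns:
            continue
        col = table[f]
        X[f] = col.astype(float).fillna(0.0) if col.dtype != bool else col.astype(float)
    return X


def pca_embed(table: pd.DataFrame, features: list[str] | None = None, loading_min: float = 0.5) -> tuple[Embedding, list[str]]:
    """Standardize and embed the feature table; return the embedding and the
    high-loading feature set (|loading| >= ``loading_min`` on PC1 or PC2).

    The high-loading cut is applied to the correlation loadings (eigenvectors
    scaled by the component standard deviations) — the scale on which a 0.5
    cut is the field's convention, since orthonormal eigenvector entries
    shrink with the feature count.
    """
    X = design_matrix(table, features)
    sd = X.std(ddof=0)
    constant = list(sd.index[sd == 0])
    if constant:
        logger.warning("dropping constant features: %s", constant)
        X = X.drop(columns=constant)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 non-constant features")
    Z = (X - X.mean()) / X.std(ddof=0)
    pca = PCA()
    scores = pca.fit_transform(Z.to_numpy())
    pc_names = [f"PC{i+1}" for i in range(scores.shape[1])]
    eigvec = pd.DataFrame(pca.components_.T, index=X.columns, columns=pc_names)
    corr = eigvec * np.sqrt(pca.explained_variance_)
    emb = Embedding(
        scores=pd.DataFrame(scores, columns=pc_names, index=table.index).assign(gene=table["gene"].values),
        loadings=eigvec,
        correlation_loadings=corr,
        explained_variance_ratio=pca.explained_variance_ratio_,
        feature_names=list(X.columns),
    )
    pcs = [c for c in ("PC1", "PC2") if c in corr.columns]
    L = corr[pcs].abs()
    high = list(L.index[(L >= loading_min).any(axis=1)])
    return emb, high


def ch_separability(embedding: Embedding, gene_a: str, gene_b: str) -> float:
    """Calinski-Harabasz score of the two gene clouds on PC1-PC2.

    CH = [B/(k-1)] / [W/(N-k)] with k=2 groups; +inf when the within-group
    dispersion is exactly zero (duplicated points).
    """
    sc = embedding.scores
    pts = {g: sc.loc[sc["gene"] == g, ["PC1", "PC2"]].to_numpy() for g in (gene_a, gene_b)}
    for g, x in pts.items():
        if x.shape[0] < 2:
            raise ValueError(f"gene {g} has fewer than 2 neurons")
    N = sum(x.shape[0] for x in pts.values())
    grand = np.vstack(list(pts.values())).mean(axis=0)
    B = sum(x.shape[0] * np.sum((x.mean(axis=0) - grand) ** 2) for x in pts.values())
    W = sum(np.sum((x - x.mean(axis=0)) ** 2) for x in pts.values())
    if W == 0:
        return float("inf")
    return float((B / (2 - 1)) / (W / (N - 2)))


def ch_matrix(embedding: Embedding) -> pd.DataFrame:
    """Pairwise CH scores for all gene pairs present in the embedding."""
    genes = sorted(embedding.scores["gene"].unique())
    out = pd.DataFrame(np.nan, index=genes, columns=genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            v = ch_separability(embedding, a, b)
            out.loc[a, b] = out.loc[b, a] = v
    return out
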