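"""Immune-phenotypic similarity: PCA embedding, biplot arrows, group separation.

PCA is computed on the centered standardized matrix. For Euclidean
distances this is exactly equivalent to principal coordinates analysis
(classical MDS) up to component signs, so "PCA on Euclidean distances" and
"PCA on the data matrix" describe the same embedding; the equivalence is
asserted in the test suite against an independent PCoA implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PcaEmbedding:
    scores: pd.DataFrame  # subjects x components
    loadings: pd.DataFrame  # variables x components
    explained_ratio: np.ndarray  # variance shares, sums to 1 over all components
    eigenvalues: np.ndarray


def pca_embed(table_df: pd.DataFrame, subset: list[str] | None = None,
              n_components: int | None = None) -> PcaEmbedding:
    """Eigen-decomposition of the covariance of the selected variables.

    Sign convention: on each component, the variable with the largest
    absolute loading is made positive, so embeddings are deterministic.
    Variance shares are computed over all components (they sum to 1).
    """
    df = table_df[subset] if subset is not None else table_df
    if df.shape[1] < 2:
        raise ValueError("need at least 2 variables to embed")
    if df.isna().to_numpy().any():
        raise ValueError("table must be complete (imputed) for PCA")
    X = df.to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=1)
    zero = [str(v) for v, s in zip(df.columns, sds) if s == 0]
    if zero:
        raise ValueError(f"zero-variance variables in subset: {zero}")
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    ratio = eig / total if total > 0 else eig
    # deterministic signs
    for j in range(Vt.shape[0]):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    m = len(eig) if n_components is None else min(n_components, len(eig))
    comp_names = [f"PC{i+1}" for i in range(m)]
    scores = pd.DataFrame((U[:, :m] * s[:m]), index=df.index, columns=comp_names)
    loadings = pd.DataFrame(Vt[:m].T, index=df.columns, columns=comp_names)
    return PcaEmbedding(scores, loadings, ratio, eig)


def biplot_projection(embedding: PcaEmbedding, markers: list[str], scale: float = 1.0) -> pd.DataFrame:
    """Arrow coordinates (loadings x scale) on the PC1/PC2 plane for selected markers."""
    missing = [m for m in markers if m not in embedding.loadings.index]
    if missing:
        raise KeyError(f"markers not in the embedded variable set: {missing}")
    arrows = embedding.loadings.loc[markers, ["PC1", "PC2"]] * scale
    arrows.columns = ["arrow_pc1", "arrow_pc2"]
    return arrows


def group_separation(scores: pd.DataFrame, labels: np.ndarray,
                     n_components: int = 2, n_bins: int = 20) -> dict:
    """Per-PC group histograms and standardized mean differences.

    The overall separation statistic is the Euclidean norm of the per-PC
    standardized mean differences over the first ``n_components``
    components (invariant to PC sign flips).
    """
    y = np.asarray(labels)
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    comp = scores.columns[:n_components]
    smds = {}
    hists = {}
    for c in comp:
        a = scores.loc[y == groups[0], c].to_numpy()
        b = scores.loc[y == groups[1], c].to_numpy()
        pooled = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                         / (len(a) + len(b) - 2))
        smds[c] = float(abs(a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
        edges = np.histogram_bin_edges(scores[c].to_numpy(), bins=n_bins)
        hists[c] = {
            str(groups[0]): np.histogram(a, bins=edges)[0],
            str(groups[1]): np.histogram(b, bins=edges)[0],
            "edges": edges,
        }
    separation = float(np.sqrt(sum(v**2 for v in smds.values())))
    return {"smd": smds, "separation": separation, "histograms": hists}
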