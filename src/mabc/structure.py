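"""Population-structure checks via PCA of the genotype dosage matrix.

Genotypes are encoded as alt-allele dosages (0/1/2, missing imputed to
the marker mean), columns centered, and the scores taken from the
singular value decomposition.  On centered data this is equivalent (up
to scale) to the eigendecomposition of the genetic relationship matrix
used by the common SNP PCA packages.  In a backcross panel the first
component is dominated by the recurrent/donor ancestry gradient, so
progeny fall between the F1 controls and the recurrent parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genio import GenotypeMatrix, MISSING, SampleSheet

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "dosage_encode", "pca", "plot_pca"]


@dataclass
class PCAResult:
    """PCA scores and per-component variance explained (%)."""

    scores: np.ndarray              # (n_samples, k)
    variance_explained: np.ndarray  # (k,), percentages, nonincreasing
    loadings: np.ndarray            # (k, n_markers)
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def dosage_encode(matrix: GenotypeMatrix) -> np.ndarray:
    """Samples x markers alt-allele dosage matrix (float).

    hom-ref -> 0, het -> 1, hom-alt -> 2; missing calls are imputed to
    the marker's mean dosage (all-missing markers to 0 — a constant
    column that centering removes).  The imputed count is logged.
    """
    calls = matrix.calls
    X = calls.astype(float)
    miss = calls == MISSING
    n_imputed = int(miss.sum())
    if n_imputed:
        valid = ~miss
        n_valid = valid.sum(axis=0)
        col_sum = np.where(valid, X, 0.0).sum(axis=0)
        col_mean = np.divide(col_sum, n_valid, out=np.zeros_like(col_sum), where=n_valid > 0)
        X[miss] = np.broadcast_to(col_mean, X.shape)[miss]
        logger.info("dosage_encode: imputed %d missing calls to marker means", n_imputed)
    return X


def pca(
    X: np.ndarray,
    n_components: int = 10,
    sample_ids: "list[str] | None" = None,
    scale: bool = False,
) -> PCAResult:
    """PCA of a dosage matrix via SVD of the centered columns.

    ``variance_explained_k = 100 * sigma_k^2 / sum(sigma^2)``.  Unit-
    variance scaling is off by default.  Component signs are fixed by
    making each component's largest-magnitude loading positive, so
    fixtures are stable across runs.  Requesting more components than
    ``min(n_samples, n_markers)`` truncates with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 2 samples and >= 1 marker")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    k_max = min(Xc.shape)
    if n_components > k_max:
        logger.warning("pca: truncating %d requested components to %d", n_components, k_max)
        n_components = k_max
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    var_exp = 100.0 * (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    return PCAResult(
        scores=scores,
        variance_explained=np.asarray(var_exp, dtype=float),
        loadings=loadings,
        sample_ids=list(sample_ids) if sample_ids is not None else [],
    )


def plot_pca(result: PCAResult, sheet: SampleSheet, path: str) -> None:
    """PC1/PC2 scatter colored by sample role (written to ``path``)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roles = [
        sheet.table.set_index("sample_id")["role"].get(s, "progeny")
        for s in result.sample_ids
    ]
    fig, ax = plt.subplots(figsize=(6, 5))
    for role in sorted(set(roles)):
        idx = [i for i, r in enumerate(roles) if r == role]
        ax.scatter(result.scores[idx, 0], result.scores[idx, 1], label=role, s=25, alpha=0.8)
    ve = result.variance_explained
    ax.set_xlabel(f"PC1 ({ve[0]:.2f}%)")
    if result.n_components > 1:
        ax.set_ylabel(f"PC2 ({ve[1]:.2f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
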