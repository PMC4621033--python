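"""Between-study concordance of PDR profiles and PCA-derived study weights.

The concordance of two studies' association patterns is the Kendall tau-b
rank correlation between their PDR profiles over the genes of the set
(tau-b handles the ties that arise when a PDR is exactly 0). The pairwise
tau matrix is condensed by principal component analysis: the first
eigenvector PC1 carries each study's loading on the common (hidden)
association pattern, and the largest eigenvalue EV1 measures how much of
the between-study variance that common pattern explains. EV1/n_s is the
"effective number of studies" and the study weights are

    w_s = PC1_s / sum_j PC1_j * EV1 / n_s,

so that sum_s w_s = EV1/n_s. With perfect pairwise concordance EV1 = n_s
and every weight is 1/n_s; with discordant studies weights shrink and may
turn negative (the permutation null of the test absorbs this).

The ``_batch`` helpers operate on stacks of profile matrices; they exist
because the permutation null recomputes tau + PCA weights for every one of
thousands of randomly drawn gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["StudyWeightSet", "kendall_matrix", "pca_weights"]

# |sum(PC1)| below this is treated as the degenerate (undefined) case
_DEGENERATE_TOL = 1e-8


@dataclass(frozen=True)
class StudyWeightSet:
    """First-PC loadings, leading eigenvalue and the resulting study weights."""

    pc1: np.ndarray
    ev1: float
    weights: np.ndarray

    @property
    def n_studies(self) -> int:
        return len(self.weights)

    @property
    def eff_studies(self) -> float:
        """EV1 / n_s, the effective number of studies as a fraction of n_s."""
        return self.ev1 / self.n_studies


def _kendall_matrices_batch(profiles: np.ndarray) -> np.ndarray:
    """Pairwise Kendall tau-b between study columns, batched.

    Parameters
    ----------
    profiles : ndarray (B, n_genes, n_studies)

    Returns
    -------
    ndarray (B, n_studies, n_studies), symmetric with unit diagonal.
    Constant columns (no rank information) get tau = 0 off-diagonal.
    """
    B, g, s = profiles.shape
    iu, ju = np.triu_indices(g, 1)
    signs = np.sign(profiles[:, iu, :] - profiles[:, ju, :])
    # concordant-minus-discordant counts; pairs tied in either column drop out
    K = np.einsum("bps,bpt->bst", signs, signs)
    untied = (signs != 0.0).sum(axis=1).astype(float)  # n0 - ties, per column
    denom = np.sqrt(untied[:, :, None] * untied[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(denom > 0.0, K / np.where(denom == 0.0, 1.0, denom), 0.0)
    idx = np.arange(s)
    tau[:, idx, idx] = 1.0
    return tau


def kendall_matrix(profiles, method: str = "kendall") -> np.ndarray:
    """Pairwise concordance matrix between study PDR profiles.

    Parameters
    ----------
    profiles : array-like or DataFrame, shape (n_genes, n_studies)
        One column per study. At least 2 studies and 2 genes.
    method : {"kendall", "spearman", "pearson"}
        Kendall tau-b is the default; the alternatives are provided for
        sensitivity analyses.

    Returns
    -------
    ndarray (n_studies, n_studies), symmetric, unit diagonal, entries in
    [-1, 1]. A constant study column carries no rank information; its
    correlations are set to 0 with a warning.
    """
    X = profiles.to_numpy(dtype=float) if isinstance(profiles, pd.DataFrame) else np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a (>=2 genes) x (>=2 studies) profile matrix")
    constant = np.all(X == X[0, :], axis=0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} study column(s) are constant; their "
            "correlations are set to 0",
            stacklevel=2,
        )
    if method == "kendall":
        return _kendall_matrices_batch(X[None])[0]
    if method == "spearman":
        X = rankdata(X, axis=0)
    elif method != "pearson":
        raise ValueError("method must be 'kendall', 'spearman' or 'pearson'")
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = np.corrcoef(X, rowvar=False)
    cm = np.where(np.isnan(cm), 0.0, cm)
    np.fill_diagonal(cm, 1.0)
    return cm


def _pca_weights_batch(cms: np.ndarray):
    """Leading-eigenvector study weights for a stack of tau matrices.

    Returns ``(weights (B, s), ev1 (B,))``. Draws whose PC1 loadings sum
    to ~0 get the equal-split fallback, as in :func:`pca_weights`.
    """
    s = cms.shape[-1]
    evals, evecs = np.linalg.eigh(cms)
    ev1 = evals[..., -1]
    pc1 = evecs[..., -1]
    total = pc1.sum(axis=-1)
    flip = np.where(total < 0.0, -1.0, 1.0)
    pc1 = pc1 * flip[..., None]
    total = np.abs(total)
    degenerate = total < _DEGENERATE_TOL
    safe_total = np.where(degenerate, 1.0, total)
    weights = pc1 / safe_total[..., None] * (ev1 / s)[..., None]
    if degenerate.any():
        # PC1 orthogonal to the ones-vector: Eq-5 normalization undefined;
        # deterministic equal split keeps sum(w) = EV1/n_s
        equal = (ev1 / (s * s))[..., None] * np.ones(s)
        weights = np.where(degenerate[..., None], equal, weights)
    return weights, ev1


def pca_weights(cm) -> StudyWeightSet:
    """Derive study weights from a concordance matrix by PCA.

    The tau matrix need not be positive semidefinite; the symmetric
    eigendecomposition is used as-is and only the largest eigenvalue and
    its eigenvector are consumed. The eigenvector sign is fixed so the
    loading sum is positive (weights of concordant studies come out
    positive); weights need not lie in [0, 1].

    When the PC1 loadings sum to (numerically) zero the normalized-load
    construction is undefined. This is reachable in routine inputs -- two
    studies with negative tau have PC1 = (1, -1)/sqrt(2), and equal
    negative pairwise taus leave the top eigenspace orthogonal to the
    ones-vector -- so instead of failing, the weights deterministically
    fall back to the equal split ``w_s = EV1 / n_s^2`` (warned). The
    fallback preserves ``sum(w) = EV1/n_s`` and is applied identically in
    the permutation null, which therefore absorbs the convention.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("concordance matrix must be square")
    if not np.allclose(cm, cm.T, atol=1e-8):
        raise ValueError("concordance matrix must be symmetric")
    if not np.allclose(np.diag(cm), 1.0, atol=1e-8):
        raise ValueError("concordance matrix must have a unit diagonal")
    n = cm.shape[0]
    evals, evecs = np.linalg.eigh(cm)
    ev1 = float(evals[-1])
    pc1 = evecs[:, -1]
    total = float(pc1.sum())
    if total < 0.0:
        pc1 = -pc1
        total = -total
    if total < _DEGENERATE_TOL:
        warnings.warn(
            "PC1 loadings sum to zero (discordant studies); falling back to "
            "the equal weight split EV1/n_s^2",
            stacklevel=2,
        )
        weights = np.full(n, ev1 / (n * n))
        return StudyWeightSet(pc1=pc1, ev1=ev1, weights=weights)
    weights = pc1 / total * (ev1 / n)
    if np.abs(weights).max() > 10.0:
        warnings.warn(
            "PC1 loadings have mixed signs with a small sum; study weights "
            f"are large (max |w| = {np.abs(weights).max():.3g}) and the "
            "statistic may be unstable",
            stacklevel=2,
        )
    return StudyWeightSet(pc1=pc1, ev1=ev1, weights=weights)
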