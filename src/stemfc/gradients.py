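"""Diffusion map embedding of connectivity-similarity matrices.

The leading embedding component ("gradient 1") orders nodes along the
dominant axis of connectivity similarity; for cortical similarity of
brainstem-connectivity profiles it recovers the unimodal-transmodal axis.

Construction follows the gradient-mapping convention: row-wise sparsification
of the similarity matrix (top 10 % of entries per row by default),
normalized-angle cosine affinity between sparsified rows, alpha-normalised
diffusion operator
(alpha = 0.5, anisotropic normalisation that discounts sampling density),
eigendecomposition of the Markov operator, and the trivial stationary
component dropped.  Components are defined only up to a global sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .connectome import Connectome, DegreeMap
from .exceptions import DataError, ParameterError
from .nulls import SpinSet, spin_pvalue

__all__ = ["GradientSet", "diffusion_map_embedding", "compare_gradients", "pole_degree"]


@dataclass
class GradientSet:
    """Embedding scores (component x node) with eigenvalues and parameters."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    alpha: float
    sparsity: float
    diffusion_time: float
    stationary_eigenvalue: float  # eigenvalue of the dropped trivial component

    @property
    def n_components(self) -> int:
        return self.scores.shape[0]

    def gradient(self, k: int = 1) -> np.ndarray:
        """1-based component accessor: gradient(1) is the leading gradient."""
        return self.scores[k - 1]


def _sparsify_rows(mat: np.ndarray, sparsity: float) -> np.ndarray:
    """Keep the top (1 - sparsity) fraction of entries per row, zero the rest."""
    if sparsity == 0:
        return mat.copy()
    n = mat.shape[1]
    keep = max(1, int(np.ceil((1.0 - sparsity) * n)))
    out = np.zeros_like(mat)
    idx = np.argpartition(mat, n - keep, axis=1)[:, n - keep:]
    rows = np.arange(mat.shape[0])[:, None]
    out[rows, idx] = mat[rows, idx]
    return out


def _cosine_affinity(rows: np.ndarray) -> np.ndarray:
    """Normalized-angle affinity: 1 - arccos(cosine)/pi, in [0, 1]."""
    norms = np.linalg.norm(rows, axis=1)
    if np.any(norms == 0):
        raise DataError("zero row after sparsification")
    cos = np.clip((rows @ rows.T) / np.outer(norms, norms), -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    np.fill_diagonal(aff, 1.0)
    return aff


def diffusion_map_embedding(similarity: np.ndarray, n_components: int = 10,
                            alpha: float = 0.5, sparsity: float = 0.9,
                            diffusion_time: float = 0.0) -> GradientSet:
    """Diffusion map embedding of a square symmetric similarity matrix.

    With ``diffusion_time = 0`` the components are scaled by
    ``lambda / (1 - lambda)`` (the multiscale convention); otherwise by
    ``lambda ** t``.  Raises if the sparsified affinity graph is disconnected.
    """
    W = np.asarray(similarity, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n) or np.abs(W - W.T).max() > 1e-10:
        raise ParameterError("similarity must be square and symmetric")
    if not (0 < n_components < n):
        raise ParameterError("n_components must lie in (0, n)")
    if not (0.0 <= alpha <= 1.0) or not (0.0 <= sparsity < 1.0):
        raise ParameterError("alpha in [0,1] and sparsity in [0,1) required")

    aff = _cosine_affinity(_sparsify_rows(W, sparsity))
    n_comp, lab = connected_components(aff > 0, directed=False)
    if n_comp > 1:
        raise DataError("affinity graph disconnected; component sizes "
                        f"{np.bincount(lab).tolist()}")

    d = aff.sum(axis=1)
    L = aff / np.outer(d ** alpha, d ** alpha)
    d1 = L.sum(axis=1)
    # symmetric conjugate of the Markov operator D1^-1 L
    Msym = L / np.outer(np.sqrt(d1), np.sqrt(d1))
    evals, evecs = np.linalg.eigh(Msym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(d1)[:, None]
    psi /= psi[:, [0]]  # normalise against the stationary component
    lam = evals[1: n_components + 1]
    if diffusion_time == 0:
        scale = lam / (1.0 - np.clip(lam, None, 1.0 - 1e-12))
    else:
        scale = lam ** diffusion_time
    scores = (psi[:, 1: n_components + 1] * scale).T
    return GradientSet(scores=scores, eigenvalues=lam, alpha=alpha,
                       sparsity=sparsity, diffusion_time=diffusion_time,
                       stationary_eigenvalue=float(evals[0]))


def compare_gradients(g1: np.ndarray, g2: np.ndarray, spins: SpinSet,
                      absolute: bool = False) -> tuple[float, float]:
    """Spearman correlation of two gradients with a spin-test p-value.

    Gradients are sign-ambiguous; with ``absolute=True`` the comparison (and
    the null counting inside the spin test, which is two-sided on |rho|
    already) is reported as |rho|.
    """
    rho, p = spin_pvalue(np.asarray(g1, float), np.asarray(g2, float), spins,
                         statistic="spearman")
    return (abs(rho) if absolute else rho), p


def pole_degree(fc: Connectome, gradient: np.ndarray,
                ) -> tuple[DegreeMap, DegreeMap]:
    """Brainstem weighted degree toward each pole of a cortical gradient.

    Returns (negative-pole, positive-pole) maps: per-brainstem-node sums of FC
    with the negatively and positively scored cortical regions.  Nodes scoring
    exactly zero belong to neither pole.
    """
    gradient = np.asarray(gradient, dtype=float)
    ctx = fc.class_indices("cortex")
    bs = fc.class_indices("brainstem")
    if len(gradient) != len(ctx):
        raise ParameterError("gradient must score every cortical node")
    neg = ctx[gradient < 0]
    pos = ctx[gradient > 0]
    if neg.size == 0 or pos.size == 0:
        raise DataError("gradient must have both signs")
    labels = [fc.node_labels[i] for i in bs]
    neg_map = DegreeMap(fc.matrix[np.ix_(bs, neg)].sum(axis=1), labels,
                        seed_class="brainstem", target_class="cortex")
    pos_map = DegreeMap(fc.matrix[np.ix_(bs, pos)].sum(axis=1), labels,
                        seed_class="brainstem", target_class="cortex")
    return neg_map, pos_map


def orient_gradient(gradient: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip a sign-ambiguous gradient so it correlates positively with a
    reference map (e.g. the planted axis or a degree map)."""
    rho = stats.spearmanr(gradient, reference)[0]
    return -gradient if rho < 0 else gradient
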