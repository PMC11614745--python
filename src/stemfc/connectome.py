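"""Functional connectome construction and hub analyses.

Functional connectivity (FC) is the Pearson correlation between the cleaned
time series of every pair of regions.  Group connectomes are elementwise means
of raw per-subject correlations; the Fisher z transform enters only the
one-sample t-test used for edge thresholding.  Weighted degree (row sums of an
FC block) is the hub measure; distance-FC profiles, split-half reliability and
class-binned ANOVAs reproduce the standard cohort-level characterisations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DataError, ParameterError
from .preprocess import TimeSeriesMatrix

__all__ = [
    "Connectome",
    "DegreeMap",
    "functional_connectivity",
    "group_average",
    "ttest_threshold",
    "weighted_degree",
    "distance_fc_profile",
    "split_half_reliability",
    "class_anova",
]


@dataclass
class Connectome:
    """Symmetric node x node correlation matrix with node metadata."""

    matrix: np.ndarray
    node_labels: list[str]
    node_class: list[str] = field(default_factory=list)
    hemisphere: list[str] = field(default_factory=list)
    subject_id: str = "group"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ParameterError("matrix must be square")
        if np.abs(self.matrix - self.matrix.T).max() > 1e-12:
            raise DataError("matrix must be symmetric within 1e-12")
        if len(self.node_labels) != n:
            raise ParameterError("one label per node required")
        if not self.node_class:
            self.node_class = ["other"] * n
        if not self.hemisphere:
            self.hemisphere = ["midline"] * n

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def class_indices(self, node_class: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.node_class) if c == node_class],
                        dtype=int)

    def block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.matrix[np.ix_(rows, cols)]


@dataclass
class DegreeMap:
    """Weighted degree per seed node: row sums of an FC block."""

    values: np.ndarray
    seed_labels: list[str]
    seed_class: str = ""
    target_class: str = ""


def functional_connectivity(ts: TimeSeriesMatrix) -> Connectome:
    """Full Pearson correlation matrix of a subject's node time series."""
    if ts.n_timepoints < 3:
        raise ParameterError("need at least 3 timepoints")
    sd = ts.values.std(axis=1)
    if np.any(sd == 0):
        names = [ts.node_labels[i] for i in np.flatnonzero(sd == 0)]
        raise DataError(f"constant time series for nodes: {names}")
    mat = np.corrcoef(ts.values)
    mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 1.0)
    return Connectome(mat, list(ts.node_labels), list(ts.node_class),
                      list(ts.hemisphere), subject_id="subject")


def _check_same_nodes(connectomes: list[Connectome]) -> None:
    if not connectomes:
        raise ParameterError("empty connectome list")
    ref = connectomes[0].node_labels
    for c in connectomes[1:]:
        if c.node_labels != ref:
            raise DataError("connectomes have mismatched node sets")


def group_average(connectomes: list[Connectome]) -> Connectome:
    """Elementwise mean of raw Pearson r values across subjects."""
    _check_same_nodes(connectomes)
    mean = np.mean([c.matrix for c in connectomes], axis=0)
    ref = connectomes[0]
    return Connectome(mean, list(ref.node_labels), list(ref.node_class),
                      list(ref.hemisphere), subject_id="group")


def ttest_threshold(connectomes: list[Connectome], alpha: float = 0.0005,
                    n_comparisons: int = 1) -> tuple[Connectome, float]:
    """Group FC thresholded by a per-edge one-sample t-test on Fisher-z values.

    Each edge's subject-wise r values are Fisher transformed and tested
    two-tailed against zero; surviving edges (p <= alpha / n_comparisons) keep
    their group-average r, the rest are set to 0.  Pass the number of unique
    off-diagonal edges as ``n_comparisons`` for Bonferroni correction over the
    full edge set, or pre-divide ``alpha`` yourself.  Returns the thresholded
    connectome and the fraction of surviving edges.
    """
    _check_same_nodes(connectomes)
    if len(connectomes) < 3:
        raise ParameterError("need at least 3 subjects")
    stack = np.stack([c.matrix for c in connectomes])  # (s, n, n)
    n = stack.shape[1]
    iu = np.triu_indices(n, k=1)
    vals = stack[:, iu[0], iu[1]]
    if np.any(np.abs(vals) >= 1.0):
        s, e = np.argwhere(np.abs(vals) >= 1.0)[0]
        raise DataError(
            f"|r| = 1 at edge ({iu[0][e]}, {iu[1][e]}) of subject {s}: "
            "Fisher transform is infinite")
    z = np.arctanh(vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_1samp(z, 0.0, axis=0)
    p = np.nan_to_num(p, nan=1.0)
    thresh = alpha / max(int(n_comparisons), 1)
    if alpha >= 1.0 and n_comparisons <= 1:
        keep = np.ones_like(p, dtype=bool)
    else:
        keep = p <= thresh
    mean = np.mean(stack, axis=0)
    out = mean.copy()
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = ~keep
    mask |= mask.T
    out[mask] = 0.0
    ref = connectomes[0]
    surviving = float(keep.mean())
    return (Connectome(out, list(ref.node_labels), list(ref.node_class),
                       list(ref.hemisphere), subject_id="group-thresholded"),
            surviving)


def weighted_degree(fc: Connectome, seeds: np.ndarray, targets: np.ndarray) -> DegreeMap:
    """Sum of FC from each seed node over the target set (self-edges excluded)."""
    seeds = np.asarray(seeds, dtype=int)
    targets = np.asarray(targets, dtype=int)
    if targets.size == 0:
        raise ParameterError("empty target set")
    block = fc.matrix[np.ix_(seeds, targets)].copy()
    overlap = np.isin(seeds, targets)
    if overlap.any():
        for r, s in enumerate(seeds):
            hit = np.flatnonzero(targets == s)
            block[r, hit] = 0.0
    values = block.sum(axis=1)
    labels = [fc.node_labels[i] for i in seeds]
    sc = {fc.node_class[i] for i in seeds}
    tc = {fc.node_class[i] for i in targets}
    return DegreeMap(values, labels,
                     seed_class=sc.pop() if len(sc) == 1 else "mixed",
                     target_class=tc.pop() if len(tc) == 1 else "mixed")


def _block_pairs(fc: Connectome, centroids: np.ndarray,
                 rows: np.ndarray, cols: np.ndarray, within: bool,
                 ) -> tuple[np.ndarray, np.ndarray]:
    if within:
        iu = np.triu_indices(len(rows), k=1)
        f = fc.matrix[np.ix_(rows, rows)][iu]
        d = np.linalg.norm(centroids[rows][iu[0]] - centroids[rows][iu[1]], axis=1)
    else:
        f = fc.matrix[np.ix_(rows, cols)].ravel()
        d = np.linalg.norm(centroids[rows][:, None, :]
                           - centroids[cols][None, :, :], axis=-1).ravel()
    return f, d


def distance_fc_profile(fc: Connectome, centroids: np.ndarray,
                        ) -> dict[str, tuple[float, float]]:
    """Spearman rho (and two-sided p) of FC against Euclidean centroid distance
    for the within-cortex, brainstem-cortex and within-brainstem pair blocks."""
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (fc.n_nodes, 3):
        raise ParameterError("need one 3-D centroid per node")
    ctx = fc.class_indices("cortex")
    bs = fc.class_indices("brainstem")
    out: dict[str, tuple[float, float]] = {}
    for name, rows, cols, within in (
            ("within_cortex", ctx, ctx, True),
            ("brainstem_cortex", bs, ctx, False),
            ("within_brainstem", bs, bs, True)):
        f, d = _block_pairs(fc, centroids, rows, cols, within)
        if len(f) < 3:
            out[name] = (np.nan, np.nan)
            continue
        rho, p = stats.spearmanr(f, d)
        out[name] = (float(rho), float(p))
    return out


def split_half_reliability(connectomes: list[Connectome], n_splits: int = 100,
                           seed: int = 0) -> dict[str, np.ndarray]:
    """Split-half resampling of group statistics.

    Subjects are randomly split into two equal halves; for each split the two
    half-group statistics (group FC over unique edges, brainstem-to-cortex
    degree, cortex-to-brainstem degree) are Spearman-correlated.
    """
    _check_same_nodes(connectomes)
    n_sub = len(connectomes)
    if n_sub < 4 or n_sub % 2:
        raise ParameterError("need an even subject count >= 4")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ref = connectomes[0]
    ctx = ref.class_indices("cortex")
    bs = ref.class_indices("brainstem")
    iu = np.triu_indices(ref.n_nodes, k=1)
    out = {"fc": np.empty(n_splits), "brainstem_to_cortex": np.empty(n_splits),
           "cortex_to_brainstem": np.empty(n_splits)}
    for s in range(n_splits):
        perm = rng.permutation(n_sub)
        halves = [perm[: n_sub // 2], perm[n_sub // 2:]]
        stats_h = []
        for h in halves:
            g = group_average([connectomes[i] for i in h])
            stats_h.append((g.matrix[iu],
                            weighted_degree(g, bs, ctx).values,
                            weighted_degree(g, ctx, bs).values))
        out["fc"][s] = stats.spearmanr(stats_h[0][0], stats_h[1][0])[0]
        out["brainstem_to_cortex"][s] = stats.spearmanr(stats_h[0][1], stats_h[1][1])[0]
        out["cortex_to_brainstem"][s] = stats.spearmanr(stats_h[0][2], stats_h[1][2])[0]
    return out


def class_anova(values: np.ndarray, class_labels: list[str],
                ) -> tuple[float, float, dict[str, dict[str, float]]]:
    """One-way ANOVA of a per-node map binned by categorical class.

    Classes with fewer than 2 members are dropped with a warning.  Returns
    (F, two-sided p, per-class median/quartile summaries).
    """
    values = np.asarray(values, dtype=float)
    groups: dict[str, np.ndarray] = {}
    for c in sorted(set(class_labels)):
        idx = [i for i, cl in enumerate(class_labels) if cl == c]
        if len(idx) < 2:
            warnings.warn(f"class {c!r} has fewer than 2 members; dropped", stacklevel=2)
            continue
        groups[c] = values[idx]
    if len(groups) < 2:
        raise ParameterError("need at least 2 classes with >= 2 members")
    f, p = stats.f_oneway(*groups.values())
    summaries = {c: {"median": float(np.median(v)),
                     "q1": float(np.percentile(v, 25)),
                     "q3": float(np.percentile(v, 75)),
                     "n": int(len(v))}
                 for c, v in groups.items()}
    return float(f), float(p), summaries
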