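"""Signed-modularity community detection on connectivity-similarity networks.

Pipeline: the dominant brainstem weighted-degree pattern is regressed out of
each cortical region's brainstem FC profile; the residual block is correlated
(Spearman) across brainstem nuclei to give a signed similarity network; the
network is partitioned by a Louvain algorithm maximising the asymmetric signed
quality function

    Q(gamma) = (1/v+) sum_ij (w+_ij - gamma p+_ij) delta(s_i, s_j)
             - (1/(v+ + v-)) sum_ij (w-_ij - gamma p-_ij) delta(s_i, s_j)

where w+/w- are the positive/negative parts of W, s±_i their node strengths,
v± = sum_ij w±_ij the total (ordered-pair) strengths, and p±_ij = s±_i s±_j / v±
the configuration null.  Sums run over ordered node pairs including the
diagonal null terms p_ii (the input diagonal w_ii is zero).  For all-positive
W this reduces to Newman-Girvan modularity with resolution gamma.

Stability is assessed by repeating Louvain (randomised sweep order) and
building a consensus partition from the run co-assignment (agreement) matrix,
thresholded at its permutation-null expectation and re-clustered until
convergence; partition similarity uses the hypergeometric z-scored Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectome import Connectome, DegreeMap
from .exceptions import DataError, ParameterError

__all__ = [
    "SignedSimilarityNetwork",
    "Partition",
    "ConsensusResult",
    "GammaSweepTable",
    "residualize_against_degree",
    "similarity_matrix",
    "signed_modularity",
    "louvain_signed",
    "zrand",
    "consensus_partition",
    "gamma_sweep",
    "community_cortical_degree",
    "community_fit",
]


@dataclass
class SignedSimilarityNetwork:
    """Signed weight matrix with zero diagonal and its modularity bookkeeping."""

    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ParameterError("W must be square")
        if np.abs(self.W - self.W.T).max() > 1e-12:
            raise DataError("W must be symmetric within 1e-12")
        if np.abs(np.diag(self.W)).max() != 0.0:
            raise DataError("W must have an exactly zero diagonal")
        self.W_pos = np.clip(self.W, 0, None)
        self.W_neg = np.clip(-self.W, 0, None)
        self.s_pos = self.W_pos.sum(axis=1)
        self.s_neg = self.W_neg.sum(axis=1)
        self.v_pos = float(self.s_pos.sum())  # = 2 m+
        self.v_neg = float(self.s_neg.sum())  # = 2 m-
        if self.v_pos <= 0:
            raise DataError("modularity undefined: no positive weight (m+ = 0)")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class Partition:
    """Community labels 1..K per node; only label equality is meaningful."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        # canonicalise to consecutive 1..K by first appearance
        remap = {}
        for lab in self.labels:
            if lab not in remap:
                remap[lab] = len(remap) + 1
        self.labels = np.array([remap[lab] for lab in self.labels], dtype=int)
        del uniq

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())

    def members(self, community: int) -> np.ndarray:
        return np.flatnonzero(self.labels == community)


@dataclass
class ConsensusResult:
    partition: Partition
    run_partitions: list[Partition]
    zrand_mean: float
    zrand_variance: float
    gamma: float


@dataclass
class GammaSweepTable:
    gamma: np.ndarray
    zrand_mean: np.ndarray
    zrand_variance: np.ndarray
    n_communities: np.ndarray
    results: list[ConsensusResult]


# --------------------------------------------------------------------------
# similarity construction
# --------------------------------------------------------------------------

def residualize_against_degree(fc_block: np.ndarray, degree_pattern: np.ndarray,
                               ) -> np.ndarray:
    """Regress the dominant degree pattern out of every row of an FC block.

    Each cortical row (its profile over brainstem nuclei) is OLS-fitted on
    [intercept, pattern] and replaced by its residuals, which are therefore
    zero-mean and orthogonal to the pattern.
    """
    fc_block = np.asarray(fc_block, dtype=float)
    pattern = np.asarray(degree_pattern, dtype=float)
    if fc_block.shape[1] != len(pattern):
        raise ParameterError("pattern length must equal the block's column count")
    if np.ptp(pattern) == 0:
        raise DataError("degree pattern is constant")
    X = np.column_stack([np.ones(len(pattern)), pattern])
    beta, *_ = np.linalg.lstsq(X, fc_block.T, rcond=None)
    return fc_block - (X @ beta).T


def similarity_matrix(residual_block: np.ndarray, axis: str = "brainstem",
                      ) -> SignedSimilarityNetwork:
    """Pairwise Spearman correlation of residual connectivity profiles.

    ``axis='brainstem'`` correlates columns (how similarly two brainstem
    nuclei connect with the cortex); ``axis='cortex'`` correlates rows.  The
    diagonal is zeroed for network use.
    """
    residual_block = np.asarray(residual_block, dtype=float)
    profiles = residual_block.T if axis == "brainstem" else residual_block
    if axis not in ("brainstem", "cortex"):
        raise ParameterError(f"unknown axis {axis!r}")
    if profiles.shape[1] < 3:
        raise ParameterError("need at least 3 profile entries per node")
    const = np.flatnonzero(np.ptp(profiles, axis=1) == 0)
    if const.size:
        raise DataError(f"constant profile for node index {const.tolist()}")
    ranks = stats.rankdata(profiles, axis=1)
    sim = np.corrcoef(ranks)
    sim = 0.5 * (sim + sim.T)
    np.fill_diagonal(sim, 0.0)
    return SignedSimilarityNetwork(sim)


# --------------------------------------------------------------------------
# signed modularity and Louvain
# --------------------------------------------------------------------------

def _signed_q(w_pos: np.ndarray, w_neg: np.ndarray, labels: np.ndarray,
              gamma: float) -> float:
    """Q over ordered pairs incl. diagonal null terms; general (self-loop-
    capable) form used by both the public API and Louvain aggregation."""
    s_pos = w_pos.sum(axis=1)
    s_neg = w_neg.sum(axis=1)
    v_pos = s_pos.sum()
    v_neg = s_neg.sum()
    delta = labels[:, None] == labels[None, :]
    q = (w_pos[delta].sum() - gamma * (np.outer(s_pos, s_pos)[delta].sum()) / v_pos) / v_pos
    if v_neg > 0:
        q -= ((w_neg[delta].sum()
               - gamma * (np.outer(s_neg, s_neg)[delta].sum()) / v_neg)
              / (v_pos + v_neg))
    return float(q)


def signed_modularity(net: SignedSimilarityNetwork, partition: Partition,
                      gamma: float = 1.0) -> float:
    """Quality of a partition under the asymmetric signed modularity."""
    if partition.n_nodes != net.n_nodes:
        raise ParameterError("partition and network sizes differ")
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    return _signed_q(net.W_pos, net.W_neg, partition.labels, gamma)


def _louvain_one_level(w_pos: np.ndarray, w_neg: np.ndarray, gamma: float,
                       rng: np.random.Generator) -> np.ndarray:
    """One Louvain level: greedy node moves until no improvement."""
    n = w_pos.shape[0]
    s_pos = w_pos.sum(axis=1)
    s_neg = w_neg.sum(axis=1)
    v_pos = s_pos.sum()
    v_neg = s_neg.sum()
    labels = np.arange(n)
    # community strength totals (exclude nothing; k_i,c below excludes self)
    com_s_pos = s_pos.copy()
    com_s_neg = s_neg.copy()
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = labels[i]
            # detach i
            com_s_pos[ci] -= s_pos[i]
            com_s_neg[ci] -= s_neg[i]
            k_pos = np.bincount(labels, weights=w_pos[i], minlength=n)
            k_neg = np.bincount(labels, weights=w_neg[i], minlength=n)
            k_pos[ci] -= w_pos[i, i]
            k_neg[ci] -= w_neg[i, i]
            gain = (k_pos - gamma * s_pos[i] * com_s_pos / v_pos) / v_pos
            if v_neg > 0:
                gain -= (k_neg - gamma * s_neg[i] * com_s_neg / v_neg) / (v_pos + v_neg)
            # candidates: communities with any member (or i's own old one)
            best = -np.inf
            best_c = ci
            order = np.flatnonzero((com_s_pos > 0) | (com_s_neg > 0)
                                   | (np.arange(n) == ci))
            for c in order:  # lowest label wins ties -> determinism at fixed seed
                if gain[c] > best + 1e-12:
                    best = gain[c]
                    best_c = c
            if best_c != ci:
                improved = True
            labels[i] = best_c
            com_s_pos[best_c] += s_pos[i]
            com_s_neg[best_c] += s_neg[i]
    return labels


def _aggregate(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    uniq = np.unique(labels)
    onehot = (labels[:, None] == uniq[None, :]).astype(float)
    return onehot.T @ w @ onehot


def louvain_signed(net: SignedSimilarityNetwork, gamma: float = 1.0,
                   seed: int = 0) -> Partition:
    """Two-phase Louvain maximisation of the signed quality function.

    Node sweep order is randomised from ``seed``; ties in the best-move search
    go to the lowest community label, so a fixed seed gives a fixed partition.
    Returns a local optimum.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    w_pos, w_neg = net.W_pos.copy(), net.W_neg.copy()
    node_labels = np.arange(net.n_nodes)
    while True:
        level = _louvain_one_level(w_pos, w_neg, gamma, rng)
        uniq, level = np.unique(level, return_inverse=True)
        node_labels = level[node_labels]
        if len(uniq) == w_pos.shape[0]:  # no merge happened
            break
        w_pos = _aggregate(w_pos, level)
        w_neg = _aggregate(w_neg, level)
    return Partition(node_labels + 1)


# --------------------------------------------------------------------------
# partition comparison and consensus
# --------------------------------------------------------------------------

def zrand(p1: Partition, p2: Partition) -> float:
    """z-scored Rand index under the hypergeometric model.

    Standardises the pair-counting Rand coefficient by its mean and variance
    over random partitions with the same community sizes.  Degenerate
    (single-community) partitions have zero variance and return NaN.
    """
    if p1.n_nodes != p2.n_nodes:
        raise ParameterError("partitions must cover the same node set")
    n = p1.n_nodes
    M = n * (n - 1) / 2
    sizes1 = np.bincount(p1.labels)[1:]
    sizes2 = np.bincount(p2.labels)[1:]
    M1 = float((sizes1 * (sizes1 - 1) // 2).sum())
    M2 = float((sizes2 * (sizes2 - 1) // 2).sum())
    # contingency table pair count
    cont = np.zeros((len(sizes1), len(sizes2)))
    np.add.at(cont, (p1.labels - 1, p2.labels - 1), 1.0)
    w = float((cont * (cont - 1) / 2).sum())
    if M1 in (0.0, M) or M2 in (0.0, M):
        return float("nan")
    c1 = n * (n ** 2 - 3 * n - 2) - 8 * (n + 1) * M1 + 4 * float((sizes1 ** 3).sum())
    c2 = n * (n ** 2 - 3 * n - 2) - 8 * (n + 1) * M2 + 4 * float((sizes2 ** 3).sum())
    a = M / 16
    b = (4 * M1 - 2 * M) ** 2 * (4 * M2 - 2 * M) ** 2 / (256 * M ** 2)
    c = c1 * c2 / (16 * n * (n - 1) * (n - 2))
    d = (((4 * M1 - 2 * M) ** 2 - 4 * c1 - 4 * M)
         * ((4 * M2 - 2 * M) ** 2 - 4 * c2 - 4 * M)
         / (64 * n * (n - 1) * (n - 2) * (n - 3)))
    var_w = a - b + c + d
    if var_w <= 0:
        return float("nan")
    return float((w - M1 * M2 / M) / np.sqrt(var_w))


def _pairwise_zrand(parts: list[Partition]) -> tuple[float, float]:
    vals = []
    for i in range(len(parts)):
        for j in range(i + 1, len(parts)):
            vals.append(zrand(parts[i], parts[j]))
    arr = np.asarray(vals, dtype=float)
    with np.errstate(invalid="ignore"):
        return float(np.nanmean(arr)), float(np.nanvar(arr))


def _agreement(parts: list[Partition]) -> np.ndarray:
    n = parts[0].n_nodes
    agree = np.zeros((n, n))
    for p in parts:
        agree += p.labels[:, None] == p.labels[None, :]
    return agree / len(parts)


def _null_agreement(parts: list[Partition]) -> float:
    """Expected off-diagonal co-assignment when each run's labels are randomly
    permuted over nodes: mean over runs of sum_c n_c (n_c - 1) / (n (n - 1))."""
    n = parts[0].n_nodes
    probs = []
    for p in parts:
        sizes = np.bincount(p.labels)[1:]
        probs.append(float((sizes * (sizes - 1)).sum()) / (n * (n - 1)))
    return float(np.mean(probs))


def consensus_partition(net: SignedSimilarityNetwork, gamma: float = 1.0,
                        n_runs: int = 250, seed: int = 0,
                        max_iter: int = 100) -> ConsensusResult:
    """Consensus over repeated Louvain runs via iterated agreement clustering.

    ``n_runs`` Louvain partitions are reduced to a co-assignment matrix; its
    entries below the permutation-null expectation are zeroed and the
    thresholded agreement network is re-clustered (again ``n_runs`` times)
    until every run agrees.  z-Rand statistics summarise the original runs.
    """
    if n_runs < 2:
        raise ParameterError("need at least 2 runs")
    run_seeds = (np.random.SeedSequence(seed)
                 .generate_state(n_runs * (max_iter + 1)) % (2 ** 31)).tolist()
    runs = [louvain_signed(net, gamma, run_seeds[r]) for r in range(n_runs)]
    zmean, zvar = _pairwise_zrand(runs)

    parts = runs
    for it in range(max_iter):
        if all(np.array_equal(p.labels, parts[0].labels) for p in parts):
            return ConsensusResult(parts[0], runs, zmean, zvar, gamma)
        agree = _agreement(parts)
        tau = _null_agreement(parts)
        thresh = np.where(agree >= tau, agree, 0.0)
        np.fill_diagonal(thresh, 0.0)
        if thresh.max() == 0:  # nothing survives the null: a single community
            return ConsensusResult(Partition(np.ones(net.n_nodes, dtype=int)),
                                   runs, zmean, zvar, gamma)
        agree_net = SignedSimilarityNetwork(thresh)
        base = (it + 1) * n_runs
        parts = [louvain_signed(agree_net, 1.0, run_seeds[base + r])
                 for r in range(n_runs)]
    raise DataError(f"consensus did not converge in {max_iter} iterations")


def gamma_sweep(net: SignedSimilarityNetwork, gamma_grid: np.ndarray | None = None,
                n_runs: int = 250, seed: int = 0) -> GammaSweepTable:
    """Consensus partitions across a resolution sweep (default 0.1..6.0 step 0.1,
    60 values); high z-Rand mean and low variance flag stable solutions."""
    if gamma_grid is None:
        gamma_grid = np.round(np.arange(1, 61) * 0.1, 10)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if gamma_grid.size == 0 or np.any(gamma_grid <= 0):
        raise ParameterError("gamma grid must be non-empty and positive")
    if np.any(np.diff(gamma_grid) <= 0):
        raise ParameterError("gamma grid must be strictly increasing")
    results = []
    for gi, g in enumerate(gamma_grid):
        sub_seed = int(np.random.SeedSequence(seed, spawn_key=(gi,)
                                              ).generate_state(1)[0] % (2 ** 31))
        results.append(consensus_partition(net, float(g), n_runs, sub_seed))
    return GammaSweepTable(
        gamma=gamma_grid,
        zrand_mean=np.array([r.zrand_mean for r in results]),
        zrand_variance=np.array([r.zrand_variance for r in results]),
        n_communities=np.array([r.partition.n_communities for r in results]),
        results=results,
    )


# --------------------------------------------------------------------------
# community-level maps
# --------------------------------------------------------------------------

def community_cortical_degree(fc: Connectome, partition: Partition,
                              community: int) -> DegreeMap:
    """Per-cortical-node sum of (unregressed) FC with the community's nuclei."""
    ctx = fc.class_indices("cortex")
    bs = fc.class_indices("brainstem")
    if partition.n_nodes != len(bs):
        raise ParameterError("partition must label the brainstem nodes")
    members = bs[partition.members(community)]
    if members.size == 0:
        raise ParameterError(f"community {community} is empty")
    values = fc.matrix[np.ix_(ctx, members)].sum(axis=1)
    return DegreeMap(values, [fc.node_labels[i] for i in ctx],
                     seed_class="cortex", target_class="brainstem")


def community_fit(residual_block: np.ndarray, partition: Partition,
                  fc: Connectome) -> np.ndarray:
    """Spearman rho between each brainstem nucleus's residual cortical profile
    and its assigned community's cortical degree map; low values flag
    functionally flexible nuclei."""
    residual_block = np.asarray(residual_block, dtype=float)
    n_bs = residual_block.shape[1]
    if partition.n_nodes != n_bs:
        raise ParameterError("partition must label the brainstem nodes")
    maps = {c: community_cortical_degree(fc, partition, c).values
            for c in range(1, partition.n_communities + 1)}
    out = np.empty(n_bs)
    for i in range(n_bs):
        profile = residual_block[:, i]
        if np.ptp(profile) == 0:
            raise DataError(f"constant residual profile for brainstem node {i}")
        out[i] = stats.spearmanr(profile, maps[int(partition.labels[i])])[0]
    return out
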