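"""Synthetic brainstem-cortex cohorts with known ground truth.

The generator emulates the statistical structure of a resting-state cohort in
which ~58 brainstem nuclei and ~400 cortical parcels share (i) a dominant
global coupling factor, (ii) K brainstem communities each projecting a
distinct smooth cortical map, (iii) a planted unimodal-transmodal cortical
axis, (iv) distance-dependent spatially correlated cortical noise, (v)
nuisance confounds with known loadings, and (vi) receptor / cognitive-term
annotation maps that are known linear mixtures of the planted cortical maps.

Signal model (per subject, per timepoint; all latent factors i.i.d. unit
normal): a brainstem node i in community k emits

    x_i = a * G_i * g + b * f_k + sigma_b * eps_i

and a cortical node j emits

    y_j = a * G_j * g + alpha_u * sum_k u_k(j) f_k
          + v_uni(j) h_uni + v_trans(j) h_trans + eta_j

where ``g`` is the shared global factor with loading map ``G`` (the planted
dominant weighted-degree pattern), ``f_k`` are community factors with smooth
zero-mean unit-variance cortical projection maps ``u_k``, ``h_uni``/``h_trans``
are pole factors with antipodal loadings +/- (s/2) * A along a smooth cortical
axis ``A`` (so the planted gradient axis is standardize(v_trans - v_uni) = A),
and ``eta`` is Gaussian noise with covariance sigma_c^2 * exp(-d_jl / decay)
over cortical centroid distances.  Any generative model with the same first
and second moments would serve equally; a linear factor model is used because
every downstream claim concerns low-rank shared covariance structure.

Brainstem nodes receive more unshared noise than cortical nodes (mirroring
their lower temporal SNR in vivo), which also reproduces the empirical block
ordering: mean brainstem-cortex FC exceeds mean within-brainstem FC.

Noise scales derive from the single ``snr`` parameter: sigma_b = 6.5/snr,
sigma_c = 1.6/snr, sigma_r = 0.6/snr.  One global seed fans out to per-subject
substreams through a counter scheme, so enlarging the cohort never perturbs
existing subjects.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ProbabilisticAtlas
from .exceptions import ConfigurationError, ParameterError
from .nulls import SphereCoordinates
from .preprocess import NuisanceDesign, TimeSeriesMatrix

__all__ = [
    "CohortTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_sphere_coordinates",
    "generate_probabilistic_atlas",
    "write_cohort",
]

# loading-scale constants of the factor model (see module docstring)
GLOBAL_LOADING = 1.0        # a
COMMUNITY_LOADING = 0.8     # b, brainstem side
CORTICAL_COMMUNITY_AMPLITUDE = 0.6  # alpha_u
COMMUNITY_MAP_DISTINCTNESS = 0.6    # weight of each map's community-private part
POLE_COUPLING = 3.0         # axis loading of the two pole communities
POLE_SCALE = 0.8            # s
MAP_SMOOTHNESS_MM = 40.0    # spatial kernel length of the planted maps
NUISANCE_LOADING_SD = 0.3
N_NUISANCE = 6
BASELINE_CORTEX = 1000.0
BASELINE_BRAINSTEM = 500.0


def _substream(seed: int, *path: str | int) -> np.random.Generator:
    """Named, order-independent random substream derived from one global seed."""
    key = tuple(zlib.crc32(str(p).encode()) for p in path)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class CohortTruth:
    """Planted ground truth of a synthetic cohort."""

    community_of_brainstem_node: np.ndarray   # (n_brainstem,) labels 1..K
    cortical_projection_maps: np.ndarray      # (K, n_cortex), each zero-mean unit-var
    global_pattern: np.ndarray                # (n_nodes,) loading on shared factor g
    gradient_axis: np.ndarray                 # (n_cortex,) standardized planted axis
    receptor_coefficients: np.ndarray         # (M, K) mixing weights beta
    dominant_receptor_per_community: np.ndarray  # (K,) receptor index per community
    seed: int

    def validate(self) -> None:
        k = int(self.community_of_brainstem_node.max())
        if set(np.unique(self.community_of_brainstem_node)) != set(range(1, k + 1)):
            raise ConfigurationError("all community labels 1..K must be used")
        mu = self.cortical_projection_maps.mean(axis=1)
        sd = self.cortical_projection_maps.std(axis=1)
        if np.abs(mu).max() > 1e-8 or np.abs(sd - 1).max() > 1e-8:
            raise ConfigurationError("projection maps must be standardized")
        for kk in range(k):
            col = np.abs(self.receptor_coefficients[:, kk])
            top = np.argsort(col)[::-1]
            if col[top[0]] <= col[top[1]]:
                raise ConfigurationError(
                    f"community {kk + 1} lacks a strictly dominant receptor")


@dataclass
class SyntheticCohort:
    """A generated cohort: raw subject series plus all shared structure."""

    subjects: list[TimeSeriesMatrix]
    centroids: np.ndarray                   # (n_nodes, 3) mm
    sphere_coords: SphereCoordinates        # cortical nodes only
    nuisance_designs: list[NuisanceDesign]
    nuisance_loadings: np.ndarray           # (n_nodes, q) known confound loadings
    receptor_maps: pd.DataFrame             # cortex x M, named columns
    term_maps: pd.DataFrame                 # cortex x T, named columns
    truth: CohortTruth

    @property
    def n_cortex(self) -> int:
        return len(self.truth.gradient_axis)

    @property
    def n_brainstem(self) -> int:
        return len(self.truth.community_of_brainstem_node)

    @property
    def node_labels(self) -> list[str]:
        return self.subjects[0].node_labels


def _fibonacci_hemisphere_pair(n_per_hemisphere: int) -> tuple[np.ndarray, list[str]]:
    """Quasi-uniform unit vectors: n points per hemisphere, right = mirror of left."""
    n = n_per_hemisphere
    i = np.arange(n, dtype=float)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    left = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    left /= np.linalg.norm(left, axis=1, keepdims=True)
    right = left * np.array([-1.0, 1.0, 1.0])
    coords = np.vstack([left, right])
    hemi = ["L"] * n + ["R"] * n
    return coords, hemi


def generate_sphere_coordinates(n_per_hemisphere: int, seed: int = 0) -> SphereCoordinates:
    """Deterministic quasi-uniform (Fibonacci spiral) points on the unit sphere,
    one set per hemisphere, mirrored across the x = 0 plane.

    The layout is deterministic; ``seed`` is accepted for interface symmetry
    with the other generators and does not alter the result.
    """
    if n_per_hemisphere < 4:
        raise ConfigurationError("need at least 4 parcels per hemisphere")
    coords, hemi = _fibonacci_hemisphere_pair(n_per_hemisphere)
    return SphereCoordinates(coords, hemi)


def _cohort_centroids(n_cortex: int, n_brainstem: int, seed: int) -> np.ndarray:
    """Cortical nodes on two mirrored hemispheric shells, brainstem nodes in a
    compact midline column, in mm, roughly matching real inter-node distance
    distributions (cortex-cortex up to ~130 mm, within-brainstem < ~60 mm)."""
    unit, hemi = _fibonacci_hemisphere_pair(n_cortex // 2)
    folded = unit.copy()
    # fold each hemisphere's points away from the midline to form half-shells
    left = np.array(hemi) == "L"
    folded[left, 0] = -np.abs(folded[left, 0]) - 0.08
    folded[~left, 0] = np.abs(folded[~left, 0]) + 0.08
    folded /= np.linalg.norm(folded, axis=1, keepdims=True)
    cortex = folded * 65.0 + np.array([0.0, -20.0, 20.0])
    rng = _substream(seed, "centroids")
    zs = np.linspace(-45.0, 10.0, n_brainstem)
    jitter = rng.normal(scale=3.0, size=(n_brainstem, 2))
    brainstem = np.column_stack([jitter[:, 0], -30.0 + jitter[:, 1], zs])
    return np.vstack([cortex, brainstem])


def _smooth_maps(n_maps: int, centroids: np.ndarray, rng: np.random.Generator,
                 smoothness_mm: float = MAP_SMOOTHNESS_MM) -> np.ndarray:
    """Standardized smooth Gaussian random fields over the given coordinates."""
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    kernel = np.exp(-d / smoothness_mm)
    raw = kernel @ rng.standard_normal((len(centroids), n_maps))
    raw -= raw.mean(axis=0)
    raw /= raw.std(axis=0)
    return raw.T  # (n_maps, n_nodes)


def _spatial_noise_chol(centroids: np.ndarray, decay: float) -> np.ndarray:
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    cov = np.exp(-d / decay)
    cov[np.diag_indices_from(cov)] += 1e-8
    return np.linalg.cholesky(cov)


def _community_sizes_to_labels(n_brainstem: int, k: int) -> np.ndarray:
    """Label vector with ~30 % of nodes in each pole community (first and
    last label) and the remainder split evenly over middle communities."""
    if k == 1:
        return np.ones(n_brainstem, dtype=int)
    pole = max(1, round(0.3 * n_brainstem))
    if k == 2:
        sizes = [n_brainstem // 2, n_brainstem - n_brainstem // 2]
    else:
        middle_total = n_brainstem - 2 * pole
        if middle_total < k - 2:
            raise ConfigurationError("too many communities for this node count")
        base = middle_total // (k - 2)
        sizes = [pole] + [base] * (k - 2) + [pole]
        for i in range(middle_total - base * (k - 2)):
            sizes[1 + i] += 1
    return np.repeat(np.arange(1, k + 1), sizes)


def generate_cohort(n_subjects: int = 20, n_cortex: int = 400, n_brainstem: int = 58,
                    k_communities: int = 5, n_timepoints: int = 630,
                    snr: float = 2.0, distance_decay: float = 30.0,
                    seed: int = 0, n_receptors: int = 18,
                    n_terms: int = 123) -> SyntheticCohort:
    """Generate a full synthetic cohort with planted ground truth.

    Defaults mirror the reference study design: 20 subjects, 400 cortical +
    58 brainstem nodes, 5 communities, 630 timepoints (three 10-minute runs of
    210 repetitions at dt = 2.5 s), 18 receptor maps and 123 term maps.
    """
    if snr <= 0:
        raise ParameterError("snr must be positive")
    if distance_decay <= 0:
        raise ParameterError("distance_decay must be positive")
    if k_communities > n_brainstem:
        raise ConfigurationError("more communities than brainstem nodes")
    if n_cortex % 2:
        raise ConfigurationError("n_cortex must be even (two hemispheres)")
    if n_timepoints < 2 * (N_NUISANCE + 2):
        raise ParameterError("too few timepoints for the nuisance design")

    n_nodes = n_cortex + n_brainstem
    sigma_b = 8.0 / snr
    sigma_c = 1.6 / snr
    sigma_r = 0.6 / snr

    centroids = _cohort_centroids(n_cortex, n_brainstem, seed)
    ctx = centroids[:n_cortex]
    sphere_coords = generate_sphere_coordinates(n_cortex // 2, seed)

    # ---- shared planted structure ------------------------------------------
    rng_struct = _substream(seed, "structure")
    # global loading map G over all nodes: smooth, positive, around 1
    g_map = _smooth_maps(1, centroids, rng_struct)[0]
    global_pattern = np.clip(1.0 + 0.08 * g_map, 0.875, 1.125)

    # planted cortical axis A and community projection maps u_k.  The two
    # extreme ("pole") communities project near-antipodally along A (their
    # similarity is strongly negative, which signed modularity separates
    # cleanly), middle communities carry mostly community-private maps; this
    # concentrates the axis variance so the leading similarity gradient is A.
    axis_raw = _smooth_maps(1, ctx, rng_struct)[0]
    lin = np.linspace(-1.0, 1.0, k_communities) if k_communities > 1 else np.zeros(1)
    pole_weights = POLE_COUPLING * np.sign(lin) * np.abs(lin) ** 3
    w_raw = _smooth_maps(k_communities, ctx, rng_struct)
    # orthogonalise the whole planted basis in sample (constant direction
    # first, then the axis, then the private maps): chance correlations
    # between smooth maps would otherwise blur both the community separation
    # and the leading gradient across seeds
    basis = np.column_stack([np.ones(n_cortex), axis_raw, w_raw.T])
    q_mat, _ = np.linalg.qr(basis)
    scale = np.sqrt(n_cortex)
    axis = q_mat[:, 1] * scale
    if axis @ axis_raw < 0:
        axis = -axis
    # winsorise the axis so its extremes do not dominate node variances
    axis = np.clip(axis, -2.0, 2.0)
    axis = (axis - axis.mean()) / axis.std()
    w_maps = (q_mat[:, 2:] * scale).T
    for k in range(k_communities):
        if w_maps[k] @ w_raw[k] < 0:
            w_maps[k] = -w_maps[k]
    u = pole_weights[:, None] * axis[None, :] + COMMUNITY_MAP_DISTINCTNESS * w_maps
    u -= u.mean(axis=1, keepdims=True)
    u /= u.std(axis=1, keepdims=True)

    v_trans = 0.5 * POLE_SCALE * axis
    v_uni = -0.5 * POLE_SCALE * axis
    gradient_axis = (v_trans - v_uni)
    gradient_axis = (gradient_axis - gradient_axis.mean()) / gradient_axis.std()

    # community sizes: pole communities larger (~30% each), middles share the
    # rest; assignment shuffled over nodes
    labels = _community_sizes_to_labels(n_brainstem, k_communities)
    rng_struct.shuffle(labels)

    # receptor mixing: one strictly dominant receptor per community.  The two
    # pole communities project near-antipodal maps, so their dominant
    # receptors are planted as cross-pole contrasts (strong weight on their
    # community, opposite-signed weight on the other pole, none on middles):
    # otherwise a receptor with an incidentally clean axis contrast could
    # out-predict the planted one in the pooled axis coordinate.
    rng_maps = _substream(seed, "annotations")
    beta = np.clip(rng_maps.normal(scale=0.2, size=(n_receptors, k_communities)),
                   -0.45, 0.45)
    dominant = rng_maps.choice(n_receptors, size=k_communities, replace=False)
    for k, m in enumerate(dominant):
        beta[m, k] = 1.0
    if k_communities >= 2:
        first, last = dominant[0], dominant[-1]
        beta[first, k_communities - 1] = -0.5
        beta[last, 0] = -0.5
        beta[first, 1: k_communities - 1] = 0.0
        beta[last, 1: k_communities - 1] = 0.0
    receptor_values = beta @ u + sigma_r * rng_maps.standard_normal((n_receptors, n_cortex))
    receptor_names = [f"receptor_{m + 1:02d}" for m in range(n_receptors)]
    receptor_maps = pd.DataFrame(receptor_values.T, columns=receptor_names)

    term_beta = rng_maps.normal(scale=1.0 / np.sqrt(k_communities),
                                size=(n_terms, k_communities))
    term_values = term_beta @ u + sigma_r * rng_maps.standard_normal((n_terms, n_cortex))
    term_names = [f"term_{t + 1:03d}" for t in range(n_terms)]
    term_maps = pd.DataFrame(term_values.T, columns=term_names)

    truth = CohortTruth(
        community_of_brainstem_node=labels,
        cortical_projection_maps=u,
        global_pattern=global_pattern,
        gradient_axis=gradient_axis,
        receptor_coefficients=beta,
        dominant_receptor_per_community=dominant,
        seed=seed,
    )
    truth.validate()

    # known confound loadings, shared across subjects
    nuisance_loadings = _substream(seed, "confounds").normal(
        scale=NUISANCE_LOADING_SD, size=(n_nodes, N_NUISANCE))

    # ---- node bookkeeping ---------------------------------------------------
    node_labels = ([f"ctx_{h}_{i:03d}" for i, h in
                    zip(range(n_cortex), sphere_coords.hemisphere)]
                   + [f"bs_{i:02d}" for i in range(n_brainstem)])
    node_class = ["cortex"] * n_cortex + ["brainstem"] * n_brainstem
    hemisphere = list(sphere_coords.hemisphere) + ["midline"] * n_brainstem
    baseline = np.concatenate([np.full(n_cortex, BASELINE_CORTEX),
                               np.full(n_brainstem, BASELINE_BRAINSTEM)])

    chol = _spatial_noise_chol(ctx, distance_decay)
    onehot = np.zeros((k_communities, n_brainstem))
    onehot[labels - 1, np.arange(n_brainstem)] = 1.0

    # per-node white noise equalising total variance within each tissue class:
    # Pearson FC then scales covariances uniformly, so the empirical weighted
    # degree aligns with the planted global factor and the similarity
    # structure is free of normalisation-induced leakage
    conf_var = (nuisance_loadings ** 2).sum(axis=1)
    var_ctx = ((GLOBAL_LOADING * global_pattern[:n_cortex]) ** 2
               + CORTICAL_COMMUNITY_AMPLITUDE ** 2 * (u ** 2).sum(axis=0)
               + v_uni ** 2 + v_trans ** 2 + sigma_c ** 2 + conf_var[:n_cortex])
    var_bs = ((GLOBAL_LOADING * global_pattern[n_cortex:]) ** 2
              + COMMUNITY_LOADING ** 2 + sigma_b ** 2 + conf_var[n_cortex:])
    eq_sd = np.sqrt(np.concatenate([var_ctx.max() + 0.01 - var_ctx,
                                    var_bs.max() + 0.01 - var_bs]))

    # ---- per-subject synthesis ---------------------------------------------
    subjects: list[TimeSeriesMatrix] = []
    designs: list[NuisanceDesign] = []
    for s in range(n_subjects):
        rng = _substream(seed, "subject", s)
        g = rng.standard_normal(n_timepoints)
        f = rng.standard_normal((k_communities, n_timepoints))
        h_uni = rng.standard_normal(n_timepoints)
        h_trans = rng.standard_normal(n_timepoints)

        cortex_sig = (GLOBAL_LOADING * global_pattern[:n_cortex, None] * g
                      + CORTICAL_COMMUNITY_AMPLITUDE * (u.T @ f)
                      + v_uni[:, None] * h_uni + v_trans[:, None] * h_trans
                      + sigma_c * (chol @ rng.standard_normal((n_cortex, n_timepoints))))
        brainstem_sig = (GLOBAL_LOADING * global_pattern[n_cortex:, None] * g
                         + COMMUNITY_LOADING * (onehot.T @ f)
                         + sigma_b * rng.standard_normal((n_brainstem, n_timepoints)))
        sig = np.vstack([cortex_sig, brainstem_sig])

        # smooth nuisance time courses (low-pass white noise), standardized
        nuis = rng.standard_normal((n_timepoints, N_NUISANCE))
        half = min(20, (n_timepoints - 1) // 2)
        ker = np.exp(-0.25 * np.arange(-half, half + 1) ** 2 / 25.0)
        ker /= ker.sum()
        for q in range(N_NUISANCE):
            nuis[:, q] = np.convolve(nuis[:, q], ker, mode="same")
        nuis -= nuis.mean(axis=0)
        nuis /= nuis.std(axis=0)

        total = (sig + nuisance_loadings @ nuis.T
                 + eq_sd[:, None] * rng.standard_normal((n_nodes, n_timepoints)))
        raw = baseline[:, None] * (1.0 + 0.01 * total)
        subjects.append(TimeSeriesMatrix(raw, list(node_labels), dt=2.5,
                                         node_class=list(node_class),
                                         hemisphere=list(hemisphere)))
        designs.append(NuisanceDesign(nuis, [f"confound_{q + 1}" for q in range(N_NUISANCE)]))

    return SyntheticCohort(subjects, centroids, sphere_coords, designs,
                           nuisance_loadings, receptor_maps, term_maps, truth)


# --------------------------------------------------------------------------
# probabilistic atlas fixtures
# --------------------------------------------------------------------------

def _blob_volume(grid: tuple[int, int, int], centers: np.ndarray, sigma: float) -> np.ndarray:
    ax = [np.arange(s, dtype=float) for s in grid]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    vols = np.empty(grid + (len(centers),))
    for li, c in enumerate(centers):
        r2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
        vols[..., li] = np.exp(-r2 / (2 * sigma ** 2))
    return vols


def _measured_overlap(probs: np.ndarray, threshold: float = 0.35) -> float:
    masks = probs >= threshold
    per_voxel = masks.sum(axis=3)
    labeled = int((per_voxel >= 1).sum())
    if labeled == 0:
        return 0.0
    return float((per_voxel >= 2).sum()) / labeled


def generate_probabilistic_atlas(grid_shape: tuple[int, int, int] = (20, 20, 20),
                                 n_labels: int = 6, overlap_fraction: float = 0.0,
                                 seed: int = 0, noise: float = 0.0,
                                 n_timepoints: int = 10,
                                 ) -> tuple[ProbabilisticAtlas, np.ndarray]:
    """Gaussian-blob probabilistic atlas plus a companion 4-D signal volume.

    Labels are Gaussian blobs; ``overlap_fraction`` requests the fraction of
    35 %-thresholded labeled voxels carrying >= 2 labels, realised by pairing
    blobs and bisecting the within-pair distance against the measured overlap.
    The companion volume's per-voxel time series equals the (1-based) index of
    the voxel's strongest label plus optional white noise, so parcel means are
    predictable by construction.
    """
    if not (0.0 <= overlap_fraction < 1.0):
        raise ParameterError("overlap_fraction must lie in [0, 1)")
    grid = tuple(int(s) for s in grid_shape)
    sigma = min(grid) / 10.0
    r35 = sigma * np.sqrt(2 * np.log(1 / 0.35))

    # lattice of well-separated anchor positions
    spacing = 2.8 * r35
    per_axis = [max(1, int((s - 2 * r35) // spacing) + 1) for s in grid]
    if np.prod(per_axis) < n_labels:
        raise ConfigurationError(
            f"grid {grid} too small to place {n_labels} blobs of radius {r35:.1f}")
    anchors = []
    for ix in range(per_axis[0]):
        for iy in range(per_axis[1]):
            for iz in range(per_axis[2]):
                anchors.append([r35 + ix * spacing, r35 + iy * spacing, r35 + iz * spacing])
    anchors = np.array(anchors)[:n_labels]

    def build(dist: float) -> np.ndarray:
        centers = anchors.copy()
        if overlap_fraction > 0:
            # move odd-indexed labels toward their even partner
            for a in range(0, n_labels - 1, 2):
                direction = np.array([1.0, 0.0, 0.0])
                centers[a + 1] = centers[a] + direction * dist
        return _blob_volume(grid, centers, sigma)

    if overlap_fraction == 0:
        probs = _blob_volume(grid, anchors, sigma)
    else:
        lo, hi = 0.05 * r35, 2.0 * r35  # heavy overlap .. none
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            f = _measured_overlap(build(mid))
            if f > overlap_fraction:
                lo = mid
            else:
                hi = mid
        probs = build(0.5 * (lo + hi))
        if abs(_measured_overlap(probs) - overlap_fraction) > 0.05:
            raise ConfigurationError("could not realise requested overlap fraction")

    label_names = [f"label_{li + 1}" for li in range(n_labels)]
    atlas = ProbabilisticAtlas(np.clip(probs, 0, 1), label_names)

    strongest = np.argmax(probs, axis=3) + 1
    strongest = np.where(probs.max(axis=3) >= 0.35, strongest, 0).astype(float)
    rng = _substream(seed, "atlas-companion")
    companion = (strongest[..., None]
                 + noise * rng.standard_normal(grid + (n_timepoints,)))
    return atlas, companion


# --------------------------------------------------------------------------
# on-disk cohort format (TSV matrices + JSON truth sidecar)
# --------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort as plain-text files: one TSV per subject (node rows,
    timepoint columns), coordinate and annotation TSVs, truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = cohort.node_labels
    for s, ts in enumerate(cohort.subjects):
        df = pd.DataFrame(ts.values, index=labels,
                          columns=[f"t{t}" for t in range(ts.n_timepoints)])
        df.to_csv(out / f"subject_{s:02d}.tsv", sep="\t", index_label="node")
    coords = pd.DataFrame(cohort.centroids, columns=["x", "y", "z"])
    coords.insert(0, "node", labels)
    coords["hemisphere"] = cohort.subjects[0].hemisphere
    coords["class"] = cohort.subjects[0].node_class
    coords.to_csv(out / "coordinates.tsv", sep="\t", index=False)
    sph = pd.DataFrame(cohort.sphere_coords.coords, columns=["x", "y", "z"])
    sph.insert(0, "node", labels[:cohort.n_cortex])
    sph["hemisphere"] = cohort.sphere_coords.hemisphere
    sph.to_csv(out / "sphere_coordinates.tsv", sep="\t", index=False)
    cohort.receptor_maps.to_csv(out / "receptor_maps.tsv", sep="\t", index=False)
    cohort.term_maps.to_csv(out / "term_maps.tsv", sep="\t", index=False)
    for s, design in enumerate(cohort.nuisance_designs):
        pd.DataFrame(design.regressors, columns=design.names).to_csv(
            out / f"confounds_{s:02d}.tsv", sep="\t", index=False)
    truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(cohort.truth).items()}
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out
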