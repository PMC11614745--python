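"""BOLD time-series cleaning.

Implements the standard resting-state cleaning chain for parcellated fMRI
signals: nuisance regression (motion/physiology/CSF regressors), scaling to
percent signal change, zero-phase band-pass filtering, per-run demeaning and
run concatenation.  The stage order follows common brainstem-fMRI practice:
regress -> scale -> band-pass -> demean -> concatenate; `clean_runs` exposes
the order so sensitivity analyses can permute it.

All operations act on :class:`TimeSeriesMatrix`, a node x timepoint array with
node labels carrying a tissue-class tag (``cortex`` | ``brainstem`` | ``other``)
and a hemisphere tag (``L`` | ``R`` | ``midline``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA

from .exceptions import DataError, ParameterError

__all__ = [
    "TimeSeriesMatrix",
    "NuisanceDesign",
    "percent_signal_change",
    "bandpass",
    "csf_principal_components",
    "nuisance_regress",
    "concatenate_runs",
    "clean_runs",
]


@dataclass
class TimeSeriesMatrix:
    """Node x timepoint signal array.

    Parameters
    ----------
    values : (n_nodes, n_timepoints) array
    node_labels : list of str, unique
    dt : float
        Sampling interval in seconds (2.5 s for the reference acquisition).
    node_class : list of str
        Tissue class per node: ``cortex``, ``brainstem`` or ``other``.
    hemisphere : list of str
        ``L``, ``R`` or ``midline`` per node.
    """

    values: np.ndarray
    node_labels: list[str]
    dt: float = 2.5
    node_class: list[str] = field(default_factory=list)
    hemisphere: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("values must be a 2-D node x timepoint array")
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if len(self.node_labels) != self.values.shape[0]:
            raise ParameterError("node_labels length must match number of rows")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise DataError("node labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise DataError("time series contain non-finite values")
        if not self.node_class:
            self.node_class = ["other"] * self.n_nodes
        if not self.hemisphere:
            self.hemisphere = ["midline"] * self.n_nodes

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "TimeSeriesMatrix":
        return replace(self, values=np.asarray(values, dtype=float))

    def class_indices(self, node_class: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.node_class) if c == node_class], dtype=int)


@dataclass
class NuisanceDesign:
    """Timepoint x regressor design matrix with named columns."""

    regressors: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.size and self.regressors.shape[1] != len(self.names):
            raise ParameterError("number of names must match number of columns")
        if self.regressors.size:
            if np.any(np.all(self.regressors == 0, axis=0)):
                raise DataError("design contains an all-zero column")

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[0]


def percent_signal_change(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Scale each node to percent signal change (divide by temporal mean, x100)."""
    means = ts.values.mean(axis=1)
    bad = np.abs(means) < 1e-12
    if np.any(bad):
        names = [ts.node_labels[i] for i in np.flatnonzero(bad)]
        raise DataError(f"zero temporal mean for nodes: {names}")
    return ts.with_values(ts.values / means[:, None] * 100.0)


def bandpass(ts: TimeSeriesMatrix, low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 2) -> TimeSeriesMatrix:
    """Zero-phase Butterworth band-pass (forward-backward filtering).

    The band must lie strictly inside (0, Nyquist) where Nyquist = 1/(2 dt).
    """
    nyq = 1.0 / (2.0 * ts.dt)
    if not (0.0 < low_hz < high_hz < nyq):
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist={nyq}")
    sos = signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    filtered = signal.sosfiltfilt(sos, ts.values, axis=1)
    return ts.with_values(filtered)


def csf_principal_components(csf_ts: np.ndarray, n_components: int = 5) -> NuisanceDesign:
    """Leading temporal principal components of CSF voxel signals.

    Voxels are treated as observations and timepoints as features, so the
    returned components are unit-norm, mutually orthogonal time courses
    ordered by explained variance — the conventional "CompCor"-style
    nuisance regressors.
    """
    csf_ts = np.asarray(csf_ts, dtype=float)
    if n_components == 0:
        return NuisanceDesign(np.empty((csf_ts.shape[1], 0)), [])
    if n_components > min(csf_ts.shape):
        raise ParameterError("n_components exceeds min(voxels, timepoints)")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(csf_ts)
    rank = np.linalg.matrix_rank(csf_ts - csf_ts.mean(axis=0))
    if rank < n_components:
        raise DataError(f"CSF data rank {rank} below requested {n_components} components")
    comps = pca.components_.T  # timepoint x k, orthonormal columns
    names = [f"csf_pc{i + 1}" for i in range(n_components)]
    return NuisanceDesign(comps, names)


def _with_intercept(design: NuisanceDesign, n_timepoints: int) -> tuple[np.ndarray, list[str]]:
    X = design.regressors
    if X.size == 0:
        X = np.empty((n_timepoints, 0))
    names = list(design.names)
    # intercept added unless a constant column is already present
    const = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    if not const:
        X = np.column_stack([np.ones(n_timepoints), X])
        names = ["intercept"] + names
    return X, names


def nuisance_regress(ts: TimeSeriesMatrix, design: NuisanceDesign) -> TimeSeriesMatrix:
    """Project out the nuisance design; returns per-node least-squares residuals."""
    if design.regressors.size and design.n_timepoints != ts.n_timepoints:
        raise ParameterError("design and series timepoint counts differ")
    X, names = _with_intercept(design, ts.n_timepoints)
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise DataError(f"collinear design (condition number {cond:.3g}); columns: {names}")
    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    resid = ts.values - (X @ beta).T
    return ts.with_values(resid)


def concatenate_runs(runs: list[TimeSeriesMatrix]) -> TimeSeriesMatrix:
    """Demean each run per node, then join along time."""
    if not runs:
        raise ParameterError("no runs supplied")
    ref = runs[0]
    for r in runs[1:]:
        if r.node_labels != ref.node_labels:
            raise DataError("runs have mismatched node labels")
        if r.dt != ref.dt:
            raise DataError("runs have mismatched sampling intervals")
    demeaned = [r.values - r.values.mean(axis=1, keepdims=True) for r in runs]
    return ref.with_values(np.concatenate(demeaned, axis=1))


def clean_runs(runs: list[TimeSeriesMatrix],
               designs: list[NuisanceDesign] | None = None,
               low_hz: float = 0.01, high_hz: float = 0.1,
               order: tuple[str, ...] = ("regress", "psc", "bandpass")) -> TimeSeriesMatrix:
    """Full cleaning chain applied per run, then demean + concatenate.

    ``order`` permutes the per-run stages for sensitivity checks; the default
    is regress -> percent signal change -> band-pass.  Because the regression
    includes an intercept (residuals are mean-zero), the raw temporal mean is
    reinstated after the regression stage so that percent-signal-change
    scaling remains defined.
    """
    if designs is None:
        designs = [NuisanceDesign(np.empty((r.n_timepoints, 0)), []) for r in runs]
    if len(designs) != len(runs):
        raise ParameterError("one design per run required")

    def _regress_keep_mean(ts: TimeSeriesMatrix, d: NuisanceDesign) -> TimeSeriesMatrix:
        mu = ts.values.mean(axis=1, keepdims=True)
        resid = nuisance_regress(ts, d)
        return resid.with_values(resid.values + mu)

    stages = {
        "regress": _regress_keep_mean,
        "psc": lambda ts, d: percent_signal_change(ts),
        "bandpass": lambda ts, d: bandpass(ts, low_hz, high_hz),
    }
    unknown = set(order) - set(stages)
    if unknown:
        raise ParameterError(f"unknown stages: {sorted(unknown)}")
    cleaned = []
    for run, des in zip(runs, designs):
        ts = run
        for st in order:
            ts = stages[st](ts, des)
        cleaned.append(ts)
    return concatenate_runs(cleaned)
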