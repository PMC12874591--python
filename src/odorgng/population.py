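"""Population trajectory analysis in auROC space.

The population's trial-averaged response is summarized as a matrix of
versus-baseline auROC values: 2 conditions x 91 nose-poking time bins as
observations (rows, go bins first), neurons as columns.  PCA reduces the
neuron dimension to three principal components — the nose-poking-epoch
subspace — and each condition's response becomes a 91-point trajectory in
that subspace.  Cue separation is the per-bin Euclidean distance between the
go and no-go trajectories, judged significant where it exceeds the mean +
2 SD of the distances computed the same way during the pre-odor baseline
window (1.2-1.0 s before odor-port entry) projected into the same subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .selectivity import AurocSeries
from .session import Refusal

__all__ = [
    "PopulationMatrix",
    "PCAResult",
    "TrajectoryPair",
    "DistanceSeries",
    "build_population_matrix",
    "pca_project",
    "trajectory_distance",
]


@dataclass(frozen=True)
class PopulationMatrix:
    """(2 x n_bins) observations x neurons matrix of auROC values; rows are
    ordered [go bins, then no-go bins]."""

    matrix: np.ndarray
    neuron_ids: list[str]
    bin_centers: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


def build_population_matrix(
    series_go: dict[str, AurocSeries | Refusal],
    series_nogo: dict[str, AurocSeries | Refusal],
) -> PopulationMatrix:
    """Stack per-neuron versus-baseline auROC series into the population
    matrix.

    Neurons with a refusal in either condition, or with NaN bins (from the
    per-bin minimum-trial rule), are dropped — never imputed.  Compute the
    input series without post-exit trial exclusion so all bins are defined.
    """
    ids = []
    cols = []
    grid = None
    for nid in series_go:
        sg, sn = series_go[nid], series_nogo.get(nid)
        if not isinstance(sg, AurocSeries) or not isinstance(sn, AurocSeries):
            continue
        if grid is None:
            grid = sg.bin_centers
        if len(sg.bin_centers) != len(grid) or not np.allclose(
            sg.bin_centers, grid
        ) or not np.allclose(sn.bin_centers, grid):
            raise ValueError(f"neuron {nid}: inconsistent bin grid")
        col = np.concatenate([sg.auroc, sn.auroc])
        if np.any(np.isnan(col)):
            continue
        ids.append(nid)
        cols.append(col)
    if grid is None or not ids:
        raise ValueError("no usable neurons")
    return PopulationMatrix(np.column_stack(cols), ids, np.asarray(grid))


@dataclass(frozen=True)
class PCAResult:
    components: np.ndarray  # (n_components, n_neurons), orthonormal rows
    mean: np.ndarray  # column means of the fitted matrix
    variance_explained: np.ndarray  # fraction per component, nonincreasing

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (matrix - self.mean) @ self.components.T


@dataclass(frozen=True)
class TrajectoryPair:
    """Per-condition trajectories through the principal subspace."""

    go: np.ndarray  # (n_bins, n_components)
    nogo: np.ndarray
    bin_centers: np.ndarray
    pca: PCAResult


def pca_project(pop: PopulationMatrix, n_components: int = 3) -> TrajectoryPair:
    """Fit PCA on the population matrix and project both conditions.

    Columns (neurons) are mean-centered; components come from the singular
    value decomposition.  Component signs follow the convention that each
    component's largest-magnitude loading is positive, which makes the
    projection deterministic across platforms.
    """
    X = pop.matrix
    if X.shape[1] < n_components:
        raise ValueError(
            f"{X.shape[1]} neurons < {n_components} requested components"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    if np.allclose(Xc, 0):
        raise ValueError("population matrix has zero variance")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    var = s**2 / np.sum(s**2)
    pca = PCAResult(vt[:n_components], mean, var[:n_components])
    proj = Xc @ pca.components.T
    n = pop.n_bins
    return TrajectoryPair(proj[:n], proj[n:], pop.bin_centers, pca)


@dataclass(frozen=True)
class DistanceSeries:
    bin_centers: np.ndarray
    distance: np.ndarray
    baseline_mean: float
    baseline_sd: float
    significant: np.ndarray  # distance > baseline_mean + 2 SD

    @property
    def threshold(self) -> float:
        return self.baseline_mean + 2 * self.baseline_sd


def trajectory_distance(
    traj: TrajectoryPair, baseline: PopulationMatrix
) -> DistanceSeries:
    """Per-bin Euclidean go/no-go separation versus the baseline threshold.

    ``baseline`` is the population matrix built on the pre-odor baseline
    window; it is projected into the already-fitted nose-poking subspace (the
    threshold must live in the same coordinates as the distances it gates).
    """
    dist = np.linalg.norm(traj.go - traj.nogo, axis=1)
    base_proj = traj.pca.transform(baseline.matrix)
    n = baseline.n_bins
    base_dist = np.linalg.norm(base_proj[:n] - base_proj[n:], axis=1)
    mean, sd = float(base_dist.mean()), float(base_dist.std())
    if sd == 0:
        raise ValueError("baseline distances have zero variance")
    return DistanceSeries(
        traj.bin_centers, dist, mean, sd, dist > mean + 2 * sd
    )
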