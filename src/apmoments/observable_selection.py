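"""Representative time-step selection from database-derived sensitivities.

Sensitivities are global linear-regression slopes of each observable column
against the collocation parameters (well defined on a scattered Sobol
cloud); time steps with similar normalized sensitivity patterns are merged
by Ward agglomerative clustering and each cluster is represented by its
medoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering

from apmoments.database import SimulationDatabase

__all__ = ["SensitivityProfile", "approximate_sensitivities", "select_timesteps"]


@dataclass
class SensitivityProfile:
    """N_t x n_p matrix of per-observable, per-parameter sensitivities."""

    matrix: np.ndarray
    labels: list[str]
    normalization: dict = field(default_factory=dict)


def approximate_sensitivities(db: SimulationDatabase) -> SensitivityProfile:
    """Least-squares slopes of u(θ, t_j) against θ over the collocation cloud.

    Each parameter column of the slope matrix is scaled to unit maximum
    absolute value (all-zero columns are left untouched).
    """
    theta = db.valid_points
    u = db.valid_observables
    n_v, n_p = theta.shape
    if n_v < n_p + 1:
        raise ValueError(
            f"need at least n_p + 1 = {n_p + 1} valid collocation points, have {n_v}"
        )
    design = np.column_stack([np.ones(n_v), theta])
    rank = np.linalg.matrix_rank(design)
    if rank < n_p + 1:
        raise ValueError(
            "collocation design is rank-deficient (collinear points); "
            "use more collocation points"
        )
    coef, *_ = np.linalg.lstsq(design, u, rcond=None)
    slopes = coef[1:].T  # N_t x n_p
    # zero out slopes that are pure least-squares noise: their induced
    # variation over the box must be negligible against the observable scale
    u_scale = max(float(np.max(np.ptp(u, axis=0), initial=0.0)),
                  1e-6 * float(np.max(np.abs(u), initial=0.0)), 1e-300)
    induced = np.abs(slopes) * np.ptp(theta, axis=0)[None, :]
    slopes = np.where(induced > 1e-8 * u_scale, slopes, 0.0)
    scale = np.max(np.abs(slopes), axis=0)
    safe = np.where(scale > 0, scale, 1.0)
    return SensitivityProfile(
        matrix=slopes / safe,
        labels=list(db.observable_index),
        normalization={"column_max_abs": scale},
    )


def select_timesteps(profile: SensitivityProfile, n_clusters: int) -> list[int]:
    """Cluster sensitivity rows (Ward, Euclidean) and pick each cluster's medoid.

    Ties in the medoid criterion break toward the smallest row index; the
    returned indices are sorted.
    """
    x = profile.matrix
    n_t = x.shape[0]
    if not 1 <= n_clusters <= n_t:
        raise ValueError(f"n_clusters must be in [1, {n_t}], got {n_clusters}")
    if n_clusters == n_t:
        return list(range(n_t))
    labels = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(x)
    selected = []
    for c in range(n_clusters):
        members = np.nonzero(labels == c)[0]
        d = cdist(x[members], x[members])
        medoid = members[int(np.argmin(d.sum(axis=1)))]  # argmin is first-on-ties
        selected.append(int(medoid))
    return sorted(selected)
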