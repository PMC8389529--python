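"""Principal path: a regularized k-means route through a conformation cloud.

The approximate minimum free energy path between two fixed endpoint
configurations is found by minimizing

    C(W, u) = sum_i ||x_i - w_{u_i}||^2  +  s * sum_j ||w_{j+1} - w_j||^2

over waypoints W = (w_1 .. w_Nc) and memberships u, with w_0 and w_{Nc+1}
fixed to the endpoints.  The first term is the standard k-means cost; the
second applies harmonic restraints between consecutive waypoints, so the
hyper-parameter s trades data fidelity against path smoothness.  The
minimization alternates nearest-waypoint assignment with an exact coupled
(tridiagonal) waypoint update, which makes the objective non-increasing by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded


@dataclass
class PointsCloud:
    """N feature vectors (flattened aligned coordinates) plus source frame ids."""

    samples: np.ndarray  # (N, d)
    source_frame_ids: np.ndarray | None = None  # (N,)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 2:
            raise ValueError("cloud needs >= 2 samples of equal dimension")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")
        if self.source_frame_ids is None:
            self.source_frame_ids = np.arange(self.samples.shape[0])
        else:
            self.source_frame_ids = np.asarray(self.source_frame_ids, dtype=int)
            if len(self.source_frame_ids) != self.samples.shape[0]:
                raise ValueError("frame ids must match sample count")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def dim(self) -> int:
        return self.samples.shape[1]


@dataclass
class PathModel:
    """Fitted waypoints, memberships and the optimization trace."""

    endpoints: np.ndarray  # (2, d): w_0 and w_{Nc+1}
    waypoints: np.ndarray  # (Nc, d), ordered
    memberships: np.ndarray  # (N,) waypoint index per sample
    smoothness: float
    cost_trace: list = field(default_factory=list)

    @property
    def n_waypoints(self) -> int:
        return self.waypoints.shape[0]

    def full_chain(self) -> np.ndarray:
        """Endpoints and waypoints as one ordered (Nc+2, d) array."""
        return np.vstack([self.endpoints[0], self.waypoints, self.endpoints[1]])


def _assign(samples: np.ndarray, waypoints: np.ndarray) -> np.ndarray:
    # squared distances (N, Nc); ties broken toward the lowest waypoint index
    d2 = ((samples[:, None, :] - waypoints[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _terms(samples, memberships, endpoints, waypoints):
    data = float(((samples - waypoints[memberships]) ** 2).sum())
    chain = np.vstack([endpoints[0], waypoints, endpoints[1]])
    smooth = float((np.diff(chain, axis=0) ** 2).sum())
    return data, smooth


def path_cost(model: PathModel, cloud: PointsCloud) -> float:
    """Evaluate the regularized k-means objective for a given model."""
    if model.waypoints.shape[1] != cloud.dim:
        raise ValueError("model/cloud dimension mismatch")
    data, smooth = _terms(cloud.samples, model.memberships,
                          model.endpoints, model.waypoints)
    return data + model.smoothness * smooth


def _update_waypoints(samples, memberships, endpoints, n_waypoints, s):
    d = samples.shape[1]
    counts = np.bincount(memberships, minlength=n_waypoints).astype(float)
    sums = np.zeros((n_waypoints, d))
    np.add.at(sums, memberships, samples)
    if s == 0.0:
        w = np.empty((n_waypoints, d))
        nonempty = counts > 0
        w[nonempty] = sums[nonempty] / counts[nonempty, None]
        # re-seed empty waypoints at the midpoint of their neighbours;
        # with s = 0 this leaves the objective untouched (no members, no
        # smoothness term) but keeps the path connected
        chain = np.vstack([endpoints[0], w, endpoints[1]])
        for j in np.flatnonzero(~nonempty):
            chain[j + 1] = 0.5 * (chain[j] + chain[j + 2])
        return chain[1:-1]
    # tridiagonal system: (n_j + 2s) w_j - s w_{j-1} - s w_{j+1} = sums_j
    # with the fixed endpoints entering the first and last right-hand sides
    rhs = sums.copy()
    rhs[0] += s * endpoints[0]
    rhs[-1] += s * endpoints[1]
    ab = np.zeros((3, n_waypoints))
    ab[0, 1:] = -s
    ab[1, :] = counts + 2.0 * s
    ab[2, :-1] = -s
    return solve_banded((1, 1), ab, rhs)


def fit_principal_path(cloud: PointsCloud, endpoints: np.ndarray,
                       n_waypoints: int, s: float,
                       init: str | np.ndarray = "linear",
                       max_iter: int = 500, tol: float = 1e-8) -> PathModel:
    """Alternating minimization of the regularized k-means objective.

    Parameters
    ----------
    endpoints : (2, d) array
        Fixed first and last points of the chain (bound and unbound states).
    init : "linear" | array
        Initial waypoints; "linear" interpolates between the endpoints.
    """
    if s < 0:
        raise ValueError("smoothness s must be non-negative")
    if n_waypoints < 1:
        raise ValueError("need at least one waypoint")
    endpoints = np.asarray(endpoints, dtype=float)
    if endpoints.shape != (2, cloud.dim):
        raise ValueError("endpoints must be a (2, d) array")
    if not np.isfinite(endpoints).all():
        raise ValueError("endpoints must be finite")

    if isinstance(init, str):
        if init != "linear":
            raise ValueError(f"unknown init strategy {init!r}")
        frac = np.arange(1, n_waypoints + 1) / (n_waypoints + 1)
        waypoints = endpoints[0] + frac[:, None] * (endpoints[1] - endpoints[0])
    else:
        waypoints = np.array(init, dtype=float)
        if waypoints.shape != (n_waypoints, cloud.dim):
            raise ValueError("init waypoints have wrong shape")

    trace: list[float] = []
    prev: float | None = None
    memberships = _assign(cloud.samples, waypoints)
    for _ in range(max_iter):
        memberships = _assign(cloud.samples, waypoints)
        waypoints = _update_waypoints(cloud.samples, memberships, endpoints,
                                      n_waypoints, s)
        data, smooth = _terms(cloud.samples, memberships, endpoints, waypoints)
        cost = data + s * smooth
        trace.append(cost)
        if prev is not None and prev - cost <= tol * max(abs(cost), 1.0):
            break
        prev = cost
    return PathModel(endpoints=endpoints, waypoints=waypoints,
                     memberships=memberships, smoothness=s, cost_trace=trace)


@dataclass
class SmoothnessScan:
    """Per-s data/smoothness terms and the advisory elbow pick."""

    s_grid: np.ndarray
    data_terms: np.ndarray
    smooth_terms: np.ndarray
    chosen_s: float
    degenerate: bool = False


def select_smoothness(cloud: PointsCloud, endpoints: np.ndarray,
                      n_waypoints: int, s_grid,
                      **fit_kwargs) -> SmoothnessScan:
    """Scan the smoothness hyper-parameter and pick the trade-off elbow.

    For each s the path is fitted and the (data term, smoothness term) pair
    recorded.  The advisory pick is the point of maximum curvature of the
    normalized data term as a function of log s; callers may override it.
    """
    s_grid = np.asarray(list(s_grid), dtype=float)
    if s_grid.size == 0:
        raise ValueError("empty s grid")
    if (s_grid <= 0).any() or (np.diff(s_grid) <= 0).any():
        raise ValueError("s grid must be positive and sorted ascending")
    data_terms = np.empty_like(s_grid)
    smooth_terms = np.empty_like(s_grid)
    for i, s in enumerate(s_grid):
        model = fit_principal_path(cloud, endpoints, n_waypoints, s,
                                   **fit_kwargs)
        data_terms[i], smooth_terms[i] = _terms(
            cloud.samples, model.memberships, model.endpoints, model.waypoints)
    if s_grid.size == 1:
        return SmoothnessScan(s_grid, data_terms, smooth_terms,
                              float(s_grid[0]))
    span = data_terms.max() - data_terms.min()
    if span < 1e-12 * max(data_terms.max(), 1e-30):
        # data term independent of s (e.g. samples on a straight line):
        # no elbow exists, return the least-regularized option
        return SmoothnessScan(s_grid, data_terms, smooth_terms,
                              float(s_grid[0]), degenerate=True)
    x = np.log(s_grid)
    y = (data_terms - data_terms.min()) / span
    dy = np.gradient(y, x)
    d2y = np.gradient(dy, x)
    kappa = np.abs(d2y) / (1.0 + dy ** 2) ** 1.5
    return SmoothnessScan(s_grid, data_terms, smooth_terms,
                          float(s_grid[int(np.argmax(kappa))]))


def snap_to_samples(model: PathModel, cloud: PointsCloud) -> np.ndarray:
    """Map the fitted chain back to the nearest physical frames.

    Each chain point (endpoints included) is replaced by the id of the
    nearest cloud sample; repeated ids are collapsed keeping the first
    occurrence, yielding an ordered, duplicate-free frame sequence.
    """
    if cloud.n == 0:
        raise ValueError("empty cloud")
    chain = model.full_chain()
    d2 = ((chain[:, None, :] - cloud.samples[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    ids = cloud.source_frame_ids[nearest]
    seen: set[int] = set()
    ordered = []
    for fid in ids:
        if int(fid) not in seen:
            seen.add(int(fid))
            ordered.append(int(fid))
    return np.array(ordered, dtype=int)
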