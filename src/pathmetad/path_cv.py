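"""Path collective variables S(x), Z(x) and the spacing heuristic for λ.

Given P ordered reference frames x_1 .. x_P and squared distances
d_i^2 = ||x - x_i||^2 (mean squared deviation in nm^2 after optional
superposition), the progress along the path and the distance from it are

    S(x) = sum_i i exp(-λ d_i^2) / sum_i exp(-λ d_i^2)          (softmin average)
    Z(x) = -(1/λ) ln sum_i exp(-λ d_i^2)

λ (nm^-2) modulates how sharply the softmin concentrates on the nearest
frames; it is set from the interframe spacing available before any biased
run: λ = 2.3 / <d^2>, which gives the reference 230.0 nm^-2 at the 1 Å
spacing target.  S is conventionally rescaled to [0, 1] with 0 the bound
and 1 the unbound endpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .geometry import AtomSelection, Conformation, msd
from .path_equidistance import interframe_distances


@dataclass
class PCVValue:
    s: float  # progress, dimensionless ([0, 1] when rescaled)
    z: float  # distance from the path, nm^2 scale (negative near the frames)


@dataclass
class PCVDefinition:
    """Reference frames, λ and the selections defining S and Z."""

    reference_frames: list  # ordered Conformations
    lam: float  # nm^-2
    align: AtomSelection | None = None
    measure: AtomSelection | None = None
    rescaled: bool = True
    superpose: bool = True  # per-frame rigid fit before measuring distances

    def __post_init__(self) -> None:
        if len(self.reference_frames) < 2:
            raise ValueError("need at least two reference frames")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.measure is None:
            self.measure = AtomSelection.all_atoms(
                self.reference_frames[0].n_atoms)
        gaps = interframe_distances(
            self.reference_frames,
            self.align if self.superpose else None, self.measure)
        if gaps.min() > 0 and gaps.max() / gaps.min() > 2.0:
            warnings.warn(
                "reference frames are far from equidistant "
                f"(max/min interframe RMSD = {gaps.max() / gaps.min():.2f}); "
                "S(x) may progress unevenly", stacklevel=2)

    @property
    def n_frames(self) -> int:
        return len(self.reference_frames)

    def feature_matrix(self) -> np.ndarray:
        """Reference measure-atom coordinates as a (P, 3*M) array (toy mode)."""
        return np.array([self.measure.take(c).ravel()
                         for c in self.reference_frames])


def lambda_from_spacing(mean_squared_interframe_distance: float) -> float:
    """Spacing heuristic λ = 2.3 / <d^2> (nm^-2).

    At the 1 Å interframe target, <d^2> = 0.01 nm^2 and λ = 230.0 nm^-2.
    """
    if mean_squared_interframe_distance <= 0:
        raise ValueError("mean squared spacing must be positive")
    return 2.3 / mean_squared_interframe_distance


def lambda_for_path(defn_frames, align, measure) -> float:
    """λ from the actual mean squared interframe RMSD of a frame list."""
    gaps = interframe_distances(defn_frames, align, measure)
    return lambda_from_spacing(float(np.mean(gaps ** 2)))


def _sz_from_squared_distances(d2: np.ndarray, lam: float,
                               rescaled: bool) -> tuple[float, float]:
    p = len(d2)
    logw = -lam * d2
    logz = logsumexp(logw)
    w = np.exp(logw - logz)
    s_raw = float(np.dot(np.arange(1, p + 1), w))
    z = float(-logz / lam)
    s = (s_raw - 1.0) / (p - 1.0) if rescaled else s_raw
    return s, z


def compute_pcv(x: Conformation, defn: PCVDefinition) -> PCVValue:
    """Evaluate (S, Z) for a configuration against the reference path."""
    align = defn.align if defn.superpose else None
    d2 = np.array([msd(ref, x, align, defn.measure)
                   for ref in defn.reference_frames])
    if not np.isfinite(d2).all():
        raise ValueError("non-finite distances to reference frames")
    s, z = _sz_from_squared_distances(d2, defn.lam, defn.rescaled)
    return PCVValue(s=s, z=z)


def pcv_value_and_jacobian(xflat: np.ndarray, refs: np.ndarray, lam: float,
                           n_atoms: int, rescaled: bool = False
                           ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(s, z) and their gradients for a flat coordinate vector (toy mode).

    ``refs`` is (P, D) with D the flattened coordinate dimension; distances
    are mean squared deviations over ``n_atoms`` atoms.  No superposition is
    performed, so the gradients are exact.
    """
    diff = xflat[None, :] - refs  # (P, D)
    d2 = (diff ** 2).sum(axis=1) / n_atoms
    p = refs.shape[0]
    logw = -lam * d2
    m = logw.max()
    e = np.exp(logw - m)
    z_norm = e.sum()
    w = e / z_norm
    idx = np.arange(1, p + 1)
    s_raw = float(idx @ w)
    z = float(-(m + np.log(z_norm)) / lam)
    grad_d2 = (2.0 / n_atoms) * diff  # (P, D)
    z_grad = w @ grad_d2
    s_grad = -lam * (((idx - s_raw) * w) @ grad_d2)
    if rescaled:
        return (s_raw - 1.0) / (p - 1.0), z, s_grad / (p - 1.0), z_grad
    return s_raw, z, s_grad, z_grad


def pcv_gradient(x: Conformation, defn: PCVDefinition
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of S and Z w.r.t. the measure-atom coordinates.

    Only supported without superposition (gradients through the rigid fit
    are not implemented); raises otherwise.  Returns arrays shaped like the
    full coordinate array, zero outside the measure selection.
    """
    if defn.superpose:
        raise NotImplementedError(
            "gradients through the superposition step are not supported; "
            "build the definition with superpose=False (fixed frame)")
    refs = defn.feature_matrix()
    xflat = defn.measure.take(x).ravel()
    _, _, s_grad, z_grad = pcv_value_and_jacobian(
        xflat, refs, defn.lam, len(defn.measure), rescaled=defn.rescaled)
    out_s = np.zeros_like(x.coords)
    out_z = np.zeros_like(x.coords)
    out_s[defn.measure.indices] = s_grad.reshape(-1, 3)
    out_z[defn.measure.indices] = z_grad.reshape(-1, 3)
    return out_s, out_z
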