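"""Equidistant waypoints: enforce uniform interframe RMSD along a path.

Path collective variables require consecutive reference frames to be as
equidistant as possible.  After snapping the principal path to physical
frames the spacing is typically very uneven, so intermediate conformations
are inserted into every oversized gap until all consecutive RMSDs fall
below a target threshold (default 0.1 nm, i.e. 1 Å).

How intermediates are produced is delegated to a *propagator*: any callable
``propagator(current, target, n_intermediates, align, measure) -> [Conformation]``.
The default geometric propagator interpolates Cartesian coordinates after a
rigid superposition; a short steered simulation could stand behind the same
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import AtomSelection, Conformation, rmsd, superpose

#: default interframe RMSD target: 1 Å expressed in nm
DEFAULT_THRESHOLD_NM = 0.1

Propagator = Callable[..., list]


class ResampleError(RuntimeError):
    """A gap could not be reduced below the threshold within the depth limit."""


@dataclass
class ResampleReport:
    original_gaps: np.ndarray
    final_gaps: np.ndarray
    inserted_per_gap: np.ndarray

    def total_inserted(self) -> int:
        return int(self.inserted_per_gap.sum())


def interframe_distances(path: Sequence[Conformation],
                         align: AtomSelection | None,
                         measure: AtomSelection) -> np.ndarray:
    """RMSD between each pair of consecutive frames (length = len(path) - 1)."""
    if len(path) < 2:
        raise ValueError("path needs at least two frames")
    return np.array([rmsd(path[i], path[i + 1], align, measure)
                     for i in range(len(path) - 1)])


def geometric_propagator(current: Conformation, target: Conformation,
                         n_intermediates: int,
                         align: AtomSelection | None = None,
                         measure: AtomSelection | None = None) -> list[Conformation]:
    """Linear Cartesian interpolation between two conformations.

    The target is first superposed onto the current frame on the align atoms
    (skipped when ``align`` is None), then all atoms are interpolated at
    fractions k/(n+1), k = 1..n.
    """
    if current.n_atoms != target.n_atoms:
        raise ValueError("conformations differ in atom count")
    if n_intermediates <= 0:
        return []
    end = target.coords
    if align is not None:
        end = superpose(target, current, align).apply(target.coords)
    out = []
    for k in range(1, n_intermediates + 1):
        f = k / (n_intermediates + 1)
        out.append(current.copy(coords=(1 - f) * current.coords + f * end,
                                frame_id=-1))
    return out


def _fill_gap(a: Conformation, b: Conformation, threshold: float,
              propagator: Propagator, align, measure, depth: int,
              max_depth: int, tol_factor: float) -> list[Conformation]:
    """Frames to insert strictly between a and b (recursive)."""
    d = rmsd(a, b, align, measure)
    if d <= threshold * tol_factor:
        return []
    if depth >= max_depth:
        raise ResampleError(
            f"gap of {d:.4f} nm between frames {a.frame_id} and {b.frame_id} "
            f"not reduced below {threshold:.4f} nm after {max_depth} rounds")
    n = int(np.ceil(d / threshold)) - 1
    n = max(n, 1)
    mids = propagator(a, b, n, align, measure)
    chain = [a] + list(mids) + [b]
    out: list[Conformation] = []
    for i in range(len(chain) - 1):
        if i > 0:
            out.append(chain[i])
        out.extend(_fill_gap(chain[i], chain[i + 1], threshold, propagator,
                             align, measure, depth + 1, max_depth, tol_factor))
    return out


def equidistant_resample(path: Sequence[Conformation],
                         threshold: float = DEFAULT_THRESHOLD_NM,
                         propagator: Propagator = geometric_propagator,
                         align: AtomSelection | None = None,
                         measure: AtomSelection | None = None,
                         max_depth: int = 5,
                         stochastic_tolerance: float = 0.05,
                         ) -> tuple[list[Conformation], ResampleReport]:
    """Insert intermediates until all consecutive RMSD gaps are <= threshold.

    For a gap d the propagator is asked for ceil(d/threshold) - 1
    intermediates; any gap still oversized after re-measuring is refined
    recursively up to ``max_depth`` rounds.  Original frames are all kept in
    order.  Stochastic propagators may overshoot slightly, hence gaps are
    accepted within ``(1 + stochastic_tolerance) * threshold``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if measure is None:
        measure = AtomSelection.all_atoms(path[0].n_atoms)
    original = interframe_distances(path, align, measure)
    tol_factor = 1.0 + stochastic_tolerance
    new_path: list[Conformation] = [path[0]]
    inserted = np.zeros(len(path) - 1, dtype=int)
    for i in range(len(path) - 1):
        mids = _fill_gap(path[i], path[i + 1], threshold, propagator,
                         align, measure, 0, max_depth, tol_factor)
        inserted[i] = len(mids)
        new_path.extend(mids)
        new_path.append(path[i + 1])
    # renumber so frame ids stay strictly increasing along the new path
    out = [c.copy(frame_id=i) for i, c in enumerate(new_path)]
    final = interframe_distances(out, align, measure)
    return out, ResampleReport(original_gaps=original, final_gaps=final,
                               inserted_per_gap=inserted)
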