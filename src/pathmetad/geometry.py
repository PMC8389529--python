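"""Rigid-body superposition and RMSD with separate align / measure selections.

Every path-based quantity in this package (interframe spacing, path
collective variables, principal-path features) reduces to an RMSD between
conformations computed after a least-squares superposition.  Alignment and
measurement may use different atom subsets: e.g. a host-guest complex is
aligned on the rigid host ring atoms while the deviation is measured on the
guest heavy atoms.

All coordinates are in nm.  RMSD is plain (unweighted) root-mean-square
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation


class DegenerateSelectionError(ValueError):
    """Raised when an alignment selection cannot define a rigid transform."""


@dataclass
class Conformation:
    """A single molecular frame: coordinates (nm) plus per-atom labels."""

    coords: np.ndarray  # (n_atoms, 3), nm
    elements: np.ndarray | None = None  # (n_atoms,) element symbols
    names: np.ndarray | None = None  # (n_atoms,) atom names
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")
        n = self.coords.shape[0]
        if self.elements is None:
            self.elements = np.array(["C"] * n)
        else:
            self.elements = np.asarray(self.elements, dtype=str)
        if self.names is None:
            self.names = self.elements.copy()
        else:
            self.names = np.asarray(self.names, dtype=str)
        if len(self.elements) != n or len(self.names) != n:
            raise ValueError("labels must match atom count")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self, coords: np.ndarray | None = None,
             frame_id: int | None = None) -> "Conformation":
        return Conformation(
            coords=self.coords.copy() if coords is None else np.asarray(coords, float),
            elements=self.elements.copy(),
            names=self.names.copy(),
            frame_id=self.frame_id if frame_id is None else frame_id,
        )


@dataclass
class AtomSelection:
    """Ordered, unique 0-based atom indices with a declared role."""

    indices: np.ndarray
    role: str = "measure"  # "align" | "measure"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise ValueError("indices must be a 1-D list")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")
        if self.role not in ("align", "measure"):
            raise ValueError(f"unknown selection role {self.role!r}")

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, n_atoms: int) -> None:
        if len(self.indices) == 0:
            raise ValueError("empty selection")
        if self.indices.min() < 0 or self.indices.max() >= n_atoms:
            raise IndexError("selection indices out of range")

    def take(self, conf: Conformation) -> np.ndarray:
        self.validate(conf.n_atoms)
        return conf.coords[self.indices]

    @classmethod
    def all_atoms(cls, n_atoms: int, role: str = "measure") -> "AtomSelection":
        return cls(np.arange(n_atoms), role=role)


@dataclass
class Superposition:
    """Proper rigid transform y = R x + t minimizing the align-atom deviation."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,), nm
    fit_rmsd: float  # nm, over the align atoms

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def transform(self, conf: Conformation) -> Conformation:
        return conf.copy(coords=self.apply(conf.coords))

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(np.eye(3), np.zeros(3), 0.0)


def _check_align_geometry(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise DegenerateSelectionError(
            "superposition needs at least 3 alignment atoms")
    centered = x - x.mean(axis=0)
    # rank < 2 means all points collinear (or coincident)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-10 * max(svals[0], 1e-30) or svals[0] < 1e-14:
        raise DegenerateSelectionError(
            "alignment atoms are collinear or coincident")


def superpose(mobile: Conformation, reference: Conformation,
              align: AtomSelection) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Solves the orthogonal Procrustes problem over the ``align`` atoms,
    restricted to proper rotations (mirror solutions are rejected by the
    solver by flipping the smallest singular direction).
    """
    xm = align.take(mobile)
    xr = align.take(reference)
    if xm.shape != xr.shape:
        raise ValueError("align selection mismatch between conformations")
    _check_align_geometry(xm)
    _check_align_geometry(xr)
    cm = xm.mean(axis=0)
    cr = xr.mean(axis=0)
    rot, rssd = Rotation.align_vectors(xr - cr, xm - cm)
    matrix = rot.as_matrix()
    translation = cr - matrix @ cm
    fit_rmsd = float(rssd) / np.sqrt(xm.shape[0])
    return Superposition(rotation=matrix, translation=translation,
                         fit_rmsd=fit_rmsd)


def rmsd(a: Conformation, b: Conformation, align: AtomSelection | None,
         measure: AtomSelection) -> float:
    """RMSD (nm) over ``measure`` atoms after superposing ``b`` onto ``a``.

    With ``align=None`` no superposition is performed (frames assumed to
    share a fixed laboratory frame, as in the toy systems).
    """
    if len(measure) == 0:
        raise ValueError("empty measure selection")
    if align is not None:
        sup = superpose(b, a, align)
        bm = sup.apply(measure.take(b))
    else:
        bm = measure.take(b)
    am = measure.take(a)
    return float(np.sqrt(np.mean(np.sum((am - bm) ** 2, axis=1))))


def msd(a: Conformation, b: Conformation, align: AtomSelection | None,
        measure: AtomSelection) -> float:
    """Mean squared deviation (nm^2); the squared-distance used by the PCVs."""
    return rmsd(a, b, align, measure) ** 2


def path_features(path: Sequence[Conformation], reference: Conformation,
                  align: AtomSelection | None,
                  measure: AtomSelection) -> np.ndarray:
    """Flattened measure-atom coordinates after superposition to a reference.

    The feature space used by the principal-path machinery: every frame is
    rigidly fitted onto ``reference`` using the align atoms, then the measure
    atom coordinates are flattened into a vector of length 3 * n_measure.
    """
    feats = np.empty((len(path), 3 * len(measure)))
    for i, conf in enumerate(path):
        if align is not None:
            sup = superpose(conf, reference, align)
            coords = sup.apply(measure.take(conf))
        else:
            coords = measure.take(conf)
        feats[i] = coords.ravel()
    return feats
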