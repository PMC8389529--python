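"""Readers and writers for conformations, paths, and selections.

Multi-model PDB (Å, MODEL/ENDMDL records) and XYZ files are handled through
MDAnalysis; coordinates are converted to nm on input and back to Å on
output.  Selection files are plain text: either a list of 0-based atom
indices, or a single pattern line ``name <NAME> [<NAME> ...]`` /
``element <EL> [<EL> ...]`` resolved against a reference conformation.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .geometry import AtomSelection, Conformation
from .units import angstrom_to_nm, nm_to_angstrom


def _elements_from_universe(u) -> np.ndarray:
    try:
        return np.asarray(u.atoms.elements, dtype=str)
    except (AttributeError, mda.exceptions.NoDataError):
        pass
    try:
        names = [str(n) for n in u.atoms.names]
    except (AttributeError, mda.exceptions.NoDataError):
        return np.array(["C"] * len(u.atoms))
    # first alphabetic character of the atom name is a serviceable element guess
    els = []
    for n in names:
        alpha = [c for c in n if c.isalpha()]
        els.append(alpha[0].upper() if alpha else "C")
    return np.array(els)


def read_path(filename: str | Path) -> list[Conformation]:
    """Read an ordered set of conformations from a multi-model PDB or XYZ file."""
    filename = str(filename)
    if not Path(filename).exists():
        raise FileNotFoundError(filename)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(filename)
        elements = _elements_from_universe(u)
        try:
            names = np.asarray(u.atoms.names, dtype=str)
        except (AttributeError, mda.exceptions.NoDataError):
            names = elements.copy()
        path = []
        for i, _ts in enumerate(u.trajectory):
            path.append(Conformation(
                coords=angstrom_to_nm(u.atoms.positions.astype(float)),
                elements=elements, names=names, frame_id=i))
    return path


def write_path(path: Sequence[Conformation], filename: str | Path) -> None:
    """Write conformations as a multi-model PDB or XYZ file (by extension)."""
    filename = str(filename)
    n = path[0].n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=1, atom_resindex=np.zeros(n, int),
                               trajectory=True)
        u.add_TopologyAttr("names", list(path[0].names))
        u.add_TopologyAttr("elements", list(path[0].elements))
        u.add_TopologyAttr("resnames", ["MOL"])
        u.add_TopologyAttr("resids", [1])
        with mda.Writer(filename, n_atoms=n, multiframe=True) as w:
            for conf in path:
                u.atoms.positions = nm_to_angstrom(conf.coords)
                w.write(u.atoms)


def read_selection(filename: str | Path, role: str = "measure",
                   reference: Conformation | None = None) -> AtomSelection:
    """Read an atom selection from a plain-text file.

    The file contains either whitespace-separated 0-based indices (``#``
    comments allowed) or one pattern line, e.g. ``name CA CB`` or
    ``element C N`` matched against ``reference`` labels.
    """
    text = Path(filename).read_text()
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tokens.extend(line.split())
    if not tokens:
        raise ValueError(f"selection file {filename} is empty")
    if tokens[0].lower() in ("name", "element"):
        if reference is None:
            raise ValueError("pattern selections need a reference conformation")
        labels = (reference.names if tokens[0].lower() == "name"
                  else reference.elements)
        wanted = set(tokens[1:])
        idx = np.flatnonzero(np.isin(labels, list(wanted)))
        if len(idx) == 0:
            raise ValueError(f"pattern {' '.join(tokens)} matched no atoms")
        return AtomSelection(idx, role=role)
    return AtomSelection(np.array([int(t) for t in tokens]), role=role)


def write_selection(sel: AtomSelection, filename: str | Path) -> None:
    Path(filename).write_text(
        "# 0-based atom indices, role=%s\n%s\n"
        % (sel.role, " ".join(str(i) for i in sel.indices)))
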