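"""Well-tempered metadynamics on (S, Z) driven by Langevin dynamics on toys.

The engine samples low-dimensional analytic potentials ("toy systems") with
underdamped Langevin dynamics and deposits repulsive Gaussians along one or
two collective variables.  Heights are tempered by the accumulated bias,

    w(t) = w0 * exp(-V(cv, t) / ((gamma - 1) kT)),

so the bias converges to -(1 - 1/gamma) F(cv) up to a constant and the free
energy is recovered as F = -(gamma/(gamma-1)) V.  An optional one-sided
harmonic wall limits the distance-from-path variable Z.

Hills and collective-variable series are written in the common plain-text
metadynamics dialect ("#! FIELDS time s z sigma_s sigma_z height biasf"), so
the analysis modules also work on externally produced files.

Units: kcal/mol, nm, ps, amu, K (kT at 300 K = 0.59616 kcal/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .path_cv import pcv_value_and_jacobian
from .units import KB_KCAL, KCAL_TO_MD, kt


# ---------------------------------------------------------------------------
# systems and collective variables


@dataclass
class ToySystem:
    """An analytic potential energy surface sampled by the toy engine."""

    dim: int
    energy: Callable[[np.ndarray], float]  # kcal/mol
    force: Callable[[np.ndarray], np.ndarray]  # -dU/dx, kcal/mol/nm
    temperature: float = 300.0  # K
    mass: float = 1.0  # amu
    domain: tuple = ()  # ((lo, hi), ...) where exp(-U/kT) has support
    name: str = "toy"

    def kt(self) -> float:
        return kt(self.temperature)


class IdentityCV:
    """Coordinates themselves as collective variables (for 1-D/2-D toys)."""

    def __init__(self, indices: Sequence[int] = (0,)):
        self.indices = np.asarray(indices, dtype=int)
        self.ncv = len(self.indices)

    def value_and_jacobian(self, pos: np.ndarray):
        vals = pos[self.indices]
        jac = np.zeros((self.ncv, len(pos)))
        jac[np.arange(self.ncv), self.indices] = 1.0
        return vals, jac


class PathCV:
    """(S, Z) over a fixed set of reference vectors, exact gradients.

    ``refs`` is (P, D); the toy configuration is the flat vector itself
    (``n_atoms`` controls the mean in the squared-deviation metric).
    """

    ncv = 2

    def __init__(self, refs: np.ndarray, lam: float, n_atoms: int = 1,
                 rescaled: bool = False):
        self.refs = np.asarray(refs, dtype=float)
        self.lam = float(lam)
        self.n_atoms = int(n_atoms)
        self.rescaled = bool(rescaled)
        if self.refs.ndim != 2 or self.refs.shape[0] < 2:
            raise ValueError("need a (P, D) reference array with P >= 2")

    @property
    def n_frames(self) -> int:
        return self.refs.shape[0]

    def value_and_jacobian(self, pos: np.ndarray):
        s, z, gs, gz = pcv_value_and_jacobian(
            pos, self.refs, self.lam, self.n_atoms, rescaled=self.rescaled)
        return np.array([s, z]), np.vstack([gs, gz])


# ---------------------------------------------------------------------------
# hills bookkeeping


@dataclass
class Hill:
    time: float  # ps
    center: np.ndarray  # (ncv,)
    widths: np.ndarray  # (ncv,)
    height: float  # kcal/mol


@dataclass
class HillsLedger:
    """Deposited Gaussians as flat arrays, plus the run metadata."""

    times: np.ndarray  # (n,)
    centers: np.ndarray  # (n, ncv)
    widths: np.ndarray  # (n, ncv)
    heights: np.ndarray  # (n,)
    bias_factor: float
    initial_height: float
    cv_names: tuple = ("s", "z")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def ncv(self) -> int:
        return self.centers.shape[1]

    def __iter__(self):
        for i in range(len(self)):
            yield Hill(self.times[i], self.centers[i], self.widths[i],
                       self.heights[i])


@dataclass
class ColvarSeries:
    """Uniformly strided time series of the CVs and the instantaneous bias."""

    times: np.ndarray  # (n,)
    values: np.ndarray  # (n, ncv)
    bias: np.ndarray  # (n,)
    cv_names: tuple = ("s", "z")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class WTMetaDParams:
    """Deposition parameters; the defaults follow the host-guest protocol."""

    initial_height: float = 0.2  # kcal/mol
    bias_factor: float = 15.0
    sigma: tuple = (0.2, 0.01)  # per-CV Gaussian widths (raw S units, nm^2)
    pace: int = 500  # steps between depositions
    wall_position: float | None = 0.05  # nm^2, upper wall on Z
    wall_constant: float = 2000.0  # kcal/mol/nm^4
    wall_cv: int = 1  # index of the walled CV

    def __post_init__(self) -> None:
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("Gaussian widths must be positive")
        if self.pace < 1:
            raise ValueError("pace must be >= 1")


def next_height(initial_height: float, bias_factor: float,
                current_bias: float, temperature: float) -> float:
    """Tempered height w0 * exp(-V / ((gamma - 1) kT))."""
    if bias_factor <= 1:
        raise ValueError("bias factor must exceed 1")
    return initial_height * math.exp(
        -current_bias / ((bias_factor - 1.0) * kt(temperature)))


def bias_energy(point, hills: HillsLedger | Sequence[Hill]) -> float:
    """Exact sum of deposited Gaussians at a CV-space point."""
    point = np.atleast_1d(np.asarray(point, dtype=float))
    total = 0.0
    for h in hills:
        arg = ((point - h.center) ** 2 / (2.0 * h.widths ** 2)).sum()
        total += h.height * math.exp(-arg)
    return total


def bias_force(point, hills: HillsLedger | Sequence[Hill]) -> np.ndarray:
    """Minus the CV-space gradient of the summed Gaussians."""
    point = np.atleast_1d(np.asarray(point, dtype=float))
    grad = np.zeros_like(point)  # dV/dcv
    for h in hills:
        d = point - h.center
        g = h.height * math.exp(-(d ** 2 / (2.0 * h.widths ** 2)).sum())
        grad += g * (-d / h.widths ** 2)
    return -grad


def wall_energy(value: float, position: float, constant: float) -> float:
    """One-sided harmonic upper wall k * (v - v0)^2, zero below the wall."""
    d = value - position
    return constant * d * d if d > 0 else 0.0


# ---------------------------------------------------------------------------
# grid-accumulated bias (engine internal, keeps per-step cost O(1))


class GridBias:
    """Bias potential and its CV-gradient accumulated on a regular grid."""

    def __init__(self, axes: Sequence[tuple]):
        # axes: ((lo, hi, n), ...) one per CV, ncv in {1, 2}
        self.ncv = len(axes)
        self.axes = [np.linspace(lo, hi, int(n)) for lo, hi, n in axes]
        self.lo = np.array([a[0] for a in self.axes])
        self.dx = np.array([a[1] - a[0] for a in self.axes])
        self.nn = np.array([len(a) for a in self.axes])
        shape = tuple(self.nn)
        self.v = np.zeros(shape)
        self.grad = [np.zeros(shape) for _ in range(self.ncv)]

    def deposit(self, center: np.ndarray, widths: np.ndarray,
                height: float) -> None:
        if self.ncv == 1:
            d = self.axes[0] - center[0]
            g = height * np.exp(-d ** 2 / (2 * widths[0] ** 2))
            self.v += g
            self.grad[0] += g * (-d / widths[0] ** 2)
        else:
            d0 = self.axes[0] - center[0]
            d1 = self.axes[1] - center[1]
            g0 = np.exp(-d0 ** 2 / (2 * widths[0] ** 2))
            g1 = np.exp(-d1 ** 2 / (2 * widths[1] ** 2))
            g = height * np.outer(g0, g1)
            self.v += g
            self.grad[0] += g * (-d0 / widths[0] ** 2)[:, None]
            self.grad[1] += g * (-d1 / widths[1] ** 2)[None, :]

    def _locate(self, point):
        u = (point - self.lo) / self.dx
        i = np.clip(u.astype(int), 0, self.nn - 2)
        f = np.clip(u - i, 0.0, 1.0)
        return i, f

    def value_and_grad(self, point: np.ndarray):
        i, f = self._locate(point)
        if self.ncv == 1:
            i0, f0 = i[0], f[0]
            val = (1 - f0) * self.v[i0] + f0 * self.v[i0 + 1]
            g0 = (1 - f0) * self.grad[0][i0] + f0 * self.grad[0][i0 + 1]
            return float(val), np.array([g0])
        i0, i1 = i
        f0, f1 = f
        w00 = (1 - f0) * (1 - f1)
        w01 = (1 - f0) * f1
        w10 = f0 * (1 - f1)
        w11 = f0 * f1

        def interp(a):
            return (w00 * a[i0, i1] + w01 * a[i0, i1 + 1]
                    + w10 * a[i0 + 1, i1] + w11 * a[i0 + 1, i1 + 1])

        return float(interp(self.v)), np.array(
            [interp(self.grad[0]), interp(self.grad[1])])


# ---------------------------------------------------------------------------
# Langevin dynamics


def langevin_coefficients(mass: float, dt: float, friction: float,
                          temperature: float) -> tuple[float, float]:
    """(c1, c2) for the OU substep of the BAOAB splitting (MD units)."""
    c1 = math.exp(-friction * dt)
    kt_md = kt(temperature) * KCAL_TO_MD  # amu nm^2/ps^2
    c2 = math.sqrt(kt_md * (1.0 - c1 * c1) / mass)
    return c1, c2


def langevin_step(x: np.ndarray, v: np.ndarray, accel: np.ndarray,
                  force_fn: Callable[[np.ndarray], np.ndarray],
                  mass: float, dt: float, c1: float, c2: float,
                  noise: np.ndarray):
    """One BAOAB step of underdamped Langevin dynamics.

    ``accel`` is the cached acceleration at ``x`` (nm/ps^2); the returned
    triple carries the new cached acceleration so the force is evaluated
    once per step.  Each force enters two half-kicks: the trailing one here
    and the leading one of the next call, via the cached acceleration.
    Deterministic given the supplied ``noise`` vector.
    """
    v = v + 0.5 * dt * accel
    x = x + 0.5 * dt * v
    v = c1 * v + c2 * noise
    x = x + 0.5 * dt * v
    f = force_fn(x)
    if not np.isfinite(f).all():
        raise FloatingPointError("non-finite force")
    accel = f * (KCAL_TO_MD / mass)
    v = v + 0.5 * dt * accel
    return x, v, accel


# ---------------------------------------------------------------------------
# the WT-MetaD run


def run_wtmetad(system: ToySystem, cv, params: WTMetaDParams, n_steps: int,
                seed: int, dt: float = 0.002, friction: float = 5.0,
                x0: np.ndarray | None = None, stride: int = 50,
                grid: Sequence[tuple] | None = None
                ) -> tuple[HillsLedger, ColvarSeries]:
    """Run WT-MetaD on a toy system, biasing the CVs of ``cv``.

    A hill is deposited every ``params.pace`` steps at the current CV point
    with the tempered height; the one-sided wall (if configured and the CV
    count allows) restrains ``params.wall_cv``.  ``grid`` bounds the internal
    bias accumulation; it must generously cover the reachable CV range.
    """
    rng = np.random.default_rng(seed)
    ncv = cv.ncv
    sigma = np.asarray(params.sigma[:ncv], dtype=float)
    if grid is None:
        if isinstance(cv, IdentityCV) and system.domain:
            grid = [(lo - 0.5, hi + 0.5, 400) for lo, hi in
                    [system.domain[j] for j in cv.indices]]
        else:
            raise ValueError("a bias grid specification is required")
    gridbias = GridBias(grid)

    wall_on = (params.wall_position is not None and ncv > params.wall_cv)

    x = (np.zeros(system.dim) if x0 is None
         else np.asarray(x0, dtype=float).copy())
    kt_md = kt(system.temperature) * KCAL_TO_MD
    v = rng.standard_normal(system.dim) * math.sqrt(kt_md / system.mass)
    c1, c2 = langevin_coefficients(system.mass, dt, friction,
                                   system.temperature)

    cvals, jac = cv.value_and_jacobian(x)

    def total_force(pos):
        nonlocal cvals, jac
        f = system.force(pos)
        cvals, jac = cv.value_and_jacobian(pos)
        _, gv = gridbias.value_and_grad(cvals)
        if wall_on:
            d = cvals[params.wall_cv] - params.wall_position
            if d > 0:
                gv = gv.copy()
                gv[params.wall_cv] += 2.0 * params.wall_constant * d
        return f - gv @ jac

    accel = total_force(x) * (KCAL_TO_MD / system.mass)

    h_times, h_centers, h_heights = [], [], []
    c_times, c_vals, c_bias = [], [], []
    pace, w0, gamma = params.pace, params.initial_height, params.bias_factor
    step = 0
    while step < n_steps:
        chunk = min(pace, n_steps - step)
        noise = rng.standard_normal((chunk, system.dim))
        for k in range(chunk):
            x, v, accel = langevin_step(x, v, accel, total_force,
                                        system.mass, dt, c1, c2, noise[k])
            step += 1
            if step % stride == 0:
                vb, _ = gridbias.value_and_grad(cvals)
                c_times.append(step * dt)
                c_vals.append(cvals.copy())
                c_bias.append(vb)
        if chunk == pace and step % pace == 0:
            vb, _ = gridbias.value_and_grad(cvals)
            h = next_height(w0, gamma, vb, system.temperature)
            gridbias.deposit(cvals, sigma, h)
            h_times.append(step * dt)
            h_centers.append(cvals.copy())
            h_heights.append(h)

    names = ("s", "z")[:ncv]
    ledger = HillsLedger(
        times=np.array(h_times), centers=np.array(h_centers).reshape(-1, ncv),
        widths=np.tile(sigma, (len(h_times), 1)),
        heights=np.array(h_heights), bias_factor=gamma, initial_height=w0,
        cv_names=names)
    series = ColvarSeries(times=np.array(c_times),
                          values=np.array(c_vals).reshape(-1, ncv),
                          bias=np.array(c_bias), cv_names=names)
    return ledger, series


# ---------------------------------------------------------------------------
# HILLS / COLVAR plain-text dialect


def write_hills(ledger: HillsLedger, filename: str | Path) -> None:
    names = list(ledger.cv_names)
    fields = (["time"] + names + [f"sigma_{n}" for n in names]
              + ["height", "biasf"])
    lines = ["#! FIELDS " + " ".join(fields)]
    for i in range(len(ledger)):
        row = ([ledger.times[i]] + list(ledger.centers[i])
               + list(ledger.widths[i])
               + [ledger.heights[i], ledger.bias_factor])
        lines.append(" ".join(f"{x:.10g}" for x in row))
    Path(filename).write_text("\n".join(lines) + "\n")


def read_hills(filename: str | Path,
               initial_height: float | None = None) -> HillsLedger:
    """Read a HILLS file; tolerant to comment lines after the header."""
    lines = Path(filename).read_text().splitlines()
    header = None
    rows = []
    for line in lines:
        if line.startswith("#!"):
            if header is None and "FIELDS" in line:
                header = line.split()[2:]
            continue
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(t) for t in line.split()])
    if header is None or not rows:
        raise ValueError(f"{filename}: not a HILLS file or empty")
    data = np.array(rows)
    cols = {n: i for i, n in enumerate(header)}
    names = [n for n in header
             if n not in ("time", "height", "biasf")
             and not n.startswith("sigma_")]
    centers = np.column_stack([data[:, cols[n]] for n in names])
    widths = np.column_stack([data[:, cols[f"sigma_{n}"]] for n in names])
    heights = data[:, cols["height"]]
    biasf = float(data[0, cols["biasf"]]) if "biasf" in cols else 1.0
    return HillsLedger(
        times=data[:, cols["time"]], centers=centers, widths=widths,
        heights=heights, bias_factor=biasf,
        initial_height=(float(heights.max()) if initial_height is None
                        else initial_height),
        cv_names=tuple(names))


def write_colvar(series: ColvarSeries, filename: str | Path) -> None:
    names = list(series.cv_names)
    lines = ["#! FIELDS time " + " ".join(names) + " bias"]
    for i in range(len(series)):
        row = [series.times[i]] + list(series.values[i]) + [series.bias[i]]
        lines.append(" ".join(f"{x:.10g}" for x in row))
    Path(filename).write_text("\n".join(lines) + "\n")


def read_colvar(filename: str | Path) -> ColvarSeries:
    lines = Path(filename).read_text().splitlines()
    header = None
    rows = []
    for line in lines:
        if line.startswith("#!"):
            if header is None and "FIELDS" in line:
                header = line.split()[2:]
            continue
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(t) for t in line.split()])
    if header is None or not rows:
        raise ValueError(f"{filename}: not a COLVAR file or empty")
    data = np.array(rows)
    cols = {n: i for i, n in enumerate(header)}
    names = [n for n in header if n not in ("time", "bias")]
    values = np.column_stack([data[:, cols[n]] for n in names])
    bias = (data[:, cols["bias"]] if "bias" in cols
            else np.zeros(len(data)))
    return ColvarSeries(times=data[:, cols["time"]], values=values,
                        bias=bias, cv_names=tuple(names))
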