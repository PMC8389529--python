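"""Synthetic systems and data generators used for testing and demos.

Three families, all reproducible from a seed:

* noisy point clouds around a curved 1-D manifold (a quarter circle), the
  natural test bed for the principal-path machinery;
* analytic toy potentials with exactly integrable free energies: a 1-D
  double well and a 2-D "host-guest" funnel (a deep bound well connected by
  a narrow channel to a flat plateau, harmonically confined in the spare
  dimensions), so the end-to-end binding free energy can be checked against
  direct quadrature;
* dG_b-vs-divider curves with known inflection structure for the
  dividing-frame logic.

These toys emulate the *shape* of an unbinding problem (metastable bound
state, barrier, entropic bulk) at desk scale; they have no solvent, no
force field and no rotational degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .geometry import Conformation
from .metad_engine import ToySystem
from .principal_path import PointsCloud
from .units import kt


# ---------------------------------------------------------------------------
# point clouds for path finding


def arc_cloud(n: int = 200, noise: float = 0.05, seed: int = 0,
              radius: float = 1.0) -> tuple[PointsCloud, np.ndarray]:
    """Noisy samples around a quarter circle, ordered by arc position.

    Returns the cloud and the (2, 2) endpoints array (the exact arc ends).
    """
    rng = np.random.default_rng(seed)
    theta = np.sort(rng.uniform(0.0, np.pi / 2, n))
    r = radius + noise * rng.standard_normal(n)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    endpoints = np.array([[radius, 0.0], [0.0, radius]])
    return PointsCloud(samples=pts), endpoints


# ---------------------------------------------------------------------------
# 1-D double well


@dataclass
class DoubleWellSpec:
    barrier: float = 3.0  # kcal/mol
    half_separation: float = 0.7  # nm, minima at +-a
    temperature: float = 300.0


def double_well_system(spec: DoubleWellSpec | None = None) -> ToySystem:
    """Symmetric quartic double well U = B ((x/a)^2 - 1)^2."""
    spec = spec or DoubleWellSpec()
    b, a = spec.barrier, spec.half_separation

    def energy(x):
        u = (x[0] / a) ** 2 - 1.0
        return b * u * u

    def force(x):
        u = (x[0] / a) ** 2 - 1.0
        return np.array([-4.0 * b * u * x[0] / a ** 2])

    lim = a * (1.0 + (8.0 * kt(spec.temperature) / b) ** 0.25)
    return ToySystem(dim=1, energy=energy, force=force,
                     temperature=spec.temperature, mass=1.0,
                     domain=((-lim, lim),), name="double-well")


def double_well_profile(spec: DoubleWellSpec, x: np.ndarray) -> np.ndarray:
    """Exact free energy profile (the potential itself, gauged to 0)."""
    u = spec.barrier * ((x / spec.half_separation) ** 2 - 1.0) ** 2
    return u - u.min()


# ---------------------------------------------------------------------------
# 2-D funnel ("host-guest") system


@dataclass
class FunnelSpec:
    """Analytic parameters of the toy unbinding funnel (kcal/mol, nm)."""

    well_depth: float = 4.0  # A: bound-state well
    well_width: float = 0.12  # sigma of the bound well
    barrier_height: float = 1.5  # B: exit barrier
    barrier_pos: float = 0.35  # x_b
    barrier_width: float = 0.08
    k_channel: float = 80.0  # harmonic confinement across the channel (y)
    k_spare: float = 80.0  # confinement of the spare z coordinate
    x_lo: float = -0.25  # soft quartic walls closing the channel
    x_hi: float = 0.9
    k_edge: float = 10000.0  # kcal/mol/nm^4
    temperature: float = 300.0


def funnel_system(spec: FunnelSpec | None = None) -> ToySystem:
    """Bound well + exit barrier + flat channel, embedded in 3-D.

    The spare z coordinate is an independent harmonic mode, so it cancels
    exactly in the bound/unbound partition-function ratio; the reference
    binding free energy is a 2-D quadrature.
    """
    spec = spec or FunnelSpec()
    a, sw = spec.well_depth, spec.well_width
    b, xb, sb = spec.barrier_height, spec.barrier_pos, spec.barrier_width
    ky, kz, ke = spec.k_channel, spec.k_spare, spec.k_edge
    xlo, xhi = spec.x_lo, spec.x_hi

    def energy(p):
        x, y = p[0], p[1]
        z = p[2] if len(p) > 2 else 0.0
        u = (-a * math.exp(-(x * x + y * y) / (2 * sw * sw))
             + b * math.exp(-((x - xb) ** 2) / (2 * sb * sb))
             + 0.5 * ky * y * y + 0.5 * kz * z * z)
        if x > xhi:
            u += ke * (x - xhi) ** 4
        elif x < xlo:
            u += ke * (x - xlo) ** 4
        return u

    def force(p):
        # fx, fy accumulate dU/dx, dU/dy; negated at the end
        x, y = p[0], p[1]
        gwell = -a * math.exp(-(x * x + y * y) / (2 * sw * sw))
        gbar = b * math.exp(-((x - xb) ** 2) / (2 * sb * sb))
        fx = -gwell * x / (sw * sw) - gbar * (x - xb) / (sb * sb)
        fy = -gwell * y / (sw * sw) + ky * y
        if x > xhi:
            fx += 4.0 * ke * (x - xhi) ** 3
        elif x < xlo:
            fx += 4.0 * ke * (x - xlo) ** 3
        out = np.empty(len(p))
        out[0] = -fx
        out[1] = -fy
        if len(p) > 2:
            out[2] = -kz * p[2]
        return out

    return ToySystem(dim=3, energy=energy, force=force,
                     temperature=spec.temperature, mass=1.0,
                     domain=((xlo - 0.3, xhi + 0.3), (-0.6, 0.6),
                             (-0.5, 0.5)),
                     name="funnel")


def _funnel_energy_2d(spec: FunnelSpec, x, y):
    a, sw = spec.well_depth, spec.well_width
    b, xb, sb = spec.barrier_height, spec.barrier_pos, spec.barrier_width
    u = (-a * np.exp(-(x ** 2 + y ** 2) / (2 * sw ** 2))
         + b * np.exp(-((x - xb) ** 2) / (2 * sb ** 2))
         + 0.5 * spec.k_channel * y ** 2)
    u = u + np.where(x > spec.x_hi, spec.k_edge * (x - spec.x_hi) ** 4, 0.0)
    u = u + np.where(x < spec.x_lo, spec.k_edge * (x - spec.x_lo) ** 4, 0.0)
    return u


def funnel_divider_x(spec: FunnelSpec | None = None) -> float:
    """The natural bound/unbound divider: the top of the exit barrier."""
    spec = spec or FunnelSpec()
    return spec.barrier_pos


def funnel_exact_dg(spec: FunnelSpec | None = None,
                    x_divider: float | None = None,
                    method: str = "trapezoid") -> float:
    """Reference dG_b = -kT ln(Q_site/Q_bulk) by direct 2-D quadrature.

    ``method`` selects one of two independent quadrature routes
    ("trapezoid": dense grid + trapezoidal rule; "quad": adaptive
    scipy.integrate.dblquad), which agree to ~1e-6 and cross-check each
    other.
    """
    spec = spec or FunnelSpec()
    xd = funnel_divider_x(spec) if x_divider is None else x_divider
    ktt = kt(spec.temperature)
    xa, xb_ = spec.x_lo - 0.35, spec.x_hi + 0.35
    ya, yb = -0.6, 0.6
    if method == "trapezoid":
        x = np.linspace(xa, xb_, 4001)
        y = np.linspace(ya, yb, 801)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        w = np.exp(-_funnel_energy_2d(spec, xx, yy) / ktt)
        gy = np.trapezoid(w, y, axis=1)
        mask_site = x <= xd
        g_at = np.interp(xd, x, gy)
        xs = np.append(x[mask_site], xd)
        gs = np.append(gy[mask_site], g_at)
        xu = np.insert(x[~mask_site], 0, xd)
        gu = np.insert(gy[~mask_site], 0, g_at)
        q_site = np.trapezoid(gs, xs)
        q_bulk = np.trapezoid(gu, xu)
    elif method == "quad":
        def integrand(y_, x_):
            return math.exp(-_funnel_energy_2d(spec, x_, y_) / ktt)

        q_site, _ = integrate.dblquad(integrand, xa, xd, ya, yb,
                                      epsabs=1e-12, epsrel=1e-10)
        q_bulk, _ = integrate.dblquad(integrand, xd, xb_, ya, yb,
                                      epsabs=1e-12, epsrel=1e-10)
    else:
        raise ValueError(f"unknown quadrature method {method!r}")
    return float(-ktt * np.log(q_site / q_bulk))


def funnel_guess_path(spec: FunnelSpec | None = None, n_frames: int = 120,
                      noise: float = 0.04, seed: int = 0,
                      x_end: float = 0.85) -> list[Conformation]:
    """A noisy guess unbinding trajectory: single-particle frames along the channel.

    Emulates the output of a crude steering run: ordered frames from the
    bound well to the far plateau with transverse thermal noise.
    """
    spec = spec or FunnelSpec()
    rng = np.random.default_rng(seed)
    x = np.linspace(-0.05, x_end, n_frames)
    y = noise * rng.standard_normal(n_frames)
    z = noise * rng.standard_normal(n_frames)
    path = []
    for i in range(n_frames):
        path.append(Conformation(coords=np.array([[x[i], y[i], z[i]]]),
                                 elements=np.array(["C"]),
                                 names=np.array(["P1"]), frame_id=i))
    return path


# ---------------------------------------------------------------------------
# dG_b(s*) curves with known inflection structure


def logistic_dg_curve(n: int = 201, amplitude: float = 6.0,
                      steepness: float = 25.0, s0: float = 0.4
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Smooth sigmoidal dG_b(s*) with its analytic inflection at s0."""
    s = np.linspace(0.01, 0.99, n)
    dg = -amplitude / (1.0 + np.exp(-steepness * (s - s0)))
    return s, dg


def matching_pmf(n: int = 201, s0: float = 0.4, barrier: float = 3.0,
                 width: float = 0.06) -> tuple[np.ndarray, np.ndarray]:
    """A PMF with a transition-state-like barrier at s0 and a bound well at 0."""
    s = np.linspace(0.0, 1.0, n)
    f = (barrier * np.exp(-((s - s0) ** 2) / (2 * width ** 2))
         - 4.0 * np.exp(-(s ** 2) / (2 * 0.1 ** 2)))
    return s, f - f.min()


def two_plateau_dg_curve(n: int = 201, step: float = 5.0, s0: float = 0.5,
                         steepness: float = 120.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Two flat plateaus joined by a single sharp step at s0."""
    s = np.linspace(0.01, 0.99, n)
    dg = -step / (1.0 + np.exp(-steepness * (s - s0)))
    return s, dg


def featureless_pmf(n: int = 201) -> tuple[np.ndarray, np.ndarray]:
    """A monotone PMF with no interior barrier (no local maxima)."""
    s = np.linspace(0.0, 1.0, n)
    return s, 5.0 * s
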