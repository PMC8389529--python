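"""Free energy surface reconstruction and the standard binding free energy.

The FES over the path variables is the tempered sum of deposited hills,

    F(S, Z) = -(gamma / (gamma - 1)) * V_bias(S, Z),     min F = 0,

and the binding free energy follows from the partition-function ratio of the
bound and unbound regions of the surface,

    dG_b = -kT ln(Q_site / Q_bulk),
    Q_site = ∫∫_{s < s*} exp(-F/kT) ds dz,   Q_bulk = ∫∫_{s >= s*} ...,

with the dividing value s* located from the inflection structure of the
dG_b(s*) curve cross-checked against the barrier structure of the 1-D PMF.
The standard-state correction dG_V = kT ln(V_bulk / V°) converts the result
to the 1 M reference (V° = 1661 Å^3):  dG°_b = dG_b + dG_V.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .metad_engine import GridBias, HillsLedger, ColvarSeries
from .units import kt

#: standard-state volume at 1 M, Å^3 (printed convention)
V_STANDARD = 1661.0


class NoDividerError(RuntimeError):
    """No inflection point separates bound and unbound states.

    The dividing frame cannot be assigned automatically; human intervention
    is needed (supply it manually)."""


@dataclass
class FreeEnergySurface:
    """F on a regular (s,) or (s, z) grid, gauged so the minimum is zero."""

    s_axis: np.ndarray
    values: np.ndarray  # (ns,) or (ns, nz), kcal/mol
    z_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("FES values must be finite")
        self.values = self.values - self.values.min()

    @property
    def is_2d(self) -> bool:
        return self.z_axis is not None


@dataclass
class DividingFrame:
    """The bound/unbound divider x*: rescaled progress value plus provenance."""

    s_star: float
    frame_index: int
    method: str  # "first-inflection" | "midpoint-fallback" | "manual"

    def __post_init__(self) -> None:
        if not 0.0 < self.s_star < 1.0:
            raise ValueError("s_star must lie strictly inside (0, 1)")


@dataclass
class ConvergenceWindow:
    t_start: float
    t_end: float
    converged: bool
    residual_fraction: float  # max hill height in window / initial height
    diffusive: bool


@dataclass
class BindingResult:
    dg_b: float  # kcal/mol
    dg_v: float
    dg_standard: float
    stderr: float
    v_bulk: float  # Å^3
    divider: DividingFrame | None = None
    converged_window: tuple | None = None
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FES reconstruction


def fes_from_hills(hills: HillsLedger, grid, gamma: float | None = None,
                   rescale_s: int | None = None) -> FreeEnergySurface:
    """Tempered negative hill sum on a regular grid.

    ``grid`` is ((lo, hi, n), ...) in the raw CV coordinates of the hills.
    With ``rescale_s = P`` the s axis is mapped from raw frame units (1..P)
    to the rescaled [0, 1] convention.
    """
    if len(hills) == 0:
        raise ValueError("empty hills ledger")
    gamma = hills.bias_factor if gamma is None else gamma
    gb = GridBias(grid)
    for i in range(len(hills)):
        gb.deposit(hills.centers[i], hills.widths[i], hills.heights[i])
    factor = gamma / (gamma - 1.0)
    values = -factor * gb.v
    s_axis = gb.axes[0]
    if rescale_s is not None:
        s_axis = (s_axis - 1.0) / (rescale_s - 1.0)
    z_axis = gb.axes[1] if len(gb.axes) > 1 else None
    return FreeEnergySurface(s_axis=s_axis, values=values, z_axis=z_axis)


def _boltzmann_profile(fes: FreeEnergySurface, temperature: float,
                       z_max: float | None = None) -> np.ndarray:
    """g(s) = ∫ exp(-F/kT) dz (or exp(-F/kT) itself for a 1-D surface)."""
    ktt = kt(temperature)
    if not fes.is_2d:
        return np.exp(-fes.values / ktt)
    z = fes.z_axis
    w = np.exp(-fes.values / ktt)
    if z_max is not None:
        mask = z <= z_max
        if mask.sum() < 2:
            raise ValueError("z_max leaves fewer than two grid columns")
        return np.trapezoid(w[:, mask], z[mask], axis=1)
    return np.trapezoid(w, z, axis=1)


def pmf_along_s(fes: FreeEnergySurface, temperature: float,
                z_max: float | None = None) -> np.ndarray:
    """1-D potential of mean force along s, gauged to zero at its minimum."""
    g = _boltzmann_profile(fes, temperature, z_max)
    f = -kt(temperature) * np.log(np.maximum(g, 1e-300))
    return f - f.min()


def _split_integral(s: np.ndarray, g: np.ndarray,
                    s_star: float) -> tuple[float, float]:
    """Trapezoidal integrals of g over [s0, s*] and [s*, s1]."""
    if not s[0] < s_star < s[-1]:
        raise ValueError("divider outside the s grid: empty region")
    g_star = float(np.interp(s_star, s, g))
    left = s <= s_star
    right = s >= s_star
    s_left = np.append(s[left], s_star)
    g_left = np.append(g[left], g_star)
    s_right = np.insert(s[right], 0, s_star)
    g_right = np.insert(g[right], 0, g_star)
    return (float(np.trapezoid(g_left, s_left)),
            float(np.trapezoid(g_right, s_right)))


def dg_bound_unbound(fes: FreeEnergySurface, divider: "DividingFrame | float",
                     temperature: float = 300.0,
                     z_max: float | None = None) -> float:
    """-kT ln(Q_site / Q_bulk) with the site/bulk split at the divider."""
    s_star = divider.s_star if isinstance(divider, DividingFrame) else float(divider)
    g = _boltzmann_profile(fes, temperature, z_max)
    q_site, q_bulk = _split_integral(fes.s_axis, g, s_star)
    return float(-kt(temperature) * np.log(q_site / q_bulk))


def dg_vs_divider_curve(fes: FreeEnergySurface, temperature: float,
                        candidates) -> np.ndarray:
    """dG_b evaluated for every candidate divider (inflection analysis input)."""
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size < 10:
        raise ValueError("need at least 10 candidate dividers")
    g = _boltzmann_profile(fes, temperature)
    out = np.empty(candidates.size)
    for i, s_star in enumerate(candidates):
        q_site, q_bulk = _split_integral(fes.s_axis, g, s_star)
        out[i] = -kt(temperature) * np.log(q_site / q_bulk)
    return out


# ---------------------------------------------------------------------------
# dividing-frame identification


def _smooth(y: np.ndarray, window_fraction: float) -> np.ndarray:
    n = len(y)
    win = max(5, int(round(window_fraction * n)))
    if win % 2 == 0:
        win += 1
    if win >= n:
        win = n - 1 if (n - 1) % 2 == 1 else n - 2
    if win < 5:
        return y.copy()
    return savgol_filter(y, win, polyorder=2)


def find_x_star(curve_s: np.ndarray, curve_dg: np.ndarray,
                pmf_s: np.ndarray | None = None,
                pmf_f: np.ndarray | None = None,
                n_frames: int | None = None,
                smooth_window: float = 0.05,
                barrier_window: float = 0.05) -> DividingFrame:
    """Locate the bound/unbound divider from the dG_b(s*) curve.

    The curve is smoothed with a local quadratic filter, inflection
    candidates are the significant sign changes of its second derivative,
    and the first candidate (from the bound side) whose position coincides
    with a local maximum of the PMF within ``barrier_window`` is accepted.
    If no candidate survives the barrier cross-check and the curve shows a
    single sharp step between two plateaus, the midpoint of the two
    curvature extrema bracketing the step is returned instead.  A curve with
    no significant inflection (e.g. strictly linear) raises
    :class:`NoDividerError`.
    """
    s = np.asarray(curve_s, dtype=float)
    y = np.asarray(curve_dg, dtype=float)
    if len(s) < 10:
        raise ValueError("curve sampled too sparsely")
    ys = _smooth(y, smooth_window)
    dy = np.gradient(ys, s)
    d2 = np.gradient(dy, s)
    span_y = ys.max() - ys.min()
    span_s = s[-1] - s[0]
    if span_y <= 0 or span_s <= 0:
        raise NoDividerError("flat dG_b curve: no divider; "
                             "human intervention is needed")
    tau = 1e-4 * span_y / span_s ** 2
    if np.abs(d2).max() < tau:
        raise NoDividerError("no significant inflection on the dG_b curve "
                             "(monotone/linear); human intervention is needed")
    # significant zero crossings of the second derivative
    candidates = []
    for i in range(1, len(s) - 1):
        if d2[i] == 0 or d2[i] * d2[i + 1] < 0:
            lo = max(0, i - max(2, len(s) // 50))
            hi = min(len(s), i + max(3, len(s) // 50))
            if np.abs(d2[lo:i + 1]).max() >= tau and np.abs(d2[i:hi]).max() >= tau:
                si = float(s[i]) if d2[i] == 0 else float(
                    s[i] - d2[i] * (s[i + 1] - s[i]) / (d2[i + 1] - d2[i]))
                if s[0] < si < s[-1]:
                    candidates.append(si)
    if not candidates:
        raise NoDividerError("no inflection point found on the dG_b curve; "
                             "human intervention is needed")

    def _frame(si: float) -> int:
        if n_frames is not None:
            return int(round(si * (n_frames - 1)))
        return int(np.argmin(np.abs(s - si)))

    if pmf_s is not None and pmf_f is not None:
        pmf_s = np.asarray(pmf_s, dtype=float)
        pmf_f = np.asarray(pmf_f, dtype=float)
        peaks, _ = find_peaks(pmf_f)
        barrier_s = pmf_s[peaks]
        for si in candidates:
            if any(abs(si - sm) <= barrier_window for sm in barrier_s):
                return DividingFrame(si, _frame(si), "first-inflection")

    if len(candidates) == 1:
        # single sharp step between two plateaus: take the midpoint of the
        # two curvature extrema bracketing the step
        si = 0.5 * (float(s[int(np.argmax(d2))]) + float(s[int(np.argmin(d2))]))
        si = min(max(si, s[1]), s[-2])
        return DividingFrame(float(si), _frame(si), "midpoint-fallback")
    si = candidates[0]
    return DividingFrame(si, _frame(si), "first-inflection")


# ---------------------------------------------------------------------------
# corrections, convergence and statistics


def volume_correction(v_bulk: float, temperature: float = 300.0,
                      v_standard: float = V_STANDARD) -> float:
    """Standard-state correction dG_V = kT ln(V_bulk / V°), kcal/mol.

    Positive when the sampled unbound volume exceeds the 1 M volume per
    molecule: confining the free ligand to V° costs entropy.
    """
    if v_bulk <= 0:
        raise ValueError("bulk volume must be positive")
    return float(kt(temperature) * np.log(v_bulk / v_standard))


def convergence_window(hills: HillsLedger, colvar: ColvarSeries,
                       height_fraction: float = 0.1,
                       span_fraction: float = 0.9,
                       n_subwindows: int = 5,
                       smoothing_hills: int = 51) -> ConvergenceWindow:
    """Locate the converged tail of a WT-MetaD run.

    The window [t_start, t_end] is the earliest suffix in which (a) the
    rolling mean (over ``smoothing_hills`` deposits) of the hill heights
    stays below ``height_fraction`` of the initial height and (b) the S
    variable is diffusive: every sliding sub-window (the suffix is cut into
    ``n_subwindows`` half-overlapping pieces) spans at least
    ``span_fraction`` of the globally visited S range.

    Individual hills are smoothed before thresholding because even a
    well-converged run keeps dropping occasional near-full-height hills in
    rarely visited corners of CV space (against the Z wall, beyond the path
    ends); the instantaneous height is not a stationary convergence signal.
    """
    if len(hills) == 0 or len(colvar) == 0:
        raise ValueError("empty hills or colvar input")
    t_end = float(colvar.times[-1])
    w0 = hills.initial_height
    win = max(1, min(smoothing_hills, len(hills)))
    kernel = np.ones(win)
    # normalize by the actual number of hills under the kernel so the edges
    # are true running means, not zero-padded (attenuated) ones
    smoothed = (np.convolve(hills.heights, kernel, mode="same")
                / np.convolve(np.ones(len(hills)), kernel, mode="same"))
    ok_height = smoothed < height_fraction * w0
    # require the smoothed series to stay below threshold to the end
    bad = np.flatnonzero(~ok_height)
    if bad.size:
        ok_height[:bad[-1] + 1] = False
    s_series = colvar.values[:, 0]
    s_lo, s_hi = float(s_series.min()), float(s_series.max())
    global_span = s_hi - s_lo

    def diffusive_from(t0: float) -> bool:
        mask = colvar.times >= t0
        tt = colvar.times[mask]
        ss = s_series[mask]
        if len(tt) < 4 or tt[-1] <= t0:
            return False
        width = (tt[-1] - t0) / n_subwindows
        if width <= 0:
            return False
        starts = np.arange(t0, tt[-1] - width + 1e-12, width / 2)
        for a in starts:
            sel = (tt >= a) & (tt <= a + width)
            if sel.sum() < 2:
                return False
            span = ss[sel].max() - ss[sel].min()
            if span < span_fraction * global_span:
                return False
        return True

    candidates = np.flatnonzero(ok_height)
    resid = float(smoothed[-1] / w0)
    # try at most ~50 start points, earliest first
    stride = max(1, len(candidates) // 50)
    for i in candidates[::stride]:
        t0 = float(hills.times[i])
        if t0 >= t_end:
            break
        if diffusive_from(t0):
            return ConvergenceWindow(t0, t_end, True, resid, True)
    return ConvergenceWindow(t_end, t_end, False, resid, False)


def dg_time_stats(dg_series) -> tuple[float, float]:
    """Mean and standard error of a dG series over the converged window."""
    dg_series = np.asarray(dg_series, dtype=float)
    if dg_series.size < 2:
        raise ValueError("need at least two points")
    mean = float(dg_series.mean())
    stderr = float(dg_series.std(ddof=1) / np.sqrt(dg_series.size))
    return mean, stderr


def dg_time_series(hills: HillsLedger, grid, s_star: float,
                   temperature: float, checkpoint_times,
                   rescale_s: int | None = None,
                   z_max: float | None = None) -> np.ndarray:
    """dG_b recomputed from the hills accumulated up to each checkpoint."""
    out = []
    for t in checkpoint_times:
        n = int(np.searchsorted(hills.times, t, side="right"))
        if n < 1:
            out.append(np.nan)
            continue
        sub = HillsLedger(times=hills.times[:n], centers=hills.centers[:n],
                          widths=hills.widths[:n], heights=hills.heights[:n],
                          bias_factor=hills.bias_factor,
                          initial_height=hills.initial_height,
                          cv_names=hills.cv_names)
        fes = fes_from_hills(sub, grid, rescale_s=rescale_s)
        out.append(dg_bound_unbound(fes, s_star, temperature, z_max=z_max))
    return np.array(out)
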