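# Methods

Definitions, conventions and numerical choices, module by module. Units
throughout: kcal/mol (energies), nm (lengths, except SES volumes in Å/Å³),
ps (times), amu (masses). k_B = 0.0019872041 kcal/(mol·K); the Langevin
integrator converts forces to MD units with 1 kcal = 4.184 kJ.

## Geometry and RMSD (`geometry`)

Conformations are (n_atoms, 3) coordinate arrays in nm with element/name
labels. Superposition is the proper-rotation least-squares fit
(`scipy.spatial.transform.Rotation.align_vectors`), which never returns a
reflection. Selections carry a role: `align` atoms define the fit (at least
three, non-collinear — otherwise `DegenerateSelectionError`), `measure`
atoms enter the RMSD. `rmsd(a, b, align, measure)` superposes `a` onto `b`
on the align atoms (skipped when `align is None`) and evaluates the RMSD on
the measure atoms. `path_features` flattens aligned measure-atom coordinates
into feature vectors for the path fit and the path CVs.

## Principal path (`principal_path`)

The path model is a chain of `n_waypoints` free waypoints between two fixed
endpoints. The cost is the k-means data term (squared distance of every
sample to its assigned waypoint) plus `s` times the squared lengths of all
chain links (endpoint–waypoint and waypoint–waypoint). Minimization
alternates assignment and a tridiagonal linear solve for the waypoints; the
cost trace is monotonically non-increasing and iteration stops at relative
improvement < 1e-10. Empty clusters are handled by the regularization term,
which keeps the linear system non-singular. `select_smoothness` scans a
grid of `s` values and picks the elbow of the data-term curve; a degenerate
scan (data term independent of `s`) is flagged. `snap_to_samples` maps each
waypoint to its nearest sample frame, deduplicated and ordered.

The fit is validated in the tests against an exhaustive-assignment oracle
(enumerate all memberships, solve exactly per assignment) on small
instances, using multi-start alternating minimization.

## Equidistant resampling (`path_equidistance`)

For every gap between consecutive frames larger than the threshold
(default 0.1 nm = 1 Å RMSD), `ceil(d/threshold) − 1` intermediates are
requested from a propagator (default: geometric interpolation at fractions
k/(n+1); a stochastic propagator may return approximate frames within a 5%
tolerance). Insertion recurses at most 5 levels; an unproductive propagator
raises `ResampleError`. Original frames are preserved in order and frame
ids are renumbered consecutively.

## Path collective variables (`path_cv`)

With P ordered references and squared distances d_i²(x):

- S_raw(x) = Σ_i i·exp(−λ d_i²) / Σ_i exp(−λ d_i²), i = 1..P
  (rescaled variant: (S_raw − 1)/(P − 1) ∈ [0, 1]);
- Z(x) = −(1/λ) ln Σ_i exp(−λ d_i²).

λ defaults to 2.3/⟨d²⟩ with ⟨d²⟩ the mean squared interframe distance
(230 nm⁻² at the 1 Å spacing target). A warning is emitted when the
reference spacing is uneven by more than a factor 2. Distances are RMSDs
over the measure atoms after optional superposition; analytic gradients are
available for the fixed-frame (no superposition) case and are
finite-difference validated.

## Well-tempered metadynamics engine (`metad_engine`)

Dynamics: BAOAB-split underdamped Langevin with force caching (each cached
force supplies the trailing half-kick of one step and the leading half-kick
of the next). Default dt 0.002 ps, friction 5 ps⁻¹, 300 K. Equipartition
and unbiased Boltzmann sampling are test-validated.

Bias: Gaussians of per-CV widths σ deposited every `pace` steps at the
current CV point with tempered height ω = ω₀ exp(−V/((γ−1)kT)). The running
bias is accumulated on a regular grid with bilinear interpolation for O(1)
force evaluation; a one-sided harmonic wall k(z−z_wall)² optionally
restrains the second CV. HILLS and COLVAR files use a plain-text dialect
with a `#! FIELDS …` header; readers tolerate comments and blank lines.

`WTMetaDParams` defaults (ω₀ = 0.2 kcal/mol, γ = 15, σ = (0.2, 0.01),
pace 500, wall at Z = 0.05 nm²) follow the production protocol for
host–guest systems. The toy pipeline overrides them with a desk-scale
calibration (γ = 8, σ = (0.75, 0.01) in raw-S/nm² units, pace 250, wall at
0.03 nm² with k = 10⁴) sized by a bias-capacity estimate so a 2M-step run
converges on one CPU in ~2.5 minutes.

## Free energy analysis (`free_energy`)

FES: F = −(γ/(γ−1)) V from the deposited hills, gauged to min 0; the S axis
can be rescaled from frame units (1..P) to [0, 1]. The 1-D PMF along S and
all partition integrals use g(s) = ∫ exp(−F/kT) dz (trapezoid).

Binding free energy: ΔG_b = −kT ln(Q_site/Q_bulk) with the site/bulk split
at the divider s*; the divider-dependence curve ΔG_b(s*) over ≥10 candidates
feeds `find_x_star`, which smooths the curve (Savitzky–Golay, 5% window),
finds significant second-derivative sign changes, and accepts the first
inflection that coincides with a PMF barrier within ±0.05. A single sharp
step between plateaus falls back to the midpoint of the bracketing
curvature extrema; a featureless curve raises `NoDividerError` asking for a
manually supplied divider.

Standard-state correction: ΔG_V = kT ln(V_bulk/V°), V° = 1661 Å³ (the 1 M
volume per molecule, 10²⁷/N_A). Sign convention: confining the free ligand
from a larger sampled volume to V° costs entropy, so ΔG_V > 0 when
V_bulk > V°.

Convergence window: the earliest suffix of the run in which (a) the rolling
mean (51 hills, edge-normalized) of deposit heights stays below 10% of ω₀
to the end, and (b) S is diffusive — each of 5 half-overlapping sub-windows
spans ≥90% of the globally visited S range. Instantaneous heights are not
used because converged runs still drop occasional full-height hills in
rarely visited CV corners. ΔG_b is then averaged over checkpoints in the
window (mean ± standard error); an unconverged run falls back to the second
half of the ledger and is flagged.

## SES volume (`ses_volume`)

Grid probe-rolling in Å: candidate solvent points lie farther than
r_i + probe from every atom; the boundary-connected component (flood fill)
of those is the accessible probe-center set; re-entrant SES volume is the
set of near points at Euclidean-distance-transform distance ≥ probe + h/2
from it (h/2 corrects voxel-center sampling). The bare van-der-Waals union
is measured separately with anti-aliased (fractional) voxel occupancy, and
the SES volume is the union of the two parts. A single sphere at the
default 0.3 Å spacing is accurate to ~1%; thresholding the EDT alone would
alias the thin boundary shell by ~8%. Bondi-type radii; unknown elements
fall back to carbon (1.70 Å). Default probe 1.4 Å. `unbound_frames_by_contact`
selects frames with no ligand–environment contact within 0.6 nm.

## Benchmark statistics (`benchmark_stats`)

Two packaged tables: `cb8` (six host–guest complexes) and `gsk3b` (eight
kinase inhibitors), aliased `table1`/`table3` by their position in the
benchmark write-up. Metrics between computed ΔG°_b and experiment: Pearson,
Spearman, RMSE, mean error (experimental − computed), rounded half-away-
from-zero to the printed precision (2, 1, 1, 1 decimals). Bootstrap Pearson
resamples pairs with replacement, redrawing degenerate (constant-vector)
resamples, and reports the replicate mean, the standard error of that mean
and the replicate standard deviation. Rank consistency uses ordinal
(row-order tie-broken) ranks by ascending ΔG°_b, which reproduces the
printed rank columns exactly; ties trigger a warning.

Known data caveat: the source tables round ΔG_b, ΔG_V and ΔG°_b
independently to 0.1 kcal/mol, so three of the 14 printed rows violate
ΔG°_b = ΔG_b + ΔG_V by one last digit. The CSVs transcribe the printed
values faithfully.

## Pipeline (`pipeline`) and CLI

`run_pipeline(PipelineConfig)` executes validate → input → path-find →
resample → pcv → metad → fes → xstar → dg → volume, persisting every
intermediate and a `report.json` with all terms, the x* method fired,
convergence diagnostics and a per-stage log. Supplying `hills_file`
(optionally `colvar_file`) bypasses the sampling stages for analysis-only
runs. Identical config + seed gives identical outputs. `StageError` names
the failing stage and the offending path. The `pathmetad` CLI exposes each
stage as a subcommand (`path-find`, `resample`, `pcv-eval`, `metad`, `fes`,
`xstar`, `dg`, `volume`, `stats`, `pipeline`, `fixtures`).

## Toy systems and references (`fixtures`)

- Double well: U = B((x/a)² − 1)², B = 3 kcal/mol, a = 0.7 nm; the exact
  profile is the potential itself.
- Funnel: bound Gaussian well (depth 4, σ 0.12 nm) at the origin, exit
  barrier (height 1.5, σ 0.1) at x = 0.35 nm, harmonic channel in y,
  quartic edge beyond x = 0.9 nm, independent harmonic spare z (cancels in
  the ratio). Exact ΔG_b by two independent quadratures (dense trapezoid
  and adaptive `dblquad`, agreeing to <1e-6): −2.765 kcal/mol with the
  divider at the barrier top. The guess path is a noisy ordered
  single-particle trajectory along the channel.
- Analytic ΔG_b(s*) curves (logistic with known inflection, two-plateau
  step) and PMFs (barrier at the inflection; featureless monotone) for
  divider-identification tests.
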