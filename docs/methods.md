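# Methods

## Model and procedure

`trajgeom` treats a pseudotime trajectory as a curve through a
reduced-dimension expression space and asks how well-defined its
direction of motion is. The analysis has four stages.

**Spherical projection.** For an ordered path `p_1 … p_n` (n ≥ 3 points,
d ≥ 2 dimensions), the unit displacement vectors
`s_i = (p_i − p_1)/‖p_i − p_1‖` place the path's directions on the unit
hypersphere S^{d−1}. Displacements with norm ≤ `min_norm` (default
1e−8), i.e. near-duplicates of the start point, are dropped and counted
rather than normalised into NaN; a path whose displacements are all
degenerate is an error.

**msd minimisation.** The compactness statistic is
`msd(c) = mean_i arccos(c · s_i)`, minimised over unit `c`. This is a
spherical-median-type (Fréchet) problem: the objective is smooth where
no `s_i` coincides with `c`, cone-like at data points, and can be
multimodal for dispersed sets. The optimiser parametrises `c`
unconstrained and renormalises inside the objective, so the reported
center is the normalised argmin; dot products are clamped to [−1, 1]
before `arccos`. Descent is quasi-Newton (L-BFGS-B) with the analytic
gradient (its 1/√(1−(c·s)²) factor clipped at 1e−12 to stay finite at
coincident or antipodal vectors), capped at `max_steps` (default 1000)
iterations. The canonical starting point is the normalised vector sum
`Σs_i/‖Σs_i‖`; when the vector sum is numerically zero (an antipodal
pair) the first vector seeds the search and the result is flagged
unconverged if nothing improves. Two safeguards define the contract:

- *Monotone improvement*: if no candidate improves on the start by more
  than 1e−12, the starting point itself is returned. This also fixes
  the tie-break on flat minima (e.g. two orthogonal vectors, where the
  whole connecting geodesic attains π/4): the returned center is the
  deterministic starting point, and only the msd — not the center — is
  unique in such degenerate cases.
- *Multimodality fallback*: when the mean resultant length `‖Σs_i‖/m`
  falls below 0.95 the set is dispersed enough to carry several local
  minima, and a second descent is run from the best-scoring input
  vector; its result replaces the canonical one only if it is lower by
  more than 1e−9 (so flat minima keep the canonical tie-break).
  Concentrated sets — every path with real directional signal — never
  trigger it. With this fallback the optimiser agrees with an
  exhaustive grid search (0.25° global grid plus a dense local
  refinement patch) to better than 1e−4 radians on random sets of up to
  12 vectors; without it, dispersed sets could land ~3e−3 high.

**Path resampling.** Pseudotime is min-max normalised to [0, 100]
*per trajectory*. The axis is split into windows of `window_width`
(default 10) pseudotime units; the default stepping is contiguous
(step = width, half-open windows, last window closed at 100), giving ten
windows per full trajectory, and an overlapping sliding step is
available via `window_step`. One cell is drawn uniformly at random per
non-empty window; empty windows are skipped, and a path needs at least
`min_points` (default 3) surviving windows. The draw is repeated
`n_paths` times (default 1000) from one seeded generator. The first
`dims` (default 3) coordinate columns are used.

**Testing.** Each sampled path is paired with exactly one randomised
copy of itself in which every coordinate column is permuted
independently across rows — each column's value multiset is preserved
exactly while any consistent direction is destroyed. The paired
minimised msd values feed a two-sided Wilcoxon signed-rank test
(zero differences dropped and counted, standard practice). Two
trajectories are compared by a two-sided Mann–Whitney U test on their
empirical msd distributions. The branch-point scan repeats the
directionality test from start offsets t₀ (default 0, 5, …, 85),
restricting to cells with normalised pseudotime ≥ t₀ *on the original
scale* (never re-normalising the suffix, so an offset means the same
pseudotime at every step) and re-windowing the remaining range with the
configured width; offsets leaving fewer than `min_points` non-empty
windows are recorded as skipped. Raw p-values are reported per offset
(no multiple-testing correction by default, Benjamini–Hochberg
optional). A representative center — the consensus direction of the
trajectory — is obtained by running the same msd minimisation over the
per-path centers. Genes are scored as the dot product of their loading
rows with that consensus direction; scores are raw products by default
(the formula `F·c`), optionally cosines via row normalisation.

## Synthetic data

The simulators generate the geometry the method is designed to detect,
in the reduced space itself (they do not emulate count-level scRNA-seq
noise — no library-size variation, dropout, or pseudotime-inference
error; pseudotime is exact by design, since the method consumes
pseudotime as an input):

- *linear*: cells at pseudotime t ~ U(0, 100) placed at
  `(t/100)·L·direction` plus isotropic Gaussian noise with
  sd = `noise_sd`·L, with arc length L fixed at 100 so the pseudotime
  and coordinate scales coincide. Default 300 cells, d = 3,
  `noise_sd` = 0.05 (5% of the trajectory length) — enough noise that
  single paths are visibly scattered while the drift is recoverable.
- *branching*: a straight backbone plus a second lineage sharing it up
  to `branch_time` (default 50) and then departing along an orthogonal
  unit vector; pseudotime continues monotonically across the turn.
- *isotropic*: random pseudotime with i.i.d. Gaussian coordinates — the
  null case for calibration.
- *with loadings*: a linear embedding plus a random unit-row loadings
  matrix, so each gene's true alignment with the drift is known.

Ground truth (direction, branch time, noise, seed) is serialised next
to every simulated data set. Passing tests on these data show the
geometry pipeline is correct and calibrated *given* a reduced-space
embedding and pseudotime; they do not validate upstream embedding or
pseudotime inference on real data.

## Numerical and statistical caveats

**Anti-conservatism of the paired test at high path:cell ratios.**
The `n_paths` Wilcoxon pairs are not independent: resampled paths share
cells (two paths share on average `n_windows`/cells-per-window cells).
The positive correlation between paired differences inflates the
variance of the signed-rank statistic relative to its nominal null, so
p-values on directionless data are anti-conservative, increasingly so
as `n_paths` grows at fixed cell count. Measured at 300 cells /
100 paths over 200 independent null data sets, the empirical rejection
rate at α = 0.05 is ≈ 12–16% and the p-value distribution is detectably
non-uniform. Interpret borderline p-values with this in mind (the
regime the method targets — p-values tens of orders of magnitude below
α — is unaffected), or keep `n_paths` well below the number of cells
per window when calibration matters.

**Branch-scan trends under constant absolute noise.** Re-anchoring at a
later offset shortens displacements while the coordinate noise stays
constant, so the angular noise of each unit vector grows as the
remaining pseudotime range shrinks. Two consequences, both verified by
simulation: a straight trajectory shows a systematic *upward* msd trend
across offsets (this is an artefact of the geometry, not evidence of a
turn — compare against a straight control at the same offsets rather
than against zero trend); and for a turning trajectory the msd drop
after the turn is partly offset by this inflation, with test power
also falling as paths shorten. The branch point therefore shows up most
clearly as the *stabilisation* of msd relative to the matched straight
control, and clearly at low noise (≤ 2% of arc length the drop is
unambiguous; at 5% the two effects nearly cancel).

**Other numerical choices.** Unit-norm inputs are validated to 1e−6;
internally produced unit vectors to 1e−9. Convergence is declared on
the optimiser's improvement tolerance (1e−14 relative) or the step
budget, both recorded in the result. All p-values of 0 are floored at
the smallest positive float before −log10 transforms. Identical
(input, config, seed) runs produce byte-identical outputs; every CLI
output echoes the seed and package version.

## Problem sizes used in the checks

The automated checks run the pipeline at 300 cells per trajectory,
d = 3, 100–200 resampled paths, 200 independent runs for calibration,
and 50 random vector sets against the grid oracle — sizes chosen so the
whole suite completes in minutes on one CPU while every qualitative
contrast (straight vs turning, empirical vs null, pre- vs post-turn)
is decisively powered.
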