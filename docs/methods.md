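# Methods

## Model

`minpat` implements the cooperative-recruitment ("canalized transfer")
MinD/MinE reaction scheme with bulk–boundary coupling. Cytosolic MinD-ADP
is converted to MinD-ATP by nucleotide exchange at rate λ; MinD-ATP
attaches to the membrane at basal rate k_D and is recruited by
membrane-bound MinD at rate k_dD (the cooperativity that creates polar
zones); MinE is recruited by membrane MinD at rate k_dE, forming MinDE
complexes that detach at rate k_de, releasing MinD-ADP and MinE back into
the cytosol. The model conserves total MinD and total MinE exactly;
pattern formation comes from an oscillatory (Hopf–Turing) instability of
the stationary state, not from any source or sink.

Two structural facts drive everything downstream. First, in a confined
geometry with nucleotide exchange there is no homogeneous steady state:
the basal state is spatially non-uniform and carries the mirror
symmetries of the cell outline. Second, eigenmodes of the linearization
split into even and odd classes under long-axis reflection; even modes
correspond to longitudinal patterns, odd modes to transverse ones, and
the "non-degeneracy" d (the Euclidean distance between the three leading
even and odd growth rates) measures how close the two families are to
competing on equal terms.

## Quasi-2D reduction

The primary simulation mode treats the bulk as the lateral (x–y)
cross-section and the membrane as its closed 1D boundary curve,
justified for chamber heights around 1.1 µm where no structure forms
along z. Under the mapping to areal bulk densities (H·u) and lineal
membrane densities, the equations keep their form with the bimolecular
recruitment constants divided by H (`quasi_2d_parameters`); k_D and all
first-order rates are unchanged.

The reduction has one important structural loss, documented here because
it sets the limits of what the package reproduces: a real flattened cell
is bounded above and below by membrane, so its membrane-to-cytosol ratio
is ≈ 2/H independent of cell width. The cross-section model only keeps
the lateral wall, whose perimeter-to-area ratio *falls* as the cell
widens (1.25 µm⁻¹ at 8×2 µm, 0.62 µm⁻¹ at 9×5 µm). Consequences at the
shipped defaults:

- narrow cells (width ≈ 2 µm, lengths 4–9 µm) sustain large-amplitude
  oscillations: pole-to-pole, with a striped-symmetry transient after a
  homogeneous start (the geometric even-mode bias), period ≈ 14–20 s;
- cells wider than about 3 µm fall below the instability threshold and
  relax to the basal state, so the wide-cell striped/transverse
  selection and the critical length for stripe onset at width 3 µm are
  *not* reproduced — the corresponding acceptance tests assert the
  study phenomenology and fail honestly;
- the basal membrane profile has its minimum at the poles and maximum at
  midcell (the high-curvature poles deplete cytosolic MinD-ATP more per
  unit bulk), the opposite polarity of the full-3D picture;
- an artificial "transverse" mode, with the two long boundary arcs in
  antiphase, can win in short/narrow cells for some discretizations:
  in 3D it would be shorted out by the top/bottom membrane faces.
  Larger membrane diffusion (the default D_m = 0.06 µm²/s) suppresses
  it in the geometries used by the test suite.

## Parameters

Defaults live in `src/minpat/data/default_params.yaml` (every value
overridable; a provenance string is mandatory). Diffusion constants,
λ, k_D and k_de follow the published in-vivo parameterization of the
canalized-transfer model (D_D = 16, D_E = 10 µm²/s, λ = 6 s⁻¹,
k_D = 0.1 µm/s, k_de = 0.4 s⁻¹). The recruitment constants, membrane
diffusion and mean copy-number densities (k_dD = 0.04 µm³/s,
k_dE = 0.12 µm³/s, D_m = 0.06 µm²/s, ρ_D = 800 µm⁻³, ρ_E = 500 µm⁻³)
were calibrated once, using the dispersion relation and nonlinear runs,
so that the quasi-2D reduction sits inside its oscillatory regime with
the even (longitudinal) mode leading in narrow cells. With the
literature values unchanged the reduction is weakly sub-/super-critical
and saturates at small amplitude. The resulting oscillation period
(≈ 16 s at 8×2 µm) is shorter than the ≈ 68 s measured in vivo; the
68 ± 13 s figure is used where it belongs, as the default period
distribution of the synthetic movie generator.

## Numerics

*Meshes.* Symmetry-preserving triangulations: union-jack quads for
rectangles, concentric rings for ellipses, Delaunay for stadiums.
Node sets and connectivity are exactly invariant under both axis
reflections, so reflections act as node permutations; the discrete
operators commute with them and mirror-symmetric runs stay symmetric to
rounding error (this is also why the homogeneous-start protocol seeds a
0.1 % multiplicative cytosolic heterogeneity by default — without it the
antisymmetric pole-to-pole mode could only grow out of round-off).

*Time stepping.* Lie splitting. The reaction substep moves mass between
paired pools (exchange, attachment+recruitment, MinE
recruitment/hydrolysis, detachment) as explicit pointwise transfers,
subcycled so no first-order loss exceeds 1/4 per substep and capped so
no pool can overdraw — exactly conservative and positivity-safe despite
membrane loss rates of order 50 s⁻¹. Diffusion is backward Euler with
lumped P1 mass matrices (prefactored sparse LU per species and
timestep). Default dt = 0.2 s gives ≥ 70 steps per cycle at the default
period; an accepted step with any field below −10⁻¹⁰ of its maximum is
rejected and dt halved (aborting below 0.1 ms), tiny undershoots are
clipped and counted. Mass drift in practice: ~10⁻¹²–10⁻⁹ relative over
hundreds of seconds, orders of magnitude inside the 10⁻⁶-per-cycle
audit. The step map was verified first-order consistent against the
assembled semi-discrete right-hand side (error ∝ dt).

*Basal states.* Mass-constrained pseudo-transient continuation (SER:
pseudo-timestep ∝ 1/residual, bordered with the two mass constraints,
best-point restarts), which turns into Newton near the solution;
geometries where the pseudo-flow escapes toward the oscillation use a
cell-size homotopy (same mesh topology, coordinates scaled up from 30 %)
as fallback. Residuals reach ~10⁻¹³ relative.

*Spectra.* Shift-invert Arnoldi on the generalized problem J v = σ M v
at the basal state (mass matrices diagonal). The two numerically-zero
conservation modes are excluded before mode counting (they are even
artifacts of mass conservation, not pattern modes; threshold |σ| <
10⁻⁷ s⁻¹). Parity is the mass-weighted score ρ = Re⟨v, Rv⟩/⟨v, v⟩, with
|ρ| ≤ 0.5 flagged mixed; numerically degenerate eigenvalue groups
(circles) are re-expressed as pure-parity modes by projecting their
eigenspace onto the symmetric/antisymmetric subspaces. Reported
eigenpairs satisfy ‖Jv − σMv‖/‖Mv‖ < 10⁻⁸.

## Pattern classification

A window is a membrane-density time series over ≥ 2 cycles on the
boundary curve. Conventions and thresholds, all configurable:

- angles are reported with the long axis vertical, folded to [0°, 90°]
  (longitudinal = 90°, transverse = 0°), transverse iff below 45°;
- homogeneous iff the spatial coefficient of variation stays below 0.1
  throughout the window;
- a dominant temporal frequency requires a spectral peak ≥ 3× the
  median; the axis is the whitened spatial dipole of that Fourier
  component, falling back to the amplitude-weighted second moment
  (generalized eigenvector against the boundary's shape tensor) when
  the dipole vanishes, as it does for striped patterns;
- node counting evaluates the deviation-from-time-mean profile along
  the axis at the two opposite oscillation phases and sums connected
  above-half-maximum domains (pole-to-pole 1+1 = 2, striped 2+1 ≥ 3);
  thresholding the deviation rather than the raw profile matters
  because simulated membrane baselines are high;
- periods come from the FFT peak of the dipole-projection series
  refined by the nearest autocorrelation maximum with parabolic
  interpolation;
- confidence scales with the spectral dominance ratio (saturating at
  10× the decision threshold); "other" is the catch-all, never dropped.

## Movie pipeline

Segmentation: Gaussian smoothing, Otsu threshold, hole filling, largest
component, 100 px area floor. Feret diameters are caliper extents of the
convex hull at 1° steps (+1 px to account for pixel width); the
minimum aligns with the short symmetry axis, the maximum with the long
axis of elliptical masks and the diagonal of rectangular ones. The MinD
cluster is the largest connected region above the 75th in-mask intensity
percentile, accepted only if its mean exceeds 1.2× the cell mean (so
near-homogeneous frames yield no angle); its intensity-weighted centroid
joined to the cell centroid gives the oscillation angle, folded to
[0°, 90°]. The tracker targets two-node oscillations; striped movies
belong to the window classifier. Transitions are monotone angle
excursions across 45° between ≥ 3-frame plateaus outside the 15°/75°
bands, fitted by a logistic; events need R² ≥ 0.8 and the duration is
the 10 %→90 % rise time (ln 81 · τ).

## Synthetic data

The generator emulates the experimental structure, not the PDE: masks
are superellipses interpolating ellipse → rounded rectangle under linear
area growth; the MinD channel renders two Gaussian polar caps in
antiphase (∝ (1 ± cos 2πt/T)/2) along the scripted axis, three zones for
striped segments, uniform intensity for homogeneous episodes; the
cytosolic channel is the smoothed mask; Gaussian read noise at a
configurable SNR (default 5) plus multiplicative intensity jitter.
Defaults mirror the measured statistics: period 68 ± 13 s (truncated
normal), transition durations uniform on 4–8 min, frame interval 5 s.
Every artifact ships machine-readable ground truth (angles, period, mode
timeline, events, analytic Feret extents), and a fixed seed reproduces a
cohort bit-for-bit. Not emulated: photobleaching, z-structure,
multi-cell scenes, drift, cell death — so passing recovery tests shows
the pipeline is correct on idealized single-cell data, not that it is
robust to every real-microscopy artifact.

## Problem sizes

The test and acceptance runs use meshes at 0.2–0.3 µm resolution
(≈ 400–1700 nodes), dt = 0.2–0.3 s, runs of 400–700 s (≈ 20–40 cycles),
a 7-angle × 5-amplitude deflect grid with 15 relax / 12 deflect cycles,
basin sweeps over {0°, 45°, 90°} × 30 cycles, and 50-movie cohorts of
100 frames at 0.15 µm/px. These are the package's own desk-scale
choices; all protocol functions accept larger grids, cycle counts and
finer meshes unchanged.

## Known limitations

Beyond the quasi-2D effects above: no moving-boundary (growing-domain)
simulation — growth is studied on the synthetic-movie side only; no
stochastic kinetics; pattern selection in the multistable regime is
sensitive to mesh, timestep and noise seed (runs are bit-reproducible
for a fixed triple, and the acceptance suite pins one); the stability
probe measures persistence of the classifier label, which inherits the
classifier's 45° convention.
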