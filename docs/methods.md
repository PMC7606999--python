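# Methods

## Problem

In high-dose-rate (HDR) brachytherapy a single stepping source dwells at
discrete positions (0.25 cm apart) inside implanted applicator channels.
Inverse planning chooses the dwell times `t_{m,n}` (channel `m`, position
`n`) so the target receives at least the prescription dose while organs at
risk (OARs) stay under their limits. A known failure mode of inverse
optimizers is a plan with a few very long dwells: local hot spots, and high
sensitivity to source-position uncertainty. The method implemented here
adds a dwell-time modulation penalty to a quadratic objective and solves
the resulting bound-constrained problem with a limited-memory quasi-Newton
method.

## Dose model

Dose is computed with the AAPM TG-43 formalism in its 1D point-source
form:

    dD/dt(r) = S_K · Λ · (r₀/r)² · g(r) · φ_an(r)

with air-kerma strength `S_K` (U), dose-rate constant `Λ` (Gy h⁻¹ U⁻¹),
reference radius `r₀ = 1` cm, radial dose function `g(r)` and 1D
anisotropy factor `φ_an(r)` interpolated linearly in `r` from tables.
Design choices:

- **1D vs 2D.** The point-source geometry function `1/r²` with a 1D
  anisotropy factor is sufficient for studying the optimizer; the 2D
  line-source formalism is an extension point, not needed for any result
  computed here.
- **Near-source clamp.** Source-to-point distances are clamped to
  `r_min = 0.1` cm (one voxel of the default dose grid); smaller distances
  are unresolvable on that grid, and the clamp keeps every kernel entry
  finite even when a calculation point coincides with a dwell.
- **Out-of-table radii** clamp to the nearest table end; no extrapolation.
- **Units.** Dwell variables are seconds, the kernel is Gy/s (per-hour
  constants are converted once at kernel build), so doses are directly
  comparable with the Gy objectives. The published formulation calls `t`
  both a dwell "weight" and a "time"; one consistent unit is used, and the
  final absolute scale is set by normalization anyway.
- **Source data.** The packaged table (`data/ir192_synthetic.csv`) is a
  *synthetic* Ir-192-like characterization (Λ = 0.01109 Gy h⁻¹ U⁻¹,
  default S_K = 40800 U, a typical 10 Ci source) with smooth plausible
  `g`, `φ_an` tables. No result depends on the exact values: every check
  is analytic or relative.

Total dose is the linear superposition `D_i = Σ_{m,n} d_{m,n,i} t_{m,n}`,
held as a dense (points × dwells) kernel matrix — desk-scale problems
(≲10⁵ points × ≲10² dwells) fit comfortably in memory.

## Objective

    F(t) =  Σ_{i∈TAR}  p_TAR  · H(D₀-D_i) · (D_i − D₀)²
          + Σ_{i∈OARs} p_OAR  · H(D_i-D₀) · (D_i − D₀)²
          + p_SOU · Σ_m Σ_n (1/N_m) · (t_{m,n} − t_{m,min})²

One-sided quadratic penalties: a target voxel is penalized when its dose
falls at or below the minimum objective, an OAR voxel when it reaches or
exceeds the maximum objective. The switch is "on" at exact equality, where
the squared factor vanishes, so the convention is value- and
gradient-neutral. Each ROI may carry both a minimum and a maximum
objective (a superset of the one-per-ROI form).

The last term is the dwell time modulation penalty with weight `p_SOU`
(the DTMF). It is anchored at each channel's *minimum* dwell time rather
than the mean: long dwells are shortened while positions that should
barely dwell (e.g. those suppressed by an OAR) keep their small times.
The DTMF is deliberately not normalized to [0, 1]; its useful range
depends on the clinical site.

**Gradient.** The dose terms differentiate to `2 Kᵀ (p·H·(D − D₀))`. The
per-channel minimum is piecewise linear in `t`; the gradient uses the
exact derivative with the argmin frozen at the evaluation point
(first-listed index wins ties), including the coupling on the minimizing
coordinate: `−(2 p_SOU/N_m) Σ_n (t_{m,n} − t_{m,min})` there and
`+(2 p_SOU/N_m)(t_{m,n} − t_{m,min})` elsewhere. This is exact almost
everywhere; ties are measure-zero and the squared differences vanish at a
tie. Finite-difference agreement is tested away from switching surfaces
and min ties.

**Subsampled objectives.** The reference conditions evaluate penalties on
every voxel of the 0.1 cm dose grid. When calculation points are
subsampled (a speed option for desk-scale runs), each sampled point is
weighted by the number of grid voxels it represents, so the subsampled
objective is an unbiased estimate of the full-grid objective. Without
this weighting, subsampling would silently shrink the dose terms relative
to the DTMF term and inflate the effective modulation weight by `1/f`.
Exhaustive sampling (`f = 1`) is bit-for-bit unaffected.

## Optimization

`scipy.optimize.minimize(method="L-BFGS-B")` with the analytic gradient,
a lower bound of 1e-6 s on every dwell time (strict positivity), initial
time 1 s at every position, and at most 100 outer iterations —
"iteration" means outer quasi-Newton iterations; the convergence
tolerances are pinned low (ftol 1e-16, projected-gradient tolerance 1e-8)
so the iteration budget or gradient norm governs stopping. The recorded
objective trace (initial point plus each accepted iterate) is
non-increasing by the solver's monotone line search, and the whole fit is
deterministic for fixed inputs.

## Plan evaluation

DVH metrics follow the empirical (non-interpolated) convention: sort the
per-point doses descending and read with `≥` thresholds.

- `D_x%` — the dose of the point at the smallest cumulative volume ≥ x%;
- `V_y%` — 100 × (volume with dose ≥ y%·prescription) / total volume,
  anchored at the *prescription* (6 Gy default), not at D90%;
- `D_zcc` — the same descending-sort construction on absolute volume.

On a 0.1 cm grid the sub-voxel difference against interpolated DVHs is
irrelevant, and the empirical form is exactly checkable against a
brute-force threshold scan (which the tests do).

Reported plans are first normalized: all dwell times are multiplied by
`prescription / D90%(target)`. Dose is exactly linear in the times, so the
recomputed D90% equals the prescription to floating-point precision and
every other D metric scales by the same factor.

**DTSD** (dwell time standard deviation) is the *population* SD pooled
over all dwell positions in all channels of the *un-normalized* optimized
plan. The quantity is not formally defined in the literature this
implements; pooled population SD is the plainest reading, and
normalization would only rescale the DTMF–DTSD curve, not change its
shape. With per-channel anchoring the pooled DTSD retains the
between-channel component even at large DTMF — the curve flattens rather
than reaching zero.

## Synthetic phantoms

The generator emulates the *scale* of a radical cervix case, not patient
anatomy (which is not recoverable from cohort summary statistics):

- **HR-CTV**: a randomly perturbed ellipsoid (smooth ~3–8% radial
  modulation) around the applicator, radii iterated until the voxelized
  volume is within ±5% of the requested volume (52.65 cm³ default, the
  cohort-mean scale; exact volumes are grid-impossible). Default grid
  spacing 0.1 cm isotropic.
- **Applicators**: stylized straight/arc tubes with exact 0.25 cm dwell
  spacing — Fletcher (tandem + two ovoids, 3 channels), double ovoid,
  tandem-ring, multichannel (7), tandem-needles (5). Channel topology and
  dwell spacing are what the optimization behaviour depends on; vendor
  geometry is not reproduced.
- **OARs**: bladder (anterior), rectum (posterior), sigmoid (superior)
  ellipsoids with seeded jitter, placed 0.3 cm from the target surface so
  the 4.5 Gy maxima are active but satisfiable — an optimization benchmark
  is only informative when constraints bind. OAR masks exclude any
  target voxel.

Generation is a pure function of the spec: same seed, same phantom, bit
for bit. What passing tests on these phantoms shows is that the
optimizer, objective and evaluation chain behave correctly and reproduce
the qualitative DTMF–DTSD behaviour; they say nothing about absolute
dosimetric quality on real anatomies, real applicator reconstructions, or
tissue heterogeneity (TG-43 assumes water).

## Benchmark conditions and problem sizes

The canonical regression case is the Fletcher phantom (seed 1, 52.65 cm³
target, 0.1 cm grid) with the standard cervix objectives — HR-CTV min
6.0 Gy (weight 100), bladder max 4.5 Gy (50), rectum and sigmoid max
4.5 Gy (80) — DTMF 10, 100 iterations, 6 Gy prescription. On the full
grid this is ~1.1×10⁵ calculation points × 25 dwells; the DTMF–DTSD sweep
runs on the full grid, while single-fit checks use a 10% voxel subsample
(~10⁴ points), which the multiplicity weighting makes equivalent in
expectation. Both complete in seconds on one CPU.

## Known limitations

- 1D TG-43 only; no 2D anisotropy, scatter, heterogeneity or source decay.
- Dwell positions are inputs; there is no dwell-position activation or
  applicator reconstruction.
- Simulated-annealing (IPSA-style) and hybrid (HIPO-style) comparators,
  their DTDC/DTGR modulation parameters, cohort statistics and DICOM-RT
  I/O are out of scope.
- The absolute DTMF scale is tied to this package's units (seconds,
  unnormalized penalties); DTMF–DTSD curves are comparable in shape but
  not in x-axis value across implementations with other conventions.
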