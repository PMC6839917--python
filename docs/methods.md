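# Methods

This note records the models, conventions and numerical choices behind
`saxstate`, in the order data flow through the package.

## Scattering model

Theoretical curves are computed from Cα traces with the Debye equation,

I(q) = Σᵢ Σⱼ fᵢ(q) fⱼ(q) sin(q rᵢⱼ)/(q rᵢⱼ),

with one bead per residue. The default form factor is a uniform,
q-independent dummy-residue factor (f = 1); an optional shared Gaussian
attenuation f(q) = f₀ exp(−(qw)²/2) with width w (Å) models finite bead
size. There is deliberately **no hydration-layer or excluded-volume
term**: Cα traces do not contain the information those corrections need,
so profiles are meant for *relative* comparisons — conformer against
conformer, model mixture against a synthetic experiment generated by the
same forward model — not for absolute fitting of measured intensities of
a real protein.

Two consequences are worth knowing:

- The i = j self term contributes a flat n·f² background, the real-space
  image of which is a delta at r = 0. A P(r) inversion constrained to
  P(0) = 0 therefore sees a small inconsistency for point-bead curves;
  tests that compare the inversion against the coordinate distance
  histogram subtract the self term first.
- The flat self term keeps extra intensity at high q, which inflates
  ∫ q I(q) dq and hence deflates the volume of correlation (below).

For models above 400 beads the pair sum is evaluated on a 0.01 Å distance
histogram (weighted mean distance per bin). At the instrument-like
q ≤ 0.4 Å⁻¹ the phase error is ~2×10⁻³ rad and the evaluation agrees
with the exact double sum to ~2×10⁻⁵ relative (tested at 10⁻³
tolerance); both paths remain available.

## Curve analysis

**Guinier.** ln I is regressed on q² with weights (I/σ)², starting from
the 5 lowest usable points and iterating the window to the fixed point of
q_max·R_g ≤ 1.3 (cycle-safe: a two-cycle settles on the smaller window),
then shrinking while the coefficient of determination is below 0.9. A
flat profile returns R_g = 0 flagged degenerate; a rising low-q slope
(R_g² < 0) is an error. The 1.3 limit is the standard globular default —
for strongly elongated particles the law holds over a shorter window, and
the self-consistency tests use q·R_g ≤ 0.7 for dumbbell shapes.

**P(r).** The indirect transform I(q) = 4π ∫₀^Dmax P(r) sinc(qr) dr is
discretized by the trapezoid rule on an n_bins grid (default 101), with
hard endpoint constraints P(0) = P(Dmax) = 0, non-negativity (bounded
BVLS solve), and a Tikhonov penalty on second differences. The penalty
weight is dimensionless (scaled by ‖W A‖_F/‖D₂‖_F) and selected by the
L-curve corner (triangle method on a 13-point log grid) unless fixed by
the user. When the profile carries no σ, a nominal 1% relative
uncertainty with a 10⁻⁴·I_max floor provides the weights; the floor keeps
weights finite at the zeros of oscillatory curves. The back-transform
reduced χ² is always reported.

**Dmax.** Candidates are scanned with a fixed smoothness (chosen once at
the median candidate); because χ² flattens once the support covers the
true dimension, the smallest candidate within 5% of the minimal χ² is
returned. This parsimony rule reproduces Dmax = 2R for an analytic
sphere; the non-negative solver makes a separate negativity penalty
identically zero, so none is added.

**Volume of correlation.** V_c = I(0)/∫ q I(q) dq with the integral
taken on the measured range only — a range ending short of 0.3 Å⁻¹ warns
and flags truncation instead of extrapolating. The protein mass estimate
uses the published calibration MW(Da) = (V_c²/R_g)/0.1231, reported in
kDa. On one-bead-per-residue models this estimate is a **systematic
underestimate** (by roughly a factor of two for the synthetic dumbbell,
bounded in the tests at ≤2.5×) because of the high-q self-term excess
noted above; it is reported for curve-level consistency, not as a
calibrated mass for coarse models.

## Geometry

Superposition is Kabsch (SVD with determinant correction, proper
rotations only); inputs need ≥3 points with rank ≥2 after centering.
Domain rotations are measured with a fixed convention: align the two
models on the *reference* selection, then take the best-fit rotation
carrying the *moving* selection between them, reported as axis/angle
(trace formula, angle ∈ [0°, 180°]) plus the screw translation along the
axis. Angles below 10⁻⁴ degrees are reported as zero with the axis
flagged undefined, because arccos amplifies rounding near identity.
Rotation values depend on the alignment convention; comparisons across
tools should fix the same one. Residues are paired across models by
(chain, residue number, insertion code); name mismatches warn but pair.
Interfaces use an inclusive ≤ cutoff (default 10 Å Cα–Cα).

## Hinge sampling

Conformers are generated by single-pivot rigid rotations: each hinge
rotates a rigid domain group about an axis through its pivot Cα, angle
drawn uniformly on [−max_angle, +max_angle] (default 40°), axis isotropic
unless fixed. A protocol is an ordered list of stages; a member of stage
k applies one fresh draw of every hinge of stages 1..k, so later stages
explore a superset of the earlier motion while the held-fixed core never
moves. Conformers with any non-adjacent Cα pair (|Δresidue| > 2 or
different chains) closer than 3.5 Å — a typical Cα steric diameter — are
rejected and redrawn, up to 50 retries before a starvation error names
the stage. Pools are bitwise reproducible from the protocol seed.

The default two-stage protocol for a labelled dumbbell swings the
regulatory lobe about the point where the linker exits it, then the lobe
plus linker about the point where the linker enters the catalytic lobe.
Pivots are placed at the linker bead with ≥2 Å clearance outside the
lobe's bead envelope (relaxed to ≥0 for short linkers): the linker
termini are embedded in the lobes as connective density, and pivoting at
an embedded bead would sweep buried beads through the lobe and make
clash-free sampling unsatisfiable.

This is deliberately *not* molecular dynamics: no energetics beyond the
clash filter, no loop remodelling, no side chains.

## Ensemble fitting

χ² = (N−1)⁻¹ Σ ((I_e − c·I_m)/σ)² with the scale c fitted analytically;
theoretical curves are linearly interpolated onto the experimental grid
(never the reverse, preserving σ; extrapolation is an error). Mixture
weights come from non-negative least squares on σ-weighted intensities,
renormalized to the simplex with the magnitude absorbed into a scale
factor; with duplicated members the split is degenerate but the summed
weight is well defined.

The minimal ensemble search evaluates, for each n up to max_states, the
best size-n subset. While C(pool, n) ≤ 10⁵ the search is exhaustive,
implemented as support enumeration with batched Gram-matrix solves: by
the NNLS optimality conditions, the optimum over a support is either the
unconstrained solution on that support (when non-negative) or coincides
with a smaller support's optimum, which a previous n already covers — so
the per-n minima are exact. Larger pools use a seeded random-restart +
greedy-exchange search (the seed is then mandatory), always including
supersets of the previous best subset so χ² stays non-increasing in n.
The selected size is the smallest n whose χ² the next size fails to
improve by more than 10% (a numerically exact fit, χ² ≤ 10⁻¹⁰, is
selected immediately); all per-n fits are exposed so users can apply
their own rule.

K_eq is defined as the *extended-state over compact-state* weight ratio.
For a 0.72/0.28 compact/extended split this gives 0.28/0.72 ≈ 0.39 —
note the equilibrium constant of a mostly-compact ensemble is below one
by this definition. An all-extended fit returns +inf rather than raising.
`classify_members` assigns fitted members to states by Cα RMSD (after
superposition) to reference models; this matters because a sampled decoy
can be structurally indistinguishable from a generator, in which case the
per-member weight is arbitrary but the per-state sum is not.

## Synthetic data

The generator emulates a two-lobed ~150 kDa heterodimer-like particle:
two quasi-spherical bead lobes (default 25 Å radius, 625 beads each,
uniformly rejection-sampled at ≥3.8 Å separation and recentred onto the
construction centers) joined by an ideal α-helical linker (default 50
residues, 1.5 Å/residue rise, 100° twist, radius set so consecutive Cα
sit 3.8 Å apart) whose midpoint kink sets the hinge angle; the kink is
spread over ≤5 virtual bonds to keep the trace self-avoiding. Lobe
centers sit on the linker axis, 0.3 lobe radii beyond its ends, so the
linker termini are buried as connective density. Defaults are calibrated
so the bent (120°) conformer's R_g falls in the 40–46 Å band of the
compact state it emulates; the benchmark's extended member uses a 145°
hinge — a *partially* extended state chosen so the 72:28 mixture's R_g
exceeds the compact value by the measured ~0.7 Å and the pair-distance
mass shifts into the 70–100 Å band, rather than the fully straight limit.

Simulated experiments add Gaussian noise with σ(q) = rel·I_mix(q) + floor
(default 1% relative, no floor) to the weighted Debye mixture, emitting
the σ column; a zero noise model returns the exact mixture. The two-state
benchmark bundles both generators, one noisy mixture, and a
JSON-serializable truth record.

What the generator does **not** emulate: sequence-realistic residue
composition and form factors, hydration, interparticle effects,
SEC elution and buffer subtraction, instrument smearing, and
q-correlated noise. Passing the recovery benchmark therefore shows the
*inference machinery* is correct under the stated noise model, not that
real measured curves of a given protein will resolve the same
composition.

## Pipeline

`run_pipeline` chains analyze → sample → scatter → MES → K_eq from one
validated configuration (YAML or dict), persists every intermediate
(pool PDBs with a provenance table, per-member profiles, P(r)/Kratky
tables) and writes a sorted-key JSON report; identical configuration and
seed give byte-identical reports. A seed is refused as missing *before*
any computation when stochastic sampling is enabled. Domain labels
travel in a `<model>.domains.json` sidecar because PDB records cannot
carry them. The report's K_eq counts a fitted member as extended when
its coordinate R_g exceeds the start model's — a deliberately simple
rule, overridable by calling `equilibrium_constant` directly with an
explicit partition.

## Known limitations

- Absolute-intensity comparison to atomistic predictions or measured
  curves is out of scope (no hydration/excluded-volume physics).
- The Vc mass estimate is biased low on coarse bead models, as above.
- Domain-rotation angles are convention-dependent; only the convention
  stated here is implemented.
- Hinge sampling explores rotations about fixed pivots only — no
  translation, torsion-space or concerted motions.
- The P(r) solver targets well-conditioned desk-scale problems
  (≲200 bins); it is not a Bayesian or error-propagating inversion.
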