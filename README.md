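# saxstate

Solution-state SAXS analysis of multi-domain conformational equilibria.

Many multi-domain signalling proteins — the soluble guanylate cyclase (sGC)
heterodimer, the nitric-oxide receptor, is the motivating case — interconvert
in solution between a compact and an elongated conformation. A single
small-angle X-ray scattering (SAXS) curve of such a sample is a
population-weighted average; the analysis problem is to (i) extract the
standard one-dimensional descriptors of the curve, (ii) generate candidate
rigid-body conformers of a coarse-grained (Cα) model, and (iii) find the
smallest weighted conformer ensemble whose mixed theoretical curve explains
the data — yielding the state populations and hence the conformational
equilibrium constant. `saxstate` implements that whole chain for
structural biologists who have a Cα model and a measured (or simulated)
scattering curve.

## What it computes

Given an experimental profile I(q) with uncertainties σ(q) on
q ∈ [0.01, 0.4] Å⁻¹ (q = 4π sinθ/λ):

- **Guinier analysis** — weighted fit of ln I = ln I(0) − q²R_g²/3 over the
  largest self-consistent low-q window with q·R_g ≤ 1.3.
- **Dimensionless Kratky transform** — (qR_g)² I/I(0) vs qR_g, with peak
  location (√3, 3/e) for an ideal globule.
- **Pair-distance distribution** P(r) — regularized indirect Fourier
  transform of I(q) = 4π ∫₀^Dmax P(r) sin(qr)/(qr) dr with P(0) = P(Dmax) = 0,
  P ≥ 0, second-difference smoothing (L-curve-selected), plus a Dmax scan.
- **Volume of correlation** V_c = I(0)/∫ q I(q) dq and the
  concentration-independent protein mass estimate MW = (V_c²/R_g)/0.1231.
- **Theoretical profiles from Cα models** via the Debye equation
  I(q) = Σᵢ Σⱼ fᵢ(q) fⱼ(q) sin(q rᵢⱼ)/(q rᵢⱼ), one bead per residue
  (histogram-accelerated for large models, verified against the exact sum).
- **Rigid-body hinge sampling** — staged, seeded rotation of domain groups
  about hinge pivots with a Cα steric clash filter, producing a reproducible
  conformer pool.
- **Minimal ensemble search (MES)** — for each ensemble size n, the
  best-fitting member subset under non-negative least-squares weights and an
  analytic global scale, scored by reduced χ²; the smallest n that the next
  size fails to improve by >10% is selected.
- **State populations and K_eq** = w(extended)/w(compact), and geometric
  descriptors of the underlying motion (domain rotation axis/angle by Kabsch
  superposition, ≤10 Å Cα–Cα interface maps, end-to-end and pair distances).

A synthetic-data module generates the calibrated test system: a two-lobed
~150 kDa dumbbell (25 Å lobes, 50-residue helical linker, R_g ≈ 43 Å
when bent at 120°) in bent and partially extended conformations, mixed
72:28 with 1% Gaussian noise — so the entire pipeline runs and is tested
with no downloads.

## Worked example

```python
from saxstate import (
    debye_profile, equilibrium_constant, guinier_fit,
    make_two_state_benchmark, minimal_ensemble_search,
    pair_distribution, volume_of_correlation,
)

bench = make_two_state_benchmark(weights=(0.72, 0.28), seed=11)

g = guinier_fit(bench.profile)
print(f"Guinier: Rg = {g.rg:.1f} A, I(0) = {g.i0:.3g}")
pr = pair_distribution(bench.profile, dmax=140.0)
print(f"P(r):    back-transform chi2 = {pr.chi2:.2f}")
vc = volume_of_correlation(bench.profile, g)
print(f"Vc:      {vc.vc:.0f} A^2 -> MW estimate {vc.mw_kda:.0f} kDa")

members = [
    debye_profile(bench.bent, bench.profile.q, label="bent"),
    debye_profile(bench.extended, bench.profile.q, label="extended"),
]
mes = minimal_ensemble_search(bench.profile, members, max_states=3)
fit = mes.selected
print(f"MES:     {mes.selected_n} states, chi2 = {fit.chi2:.2f}")
for mid, w in zip(fit.member_ids, fit.weights):
    print(f"         {mid:9s} weight = {w:.3f}")
print(f"Keq:     extended/compact = {equilibrium_constant(fit, {'extended'}):.2f}")
```

prints

```
Guinier: Rg = 42.1 A, I(0) = 1.68e+06
P(r):    back-transform chi2 = 0.84
Vc:      579 A^2 -> MW estimate 65 kDa
MES:     2 states, chi2 = 1.01
         bent      weight = 0.711
         extended  weight = 0.289
Keq:     extended/compact = 0.41
```

The Guinier radius of the 72:28 mixture sits just above the pure compact
conformer's (42 Å scale), the ensemble search identifies exactly two states
at χ² ≈ 1 (consistent with the 1% simulated noise), and the recovered
weights reproduce the 0.72/0.28 composition the curve was generated from;
K_eq ≈ 0.4 is the corresponding equilibrium constant. The Vc mass estimate
is a known systematic underestimate for one-bead-per-residue models (see
`docs/methods.md`).

## Command line

`saxstate` exposes the stages as subcommands:

```sh
saxstate simulate --seed 11 --out bench/          # synthetic benchmark bundle
saxstate analyze bench/mixture.dat --dmax auto    # Guinier / P(r) / Vc report
saxstate scatter bench/bent.pdb --out bent.dat    # theoretical Debye curve
saxstate sample bench/bent.pdb --n 100 --seed 17 --out pool/
saxstate mes bench/mixture.dat pool/ --max-states 3 --seed 7
saxstate compare inactive.pdb active.pdb --reference A:406-457 --moving B:1-180
saxstate run config.yaml                          # full pipeline
```

Domain labels travel in a `<model>.domains.json` sidecar (PDB files cannot
carry them); `simulate` writes one next to each model.

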