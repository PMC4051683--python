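# Methods

Model, conventions, parameters and numerical choices behind `memdiff`.
Everything quantitative stated here is either a definition or is computed
and asserted by the test suite.

## Scattering model and conventions

An oriented lamellar membrane stack of period `d_z` gives specular Bragg
reflections at `q_n = 2πn/d_z`. The time-averaged bilayer is
centrosymmetric, so the form factor at each order is a real number
`F_n = ν_n·|F_n|`, `ν_n ∈ {−1, +1}`, and the electron density along the
normal is

```
ρ(z) = ρ_w + (2/d) Σ_n ν_n |F_n| cos(2πnz/d)
```

with the water density `ρ_w` absorbed into the affine absolute-scaling
step. Conventions:

* `ν_1 = −1`: the first order is chosen negative so that the profile has
  its minimum (the methyl trough) at the bilayer center, `z = 0`.
* Orders not observed are *absent*, not zero: the synthesis truncates
  over observed orders only.
* Lorentz correction for oriented stacks: `|F_n| = √(I_n·q_n^e)` with the
  background-subtracted integrated peak area `I_n` and exponent `e = 1`
  by default (`e = ½` available via `lorentz_exponent` for sensitivity
  checks, and the simulator honours the same option so round trips stay
  self-consistent).

## Bragg-series fitting

Each candidate order is fitted independently in a window of ±4 expected
widths around `n·2π/d_hint` as a Gaussian plus a *local* linear
background. A candidate is kept only if

1. its window's maximum excess over the endpoint-interpolated baseline
   exceeds `significance` (default 3) times the noise level (supplied
   per-point errors where available, otherwise √(median counts) in the
   window), and
2. the fitted peak is physically sensible: `σ` smaller than the window
   half-width and center within two expected widths of the predicted
   position — anything else is the fit chasing noise.

Without a `d_hint`, a first pass locates prominent maxima, assigns
integer order indices from the smallest peak-to-peak gap, and refines the
slope. The lamellar spacing is `d_z = 2π/slope` of the zero-intercept
least-squares line of `q_n` vs `n`; a residual above 2% of the slope
rejects the order assignment as inconsistent.

## Sign assignment by the swelling method

Magnitude sets measured at two or more hydration states (different `d`,
same bilayer) must fall on one smooth continuous transform. The
continuous transform of the *periodized* profile known from one state is
the Shannon-type sampling expansion

```
T(q) = Σ_n ν_n |F_n| [sinc(qd/2 − πn) + sinc(qd/2 + πn)] + f0·sinc(qd/2)
```

Two terms beyond a naive single-sided sum are essential, and both are
exact consequences of the cosine series rather than tuning:

* **Mirror terms** `sinc(qd/2 + πn)`: each cosine order contributes at
  `±q_n`; dropping the mirror term misplaces `T` between samples by an
  amount comparable to the weak high-order magnitudes.
* **Zeroth coefficient** `f0 = ∫(ρ − ρ_w) dz = 2·budget/A_L − ρ_w·d`:
  the per-area excess electron count of one bilayer. It is
  hydration-invariant (adding interbilayer water changes `d` but not the
  excess), so it is known from the composition alone.

Without both corrections the acceptance property "100% sign recovery
over 50 seeded swelling pairs" measured 0/50; with them it measures
50/50 (`tests/test_acceptance.py`).

The reference set is the one with the largest `d` (densest sampling);
`ν_1 = −1` is fixed and the remaining `2^(N−1)` sign vectors are searched
exhaustively (capped at 16 orders). The misfit is the error-weighted
squared deviation of every other set's samples from `T`, restricted to
`q ≤ q_max` of the reference set — beyond its last order the expansion
extrapolates and carries no information. Near-degenerate alternatives
(within the error bars) are reported via a degeneracy flag.

## Absolute scaling

The relative profile is mapped to e⁻/Å³ by an affine transform
`ρ = α·ρ_rel + β` with two linear constraints:

* `ρ(0) = center_density` (default 0.22 e⁻/Å³, the electron density of
  terminal methyl/methylene at the gel-phase bilayer center), and
* conservation: `A_L·∫ρ dz = 2·budget` over one period, with the
  per-lipid leaflet budget from the composition module.

Conservation therefore holds *by construction* on every grid (asserted
to 0.1% on grids ≥ 512 points). If the solution has `α ≤ 0` (profile
upside-down relative to the conventions), the sign vector is globally
flipped with a warning rather than silently accepting a negative scale.

## Electron bookkeeping

Species carry parsed chemical formulae; electron counts are
formula-derived (Σ atomic numbers). Published tabulated counts may be
attached for bookkeeping reproduction; a species whose tabulated count
disagrees with its formula raises a `PrintedValueWarning` when the
tabulated value is used. Peptides are condensed from one-letter
sequences: Σ residues − (n−1) waters. The per-lipid leaflet budget is

```
budget = Σ_lipids x_i·e_i + Σ_additives r_j·e_j + n_w·10
```

with mole fractions `x_i` (summing to 1), per-lipid ratios `r_j` and
`n_w` waters per lipid.

## Difference-density decomposition

`Δρ(z) = ρ_sample(z) − ρ_reference(z)` on the common half-period
`[0, d/2]` (both inputs must be absolute-scale; mismatched periods warn
and truncate to the overlap). The difference is modelled as `k` mirrored
Gaussian pairs; fitting uses `lmfit` least squares from multiple seeded
starts (default 8) to avoid local minima, with `σ` bounded in
[0.5, 12] Å. Each component's electron count is *per leaflet*:

```
N_i = A_L·|a_i|·σ_i·√(2π)
```

(the mirrored partner belongs to the opposite leaflet). Population
percentages are `100·N_i/ΣN_j`; a population is "embedded" when its
center lies inside the hydrocarbon core, `z < boundary_z` (default 14 Å,
the head-group/chain interface of a gel-phase C14 bilayer).

## Atomic projection and pose fitting

Atoms (atomic-number weighted; gemmi-parsed PDB, first model) are
projected onto the bilayer normal as Gaussians of FWHM 4 Å (thermal and
conformational smearing). The projected profile is shifted by the trial
depth, folded into the `d`-periodic cell, and centro-symmetrized —
exactly what a lamellar experiment measures.

The z-projection of a rotated rigid body depends on the orientation only
through the body-frame direction of the projection axis, `u = Rᵀẑ`.
With z–y–z Euler angles `(α, β, γ)` the first angle rotates about the
projection axis itself, so the grid search runs over `(β, γ)` only and
reports `α` as the first grid value. Two exact degeneracies remain:
`(β, γ) ↔ (360°−β, γ+180°)` (same `u`) and `u ↔ −u` after
centro-symmetrization. The fit is scale-free by default (the profile
amplitude is solved per pose in closed form); exact score ties are
resolved lexicographically and reported with a degeneracy warning.

Pose *recovery* is therefore only well-posed up to these degeneracies,
and only for targets whose true pose is representable on the search
grid: for an off-grid truth the nearest grid pose is in general not the
best-fitting grid pose, so an exhaustive-search optimum can legitimately
sit several grid steps away (observed and verified: in every such case
the returned pose scored strictly better than the grid-snapped truth).
The acceptance suite draws true poses from the grid and judges
orientation by the cone angle between recovered and true `±u`.

## In-plane analysis

* Chain packing: the gel-phase chain-correlation peak at `q_T` indexed
  as the [10] reflection of a hexagonal chain net gives
  `a_T = 2π/(q_T·cos 30°)` and, with two chains per lipid,
  `A_L = √3·a_T²`.
* Oblique (2-D monoclinic) lattices: reflection positions
  `q(h,k) = (2π/sin γ)·√(h²/a² + k²/b² − 2hk·cos γ/(ab))`; `fit_lattice`
  inverts observed positions for any subset of `(a, b, γ)` by bounded
  least squares.
* Plaque growth: percent change of the summed [110]+[200] integrated
  intensities between two peak tables, alongside the chain-peak change.

## Forward simulator

Bilayer models are sums of mirrored Gaussians (center, σ, amplitude)
on a flat water background (0.333 e⁻/Å³). Their form factors are
analytic, which provides closed-form oracles for every round trip. The
default gel-phase model has head-group Gaussians at ±22 Å (σ 3 Å,
amplitude +0.20 e⁻/Å³) and a methyl trough at 0 (σ 2.5 Å, −0.12 e⁻/Å³)
with `d = 55.07 Å`.

Intensity curves place Gaussian peaks of area `I_n = |F_n|²/q_n^e` on a
linear background. The noise contract makes "x% noise" well-defined:
`noise_scale = f` scales the noiseless curve so its maximum is `(1/f)²`
counts, Poisson-samples every point, and rescales — the strongest point
then fluctuates by ≈ `f` relative. All randomness flows through explicit
seeds; identical seeds give bit-identical curves and fixture packs.

The helix generator places one pseudo-atom per residue on an ideal
α-helix (rise 1.5 Å, twist 100°, radius 2.3 Å), each carrying its
residue's electron count so the total matches the peptide exactly. The
fixture-pack PDB necessarily writes these as CA carbon records (a PDB
atom is a real element), so a loaded fixture helix carries carbon
weights; pose fitting is unaffected because it is scale-free.

## Numerical notes and limitations

* **Periodization of the continuous transform.** The sampling expansion
  `T(q)` represents the transform of the *period-folded* contrast. For
  models whose Gaussian tails cross the cell boundary (the default gel
  model's heads at 22 Å with σ 3 Å against `d/2 = 27.5 Å`), `T` differs
  from the infinite-line analytic transform by a few percent, and the
  difference does not shrink with more orders — it is window folding,
  not truncation. For period-contained models the two agree to < 1%
  (asserted in the test suite).
* **Detection floor and round-trip accuracy.** The default gel model's
  analytic magnitudes at `d = 55.07 Å` decay fast:
  |F| ≈ [3.012, 0.082, 0.043, 1.354, 0.423, 0.465, 0.053, 0.032, 0.050,
  0.004] for orders 1–10. Orders 2, 3 and 7–9 jointly carry ≈ 3.6% of
  the profile's L2 weight but, under the 1% noise contract (10⁴ counts
  at the strongest point, background 50), their peak heights are 3.6,
  0.7, 0.4, 0.1 and 0.3 counts against a per-point Poisson floor of
  ≈ 7.9 counts; even an integrated matched-filter amplitude estimate has
  σ ≈ 1.5 counts. Including estimates whose variance exceeds the true
  |F|² *increases* the L2 error over omitting the order, so dropping
  them is optimal and the full-pipeline reconstruction is
  truncation-limited at ≈ 3.7% relative L2 for this model (measured
  3.68%, identical with noise removed; detected orders' magnitudes and
  signs are exact). A sub-2% round trip at 10 orders requires a model
  whose ten orders are all above the detection floor.
* **No instrument model.** No resolution-function deconvolution,
  absorption, footprint or mosaicity corrections; peak widths are
  treated as free Gaussian parameters.
* **Rigid-body pose only.** The projection module fits depth and
  orientation of a fixed conformation; no internal degrees of freedom,
  and orientation only up to the degeneracies listed above.
* **Centrosymmetric average.** All profiles are even by construction;
  asymmetric bilayers are out of scope.

## Key parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `lorentz_exponent` | 1 | – | `|F| = √(I·q^e)`; ½ selectable |
| `sigma_guess` | 0.004 | Å⁻¹ | expected Bragg width; window = ±4σ |
| `significance` | 3 | – | detection threshold in noise units |
| `max_order` | 10 | – | highest Bragg order searched |
| `grid_points` | 1024 | – | synthesis grid (forced odd, ≥ 4·N) |
| `center_density` | 0.22 | e⁻/Å³ | methyl density at `z = 0` |
| `area_per_lipid` | 60.6 | Å² | composition default (fluid); 40.95 gel |
| `waters_per_lipid` | 0 | – | hydration in the budget |
| `sigma_bounds` | (0.5, 12) | Å | decomposition width bounds |
| `embedded_boundary` | 14 | Å | hydrocarbon-core boundary |
| `fwhm` | 4 | Å | atomic projection broadening |
| `pose_z_step` / `pose_angle_step` | 0.5 / 15 | Å / ° | pose search grid |
| `water_level` | 0.333 | e⁻/Å³ | simulator water density |
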