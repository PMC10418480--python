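# Methods

## Model

`torsionforge` converts a scored structural ensemble into per-residue
backbone torsion potentials.  The chain of estimators is:

1. **Torsion extraction.**  Backbone φ (C⁻¹–N–Cα–C), ψ (N–Cα–C–N⁺¹)
   and, on request, ω (Cα–C–N⁺¹–Cα⁺¹) are computed per model with the
   IUPAC sign convention and wrapped to [−180°, 180°) with +180 mapped
   to −180 (a fixed representative of the periodic boundary).  φ is
   undefined at the first residue of a chain, ψ/ω at the last.  ω is
   never exported as a potential: trans peptide bonds keep it nearly
   constant, so it carries no usable distribution and the force field's
   own term is the better description.

2. **Score weighting.**  Each model contributes with weight
   `c_j = exp(−s_j/s_ref)`.  `s_ref` (default 10, Rosetta energy units)
   sets the score difference per e-fold of weight: small enough to damp
   clearly bad models, large enough not to collapse the ensemble onto
   the single best one.  Scores with `|s|/s_ref > 700` are rejected
   (exp overflow) with advice to rescale.

3. **Circular KDE.**  The kernel is the power-raised cosine
   `cos^k(Δ·π/360°)` with Δ the circular distance in degrees.  The
   width rule `w = 2π·N^(−1/3)` (radians) follows the Scott-style
   dependence of bandwidth on sample size, and `k = 1 + 1/tan²(w/2)`
   maps width to exponent.  One global width is used per run, derived
   from the full ensemble size N even for torsions missing in a few
   models — a single provenance entry instead of per-residue widths.
   Angles are stored in degrees throughout; the width/exponent relation
   is in radians.  These mixed units match the estimator's printed
   form, and conversion happens only inside the kernel evaluation.

4. **Boltzmann inversion and scaling.**  `U(α) = −ln max(P, ε)` with a
   density floor `ε` at 1e−8 of the peak density: unsampled regions get
   a finite energy plateau and zero force instead of infinities.  The
   scaling factor `f_i = ratio·σ_ref/σ(U)` makes the standard deviation
   of the final energy exactly `ratio·σ_ref`, where σ_ref is the
   standard deviation (over a uniform angle) of the reference force
   field's backbone proper-dihedral cosine series and the ratios
   default to 14.77 (φ) and 5.30 (ψ).  σ_ref must be supplied — as a
   number or a `ReferenceTermSpec` cosine series — because "the
   corresponding dihedral term" is a property of the force field being
   patched, and φ/ψ each overlap several proper-dihedral types in AMBER
   ff99-family force fields; guessing silently would be worse than
   requiring one explicit input.  Energies are shifted so the global
   minimum is zero (additive constants are dynamically irrelevant).

5. **Analytic forces.**  `−dE/dα` is evaluated in closed form through
   the kernel sum (chain rule through the logarithm), in kJ/mol/rad
   while grids stay in degrees.  Where the density is floored the force
   is exactly zero.  Because energy and force come from the same
   analytic expressions, emitted tables are self-consistent to machine
   precision rather than to a finite-difference approximation.

No explicit kT appears in the inversion; the temperature factor is
absorbed into `f_i`, which is pinned by the scaling contract anyway.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `s_ref` | 10 | score units | e-fold scale of model weights |
| `w` | 2π·N^(−1/3) | rad | kernel width; must lie in (0, π] |
| grid step | 1.0 | deg | density/energy grid; divides 360 |
| `ratio` | 14.77 (φ), 5.30 (ψ) | — | std multiple of the reference term |
| `std_ref` | *required* | kJ/mol | reference-term standard deviation |
| floor fraction | 1e−8 | of peak density | energy cap in unsampled regions |
| `top_fraction` | all models | — | optional best-scoring subset selector |

The width rule needs N ≥ 9: for N ≤ 8 it gives w ≥ π, outside the
kernel's validity range (k would fall below 1), and the configuration
constructor raises rather than extrapolating; tiny ensembles can pass
an explicit width instead.  Whether all models or a top-scoring
fraction feed the estimator is exposed as `top_fraction`; the default
uses everything, since the exponential weights already suppress
poorly scored models smoothly.

PDF normalization (unit circular integral, per-degree measure) is on by
default and recorded in the manifest.  It changes the energies only by
an additive constant — which the min-zero shift removes — and the
forces not at all, so the flag is provenance, not physics.

## Synthetic ensembles

The generator draws per-residue φ/ψ from von Mises mixtures (mode,
concentration κ, mass per component), rebuilds backbone coordinates by
sequential internal-coordinate (NeRF) extension with ideal bond
geometry and planar trans peptide bonds, and assigns synthetic scores
`s_j = base + σ·ε_j + coupling·(number of minority-component draws)`.
All randomness flows through one seeded generator; a fixed seed gives
byte-identical output, and the emitted manifest stores the spec hash.

What it emulates: a scored ensemble whose torsion statistics are known
exactly — uni/multimodal distributions, controllable score–conformer
coupling.  What it does not: real fragment-assembly artifacts
(correlated neighboring torsions, Ramachandran coupling between φ and
ψ, sidechain packing, physical score landscapes).  Tests passing on
this generator therefore validate the estimator and export machinery,
not the adequacy of any particular experimental ensemble.

## Numerical choices

- **Grid.**  1° steps, 360 points on [−180, 180); export tables add the
  +180 wrap point (361 rows) with the first row's values copied for
  exact periodic closure.
- **Standard deviations** are population statistics over the uniform
  grid — the same uniform-angle measure used for the reference cosine
  series, making the ratio contract exact by construction.  A profile
  whose std is below 1e−12 (relative) is declared degenerate (uniform
  density, e.g. a torsion with no information) and skipped with a
  warning; the force-field term stays in place for that residue.
- **Force verification.**  The test oracle is Richardson-extrapolated
  (5-point) central differences of the analytic energy at 0.01°
  half-step.  A plain 3-point stencil cannot reach 1e−6 relative
  agreement for this energy family: `−ln P` inherits large high-order
  derivatives where the density is small, and for kernel exponents
  k < 3 the kernel's third derivative is unbounded at sample antipodes,
  so the randomized verification suite uses ensembles large enough
  (N = 150, k ≈ 3.2) that the oracle's truncation term is bounded.  An
  FFT spectral derivative is not used: non-integer cosine powers are
  not band-limited and alias at the 1e−5 level on a 1° grid.
- **Width/exponent round trip** is exact to 1e−12 on w ∈ [1e−3,
  π−1e−3]; nearer π, `k−1 = 1/tan²(w/2)` falls below the float64
  resolution of k and the width is no longer recoverable — the rule's
  N ≥ 9 guard keeps practical runs far from this boundary.
- **Ties.**  Density argmax and energy argmin use the first grid index;
  mode detection counts plateau runs once, at their first point, and
  requires 5% of peak density (configurable) to suppress grid noise.

## Export conventions

Tables are three columns — angle (deg), energy (kJ/mol), −dE/dα
(kJ/mol/rad) — at 1° spacing (configurable), named `table_d<i>.xvg`
with indices assigned in sorted (residue, kind) order; identical inputs
give byte-identical files.  Topology patching operates on plain,
include-expanded topology text (preprocessor directives are rejected,
never silently passed through): every proper-dihedral line whose
quadruplet matches a targeted φ/ψ — in either atom order — is removed,
one tabulated-dihedral line (function type 8, scale 1.0: the scaling
already lives in `f_i`) is added per quadruplet, and ω, impropers and
1–4 pairs are untouched.  A quadruplet found in no proper line is an
error: adding a tabulated term on top of an unknown parametrization
would double-count.  The patch record stores removed lines with their
positions, so unpatching restores the original byte-identically, and
re-patching an already patched topology is a warned no-op.

## Analysis conventions

Superposition is least-squares rigid-body (proper rotations only, via
SVD/Kabsch); subset RMSD fits one selection and measures another
(optionally its centroid), reported as mean ± std over models; RMSF is
taken about the ensemble-mean coordinates after fitting every model on
a common selection (default atoms: Cα).  Circular summaries use the
mean resultant length R: mean = arg Σ w·e^{iθ} (flagged undefined for
R < 10⁻³), std = √(−2 ln R).  The KRAS segment presets (P-loop 10–17,
Switch-I 28–40, Switch-II 60–76 and their complement over 1–169) ship
as documented constants for fit selections.  The combined amide CSP
`√(ΔδH² + (0.2·ΔδN)²)` is a common literature convention whose
nitrogen scaling is configurable; it is provided as plumbing and
labelled as such in its docstring.

## Limitations

- Potentials are independent per torsion: the joint (φ, ψ) Ramachandran
  correlation present in the source ensemble is not preserved, only the
  marginals.
- One kernel family (cosine power) and one width rule; no
  cross-validated bandwidth, no von Mises or wrapped-Gaussian kernels.
- Topology support covers pre-processed single-molecule topology text;
  macros and `#include` resolution belong to the engine's preprocessor.
- No sidechain χ angles, mmCIF, insertion codes or trajectory formats;
  alternate locations keep the first conformer.
- The package produces MD inputs; running, solvating or thermostatting
  the simulation is out of scope.
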