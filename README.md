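# torsionforge

Ensemble-derived backbone torsion potentials for molecular dynamics.

## The problem

Chemical-shift-based structure generators (CS-Rosetta and kin) turn NMR
chemical shifts into large scored ensembles of all-atom protein models —
but those models lack cofactors, ligands and ions, and the ensemble
itself is a static bag of conformers.  A practical way to carry the
chemical-shift information into an MD refinement (where the nonprotein
components can be reinserted and equilibrated) is to convert the
ensemble's backbone φ/ψ statistics into per-residue torsion potentials
that *replace* the force field's own backbone dihedral terms: the
simulation is then pulled toward backbone conformations consistent with
the measured shifts, while everything else (sidechains, ligands,
solvent) evolves under the normal force field.

`torsionforge` builds those potentials.  It reads a multi-model PDB
ensemble plus its score table, estimates each torsion's distribution
with a score-weighted circular kernel density estimator, Boltzmann-
inverts the densities into energy profiles with analytic forces, scales
them to force-field magnitude, and writes GROMACS-style tabulated
dihedral files together with a reversible topology patch.  It also
ships the analytics used to compare refined and unrefined ensembles
(circular summaries, subset RMSD after fitting another subset,
per-residue RMSF) and a synthetic-ensemble generator with known torsion
statistics, so the entire pipeline is testable without external data.

## The model

For residue *i* with ensemble torsion observations α*ᵢⱼ* (model *j* of
*N*) and total scores *sⱼ* (lower is better), the density on the circle
is

    P_i(α) = (1/C) Σ_j c_j · cos^k( Δ(α, α_ij) · π/360° )

where Δ is the circular distance in degrees (0–180), the weights are
`c_j = exp(−s_j / s_ref)` with `s_ref = 10` by default (one e-fold of
weight per `s_ref` score units), `C = Σ c_j`, and the kernel exponent
follows from the kernel width via `k = 1 + 1/tan²(w/2)` with the
Scott-style rule `w = 2π·N^(−1/3)`.

The potential is the Boltzmann inversion `E_i(α) = −f_i · ln P_i(α)`,
with the scaling factor `f_i` chosen so the standard deviation of the
profile is a fixed multiple of the standard deviation of the reference
force field's backbone proper-dihedral term (its cosine series):
14.77× for φ and 5.30× for ψ by default.  Forces are the analytic
`−dE/dα` through the kernel sum, so the emitted energy and force
columns are consistent to machine precision.

## Worked example

```python
import torsionforge as tf

# a synthetic scored ensemble: 4 residues, 500 models; phi is bimodal
# (70% near -63, 30% near +55) and the minority mode scores worse
mix_phi = tf.AngleMixture(((-63.0, 12.0, 0.7), (55.0, 12.0, 0.3)))
spec = tf.GeneratorSpec.uniform(n_residues=4, n_models=500, seed=42,
                                phi=mix_phi, score_coupling=3.0)
ens = tf.generate_ensemble(spec)

model = tf.EnsembleTorsionModel(ens)          # w, k derived from N=500
print(f"N = {ens.N}, kernel width w = {model.config.width_w:.4f} rad "
      f"({model.config.width_deg:.1f} deg), exponent k = {model.config.exponent_k:.3f}")
results = model.fit(std_ref=1.86)             # reference term std, kJ/mol
print(results.summary().round(3).to_string(index=False))
```

prints

```
N = 500, kernel width w = 0.7916 rad (45.4 deg), exponent k = 6.727
 residue_index angle_kind  n_samples  mode_deg  energy_min_deg    f_i  std_energy_kJ_mol  std_ratio  max_energy_kJ_mol
             1        psi        500     -43.0           -43.0  2.867              9.858       5.30             34.332
             2        phi        500     -62.0           -62.0 24.344             27.472      14.77             92.775
             2        psi        500     -42.0           -42.0  3.016              9.858       5.30             33.505
             3        phi        500     -62.0           -62.0 24.629             27.472      14.77             93.135
             3        psi        500     -43.0           -43.0  2.963              9.858       5.30             34.105
             4        phi        500     -61.0           -61.0 25.728             27.472      14.77             93.392
```

Each torsion's energy minimum (`energy_min_deg`) coincides with its
density mode (`mode_deg`), which sits on the generating major mode
(−63°/−43°) to within the 1° grid: the score weighting suppresses the
worse-scoring minority φ mode.  `std_energy/std_ref` equals the target
ratios 14.77 (φ) and 5.30 (ψ) exactly; `f_i` is the per-torsion factor
that achieves this.  From here,

```python
results.export_tables("out/")                       # table_d0.xvg, ...
results.patch_topology("protein.top", "out/")       # patched top + patch.json
```

writes one three-column table (angle [deg], energy [kJ/mol], force
[kJ/mol/rad]) per torsion and replaces the matching backbone φ/ψ proper
dihedrals in a pre-processed topology by tabulated terms (ω and
impropers untouched; the patch record makes the edit fully reversible).

A CLI mirrors the library: `torsionforge extract | pef | export-gromacs
| analyze | synth` (see `torsionforge --help`).

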