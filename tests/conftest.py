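import numpy as np
import pytest

import torsionforge as tf


def make_topology_text(n_res: int, phi_lines_per_quad: int = 2) -> str:
    """Synthetic pre-processed GROMACS-style topology for an N/CA/C/O backbone.

    Proper dihedrals (funct 9) cover phi (with multiple multiplicity
    lines), psi and omega; one improper (funct 4) per residue is added
    so patching can prove it leaves impropers alone.
    """
    lines = [
        "[ moleculetype ]",
        "; name  nrexcl",
        "Protein  3",
        "",
        "[ atoms ]",
        ";   nr  type  resnr  residue  atom  cgnr  charge  mass",
    ]
    names = ("N", "CA", "C", "O")
    nr = 0
    for r in range(1, n_res + 1):
        for name in names:
            nr += 1
            lines.append(f"{nr:6d}  X  {r:5d}  ALA  {name:>4}  {nr:5d}  0.000  14.0")

    def idx(resid, name):
        return (resid - 1) * 4 + names.index(name) + 1

    lines += ["", "[ dihedrals ]", "; backbone propers"]
    for r in range(2, n_res + 1):  # phi
        q = (idx(r - 1, "C"), idx(r, "N"), idx(r, "CA"), idx(r, "C"))
        for mult in range(1, phi_lines_per_quad + 1):
            lines.append(f"{q[0]:6d} {q[1]:6d} {q[2]:6d} {q[3]:6d}     9 "
                         f"180.0  {0.5 * mult:.3f}  {mult}")
    for r in range(1, n_res):  # psi
        q = (idx(r, "N"), idx(r, "CA"), idx(r, "C"), idx(r + 1, "N"))
        lines.append(f"{q[0]:6d} {q[1]:6d} {q[2]:6d} {q[3]:6d}     9 "
                     f"180.0  0.450  2")
    for r in range(1, n_res):  # omega (must stay untouched)
        q = (idx(r, "CA"), idx(r, "C"), idx(r + 1, "N"), idx(r + 1, "CA"))
        lines.append(f"{q[0]:6d} {q[1]:6d} {q[2]:6d} {q[3]:6d}     9 "
                     f"180.0  10.000  2")
    lines += ["", "[ dihedrals ]", "; impropers"]
    for r in range(1, n_res):
        q = (idx(r, "CA"), idx(r + 1, "N"), idx(r, "C"), idx(r, "O"))
        lines.append(f"{q[0]:6d} {q[1]:6d} {q[2]:6d} {q[3]:6d}     4 "
                     f"180.0  43.9  2")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def small_spec():
    return tf.GeneratorSpec.uniform(n_residues=5, n_models=120, seed=7)


@pytest.fixture(scope="session")
def small_ensemble(small_spec):
    return tf.generate_ensemble(small_spec)


@pytest.fixture(scope="session")
def fitted_results(small_ensemble):
    model = tf.EnsembleTorsionModel(small_ensemble)
    return model.fit(std_ref=1.0)


@pytest.fixture()
def topology_text():
    return make_topology_text(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
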