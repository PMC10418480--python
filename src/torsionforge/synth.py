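"""Synthetic scored ensembles with known torsion statistics.

Stands in for the output of a chemical-shift-driven model generator:
per-residue phi/psi angles are drawn from specified circular (von Mises
mixture) distributions, reconstructed into valid backbone coordinates
with ideal bond geometry, and paired with synthetic total scores.  The
generator is the ground truth for every statistical test downstream —
mode locations, concentrations and mixture masses are known exactly, so
density estimates, potentials and analytics can be checked against the
parameters that produced the data.

Backbone reconstruction uses sequential internal-coordinate (NeRF)
chain extension with fixed ideal bond lengths and angles and planar
trans peptide bonds (omega = 180).  Only N, CA, C, O atoms are built:
sidechains do not enter any torsion downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ensemble import Atom, ModelRecord, ScoreTable, ScoredEnsemble, wrap_angle

# ideal backbone geometry (Angstrom / degrees), Engh-Huber-style constants
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA_TRANS = 180.0


class GeneratorError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class AngleMixture:
    """Circular von Mises mixture: components of (mode_deg, kappa, mass)."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if not self.components:
            raise GeneratorError("mixture needs at least one component")
        masses = np.array([m for _, _, m in self.components], dtype=float)
        if np.any(masses < 0) or not np.isclose(masses.sum(), 1.0, atol=1e-9):
            raise GeneratorError(
                f"mixture masses must be nonnegative and sum to 1, got {masses}"
            )
        if any(kappa <= 0 for _, kappa, _ in self.components):
            raise GeneratorError("von Mises concentration kappa must be > 0")

    @classmethod
    def single(cls, mode_deg: float, kappa: float) -> "AngleMixture":
        return cls(((float(mode_deg), float(kappa), 1.0),))

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw n angles (degrees, wrapped) and their component indices."""
        masses = np.array([m for _, _, m in self.components])
        comp = rng.choice(len(self.components), size=n, p=masses)
        out = np.empty(n)
        for idx, (mode, kappa, _) in enumerate(self.components):
            sel = comp == idx
            if np.any(sel):
                out[sel] = np.degrees(
                    rng.vonmises(np.radians(mode), kappa, size=int(sel.sum()))
                )
        return wrap_angle(out), comp


@dataclass(frozen=True)
class GeneratorSpec:
    """Full recipe for one synthetic scored ensemble.

    ``phi``/``psi`` hold one :class:`AngleMixture` per residue (phi of
    the first and psi of the last residue are still specified but do not
    influence the built chain's defined torsions beyond construction).
    The score model is s_j = base + sigma*eps_j + coupling * (number of
    torsions drawn from a secondary mixture component in model j), so a
    positive coupling makes minority-mode conformers score worse.
    """

    n_residues: int
    phi: tuple[AngleMixture, ...]
    psi: tuple[AngleMixture, ...]
    n_models: int
    seed: int
    score_base: float = -100.0
    score_sigma: float = 2.0
    score_coupling: float = 0.0

    def __post_init__(self):
        if self.n_residues < 2:
            raise GeneratorError("need at least 2 residues for any torsion")
        if len(self.phi) != self.n_residues or len(self.psi) != self.n_residues:
            raise GeneratorError("need one phi and one psi mixture per residue")
        if self.n_models < 1:
            raise GeneratorError("need at least one model")

    @classmethod
    def uniform(cls, n_residues: int, n_models: int, seed: int,
                phi: AngleMixture | None = None,
                psi: AngleMixture | None = None, **score_kw) -> "GeneratorSpec":
        """Same per-residue distribution everywhere (helix-like defaults)."""
        phi = phi or AngleMixture.single(-63.0, 20.0)
        psi = psi or AngleMixture.single(-43.0, 20.0)
        return cls(n_residues=n_residues, phi=(phi,) * n_residues,
                   psi=(psi,) * n_residues, n_models=n_models, seed=seed,
                   **score_kw)

    def to_dict(self) -> dict:
        return {
            "n_residues": self.n_residues,
            "phi": [list(map(list, m.components)) for m in self.phi],
            "psi": [list(map(list, m.components)) for m in self.psi],
            "n_models": self.n_models,
            "seed": self.seed,
            "score_base": self.score_base,
            "score_sigma": self.score_sigma,
            "score_coupling": self.score_coupling,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        return cls(
            n_residues=d["n_residues"],
            phi=tuple(AngleMixture(tuple(tuple(c) for c in m)) for m in d["phi"]),
            psi=tuple(AngleMixture(tuple(tuple(c) for c in m)) for m in d["psi"]),
            n_models=d["n_models"], seed=d["seed"],
            score_base=d.get("score_base", -100.0),
            score_sigma=d.get("score_sigma", 2.0),
            score_coupling=d.get("score_coupling", 0.0),
        )

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class DihedralDraw:
    """Sampled torsions: (n_models, n_residues) arrays plus component labels."""

    phi_deg: np.ndarray
    psi_deg: np.ndarray
    phi_component: np.ndarray
    psi_component: np.ndarray


def sample_dihedrals(spec: GeneratorSpec) -> DihedralDraw:
    """Draw all torsions for the ensemble from the spec's mixtures."""
    rng = np.random.default_rng(spec.seed)
    n_m, n_r = spec.n_models, spec.n_residues
    phi = np.empty((n_m, n_r)); psi = np.empty((n_m, n_r))
    phi_c = np.empty((n_m, n_r), dtype=int); psi_c = np.empty((n_m, n_r), dtype=int)
    for r in range(n_r):
        phi[:, r], phi_c[:, r] = spec.phi[r].sample(rng, n_m)
        psi[:, r], psi_c[:, r] = spec.psi[r].sample(rng, n_m)
    return DihedralDraw(phi_deg=phi, psi_deg=psi,
                        phi_component=phi_c, psi_component=psi_c)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, angle(b,c,d) and torsion(a,b,c,d)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_deg, psi_deg, model_id: int = 1,
                   omega_deg: float = OMEGA_TRANS, chain: str = "A") -> ModelRecord:
    """Build an N/CA/C/O backbone whose torsions equal the given angles.

    ``phi_deg[0]`` and ``psi_deg[-1]`` are ignored (undefined at chain
    termini).  Re-extracting phi/psi from the built coordinates
    reproduces the inputs to well below 0.1 degrees.
    """
    phi = np.asarray(phi_deg, dtype=float)
    psi = np.asarray(psi_deg, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1:
        raise GeneratorError("phi and psi must be 1-D arrays of equal length")
    n_res = len(phi)
    if n_res < 2:
        raise GeneratorError("need at least 2 residues")

    N = np.empty((n_res, 3)); CA = np.empty((n_res, 3)); C = np.empty((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1],
                           BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i],
                            BOND_N_CA, ANGLE_C_N_CA, omega_deg)
        C[i] = _place_atom(C[i - 1], N[i], CA[i],
                           BOND_CA_C, ANGLE_N_CA_C, phi[i])

    atoms: list[Atom] = []
    for i in range(n_res):
        resid = i + 1
        for name, pos in (("N", N[i]), ("CA", CA[i]), ("C", C[i])):
            atoms.append(Atom(name=name, resid=resid, resname="ALA",
                              chain=chain, xyz=tuple(float(v) for v in pos)))
        # carbonyl O: anti to the next N (or to psi=180 for the last residue)
        o_torsion = wrap_angle(psi[i] + 180.0) if i < n_res - 1 else 180.0
        O = _place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, o_torsion)
        atoms.append(Atom(name="O", resid=resid, resname="ALA",
                          chain=chain, xyz=tuple(float(v) for v in O)))
    return ModelRecord(model_id=model_id, atoms=atoms)


def model_scores(spec: GeneratorSpec, draw: DihedralDraw) -> np.ndarray:
    """Synthetic total scores for each model (lower is better)."""
    rng = np.random.default_rng(spec.seed + 1)
    noise = rng.normal(0.0, spec.score_sigma, size=spec.n_models)
    minority = (draw.phi_component > 0).sum(axis=1) + (draw.psi_component > 0).sum(axis=1)
    return spec.score_base + noise + spec.score_coupling * minority


def generate_ensemble(spec: GeneratorSpec) -> ScoredEnsemble:
    """Build the full in-memory scored ensemble (models + scores + samples)."""
    from .ensemble import extract_dihedrals

    draw = sample_dihedrals(spec)
    scores = model_scores(spec, draw)
    models = [build_backbone(draw.phi_deg[j], draw.psi_deg[j], model_id=j + 1)
              for j in range(spec.n_models)]
    table = ScoreTable({str(j + 1): float(scores[j]) for j in range(spec.n_models)})
    ens = ScoredEnsemble(models=models, scores=table)
    ens.samples = extract_dihedrals(models)
    return ens


def emit_scored_ensemble(spec: GeneratorSpec, out_prefix) -> dict:
    """Write <prefix>.pdb, <prefix>.sc and <prefix>.manifest.json to disk.

    The emitted files are readable by the ensemble readers; the manifest
    records the full spec, its hash and the seed for provenance.
    """
    from .ensemble import write_ensemble

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    draw = sample_dihedrals(spec)
    scores = model_scores(spec, draw)
    models = [build_backbone(draw.phi_deg[j], draw.psi_deg[j], model_id=j + 1)
              for j in range(spec.n_models)]

    pdb_path = out_prefix.with_suffix(".pdb")
    write_ensemble(models, pdb_path)
    sc_path = out_prefix.with_suffix(".sc")
    with open(sc_path, "w") as fh:
        fh.write("SCORE: total_score description\n")
        for j in range(spec.n_models):
            fh.write(f"SCORE: {scores[j]:.4f} {j + 1}\n")
    manifest = {
        "spec": spec.to_dict(),
        "spec_sha256": spec.content_hash(),
        "pdb": pdb_path.name,
        "scores": sc_path.name,
    }
    manifest_path = Path(str(out_prefix) + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
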