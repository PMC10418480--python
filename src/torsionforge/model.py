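"""Model/Results surface tying the pipeline together.

:class:`EnsembleTorsionModel` is constructed from a scored ensemble and
the estimator settings (reference score, kernel width rule, grid);
calling :meth:`~EnsembleTorsionModel.fit` runs the score-weighted
circular KDE and Boltzmann inversion for every exportable torsion and
returns a :class:`TorsionPotentialResults` carrying the densities,
potentials, scaling diagnostics, a ``summary()`` table, plotting, and
the MD export methods (tabulated dihedral files + topology patch).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gromacs
from .ensemble import ScoredEnsemble, EXPORTABLE_KINDS
from .kde import (CircularKernelConfig, DEFAULT_GRID_STEP, DEFAULT_S_REF,
                  TorsionPDF, WeightSet, score_weights, weighted_pdf)
from .pef import (DEFAULT_FLOOR_FRACTION, DEFAULT_RATIOS, PEFError,
                  ReferenceTermSpec, TorsionPEF, reference_term_std, scale_pef)

logger = logging.getLogger(__name__)


class EnsembleTorsionModel:
    """Score-weighted torsion-potential model of a structural ensemble.

    Parameters
    ----------
    ensemble : ScoredEnsemble
        Models, scores and extracted dihedral samples.
    s_ref : float
        Reference score of the exponential weighting (default 10).
    config : CircularKernelConfig, optional
        Kernel width/exponent; derived from the ensemble size via the
        w = 2*pi*N^(-1/3) rule when omitted.  One global width is used
        for every torsion, including those missing from some models.
    grid_step : float
        Angle grid spacing in degrees (default 1).
    normalize_pdf : bool
        Normalize densities to unit circular integral before inversion.
        Energies change only by an additive constant, forces not at all;
        the flag is recorded in the manifest.
    """

    def __init__(self, ensemble: ScoredEnsemble, *,
                 s_ref: float = DEFAULT_S_REF,
                 config: CircularKernelConfig | None = None,
                 grid_step: float = DEFAULT_GRID_STEP,
                 normalize_pdf: bool = True):
        self.ensemble = ensemble
        self.s_ref = float(s_ref)
        self.config = config or CircularKernelConfig.from_ensemble_size(ensemble.N)
        self.grid_step = float(grid_step)
        self.normalize_pdf = bool(normalize_pdf)
        self.weights: WeightSet = score_weights(ensemble.scores, s_ref=self.s_ref)

    @classmethod
    def from_files(cls, pdb_path, score_path, *,
                   top_fraction: float | None = None, **kwargs) -> "EnsembleTorsionModel":
        ens = ScoredEnsemble.from_files(pdb_path, score_path,
                                        top_fraction=top_fraction)
        return cls(ens, **kwargs)

    def fit(self, *, std_ref: float | dict[str, float] | None = None,
            reference_terms: dict[str, ReferenceTermSpec] | None = None,
            ratios: dict[str, float] | None = None,
            floor_fraction: float = DEFAULT_FLOOR_FRACTION) -> "TorsionPotentialResults":
        """Estimate all densities and build the scaled potentials.

        ``std_ref`` (kJ/mol, per angle kind or one number for both) or
        ``reference_terms`` must be supplied: the reference standard
        deviation belongs to the force field being patched and is not
        guessed.  Degenerate torsions (flat profiles) are skipped with a
        warning and listed in the results.
        """
        ratios = dict(DEFAULT_RATIOS, **(ratios or {}))
        std_ref_by_kind: dict[str, float] = {}
        for kind in EXPORTABLE_KINDS:
            if reference_terms and kind in reference_terms:
                std_ref_by_kind[kind] = reference_term_std(reference_terms[kind])
            elif isinstance(std_ref, dict):
                if kind in std_ref:
                    std_ref_by_kind[kind] = float(std_ref[kind])
            elif std_ref is not None:
                std_ref_by_kind[kind] = float(std_ref)
        missing = [k for k in EXPORTABLE_KINDS if k not in std_ref_by_kind]
        if missing:
            raise PEFError(
                f"no reference std for {missing}: pass std_ref or reference_terms"
            )

        pdfs: dict[tuple[int, str], TorsionPDF] = {}
        pefs: dict[tuple[int, str], TorsionPEF] = {}
        skipped: list[tuple[int, str, str]] = []
        for samples in self.ensemble.samples:
            if not samples.exportable:
                continue
            pdf = weighted_pdf(samples, self.weights, self.config,
                               grid_step=self.grid_step,
                               normalize=self.normalize_pdf)
            pdfs[(samples.residue_index, samples.angle_kind)] = pdf
            try:
                pefs[(samples.residue_index, samples.angle_kind)] = scale_pef(
                    pdf, ratio=ratios[samples.angle_kind],
                    std_ref=std_ref_by_kind[samples.angle_kind],
                    floor_fraction=floor_fraction,
                )
            except PEFError as exc:
                warnings.warn(
                    f"residue {samples.residue_index} {samples.angle_kind}: "
                    f"{exc}; left on the original force-field term"
                )
                skipped.append((samples.residue_index, samples.angle_kind, str(exc)))
        return TorsionPotentialResults(
            model=self, pdfs=pdfs, pefs=pefs, skipped=skipped,
            ratios=ratios, std_ref=std_ref_by_kind,
            floor_fraction=floor_fraction,
        )


@dataclass
class TorsionPotentialResults:
    """Fitted densities, potentials and export methods."""

    model: EnsembleTorsionModel
    pdfs: dict[tuple[int, str], TorsionPDF]
    pefs: dict[tuple[int, str], TorsionPEF]
    skipped: list[tuple[int, str, str]]
    ratios: dict[str, float]
    std_ref: dict[str, float]
    floor_fraction: float
    tables: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Per-torsion diagnostics: samples, mode, scaling, energy spread."""
        rows = []
        for (resid, kind), pef in sorted(self.pefs.items()):
            pdf = self.pdfs[(resid, kind)]
            rows.append({
                "residue_index": resid,
                "angle_kind": kind,
                "n_samples": len(pdf.samples_deg),
                "mode_deg": pdf.argmax_deg(),
                "energy_min_deg": pef.argmin_deg(),
                "f_i": pef.f_i,
                "std_energy_kJ_mol": float(np.std(pef.energy)),
                "std_ratio": float(np.std(pef.energy)) / pef.std_ref,
                "max_energy_kJ_mol": float(np.max(pef.energy)),
            })
        return pd.DataFrame(rows)

    def export_tables(self, out_dir, spacing: float = 1.0):
        """Write tabulated dihedral files; returns the table descriptors."""
        self.tables = gromacs.write_dihedral_tables(
            self.pefs.values(), out_dir, spacing=spacing
        )
        return self.tables

    def patch_topology(self, topology_path, out_dir, spacing: float = 1.0):
        """Export tables and patch the topology in one step.

        Writes the tables, the patched topology (``<name>.patched.top``)
        and the patch record (``patch.json``) into ``out_dir``.  Only
        residues with an exported potential are patched; all other
        dihedral terms are untouched.
        """
        out_dir = Path(out_dir)
        tables = self.export_tables(out_dir, spacing=spacing)
        topology = gromacs.Topology.from_file(topology_path)
        quads = gromacs.identify_backbone_quadruplets(topology)
        exported = {(r, k) for r, k in self.pefs}
        targeted = {
            resid: {k: q for k, q in kinds.items() if (resid, k) in exported}
            for resid, kinds in quads.items()
        }
        targeted = {r: k for r, k in targeted.items() if k}
        patched_text, patch = gromacs.patch_topology(topology, tables, targeted)
        top_out = out_dir / (Path(topology_path).stem + ".patched.top")
        top_out.write_text(patched_text)
        (out_dir / "patch.json").write_text(patch.to_json())
        return top_out, patch

    def write_manifest(self, path) -> dict:
        """Record the full provenance of the run as JSON."""
        m = self.model
        manifest = {
            "N": m.ensemble.N,
            "width_w_rad": m.config.width_w,
            "exponent_k": m.config.exponent_k,
            "s_ref": m.s_ref,
            "grid_step_deg": m.grid_step,
            "pdf_normalized": m.normalize_pdf,
            "ratios": self.ratios,
            "std_ref_kJ_mol": self.std_ref,
            "floor_fraction": self.floor_fraction,
            "n_potentials": len(self.pefs),
            "skipped": [list(s) for s in self.skipped],
            "tables": [
                {"index": t.table_index, "residue_index": t.residue_index,
                 "angle_kind": t.angle_kind, "file": t.filename}
                for t in self.tables
            ],
        }
        Path(path).write_text(json.dumps(manifest, indent=2))
        return manifest

    def write_pef_tables(self, out_dir) -> None:
        """Per-torsion text tables: angle_deg, energy_kJ_mol, force_kJ_mol_rad."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (resid, kind), pef in sorted(self.pefs.items()):
            df = pd.DataFrame({
                "angle_deg": pef.grid_deg,
                "energy_kJ_mol": pef.energy,
                "force_kJ_mol_rad": pef.force,
            })
            df.to_csv(out_dir / f"pef_{resid:04d}_{kind}.tsv", sep="\t",
                      index=False, float_format="%.10g")

    def plot_torsion(self, residue_index: int, angle_kind: str, ax=None):
        """Density, potential and force for one torsion (diagnostic plot)."""
        import matplotlib.pyplot as plt

        pdf = self.pdfs[(residue_index, angle_kind)]
        pef = self.pefs[(residue_index, angle_kind)]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(pdf.grid_deg, pdf.density / pdf.density.max(), label="density (scaled)")
        ax.plot(pef.grid_deg, pef.energy / pef.energy.max(), label="energy (scaled)")
        ax2 = ax.twinx()
        ax2.plot(pef.grid_deg, pef.force, color="tab:orange", alpha=0.6,
                 label="force [kJ/mol/rad]")
        ax.set_xlabel("angle [deg]")
        ax.set_title(f"residue {residue_index} {angle_kind}")
        ax.legend(loc="upper left")
        return ax

    def plot_polar_distribution(self, residue_index: int, angle_kind: str, ax=None):
        """Polar histogram of the sample angles (refined-vs-unrefined style)."""
        import matplotlib.pyplot as plt

        pdf = self.pdfs[(residue_index, angle_kind)]
        if ax is None:
            _, ax = plt.subplots(subplot_kw={"projection": "polar"})
        theta = np.radians(pdf.samples_deg)
        ax.hist(theta, bins=72, weights=pdf.weights, density=True, alpha=0.6)
        ax.set_title(f"residue {residue_index} {angle_kind}")
        return ax
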