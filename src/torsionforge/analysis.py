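"""Ensemble-comparison analytics.

Tools to characterize structural ensembles before and after refinement:
rigid-body superposition, RMSD of one selection after fitting another
(e.g. cofactor deviation after fitting the backbone of the non-Switch
regions), per-residue RMSF about the ensemble mean, circular summaries
(mean/std/modes) of torsion distributions, and a conventional combined
amide chemical-shift-perturbation measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import Atom, DihedralSampleSet, ModelRecord, wrap_angle
from . import kde

BACKBONE_NAMES = ("N", "CA", "C", "O")

# KRAS functional segments (P-loop, Switch-I, Switch-II) and their
# complement over the 1-169 construct, shipped as analysis presets.
KRAS_P_LOOP = range(10, 18)
KRAS_SWITCH_I = range(28, 41)
KRAS_SWITCH_II = range(60, 77)
KRAS_NON_SWITCH = tuple(
    r for r in range(1, 170)
    if r not in KRAS_P_LOOP and r not in KRAS_SWITCH_I and r not in KRAS_SWITCH_II
)


class AnalysisError(ValueError):
    """Raised for invalid selections or degenerate analysis input."""


AtomPredicate = Callable[[Atom], bool]


def make_selection(resids: Sequence[int] | None = None,
                   atom_names: Sequence[str] | None = None,
                   chain: str | None = None) -> AtomPredicate:
    """Build an atom predicate from residue ids / atom names / chain."""
    resid_set = set(resids) if resids is not None else None
    name_set = set(atom_names) if atom_names is not None else None

    def predicate(a: Atom) -> bool:
        if resid_set is not None and a.resid not in resid_set:
            return False
        if name_set is not None and a.name not in name_set:
            return False
        if chain is not None and a.chain != chain:
            return False
        return True

    return predicate


def parse_selection(expr: str) -> AtomPredicate:
    """Parse a small selection grammar: ``resid 1-9,18-27 and backbone``.

    Supported atoms clauses: ``backbone`` (N, CA, C, O), ``name X[,Y...]``;
    residue clause: ``resid`` with comma-separated ranges; ``all``.
    """
    expr = expr.strip().lower()
    if expr == "all":
        return lambda a: True
    resids: list[int] | None = None
    names: list[str] | None = None
    for clause in expr.split(" and "):
        clause = clause.strip()
        if clause.startswith("resid"):
            resids = []
            for part in clause.removeprefix("resid").strip().split(","):
                if "-" in part:
                    lo, hi = part.split("-")
                    resids.extend(range(int(lo), int(hi) + 1))
                elif part:
                    resids.append(int(part))
        elif clause == "backbone":
            names = list(BACKBONE_NAMES)
        elif clause.startswith("name"):
            names = [n.upper() for n in
                     clause.removeprefix("name").replace(",", " ").split()]
        else:
            raise AnalysisError(f"cannot parse selection clause {clause!r}")
    return make_selection(resids=resids, atom_names=names)


@dataclass
class SelectionSpec:
    """Which atoms to fit on and which atoms' deviation to measure."""

    fit_selection: AtomPredicate
    measure_selection: AtomPredicate | None = None

    @classmethod
    def from_strings(cls, fit: str, measure: str | None = None) -> "SelectionSpec":
        return cls(fit_selection=parse_selection(fit),
                   measure_selection=parse_selection(measure) if measure else None)


def _matched_coords(mobile: ModelRecord, reference: ModelRecord,
                    predicate: AtomPredicate) -> tuple[np.ndarray, np.ndarray]:
    ref_keys = [(a.chain, a.resid, a.name) for a in reference.atoms if predicate(a)]
    if not ref_keys:
        raise AnalysisError("empty selection")
    mob, ref = [], []
    for key in ref_keys:
        m = mobile.coord(*key)
        r = reference.coord(*key)
        if m is None:
            raise AnalysisError(f"selection atom {key} missing in mobile model")
        mob.append(m); ref.append(r)
    return np.asarray(mob), np.asarray(ref)


def superpose(mobile: ModelRecord, reference: ModelRecord,
              fit: SelectionSpec) -> tuple[ModelRecord, float]:
    """Least-squares rigid-body superposition (proper rotation only).

    Returns the transformed copy of ``mobile`` and the RMSD of the fit
    selection after superposition.
    """
    mob, ref = _matched_coords(mobile, reference, fit.fit_selection)
    if len(mob) < 3:
        raise AnalysisError(f"need >= 3 fit atoms, got {len(mob)}")
    mob_c, ref_c = mob.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    fitted = rot.apply(mob - mob_c) + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))

    moved = [Atom(a.name, a.resid, a.resname, a.chain,
                  tuple(rot.apply(np.asarray(a.xyz) - mob_c) + ref_c))
             for a in mobile.atoms]
    return ModelRecord(model_id=mobile.model_id, atoms=moved), rmsd


def subset_rmsd(ensemble: Sequence[ModelRecord], reference: ModelRecord,
                spec: SelectionSpec, centroid: bool = False,
                ) -> tuple[float, float, np.ndarray]:
    """Deviation of one selection after fitting another, per model.

    Each model is superposed onto the reference using the fit selection;
    the RMSD of the measure selection (or the distance between its
    centroid and the reference centroid, with ``centroid=True``) is then
    reported as mean, std and the per-model values in Angstrom.
    """
    if spec.measure_selection is None:
        raise AnalysisError("SelectionSpec.measure_selection is required")
    values = []
    for model in ensemble:
        fitted, _ = superpose(model, reference, spec)
        mob, ref = _matched_coords(fitted, reference, spec.measure_selection)
        if centroid:
            values.append(float(np.linalg.norm(mob.mean(axis=0) - ref.mean(axis=0))))
        else:
            values.append(float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))))
    values = np.asarray(values)
    return float(values.mean()), float(values.std()), values


def per_residue_rmsf(ensemble: Sequence[ModelRecord], fit: SelectionSpec,
                     atoms: AtomPredicate | None = None) -> dict[int, float]:
    """RMSF per residue about the ensemble mean after superposition.

    All models are fitted (on ``fit``) to the first model; the RMSF of
    each residue's selected atoms (default: CA) is computed about their
    ensemble-mean positions and averaged within the residue.
    """
    if len(ensemble) < 2:
        raise AnalysisError("RMSF needs at least two models")
    atoms = atoms or make_selection(atom_names=["CA"])
    reference = ensemble[0]
    fitted = [superpose(m, reference, fit)[0] for m in ensemble]

    keys = [(a.chain, a.resid, a.name) for a in reference.atoms if atoms(a)]
    if not keys:
        raise AnalysisError("empty RMSF atom selection")
    coords = np.array([[m.coord(*k) for k in keys] for m in fitted])  # (M, K, 3)
    mean = coords.mean(axis=0)
    msf = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)  # (K,)

    out: dict[int, list[float]] = {}
    for (chain, resid, name), v in zip(keys, msf):
        out.setdefault(resid, []).append(v)
    return {r: float(np.sqrt(np.mean(v))) for r, v in out.items()}


@dataclass
class CircularSummary:
    """Weighted circular statistics of one torsion distribution."""

    residue_index: int
    angle_kind: str
    circular_mean_deg: float
    circular_std_deg: float
    resultant_length: float
    mean_defined: bool
    modes_deg: list[float] = field(default_factory=list)

    @property
    def multimodality(self) -> int:
        return len(self.modes_deg)


def circular_summary(samples: DihedralSampleSet,
                     weights: np.ndarray | None = None,
                     mode_prominence: float = 0.05,
                     config: kde.CircularKernelConfig | None = None) -> CircularSummary:
    """Weighted circular mean/std and KDE-based mode detection.

    The circular std is sqrt(-2 ln R) with R the weighted mean resultant
    length.  Modes are local maxima of the circular KDE whose density
    exceeds ``mode_prominence`` of the peak; with fewer than 9 samples
    an explicit kernel ``config`` must be supplied.
    """
    if len(samples) == 0:
        raise AnalysisError("empty sample set")
    theta = np.radians(samples.angles_deg)
    w = np.ones(len(theta)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(theta):
        raise AnalysisError("weights length mismatch")
    w = w / w.sum()
    z = np.sum(w * np.exp(1j * theta))
    resultant = min(float(np.abs(z)), 1.0)  # guard eps overshoot for point masses
    mean_defined = resultant > 1e-3
    mean_deg = wrap_angle(np.degrees(np.angle(z))) if mean_defined else float("nan")
    std_deg = float(np.degrees(np.sqrt(-2.0 * np.log(max(resultant, 1e-300)))))

    if config is None:
        config = kde.CircularKernelConfig.from_ensemble_size(len(samples))
    density = kde._kernel_sum(kde.make_grid(1.0), samples.angles_deg,
                              w, config.exponent_k)
    modes = _circular_local_maxima(kde.make_grid(1.0), density,
                                   mode_prominence * float(density.max()))
    return CircularSummary(
        residue_index=samples.residue_index, angle_kind=samples.angle_kind,
        circular_mean_deg=mean_deg if mean_defined else 0.0,
        circular_std_deg=std_deg, resultant_length=resultant,
        mean_defined=mean_defined, modes_deg=modes,
    )


def _circular_local_maxima(grid: np.ndarray, density: np.ndarray,
                           threshold: float) -> list[float]:
    """Strict local maxima on the periodic grid above a density threshold.

    Plateaus (runs of equal density) count once, at their first grid point.
    """
    n = len(density)
    modes = []
    i = 0
    while i < n:
        j = i
        while density[(j + 1) % n] == density[i] and j - i < n:
            j += 1
        left = density[(i - 1) % n]
        right = density[(j + 1) % n]
        if density[i] > left and density[i] > right and density[i] >= threshold:
            modes.append(float(grid[i]))
        i = j + 1
    return modes


def combined_csp(delta_h: float, delta_n: float, n_scale: float = 0.2) -> float:
    """Combined amide chemical-shift perturbation, sqrt(dH^2 + (a*dN)^2).

    The nitrogen scaling ``n_scale`` defaults to 0.2, a common literature
    convention for 1H/15N CSP comparisons (a convention of this package,
    not a value taken from any particular study); it is configurable.
    """
    return float(np.sqrt(float(delta_h) ** 2 + (n_scale * float(delta_n)) ** 2))
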