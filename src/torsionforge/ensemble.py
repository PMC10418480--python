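"""Scored structural ensembles and backbone dihedral extraction.

This module is the data layer of the package: it reads NMR-style
multi-model PDB files (one ``MODEL``/``ENDMDL`` block per conformer,
e.g. CS-Rosetta output), reads the accompanying score table (Rosetta
``.sc`` dialect or a plain two-column file), computes backbone torsion
angles and exposes everything as a :class:`ScoredEnsemble` — the
canonical in-memory dataset every downstream module consumes.

Angle conventions
-----------------
Torsions follow the IUPAC sign convention (clockwise positive looking
from the second to the third atom) and are wrapped to ``[-180, 180)``
degrees with ``+180`` mapped to ``-180``.  The backbone quadruplets are

* phi:   C(i-1) - N(i) - CA(i) - C(i)
* psi:   N(i)  - CA(i) - C(i)  - N(i+1)
* omega: CA(i) - C(i)  - N(i+1)- CA(i+1)

so phi is undefined for the first residue of a chain and psi/omega for
the last.  Omega is nearly constant for trans peptide bonds and is
computed only on request, for diagnostics; it is never turned into an
exportable potential.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C")

EXPORTABLE_KINDS = ("phi", "psi")
ANGLE_KINDS = ("phi", "psi", "omega")


class EnsembleError(ValueError):
    """Raised for malformed or inconsistent ensemble input."""


class GeometryError(ValueError):
    """Raised for degenerate atom geometry (collinear/zero-length bonds)."""


def wrap_angle(angle_deg):
    """Wrap angle(s) in degrees into ``[-180, 180)``; idempotent."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = np.mod(a + 180.0, 360.0) - 180.0
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class Atom:
    name: str
    resid: int          # 1-based residue index
    resname: str
    chain: str
    xyz: tuple[float, float, float]


@dataclass
class ModelRecord:
    """A single conformer of the ensemble."""

    model_id: int
    atoms: list[Atom]

    def __post_init__(self):
        self._index: dict[tuple[str, int, str], np.ndarray] = {}
        for a in self.atoms:
            key = (a.chain, a.resid, a.name)
            # first altloc wins; duplicates from altlocs are dropped
            self._index.setdefault(key, np.asarray(a.xyz, dtype=float))

    def coord(self, chain: str, resid: int, name: str) -> np.ndarray | None:
        return self._index.get((chain, resid, name))

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resid, resname) triples."""
        seen: dict[tuple[str, int], str] = {}
        order: list[tuple[str, int, str]] = []
        for a in self.atoms:
            key = (a.chain, a.resid)
            if key not in seen:
                seen[key] = a.resname
                order.append((a.chain, a.resid, a.resname))
        return order

    def coords_array(self, selection=None) -> np.ndarray:
        """(n_atoms, 3) array, optionally filtered by a predicate on Atom."""
        atoms = self.atoms if selection is None else [a for a in self.atoms if selection(a)]
        return np.array([a.xyz for a in atoms], dtype=float)


@dataclass
class ScoreTable:
    """Per-model total scores (Rosetta energy units; lower is better)."""

    entries: dict[str, float]

    def __post_init__(self):
        for mid, s in self.entries.items():
            if not np.isfinite(s):
                raise EnsembleError(f"non-finite score for model {mid!r}: {s}")

    def __len__(self) -> int:
        return len(self.entries)

    def scores_for(self, model_ids: Sequence) -> np.ndarray:
        out = []
        for mid in model_ids:
            key = str(mid)
            if key not in self.entries:
                raise EnsembleError(f"model {mid!r} has no score entry")
            out.append(self.entries[key])
        return np.asarray(out, dtype=float)


@dataclass
class DihedralSampleSet:
    """All observations of one (residue, angle kind) across the ensemble."""

    residue_index: int
    angle_kind: str
    angles_deg: np.ndarray
    model_ids: list
    chain: str = "A"
    exportable: bool = True

    def __post_init__(self):
        self.angles_deg = wrap_angle(np.asarray(self.angles_deg, dtype=float))
        if self.angle_kind not in ANGLE_KINDS:
            raise EnsembleError(f"unknown angle kind {self.angle_kind!r}")
        if len(self.angles_deg) != len(self.model_ids):
            raise EnsembleError("angles and model_ids length mismatch")
        if self.angle_kind == "omega":
            self.exportable = False

    def __len__(self) -> int:
        return len(self.angles_deg)


@dataclass
class ScoredEnsemble:
    """Models + scores + extracted dihedral samples; N is the ensemble size."""

    models: list[ModelRecord]
    scores: ScoreTable
    samples: list[DihedralSampleSet] = field(default_factory=list)

    def __post_init__(self):
        if self.scores is not None and len(self.models) != len(self.scores):
            raise EnsembleError(
                f"{len(self.models)} models but {len(self.scores)} scores"
            )

    @property
    def N(self) -> int:
        return len(self.models)

    def sample(self, residue_index: int, angle_kind: str) -> DihedralSampleSet:
        for s in self.samples:
            if s.residue_index == residue_index and s.angle_kind == angle_kind:
                return s
        raise KeyError((residue_index, angle_kind))

    @classmethod
    def from_files(cls, pdb_path, score_path=None, kinds=EXPORTABLE_KINDS,
                   top_fraction: float | None = None) -> "ScoredEnsemble":
        """Read a multi-model PDB plus score table and extract dihedrals.

        ``top_fraction`` keeps only the best-scoring fraction of models
        (by ascending score) before extraction; default uses all models.
        """
        models = read_ensemble(pdb_path)
        if score_path is not None:
            scores = read_scores(score_path)
        else:
            scores = ScoreTable({str(m.model_id): 0.0 for m in models})
        if top_fraction is not None:
            if not 0.0 < top_fraction <= 1.0:
                raise EnsembleError("top_fraction must be in (0, 1]")
            keep = max(1, int(round(top_fraction * len(models))))
            ranked = sorted(models, key=lambda m: scores.entries[str(m.model_id)])
            kept = ranked[:keep]
            kept_ids = {m.model_id for m in kept}
            models = [m for m in models if m.model_id in kept_ids]
            scores = ScoreTable({str(m.model_id): scores.entries[str(m.model_id)]
                                 for m in models})
        ens = cls(models=models, scores=scores)
        ens.samples = extract_dihedrals(models, kinds=kinds)
        return ens


# ---------------------------------------------------------------------------
# readers / writers

def _validate_pdb_text(path) -> None:
    """Cheap pre-pass: reject malformed ATOM records with a line number."""
    n_models = 0
    model_has_atoms = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if n_models and not model_has_atoms:
                    raise EnsembleError(
                        f"{path}: MODEL block ending before line {lineno} has no atoms"
                    )
                n_models += 1
                model_has_atoms = False
            elif rec == "ENDMDL":
                if not model_has_atoms:
                    raise EnsembleError(
                        f"{path}: line {lineno}: ENDMDL before any ATOM record"
                    )
            elif rec in ("ATOM", "HETATM"):
                model_has_atoms = True
                if len(line.rstrip("\n")) < 54:
                    raise EnsembleError(
                        f"{path}: line {lineno}: truncated ATOM record"
                    )
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError as exc:
                    raise EnsembleError(
                        f"{path}: line {lineno}: unparsable coordinates"
                    ) from exc
                if line[26] != " ":
                    raise EnsembleError(
                        f"{path}: line {lineno}: insertion codes are not supported"
                    )


def read_ensemble(path) -> list[ModelRecord]:
    """Read a multi-model PDB file into a list of :class:`ModelRecord`.

    A file without MODEL/ENDMDL keywords is treated as a single model.
    Only the first alternate location of each atom is kept.
    """
    path = Path(path)
    _validate_pdb_text(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("ensemble", str(path))
    records: list[ModelRecord] = []
    for model in structure:
        atoms: list[Atom] = []
        for chain in model:
            for residue in chain:
                het, resseq, icode = residue.id
                if het.strip():
                    continue  # waters/heteroatoms are not ensemble backbone
                for atom in residue:
                    pos = atom.get_coord()
                    atoms.append(Atom(
                        name=atom.get_name(),
                        resid=int(resseq),
                        resname=residue.get_resname(),
                        chain=chain.id if chain.id.strip() else "A",
                        xyz=(float(pos[0]), float(pos[1]), float(pos[2])),
                    ))
        if atoms:
            records.append(ModelRecord(model_id=int(model.id) + 1 if isinstance(model.id, int) else model.id,
                                       atoms=atoms))
    if not records:
        raise EnsembleError(f"{path}: no models with atoms found")
    return records


def write_ensemble(models: Iterable[ModelRecord], path) -> None:
    """Write models as a multi-model PDB (3-decimal coordinate precision)."""
    with open(path, "w") as fh:
        for model in models:
            fh.write(f"MODEL     {model.model_id:>4}\n")
            serial = 1
            for a in model.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3}"
                fh.write(
                    f"ATOM  {serial:>5} {name}{'':1}{a.resname:<3} {a.chain:1}"
                    f"{a.resid:>4}    "
                    f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          "
                    f"{a.name[0]:>2}\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_scores(path) -> ScoreTable:
    """Read a Rosetta ``.sc``-style score table.

    Accepts a whitespace-delimited table whose header names a total-score
    column (``total_score``, ``score`` or ``total``) and a model column
    (``description``, ``model`` or ``id``); a headerless two-column
    ``(model_id, score)`` file is accepted as a fallback.
    """
    path = Path(path)
    raw = [ln for ln in path.read_text().splitlines()
           if ln.strip() and not ln.startswith("#")]
    # Rosetta prepends "SCORE:" tags; strip them before tokenizing
    rows = [ln.removeprefix("SCORE:").split() for ln in raw]
    if not rows:
        raise EnsembleError(f"{path}: empty score table")

    header = [tok.lower() for tok in rows[0]]
    score_names = ("total_score", "score", "total")
    id_names = ("description", "model", "id", "model_id")
    score_col = next((header.index(n) for n in score_names if n in header), None)
    id_col = next((header.index(n) for n in id_names if n in header), None)

    if score_col is not None:
        if id_col is None:
            raise EnsembleError(f"{path}: header has a score column but no model column")
        data_rows = rows[1:]
    elif len(rows[0]) == 2:
        id_col, score_col = 0, 1
        data_rows = rows
        # tolerate a two-column header line
        try:
            float(rows[0][1])
        except ValueError:
            data_rows = rows[1:]
    else:
        raise EnsembleError(
            f"{path}: no recognizable score column (expected one of {score_names})"
        )
    if not data_rows:
        raise EnsembleError(f"{path}: score table has a header but no rows")

    entries: dict[str, float] = {}
    for row in data_rows:
        if len(row) <= max(score_col, id_col):
            raise EnsembleError(f"{path}: short row {row!r}")
        mid = row[id_col]
        try:
            s = float(row[score_col])
        except ValueError as exc:
            raise EnsembleError(f"{path}: non-numeric score {row[score_col]!r} "
                                f"for model {mid!r}") from exc
        if mid in entries:
            raise EnsembleError(f"{path}: duplicate model id {mid!r}")
        entries[mid] = s
    return ScoreTable(entries)


# ---------------------------------------------------------------------------
# torsion geometry

def compute_dihedral(p1, p2, p3, p4) -> float:
    """IUPAC-signed torsion angle of the chain p1-p2-p3-p4, in degrees.

    Returns a value in ``[-180, 180)``: an eclipsed (cis) arrangement
    gives 0 and an antiperiplanar (trans) one gives -180.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise GeometryError("zero-length bond vector in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear atoms: dihedral undefined")
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


_QUADRUPLETS = {
    # kind -> ((residue offset, atom name) x 4)
    "phi": ((-1, "C"), (0, "N"), (0, "CA"), (0, "C")),
    "psi": ((0, "N"), (0, "CA"), (0, "C"), (1, "N")),
    "omega": ((0, "CA"), (0, "C"), (1, "N"), (1, "CA")),
}


def extract_dihedrals(models: Sequence[ModelRecord],
                      kinds: Iterable[str] = EXPORTABLE_KINDS) -> list[DihedralSampleSet]:
    """Extract backbone dihedral sample sets across the ensemble.

    One :class:`DihedralSampleSet` is produced per (residue, kind) that is
    defined in at least one model.  Models missing a required backbone
    atom for a residue are skipped for that residue with a logged
    warning.  Omega sets are flagged non-exportable.
    """
    kinds = list(kinds)
    for k in kinds:
        if k not in ANGLE_KINDS:
            raise EnsembleError(f"unknown angle kind {k!r}")
    if not models:
        raise EnsembleError("empty ensemble")

    layout = models[0].residues()
    for m in models[1:]:
        other = m.residues()
        if len(other) != len(layout) or any(a != b for a, b in zip(layout, other)):
            first_bad = next(
                (a for a, b in zip(layout, other) if a != b),
                layout[min(len(layout), len(other)) - 1] if layout else None,
            )
            raise EnsembleError(
                f"inconsistent sequences across models; first mismatch at {first_bad}"
            )

    by_chain: dict[str, list[int]] = {}
    for chain, resid, _ in layout:
        by_chain.setdefault(chain, []).append(resid)

    out: list[DihedralSampleSet] = []
    for chain, resids in by_chain.items():
        resid_set = set(resids)
        for resid in resids:
            for kind in kinds:
                quad = _QUADRUPLETS[kind]
                needed = [(resid + off, name) for off, name in quad]
                if any(r not in resid_set for r, _ in needed):
                    continue  # chain terminus: angle not defined
                angles, mids = [], []
                for m in models:
                    pts = [m.coord(chain, r, name) for r, name in needed]
                    if any(p is None for p in pts):
                        logger.warning(
                            "model %s: residue %s%d missing backbone atom for %s; skipped",
                            m.model_id, chain, resid, kind,
                        )
                        continue
                    angles.append(compute_dihedral(*pts))
                    mids.append(m.model_id)
                if angles:
                    out.append(DihedralSampleSet(
                        residue_index=resid, angle_kind=kind,
                        angles_deg=np.asarray(angles), model_ids=mids,
                        chain=chain,
                    ))
    return out


def dihedral_table(ensemble: ScoredEnsemble) -> pd.DataFrame:
    """Long-format table of all dihedral samples with per-model scores."""
    rows = []
    for s in ensemble.samples:
        scores = ensemble.scores.scores_for(s.model_ids)
        for mid, ang, sc in zip(s.model_ids, s.angles_deg, scores):
            rows.append((s.residue_index, s.angle_kind, mid, ang, sc))
    return pd.DataFrame(
        rows, columns=["residue_index", "angle_kind", "model_id", "angle_deg", "score"]
    )


def write_dihedral_table(ensemble: ScoredEnsemble, path) -> None:
    dihedral_table(ensemble).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_dihedral_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
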