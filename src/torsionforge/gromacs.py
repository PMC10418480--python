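"""Export of torsion potentials as GROMACS tabulated dihedrals.

Two artifacts are produced:

* one three-column table file per (residue, angle kind) — angle in
  degrees from -180 to 180 inclusive, energy in kJ/mol, and the force
  -dE/d(alpha) in kJ/mol/rad — suitable as a tabulated bonded
  interaction;
* a patched topology in which every targeted backbone phi/psi proper
  dihedral (all multiplicity lines for the quadruplet) is replaced by a
  single tabulated-dihedral line (function type 8) referencing its
  table with unit scale factor.  Omega and improper dihedrals are never
  touched; the scaling already lives inside the tabulated energies.

The topology reader handles plain, include-expanded (pre-processed)
GROMACS topology text; preprocessor directives must be resolved by
``grompp -pp`` first and are rejected rather than passed through
silently.  Patches are recorded line-exactly, so applying the stored
"removed" record restores the original topology byte-identically.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pef import TorsionPEF

logger = logging.getLogger(__name__)

TABULATED_DIHEDRAL_FUNCT = 8
PROPER_DIHEDRAL_FUNCTS = {1, 3, 9}  # proper, Ryckaert-Bellemans, multi-proper
IMPROPER_DIHEDRAL_FUNCTS = {2, 4}


class ExportError(ValueError):
    """Raised for invalid table or topology export requests."""


class TopologyError(ValueError):
    """Raised for unsupported or inconsistent topology input."""


# ---------------------------------------------------------------------------
# dihedral table files

@dataclass
class DihedralTableFile:
    """One tabulated-dihedral file: (angle_deg, energy, minus dE/d(alpha))."""

    table_index: int
    residue_index: int
    angle_kind: str
    rows: np.ndarray  # (n, 3)
    filename: str

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 2 or rows.shape[1] != 3:
            raise ExportError("table rows must be (n, 3)")
        steps = np.diff(rows[:, 0])
        if not np.allclose(steps, steps[0], atol=1e-9):
            raise ExportError("table grid is not uniform")
        if abs(rows[0, 1] - rows[-1, 1]) > 1e-9 * max(1.0, abs(rows[0, 1])):
            raise ExportError("table energies are not periodic")
        self.rows = rows


def table_filename(index: int) -> str:
    return f"table_d{index}.xvg"


def write_dihedral_tables(pefs, out_dir, spacing: float = 1.0) -> list[DihedralTableFile]:
    """Write one table file per potential; deterministic index assignment.

    Tables are ordered by (residue index, angle kind) and numbered from
    0; the grid covers -180..180 inclusive at ``spacing`` degrees (which
    must divide 360 evenly).  Energies and forces are evaluated from the
    analytic closed form, so the two columns are mutually consistent to
    machine precision.
    """
    n = 360.0 / spacing
    if abs(n - round(n)) > 1e-9:
        raise ExportError(f"spacing {spacing} does not divide 360 evenly")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ordered = sorted(pefs, key=lambda p: (p.residue_index, p.angle_kind))
    grid = -180.0 + spacing * np.arange(int(round(n)) + 1)
    tables: list[DihedralTableFile] = []
    seen = set()
    for index, pef in enumerate(ordered):
        key = (pef.residue_index, pef.angle_kind)
        if key in seen:
            raise ExportError(f"duplicate potential for {key}; index clash")
        seen.add(key)
        energy = pef.energy_at(grid)
        force = pef.force_at(grid)
        energy[-1] = energy[0]  # exact periodic closure of the wrap point
        force[-1] = force[0]
        rows = np.column_stack([grid, energy, force])
        fname = table_filename(index)
        _write_table(rows, out_dir / fname)
        tables.append(DihedralTableFile(
            table_index=index, residue_index=pef.residue_index,
            angle_kind=pef.angle_kind, rows=rows, filename=fname,
        ))
    return tables


def _write_table(rows: np.ndarray, path: Path) -> None:
    with open(path, "w") as fh:
        for angle, energy, force in rows:
            fh.write(f"{angle:12.4f} {energy:20.12e} {force:20.12e}\n")


def read_dihedral_table(path) -> np.ndarray:
    return np.loadtxt(path)


# ---------------------------------------------------------------------------
# topology model

@dataclass
class TopologyAtom:
    index: int       # 1-based topology atom index
    name: str
    resnr: int
    resname: str


@dataclass
class Topology:
    """Light structural view over pre-processed GROMACS topology text."""

    lines: list[str]
    atoms: list[TopologyAtom]
    # (line number, (ai, aj, ak, al), funct) for every dihedral line
    dihedral_lines: list[tuple[int, tuple[int, int, int, int], int]]
    dihedrals_section_end: int  # line index after the last propers line

    @classmethod
    def parse(cls, text: str) -> "Topology":
        lines = text.splitlines(keepends=True)
        atoms: list[TopologyAtom] = []
        dihedral_lines: list[tuple[int, tuple[int, int, int, int], int]] = []
        section = None
        last_dihedral_line = -1
        for i, raw in enumerate(lines):
            stripped = raw.split(";", 1)[0].strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                raise TopologyError(
                    f"line {i + 1}: preprocessor directive {stripped.split()[0]!r} "
                    "not supported; run the topology through the engine "
                    "preprocessor (grompp -pp) first"
                )
            if stripped.startswith("["):
                section = stripped.strip("[] ").lower()
                continue
            if section == "atoms":
                tok = stripped.split()
                if len(tok) < 5:
                    raise TopologyError(f"line {i + 1}: short [ atoms ] entry")
                atoms.append(TopologyAtom(
                    index=int(tok[0]), name=tok[4],
                    resnr=int(tok[2]), resname=tok[3],
                ))
            elif section == "dihedrals":
                tok = stripped.split()
                if len(tok) < 5:
                    raise TopologyError(f"line {i + 1}: short [ dihedrals ] entry")
                quad = tuple(int(t) for t in tok[:4])
                funct = int(tok[4])
                dihedral_lines.append((i, quad, funct))
                last_dihedral_line = i
        if not atoms:
            raise TopologyError("no [ atoms ] section found")
        return cls(lines=lines, atoms=atoms, dihedral_lines=dihedral_lines,
                   dihedrals_section_end=last_dihedral_line + 1)

    @classmethod
    def from_file(cls, path) -> "Topology":
        return cls.parse(Path(path).read_text())

    def text(self) -> str:
        return "".join(self.lines)


def identify_backbone_quadruplets(topology: Topology) -> dict[int, dict[str, tuple[int, int, int, int]]]:
    """Map residue number -> backbone phi/psi atom-index quadruplets.

    phi(i) = C(i-1), N(i), CA(i), C(i); psi(i) = N(i), CA(i), C(i), N(i+1).
    Terminal residues lacking an angle are omitted; angles spanning a
    residue-numbering break are omitted with a warning.
    """
    backbone: dict[int, dict[str, int]] = {}
    for a in topology.atoms:
        if a.name in ("N", "CA", "C"):
            slot = backbone.setdefault(a.resnr, {})
            if a.name not in slot:
                slot[a.name] = a.index
    resnrs = sorted(backbone)
    for r in resnrs:
        missing = [n for n in ("N", "CA", "C") if n not in backbone[r]]
        if missing:
            raise TopologyError(f"residue {r}: missing backbone atom(s) {missing}")

    out: dict[int, dict[str, tuple[int, int, int, int]]] = {}
    present = set(resnrs)
    for r in resnrs:
        entry: dict[str, tuple[int, int, int, int]] = {}
        if r - 1 in present:
            entry["phi"] = (backbone[r - 1]["C"], backbone[r]["N"],
                            backbone[r]["CA"], backbone[r]["C"])
        elif r != resnrs[0]:
            warnings.warn(f"chain break before residue {r}: phi omitted")
        if r + 1 in present:
            entry["psi"] = (backbone[r]["N"], backbone[r]["CA"],
                            backbone[r]["C"], backbone[r + 1]["N"])
        elif r != resnrs[-1]:
            warnings.warn(f"chain break after residue {r}: psi omitted")
        if entry:
            out[r] = entry
    return out


# ---------------------------------------------------------------------------
# topology patching

@dataclass
class TopologyPatch:
    """Record of a topology patch: removed proper lines, added tabulated lines.

    ``removed`` holds (original line number (0-based), verbatim line text);
    ``added`` holds the verbatim tabulated-dihedral lines inserted.  The
    original topology is reconstructed exactly by dropping the added
    lines and re-inserting the removed ones at their recorded positions.
    """

    removed: list[tuple[int, str]] = field(default_factory=list)
    added: list[str] = field(default_factory=list)
    mapping: list[dict] = field(default_factory=list)  # quadruplet/table bookkeeping

    def to_json(self) -> str:
        return json.dumps({
            "removed": [[i, t] for i, t in self.removed],
            "added": list(self.added),
            "mapping": self.mapping,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TopologyPatch":
        d = json.loads(text)
        return cls(removed=[(int(i), t) for i, t in d["removed"]],
                   added=list(d["added"]), mapping=list(d["mapping"]))


def patch_topology(topology: Topology, tables: list[DihedralTableFile],
                   quadruplets: dict[int, dict[str, tuple[int, int, int, int]]],
                   ) -> tuple[str, TopologyPatch]:
    """Replace targeted backbone propers with tabulated dihedral terms.

    Every proper-dihedral line (any multiplicity) whose atom quadruplet
    matches a targeted phi/psi — in either direction — is removed, and a
    single ``funct 8`` line referencing the matching table (scale 1.0)
    is appended to the propers section.  Quadruplets already carrying
    our tabulated term are skipped with a warning (idempotency); a
    quadruplet found in no proper line is an error, because silently
    adding a term on top of force-field propers would double-count.
    """
    by_key = {(t.residue_index, t.angle_kind): t for t in tables}
    targets: dict[tuple[int, int, int, int], DihedralTableFile] = {}
    for resid, kinds in quadruplets.items():
        for kind, quad in kinds.items():
            table = by_key.get((resid, kind))
            if table is None:
                raise ExportError(f"no table provided for residue {resid} {kind}")
            targets[tuple(quad)] = table

    def canon(q):
        return min(tuple(q), tuple(reversed(q)))

    canon_targets = {canon(q): (q, t) for q, t in targets.items()}

    remove_idx: list[int] = []
    already_patched: set[tuple] = set()
    matched: set[tuple] = set()
    for line_no, quad, funct in topology.dihedral_lines:
        cq = canon(quad)
        if cq not in canon_targets:
            continue
        if funct == TABULATED_DIHEDRAL_FUNCT:
            already_patched.add(cq)
        elif funct in PROPER_DIHEDRAL_FUNCTS:
            remove_idx.append(line_no)
            matched.add(cq)
        # impropers sharing atoms are left untouched

    missing = [canon_targets[cq][0] for cq in canon_targets
               if cq not in matched and cq not in already_patched]
    if missing:
        raise TopologyError(
            f"quadruplet(s) {missing} not found among proper dihedrals; "
            "refusing to add tabulated terms on top of unknown parametrization"
        )
    if already_patched:
        warnings.warn(
            f"{len(already_patched)} quadruplet(s) already use tabulated "
            "dihedrals; skipped (patch is idempotent)"
        )

    patch = TopologyPatch()
    for i in sorted(remove_idx):
        patch.removed.append((i, topology.lines[i]))

    added_lines: list[str] = []
    for cq in sorted(canon_targets):
        if cq in already_patched or cq not in matched:
            continue
        quad, table = canon_targets[cq]
        line = (f"{quad[0]:6d} {quad[1]:6d} {quad[2]:6d} {quad[3]:6d} "
                f"{TABULATED_DIHEDRAL_FUNCT:5d} {table.table_index:5d} "
                f"{1.0:8.3f}\n")
        added_lines.append(line)
        patch.mapping.append({
            "residue_index": table.residue_index,
            "angle_kind": table.angle_kind,
            "quadruplet": list(quad),
            "table_index": table.table_index,
            "table_file": table.filename,
            "scale": 1.0,
        })
    patch.added = added_lines

    keep = set(remove_idx)
    new_lines: list[str] = []
    insert_at = topology.dihedrals_section_end
    for i, line in enumerate(topology.lines):
        if i == insert_at:
            new_lines.extend(added_lines)
        if i in keep:
            continue
        new_lines.append(line)
    if insert_at >= len(topology.lines):
        new_lines.extend(added_lines)
    return "".join(new_lines), patch


def unpatch_topology(patched_text: str, patch: TopologyPatch) -> str:
    """Invert :func:`patch_topology` using the stored patch record."""
    lines = patched_text.splitlines(keepends=True)
    remaining = list(patch.added)
    kept: list[str] = []
    for line in lines:
        if line in remaining:
            remaining.remove(line)
            continue
        kept.append(line)
    if remaining:
        raise TopologyError("patched topology does not contain all added lines")
    for idx, text in sorted(patch.removed):
        kept.insert(idx, text)
    return "".join(kept)
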