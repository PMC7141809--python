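"""Shared data model: atomic structures, density volumes, sigma scaling, selections.

Coordinates are Å in a right-handed world frame.  For volumes the world
position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * voxel_size``; the
origin comes from the MRC ORIGIN record when any component is nonzero,
otherwise from the NXSTART/NYSTART/NZSTART offsets times the voxel size.
"""

from __future__ import annotations

import ast
import copy
import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "DensityMap",
    "RecordClass",
    "Structure",
    "StructureError",
    "MapError",
    "SelectionError",
    "DegenerateMapError",
    "read_structure",
    "write_structure",
    "read_map",
    "write_map",
    "sigma_scale",
    "select_atoms",
]


class StructureError(ValueError):
    """Unparseable or empty coordinate file."""


class MapError(ValueError):
    """Unsupported or malformed density volume."""


class DegenerateMapError(MapError):
    """Volume with zero standard deviation cannot be sigma-scaled."""


class SelectionError(ValueError):
    """Malformed atom-selection expression."""


class RecordClass(str, enum.Enum):
    PROTEIN = "protein"
    ION = "ion"
    WATER = "water"
    OTHER = "other"


_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
_WATERS = {"HOH", "WAT", "DOD", "H2O"}
_IONS = {"K", "CS", "NA", "LI", "RB", "MG", "CA", "ZN", "CL", "BR", "IOD", "MN", "FE"}

_ELEMENTS = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "MN", "FE", "CO", "NI", "CU",
    "ZN", "SE", "BR", "RB", "MO", "I", "CS", "BA", "W", "PT", "AU", "HG",
}


def classify_residue(residue_name: str) -> RecordClass:
    """Record class from the residue name via a fixed lookup table."""
    name = residue_name.strip().upper()
    if name in _WATERS:
        return RecordClass.WATER
    if name in _IONS:
        return RecordClass.ION
    if name in _AMINO_ACIDS:
        return RecordClass.PROTEIN
    return RecordClass.OTHER


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``position`` is Å in the world frame; ``record_class`` is derived from
    the residue name (HOH -> water, K/CS/NA -> ion, amino acids -> protein).
    """

    element: str
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    record_class: RecordClass = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.atom_name}: non-finite or non-3D position")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")
        if self.element.upper() not in _ELEMENTS:
            raise StructureError(f"atom {self.atom_name}: unknown element {self.element!r}")
        if self.record_class is None:
            object.__setattr__(self, "record_class", classify_residue(self.residue_name))

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class Structure:
    """Ordered atom collection with condition and repeat-domain annotations.

    ``repeat_annotations`` maps ``(chain_id, first_residue, last_residue)``
    ranges to repeat labels (``"repeatI"`` / ``"repeatII"``); ranges must not
    overlap within a chain.
    """

    atoms: list[Atom]
    label: str = ""
    condition: str = "synthetic"
    repeat_annotations: dict[tuple[str, int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("empty structure")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int, str]] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise StructureError(f"duplicate atom key {dup}")
        ranges: dict[str, list[tuple[int, int]]] = {}
        for (chain, lo, hi) in self.repeat_annotations:
            ranges.setdefault(chain, []).append((lo, hi))
        for chain, rs in ranges.items():
            rs.sort()
            for (a_lo, a_hi), (b_lo, b_hi) in zip(rs, rs[1:]):
                if b_lo <= a_hi:
                    raise StructureError(f"overlapping repeat ranges on chain {chain}")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(N, 3) array of positions in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def subset(self, atoms: Sequence[Atom], label: str | None = None) -> "Structure":
        return Structure(
            atoms=list(atoms),
            label=self.label if label is None else label,
            condition=self.condition,
            repeat_annotations=dict(self.repeat_annotations),
        )


@dataclass
class DensityMap:
    """3D scalar volume with voxel geometry and scaling statistics.

    ``grid[i, j, k]`` sits at world position ``origin + (i, j, k) * voxel_size``.
    After :func:`sigma_scale` the values are in sigma units (mean 0, sd 1) and
    the raw statistics are retained in ``raw_mean`` / ``raw_sd``.
    """

    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    sigma_scaled: bool = False
    raw_mean: float | None = None
    raw_sd: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise MapError(f"grid must be 3D, got {self.grid.ndim}D")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise MapError("voxel sizes must be three positive lengths")
        if self.origin.shape != (3,):
            raise MapError("origin must be a 3-vector")

    @property
    def mean(self) -> float:
        return float(self.grid.mean())

    @property
    def sd(self) -> float:
        return float(self.grid.std())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates of the given (M, 3) integer voxel indices."""
        return self.origin + np.asarray(indices, dtype=float) * self.voxel_size

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of (M, 3) world points."""
        return (np.asarray(points, dtype=float) - self.origin) / self.voxel_size

    def copy(self) -> "DensityMap":
        return DensityMap(
            grid=self.grid.copy(),
            voxel_size=self.voxel_size.copy(),
            origin=self.origin.copy(),
            sigma_scaled=self.sigma_scaled,
            raw_mean=self.raw_mean,
            raw_sd=self.raw_sd,
        )


# ---------------------------------------------------------------------------
# Coordinate I/O (gemmi-backed)

def _structure_from_gemmi(st: gemmi.Structure, label: str, condition: str) -> Structure:
    atoms: list[Atom] = []
    best_occ: dict[tuple[str, int, str], int] = {}
    if len(st) == 0:
        raise StructureError(f"{st.name or 'structure'}: no models")
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                el = atom.element.name.upper() if atom.element else "C"
                if el not in _ELEMENTS:
                    el = "C"
                key = (chain.name, residue.seqid.num, atom.name)
                rec = Atom(
                    element=el,
                    atom_name=atom.name,
                    residue_name=residue.name,
                    residue_number=residue.seqid.num,
                    chain_id=chain.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    b_factor=atom.b_iso,
                )
                if key in best_occ:
                    # altloc: keep the highest-occupancy conformer
                    if rec.occupancy > atoms[best_occ[key]].occupancy:
                        atoms[best_occ[key]] = rec
                else:
                    best_occ[key] = len(atoms)
                    atoms.append(rec)
    if not atoms:
        raise StructureError(f"{st.name or 'structure'}: model contains no atoms")
    return Structure(atoms=atoms, label=label, condition=condition)


def read_structure(path: str | Path, format: str = "auto", *,
                   label: str | None = None, condition: str = "synthetic") -> Structure:
    """Read a PDB or mmCIF coordinate file into a :class:`Structure`.

    Parameters
    ----------
    path:
        Coordinate file.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (extension-based detection).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise ValueError(f"format must be pdb, mmcif or auto, got {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: cannot parse coordinate file: {exc}") from exc
    st.setup_entities()
    return _structure_from_gemmi(st, label=label or path.stem, condition=condition)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` to PDB (``.pdb``) or mmCIF (``.cif``)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = structure.label or "model"
    model = gemmi.Model("1")
    # gemmi's add_* methods copy, so group first and assemble bottom-up
    by_chain: dict[str, dict[tuple[int, str], list[Atom]]] = {}
    for a in structure.atoms:
        by_chain.setdefault(a.chain_id, {}).setdefault(
            (a.residue_number, a.residue_name), []).append(a)
    for chain_id, residues in by_chain.items():
        chain = gemmi.Chain(chain_id)
        for (resnum, resname), members in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = ("A" if members[0].record_class is RecordClass.PROTEIN
                            else "H")
            for a in members:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element.capitalize())
                at.pos = gemmi.Position(*a.position)
                at.occ = a.occupancy
                at.b_iso = a.b_factor
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if path.suffix.lower() in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Volume I/O (MRC/CCP4 2014 dialect via gemmi)

def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 volume.

    Axis order is normalised to x-fastest storage indexed ``grid[ix, iy, iz]``.
    Requires an orthogonal cell and data mode 0, 1 or 2.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cc = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapError(f"{path}: cannot parse MRC/CCP4 file: {exc}") from exc
    mode = cc.header_i32(4)
    if mode not in (0, 1, 2):
        raise MapError(f"{path}: unsupported MRC data mode {mode}")
    cell = cc.grid.unit_cell
    if not (np.isclose(cell.alpha, 90) and np.isclose(cell.beta, 90) and np.isclose(cell.gamma, 90)):
        raise MapError(f"{path}: non-orthogonal cell ({cell.alpha}, {cell.beta}, {cell.gamma})")
    origin_rec = np.array([cc.header_float(i) for i in (50, 51, 52)])
    nstart = np.array([cc.header_i32(i) for i in (5, 6, 7)], dtype=float)
    cc.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = np.array(cc.grid, copy=True, dtype=np.float64)
    n = np.array(grid.shape, dtype=float)
    voxel = np.array([cell.a, cell.b, cell.c]) / n
    origin = origin_rec if np.any(origin_rec != 0) else nstart * voxel
    return DensityMap(grid=grid, voxel_size=voxel, origin=origin)


def write_map(density: DensityMap, path: str | Path) -> None:
    """Write a volume as MRC mode 2 with the origin in the ORIGIN record."""
    path = Path(path)
    cc = gemmi.Ccp4Map()
    cc.grid = gemmi.FloatGrid(np.ascontiguousarray(density.grid, dtype=np.float32))
    nx, ny, nz = density.grid.shape
    vx, vy, vz = density.voxel_size
    cc.grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90, 90, 90)
    cc.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    cc.update_ccp4_header()
    for word, value in zip((50, 51, 52), density.origin):
        cc.set_header_float(word, float(value))
    cc.write_ccp4_map(str(path))


def sigma_scale(density: DensityMap) -> DensityMap:
    """Standardise a volume to sigma units: (value - mean) / sd over the full grid.

    Idempotent; raw statistics are preserved in ``raw_mean`` / ``raw_sd``.
    Raises :class:`DegenerateMapError` for a constant volume.
    """
    if density.sigma_scaled:
        return density.copy()
    mean = density.mean
    sd = density.sd
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateMapError("volume has zero standard deviation; cannot sigma-scale")
    out = density.copy()
    out.grid = (density.grid - mean) / sd
    out.sigma_scaled = True
    out.raw_mean = mean
    out.raw_sd = sd
    return out


# ---------------------------------------------------------------------------
# Atom selections
#
# Selections are boolean expressions over per-atom fields:
#   chain, resname, resnum, name, element, record_class, occupancy, b_factor
# with comparisons (== != < <= > >=, chained), membership (`in`), boolean
# operators (and/or/not) and parentheses.  The literal `true` selects all
# atoms.  Examples:
#   "record_class == 'water'"
#   "chain == 'A' and 30 <= resnum <= 173"
#   "name in ('CA', 'CB') and element == 'C'"

_ALLOWED_NODES = (
    ast.Expression, ast.BoolOp, ast.UnaryOp, ast.Compare, ast.Name, ast.Load,
    ast.Constant, ast.And, ast.Or, ast.Not, ast.Eq, ast.NotEq, ast.Lt,
    ast.LtE, ast.Gt, ast.GtE, ast.In, ast.NotIn, ast.Tuple, ast.List,
    ast.USub,
)
_FIELDS = {"chain", "resname", "resnum", "name", "element", "record_class",
           "occupancy", "b_factor"}


def _compile_predicate(expression: str) -> Callable[[Atom], bool]:
    text = expression.strip()
    if text.lower() in {"true", "all", "*"}:
        return lambda atom: True
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise SelectionError(f"cannot parse selection {expression!r}: {exc}") from exc
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise SelectionError(
                f"selection {expression!r}: construct {type(node).__name__} not allowed")
        if isinstance(node, ast.Name) and node.id not in _FIELDS:
            raise SelectionError(
                f"selection {expression!r}: unknown field {node.id!r} "
                f"(known: {', '.join(sorted(_FIELDS))})")
    code = compile(tree, "<selection>", "eval")

    def predicate(atom: Atom) -> bool:
        namespace = {
            "chain": atom.chain_id,
            "resname": atom.residue_name,
            "resnum": atom.residue_number,
            "name": atom.atom_name,
            "element": atom.element,
            "record_class": atom.record_class.value,
            "occupancy": atom.occupancy,
            "b_factor": atom.b_factor,
        }
        return bool(eval(code, {"__builtins__": {}}, namespace))

    return predicate


def select_atoms(structure: Structure, predicate: str | Callable[[Atom], bool]) -> Structure:
    """Subset of ``structure`` matching the selection, order preserved.

    ``predicate`` is either a selection expression string (see module docs)
    or a callable ``Atom -> bool``.  An empty selection is allowed and
    yields a structure-like object with zero atoms.
    """
    fn = _compile_predicate(predicate) if isinstance(predicate, str) else predicate
    try:
        chosen = [a for a in structure.atoms if fn(a)]
    except (TypeError, NameError) as exc:
        raise SelectionError(f"selection failed: {exc}") from exc
    if not chosen:
        # bypass the non-empty invariant for legitimate empty selections
        empty = copy.copy(structure)
        empty.atoms = []
        return empty
    return structure.subset(chosen)
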