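"""Core containers and file I/O for models and density maps.

Structure files (PDB / mmCIF) and density maps (MRC / CCP4 mode 2) are read
and written through :mod:`gemmi`.  The in-memory containers are deliberately
small: a :class:`Model` is one protein chain with per-residue confidence
(plDDT semantics, carried in the B-value column of structure files), a
:class:`DensityMap` is a 3-D scalar grid with voxel size and origin, and a
:class:`Transform` is a proper rigid-body motion.

Conventions used throughout the package:

* residue intervals are half-open ``[start, stop)`` over 0-based positions
  in the chain; the author-assigned ``residue_number`` is kept separately
  as a label and never used for indexing;
* hydrogens are dropped on input;
* only orthogonal (90/90/90) cells are supported for maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Model",
    "DensityMap",
    "Transform",
    "FormatError",
    "EmptyModelError",
    "load_structure",
    "load_structures",
    "save_structure",
    "load_map",
    "backbone_from_ca",
    "save_map",
]


class FormatError(ValueError):
    """A file could not be parsed in the requested format."""


class EmptyModelError(ValueError):
    """An operation received or produced a model with no usable residues."""


# Electron counts for the elements that occur in backbone-level models.
ELECTRON_COUNTS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SE": 34, "FE": 26,
    "MG": 12, "ZN": 30, "CA": 20, "MN": 25, "NA": 11, "K": 19, "CL": 17,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Å
    b_value: float = 0.0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: bad coordinates {self.xyz}")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.xyz.copy(), self.b_value)


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def copy(self) -> "Residue":
        return Residue(self.number, self.name, [a.copy() for a in self.atoms])


class Model:
    """One protein chain: ordered residues plus per-residue confidence.

    ``confidence`` mirrors the B-value column on input (plDDT values for
    predicted models); rescaling to the 0-100 convention is done explicitly
    by :func:`foldfit.confidence_domains.normalize_confidence`.
    """

    def __init__(self, chain_id: str, residues: Sequence[Residue],
                 confidence: Sequence[float] | None = None):
        self.chain_id = chain_id
        self.residues = list(residues)
        nums = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("residue numbers must be strictly increasing")
        if confidence is None:
            confidence = [r.ca.b_value if r.ca is not None else 0.0
                          for r in self.residues]
        self.confidence = np.asarray(confidence, dtype=float)
        if len(self.confidence) != len(self.residues):
            raise ValueError("confidence length != residue count")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.array([r.number for r in self.residues], dtype=int)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of CA coordinates; NaN rows for CA-less residues."""
        out = np.full((len(self), 3), np.nan)
        for i, r in enumerate(self.residues):
            if r.ca is not None:
                out[i] = r.ca.xyz
        return out

    def all_atoms(self) -> list[tuple[int, Atom]]:
        """Flat list of (residue position, atom)."""
        return [(i, a) for i, r in enumerate(self.residues) for a in r.atoms]

    def atom_coords(self) -> np.ndarray:
        return np.array([a.xyz for _, a in self.all_atoms()], dtype=float)

    def set_atom_coords(self, coords: np.ndarray) -> None:
        flat = self.all_atoms()
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(flat), 3):
            raise ValueError("coordinate array shape mismatch")
        for (_, a), xyz in zip(flat, coords):
            a.xyz = np.array(xyz, dtype=float)

    def set_ca_coords(self, coords: np.ndarray) -> None:
        for r, xyz in zip(self.residues, np.asarray(coords, dtype=float)):
            if r.ca is not None:
                r.ca.xyz = np.array(xyz, dtype=float)

    def elements(self) -> list[str]:
        return [a.element for _, a in self.all_atoms()]

    def copy(self) -> "Model":
        return Model(self.chain_id, [r.copy() for r in self.residues],
                     self.confidence.copy())

    def subset(self, positions: Iterable[int]) -> "Model":
        """New model containing the residues at the given 0-based positions."""
        pos = sorted(set(int(p) for p in positions))
        if not pos:
            raise EmptyModelError("subset of zero residues")
        return Model(self.chain_id, [self.residues[p].copy() for p in pos],
                     self.confidence[pos])

    def transformed(self, transform: "Transform") -> "Model":
        m = self.copy()
        m.set_atom_coords(transform.apply(m.atom_coords()))
        return m

    def position_of_number(self, number: int) -> int:
        nums = self.residue_numbers
        idx = np.nonzero(nums == number)[0]
        if len(idx) == 0:
            raise KeyError(f"residue number {number} not in chain")
        return int(idx[0])


@dataclass
class Transform:
    """Proper rigid-body transform: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("transform shape mismatch")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1")

    @staticmethod
    def identity() -> "Transform":
        return Transform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)

    def is_close(self, other: "Transform", points: np.ndarray,
                 tol: float) -> bool:
        """Whether the two transforms move ``points`` within ``tol`` r.m.s."""
        d = self.apply(points) - other.apply(points)
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1)))) <= tol


@dataclass
class DensityMap:
    """Orthogonal-cell 3-D density grid.

    ``grid[i, j, k]`` is the value at Cartesian position
    ``origin + (i, j, k) * voxel_size``.
    """

    grid: np.ndarray
    voxel_size: np.ndarray  # Å per step along (x, y, z)
    origin: np.ndarray      # Å position of grid index (0, 0, 0)
    resolution_hint: float | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3-D with all dimensions >= 2")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower corner, upper corner) in Å."""
        upper = self.origin + (np.array(self.shape) - 1) * self.voxel_size
        return self.origin.copy(), upper

    def to_fractional_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.voxel_size

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size.copy(),
                          self.origin.copy(), self.resolution_hint)

    def like(self, grid: np.ndarray) -> "DensityMap":
        """New map with the same geometry but different values."""
        return DensityMap(np.asarray(grid, dtype=np.float32),
                          self.voxel_size.copy(), self.origin.copy(),
                          self.resolution_hint)


def backbone_from_ca(ca: np.ndarray) -> list[list[Atom]]:
    """Approximate N, CA, C, O positions from a CA trace.

    Offsets are built from the local chain frame; the geometry is
    deterministic and close to canonical bond lengths, which is all that
    density synthesis and refinement need.
    """
    n = len(ca)
    atoms_per_res = []
    for i in range(n):
        prev = ca[i - 1] if i > 0 else 2 * ca[0] - ca[min(1, n - 1)]
        nxt = ca[i + 1] if i < n - 1 else 2 * ca[-1] - ca[max(n - 2, 0)]
        e_prev = prev - ca[i]
        e_next = nxt - ca[i]
        for v in (e_prev, e_next):
            nv = np.linalg.norm(v)
            if nv < 1e-6:
                v[:] = (1.0, 0.0, 0.0)
        e_prev = e_prev / np.linalg.norm(e_prev)
        e_next = e_next / np.linalg.norm(e_next)
        perp = np.cross(e_prev, e_next)
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(e_prev, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(e_prev, [0.0, 1.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        nd = e_prev + 0.4 * perp
        cd = e_next + 0.4 * perp
        nd = nd / np.linalg.norm(nd)
        cd = cd / np.linalg.norm(cd)
        n_xyz = ca[i] + 1.46 * nd
        c_xyz = ca[i] + 1.52 * cd
        od = perp + 0.4 * e_next
        od = od / np.linalg.norm(od)
        o_xyz = c_xyz + 1.23 * od
        atoms_per_res.append([
            Atom("N", "N", n_xyz),
            Atom("CA", "C", ca[i].copy()),
            Atom("C", "C", c_xyz),
            Atom("O", "O", o_xyz),
        ])
    return atoms_per_res


# ---------------------------------------------------------------------------
# structure I/O


def _detect_format(path: str | Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # sniff: mmCIF files start with 'data_'
    with open(path, "r", errors="replace") as fh:
        head = fh.read(64)
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def _read_gemmi(path: str | Path, fmt: str) -> gemmi.Structure:
    fmt = _detect_format(path, fmt)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise FormatError(f"unknown structure format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return st


def _chain_to_model(chain: gemmi.Chain) -> Model | None:
    residues: list[Residue] = []
    last_num = None
    for gres in chain:
        atoms = []
        for ga in gres:
            el = ga.element.name.upper()
            if el == "H" or el == "D":
                continue
            atoms.append(Atom(ga.name, el,
                              np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                              float(ga.b_iso)))
        if not atoms:
            continue
        num = gres.seqid.num
        if last_num is not None and num <= last_num:
            continue  # altloc / insertion duplicates: keep first occurrence
        residues.append(Residue(num, gres.name, atoms))
        last_num = num
    if not residues:
        return None
    if not any(r.ca is not None for r in residues):
        return None
    return Model(chain.name, residues)


def load_structures(path: str | Path, format: str = "auto") -> list[Model]:
    """Load every polymer chain in a structure file, one :class:`Model` each."""
    st = _read_gemmi(path, format)
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    models = []
    for chain in st[0]:
        m = _chain_to_model(chain)
        if m is not None:
            models.append(m)
    if not models:
        raise EmptyModelError(f"{path}: no chain with CA atoms")
    return models


def load_structure(path: str | Path, format: str = "auto",
                   chain_id: str | None = None) -> Model:
    """Load one chain (the first, or the one named ``chain_id``)."""
    models = load_structures(path, format)
    if chain_id is None:
        return models[0]
    for m in models:
        if m.chain_id == chain_id:
            return m
    raise KeyError(f"chain {chain_id!r} not found in {path}")


def save_structure(model: Model | Sequence[Model], path: str | Path,
                   format: str = "auto") -> None:
    """Write one or more chains to PDB or mmCIF.

    The per-residue ``confidence`` value is written into the B-value column
    of every atom of the residue, preserving the plDDT-in-B convention of
    predicted models.
    """
    models = [model] if isinstance(model, Model) else list(model)
    if not models or any(len(m) == 0 for m in models):
        raise EmptyModelError("cannot save an empty model")
    fmt = _detect_format(path, format)
    st = gemmi.Structure()
    st.name = Path(path).stem
    gm = gemmi.Model("1")
    for m in models:
        ch = gemmi.Chain(m.chain_id)
        for res, conf in zip(m.residues, m.confidence):
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(int(res.number), " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element.capitalize())
                ga.pos = gemmi.Position(*a.xyz)
                ga.b_iso = float(conf)
                ga.occ = 1.0
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# map I/O
#
# Origin convention: if the ORIGIN header record (words 50-52) is nonzero it
# wins; otherwise the origin is NSTART * voxel.  The same convention is
# applied on write (ORIGIN record set, NSTART zeroed).


def load_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 map; axes are normalised to (x, y, z) order."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    # NSTART is consumed by setup(); capture it first, permuted to x,y,z
    # via the MAPC/MAPR/MAPS axis assignment
    nstart_crs = [ccp4.header_i32(w) for w in (5, 6, 7)]
    axis_map = [ccp4.header_i32(w) for w in (17, 18, 19)]  # 1=x, 2=y, 3=z
    nstart = np.zeros(3, dtype=int)
    for crs_axis, cell_axis in enumerate(axis_map):
        nstart[cell_axis - 1] = nstart_crs[crs_axis]
    ccp4.setup(float("nan"))  # reorders axes to X, Y, Z and fills gaps
    cell = ccp4.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise ValueError(f"{path}: non-orthogonal cell not supported "
                         f"({cell.alpha}, {cell.beta}, {cell.gamma})")
    grid = np.array(ccp4.grid, copy=True)
    if np.any(np.isnan(grid)):
        grid = np.nan_to_num(grid, nan=float(np.nanmin(grid)))
    shape = np.array(grid.shape)
    voxel = np.array([cell.a, cell.b, cell.c]) / shape
    header_origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    if np.any(header_origin != 0.0):
        origin = header_origin
    else:
        origin = nstart * voxel
    return DensityMap(grid, voxel, origin)


def save_map(density_map: DensityMap, path: str | Path) -> None:
    """Write a map as MRC mode 2 (32-bit float)."""
    dm = density_map
    grid = gemmi.FloatGrid(np.ascontiguousarray(dm.grid, dtype=np.float32))
    a, b, c = np.array(dm.shape) * dm.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), dm.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))
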