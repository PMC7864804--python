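"""Density-map and coordinate-model containers with I/O, interpolation and masking.

Everything downstream (fit-to-map scoring, geometry validation, model
comparison) works on two in-memory objects defined here:

:class:`DensityMap`
    A voxel grid with physical geometry.  Values are stored x-fastest with
    0-based indices, so the Cartesian position of voxel ``(i, j, k)`` is
    ``origin + (i, j, k) * voxel_size``.  All physical quantities are in Å.

:class:`AtomicModel`
    A chain/residue/atom hierarchy with occupancies and isotropic B factors.

Maps are read and written as MRC/CCP4 2014 files (modes 0/1/2) and models as
PDB or mmCIF, both through :mod:`gemmi`.  Maps are never resampled
implicitly: combining two grids with different geometry raises
:class:`GridMismatchError` rather than silently regridding, because a silent
regrid corrupts every correlation score computed afterwards.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy import ndimage

__all__ = [
    "DensityMap",
    "AtomicModel",
    "Atom",
    "Residue",
    "Chain",
    "Mask",
    "MapFormatError",
    "GridMismatchError",
    "read_density",
    "write_density",
    "read_model",
    "write_model",
    "interpolate",
    "mask_from_model",
    "normalize_for_scoring",
]

_GEOM_ATOL = 1e-4  # Å tolerance when checking grid congruence


class MapFormatError(ValueError):
    """Raised for unreadable, truncated or unsupported density files."""


class GridMismatchError(ValueError):
    """Raised when two grids that must be congruent are not."""


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """A scalar density field on a regular orthogonal grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Density values, one per voxel, arbitrary units.
    voxel_size : (3,) float
        Voxel edge lengths in Å, all > 0.
    origin : (3,) float
        Cartesian position (Å) of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if any(d < 2 for d in self.values.shape):
            raise ValueError("all grid dimensions must be >= 2")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def voxel_center(self, ijk) -> np.ndarray:
        """Cartesian position (Å) of voxel index ``ijk`` (0-based)."""
        return self.origin + np.asarray(ijk, dtype=float) * self.voxel_size

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.dims[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def congruent(self, other: "DensityMap | Mask") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.voxel_size, other.voxel_size, atol=_GEOM_ATOL)
            and np.allclose(self.origin, other.origin, atol=_GEOM_ATOL)
        )

    def require_congruent(self, other: "DensityMap | Mask") -> None:
        if not self.congruent(other):
            raise GridMismatchError(
                f"grids are not congruent: dims {self.dims} vs {other.dims}, "
                f"voxel {tuple(self.voxel_size)} vs {tuple(other.voxel_size)}, "
                f"origin {tuple(self.origin)} vs {tuple(other.origin)}"
            )

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.voxel_size.copy(), self.origin.copy())


@dataclass
class Mask:
    """Boolean voxel selection congruent with a parent :class:`DensityMap`."""

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def union(self, other: "Mask") -> "Mask":
        if self.dims != other.dims:
            raise GridMismatchError("mask dims differ")
        return Mask(self.values | other.values, self.voxel_size, self.origin,
                    provenance=f"union({self.provenance},{other.provenance})")


# ---------------------------------------------------------------------------
# Atomic models
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        """Residue identity: (chain, author number, insertion code)."""
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class AtomicModel:
    chains: list[Chain] = field(default_factory=list)
    name: str = ""

    def iter_residues(self):
        for chain in self.chains:
            yield from chain.residues

    def iter_atoms(self, heavy_only: bool = False):
        for res in self.iter_residues():
            for atom in res.atoms:
                if heavy_only and atom.is_hydrogen:
                    continue
                yield res, atom

    def atom_coords(self, heavy_only: bool = True) -> np.ndarray:
        pts = [a.xyz for _, a in self.iter_atoms(heavy_only=heavy_only)]
        if not pts:
            return np.empty((0, 3))
        return np.array(pts)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def copy(self) -> "AtomicModel":
        return _copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        """Return a rigid-body transformed copy (x -> R x + t)."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        for _, atom in out.iter_atoms():
            atom.xyz = R @ atom.xyz + t
        return out


# ---------------------------------------------------------------------------
# Map I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_density(path: str) -> DensityMap:
    """Read an MRC/CCP4 2014 map (mode 0, 1 or 2).

    Axis order is canonicalized to x-fastest regardless of the file's
    MAPC/MAPR/MAPS permutation.  The grid origin comes from the ORIGIN header
    record when it is nonzero, otherwise from NXSTART/NYSTART/NZSTART scaled
    by the voxel size.  Non-orthogonal cells are refused.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read map {path!r}: {exc}") from exc

    mode = ccp4.header_i32(4)
    if mode not in (0, 1, 2):
        raise MapFormatError(f"unsupported MRC mode {mode} (expected 0, 1 or 2)")

    cell = ccp4.grid.unit_cell
    if not (math.isclose(cell.alpha, 90.0, abs_tol=1e-3)
            and math.isclose(cell.beta, 90.0, abs_tol=1e-3)
            and math.isclose(cell.gamma, 90.0, abs_tol=1e-3)):
        raise MapFormatError(
            f"non-orthogonal cell (angles {cell.alpha:.2f}, {cell.beta:.2f}, "
            f"{cell.gamma:.2f}) is unsupported"
        )

    # starts along crystallographic axes, before axis reordering
    axis_map = [ccp4.header_i32(17), ccp4.header_i32(18), ccp4.header_i32(19)]
    starts_file = [ccp4.header_i32(5), ccp4.header_i32(6), ccp4.header_i32(7)]
    starts = [0, 0, 0]
    for file_axis, xyz_axis in enumerate(axis_map):
        starts[xyz_axis - 1] = starts_file[file_axis]
    origin_rec = np.array([ccp4.header_float(i) for i in (50, 51, 52)])

    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(ccp4.grid, copy=True)  # indexed [x][y][z] after reorder
    if not np.all(np.isfinite(values)):
        raise MapFormatError("map contains non-finite values (truncated file?)")

    mx, my, mz = ccp4.header_i32(8), ccp4.header_i32(9), ccp4.header_i32(10)
    if min(mx, my, mz) <= 0:
        raise MapFormatError("invalid sampling counts in header")
    voxel_size = np.array([cell.a / mx, cell.b / my, cell.c / mz])

    if np.any(origin_rec != 0.0):
        origin = origin_rec
    else:
        origin = np.array(starts) * voxel_size
    return DensityMap(values, voxel_size, origin)


def write_density(density: DensityMap, path: str) -> None:
    """Write a mode-2 (float32) MRC/CCP4 2014 map.

    The cell is dims * voxel_size, the ORIGIN record carries the Cartesian
    origin, and DMIN/DMAX/DMEAN are recomputed from the data.
    """
    nx, ny, nz = density.dims
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.asarray(density.values, dtype=np.float32))
    a, b, c = np.array(density.dims) * density.voxel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header(2, True)
    for word, val in zip((50, 51, 52), density.origin):
        ccp4.set_header_float(word, float(val))
    ccp4.set_header_float(20, float(density.values.min()))
    ccp4.set_header_float(21, float(density.values.max()))
    ccp4.set_header_float(22, float(density.values.mean()))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write map to {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Model I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _from_gemmi(structure: gemmi.Structure) -> AtomicModel:
    structure.setup_entities()
    if len(structure) == 0:
        raise ValueError("no models in coordinate file")
    gmodel = structure[0]
    chains: list[Chain] = []
    for gchain in gmodel:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            res = Residue(
                chain_id=gchain.name,
                number=gres.seqid.num,
                name=gres.name.strip(),
                icode=(gres.seqid.icode or "").strip(),
            )
            # alternate locations: keep the highest-occupancy conformer
            # (ties broken by file order)
            best: dict[str, Atom] = {}
            best_occ: dict[str, float] = {}
            for gatom in gres:
                occ = float(gatom.occ)
                name = gatom.name.strip()
                if name in best and occ <= best_occ[name]:
                    continue
                best[name] = Atom(
                    name=name,
                    element=gatom.element.name,
                    xyz=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=occ,
                    b_factor=float(gatom.b_iso),
                )
                best_occ[name] = occ
            res.atoms = list(best.values())
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.number, r.icode))
            chains.append(chain)
    model = AtomicModel(chains=chains, name=structure.name)
    if model.n_atoms == 0:
        raise ValueError("coordinate file contains no atom records")
    return model


def read_model(path: str) -> AtomicModel:
    """Read a PDB or mmCIF coordinate file into an :class:`AtomicModel`."""
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"cannot parse coordinate file {path!r}: {exc}") from exc
    return _from_gemmi(structure)


def to_gemmi(model: AtomicModel) -> gemmi.Structure:
    structure = gemmi.Structure()
    structure.name = model.name or "model"
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.xyz)
                gatom.occ = atom.occupancy
                gatom.b_iso = atom.b_factor
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    structure.add_model(gmodel)
    structure.setup_entities()
    return structure


def write_model(model: AtomicModel, path: str) -> None:
    """Write a model as PDB (default) or mmCIF when the path ends in .cif."""
    structure = to_gemmi(model)
    path = str(path)
    if path.endswith(".cif") or path.endswith(".mmcif"):
        doc = structure.make_mmcif_document()
        doc.write_file(path)
    else:
        structure.write_pdb(path)


# ---------------------------------------------------------------------------
# Interpolation and masking
# ---------------------------------------------------------------------------

def interpolate(density: DensityMap, xyz, fill_value: float = 0.0) -> np.ndarray | float:
    """Trilinear interpolation of the map at Cartesian point(s) ``xyz`` (Å).

    Points outside the grid return ``fill_value`` (default 0, the background
    level of a masked map).
    """
    pts = np.asarray(xyz, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    frac = (pts - density.origin) / density.voxel_size
    out = ndimage.map_coordinates(
        density.values, frac.T, order=1, mode="constant", cval=fill_value
    )
    return float(out[0]) if scalar else out


def mask_from_model(density: DensityMap, model: AtomicModel, radius: float,
                    provenance: str = "model-radius") -> Mask:
    """Mask of voxels whose centers lie within ``radius`` Å of any heavy atom."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    coords = model.atom_coords(heavy_only=True)
    if coords.shape[0] == 0:
        raise ValueError("model has no heavy atoms to mask around")
    out = np.zeros(density.dims, dtype=bool)
    dims = np.array(density.dims)
    r2 = radius * radius
    for pos in coords:
        frac = (pos - density.origin) / density.voxel_size
        lo = np.maximum(np.ceil(frac - radius / density.voxel_size).astype(int), 0)
        hi = np.minimum(np.floor(frac + radius / density.voxel_size).astype(int), dims - 1)
        if np.any(lo > hi):
            continue
        ii = density.axis_coords(0)[lo[0]:hi[0] + 1] - pos[0]
        jj = density.axis_coords(1)[lo[1]:hi[1] + 1] - pos[1]
        kk = density.axis_coords(2)[lo[2]:hi[2] + 1] - pos[2]
        d2 = (ii[:, None, None] ** 2 + jj[None, :, None] ** 2 + kk[None, None, :] ** 2)
        out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= d2 <= r2
    return Mask(out, density.voxel_size, density.origin, provenance=provenance)


# ---------------------------------------------------------------------------
# Pre-scoring normalization
# ---------------------------------------------------------------------------

def normalize_for_scoring(model: AtomicModel) -> AtomicModel:
    """Normalize a model for metric scoring, leaving the input untouched.

    Hydrogens are removed and all B factors are set to zero, so that metric
    values do not depend on whether a depositor included predicted H
    positions or refined isotropic B factors.  If *every* occupancy in the
    input is zero (a submission convention that would zero out density-based
    scores), occupancies are reset to one; mixed occupancies are kept as-is.
    """
    out = model.copy()
    occs = [a.occupancy for _, a in out.iter_atoms()]
    reset_occ = len(occs) > 0 and all(o == 0.0 for o in occs)
    for chain in out.chains:
        for res in chain.residues:
            res.atoms = [a for a in res.atoms if not a.is_hydrogen]
            for atom in res.atoms:
                atom.b_factor = 0.0
                if reset_occ:
                    atom.occupancy = 1.0
        chain.residues = [r for r in chain.residues if r.atoms]
    out.chains = [c for c in out.chains if c.residues]
    return out
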