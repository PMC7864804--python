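"""Synthetic structures, resolution-limited maps, and controlled perturbations.

This module gives every metric a self-contained test surface: ideal-geometry
peptide fixtures (helix, strand, or a two-segment helix+strand domain),
density maps simulated from a model to a target resolution, and perturbations
that emulate the error classes seen in real cryo-EM model building —
coordinate jitter, peptide-plane flips, local sequence misthreading and
side-chain rotamer changes.

Map simulation places point-atom density (weighted by atomic number as a
proxy for relative scattering), optionally blurs by the model's B factors,
low-pass filters in Fourier space with a cosine edge centered at the
spatial frequency ``1/resolution`` (edge full-width 10% of the cutoff), and
finally adds seeded Gaussian white noise.  No claim is made that the
FSC-measured resolution of the product equals the target exactly; tests
check the spectral content empirically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geom import dihedral, nerf_place, rotate_about_line
from .restraints import ATOMIC_NUMBERS, RestraintLibrary
from .voxmap_io import Atom, AtomicModel, Chain, DensityMap, Residue

__all__ = [
    "FixtureSpec",
    "SimulationSpec",
    "PerturbationSpec",
    "build_fixture",
    "simulate_map",
    "simulate_map_on_grid",
    "perturb",
    "AA_1TO3",
]

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# ideal backbone torsions by secondary-structure kind
_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
}


@dataclass
class FixtureSpec:
    """Recipe for an ideal-geometry peptide fixture.

    ``sequence`` is a 1-letter string; when omitted, poly-Ala with a Leu at
    every fourth position is used so that χ1-bearing metrics have eligible
    residues.
    """

    kind: str = "helix"
    n_residues: int = 10
    sequence: str | None = None
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "strand", "two_segment"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_residues < 4:
            raise ValueError("fixtures need n_residues >= 4")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")

    def resolved_sequence(self) -> list[str]:
        if self.sequence is not None:
            return [AA_1TO3[c.upper()] for c in self.sequence]
        return [("LEU" if (i + 1) % 4 == 0 else "ALA") for i in range(self.n_residues)]


@dataclass
class SimulationSpec:
    """Conditions for simulating a density map from a model."""

    resolution: float
    voxel_size: float = 0.75
    padding: float = 5.0
    noise_sigma: float = 0.0
    b_factor_policy: str = "zero"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.voxel_size > self.resolution / 2.5:
            raise ValueError(
                f"voxel_size {self.voxel_size} undersamples resolution "
                f"{self.resolution} (need voxel <= resolution/2.5)"
            )
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.b_factor_policy not in ("zero", "from-model"):
            raise ValueError(f"unknown b_factor_policy {self.b_factor_policy!r}")


@dataclass
class PerturbationSpec:
    """A controlled model error: jitter, peptide_flip, misthread or rotamer_swap."""

    kind: str
    magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        kinds = ("jitter", "peptide_flip", "misthread", "rotamer_swap")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.kind == "jitter" and self.magnitude < 0:
            raise ValueError("jitter RMS must be >= 0")


# ---------------------------------------------------------------------------
# Fixture building
# ---------------------------------------------------------------------------

def _build_sidechain(res: Residue, lib: RestraintLibrary,
                     chis: dict[str, float] | None = None) -> None:
    """Append side-chain atoms beyond CB from the library template."""
    specs = lib.sidechains.get(res.name, [])
    if not specs:
        return
    chis = chis or lib.default_chis(res.name)
    pos = {a.name: a.xyz for a in res.atoms}
    for spec in specs:
        a, b, c = (pos[n] for n in spec.frame)
        xyz = nerf_place(a, b, c, spec.bond, spec.angle,
                         spec.resolve_torsion(chis))
        res.atoms.append(Atom(spec.name, spec.element, xyz))
        pos[spec.name] = xyz


def build_fixture(spec: FixtureSpec, lib: RestraintLibrary | None = None) -> AtomicModel:
    """Build an ideal-geometry fixture model.

    Backbone torsions are φ=-57°, ψ=-47° for helices and φ=-120°, ψ=+120° for
    strands (ω=180° throughout); a ``two_segment`` fixture is helix for the
    first half and strand for the second.  All bond lengths and angles come
    from the shipped :class:`RestraintLibrary`, so geometry RMSDs of an
    unperturbed fixture are zero.
    """
    lib = lib or RestraintLibrary()
    seq = spec.resolved_sequence()
    n = spec.n_residues

    def torsions(i: int) -> tuple[float, float]:
        if spec.kind == "two_segment":
            return _TORSIONS["helix"] if i < n // 2 else _TORSIONS["strand"]
        return _TORSIONS[spec.kind]

    b_nca, _ = lib.backbone_bonds["N-CA"]
    b_cac, _ = lib.backbone_bonds["CA-C"]
    b_co, _ = lib.backbone_bonds["C-O"]
    b_cn, _ = lib.peptide_bond()
    a_ncac = lib.backbone_angles["N-CA-C"][0]
    a_caco = lib.backbone_angles["CA-C-O"][0]
    a_cacn = lib.backbone_angles["CA-C-N+"][0]
    a_cnca = lib.backbone_angles["C-N-CA"][0]

    chain = Chain(chain_id=spec.chain_id)
    prev: dict[str, np.ndarray] | None = None
    for i in range(n):
        phi, psi = torsions(i)
        res = Residue(chain_id=spec.chain_id, number=i + 1, name=seq[i])
        if prev is None:
            npos = np.zeros(3)
            ca = npos + np.array([b_nca, 0.0, 0.0])
            ang = np.radians(a_ncac)
            c = ca + b_cac * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev_phi, prev_psi = torsions(i - 1)
            npos = nerf_place(prev["N"], prev["CA"], prev["C"],
                              b_cn, a_cacn, prev_psi)
            ca = nerf_place(prev["CA"], prev["C"], npos, b_nca, a_cnca, 180.0)
            c = nerf_place(prev["C"], npos, ca, b_cac, a_ncac, phi)
        o = nerf_place(npos, ca, c, b_co, a_caco, psi + 180.0)
        res.atoms = [Atom("N", "N", npos), Atom("CA", "C", ca),
                     Atom("C", "C", c), Atom("O", "O", o)]
        if res.name != "GLY":
            res.atoms.append(Atom("CB", "C", lib.place_cb(npos, ca, c)))
        _build_sidechain(res, lib)
        chain.residues.append(res)
        prev = {"N": npos, "CA": ca, "C": c}
    return AtomicModel(chains=[chain], name=f"{spec.kind}-{n}")


# ---------------------------------------------------------------------------
# Map simulation
# ---------------------------------------------------------------------------

ATOM_WIDTH_FRACTION = 0.225  # intrinsic atom Gaussian width as fraction of d


def _lowpass_filter(values: np.ndarray, voxel_size: np.ndarray,
                    resolution: float, edge_frac: float = 0.1) -> np.ndarray:
    """Resolution-limiting Fourier filter.

    Atoms acquire an intrinsic Gaussian width sigma = 0.225*resolution (the
    convention of common map simulators), which keeps the density compact
    and suppresses truncation ringing; a cosine edge centered at the cutoff
    frequency 1/resolution (full width ``edge_frac`` of the cutoff) then
    removes all content beyond the stated resolution.
    """
    freqs = np.meshgrid(
        *[np.fft.fftfreq(n, d=v) for n, v in zip(values.shape, voxel_size)],
        indexing="ij",
    )
    f = np.sqrt(sum(fr ** 2 for fr in freqs))
    fc = 1.0 / resolution
    half = 0.5 * edge_frac * fc
    H = np.ones_like(f)
    H[f >= fc + half] = 0.0
    ramp = (f > fc - half) & (f < fc + half)
    H[ramp] = 0.5 * (1.0 + np.cos(np.pi * (f[ramp] - (fc - half)) / (2 * half)))
    sigma = ATOM_WIDTH_FRACTION * resolution
    H *= np.exp(-2.0 * np.pi ** 2 * sigma ** 2 * f ** 2)
    return np.real(np.fft.ifftn(np.fft.fftn(values) * H))


def simulate_map(model: AtomicModel, spec: SimulationSpec) -> DensityMap:
    """Simulate a resolution-limited density map from a model.

    Atoms contribute point density proportional to atomic number times
    occupancy, splatted trilinearly onto the grid (or as a Gaussian of width
    σ_B = sqrt(B/(8π²)) under the ``from-model`` B-factor policy), then the
    grid is low-pass filtered to the target resolution and seeded white
    noise of sd ``noise_sigma`` is added.
    """
    coords = model.atom_coords(heavy_only=False)
    if coords.shape[0] == 0:
        raise ValueError("cannot simulate a map from an empty model")
    voxel = np.full(3, float(spec.voxel_size))
    lo = coords.min(axis=0) - spec.padding
    hi = coords.max(axis=0) + spec.padding
    dims = np.ceil((hi - lo) / voxel).astype(int) + 1
    if np.any(dims < 4):
        raise ValueError("grid too small for model plus padding")
    values = np.zeros(dims)
    origin = lo

    for res, atom in model.iter_atoms():
        weight = ATOMIC_NUMBERS.get(atom.element.upper(), 6) * atom.occupancy
        if weight == 0:
            continue
        frac = (atom.xyz - origin) / voxel
        sigma_b = 0.0
        if spec.b_factor_policy == "from-model" and atom.b_factor > 0:
            sigma_b = np.sqrt(atom.b_factor / (8 * np.pi ** 2))
        if sigma_b < 0.3 * spec.voxel_size:
            _splat_trilinear(values, frac, weight)
        else:
            _splat_gaussian(values, frac, weight, sigma_b / spec.voxel_size)

    values = _lowpass_filter(values, voxel, spec.resolution)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sigma, size=values.shape)
    return DensityMap(values, voxel, origin)


def simulate_map_on_grid(model: AtomicModel, like: DensityMap,
                         resolution: float) -> DensityMap:
    """Simulate a model-map on exactly the grid geometry of ``like``.

    Used when a model-map must be congruent with an experimental map for
    correlation or FSC scoring: maps are never regridded implicitly, so the
    simulation is repeated on the target geometry instead.
    """
    values = np.zeros(like.dims)
    for res, atom in model.iter_atoms():
        weight = ATOMIC_NUMBERS.get(atom.element.upper(), 6) * atom.occupancy
        if weight == 0:
            continue
        frac = (atom.xyz - like.origin) / like.voxel_size
        _splat_trilinear(values, frac, weight)
    values = _lowpass_filter(values, like.voxel_size, resolution)
    return DensityMap(values, like.voxel_size.copy(), like.origin.copy())


def _splat_trilinear(values: np.ndarray, frac: np.ndarray, weight: float) -> None:
    base = np.floor(frac).astype(int)
    t = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = base + (dx, dy, dz)
                if np.any(idx < 0) or np.any(idx >= values.shape):
                    continue
                w = ((t[0] if dx else 1 - t[0])
                     * (t[1] if dy else 1 - t[1])
                     * (t[2] if dz else 1 - t[2]))
                values[tuple(idx)] += weight * w


def _splat_gaussian(values: np.ndarray, frac: np.ndarray, weight: float,
                    sigma_vox: float) -> None:
    r = max(int(np.ceil(3 * sigma_vox)), 1)
    base = np.round(frac).astype(int)
    lo = np.maximum(base - r, 0)
    hi = np.minimum(base + r, np.array(values.shape) - 1)
    if np.any(lo > hi):
        return
    axes = [np.arange(lo[d], hi[d] + 1) - frac[d] for d in range(3)]
    g = np.exp(-(axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
                 + axes[2][None, None, :] ** 2) / (2 * sigma_vox ** 2))
    g *= weight / g.sum()
    values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += g


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def perturb(model: AtomicModel, spec: PerturbationSpec,
            lib: RestraintLibrary | None = None) -> AtomicModel:
    """Apply a controlled error to a copy of ``model``."""
    out = model.copy()
    if spec.kind == "jitter":
        _jitter(out, spec.magnitude, spec.seed)
    elif spec.kind == "peptide_flip":
        _peptide_flip(out, int(spec.magnitude))
    elif spec.kind == "misthread":
        _misthread(out, int(spec.magnitude), lib or RestraintLibrary())
    elif spec.kind == "rotamer_swap":
        _rotamer_swap(out, spec.magnitude, lib or RestraintLibrary())
    return out


def _jitter(model: AtomicModel, rms: float, seed: int) -> None:
    if rms == 0:
        return
    rng = np.random.default_rng(seed)
    sigma = rms / np.sqrt(3.0)  # per-coordinate sd for the requested RMS norm
    for _, atom in model.iter_atoms():
        atom.xyz = atom.xyz + rng.normal(0.0, sigma, size=3)


def _peptide_flip(model: AtomicModel, res_index: int) -> None:
    """Rotate the peptide unit after residue ``res_index`` (0-based, over all
    residues) by 180° about the Cα(i)-Cα(i+1) axis.  Cα positions are fixed;
    the carbonyl O swings to the other side of the backbone tube."""
    residues = list(model.iter_residues())
    if not 0 <= res_index < len(residues) - 1:
        raise ValueError("peptide_flip index must have a following residue")
    ri, rj = residues[res_index], residues[res_index + 1]
    if ri.chain_id != rj.chain_id:
        raise ValueError("cannot flip across a chain boundary")
    ca_i, ca_j = ri.atom("CA"), rj.atom("CA")
    if ca_i is None or ca_j is None:
        raise ValueError("peptide_flip requires CA atoms on both residues")
    axis = ca_j.xyz - ca_i.xyz
    for atom in (ri.atom("C"), ri.atom("O"), rj.atom("N")):
        if atom is not None:
            atom.xyz = rotate_about_line(atom.xyz, ca_i.xyz, axis, 180.0)[0]


def _misthread(model: AtomicModel, k: int, lib: RestraintLibrary) -> None:
    """Shift residue type assignments by ``k`` along each chain (cyclic),
    keeping backbone coordinates and rebuilding side chains for the new type."""
    for chain in model.chains:
        nres = len(chain.residues)
        if k == 0:
            continue
        if abs(k) >= nres:
            raise ValueError("misthread offset must be smaller than chain length")
        names = [r.name for r in chain.residues]
        shifted = [names[(i + k) % nres] for i in range(nres)]
        for res, new_name in zip(chain.residues, shifted):
            if new_name == res.name:
                continue
            res.name = new_name
            backbone = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")]
            res.atoms = backbone
            pos = {a.name: a.xyz for a in backbone}
            if new_name != "GLY" and all(n in pos for n in ("N", "CA", "C")):
                res.atoms.append(
                    Atom("CB", "C", lib.place_cb(pos["N"], pos["CA"], pos["C"])))
                _build_sidechain(res, lib)


def _chi1_partner(res: Residue, lib: RestraintLibrary) -> str | None:
    for spec in lib.sidechains.get(res.name, []):
        if spec.torsion == "chi1":
            return spec.name
    return None


def _rotamer_swap(model: AtomicModel, target_chi1: float,
                  lib: RestraintLibrary) -> None:
    """Rotate every eligible side chain about CA-CB so that χ1 equals
    ``target_chi1`` degrees.  Proline (ring) is left alone."""
    backbone = {"N", "CA", "C", "O", "CB"}
    for res in model.iter_residues():
        if res.name == "PRO":
            continue
        partner = _chi1_partner(res, lib)
        n, ca, cb = res.atom("N"), res.atom("CA"), res.atom("CB")
        if partner is None or n is None or ca is None or cb is None:
            continue
        g = res.atom(partner)
        if g is None:
            continue
        current = dihedral(n.xyz, ca.xyz, cb.xyz, g.xyz)
        # right-handed rotation about CA->CB increases the N-CA-CB-G dihedral
        delta = target_chi1 - current
        axis = cb.xyz - ca.xyz
        for atom in res.atoms:
            if atom.name not in backbone:
                atom.xyz = rotate_about_line(atom.xyz, ca.xyz, axis, delta)[0]
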