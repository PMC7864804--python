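"""Map-independent stereochemistry and conformation validation.

Covers restraint RMSDs (bond, angle, chirality, planarity, torsion), steric
clashes, Ramachandran and rotamer outliers, CaBLAM-style virtual-dihedral
backbone validation, and cis-peptide detection.

Outlier calls are made against pluggable :class:`ReferenceDistribution`
grids — binned, smoothed conformational frequency maps with percentile
cutoffs (defaults 1% outlier / 5% disfavored, the MolProbity convention).
Production-quality grids can be loaded from JSON; the package ships compact
synthetic grids for φ/ψ and χ1 (textbook allowed regions, see
``data/rama_synthetic.json``), and CaBLAM grids are built from conformer
ensembles with :func:`reference_from_models`.

All scores operate on heavy atoms; run models through
:func:`emvalid.voxmap_io.normalize_for_scoring` first so that H atoms and
B-factor conventions cannot skew comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geom import angular_diff, bond_angle, bond_length, dihedral
from .restraints import VDW_RADII, RestraintLibrary
from .voxmap_io import AtomicModel, Residue

__all__ = [
    "ReferenceDistribution", "GeometryRmsd", "ClashReport", "OutlierReport",
    "CablamReport", "GeometryReport",
    "geometry_rmsd", "clashscore", "rama_rotamer_outliers", "cablam",
    "cis_peptides", "full_report",
    "reference_from_models", "load_rama_reference", "load_rotamer_reference",
    "default_cablam_references", "phi_psi_list", "cablam_parameters",
    "CHAIN_BREAK_CA_DISTANCE",
]

CHAIN_BREAK_CA_DISTANCE = 4.5  # Å; longer Cα-Cα gaps terminate a stretch


# ---------------------------------------------------------------------------
# Reference distributions
# ---------------------------------------------------------------------------

@dataclass
class ReferenceDistribution:
    """Binned conformational frequency grid with percentile cutoffs.

    ``edges`` are per-dimension bin edges covering the full domain;
    ``frequencies`` are smoothed non-negative weights.  A query point is
    scored by the *coverage percentile*: the percentage of total reference
    mass lying in bins whose frequency does not exceed the query bin's.
    Points below ``outlier_pct`` are outliers; below ``disfavored_pct``,
    disfavored.
    """

    name: str
    edges: list[np.ndarray]
    frequencies: np.ndarray
    periodic: list[bool]
    outlier_pct: float = 1.0
    disfavored_pct: float = 5.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be >= 0")
        if not 0 < self.outlier_pct < 100 or not 0 < self.disfavored_pct < 100:
            raise ValueError("percentile cutoffs must be in (0, 100)")
        # precompute coverage percentile per bin
        flat = self.frequencies.ravel()
        order = np.argsort(flat, kind="stable")
        cum = np.cumsum(flat[order])
        total = cum[-1] if cum.size else 0.0
        cov = np.empty_like(flat)
        if total > 0:
            # mass in bins with frequency <= this bin's (ties included)
            sorted_f = flat[order]
            cum_by_val = {}
            for f_val, c in zip(sorted_f, cum):
                cum_by_val[f_val] = c  # last occurrence keeps the full tie mass
            cov[order] = [cum_by_val[f] / total * 100.0 for f in sorted_f]
        else:
            cov[:] = 0.0
        self._coverage = cov.reshape(self.frequencies.shape)

    def _bin_index(self, point) -> tuple[int, ...]:
        idx = []
        for x, edges, per in zip(np.atleast_1d(point), self.edges, self.periodic):
            lo, hi = edges[0], edges[-1]
            if per:
                x = lo + (x - lo) % (hi - lo)
            i = int(np.searchsorted(edges, x, side="right")) - 1
            idx.append(int(np.clip(i, 0, len(edges) - 2)))
        return tuple(idx)

    def score(self, point) -> float:
        """Coverage percentile of ``point`` in [0, 100]."""
        return float(self._coverage[self._bin_index(point)])

    def is_outlier(self, point) -> bool:
        return self.score(point) < self.outlier_pct

    def is_disfavored(self, point) -> bool:
        return self.score(point) < self.disfavored_pct

    # -- construction -----------------------------------------------------

    @classmethod
    def from_samples(cls, name: str, samples: np.ndarray, bins: list[int],
                     ranges: list[tuple[float, float]], periodic: list[bool],
                     smooth_sigma_bins: float = 1.0, **kw) -> "ReferenceDistribution":
        samples = np.atleast_2d(np.asarray(samples, float))
        edges = [np.linspace(lo, hi, n + 1) for (lo, hi), n in zip(ranges, bins)]
        wrapped = samples.copy()
        for d, ((lo, hi), per) in enumerate(zip(ranges, periodic)):
            if per:
                wrapped[:, d] = lo + (wrapped[:, d] - lo) % (hi - lo)
        hist, _ = np.histogramdd(wrapped, bins=edges)
        if smooth_sigma_bins > 0:
            modes = ["wrap" if p else "nearest" for p in periodic]
            hist = ndimage.gaussian_filter(hist, sigma=smooth_sigma_bins,
                                           mode=modes)
        return cls(name=name, edges=edges, frequencies=hist,
                   periodic=list(periodic), **kw)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceDistribution":
        d = json.loads(text)
        return cls(
            name=d["name"],
            edges=[np.asarray(e, float) for e in d["edges"]],
            frequencies=np.asarray(d["frequencies"], float).reshape(d["shape"]),
            periodic=list(d["periodic"]),
            outlier_pct=d.get("outlier_pct", 1.0),
            disfavored_pct=d.get("disfavored_pct", 5.0),
        )

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "edges": [e.tolist() for e in self.edges],
            "shape": list(self.frequencies.shape),
            "frequencies": self.frequencies.ravel().tolist(),
            "periodic": self.periodic,
            "outlier_pct": self.outlier_pct,
            "disfavored_pct": self.disfavored_pct,
        })


def load_rama_reference() -> ReferenceDistribution:
    """Shipped synthetic φ×ψ grid covering the textbook allowed regions."""
    text = resources.files("emvalid.data").joinpath("rama_synthetic.json").read_text()
    return ReferenceDistribution.from_json(text)


def load_rotamer_reference() -> ReferenceDistribution:
    """Shipped synthetic χ1 grid with staggered rotamer wells at 60/180/300°."""
    text = resources.files("emvalid.data").joinpath("rotamer_synthetic.json").read_text()
    return ReferenceDistribution.from_json(text)


# ---------------------------------------------------------------------------
# Torsion extraction helpers
# ---------------------------------------------------------------------------

def _chain_stretches(residues: list[Residue]) -> list[list[Residue]]:
    """Split a chain's residues into continuous stretches at Cα-Cα breaks."""
    stretches: list[list[Residue]] = []
    current: list[Residue] = []
    prev_ca = None
    for res in residues:
        ca = res.atom("CA")
        if ca is None:
            if current:
                stretches.append(current)
            current, prev_ca = [], None
            continue
        if prev_ca is not None and bond_length(prev_ca.xyz, ca.xyz) > CHAIN_BREAK_CA_DISTANCE:
            stretches.append(current)
            current = []
        current.append(res)
        prev_ca = ca
    if current:
        stretches.append(current)
    return stretches


def phi_psi_list(model: AtomicModel) -> list[tuple[Residue, float, float]]:
    """(residue, φ, ψ) for every residue with both torsions defined."""
    out = []
    for chain in model.chains:
        for stretch in _chain_stretches(chain.residues):
            for i in range(1, len(stretch) - 1):
                prv, cur, nxt = stretch[i - 1], stretch[i], stretch[i + 1]
                atoms = (prv.atom("C"), cur.atom("N"), cur.atom("CA"),
                         cur.atom("C"), nxt.atom("N"))
                if any(a is None for a in atoms):
                    continue
                c0, n, ca, c, n1 = (a.xyz for a in atoms)
                out.append((cur, dihedral(c0, n, ca, c), dihedral(n, ca, c, n1)))
    return out


def cablam_parameters(model: AtomicModel) -> list[tuple[Residue, float, float, float, float]]:
    """(residue, μ_in, μ_out, CO virtual dihedral, Cα virtual angle).

    μ_in is the Cα virtual dihedral over residues i-2..i+1, μ_out over
    i-1..i+2; the CO dihedral is the virtual torsion of the two carbonyl
    groups flanking residue i (O(i-1), C(i-1), C(i), O(i)); the Cα virtual
    angle is at residue i.  Requires five consecutive residues within a
    continuous stretch.
    """
    out = []
    for chain in model.chains:
        for stretch in _chain_stretches(chain.residues):
            for i in range(2, len(stretch) - 2):
                window = stretch[i - 2:i + 3]
                cas = [r.atom("CA") for r in window]
                prv, cur = stretch[i - 1], stretch[i]
                c_prv, o_prv = prv.atom("C"), prv.atom("O")
                c_cur, o_cur = cur.atom("C"), cur.atom("O")
                if any(a is None for a in cas + [c_prv, o_prv, c_cur, o_cur]):
                    continue
                ca = [a.xyz for a in cas]
                mu_in = dihedral(ca[0], ca[1], ca[2], ca[3])
                mu_out = dihedral(ca[1], ca[2], ca[3], ca[4])
                co = dihedral(o_prv.xyz, c_prv.xyz, c_cur.xyz, o_cur.xyz)
                virt_angle = bond_angle(ca[1], ca[2], ca[3])
                out.append((cur, mu_in, mu_out, co, virt_angle))
    return out


def reference_from_models(name: str, models: list[AtomicModel],
                          kind: str, bins: list[int] | None = None,
                          smooth_sigma_bins: float = 1.0, **kw) -> ReferenceDistribution:
    """Build a reference grid from an ensemble of models.

    ``kind`` selects the parameterization: ``rama`` (φ, ψ), ``rotamer``
    (χ1), ``cablam`` (μ_in, μ_out, CO dihedral) or ``ca_geom`` (μ_in,
    μ_out, Cα virtual angle).  The test suite and default CaBLAM references
    use jittered ideal-geometry ensembles as a stand-in for the curated
    high-quality structure sets behind production grids.
    """
    lib = RestraintLibrary()
    rows = []
    if kind == "rama":
        for m in models:
            rows += [(phi, psi) for _, phi, psi in phi_psi_list(m)]
        bins = bins or [72, 72]
        ranges = [(-180.0, 180.0)] * 2
        periodic = [True, True]
    elif kind == "rotamer":
        for m in models:
            for res in m.iter_residues():
                chi = _chi1(res, lib)
                if chi is not None:
                    rows.append((chi,))
        bins = bins or [36]
        ranges = [(0.0, 360.0)]
        periodic = [True]
    elif kind == "cablam":
        for m in models:
            rows += [(a, b, c) for _, a, b, c, _ in cablam_parameters(m)]
        bins = bins or [12, 12, 12]
        ranges = [(-180.0, 180.0)] * 3
        periodic = [True, True, True]
    elif kind == "ca_geom":
        for m in models:
            rows += [(a, b, d) for _, a, b, _, d in cablam_parameters(m)]
        bins = bins or [12, 12, 12]
        ranges = [(-180.0, 180.0), (-180.0, 180.0), (0.0, 180.0)]
        periodic = [True, True, False]
    else:
        raise ValueError(f"unknown reference kind {kind!r}")
    if not rows:
        raise ValueError("no samples extracted from the supplied models")
    return ReferenceDistribution.from_samples(
        name, np.array(rows, float), bins, ranges, periodic,
        smooth_sigma_bins=smooth_sigma_bins, **kw)


def default_cablam_references(seed: int = 0, n_models: int = 60,
                              jitter_rms: float = 0.12):
    """CaBLAM and Cα-geometry grids from jittered helix/strand ensembles.

    A deterministic stand-in for grids derived from curated PDB structures:
    ideal helix and strand fixtures are jittered (default 0.12 Å RMS) to
    populate the regular-secondary-structure basins.
    """
    from .simulate import FixtureSpec, PerturbationSpec, build_fixture, perturb
    models = []
    for kind_i, kind in enumerate(("helix", "strand")):
        base = build_fixture(FixtureSpec(kind, 16))
        for j in range(n_models):
            models.append(perturb(base, PerturbationSpec(
                "jitter", jitter_rms, seed=seed + 1000 * kind_i + j)))
    cab = reference_from_models("cablam-ensemble", models, "cablam")
    cag = reference_from_models("ca-geom-ensemble", models, "ca_geom")
    return cab, cag


def _chi1(res: Residue, lib: RestraintLibrary) -> float | None:
    spec = next((s for s in lib.sidechains.get(res.name, [])
                 if s.torsion == "chi1"), None)
    if spec is None or res.name == "PRO":
        return None
    atoms = (res.atom("N"), res.atom("CA"), res.atom("CB"), res.atom(spec.name))
    if any(a is None for a in atoms):
        return None
    chi = dihedral(*(a.xyz for a in atoms))
    return chi % 360.0


# ---------------------------------------------------------------------------
# Restraint RMSDs
# ---------------------------------------------------------------------------

@dataclass
class GeometryRmsd:
    bond: float
    angle: float
    chiral: float
    planar: float
    dihedral: float
    n_bonds: int
    n_angles: int
    n_chirals: int
    n_planar_atoms: int
    n_dihedrals: int
    skipped_residues: list[tuple[str, int, str]] = field(default_factory=list)
    chiral_outliers: list[tuple[str, int, str]] = field(default_factory=list)


def _plane_rms(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    _, s, _ = np.linalg.svd(centered, full_matrices=False)
    # smallest singular value^2 = sum of squared out-of-plane distances
    return float(np.sqrt(s[-1] ** 2 / len(points)))


def geometry_rmsd(model: AtomicModel, lib: RestraintLibrary | None = None,
                  chiral_flag_cut: float = 1.0) -> GeometryRmsd:
    """RMS deviations from ideal internal coordinates.

    Bond and angle deviations are matched against the restraint library
    (unknown residue types are skipped and counted); chirality is the Cα
    chiral volume against its ideal; planarity pools out-of-plane distances
    of peptide planes and side-chain planar groups; the torsion term pools
    ω deviations from the nearer of trans (180°) and cis (0°).
    Mirror-imaged residues (chiral deviation beyond ``chiral_flag_cut`` ų)
    are listed as chirality outliers.
    """
    lib = lib or RestraintLibrary()
    bond_dev, angle_dev, chiral_dev, omega_dev = [], [], [], []
    plane_sq_dists: list[float] = []
    n_planar_atoms = 0
    skipped, chiral_outliers = [], []

    for chain in model.chains:
        residues = chain.residues
        for i, res in enumerate(residues):
            if not lib.knows(res.name):
                skipped.append((res.chain_id, res.number, res.name))
                continue
            pos = {a.name: a.xyz for a in res.heavy_atoms()}
            for a1, a2, ideal, _sig in lib.intra_bonds(res.name):
                if a1 in pos and a2 in pos:
                    bond_dev.append(bond_length(pos[a1], pos[a2]) - ideal)
            for a1, a2, a3, ideal, _sig in lib.intra_angles(res.name):
                if all(n in pos for n in (a1, a2, a3)):
                    angle_dev.append(bond_angle(pos[a1], pos[a2], pos[a3]) - ideal)
            if all(n in pos for n in ("N", "CA", "C", "CB")):
                vol = float(np.dot(pos["N"] - pos["CA"],
                                   np.cross(pos["C"] - pos["CA"],
                                            pos["CB"] - pos["CA"])))
                dev = vol - lib.ideal_chiral_volume
                chiral_dev.append(dev)
                if abs(dev) > chiral_flag_cut:
                    chiral_outliers.append((res.chain_id, res.number, res.name))
            for group in lib.planar_groups_for(res.name):
                pts = [pos[n] for n in group if n in pos]
                if len(pts) >= 4:
                    rms = _plane_rms(np.array(pts))
                    plane_sq_dists.extend([rms ** 2] * len(pts))
                    n_planar_atoms += len(pts)

            # peptide link to the next residue
            if i + 1 < len(residues):
                nxt = residues[i + 1]
                npos = {a.name: a.xyz for a in nxt.heavy_atoms()}
                if "C" not in pos or "N" not in npos:
                    continue
                d = bond_length(pos["C"], npos["N"])
                if d > 2.5:  # chain break, not a bond
                    continue
                ideal, _sig = lib.peptide_bond()
                bond_dev.append(d - ideal)
                pa = lib.peptide_angles()
                if "CA" in pos:
                    angle_dev.append(bond_angle(pos["CA"], pos["C"], npos["N"])
                                     - pa["CA-C-N+"][0])
                if "O" in pos:
                    angle_dev.append(bond_angle(pos["O"], pos["C"], npos["N"])
                                     - pa["O-C-N+"][0])
                if "CA" in npos:
                    angle_dev.append(bond_angle(pos["C"], npos["N"], npos["CA"])
                                     - pa["C-N-CA"][0])
                if all(n in pos for n in ("CA", "C", "O")) and "CA" in npos:
                    plane_pts = np.array([pos["CA"], pos["C"], pos["O"],
                                          npos["N"], npos["CA"]])
                    rms = _plane_rms(plane_pts)
                    plane_sq_dists.extend([rms ** 2] * len(plane_pts))
                    n_planar_atoms += len(plane_pts)
                if all(n in pos for n in ("CA", "C")) and "CA" in npos:
                    omega = dihedral(pos["CA"], pos["C"], npos["N"], npos["CA"])
                    dev = angular_diff(omega, 180.0)
                    if abs(omega) < 90.0:  # cis peptide: measure against 0
                        dev = angular_diff(omega, 0.0)
                    omega_dev.append(dev)

    def rms(x):
        return float(np.sqrt(np.mean(np.square(x)))) if len(x) else 0.0

    return GeometryRmsd(
        bond=rms(bond_dev), angle=rms(angle_dev), chiral=rms(chiral_dev),
        planar=float(np.sqrt(np.mean(plane_sq_dists))) if plane_sq_dists else 0.0,
        dihedral=rms(omega_dev),
        n_bonds=len(bond_dev), n_angles=len(angle_dev),
        n_chirals=len(chiral_dev), n_planar_atoms=n_planar_atoms,
        n_dihedrals=len(omega_dev),
        skipped_residues=skipped, chiral_outliers=chiral_outliers,
    )


# ---------------------------------------------------------------------------
# Clashscore
# ---------------------------------------------------------------------------

@dataclass
class ClashReport:
    score: float                      # clashes per 1,000 atoms
    n_atoms: int
    clashes: list[tuple[tuple[str, int, str], tuple[str, int, str], float]]


def _bonded_pairs(model: AtomicModel, lib: RestraintLibrary):
    """Atom-index pairs within graph distance 3 (bonded, 1-3 or 1-4)."""
    index = {}
    atoms = []
    for ri, (res, atom) in enumerate(model.iter_atoms(heavy_only=True)):
        index[id(atom)] = ri
        atoms.append((res, atom))

    adj: dict[int, set[int]] = {i: set() for i in range(len(atoms))}

    def link(i, j):
        adj[i].add(j)
        adj[j].add(i)

    # intra-residue bonds from the library topology
    offset = 0
    per_res: list[tuple[Residue, dict[str, int]]] = []
    for chain in model.chains:
        for res in chain.residues:
            names = {}
            for a in res.heavy_atoms():
                names[a.name] = offset
                offset += 1
            per_res.append((res, names))
    for res, names in per_res:
        if lib.knows(res.name):
            bonds = lib.intra_bonds(res.name)
        else:
            # unknown type: treat every intra-residue pair as excluded
            keys = list(names)
            bonds = [(keys[i], keys[j], 0, 0)
                     for i in range(len(keys)) for j in range(i + 1, len(keys))]
        for a1, a2, *_ in bonds:
            if a1 in names and a2 in names:
                link(names[a1], names[a2])
        for a1, a2 in lib.ring_closures.get(res.name, []):
            if a1 in names and a2 in names:
                link(names[a1], names[a2])
    # peptide links
    flat = per_res
    for (res, names), (nres, nnames) in zip(flat, flat[1:]):
        if res.chain_id != nres.chain_id:
            continue
        if "C" in names and "N" in nnames:
            ci, nj = names["C"], nnames["N"]
            ca_i = atoms[ci][1].xyz if True else None
            if bond_length(atoms[ci][1].xyz, atoms[nj][1].xyz) <= 2.5:
                link(ci, nj)

    excluded = set()
    for i, nbrs in adj.items():
        for j in nbrs:
            excluded.add((min(i, j), max(i, j)))        # 1-2
            for k in adj[j]:
                if k == i:
                    continue
                excluded.add((min(i, k), max(i, k)))    # 1-3
                for l in adj[k]:
                    if l not in (i, j):
                        excluded.add((min(i, l), max(i, l)))  # 1-4
    return atoms, excluded


def clashscore(model: AtomicModel, vdw: dict[str, float] | None = None,
               overlap_cut: float = 0.4,
               lib: RestraintLibrary | None = None) -> ClashReport:
    """Steric overlaps >= ``overlap_cut`` Å per 1,000 heavy atoms.

    A clash is a heavy-atom pair whose van der Waals overlap
    (r_i + r_j - d) reaches the cutoff, excluding pairs within three bonds
    of each other (1-2, 1-3, 1-4): the 1-4 contacts across a trans peptide
    plane (e.g. O(i)...CA(i+1)) are fixed by the connectivity, not by the
    modeler, and would otherwise flag every peptide bond.
    """
    vdw = vdw or VDW_RADII
    lib = lib or RestraintLibrary()
    atoms, excluded = _bonded_pairs(model, lib)
    if not atoms:
        return ClashReport(score=0.0, n_atoms=0, clashes=[])
    coords = np.array([a.xyz for _, a in atoms])
    radii = np.array([vdw.get(a.element.upper(), 1.7) for _, a in atoms])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=float(2 * radii.max()), output_type="ndarray")
    clashes = []
    for i, j in pairs:
        if (min(i, j), max(i, j)) in excluded:
            continue
        d = bond_length(coords[i], coords[j])
        overlap = radii[i] + radii[j] - d
        if overlap >= overlap_cut - 1e-9:  # ties count as clashes
            ri, ai = atoms[i]
            rj, aj = atoms[j]
            clashes.append(((ri.chain_id, ri.number, ai.name),
                            (rj.chain_id, rj.number, aj.name), float(overlap)))
    return ClashReport(score=1000.0 * len(clashes) / len(atoms),
                       n_atoms=len(atoms), clashes=clashes)


# ---------------------------------------------------------------------------
# Ramachandran / rotamer outliers
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    fraction: float | None            # None when nothing could be scored
    n_scored: int
    outliers: list[tuple[str, int, str]]
    unscored: list[tuple[str, int, str]] = field(default_factory=list)


def rama_rotamer_outliers(model: AtomicModel,
                          rama_ref: ReferenceDistribution | None = None,
                          rotamer_ref: ReferenceDistribution | None = None,
                          ) -> tuple[OutlierReport, OutlierReport]:
    """Ramachandran (φ, ψ) and rotamer (χ1) outlier fractions and lists.

    Terminal residues (no φ or ψ) and residues with missing backbone atoms
    are unscored and listed as such; a chain too short to define any torsion
    yields ``fraction=None`` rather than a fake zero.
    """
    rama_ref = rama_ref or load_rama_reference()
    rotamer_ref = rotamer_ref or load_rotamer_reference()
    lib = RestraintLibrary()

    scored_keys = set()
    rama_out: list[tuple[str, int, str]] = []
    pp = phi_psi_list(model)
    for res, phi, psi in pp:
        scored_keys.add(res.key)
        if rama_ref.is_outlier((phi, psi)):
            rama_out.append((res.chain_id, res.number, res.name))
    unscored = [(r.chain_id, r.number, r.name) for r in model.iter_residues()
                if r.key not in scored_keys]
    rama = OutlierReport(
        fraction=len(rama_out) / len(pp) if pp else None,
        n_scored=len(pp), outliers=rama_out, unscored=unscored)

    rot_out: list[tuple[str, int, str]] = []
    n_rot = 0
    for res in model.iter_residues():
        chi = _chi1(res, lib)
        if chi is None:
            continue
        n_rot += 1
        if rotamer_ref.is_outlier((chi,)):
            rot_out.append((res.chain_id, res.number, res.name))
    rot = OutlierReport(
        fraction=len(rot_out) / n_rot if n_rot else None,
        n_scored=n_rot, outliers=rot_out)
    return rama, rot


# ---------------------------------------------------------------------------
# CaBLAM
# ---------------------------------------------------------------------------

@dataclass
class CablamReport:
    cablam: OutlierReport             # (μ_in, μ_out, CO dihedral) triplet
    ca_geometry: OutlierReport        # (μ_in, μ_out, Cα virtual angle)
    parameters: list[tuple[tuple[str, int, str], float, float, float, float]]


def cablam(model: AtomicModel,
           cablam_ref: ReferenceDistribution,
           ca_geom_ref: ReferenceDistribution) -> CablamReport:
    """Backbone conformation outliers from Cα-trace virtual dihedrals.

    Flags residues whose (μ_in, μ_out, CO-dihedral) triplet — or, for the
    Cα-geometry variant, (μ_in, μ_out, Cα virtual angle) — is rare in the
    reference.  Catches peptide-orientation errors that keep φ/ψ in allowed
    territory: the Cα trace (μ values) is untouched by a peptide flip while
    the carbonyl direction swings ~180°.
    """
    params = cablam_parameters(model)
    cab_out, cag_out = [], []
    for res, mu_in, mu_out, co, virt in params:
        key = (res.chain_id, res.number, res.name)
        if cablam_ref.is_outlier((mu_in, mu_out, co)):
            cab_out.append(key)
        if ca_geom_ref.is_outlier((mu_in, mu_out, virt)):
            cag_out.append(key)
    scored = {(r.chain_id, r.number, r.name) for r, *_ in params}
    unscored = [(r.chain_id, r.number, r.name) for r in model.iter_residues()
                if (r.chain_id, r.number, r.name) not in scored]
    n = len(params)
    return CablamReport(
        cablam=OutlierReport(len(cab_out) / n if n else None, n, cab_out, unscored),
        ca_geometry=OutlierReport(len(cag_out) / n if n else None, n, cag_out, unscored),
        parameters=[((r.chain_id, r.number, r.name), a, b, c, d)
                    for r, a, b, c, d in params],
    )


# ---------------------------------------------------------------------------
# Cis-peptides
# ---------------------------------------------------------------------------

def cis_peptides(model: AtomicModel) -> list[dict]:
    """Classify every peptide ω torsion as trans, cis or twisted.

    |ω| <= 30° is cis (split into cis-Pro and cis-nonPro by the following
    residue type); within 30° of 180° is trans; anything else is twisted.
    Returns one record per classified non-trans peptide bond.
    """
    records = []
    for chain in model.chains:
        for prv, nxt in zip(chain.residues, chain.residues[1:]):
            atoms = (prv.atom("CA"), prv.atom("C"), nxt.atom("N"), nxt.atom("CA"))
            if any(a is None for a in atoms):
                continue
            if bond_length(atoms[1].xyz, atoms[2].xyz) > 2.5:
                continue
            omega = dihedral(*(a.xyz for a in atoms))
            if abs(angular_diff(omega, 180.0)) <= 30.0:
                continue  # trans
            if abs(omega) <= 30.0:
                cls = "cis-Pro" if nxt.name == "PRO" else "cis-nonPro"
            else:
                cls = "twisted"
            records.append({
                "residue_pair": ((prv.chain_id, prv.number, prv.name),
                                 (nxt.chain_id, nxt.number, nxt.name)),
                "omega": float(omega),
                "class": cls,
            })
    return records


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

@dataclass
class GeometryReport:
    rmsd: GeometryRmsd
    clash: ClashReport
    rama: OutlierReport
    rotamer: OutlierReport
    cablam_report: CablamReport
    cis: list[dict]

    def summary(self) -> dict:
        return {
            "bond_rmsd": self.rmsd.bond,
            "angle_rmsd": self.rmsd.angle,
            "chiral_rmsd": self.rmsd.chiral,
            "planar_rmsd": self.rmsd.planar,
            "dihedral_rmsd": self.rmsd.dihedral,
            "clashscore": self.clash.score,
            "rama_outlier_fraction": self.rama.fraction,
            "rotamer_outlier_fraction": self.rotamer.fraction,
            "cablam_outlier_fraction": self.cablam_report.cablam.fraction,
            "ca_geom_outlier_fraction": self.cablam_report.ca_geometry.fraction,
            "n_cis_pro": sum(1 for r in self.cis if r["class"] == "cis-Pro"),
            "n_cis_nonpro": sum(1 for r in self.cis if r["class"] == "cis-nonPro"),
            "n_twisted": sum(1 for r in self.cis if r["class"] == "twisted"),
        }


def full_report(model: AtomicModel,
                lib: RestraintLibrary | None = None,
                rama_ref: ReferenceDistribution | None = None,
                rotamer_ref: ReferenceDistribution | None = None,
                cablam_refs=None, seed: int = 0) -> GeometryReport:
    """All coordinates-only scores in one pass with default references."""
    lib = lib or RestraintLibrary()
    if cablam_refs is None:
        cablam_refs = default_cablam_references(seed=seed)
    rama, rot = rama_rotamer_outliers(model, rama_ref, rotamer_ref)
    return GeometryReport(
        rmsd=geometry_rmsd(model, lib),
        clash=clashscore(model, lib=lib),
        rama=rama,
        rotamer=rot,
        cablam_report=cablam(model, *cablam_refs),
        cis=cis_peptides(model),
    )
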