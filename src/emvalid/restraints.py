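"""Ideal-geometry restraint library for the 20 standard amino acids.

The library ships as package data (``data/restraints.json``): backbone bond
lengths and angles from the standard protein dictionary, plus per-residue
side-chain templates in NeRF form (each atom defined by a bond length, bond
angle and torsion relative to three frame atoms).  The same templates drive
both the fixture builder (:mod:`emvalid.simulate`) and geometry validation
(:mod:`emvalid.coords_only`), so an unperturbed fixture scores zero RMSD by
construction.

Side-chain ideals are bond-class values (sp3 C-C 1.52-1.53 Å, aromatic
1.38-1.40 Å, and so on) rather than the full crystallographic dictionary;
they are a compact stand-in adequate for validating deviations, documented
as such.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np


__all__ = ["RestraintLibrary", "SidechainAtomSpec", "VDW_RADII", "ATOMIC_NUMBERS"]

# heavy-atom van der Waals radii (Å), used by clashscore and CAD
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "SE": 1.90, "ZN": 1.39, "FE": 1.40, "MG": 1.73}

ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15,
                  "SE": 34, "ZN": 30, "FE": 26, "MG": 12}

_TORSION_RE = re.compile(r"^(chi\d)([+-]\d+(?:\.\d+)?)?$")


@dataclass(frozen=True)
class SidechainAtomSpec:
    name: str
    element: str
    frame: tuple[str, str, str]   # (a, b, c); atom bonds to c
    bond: float
    angle: float
    torsion: str | float          # number or "chiN±offset"

    @property
    def parent(self) -> str:
        return self.frame[2]

    def resolve_torsion(self, chis: dict[str, float]) -> float:
        if isinstance(self.torsion, (int, float)):
            return float(self.torsion)
        m = _TORSION_RE.match(self.torsion)
        if not m:
            raise ValueError(f"bad torsion expression {self.torsion!r}")
        base = chis[m.group(1)]
        return base + (float(m.group(2)) if m.group(2) else 0.0)


class RestraintLibrary:
    """Ideal bonds, angles, chirality, planarity and torsion targets."""

    def __init__(self, data: dict | None = None):
        if data is None:
            text = resources.files("emvalid.data").joinpath("restraints.json").read_text()
            data = json.loads(text)
        self._data = data
        self.backbone_bonds = {k: tuple(v) for k, v in data["backbone_bonds"].items()}
        self.backbone_angles = {k: tuple(v) for k, v in data["backbone_angles"].items()}
        self.sidechains = {
            res: [SidechainAtomSpec(n, e, tuple(f), b, a,
                                    t if isinstance(t, (int, float)) else str(t))
                  for n, e, f, b, a, t in specs]
            for res, specs in data["sidechains"].items()
        }
        self.chi_defaults = dict(data["chi_defaults"])
        self.chi_overrides = {k: dict(v) for k, v in data["chi_overrides"].items()}
        self.sigma_bond = float(data["sigma_bond"])
        self.sigma_angle = float(data["sigma_angle"])
        self.planar_groups = {k: [list(g) for g in v]
                              for k, v in data["planar_groups"].items()}
        # ring-closure bonds: connectivity only (clash exclusion), not
        # restrained as internal coordinates
        self.ring_closures = {k: [tuple(b) for b in v]
                              for k, v in data.get("ring_closures", {}).items()}
        self.omega_ideal = float(data["omega_ideal"])
        self.omega_sigma = float(data["omega_sigma"])
        self._ideal_chiral_volume = self._compute_ideal_chiral_volume()

    def knows(self, resname: str) -> bool:
        return resname in self.sidechains or resname in ("ALA", "GLY")

    def default_chis(self, resname: str) -> dict[str, float]:
        chis = dict(self.chi_defaults)
        chis.update(self.chi_overrides.get(resname, {}))
        return chis

    # -- internal-coordinate enumeration used by geometry_rmsd ------------

    def intra_bonds(self, resname: str) -> list[tuple[str, str, float, float]]:
        """(atom1, atom2, ideal, sigma) for bonds within one residue."""
        out = [("N", "CA", *self.backbone_bonds["N-CA"]),
               ("CA", "C", *self.backbone_bonds["CA-C"]),
               ("C", "O", *self.backbone_bonds["C-O"])]
        if resname != "GLY":
            out.append(("CA", "CB", *self.backbone_bonds["CA-CB"]))
        for spec in self.sidechains.get(resname, []):
            out.append((spec.parent, spec.name, spec.bond, self.sigma_bond))
        return out

    def intra_angles(self, resname: str) -> list[tuple[str, str, str, float, float]]:
        """(a, b, c, ideal, sigma) for bond angles within one residue."""
        out = [("N", "CA", "C", *self.backbone_angles["N-CA-C"]),
               ("CA", "C", "O", *self.backbone_angles["CA-C-O"])]
        if resname != "GLY":
            out.append(("N", "CA", "CB", *self.backbone_angles["N-CA-CB"]))
        for spec in self.sidechains.get(resname, []):
            out.append((spec.frame[1], spec.frame[2], spec.name,
                        spec.angle, self.sigma_angle))
        return out

    def peptide_bond(self) -> tuple[float, float]:
        return self.backbone_bonds["C-N+"]

    def peptide_angles(self) -> dict[str, tuple[float, float]]:
        return {
            "CA-C-N+": self.backbone_angles["CA-C-N+"],
            "O-C-N+": self.backbone_angles["O-C-N+"],
            "C-N-CA": self.backbone_angles["C-N-CA"],
        }

    def planar_groups_for(self, resname: str) -> list[list[str]]:
        return self.planar_groups.get(resname, [])

    # -- chirality --------------------------------------------------------

    def _compute_ideal_chiral_volume(self) -> float:
        """CA chiral volume (N-CA)·((C-CA)×(CB-CA)) for ideal L geometry."""
        ca = np.zeros(3)
        n = np.array([self.backbone_bonds["N-CA"][0], 0.0, 0.0])
        ang_nc = np.radians(self.backbone_angles["N-CA-C"][0])
        c = self.backbone_bonds["CA-C"][0] * np.array(
            [np.cos(ang_nc), np.sin(ang_nc), 0.0])
        # place CB to satisfy both N-CA-CB and C-CA-CB ideals, above the plane
        cb = self.place_cb(n, ca, c)
        return float(np.dot(n - ca, np.cross(c - ca, cb - ca)))

    def place_cb(self, n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Ideal CB position for an L-amino acid given N, CA, C."""
        b = self.backbone_bonds["CA-CB"][0]
        t1 = np.radians(self.backbone_angles["N-CA-CB"][0])
        t2 = np.radians(self.backbone_angles["C-CA-CB"][0])
        u = n - ca
        u /= np.linalg.norm(u)
        v = c - ca
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        w /= np.linalg.norm(w)
        # solve cb_dir = x*u + y*v + z*w with cb_dir·u=cos t1, cb_dir·v=cos t2
        dot_uv = np.dot(u, v)
        A = np.array([[1.0, dot_uv], [dot_uv, 1.0]])
        rhs = np.array([np.cos(t1), np.cos(t2)])
        x, y = np.linalg.solve(A, rhs)
        rem = 1.0 - (x * x + y * y + 2 * x * y * dot_uv)
        z = np.sqrt(max(rem, 0.0))
        # L chirality: CB on the +w side (makes (N-CA)·((C-CA)×(CB-CA)) > 0)
        d = x * u + y * v + z * w
        return ca + b * d / np.linalg.norm(d)

    @property
    def ideal_chiral_volume(self) -> float:
        return self._ideal_chiral_volume
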