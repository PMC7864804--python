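"""Generate src/emvalid/data/restraints.json.

Engh–Huber-style ideal values: backbone internal coordinates from the
standard protein dictionary; side-chain bonds/angles from bond-class ideals.
Each side-chain atom is specified in NeRF form: (name, element,
[a, b, c] torsion-frame atom names, bond Å, angle deg, torsion expression).
Torsion expressions are either a number or "chiN[+offset]".
"""
import json, pathlib

BACKBONE_BONDS = {
    "N-CA": [1.458, 0.019],
    "CA-C": [1.525, 0.021],
    "C-O": [1.231, 0.020],
    "CA-CB": [1.530, 0.020],
    "C-N+": [1.329, 0.014],   # peptide link C(i)-N(i+1)
}
BACKBONE_ANGLES = {
    "N-CA-C": [111.2, 2.8],
    "CA-C-O": [120.8, 1.7],
    "CA-C-N+": [116.2, 2.0],
    "O-C-N+": [123.0, 1.6],
    "C-N-CA": [121.7, 1.8],   # C(i-1)-N(i)-CA(i)
    "N-CA-CB": [110.5, 1.7],
    "C-CA-CB": [110.1, 1.9],
}

# (name, element, (a, b, c), bond, angle, torsion)
T = {
 "ALA": [],
 "GLY": [],
 "SER": [("OG","O",("N","CA","CB"),1.417,110.8,"chi1")],
 "CYS": [("SG","S",("N","CA","CB"),1.808,114.4,"chi1")],
 "THR": [("OG1","O",("N","CA","CB"),1.433,109.6,"chi1"),
         ("CG2","C",("N","CA","CB"),1.521,110.5,"chi1-120")],
 "VAL": [("CG1","C",("N","CA","CB"),1.527,110.5,"chi1"),
         ("CG2","C",("N","CA","CB"),1.527,110.5,"chi1+120")],
 "LEU": [("CG","C",("N","CA","CB"),1.530,116.3,"chi1"),
         ("CD1","C",("CA","CB","CG"),1.521,110.7,"chi2"),
         ("CD2","C",("CA","CB","CG"),1.521,110.7,"chi2+120")],
 "ILE": [("CG1","C",("N","CA","CB"),1.530,110.4,"chi1"),
         ("CG2","C",("N","CA","CB"),1.521,110.5,"chi1-120"),
         ("CD1","C",("CA","CB","CG1"),1.513,113.8,"chi2")],
 "MET": [("CG","C",("N","CA","CB"),1.520,114.1,"chi1"),
         ("SD","S",("CA","CB","CG"),1.803,112.7,"chi2"),
         ("CE","C",("CB","CG","SD"),1.791,100.9,"chi3")],
 "PRO": [("CG","C",("N","CA","CB"),1.492,104.5,"chi1"),
         ("CD","C",("CA","CB","CG"),1.503,106.1,"chi2")],
 "PHE": [("CG","C",("N","CA","CB"),1.502,113.8,"chi1"),
         ("CD1","C",("CA","CB","CG"),1.384,120.8,"chi2"),
         ("CD2","C",("CA","CB","CG"),1.384,120.8,"chi2+180"),
         ("CE1","C",("CB","CG","CD1"),1.382,120.8,180.0),
         ("CE2","C",("CB","CG","CD2"),1.382,120.8,180.0),
         ("CZ","C",("CG","CD1","CE1"),1.382,120.0,0.0)],
 "TYR": [("CG","C",("N","CA","CB"),1.502,113.8,"chi1"),
         ("CD1","C",("CA","CB","CG"),1.384,120.8,"chi2"),
         ("CD2","C",("CA","CB","CG"),1.384,120.8,"chi2+180"),
         ("CE1","C",("CB","CG","CD1"),1.382,120.8,180.0),
         ("CE2","C",("CB","CG","CD2"),1.382,120.8,180.0),
         ("CZ","C",("CG","CD1","CE1"),1.382,120.0,0.0),
         ("OH","O",("CD1","CE1","CZ"),1.376,119.9,180.0)],
 "TRP": [("CG","C",("N","CA","CB"),1.498,113.6,"chi1"),
         ("CD1","C",("CA","CB","CG"),1.365,126.9,"chi2"),
         ("CD2","C",("CA","CB","CG"),1.433,126.8,"chi2+180"),
         ("NE1","N",("CB","CG","CD1"),1.374,110.2,180.0),
         ("CE2","C",("CB","CG","CD2"),1.409,107.2,180.0),
         ("CE3","C",("CB","CG","CD2"),1.398,133.9,0.0),
         ("CZ2","C",("CG","CD2","CE2"),1.394,122.4,180.0),
         ("CZ3","C",("CG","CD2","CE3"),1.382,118.6,180.0),
         ("CH2","C",("CD2","CE2","CZ2"),1.368,117.5,0.0)],
 "ASP": [("CG","C",("N","CA","CB"),1.516,112.6,"chi1"),
         ("OD1","O",("CA","CB","CG"),1.249,118.4,"chi2"),
         ("OD2","O",("CA","CB","CG"),1.249,118.4,"chi2+180")],
 "ASN": [("CG","C",("N","CA","CB"),1.516,112.6,"chi1"),
         ("OD1","O",("CA","CB","CG"),1.231,120.8,"chi2"),
         ("ND2","N",("CA","CB","CG"),1.328,116.4,"chi2+180")],
 "GLU": [("CG","C",("N","CA","CB"),1.520,114.1,"chi1"),
         ("CD","C",("CA","CB","CG"),1.516,112.6,"chi2"),
         ("OE1","O",("CB","CG","CD"),1.249,118.4,"chi3"),
         ("OE2","O",("CB","CG","CD"),1.249,118.4,"chi3+180")],
 "GLN": [("CG","C",("N","CA","CB"),1.520,114.1,"chi1"),
         ("CD","C",("CA","CB","CG"),1.516,112.6,"chi2"),
         ("OE1","O",("CB","CG","CD"),1.231,120.8,"chi3"),
         ("NE2","N",("CB","CG","CD"),1.328,116.4,"chi3+180")],
 "LYS": [("CG","C",("N","CA","CB"),1.520,114.1,"chi1"),
         ("CD","C",("CA","CB","CG"),1.520,111.3,"chi2"),
         ("CE","C",("CB","CG","CD"),1.520,111.3,"chi3"),
         ("NZ","N",("CG","CD","CE"),1.489,111.9,"chi4")],
 "ARG": [("CG","C",("N","CA","CB"),1.520,114.1,"chi1"),
         ("CD","C",("CA","CB","CG"),1.520,111.3,"chi2"),
         ("NE","N",("CB","CG","CD"),1.460,112.0,"chi3"),
         ("CZ","C",("CG","CD","NE"),1.329,124.2,"chi4"),
         ("NH1","N",("CD","NE","CZ"),1.326,120.0,0.0),
         ("NH2","N",("CD","NE","CZ"),1.326,120.0,180.0)],
 "HIS": [("CG","C",("N","CA","CB"),1.492,113.8,"chi1"),
         ("ND1","N",("CA","CB","CG"),1.380,122.7,"chi2"),
         ("CD2","C",("CA","CB","CG"),1.354,131.2,"chi2+180"),
         ("CE1","C",("CB","CG","ND1"),1.326,109.3,180.0),
         ("NE2","N",("CB","CG","CD2"),1.373,107.2,180.0)],
}

# default side-chain torsion values (deg) used by the fixture builder
CHI_DEFAULTS = {
    "chi1": -60.0, "chi2": 180.0, "chi3": 180.0, "chi4": 180.0,
}
CHI_OVERRIDES = {  # ring / branched geometries where trans is meaningless,
    # χ1 default is the common m rotamer (-60°)
    "PHE": {"chi2": 90.0}, "TYR": {"chi2": 90.0}, "TRP": {"chi2": -90.0},
    "HIS": {"chi2": -90.0}, "ASP": {"chi2": -20.0}, "ASN": {"chi2": -20.0},
    "PRO": {"chi1": 30.0, "chi2": -35.0},
}

SIGMA_BOND = 0.02   # generic side-chain sigmas
SIGMA_ANGLE = 2.0

# bonds closing rings that the NeRF tree cannot express; used for
# connectivity (clash exclusion), not restrained as internal coordinates
RING_CLOSURES = {
    "HIS": [["CE1", "NE2"]],
    "PHE": [["CE2", "CZ"]],
    "TYR": [["CE2", "CZ"]],
    "TRP": [["NE1", "CE2"], ["CZ3", "CH2"]],
    "PRO": [["CD", "N"]],
}

PLANAR = {
    "PHE": [["CG","CD1","CD2","CE1","CE2","CZ"]],
    "TYR": [["CG","CD1","CD2","CE1","CE2","CZ","OH"]],
    "TRP": [["CG","CD1","CD2","NE1","CE2","CE3","CZ2","CZ3","CH2"]],
    "HIS": [["CG","ND1","CD2","CE1","NE2"]],
    "ARG": [["NE","CZ","NH1","NH2"]],
    "ASP": [["CB","CG","OD1","OD2"]],
    "GLU": [["CG","CD","OE1","OE2"]],
    "ASN": [["CB","CG","OD1","ND2"]],
    "GLN": [["CG","CD","OE1","NE2"]],
}

out = {
    "backbone_bonds": BACKBONE_BONDS,
    "backbone_angles": BACKBONE_ANGLES,
    "sidechains": {k: [list(map(list, [x[2]])) and
                       [x[0], x[1], list(x[2]), x[3], x[4], x[5]] for x in v]
                   for k, v in T.items()},
    "chi_defaults": CHI_DEFAULTS,
    "chi_overrides": CHI_OVERRIDES,
    "sigma_bond": SIGMA_BOND,
    "sigma_angle": SIGMA_ANGLE,
    "planar_groups": PLANAR,
    "ring_closures": RING_CLOSURES,
    "omega_ideal": 180.0,
    "omega_sigma": 5.0,
}
path = pathlib.Path(__file__).resolve().parents[1] / "src/emvalid/data/restraints.json"
path.write_text(json.dumps(out, indent=1))
print("wrote", path, path.stat().st_size, "bytes")
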