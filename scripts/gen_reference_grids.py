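"""Generate synthetic rama/rotamer reference grids (package data).

Textbook allowed-region polygons rasterized on coarse grids; favored bins
weight 10, allowed bins weight 1.  These are synthetic stand-ins for grids
derived from curated PDB structures.
"""
import json
import numpy as np
import pathlib

def in_box(phi, psi, phl, phh, psl, psh):
    return (phl <= phi <= phh) and (psl <= psi <= psh)

nbins = 72
edges = np.linspace(-180, 180, nbins + 1)
centers = (edges[:-1] + edges[1:]) / 2
freq = np.zeros((nbins, nbins))
for i, phi in enumerate(centers):
    for j, psi in enumerate(centers):
        allowed = (
            in_box(phi, psi, -180, -45, 75, 180) or      # beta / PPII
            in_box(phi, psi, -180, -45, -180, -160) or   # beta wrap
            in_box(phi, psi, -160, -45, -80, 10) or      # alpha
            in_box(phi, psi, -130, -45, 10, 75) or       # alpha-beta bridge
            in_box(phi, psi, 30, 100, -25, 90)           # left-handed alpha
        )
        favored = (
            in_box(phi, psi, -155, -85, 105, 175) or
            in_box(phi, psi, -90, -45, -60, -25)
        )
        if favored:
            freq[i, j] = 10.0
        elif allowed:
            freq[i, j] = 1.0

rama = {
    "name": "rama-synthetic-general",
    "edges": [edges.tolist(), edges.tolist()],
    "shape": [nbins, nbins],
    "frequencies": freq.ravel().tolist(),
    "periodic": [True, True],
    "outlier_pct": 1.0,
    "disfavored_pct": 5.0,
}

nchi = 72
cedges = np.linspace(0, 360, nchi + 1)
ccent = (cedges[:-1] + cedges[1:]) / 2
cfreq = np.zeros(nchi)
for i, chi in enumerate(ccent):
    d = min(abs((chi - c + 180) % 360 - 180) for c in (60, 180, 300))
    if d <= 20:
        cfreq[i] = 10.0
    elif d <= 35:
        cfreq[i] = 1.0

rot = {
    "name": "rotamer-synthetic-chi1",
    "edges": [cedges.tolist()],
    "shape": [nchi],
    "frequencies": cfreq.tolist(),
    "periodic": [True],
    "outlier_pct": 1.0,
    "disfavored_pct": 5.0,
}

base = pathlib.Path(__file__).resolve().parents[1] / "src/emvalid/data"
(base / "rama_synthetic.json").write_text(json.dumps(rama))
(base / "rotamer_synthetic.json").write_text(json.dumps(rot))
for f in ("rama_synthetic.json", "rotamer_synthetic.json"):
    print(f, (base / f).stat().st_size, "bytes")
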