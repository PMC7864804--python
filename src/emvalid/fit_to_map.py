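"""Fit-to-Map metrics: how well a coordinate model explains a density map.

Two families live here.  Correlation-class metrics compare the experimental
map with a *model-map* simulated from the coordinates at a stated resolution
(CCbox/CCC over the full grid, CCmask over modeled regions, CCpeaks over
high-density regions, CCC_OV over the overlap region, Laplacian-filtered
correlation, mutual information, SMOC, map-model FSC).  For this class the
resolution used to make the model-map is an explicit input that changes the
score.  Atom-class metrics read the experimental map directly at model
positions (atom inclusion, the molecular-weight envelope score, Q-score atom
resolvability, EMRinger side-chain density peaks) and need no resolution
parameter.

Per-residue variants return a :class:`ResidueProfile`; residues that cannot
be scored carry an explicit ``covered=False`` flag rather than a fake zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geom import nerf_place
from .restraints import RestraintLibrary
from .voxmap_io import AtomicModel, DensityMap, Mask, interpolate, mask_from_model

__all__ = [
    "CCSet", "FSCCurve", "FSC05Result", "ResidueProfile", "QScoreResult",
    "EMRingerResult",
    "correlation_scores", "smoc_profile", "fsc_curve", "fsc05", "fsc_avg",
    "soft_mask_from_model", "atom_inclusion", "env_score", "qscore", "emringer",
]

# residues whose Cγ-equivalent is branched or absent: not EMRinger-eligible
_EMRINGER_INELIGIBLE = {"ALA", "GLY", "SER", "THR", "VAL", "ILE", "CYS", "PRO"}


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson r, or None when either side has zero variance."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size < 2:
        return None
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt((da * da).sum())
    nb = np.sqrt((db * db).sum())
    if na == 0.0 or nb == 0.0:
        return None
    return float(np.clip((da * db).sum() / (na * nb), -1.0, 1.0))


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    """MI (nats) of the joint histogram with equal-width bins per map."""
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class CCSet:
    """Named global map/model-map agreement scores.

    Correlation entries lie in [-1, 1]; MI entries are >= 0 nats.  An entry
    is ``None`` (and listed in ``undefined``) when its voxel selection had
    zero variance.
    """

    ccbox: float | None
    ccmask: float | None
    ccpeaks: float | None
    ccc: float | None
    ccc_ov: float | None
    lap: float | None
    mi: float
    mi_ov: float

    @property
    def undefined(self) -> list[str]:
        return [k for k in ("ccbox", "ccmask", "ccpeaks", "ccc", "ccc_ov", "lap")
                if getattr(self, k) is None]

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k)
                for k in ("ccbox", "ccmask", "ccpeaks", "ccc", "ccc_ov",
                          "lap", "mi", "mi_ov")}


@dataclass
class FSCCurve:
    """Shell-wise Fourier shell correlation between two maps."""

    centers: np.ndarray       # shell-center spatial frequencies, 1/Å
    values: np.ndarray        # FSC per shell, [-1, 1]
    counts: np.ndarray        # Fourier terms per shell
    nyquist: float            # 1/(2*voxel), 1/Å


@dataclass
class FSC05Result:
    resolution: float         # Å
    at_limit: bool            # True when the curve never crossed 0.5


@dataclass
class ResidueProfile:
    """Ordered per-residue scores; uncovered residues are flagged, not zeroed."""

    entries: list[tuple[str, int, str, float | None, bool]] = field(default_factory=list)

    def add(self, chain: str, number: int, name: str,
            score: float | None, covered: bool = True) -> None:
        self.entries.append((chain, number, name, score, covered))

    def scores(self) -> np.ndarray:
        return np.array([e[3] for e in self.entries if e[4] and e[3] is not None])

    def score_for(self, chain: str, number: int) -> float | None:
        for c, n, _, s, cov in self.entries:
            if c == chain and n == number:
                return s if cov else None
        return None


@dataclass
class QScoreResult:
    per_atom: list[tuple[str, int, str, float, bool]]  # chain, resnum, atom, Q, ok
    per_residue: ResidueProfile
    global_q: float | None

    @property
    def atom_scores(self) -> np.ndarray:
        return np.array([q for *_, q, ok in [(a, b, c, q, ok) for a, b, c, q, ok
                                             in self.per_atom] if ok])


@dataclass
class EMRingerResult:
    score: float
    n_scored: int             # residues above the chosen peak threshold
    threshold: float
    rotameric_fraction: float
    profile: ResidueProfile   # sliding-window rotameric fraction


# ---------------------------------------------------------------------------
# Correlation scores
# ---------------------------------------------------------------------------

def correlation_scores(density: DensityMap, model_map: DensityMap,
                       model: AtomicModel, mask_radius: float = 2.5,
                       mi_bins: int = 20) -> CCSet:
    """Global correlation-class scores between a map and a model-map.

    ``ccbox``/``ccc`` are Pearson over the full grid; ``ccmask`` restricts to
    voxels within ``mask_radius`` Å of the model; ``ccpeaks`` uses the union
    of each map's top-k voxels with k equal to the mask size; ``ccc_ov``
    uses the region where each map exceeds half its own masked mean;
    ``lap`` correlates discrete-Laplacian-filtered maps; ``mi``/``mi_ov``
    are mutual information (equal-width binning) over the full grid and the
    mask respectively.
    """
    density.require_congruent(model_map)
    a = density.values
    b = model_map.values

    mask = mask_from_model(density, model, mask_radius)
    sel = mask.values

    cc_all = _pearson(a, b)
    ccmask = _pearson(a[sel], b[sel]) if sel.any() else None

    k = int(sel.sum())
    if k > 0:
        top_a = np.zeros(a.size, dtype=bool)
        top_a[np.argpartition(a.ravel(), -k)[-k:]] = True
        top_b = np.zeros(b.size, dtype=bool)
        top_b[np.argpartition(b.ravel(), -k)[-k:]] = True
        peaks = (top_a | top_b).reshape(a.shape)
        ccpeaks = _pearson(a[peaks], b[peaks])
    else:
        ccpeaks = None

    if sel.any():
        ta = 0.5 * a[sel].mean()
        tb = 0.5 * b[sel].mean()
        overlap = (a > ta) & (b > tb)
        ccc_ov = _pearson(a[overlap], b[overlap]) if overlap.sum() >= 2 else None
        mi_ov = _mutual_information(a[sel], b[sel], mi_bins)
    else:
        ccc_ov, mi_ov = None, 0.0

    lap = _pearson(ndimage.laplace(a), ndimage.laplace(b))
    mi = _mutual_information(a, b, mi_bins)

    return CCSet(ccbox=cc_all, ccmask=ccmask, ccpeaks=ccpeaks, ccc=cc_all,
                 ccc_ov=ccc_ov, lap=lap, mi=mi, mi_ov=mi_ov)


# ---------------------------------------------------------------------------
# SMOC
# ---------------------------------------------------------------------------

def smoc_profile(density: DensityMap, model: AtomicModel,
                 model_map: DensityMap, window: int = 9,
                 mask_radius: float = 2.5) -> tuple[ResidueProfile, float | None]:
    """Sliding-window Manders' overlap of map and model-map near each residue.

    For the window centered at residue i, the Manders coefficient
    sum(a*b)/sqrt(sum(a^2)*sum(b^2)) is computed over voxels within
    ``mask_radius`` Å of any window atom.  ``window=1`` gives the
    single-residue variant; the default nine-residue window follows common
    practice for this score.  Returns the profile and the mean over scored
    residues.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    density.require_congruent(model_map)

    residues = list(model.iter_residues())
    voxsets: list[np.ndarray | None] = []
    for res in residues:
        sub = AtomicModel(chains=[])
        from .voxmap_io import Chain  # local import to avoid cycle noise
        sub.chains = [Chain(res.chain_id, [res])]
        if not res.heavy_atoms():
            voxsets.append(None)
            continue
        m = mask_from_model(density, sub, mask_radius)
        voxsets.append(np.flatnonzero(m.values.ravel()))

    a = density.values.ravel()
    b = model_map.values.ravel()
    half = window // 2
    profile = ResidueProfile()
    for i, res in enumerate(residues):
        lo = max(0, i - half)
        hi = min(len(residues), i + half + 1)
        idx_sets = [voxsets[j] for j in range(lo, hi)
                    if voxsets[j] is not None
                    and residues[j].chain_id == res.chain_id]
        if voxsets[i] is None or not idx_sets:
            profile.add(res.chain_id, res.number, res.name, None, covered=False)
            continue
        idx = np.unique(np.concatenate(idx_sets))
        num = float((a[idx] * b[idx]).sum())
        den = math.sqrt(float((a[idx] ** 2).sum()) * float((b[idx] ** 2).sum()))
        score = num / den if den > 0 else None
        profile.add(res.chain_id, res.number, res.name, score, covered=score is not None)
    scores = profile.scores()
    return profile, (float(scores.mean()) if scores.size else None)


# ---------------------------------------------------------------------------
# FSC
# ---------------------------------------------------------------------------

def soft_mask_from_model(density: DensityMap, model: AtomicModel,
                         radius: float = 3.0, taper: float = 3.0) -> np.ndarray:
    """Soft (cosine-tapered) model mask: 1 within ``radius`` Å of any heavy
    atom, cosine falloff to 0 over the next ``taper`` Å."""
    hard = mask_from_model(density, model, radius)
    dist_vox = ndimage.distance_transform_edt(
        ~hard.values, sampling=density.voxel_size)
    w = np.zeros(density.dims)
    w[hard.values] = 1.0
    ramp = (~hard.values) & (dist_vox < taper)
    w[ramp] = 0.5 * (1.0 + np.cos(np.pi * dist_vox[ramp] / taper))
    return w


def fsc_curve(map1: DensityMap, map2: DensityMap,
              soft_mask: np.ndarray | Mask | None = None) -> FSCCurve:
    """Fourier shell correlation between two congruent cubic-sampled maps.

    Shells are half-open, uniform-width frequency bins up to Nyquist.  An
    optional soft mask (weight grid, or a boolean Mask which is applied
    as-is) multiplies both maps first.
    """
    map1.require_congruent(map2)
    voxel = map1.voxel_size
    if not np.allclose(voxel, voxel[0]):
        raise ValueError("FSC requires cubic sampling (equal voxel sizes)")
    a = map1.values
    b = map2.values
    if soft_mask is not None:
        w = soft_mask.values.astype(float) if isinstance(soft_mask, Mask) else soft_mask
        if w.shape != a.shape:
            raise ValueError("soft mask shape mismatch")
        a = a * w
        b = b * w

    F1 = np.fft.fftn(a)
    F2 = np.fft.fftn(b)
    freqs = np.meshgrid(*[np.fft.fftfreq(n, d=voxel[0]) for n in a.shape],
                        indexing="ij")
    f = np.sqrt(sum(fr ** 2 for fr in freqs))
    nyquist = 1.0 / (2.0 * voxel[0])
    width = 1.0 / (min(a.shape) * voxel[0])
    # half-open shells [k*width, (k+1)*width); f/width is quantized to 1e-6
    # first so frequencies mathematically on a shell edge (axis-aligned
    # modes) bin deterministically despite float round-off
    shell = np.floor(np.round(f / width, 6)).astype(int)
    nshells = int(np.floor(nyquist / width)) + 1
    inside = (shell < nshells) & (f <= nyquist)

    idx = shell[inside]
    num = np.bincount(idx, weights=np.real(F1 * np.conj(F2))[inside], minlength=nshells)
    p1 = np.bincount(idx, weights=(np.abs(F1) ** 2)[inside], minlength=nshells)
    p2 = np.bincount(idx, weights=(np.abs(F2) ** 2)[inside], minlength=nshells)
    counts = np.bincount(idx, minlength=nshells)

    keep = counts > 0
    den = np.sqrt(p1[keep] * p2[keep])
    values = np.zeros(keep.sum())
    nz = den > 0
    values[nz] = num[keep][nz] / den[nz]
    centers = (np.arange(nshells)[keep] + 0.5) * width
    return FSCCurve(centers=centers, values=np.clip(values, -1.0, 1.0),
                    counts=counts[keep], nyquist=nyquist)


def fsc05(curve: FSCCurve) -> FSC05Result:
    """Resolution at the first downward crossing of FSC = 0.5.

    Linear interpolation between shell centers; if the curve never drops
    below 0.5, the Nyquist-limit resolution is returned with ``at_limit``
    set.
    """
    if curve.centers.size == 0:
        raise ValueError("empty FSC curve")
    f = curve.centers
    v = curve.values
    if v[0] < 0.5:
        # crossing before the first shell center: interpolate from (0, 1)
        frac = (1.0 - 0.5) / (1.0 - v[0])
        fx = frac * f[0]
        return FSC05Result(resolution=1.0 / fx, at_limit=False)
    for i in range(len(v) - 1):
        if v[i] >= 0.5 and v[i + 1] < 0.5:
            frac = (v[i] - 0.5) / (v[i] - v[i + 1])
            fx = f[i] + frac * (f[i + 1] - f[i])
            return FSC05Result(resolution=1.0 / fx, at_limit=False)
    return FSC05Result(resolution=1.0 / curve.nyquist, at_limit=True)


def fsc_avg(curve: FSCCurve, d_limit: float) -> float:
    """Term-count-weighted mean FSC over shells with frequency <= 1/d_limit."""
    if d_limit <= 0:
        raise ValueError("d_limit must be > 0")
    f_limit = 1.0 / d_limit
    if f_limit > curve.nyquist:
        raise ValueError(f"d_limit {d_limit} Å is beyond Nyquist "
                         f"({1.0 / curve.nyquist:.2f} Å)")
    sel = curve.centers <= f_limit
    if not sel.any():
        raise ValueError("no shells below the requested limit")
    w = curve.counts[sel]
    return float((curve.values[sel] * w).sum() / w.sum())


# ---------------------------------------------------------------------------
# Atom inclusion and envelope score
# ---------------------------------------------------------------------------

def atom_inclusion(density: DensityMap, model: AtomicModel,
                   threshold: float) -> tuple[float, ResidueProfile]:
    """Fraction of heavy atoms whose interpolated density is >= threshold.

    Atoms exactly at the threshold count as inside.  Returns the global
    fraction and a per-residue profile of the same quantity.
    """
    profile = ResidueProfile()
    n_in = 0
    n_tot = 0
    for res in model.iter_residues():
        atoms = res.heavy_atoms()
        if not atoms:
            profile.add(res.chain_id, res.number, res.name, None, covered=False)
            continue
        vals = interpolate(density, np.array([a.xyz for a in atoms]))
        inside = int((vals >= threshold).sum())
        profile.add(res.chain_id, res.number, res.name, inside / len(atoms))
        n_in += inside
        n_tot += len(atoms)
    if n_tot == 0:
        raise ValueError("model has no heavy atoms")
    return n_in / n_tot, profile


def env_score(density: DensityMap, model: AtomicModel, molecular_weight: float,
              vol_per_dalton: float = 1.21, penalty_weight: float = 1.0,
              mask_radius: float = 3.5) -> float:
    """Envelope-based inclusion score penalizing unmodeled density.

    A density threshold is chosen so the enclosed volume matches the sample
    molecular weight at ``vol_per_dalton`` Å³/Da.  The score is the fraction
    of heavy atoms inside that envelope minus ``penalty_weight`` times the
    fraction of envelope voxels farther than ``mask_radius`` Å from any
    atom, clamped to [-1, 1].  The default 3.5 Å treats a voxel as modeled
    when it lies within a van der Waals radius plus typical map blur of an
    atom; the MW-based threshold is deliberately generous at near-atomic
    resolution, which is exactly the behavior this score is known for.
    """
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be > 0")
    n_env = int(round(molecular_weight * vol_per_dalton / density.voxel_volume))
    if n_env >= density.values.size:
        raise ValueError("envelope volume exceeds the map grid")
    if n_env < 1:
        raise ValueError("envelope volume smaller than one voxel")
    flat = density.values.ravel()
    threshold = np.partition(flat, flat.size - n_env)[flat.size - n_env]
    envelope = density.values >= threshold

    coords = model.atom_coords(heavy_only=True)
    if coords.shape[0] == 0:
        raise ValueError("model has no heavy atoms")
    vals = interpolate(density, coords)
    frac_in = float((vals >= threshold).mean())

    near = mask_from_model(density, model, mask_radius).values
    n_envelope = int(envelope.sum())
    frac_far = float((envelope & ~near).sum() / n_envelope) if n_envelope else 0.0
    return float(np.clip(frac_in - penalty_weight * frac_far, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Q-score
# ---------------------------------------------------------------------------

def _shell_points(rng: np.random.Generator, n: int) -> np.ndarray:
    """n random unit vectors."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def qscore(density: DensityMap, model: AtomicModel, sigma_ref: float = 0.6,
           max_radius: float = 2.0, radial_step: float = 0.1,
           points_per_shell: int = 8, min_points: int = 12,
           seed: int = 0) -> QScoreResult:
    """Per-atom resolvability: correlation of local density with a reference
    Gaussian.

    For each heavy atom, the map is sampled on concentric shells (radii 0 to
    ``max_radius`` Å in steps of ``radial_step``, ``points_per_shell`` seeded
    points per shell), rejecting points that lie closer to another atom than
    to the scored one.  Q is the Pearson correlation between the sampled
    densities and the reference profile exp(-r²/(2·sigma_ref²)); because
    Pearson correlation is invariant to the amplitude A and offset B of the
    reference A·exp(-r²/(2σ²))+B, the calibration reduces to the radial
    shape.  The default σ of 0.6 Å makes a perfectly resolved atom in a
    ~1.5 Å map score 1.  Atoms with too few usable samples are flagged and
    excluded; flat local density yields Q = 0 with a flag.  The global score
    is the mean over scored atoms.
    """
    rng = np.random.default_rng(seed)
    coords = model.atom_coords(heavy_only=True)
    if coords.shape[0] == 0:
        raise ValueError("model has no heavy atoms")
    tree = cKDTree(coords)
    radii = np.arange(0.0, max_radius + 1e-9, radial_step)

    per_atom: list[tuple[str, int, str, float, bool]] = []
    residue_values: dict[tuple[str, int, str], list[float]] = {}
    atom_i = 0
    for res, atom in model.iter_atoms(heavy_only=True):
        pts = [atom.xyz]
        ref = [1.0]
        for r in radii[1:]:
            dirs = _shell_points(rng, points_per_shell)
            cand = atom.xyz + r * dirs
            _, nearest = tree.query(cand)
            keep = nearest == atom_i
            for p in cand[keep]:
                pts.append(p)
                ref.append(math.exp(-r * r / (2.0 * sigma_ref ** 2)))
        atom_i += 1
        if len(pts) < min_points:
            per_atom.append((res.chain_id, res.number, atom.name, 0.0, False))
            continue
        dens = interpolate(density, np.array(pts))
        # flat local density (to interpolation round-off) carries no signal
        if np.std(dens) <= 1e-9 * max(1.0, abs(float(np.mean(dens)))):
            per_atom.append((res.chain_id, res.number, atom.name, 0.0, False))
            continue
        q = _pearson(dens, np.array(ref))
        if q is None:
            per_atom.append((res.chain_id, res.number, atom.name, 0.0, False))
            continue
        per_atom.append((res.chain_id, res.number, atom.name, q, True))
        residue_values.setdefault((res.chain_id, res.number, res.name), []).append(q)

    profile = ResidueProfile()
    for (chain, num, name), vals in residue_values.items():
        profile.add(chain, num, name, float(np.mean(vals)))
    scored = [q for *_, q, ok in per_atom if ok]
    global_q = float(np.mean(scored)) if scored else None
    return QScoreResult(per_atom=per_atom, per_residue=profile, global_q=global_q)


# ---------------------------------------------------------------------------
# EMRinger
# ---------------------------------------------------------------------------

def _is_rotameric(angle: float, tolerance: float = 30.0) -> bool:
    return any(abs((angle - c + 180.0) % 360.0 - 180.0) <= tolerance
               for c in (60.0, 180.0, 300.0))


def emringer(density: DensityMap, model: AtomicModel, step: float = 5.0,
             window: int = 21, n_thresholds: int = 20,
             p0: float = 0.5, lib: RestraintLibrary | None = None) -> EMRingerResult:
    """Backbone validation from side-chain density peak positions.

    For every residue with an unbranched Cγ, χ1 is swept in ``step``-degree
    increments, interpolating map density at the implied Cγ position on the
    ring path about the Cα-Cβ axis.  A residue's peak is rotameric when the
    argmax angle falls within ±30° of 60°, 180° or 300°.  The global score
    is the binomial z-statistic of the rotameric count among residues whose
    peak density clears an acceptance threshold (null probability ``p0`` =
    1/2, since the three 60°-wide rotameric windows cover half the circle),
    maximized over a sweep of thresholds and rescaled by 10/sqrt(N); a
    model with every peak rotameric scores 10.  The per-residue profile is
    the sliding-window rotameric fraction.
    """
    lib = lib or RestraintLibrary()
    angles = np.arange(0.0, 360.0, step)
    records = []  # (res, peak_angle, peak_density, rotameric)
    for res in model.iter_residues():
        if res.name in _EMRINGER_INELIGIBLE:
            continue
        spec = next((s for s in lib.sidechains.get(res.name, [])
                     if s.torsion == "chi1"), None)
        n, ca, cb = res.atom("N"), res.atom("CA"), res.atom("CB")
        if spec is None or n is None or ca is None or cb is None:
            continue
        ring = np.array([nerf_place(n.xyz, ca.xyz, cb.xyz, spec.bond,
                                    spec.angle, ang) for ang in angles])
        dens = interpolate(density, ring)
        peak_i = int(np.argmax(dens))
        records.append((res, float(angles[peak_i]), float(dens[peak_i]),
                        _is_rotameric(float(angles[peak_i]))))
    if not records:
        raise ValueError("no EMRinger-eligible residues (unbranched Cγ) in model")

    peaks = np.array([r[2] for r in records])
    rot = np.array([r[3] for r in records])
    n_total = len(records)
    thresholds = np.linspace(peaks.min(), peaks.max(), n_thresholds)
    best = (-np.inf, thresholds[0], 0, 0.0)
    for t in thresholds:
        sel = peaks >= t
        n_sel = int(sel.sum())
        if n_sel == 0:
            continue
        k = int(rot[sel].sum())
        z = (k - n_sel * p0) / math.sqrt(n_sel * p0 * (1 - p0))
        # rescale by the total eligible count, not the subset size: a high
        # threshold that keeps only a few (rotameric) peaks should not be
        # able to saturate the score
        score = 10.0 * z / math.sqrt(n_total)
        if score > best[0]:
            best = (score, float(t), n_sel, k / n_sel)
    score, threshold, n_scored, frac = best

    profile = ResidueProfile()
    half = window // 2
    for i, (res, *_rest) in enumerate(records):
        lo = max(0, i - half)
        hi = min(len(records), i + half + 1)
        vals = [records[j][3] for j in range(lo, hi)
                if records[j][0].chain_id == res.chain_id]
        profile.add(res.chain_id, res.number, res.name,
                    float(np.mean(vals)) if vals else None,
                    covered=bool(vals))
    return EMRingerResult(score=float(score), n_scored=n_scored,
                          threshold=threshold, rotameric_fraction=float(frac),
                          profile=profile)
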