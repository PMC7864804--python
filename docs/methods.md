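# Methods

This note records the models, conventions and parameter choices behind each
module, what the synthetic data do and do not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## Containers and conventions

Density maps are regular orthogonal voxel grids stored x-fastest with
0-based indices; the Cartesian position of voxel (i, j, k) is
`origin + (i, j, k) · voxel_size`, all lengths in Å. MRC/CCP4 2014 files
(modes 0/1/2) are read through gemmi with axis order canonicalized from the
MAPC/MAPR/MAPS permutation; the origin comes from the ORIGIN record when
nonzero, otherwise from NXSTART/NYSTART/NZSTART scaled by the voxel size.
Non-orthogonal cells are refused: every supported use case is orthogonal,
and declaring the limit beats applying a wrong skew transform. Grids are
never resampled implicitly — operations that need congruent grids raise on
mismatch, because a silent regrid corrupts every correlation score computed
downstream; when a model-map must live on an experimental grid, it is
re-simulated on that geometry (`simulate_map_on_grid`).

Models are chain/residue/atom hierarchies with occupancies and isotropic B
factors. On parsing, alternate conformers are resolved by keeping the
highest-occupancy location (ties: first in file). `normalize_for_scoring`
removes hydrogens, zeroes all B factors and — only when *every* occupancy
in the file is zero, a submission convention that would null density-based
scores — resets occupancies to one. All metrics are defined on normalized
models so that depositor choices about predicted H atoms or B-factor
refinement cannot skew comparisons.

Trilinear interpolation serves all point-density queries; points outside
the grid return a configurable fill value (default 0, the background of a
masked map). Model masks select voxels whose centers lie within a radius of
any heavy atom.

## Synthetic data

### Fixtures

`build_fixture` grows ideal-geometry peptides by natural-extension-frame
(NeRF) placement from the shipped restraint library: helix φ = −57°,
ψ = −47°; strand φ = −120°, ψ = +120°; ω = 180°; a `two_segment` fixture is
helix then strand. Cβ is placed to satisfy both N-Cα-Cβ and C-Cα-Cβ ideal
angles on the L-chirality side (Cα chiral volume +2.50 Å³, matching the
standard dictionary sign). Side chains for all 20 amino acids are built
from per-residue NeRF templates with bond-class ideal values (sp³ C–C
1.52–1.53 Å, aromatic 1.38–1.40 Å, C–S 1.81 Å, …) rather than the full
crystallographic dictionary — a compact stand-in that is exactly consistent
with the validation module, so an unperturbed fixture scores zero geometry
RMSD by construction. Default side-chain torsions use the common *m*
rotamer (χ1 = −60°) with ring-specific overrides; the default sequence is
poly-Ala with leucine at every fourth position so χ1-bearing metrics always
have eligible residues. Ring-closure bonds that a NeRF tree cannot express
(e.g. His CE1–NE2) are recorded for connectivity (clash exclusion) but not
restrained, since the tree construction cannot guarantee their closure.

### Map simulation

Atoms contribute point density proportional to atomic number times
occupancy (a proxy for relative scattering weight), splatted trilinearly
onto the grid; under the `from-model` B-factor policy an atom is instead
spread as a Gaussian of width σ_B = √(B/8π²). The grid is then filtered in
Fourier space: a Gaussian envelope giving atoms an intrinsic width of
σ = 0.225 · d (the convention of common map simulators, which keeps density
compact and suppresses truncation ringing) times a cosine edge centered at
the cutoff frequency 1/d with full width 10% of the cutoff. Seeded white
Gaussian noise of a stated sd is added last. The simulation spec enforces
voxel ≤ d/2.5 so the target resolution is adequately sampled. No claim is
made that the FSC-measured resolution of the product equals d exactly; the
spectral content is checked empirically in tests. The simulator does not
model electron scattering-factor tables, solvent, CTF or half-map pairs;
sharpening state is "unsharpened".

### Perturbations

Controlled errors emulating real model-building failure classes, each
seeded and equal to the identity at magnitude zero:

- **jitter** — i.i.d. Gaussian displacement with a stated RMS norm
  (per-coordinate sd = RMS/√3);
- **peptide_flip** — the peptide unit after residue i (C(i), O(i), N(i+1))
  is rotated 180° about the Cα(i)–Cα(i+1) axis. Cα positions are untouched
  and ω stays trans: the Cα trace is right while the carbonyl points the
  wrong way, the classic near-3-Å error;
- **misthread** — residue type labels shift by k along the chain
  (cyclically), keeping backbone coordinates; side chains are rebuilt for
  the new type from the template, emulating a local sequence misalignment;
- **rotamer_swap** — side chains rotate about Cα–Cβ to a target χ1.

## Fit-to-Map metrics

- **CCbox / CCC** — Pearson correlation over the full grid; **CCmask** over
  voxels within the mask radius (default 2.5 Å) of the model; **CCpeaks**
  over the union of each map's top-k voxels with k equal to the mask voxel
  count (our concretization of "high-density map and model regions");
  **CCC_OV** over voxels where each map exceeds half its own masked mean.
  All are invariant to positive affine rescaling of either map; zero-variance
  selections yield an explicitly flagged undefined entry, never a fake 0.
- **LAP** — Pearson correlation of discrete-Laplacian-filtered maps.
- **MI / MI_OV** — mutual information (nats) of the joint histogram with 20
  equal-width bins per map by default, full-grid and masked. MI depends on
  the binning; the bin count is an exposed parameter.
- **SMOC** — per-residue sliding-window (default 9 residues, window 1 =
  single-residue variant) Manders' overlap Σ(ab)/√(Σa²Σb²) over voxels near
  the window's atoms. Scale-invariant for non-negative densities; the wide
  window trades localization for smoothness, which is exactly the
  insensitivity the single-residue variant avoids.
- **Map–model FSC** — shell-wise normalized cross-correlation of Fourier
  coefficients in uniform half-open frequency shells up to Nyquist
  (shell width = 1/(N·voxel); f/width is quantized to 1e-6 before binning
  so edge frequencies assign deterministically). An optional soft mask
  (model mask with a 3 Å cosine taper, configurable) multiplies both maps
  first. **FSC05** reads the first downward 0.5 crossing with linear
  interpolation between shell centers; a curve that never drops below 0.5
  returns the Nyquist-limit resolution with an explicit at-limit flag.
  **FSCavg** is the term-count-weighted mean over shells up to 1/d_limit;
  all shells from the origin are included.
- **Atom inclusion** — fraction of heavy atoms whose interpolated density
  is ≥ the threshold (ties count as inside), globally and per residue.
- **ENV** — a threshold is chosen so the enclosed volume equals molecular
  weight × 1.21 Å³/Da; the score is (fraction of atoms inside) −
  penalty_weight × (fraction of envelope voxels farther than 3.5 Å from any
  atom), clamped to [−1, 1]. The 3.5 Å default treats a voxel as modeled
  when it is within a van der Waals radius plus typical map blur of an
  atom; the MW-based threshold is deliberately generous at near-atomic
  resolution, which is this score's known behavior.
- ***Q*-score** — for each heavy atom the map is sampled on concentric
  shells (radii 0–2.0 Å, step 0.1 Å, 8 seeded points per shell), rejecting
  points closer to another atom (omitting overlap regions); Q is the
  Pearson correlation between sampled densities and the reference profile
  exp(−r²/2σ²) with σ = 0.6 Å. Pearson correlation is invariant to the
  amplitude A and offset B of the reference A·exp(−r²/2σ²)+B, so the
  calibration reduces to the radial shape: a perfectly resolved atom in a
  ~1.5 Å map scores 1, anti-correlated density scores −1. Atoms with fewer
  than 12 usable points are flagged missing; local density flat to
  interpolation round-off yields Q = 0 with a flag. The global score is the
  mean over scored atoms. Because samples are interpolated trilinearly, the
  calibration anchor is reproduced to ~1e-3, not exactly.
- **EMRinger** — for every residue with an unbranched Cγ (excluding
  Ala/Gly/Ser/Thr/Val/Ile/Cys/Pro), χ1 is swept in 5° steps and density is
  interpolated at the implied Cγ position about the Cα–Cβ axis; the peak is
  rotameric when its angle is within ±30° of 60°/180°/300°. The global
  score is the binomial z-statistic of the rotameric count among residues
  whose peak clears a density threshold (null p₀ = 1/2: three 60° windows
  cover half the circle), maximized over a 20-point threshold sweep and
  rescaled by 10/√N with N the *total* eligible count. Rescaling by the
  total rather than the above-threshold count matters: otherwise a high
  threshold that keeps a handful of rotameric peaks saturates the score.
  The closed-form maximum at 100% rotameric is 10·(1−p₀)/√(p₀(1−p₀)) = 10.
  The per-residue profile is the sliding-window rotameric fraction (default
  21 residues).

## Coordinates-only validation

Geometry RMSDs match internal coordinates against the restraint library:
bonds and angles (intra-residue plus peptide link), Cα chiral volume
against its +2.50 Å³ ideal (mirror images flagged), planarity as the RMS
out-of-plane distance over peptide planes and side-chain planar groups, and
the torsion term as ω deviations from the nearer of trans and cis. Unknown
residue types are skipped and counted.

Clashscore counts heavy-atom pairs with van der Waals overlap ≥ 0.4 Å per
1,000 atoms, excluding pairs within three bonds (1-2, 1-3 and 1-4): the 1-4
contacts across a trans peptide (O(i)···Cα(i+1) ≈ 2.77 Å) are fixed by the
connectivity, not by the modeler, and would otherwise flag every peptide
bond. Radii: C 1.70, N 1.55, O 1.52, S 1.80 Å.

Ramachandran, rotamer and CaBLAM outliers are calls against
`ReferenceDistribution` grids: binned, smoothed frequency maps scored by
coverage percentile (the share of reference mass in bins no more frequent
than the query's bin), with MolProbity-convention cutoffs of 1% (outlier)
and 5% (disfavored). The shipped φ×ψ and χ1 grids are *synthetic*: textbook
allowed-region polygons rasterized at 5° with favored/allowed weighting
(`data/rama_synthetic.json`, `data/rotamer_synthetic.json`), a stand-in for
grids derived from curated PDB structures — adequate for flagging gross
outliers, not for reproducing production outlier percentages. CaBLAM grids
have no textbook polygon form, so they are built from conformer ensembles
(`reference_from_models`); the default uses jittered ideal helix and strand
fixtures (0.12 Å RMS, 60 models each), which populates only the
regular-secondary-structure basins — loops score as outliers against it,
so it is suitable for fixtures and perturbation studies, not real proteins.

CaBLAM parameters per residue i: μ_in = dihedral(Cα i−2…i+1), μ_out =
dihedral(Cα i−1…i+2), the CO virtual dihedral taken over (O(i−1), C(i−1),
C(i), O(i)) — our concretization of "the dihedral between the CO groups
flanking residue i" — and the Cα virtual angle at i. The CaBLAM outlier
call uses the (μ_in, μ_out, CO) triplet; the Cα-geometry call uses
(μ_in, μ_out, angle). Chains break at Cα–Cα gaps > 4.5 Å (misthreads can
create long virtual bonds, so the cutoff is explicit); the first and last
two residues of a stretch are unscored. A peptide flip leaves μ_in/μ_out
untouched while the CO dihedral swings ~180°, which is why the triplet
catches flips whose φ/ψ stay in allowed territory.

Cis-peptides: |ω| ≤ 30° is cis (split cis-Pro / cis-nonPro by the following
residue), within 30° of 180° is trans, anything else twisted.

## Comparison metrics

Atom pairing is by identical chain id, residue number (+ insertion code)
and atom name — no sequence alignment; unmatched atoms are dropped and
counted. Superposition is least-squares (SVD with proper-rotation
enforcement); collinear point sets are rejected as degenerate. GDT
approximates the maximal simultaneously-superimposable subset by iterative
trimmed superposition restarted from the full set and every 5-residue
window (fit on seed, keep pairs within the cutoff, refit to convergence);
GDT-TS averages Cα fractions over cutoffs {1, 2, 4, 8} Å, GDC_all/GDC-SC
average all-atom/side-chain fractions over {0.5, 1.0, …, 5.0} Å. A
brute-force subset oracle bounds the approximation on small instances in
the tests. LDDT averages, over thresholds {0.5, 1, 2, 4} Å, the fraction of
reference heavy-atom pairs (different residues, within 15 Å) whose model
distance matches the reference within the threshold. CAD approximates
residue-pair contact areas by summed sphere–sphere overlap cap areas of
vdW+0.5 Å shells — an analytic stand-in for Voronoi contact surfaces — and
scores 1 − Σ min(|ΔA|, A_ref)/Σ A_ref. H-bond precision uses a heavy-atom
criterion (donor N, or side-chain O/N donor types, to acceptor O within
3.5 Å; no angle term since scoring is defined on H-stripped models) with
sequence separation > 6 (cross-chain pairs count as nonlocal); a model with
no nonlocal bonds is explicitly undefined. Davis-QA is each model's mean
pairwise GDT-TS against the rest of the pool.

## Meta-analysis

Correlation matrices use pairwise-complete observations (minimum 3);
per-target-averaged matrices average the per-target coefficients, which
removes between-target score-range differences. Clustering is complete-
linkage agglomeration on 1 − |r| — the absolute value merges perfectly
anti-correlated metrics first, since they carry the same information —
with metric order canonicalized lexicographically for deterministic
tie-breaks; the number of clusters is a required argument and merge heights
are returned for inspection. Signed correlations are computed on raw metric
orientations (display convention; the |r| clustering is unaffected).
Composite Z-scores standardize each metric within each target over that
target's models, negate lower-is-better metrics, and sum with the declared
weights; the three bundled weight sets are coordinates-only
(CaBLAM 0.5 / Cα-geometry 0.3 / clashscore 0.2), fit-to-map (EMRinger 0.3 /
Q 0.3 / atom inclusion 0.2 / SMOC 0.2) and versus-reference (LDDT 0.9 /
GDC_all 0.9 / HBPR>6 0.2). Missing data are never imputed: a metric with
missing or zero-variance scores within a target is dropped for that target
and recorded. Rankings refuse metrics without a declared orientation —
silent sign errors are the worst failure mode of composite scores.
Percentile summaries use the linear-interpolation convention (stated
because box/whisker reproduction depends on it); coincident quartiles are
flagged degenerate. `planted_score_table` generates tables with a known
metric block structure (63 models over pseudo-targets of 16/15/15/17) for
validating cluster recovery.

## Study conditions used by the behavioral tests

The resolution-series test simulates one 48-residue helix (Leu at every
third position) at 1.8/2.3/3.1 Å (voxel 0.6 Å, noise sd 0.16) and scores an
imperfect model whose Leu Cα/Cβ frames are exact while all other atoms
carry 1.2 Å RMS error — the backbone-trace-right, detail-wrong situation
typical of near-atomic model building. Metric values are averaged over four
noise realizations per resolution to damp seed-to-seed variation. Under
these conditions Q-score, EMRinger and FSC05 track map quality
monotonically, while the masked correlation computed against
resolution-matched model-maps does not improve monotonically: the finer
detail a model-map must reproduce, the more the model's error costs, which
offsets the gain from a better map. The noise-sensitivity test confines
noise to the map background (> 3.5 Å from any atom) at three levels;
full-grid CCC/MI/ENV degrade strictly more than CCmask/MI_OV, whose
selections exclude the background entirely. The flip test applies 50
peptide flips along a 60-residue helix: every flip is caught by the CaBLAM
triplet (or cis-peptide detection) while the flip-site residue stays in
allowed φ/ψ territory — its ψ moves from the helical to the extended basin.

Problem sizes throughout (fixtures of 12–60 residues, grids up to ~50³
voxels, 1,000-map score batches, 100 clustering replicates) were chosen as
the smallest at which each property is stable and fast to check.

## Known limitations

Side-chain ideals are bond-class values, not the full crystallographic
dictionary; geometry RMSDs on real structures will include that systematic
difference. The shipped conformational references are synthetic or
ensemble-built stand-ins, so outlier *fractions* on real proteins are not
comparable to production validation servers, though gross outliers are
flagged correctly. The map simulator omits scattering-factor tables,
solvent and frequency-dependent noise, so passing trend tests demonstrates
the metrics' behavior under controlled blur and additive noise, not their
quantitative values on experimental reconstructions. GDT is an iterative
approximation to an exhaustive search; CAD uses sphere-overlap areas, not
Voronoi surfaces; H-bond detection is distance-only. Half-map
cross-validation, map sharpening effects, ligand/water/metal validation and
nucleic acids are out of scope.
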