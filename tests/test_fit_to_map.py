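"""Fit-to-Map metrics against brute-force oracles and construction cases."""

import math

import numpy as np
import pytest

from emvalid.fit_to_map import (
    FSCCurve, atom_inclusion, correlation_scores, emringer, env_score, fsc05,
    fsc_avg, fsc_curve, qscore, smoc_profile,
)
from emvalid.simulate import (
    FixtureSpec, PerturbationSpec, SimulationSpec, build_fixture, perturb,
    simulate_map, simulate_map_on_grid,
)
from emvalid.voxmap_io import Atom, AtomicModel, Chain, DensityMap, Residue


def _one_atom(xyz=(0.0, 0.0, 0.0)):
    return AtomicModel([Chain("A", [Residue("A", 1, "ALA",
                                            [Atom("CA", "C", xyz)])])])


def _gaussian_map(sigma=0.6, amp=2.0, offset=0.1, voxel=0.4, n=31):
    grid = (np.arange(n) - n // 2) * voxel
    X, Y, Z = np.meshgrid(grid, grid, grid, indexing="ij")
    vals = amp * np.exp(-(X**2 + Y**2 + Z**2) / (2 * sigma**2)) + offset
    return DensityMap(vals, (voxel,) * 3, (grid[0],) * 3)


def _pearson_oracle(a, b):
    """Definitional Pearson r, written out term by term."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def _mi_oracle(a, b, bins):
    """Plug-in MI from the joint histogram, double loop."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    ha = np.linspace(a.min(), a.max(), bins + 1)
    hb = np.linspace(b.min(), b.max(), bins + 1)
    joint = np.zeros((bins, bins))
    for x, y in zip(a, b):
        i = min(np.searchsorted(ha, x, side="right") - 1, bins - 1)
        j = min(np.searchsorted(hb, y, side="right") - 1, bins - 1)
        joint[i, j] += 1
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if p[i, j] > 0:
                mi += p[i, j] * math.log(p[i, j] / (px[i] * py[j]))
    return mi


class TestCorrelationScores:
    def test_self_correlation_is_one(self, helix12, helix12_map):
        cc = correlation_scores(helix12_map, helix12_map, helix12)
        for key in ("ccbox", "ccmask", "ccpeaks", "ccc", "ccc_ov", "lap"):
            assert getattr(cc, key) == pytest.approx(1.0)

    def test_anticorrelation(self, helix12, helix12_map):
        neg = DensityMap(-helix12_map.values, helix12_map.voxel_size,
                         helix12_map.origin)
        cc = correlation_scores(helix12_map, neg, helix12)
        assert cc.ccc == pytest.approx(-1.0)
        assert cc.ccbox == pytest.approx(-1.0)

    def test_fixed_grid_matches_brute_force(self):
        a = np.array([[[1, 5, 2], [0, 3, 3], [7, 1, 4]],
                      [[2, 2, 0], [6, 1, 5], [3, 8, 2]],
                      [[4, 0, 1], [2, 9, 3], [5, 2, 6]]], float)
        b = np.array([[[2, 4, 1], [1, 2, 5], [6, 2, 3]],
                      [[1, 3, 1], [5, 0, 4], [2, 7, 3]],
                      [[3, 1, 2], [1, 8, 2], [6, 1, 5]]], float)
        da = DensityMap(a, (1, 1, 1))
        db = DensityMap(b, (1, 1, 1))
        cc = correlation_scores(da, db, _one_atom((1.0, 1.0, 1.0)),
                                mask_radius=5.0, mi_bins=2)
        assert cc.ccbox == pytest.approx(_pearson_oracle(a, b), abs=1e-9)
        assert cc.mi == pytest.approx(_mi_oracle(a, b, 2), abs=1e-9)

    def test_affine_invariance_of_correlations(self, helix12, helix12_map):
        model_map = simulate_map_on_grid(helix12, helix12_map, 2.3)
        base = correlation_scores(helix12_map, model_map, helix12)
        scaled = DensityMap(3.5 * model_map.values + 7.0,
                            model_map.voxel_size, model_map.origin)
        after = correlation_scores(helix12_map, scaled, helix12)
        for key in ("ccbox", "ccmask", "ccc", "lap"):
            assert getattr(after, key) == pytest.approx(getattr(base, key),
                                                        abs=1e-9)

    def test_zero_variance_flagged(self, helix12, helix12_map):
        flat = DensityMap(np.full(helix12_map.dims, 2.0),
                          helix12_map.voxel_size, helix12_map.origin)
        cc = correlation_scores(helix12_map, flat, helix12)
        assert "ccbox" in cc.undefined
        assert cc.ccbox is None

    def test_incongruent_grids_rejected(self, helix12, helix12_map):
        other = DensityMap(helix12_map.values, helix12_map.voxel_size,
                           helix12_map.origin + 1.0)
        from emvalid.voxmap_io import GridMismatchError
        with pytest.raises(GridMismatchError):
            correlation_scores(helix12_map, other, helix12)


@pytest.fixture(scope="module")
def displaced_setup(helix12, helix12_map):
    bad = helix12.copy()
    res = bad.chains[0].residues[6]
    # displace into empty density while staying inside the map grid
    for a in res.atoms:
        a.xyz = a.xyz + np.array([0.0, 7.0, 0.0])
    model_map = simulate_map_on_grid(bad, helix12_map, 2.3)
    return bad, model_map


@pytest.fixture(scope="module")
def leu_rich():
    return build_fixture(FixtureSpec("helix", 16, sequence="ALLALLALLALLALLA"))


class TestSMOC:
    def test_scaled_map_scores_one_everywhere(self, helix12, helix12_map):
        scaled = DensityMap(3.0 * helix12_map.values, helix12_map.voxel_size,
                            helix12_map.origin)
        profile, global_score = smoc_profile(helix12_map, helix12, scaled)
        assert global_score == pytest.approx(1.0)
        assert all(s == pytest.approx(1.0) for *_, s, cov in profile.entries
                   if cov)

    def test_displaced_residue_is_window1_minimum(self, helix12_map,
                                                  displaced_setup):
        bad, model_map = displaced_setup
        profile, _ = smoc_profile(helix12_map, bad, model_map, window=1)
        scores = {num: s for _, num, _, s, cov in profile.entries if cov}
        assert min(scores, key=scores.get) == 7

    def test_wide_window_dilutes_the_error(self, helix12_map, displaced_setup):
        bad, model_map = displaced_setup
        p1, _ = smoc_profile(helix12_map, bad, model_map, window=1)
        p9, _ = smoc_profile(helix12_map, bad, model_map, window=9)
        s1 = {num: s for _, num, _, s, cov in p1.entries if cov}
        s9 = {num: s for _, num, _, s, cov in p9.entries if cov}
        # the deep single-residue dip becomes shallower ...
        assert s9[7] > s1[7]
        # ... and spreads across at least the window span
        depressed9 = [n for n, s in s9.items() if s < 0.95]
        depressed1 = [n for n, s in s1.items() if s < 0.95]
        assert len(depressed9) >= len(depressed1)
        assert len(depressed9) >= 5

    def test_even_window_rejected(self, helix12, helix12_map):
        with pytest.raises(ValueError):
            smoc_profile(helix12_map, helix12, helix12_map, window=4)


class TestFSC:
    def test_identical_maps_unity(self, helix12_map):
        curve = fsc_curve(helix12_map, helix12_map)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-9)

    def test_independent_noise_near_zero(self, rng):
        a = DensityMap(rng.normal(size=(24, 24, 24)), (1, 1, 1))
        b = DensityMap(rng.normal(size=(24, 24, 24)), (1, 1, 1))
        curve = fsc_curve(a, b)
        se = 1.0 / np.sqrt(curve.counts)
        assert abs(np.mean(curve.values / se) / np.sqrt(len(se))) < 3.0

    def test_fsc_decreases_with_noise(self, helix12, rng):
        base = simulate_map(helix12, SimulationSpec(resolution=2.3,
                                                    voxel_size=0.8, seed=0))
        means = []
        for sd in (0.05, 0.2, 0.8):
            noisy = DensityMap(base.values
                               + rng.normal(0, sd, size=base.dims),
                               base.voxel_size, base.origin)
            means.append(fsc_curve(base, noisy).values.mean())
        assert means[0] > means[1] > means[2]

    def test_fsc05_at_nyquist_limit(self):
        curve = FSCCurve(centers=np.array([0.1, 0.2, 0.3, 0.4]),
                         values=np.array([1.0, 0.95, 0.9, 0.8]),
                         counts=np.array([10, 20, 30, 40]), nyquist=0.5)
        r = fsc05(curve)
        assert r.at_limit
        assert r.resolution == pytest.approx(2.0)

    def test_fsc05_exact_shell_crossing(self):
        curve = FSCCurve(centers=np.array([0.15, 0.25, 0.35]),
                         values=np.array([0.9, 0.5, 0.1]),
                         counts=np.array([1, 1, 1]), nyquist=0.5)
        r = fsc05(curve)
        assert not r.at_limit
        assert r.resolution == pytest.approx(4.0)

    def test_fsc05_linear_interpolation(self):
        curve = FSCCurve(centers=np.array([0.20, 0.30]),
                         values=np.array([0.8, 0.2]),
                         counts=np.array([1, 1]), nyquist=0.5)
        assert fsc05(curve).resolution == pytest.approx(4.0)

    def test_fsc_avg_weighted_mean(self):
        curve = FSCCurve(centers=np.array([0.1, 0.2]),
                         values=np.array([1.0, 0.5]),
                         counts=np.array([10, 30]), nyquist=0.25)
        assert fsc_avg(curve, d_limit=4.0) == pytest.approx(0.625)
        assert fsc_avg(curve, d_limit=8.0) == pytest.approx(1.0)

    def test_fsc_avg_constant_curves(self):
        for const in (1.0, 0.5):
            curve = FSCCurve(centers=np.array([0.1, 0.2, 0.3]),
                             values=np.full(3, const),
                             counts=np.array([5, 9, 13]), nyquist=0.4)
            assert fsc_avg(curve, 2.5) == pytest.approx(const)

    def test_fsc_avg_beyond_nyquist_rejected(self):
        curve = FSCCurve(centers=np.array([0.1]), values=np.array([1.0]),
                         counts=np.array([5]), nyquist=0.25)
        with pytest.raises(ValueError):
            fsc_avg(curve, 1.0)

    def test_soft_mask_reduces_background_contribution(self, helix12):
        from emvalid.fit_to_map import soft_mask_from_model
        base = simulate_map(helix12, SimulationSpec(resolution=2.3,
                                                    voxel_size=0.8, seed=0))
        rng = np.random.default_rng(7)
        noisy = DensityMap(base.values + rng.normal(0, 0.5, size=base.dims),
                           base.voxel_size, base.origin)
        w = soft_mask_from_model(base, helix12)
        raw = fsc_curve(base, noisy).values.mean()
        masked = fsc_curve(base, noisy, soft_mask=w).values.mean()
        assert masked > raw


class TestAtomInclusion:
    def _two_atom_map(self):
        vals = np.zeros((8, 8, 8))
        vals[2, 2, 2] = 0.9
        vals[5, 5, 5] = 0.1
        dm = DensityMap(vals, (1, 1, 1))
        model = AtomicModel([Chain("A", [
            Residue("A", 1, "ALA", [Atom("CA", "C", (2, 2, 2))]),
            Residue("A", 2, "ALA", [Atom("CA", "C", (5, 5, 5))])])])
        return dm, model

    def test_half_inside(self):
        dm, model = self._two_atom_map()
        frac, _ = atom_inclusion(dm, model, threshold=0.5)
        assert frac == pytest.approx(0.5)

    def test_threshold_below_min_gives_all(self):
        dm, model = self._two_atom_map()
        frac, _ = atom_inclusion(dm, model, threshold=-1.0)
        assert frac == 1.0

    def test_tie_counts_as_inside(self):
        dm, model = self._two_atom_map()
        frac, _ = atom_inclusion(dm, model, threshold=0.1)
        assert frac == 1.0

    def test_global_equals_atom_weighted_profile_mean(self, helix12,
                                                      helix12_map):
        t = 0.3 * helix12_map.values.max()
        frac, profile = atom_inclusion(helix12_map, helix12, t)
        weights = [len(r.heavy_atoms()) for r in helix12.iter_residues()]
        per_res = [s for *_, s, cov in profile.entries if cov]
        assert frac == pytest.approx(np.average(per_res, weights=weights))


class TestEnvScore:
    # 9 Ala (71 Da) + 3 Leu (113 Da): the fixture's actual molecular weight
    MW = 9 * 71.0 + 3 * 113.0

    def test_self_consistent_model_scores_high(self, helix12, helix12_map):
        score = env_score(helix12_map, helix12, molecular_weight=self.MW)
        assert score > 0.9

    def test_translated_model_scores_poorly(self, helix12, helix12_map):
        off = helix12.transformed(np.eye(3), np.array([40.0, 40.0, 40.0]))
        score = env_score(helix12_map, off, molecular_weight=self.MW)
        assert score <= 0.0

    def test_penalty_weight_monotone(self, helix12, helix12_map):
        s1 = env_score(helix12_map, helix12, self.MW, penalty_weight=1.0)
        s2 = env_score(helix12_map, helix12, self.MW, penalty_weight=2.0)
        assert s2 <= s1

    def test_oversized_envelope_rejected(self, helix12, helix12_map):
        with pytest.raises(ValueError):
            env_score(helix12_map, helix12, molecular_weight=1e9)


class TestQScore:
    def test_exact_reference_gaussian_scores_one(self):
        dm = _gaussian_map()
        res = qscore(dm, _one_atom())
        assert res.global_q == pytest.approx(1.0, abs=2e-3)

    def test_inverted_gaussian_scores_minus_one(self):
        dm = _gaussian_map()
        inv = DensityMap(-dm.values, dm.voxel_size, dm.origin)
        res = qscore(inv, _one_atom())
        assert res.global_q == pytest.approx(-1.0, abs=2e-3)
        assert res.global_q >= -1.0

    def test_flat_density_flagged_zero(self):
        dm = DensityMap(np.full((16, 16, 16), 3.0), (0.5,) * 3, (-4,) * 3)
        res = qscore(dm, _one_atom())
        assert res.per_atom[0][4] is False
        assert res.global_q is None

    def test_improves_with_resolution(self, helix12):
        qs = []
        for d in (3.1, 2.3, 1.8):
            dm = simulate_map(helix12, SimulationSpec(resolution=d,
                                                      voxel_size=0.7, seed=3))
            qs.append(qscore(dm, helix12).global_q)
        assert qs[0] < qs[1] < qs[2]

    def test_global_is_mean_of_per_atom(self, helix12, helix12_map):
        res = qscore(helix12_map, helix12)
        scored = [q for *_, q, ok in res.per_atom if ok]
        assert res.global_q == pytest.approx(np.mean(scored), abs=1e-12)

    def test_deterministic_under_seed(self, helix12, helix12_map):
        a = qscore(helix12_map, helix12, seed=3)
        b = qscore(helix12_map, helix12, seed=3)
        assert a.global_q == b.global_q


class TestEMRinger:
    def test_all_trans_chi1_scores_at_closed_form(self, leu_rich):
        model = perturb(leu_rich, PerturbationSpec("rotamer_swap", 180.0))
        dm = simulate_map(model, SimulationSpec(resolution=1.8, voxel_size=0.6,
                                                seed=2))
        result = emringer(dm, model)
        assert result.rotameric_fraction == 1.0
        p0 = 0.5
        closed_form = 10.0 * (1 - p0) / math.sqrt(p0 * (1 - p0))
        assert result.score == pytest.approx(closed_form, abs=1e-9)

    def test_nonrotameric_chi1_scores_nonpositive(self, leu_rich):
        model = perturb(leu_rich, PerturbationSpec("rotamer_swap", 120.0))
        dm = simulate_map(model, SimulationSpec(resolution=1.8, voxel_size=0.6,
                                                seed=2))
        result = emringer(dm, model)
        assert result.rotameric_fraction <= 0.5
        assert result.score <= 0.0

    def test_poly_ala_has_no_eligible_residues(self, helix12_map):
        poly_ala = build_fixture(FixtureSpec("helix", 12, sequence="A" * 12))
        with pytest.raises(ValueError, match="eligible"):
            emringer(helix12_map, poly_ala)
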