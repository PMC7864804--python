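"""Stereochemistry and conformation validation."""

import numpy as np
import pytest

from emvalid.coords_only import (
    ReferenceDistribution, cablam, cis_peptides, clashscore, geometry_rmsd,
    load_rama_reference, load_rotamer_reference, phi_psi_list,
    rama_rotamer_outliers, reference_from_models,
)
from emvalid.geom import rotate_about_line, rotation_about_axis
from emvalid.simulate import FixtureSpec, PerturbationSpec, build_fixture, perturb
from emvalid.voxmap_io import Atom, AtomicModel, Chain, Residue


@pytest.fixture(scope="module")
def helix_ensemble_rama():
    """φ/ψ reference built from jittered ideal helices."""
    base = build_fixture(FixtureSpec("helix", 16))
    models = [perturb(base, PerturbationSpec("jitter", 0.1, seed=s))
              for s in range(40)]
    return reference_from_models("rama-helix-ensemble", models, "rama",
                                 bins=[36, 36], smooth_sigma_bins=1.5)


class TestGeometryRmsd:
    def test_ideal_fixture_scores_zero(self, helix12, lib):
        g = geometry_rmsd(helix12, lib)
        for value in (g.bond, g.angle, g.chiral, g.planar, g.dihedral):
            assert value < 1e-6

    def test_single_stretched_bond_arithmetic(self, helix12, lib):
        bent = helix12.copy()
        res = bent.chains[0].residues[4]
        c, o = res.atom("C"), res.atom("O")
        # stretch C-O by +0.02 Å along the bond: angles and planes unchanged
        direction = (o.xyz - c.xyz) / np.linalg.norm(o.xyz - c.xyz)
        o.xyz = o.xyz + 0.02 * direction
        g = geometry_rmsd(bent, lib)
        assert g.bond == pytest.approx(0.02 / np.sqrt(g.n_bonds), abs=1e-9)
        assert g.angle < 1e-6

    def test_mirror_image_flagged_by_chirality(self, helix12, lib):
        mirrored = helix12.copy()
        for _, atom in mirrored.iter_atoms():
            atom.xyz = atom.xyz * np.array([-1.0, 1.0, 1.0])
        g = geometry_rmsd(mirrored, lib)
        # every deviation is (-V_ideal) - V_ideal: twice the ideal volume
        assert g.chiral == pytest.approx(2 * lib.ideal_chiral_volume, abs=1e-6)
        assert len(g.chiral_outliers) == g.n_chirals

    def test_unknown_residue_skipped_and_counted(self, lib):
        model = AtomicModel([Chain("A", [
            Residue("A", 1, "XYZ", [Atom("CA", "C", (0, 0, 0))])])])
        g = geometry_rmsd(model, lib)
        assert g.skipped_residues == [("A", 1, "XYZ")]

    def test_rigid_motion_invariance(self, helix12, lib):
        R = rotation_about_axis((1, 1, 0), 77.0)
        moved = helix12.transformed(R, np.array([10.0, -4.0, 2.0]))
        g0 = geometry_rmsd(helix12, lib)
        g1 = geometry_rmsd(moved, lib)
        assert g1.bond == pytest.approx(g0.bond, abs=1e-9)
        assert g1.angle == pytest.approx(g0.angle, abs=1e-9)
        assert g1.chiral == pytest.approx(g0.chiral, abs=1e-9)

    def test_jitter_ladder_monotone(self, helix20, lib):
        bonds = []
        for rms in (0.1, 0.3, 0.6):
            j = perturb(helix20, PerturbationSpec("jitter", rms, seed=4))
            bonds.append(geometry_rmsd(j, lib).bond)
        assert bonds[0] < bonds[1] < bonds[2]


class TestClashscore:
    def _free_pair(self, d):
        return AtomicModel([Chain("A", [
            Residue("A", 1, "UNK", [Atom("C1", "C", (0, 0, 0))]),
            Residue("A", 5, "UNK", [Atom("C2", "C", (d, 0, 0))])])])

    def test_printed_overlap_rule(self):
        report = clashscore(self._free_pair(3.0))
        assert len(report.clashes) == 1
        assert report.score == pytest.approx(500.0)

    def test_just_beyond_cutoff_is_clean(self):
        assert clashscore(self._free_pair(3.05)).score == 0.0

    def test_bonded_pair_excluded(self):
        model = AtomicModel([Chain("A", [Residue("A", 1, "ALA", [
            Atom("N", "N", (0, 0, 0)),
            Atom("CA", "C", (1.458, 0, 0)),
        ])])])
        assert clashscore(model).score == 0.0

    def test_monotone_under_approach(self):
        scores = [clashscore(self._free_pair(d)).score
                  for d in (3.2, 3.0, 2.5, 2.0)]
        assert all(a <= b for a, b in zip(scores, scores[1:]))

    def test_ideal_fixtures_are_clash_free(self, helix12, strand8):
        assert clashscore(helix12).score == 0.0
        assert clashscore(strand8).score == 0.0


class TestRamaRotamer:
    def test_ideal_helix_clean_against_ensemble_reference(
            self, helix12, helix_ensemble_rama):
        rama, _ = rama_rotamer_outliers(helix12, rama_ref=helix_ensemble_rama)
        assert rama.fraction == 0.0

    def test_forced_torsion_flagged(self, helix12, helix_ensemble_rama):
        # rebuild residue 6's φ/ψ neighborhood by brute rotation: rotate the
        # C (and following chain) about the N-CA axis to shift φ by +130°
        bent = helix12.copy()
        residues = bent.chains[0].residues
        n, ca = residues[5].atom("N").xyz, residues[5].atom("CA").xyz
        moving = [a for a in residues[5].atoms if a.name not in ("N", "CA")]
        for r in residues[6:]:
            moving.extend(r.atoms)
        for a in moving:
            a.xyz = rotate_about_line(a.xyz, ca, ca - n, 130.0)[0]
        rama, _ = rama_rotamer_outliers(bent, rama_ref=helix_ensemble_rama)
        assert ("A", 6, "ALA") in rama.outliers

    def test_two_residue_chain_has_undefined_fraction(self):
        m = build_fixture(FixtureSpec("helix", 4))
        m.chains[0].residues = m.chains[0].residues[:2]
        rama, _ = rama_rotamer_outliers(m)
        assert rama.fraction is None
        assert rama.n_scored == 0

    def test_shipped_references_accept_ideal_fixture(self, helix12, strand8):
        for model in (helix12, strand8):
            rama, rot = rama_rotamer_outliers(model)
            assert rama.fraction == 0.0
            assert rot.fraction == 0.0

    def test_nonrotameric_chi1_flagged_by_shipped_reference(self, helix12):
        swapped = perturb(helix12, PerturbationSpec("rotamer_swap", 120.0))
        _, rot = rama_rotamer_outliers(swapped)
        assert rot.fraction == 1.0


class TestCablam:
    def test_ideal_helix_clean(self, helix12, cablam_refs):
        report = cablam(helix12, *cablam_refs)
        assert report.cablam.fraction == 0.0
        assert report.ca_geometry.fraction == 0.0

    def test_terminal_residues_unscored(self, helix12, cablam_refs):
        report = cablam(helix12, *cablam_refs)
        scored_numbers = {num for (_, num, _), *_ in report.parameters}
        assert {1, 2, 11, 12}.isdisjoint(scored_numbers)
        assert ("A", 1, "ALA") in report.cablam.unscored

    def test_peptide_flip_caught_by_cablam_not_rama(self, cablam_refs,
                                                    helix_ensemble_rama):
        """A flipped peptide keeps the flip-site residue in allowed φ/ψ
        territory while the carbonyl-direction triplet becomes an outlier."""
        base = build_fixture(FixtureSpec("helix", 16))
        flipped = perturb(base, PerturbationSpec("peptide_flip", 7))
        report = cablam(flipped, *cablam_refs)
        flagged = {num for _, num, _ in report.cablam.outliers}
        assert flagged & {7, 8, 9}, "flip not caught by CaBLAM"
        rama, _ = rama_rotamer_outliers(flipped)  # shipped textbook grid
        assert ("A", 8, "ALA") not in rama.outliers  # flip-site residue i

    def test_chain_break_terminates_stretch(self, cablam_refs):
        broken = build_fixture(FixtureSpec("helix", 16))
        for res in broken.chains[0].residues[8:]:
            for a in res.atoms:
                a.xyz = a.xyz + np.array([20.0, 0, 0])
        report = cablam(broken, *cablam_refs)
        scored = {num for (_, num, _), *_ in report.parameters}
        # residues straddling the break lack 5 consecutive neighbors
        assert {7, 8, 9, 10}.isdisjoint(scored)


class TestFlipBatchOrthogonality:
    def test_cablam_flags_more_flips_than_rama(self, cablam_refs):
        """Across a batch of peptide flips, the CaBLAM triplet catches what
        backbone φ/ψ alone misses."""
        base = build_fixture(FixtureSpec("helix", 20))
        cablam_hits = 0
        rama_hits = 0
        flips = list(range(3, 16))
        for i in flips:
            flipped = perturb(base, PerturbationSpec("peptide_flip", i))
            rep = cablam(flipped, *cablam_refs)
            if any(num in (i + 1, i + 2) for _, num, _ in rep.cablam.outliers):
                cablam_hits += 1
            rama, _ = rama_rotamer_outliers(flipped)
            if ("A", i + 1, base.chains[0].residues[i].name) in rama.outliers:
                rama_hits += 1
        assert cablam_hits == len(flips)
        assert cablam_hits > rama_hits


class TestCisPeptides:
    def test_trans_fixture_is_clean(self, helix12):
        assert cis_peptides(helix12) == []

    def _with_omega(self, omega_target):
        m = build_fixture(FixtureSpec("helix", 4, sequence="AAAA"))
        residues = m.chains[0].residues
        c = residues[1].atom("C").xyz
        n = residues[2].atom("N").xyz
        # rotate everything beyond the peptide bond about the C-N axis
        delta = omega_target - 180.0
        for r in residues[2:]:
            for a in r.atoms:
                if r.number == 3 and a.name == "N":
                    continue
                a.xyz = rotate_about_line(a.xyz, c, n - c, delta)[0]
        return m

    def test_cis_nonpro_flagged(self):
        records = cis_peptides(self._with_omega(0.0))
        assert len(records) == 1
        assert records[0]["class"] == "cis-nonPro"
        assert abs(records[0]["omega"]) <= 30.0

    def test_cis_pro_classified_separately(self):
        m = build_fixture(FixtureSpec("helix", 4, sequence="AAPA"))
        residues = m.chains[0].residues
        c = residues[1].atom("C").xyz
        n = residues[2].atom("N").xyz
        for r in residues[2:]:
            for a in r.atoms:
                if r.number == 3 and a.name == "N":
                    continue
                a.xyz = rotate_about_line(a.xyz, c, n - c, -180.0)[0]
        records = cis_peptides(m)
        assert any(rec["class"] == "cis-Pro" for rec in records)

    def test_twisted_class(self):
        records = cis_peptides(self._with_omega(90.0))
        assert len(records) == 1
        assert records[0]["class"] == "twisted"


class TestReferenceDistribution:
    def test_coverage_percentile_orders_by_frequency(self):
        ref = ReferenceDistribution(
            name="toy",
            edges=[np.array([0.0, 1.0, 2.0, 3.0])],
            frequencies=np.array([8.0, 2.0, 0.0]),
            periodic=[False])
        assert ref.score((0.5,)) == pytest.approx(100.0)
        assert ref.score((1.5,)) == pytest.approx(20.0)
        assert ref.score((2.5,)) == pytest.approx(0.0)
        assert ref.is_outlier((2.5,))
        assert not ref.is_outlier((0.5,))

    def test_json_round_trip(self):
        ref = load_rama_reference()
        back = ReferenceDistribution.from_json(ref.to_json())
        np.testing.assert_array_equal(back.frequencies, ref.frequencies)
        assert back.score((-57.0, -47.0)) == ref.score((-57.0, -47.0))

    def test_shipped_rotamer_wells(self):
        rot = load_rotamer_reference()
        for center in (60.0, 180.0, 300.0):
            assert not rot.is_outlier((center,))
        for bad in (0.0, 120.0, 240.0):
            assert rot.is_outlier((bad,))

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            ReferenceDistribution(
                name="bad", edges=[np.array([0.0, 1.0])],
                frequencies=np.array([1.0]), periodic=[False],
                outlier_pct=0.0)
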