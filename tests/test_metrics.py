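"""Geometric features: dihedrals, minimum image, H-bonds, histograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shiftselect.metrics import (
    Atom,
    FeatureSpec,
    Frame,
    HBondCriterion,
    Molecule,
    correlation2d,
    detect_hbond,
    dihedral,
    feature_values,
    hbond_census,
    histogram1d,
    make_feature_histogram,
    min_image_distance,
    promotion_map,
)


class TestDihedral:
    def test_cis_is_zero(self):
        assert dihedral((1, 1, 0), (0, 1, 0), (0, 0, 0), (1, 0, 0)) == pytest.approx(0.0)

    def test_trans_is_180(self):
        assert dihedral((-1, 1, 0), (0, 1, 0), (0, 0, 0), (1, 0, 0)) == pytest.approx(180.0)

    def test_mirror_flips_sign(self, rng):
        pts = rng.normal(size=(4, 3))
        theta = dihedral(*pts)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        if abs(theta) == pytest.approx(180.0, abs=1e-9):
            pytest.skip("sign undefined at the branch point")
        assert dihedral(*mirrored) == pytest.approx(-theta)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(4, 3)) * 3
        theta = dihedral(*pts)
        # random rotation + translation
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        moved = pts @ R.T + np.array([5.0, -2.0, 7.0])
        assert dihedral(*moved) == pytest.approx(theta, abs=1e-8)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(ValueError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestMinImage:
    def test_cubic_wraparound(self):
        cell = np.eye(3) * 10.0
        assert min_image_distance((0.5, 0, 0), (9.5, 0, 0), cell) == pytest.approx(1.0)

    def test_no_cell_is_euclidean(self):
        assert min_image_distance((0.5, 0, 0), (9.5, 0, 0)) == pytest.approx(9.0)

    def test_matches_brute_force_in_random_triclinic_cells(self, rng):
        for _ in range(50):
            cell = np.eye(3) * 8 + rng.uniform(-2, 2, (3, 3))
            if abs(np.linalg.det(cell)) < 20:
                continue
            a = rng.uniform(-5, 5, 3)
            b = rng.uniform(-5, 5, 3)
            shifts = (-2, -1, 0, 1, 2)
            brute = min(
                np.linalg.norm(b + np.array([i, j, k]) @ cell - a)
                for i in shifts for j in shifts for k in shifts
            )
            assert min_image_distance(a, b, cell) == pytest.approx(brute, abs=1e-9)

    def test_lattice_translation_invariance(self, rng):
        cell = np.eye(3) * 12 + rng.uniform(-1, 1, (3, 3))
        a, b = rng.uniform(0, 12, 3), rng.uniform(0, 12, 3)
        d0 = min_image_distance(a, b, cell)
        assert min_image_distance(a, b + np.array([2, -1, 3]) @ cell, cell) == pytest.approx(d0)

    def test_singular_cell_raises(self):
        with pytest.raises(ValueError):
            min_image_distance((0, 0, 0), (1, 0, 0), np.zeros((3, 3)))


def donor_frame(acceptor_xyz, acceptor_element="N", cell=None, extra=()):
    """A frame with an O-H donor at the origin pointing along +x."""
    donor = Molecule(0, [
        Atom("O1", "O", (0.0, 0.0, 0.0)),
        Atom("H1", "H", (1.0, 0.0, 0.0)),
        Atom("N53", acceptor_element, tuple(acceptor_xyz)),
    ])
    mols = [donor] + list(extra)
    return Frame(molecules=mols, cell=cell)


class TestDetectHbond:
    def test_linear_intra_bond_found(self):
        frame = donor_frame((2.8, 0.0, 0.0))  # H...N = 1.8, angle 180
        cls, scope = detect_hbond(frame, 0, "H1", "O1")
        assert (cls, scope) == ("N53", "intra")

    def test_distance_fail_returns_none(self):
        frame = donor_frame((4.5, 0.0, 0.0))  # H...N = 3.5
        assert detect_hbond(frame, 0, "H1", "O1") == ("none", "")

    def test_angle_fail_returns_none(self):
        frame = donor_frame((1.0, 1.8, 0.0))  # 90 deg at H
        assert detect_hbond(frame, 0, "H1", "O1") == ("none", "")

    def test_nearest_acceptor_wins(self):
        other = Molecule(1, [Atom("N99", "N", (3.2, 0.0, 0.0))])  # H...N = 2.2
        frame = donor_frame((2.8, 0.0, 0.0), extra=[other])
        cls, scope = detect_hbond(frame, 0, "H1", "O1")
        assert (cls, scope) == ("N53", "intra")

    def test_intermolecular_minimum_image(self):
        cell = np.eye(3) * 10.0
        other = Molecule(1, [Atom("O9", "O", (-7.2, 0.0, 0.0))])  # image at +2.8
        frame = donor_frame((9.0, 9.0, 9.0), cell=cell, extra=[other])
        cls, scope = detect_hbond(frame, 0, "H1", "O1",
                                  acceptor_class_map={"O9": "carbonyls"})
        assert (cls, scope) == ("carbonyls", "inter")

    def test_not_covalent_raises(self):
        bad = Molecule(0, [Atom("O1", "O", (0, 0, 0)), Atom("H1", "H", (3, 0, 0)),
                           Atom("N53", "N", (5, 0, 0))])
        with pytest.raises(ValueError, match="covalently"):
            detect_hbond(Frame(molecules=[bad]), 0, "H1", "O1")


class TestHistograms:
    def test_delta_distribution(self):
        edges, dens = histogram1d([0.0] * 100, 10.0, periodic=True)
        width = edges[1] - edges[0]
        assert dens.sum() * width == pytest.approx(1.0)
        assert dens.max() == pytest.approx(1.0 / width)

    def test_uniform_within_binomial_error(self, rng):
        n = 36000
        vals = rng.uniform(-180.0, 180.0, n)
        edges, dens = histogram1d(vals, 10.0, periodic=True)
        p = 10.0 / 360.0
        se = np.sqrt(p * (1 - p) / n) / 10.0  # density standard error per bin
        assert np.all(np.abs(dens - 1.0 / 360.0) < 4 * se)

    def test_periodic_wraparound_bin(self):
        edges, dens = histogram1d([-179.0, 179.0], 10.0, periodic=True,
                                  edge_offset=5.0)
        # both values land in the single bin centred on 180
        assert np.count_nonzero(dens) == 1

    def test_unit_integral_nonperiodic(self, rng):
        vals = rng.normal(5.0, 1.0, 5000)
        edges, dens = histogram1d(vals, 0.5)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            histogram1d([], 10.0)


class TestPromotion:
    def test_identity(self, rng):
        vals = rng.normal(0, 30, 2000)
        hist = make_feature_histogram(vals, vals, 10.0, periodic=True)
        ratios = hist.promotion
        defined = ~np.isnan(ratios)
        assert np.allclose(ratios[defined], 1.0)
        assert all(c in ("unchanged", "undefined") for c in hist.classification)

    def test_doubled_bin_promoted(self):
        md = np.concatenate([np.zeros(50), np.full(50, 90.0)])
        nmr = np.concatenate([np.zeros(25), np.full(75, 90.0)])
        hist = make_feature_histogram(md, nmr, 10.0, periodic=True)
        labels = dict(zip(hist.bin_centers, hist.classification))
        assert labels[95.0] == "promoted" or labels[85.0] == "promoted"
        assert "demoted" in hist.classification

    def test_md_zero_bins_flagged(self):
        md = np.zeros(10)
        nmr = np.concatenate([np.zeros(5), np.full(5, 90.0)])
        hist = make_feature_histogram(md, nmr, 10.0, periodic=True)
        pm = promotion_map(hist)
        undefined = [row for row in pm if row[3] == "undefined" and row[0] <= 90 < row[1]]
        assert undefined


class TestCorrelation2d:
    def test_diagonal_mass_for_identical_pairs(self, rng):
        x = rng.uniform(0, 10, 500)
        edges = np.linspace(0, 10, 11)
        H, _, _ = correlation2d(x, x, edges, edges)
        off_diag = H - np.diag(np.diag(H))
        assert np.all(off_diag == 0)

    def test_marginal_matches_1d(self, rng):
        x = rng.normal(0, 30, 4000)
        y = rng.normal(0, 2, 4000)
        ex = np.arange(-180.0, 181.0, 10.0)
        ey = np.arange(-8.0, 8.5, 0.5)
        H, _, _ = correlation2d(x, y, ex, ey)
        marg_x = H.sum(axis=1) * 0.5  # integrate over y bins
        dens_x, _ = np.histogram(x, bins=ex, density=True)
        assert np.allclose(marg_x, dens_x, atol=1e-12)

    def test_unit_integral(self, rng):
        x, y = rng.normal(size=(2, 1000))
        e = np.linspace(-4, 4, 17)
        H, _, _ = correlation2d(x, y, e, e)
        dx = dy = e[1] - e[0]
        assert H.sum() * dx * dy == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            correlation2d([1.0], [1.0, 2.0], [0, 1], [0, 1])


class TestFeatureValuesAndCensus:
    def test_distance_feature(self):
        mol = Molecule(0, [Atom("A1", "C", (0, 0, 0)), Atom("A2", "C", (2, 0, 0))])
        frame = Frame(molecules=[mol])
        spec = FeatureSpec("distance", ("A1", "A2"))
        _, vals = feature_values([(("r", 0, 0), frame, 0)], spec)
        assert vals == [pytest.approx(2.0)]

    def test_planted_torsion_feature(self):
        from shiftselect.synthetic import build_molecule
        mol = build_molecule({"O1-C2-C7-C8": 10.0, "C2-C7-C8-C9": -60.0,
                              "C7-C8-C9-N53": 120.0, "H1-O1-C2-C7": 0.0})
        frame = Frame(molecules=[mol])
        spec = FeatureSpec("dihedral", ("C2", "C7", "C8", "C9"))
        _, vals = feature_values([(("r", 0, 0), frame, 0)], spec)
        assert vals[0] == pytest.approx(-60.0, abs=1e-8)

    def test_determinism(self, small_case):
        envs = small_case.environments()[:20]
        spec = FeatureSpec("dihedral", ("C2", "C7", "C8", "C9"))
        _, v1 = feature_values(envs, spec)
        _, v2 = feature_values(envs, spec)
        assert v1 == v2

    def test_census_fractions_sum_to_one(self):
        bonded = donor_frame((2.8, 0.0, 0.0))
        unbonded = donor_frame((6.0, 0.0, 0.0))
        md = [(("r", 0, 0), bonded, 0)] * 8 + [(("r", 1, 0), unbonded, 0)] * 2
        nmr = [(("r", 0, 0), bonded, 0)] * 2
        census = hbond_census(md, nmr, [("H1", "O1")])
        fr = census.fractions["H1"]
        assert sum(v[0] for v in fr.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(v[1] for v in fr.values()) == pytest.approx(1.0, abs=1e-9)
        assert fr["N53:intra"] == (pytest.approx(0.8), pytest.approx(1.0))
        assert fr["none"][0] == pytest.approx(0.2)

    def test_missing_label_raises(self, small_case):
        envs = small_case.environments()[:1]
        spec = FeatureSpec("distance", ("H1", "Zz9"))
        with pytest.raises(KeyError):
            feature_values(envs, spec)
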