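"""Cluster extraction, the toy pair potential, and energy profiles."""

import itertools

import numpy as np
import pytest

from shiftselect.energetics import (
    BinnedEnergyProfile,
    FileBackend,
    PairwiseBackend,
    binned_energy_profile,
    extract_cluster,
    formation_energy,
    sample_md_environments,
    write_cluster_xyz,
)
from shiftselect.metrics import Atom, Frame, Molecule


def point_molecule(index, xyz, element="C", label=None):
    return Molecule(index, [Atom(label or f"{element}1", element, tuple(xyz))])


def random_frame(rng, n_mols=20, atoms_per_mol=4, triclinic=True, edge=18.0):
    cell = np.eye(3) * edge
    if triclinic:
        cell = cell + rng.uniform(-2.0, 2.0, (3, 3)) * (1 - np.eye(3))
    mols = []
    for m in range(n_mols):
        center = rng.uniform(0, edge, 3)
        atoms = [
            Atom(f"C{j+1}", "C", tuple(center + rng.uniform(-1.0, 1.0, 3)))
            for j in range(atoms_per_mol)
        ]
        mols.append(Molecule(m, atoms))
    return Frame(molecules=mols, cell=cell)


def brute_force_members(frame, central, cutoff):
    """27-image all-pairs membership oracle."""
    c = frame.molecule(central).coords()
    members = set()
    shifts = list(itertools.product((-1, 0, 1), repeat=3))
    for other in frame.molecules:
        if other.index == central:
            continue
        o = other.coords()
        for s in shifts:
            t = np.array(s) @ frame.cell
            d = np.linalg.norm(c[:, None, :] - (o + t)[None, :, :], axis=-1)
            if d.min() <= cutoff:
                members.add(other.index)
                break
    return members


class TestExtractCluster:
    def test_pair_inside_cutoff(self):
        frame = Frame(molecules=[point_molecule(0, (0, 0, 0)),
                                 point_molecule(1, (6.0, 0, 0))])
        cl = extract_cluster(frame, 0, 7.0)
        assert cl.members == [1]

    def test_pair_outside_cutoff(self):
        frame = Frame(molecules=[point_molecule(0, (0, 0, 0)),
                                 point_molecule(1, (8.0, 0, 0))])
        cl = extract_cluster(frame, 0, 7.0)
        assert cl.members == []

    def test_membership_matches_brute_force(self, rng):
        for _ in range(10):
            frame = random_frame(rng)
            central = int(rng.integers(len(frame.molecules)))
            cl = extract_cluster(frame, central, 5.0)
            assert set(cl.members) == brute_force_members(frame, central, 5.0)

    def test_neighbor_coordinates_are_nearest_images(self, rng):
        frame = random_frame(rng, n_mols=6, triclinic=False, edge=14.0)
        cl = extract_cluster(frame, 0, 6.0)
        c = cl.geometry[cl.central][2]
        for m in cl.members:
            coords = cl.geometry[m][2]
            # unwrapped member sits within cutoff in plain Cartesian space
            d = np.linalg.norm(c[:, None, :] - coords[None, :, :], axis=-1)
            assert d.min() <= 6.0 + 1e-9

    def test_cutoff_beyond_half_cell_raises(self):
        frame = Frame(molecules=[point_molecule(0, (0, 0, 0))], cell=np.eye(3) * 10)
        with pytest.raises(ValueError, match="half"):
            extract_cluster(frame, 0, 5.0)


class TestPairwiseBackend:
    def test_isolated_molecule_zero_delta(self):
        frame = Frame(molecules=[point_molecule(0, (0, 0, 0))])
        cl = extract_cluster(frame, 0, 7.0)
        en = formation_energy(cl, PairwiseBackend())
        assert en.delta == 0.0
        assert en.e_central == 0.0

    def test_lj_minimum_pair(self):
        b = PairwiseBackend()
        rmin = 2 ** (1 / 6) * b.sigma
        frame = Frame(molecules=[point_molecule(0, (0, 0, 0)),
                                 point_molecule(1, (rmin, 0, 0))])
        cl = extract_cluster(frame, 0, 7.0)
        en = formation_energy(cl, b)
        assert en.delta == pytest.approx(-b.eps, rel=1e-12)
        assert en.delta == pytest.approx(b.pair_energy("C", "C", rmin))

    def test_hbond_well_depth(self):
        b = PairwiseBackend()
        donor = point_molecule(0, (0, 0, 0), element="H", label="H1")
        acceptor = point_molecule(1, (b.hb_r0, 0, 0), element="N", label="N53")
        cl = extract_cluster(Frame(molecules=[donor, acceptor]), 0, 7.0)
        en = formation_energy(cl, b)
        assert en.delta == pytest.approx(-b.hb_depth, rel=1e-12)

    def test_locality_under_distant_duplicates(self):
        b = PairwiseBackend()
        mols = [point_molecule(0, (0, 0, 0)), point_molecule(1, (4.0, 0, 0))]
        base = formation_energy(extract_cluster(Frame(molecules=mols), 0, 7.0), b)
        far = mols + [point_molecule(2, (500.0, 0, 0)), point_molecule(3, (504.0, 0, 0))]
        cl = extract_cluster(Frame(molecules=far), 0, 7.0)
        dup = formation_energy(cl, b)
        assert dup.delta == pytest.approx(base.delta, abs=1e-9)

    def test_delta_equals_analytic_pair_sum(self, rng):
        b = PairwiseBackend()
        for _ in range(5):
            frame = random_frame(rng, n_mols=8, triclinic=False, edge=16.0)
            central = int(rng.integers(8))
            cl = extract_cluster(frame, central, 7.0)
            en = formation_energy(cl, b)
            analytic = 0.0
            _, _, c = cl.geometry[cl.central]
            els_c = cl.geometry[cl.central][0]
            for m in cl.members:
                els_m, _, xyz_m = cl.geometry[m]
                for e1, p1 in zip(els_c, c):
                    for e2, p2 in zip(els_m, xyz_m):
                        analytic += b.pair_energy(e1, e2, float(np.linalg.norm(p1 - p2)))
            assert en.delta == pytest.approx(analytic, abs=1e-9)

    def test_invariance_under_rigid_motion(self, rng):
        b = PairwiseBackend()
        frame = random_frame(rng, n_mols=5, triclinic=False, edge=14.0)
        cl = extract_cluster(frame, 0, 6.5)
        base = formation_energy(cl, b).delta
        # rotate + translate every unwrapped coordinate
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        for k, (els, labels, xyz) in cl.geometry.items():
            cl.geometry[k] = (els, labels, xyz @ R.T + np.array([3.0, -1.0, 9.0]))
        assert formation_energy(cl, b).delta == pytest.approx(base, rel=1e-9)


class TestFileBackend:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("run_id,frame,molecule,e_with,e_without,e_central\n"
                     "run0,0,3,-120.5,-100.0,-15.5\n")
        fb = FileBackend(p)
        en = fb.energies_for(("run0", 0, 3))
        assert en.delta == pytest.approx(-5.0)
        assert en.delta_env == pytest.approx(-20.5)
        with pytest.raises(KeyError):
            fb.energies_for(("run0", 0, 4))


class TestSampling:
    def test_sample_sizes_and_determinism(self):
        runs = {f"run{r}": [(f"run{r}", f, m) for f in range(10) for m in range(20)]
                for r in range(4)}
        s1 = sample_md_environments(runs, per_run=150, seed=7)
        s2 = sample_md_environments(runs, per_run=150, seed=7)
        s3 = sample_md_environments(runs, per_run=150, seed=8)
        assert len(s1) == 600
        assert s1 == s2
        assert s1 != s3
        per_run_counts = {r: sum(1 for e in s1 if e[0] == r) for r in runs}
        assert set(per_run_counts.values()) == {150}

    def test_exhaustive_sampling(self):
        runs = {"run0": [("run0", 0, m) for m in range(5)]}
        s = sample_md_environments(runs, per_run=5, seed=3)
        assert sorted(s) == runs["run0"]

    def test_insufficient_raises(self):
        with pytest.raises(ValueError, match="run0"):
            sample_md_environments({"run0": [("run0", 0, 0)]}, per_run=2)


class TestBinnedProfile:
    def test_identical_energies_flat_zero(self):
        feats = {i: float(i % 4) for i in range(40)}
        ergs = {i: -7.5 for i in range(40)}
        prof = binned_energy_profile(feats, ergs, [0, 1, 2, 3, 4])
        assert np.allclose(prof.mean[prof.count > 0], 0.0)
        assert np.allclose(prof.spread[prof.count > 0], 0.0)

    def test_referencing_between_bins(self):
        feats = {0: 0.5, 1: 1.5}
        ergs = {0: -3.0, 1: 7.0}
        prof = binned_energy_profile(feats, ergs, [0, 1, 2])
        assert prof.mean[0] == pytest.approx(0.0)
        assert prof.mean[1] == pytest.approx(10.0)

    def test_common_reference_zero_across_sets(self):
        md = binned_energy_profile({0: 0.5, 1: 1.5}, {0: -3.0, 1: 7.0}, [0, 1, 2])
        nmr = binned_energy_profile({2: 0.5}, {2: -1.0}, [0, 1, 2],
                                    reference_zero=md.reference_energy)
        assert nmr.mean[0] == pytest.approx(2.0)

    def test_planted_well_lowers_bonded_bin(self, rng):
        # intermolecular H...N geometries at the toy well minimum versus far
        b = PairwiseBackend()
        feats, ergs = {}, {}
        for i in range(30):
            bonded = i < 15
            r = b.hb_r0 if bonded else 6.0
            donor = point_molecule(0, (0, 0, 0), element="H", label="H1")
            acceptor = point_molecule(1, (r, 0, 0), element="N", label="N53")
            cl = extract_cluster(Frame(molecules=[donor, acceptor]), 0, 7.0)
            feats[i] = r
            ergs[i] = formation_energy(cl, b).delta
        prof = binned_energy_profile(feats, ergs, [0.0, 3.0, 7.0])
        assert prof.mean[0] == pytest.approx(0.0)
        assert prof.mean[1] == pytest.approx(b.hb_depth, abs=1e-6)

    def test_empty_overlap_raises(self):
        with pytest.raises(ValueError):
            binned_energy_profile({0: 1.0}, {1: 2.0}, [0, 1, 2])


def test_cluster_xyz_export(tmp_path):
    frame = Frame(molecules=[point_molecule(0, (0, 0, 0)),
                             point_molecule(1, (3.0, 0, 0))])
    cl = extract_cluster(frame, 0, 7.0, env_id=("run0", 0, 0))
    path = tmp_path / "run0_0_0.xyz"
    write_cluster_xyz(cl, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "2"
    assert lines[2].startswith("C 0.000000")
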