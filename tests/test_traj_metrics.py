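"""Superposition, RMSD/RMSF/Rg, SASA, hydrogen bonds, histograms, clustering."""

import numpy as np
import pytest

import prspath as pp
from conftest import random_rotation
from prspath.structure_io import AtomRecord, StructureModel


def quaternion_rmsd(x, y):
    """Independent optimal-superposition RMSD via the quaternion method."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    r = x.T @ y
    f = np.array(
        [
            [r[0, 0] + r[1, 1] + r[2, 2], r[1, 2] - r[2, 1], r[2, 0] - r[0, 2], r[0, 1] - r[1, 0]],
            [r[1, 2] - r[2, 1], r[0, 0] - r[1, 1] - r[2, 2], r[0, 1] + r[1, 0], r[0, 2] + r[2, 0]],
            [r[2, 0] - r[0, 2], r[0, 1] + r[1, 0], -r[0, 0] + r[1, 1] - r[2, 2], r[1, 2] + r[2, 1]],
            [r[0, 1] - r[1, 0], r[0, 2] + r[2, 0], r[1, 2] + r[2, 1], -r[0, 0] - r[1, 1] + r[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(f)[-1]
    sq = (np.sum(x**2) + np.sum(y**2) - 2.0 * lam) / len(x)
    return np.sqrt(max(sq, 0.0))


def carbon_model(coords):
    atoms = [
        AtomRecord(
            serial=i + 1, name="C", element="C", residue_name="UNK",
            residue_index=i + 1, chain_id="A", position=np.asarray(c, float),
            vdw_radius=1.70,
        )
        for i, c in enumerate(np.atleast_2d(coords))
    ]
    return StructureModel(atoms=atoms)


class TestKabsch:
    def test_self_superposition(self, helix20):
        rot, trans, rmsd = pp.kabsch_superpose(helix20.coords, helix20.coords)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered(self, helix20):
        theta = np.deg2rad(37.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = helix20.coords @ rot.T + np.array([5.0, -2.0, 1.0])
        _, _, rmsd = pp.kabsch_superpose(moved, helix20.coords)
        assert rmsd <= 1e-9

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.standard_normal((6, 3)) * 3
            y = rng.standard_normal((6, 3)) * 3
            _, _, rmsd = pp.kabsch_superpose(x, y)
            assert rmsd == pytest.approx(quaternion_rmsd(x, y), abs=1e-8)

    def test_symmetry_and_common_transform_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((8, 3))
        y = rng.standard_normal((8, 3))
        r1 = pp.kabsch_superpose(x, y)[2]
        r2 = pp.kabsch_superpose(y, x)[2]
        assert r1 == pytest.approx(r2, abs=1e-9)
        rot = random_rotation(rng)
        r3 = pp.kabsch_superpose(x @ rot.T + 4.0, y @ rot.T + 4.0)[2]
        assert r3 == pytest.approx(r1, abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            pp.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            pp.kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_static_ensemble_all_zero(self, helix20):
        ens = pp.CoordinateEnsemble(
            topology=helix20, frames=np.repeat(helix20.coords[None], 4, 0)
        )
        assert np.allclose(pp.rmsd_series(ens).values, 0.0)

    def test_rigidly_moved_frame_scores_zero(self, helix20):
        rng = np.random.default_rng(1)
        rot = random_rotation(rng)
        frames = np.stack([helix20.coords, helix20.coords @ rot.T + 2.0])
        series = pp.rmsd_series(ens := pp.CoordinateEnsemble(topology=helix20, frames=frames))
        assert series.values[1] <= 1e-9

    def test_matches_independent_superposition(self, helix_network, helix20):
        ens = pp.sample_anm_ensemble(helix_network, 50, seed=3, topology=helix20)
        series = pp.rmsd_series(ens)
        ref = np.array([quaternion_rmsd(f, ens.frames[0]) for f in ens.frames])
        assert np.abs(series.values.mean() - ref.mean()) <= 0.05 * ref.mean()


class TestRmsf:
    def test_static_ensemble_zero(self, helix20):
        ens = pp.CoordinateEnsemble(
            topology=helix20, frames=np.repeat(helix20.coords[None], 3, 0)
        )
        assert np.allclose(pp.rmsf(ens), 0.0)

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self):
        # big rigid body: superposition absorbs almost none of the noise
        rng = np.random.default_rng(6)
        base = pp.make_helix(100).coords
        frames = base[None] + 0.5 * rng.standard_normal((2000, 100, 3))
        ens = pp.CoordinateEnsemble(topology=pp.make_helix(100), frames=frames)
        values = pp.rmsf(ens)
        assert np.abs(values.mean() - 0.5 * np.sqrt(3.0)) <= 0.1 * 0.5 * np.sqrt(3.0)

    def test_two_frame_single_displacement(self):
        # displace the middle atom of a large planar grid perpendicular to
        # the plane: superposition barely reacts, RMSF of that atom -> d/2
        g = np.mgrid[0:10, 0:10].reshape(2, -1).T * 4.0
        base = np.column_stack([g, np.zeros(len(g))])
        moved = base.copy()
        moved[44, 2] += 2.0
        topo = carbon_model(base)
        ens = pp.CoordinateEnsemble(topology=topo, frames=np.stack([base, moved]))
        values = pp.rmsf(ens)
        assert values[44] == pytest.approx(1.0, rel=0.05)
        others = np.delete(values, 44)
        assert others.max() < 0.1


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert pp.radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_unit_masses(self):
        rg = pp.radius_of_gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert rg == pytest.approx(1.0)

    def test_square_equals_half_diagonal(self):
        s = 3.0
        square = np.array([[0, 0, 0], [s, 0, 0], [0, s, 0], [s, s, 0]], dtype=float)
        assert pp.radius_of_gyration(square) == pytest.approx(s / np.sqrt(2))

    def test_rigid_invariance_and_linear_scaling(self, helix20):
        rng = np.random.default_rng(3)
        rot = random_rotation(rng)
        rg = pp.radius_of_gyration(helix20.coords)
        assert pp.radius_of_gyration(helix20.coords @ rot.T + 7.0) == pytest.approx(rg)
        assert pp.radius_of_gyration(2.5 * helix20.coords) == pytest.approx(2.5 * rg)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            pp.radius_of_gyration(np.zeros((2, 3)), masses=[1.0, 0.0])


def two_sphere_sasa(r, d):
    """Closed-form accessible area of two equal spheres at separation d."""
    if d >= 2 * r:
        return 2 * 4 * np.pi * r**2
    cap = 2 * np.pi * r * (r - d / 2.0)  # buried spherical cap per sphere
    return 2 * (4 * np.pi * r**2 - cap)


class TestSasa:
    def test_lone_carbon_analytic(self):
        total, per_atom = pp.sasa(carbon_model([[0.0, 0, 0]]))
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert total == pytest.approx(expected, rel=1e-3)

    def test_disjoint_spheres_additive(self):
        total, per_atom = pp.sasa(carbon_model([[0.0, 0, 0], [20.0, 0, 0]]))
        single = pp.sasa(carbon_model([[0.0, 0, 0]]))[0]
        assert total == pytest.approx(2 * single, rel=1e-12)

    def test_two_overlapping_spheres_match_cap_formula(self):
        r = 1.70 + 1.4
        total, _ = pp.sasa(carbon_model([[0.0, 0, 0], [2.0, 0, 0]]), n_sphere_points=960)
        assert total == pytest.approx(two_sphere_sasa(r, 2.0), rel=0.01)

    def test_monotone_decrease_as_neighbor_approaches(self):
        areas = [
            pp.sasa(carbon_model([[0.0, 0, 0], [d, 0, 0]]))[1][0] for d in (6.0, 4.0, 2.0, 1.0)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))
        assert min(areas) >= 0.0

    def test_point_count_convergence(self):
        model = carbon_model([[0.0, 0, 0], [2.5, 0.5, 0.3], [1.0, 2.0, 1.0]])
        a960 = pp.sasa(model, n_sphere_points=960)[0]
        a1920 = pp.sasa(model, n_sphere_points=1920)[0]
        assert abs(a1920 - a960) / a960 < 0.005

    def test_matches_biotite_on_small_cluster(self):
        struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 6, size=(6, 3))
        model = carbon_model(coords)
        ours = pp.sasa(model, n_sphere_points=960)[1]
        arr = struc.AtomArray(6)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 6)
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                            vdw_radii=np.full(6, 1.70))
        assert np.abs(ours - theirs).max() / theirs.max() < 0.02


class TestHbonds:
    @pytest.mark.parametrize(
        "oo,angle,expected",
        [
            (2.8, 180.0, 1),  # ideal linear bond
            (2.8, 90.0, 0),  # bent below the angle cutoff
            (3.0, 180.0, 1),  # distance exactly at cutoff: inclusive
            (3.2, 180.0, 0),  # beyond distance cutoff
            (2.8, 135.0, 1),  # angle exactly at cutoff: inclusive
        ],
    )
    def test_geometries(self, oo, angle, expected):
        dimer = pp.make_water_dimer(oo_distance=oo, dha_angle_deg=angle)
        donors = [0]  # first oxygen
        acceptors = [3]  # second oxygen
        assert pp.count_hbonds(dimer, donors, acceptors) == expected

    def test_empty_selection_rejected(self):
        dimer = pp.make_water_dimer()
        with pytest.raises(ValueError):
            pp.count_hbonds(dimer, [], [3])

    def test_series_over_frames(self):
        bonded = pp.make_water_dimer(2.8, 180.0)
        broken = pp.make_water_dimer(5.0, 180.0)
        ens = pp.CoordinateEnsemble(
            topology=bonded, frames=np.stack([bonded.coords, broken.coords])
        )
        series = pp.hbond_series(ens, donors=[0], acceptors=[3])
        assert series.values.tolist() == [1.0, 0.0]


class TestHistogram:
    def test_constant_series_single_bin(self):
        edges, freq = pp.histogram(np.full(50, 3.3), n_bins=10)
        assert freq.sum() == pytest.approx(1.0)
        assert (freq > 0).sum() == 1
        assert freq.max() == pytest.approx(1.0)

    def test_uniform_grid(self):
        values = np.linspace(0, 1, 1000, endpoint=False)
        _, freq = pp.histogram(values, n_bins=10)
        assert np.allclose(freq, 0.1)

    def test_normalization_and_rightmost_inclusive(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal(333)
        edges, freq = pp.histogram(values, n_bins=17)
        assert freq.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(edges) == 18
        # the maximum lands in the last bin, not outside it
        assert freq[-1] > 0 or (values == values.max()).sum() == 0


class TestClustering:
    def test_k_equals_n_frames(self, helix_network, helix20):
        ens = pp.sample_anm_ensemble(helix_network, 6, seed=5, topology=helix20)
        result = pp.cluster_frames(ens, k=6, seed=0)
        assert sorted(result.representatives) == list(range(6))

    def test_k_one_representative_nearest_mean(self, helix_network, helix20):
        ens = pp.sample_anm_ensemble(helix_network, 30, seed=5, topology=helix20)
        result = pp.cluster_frames(ens, k=1, seed=0)
        frames, mean = pp.superpose_frames(ens.frames)
        d = np.linalg.norm(frames.reshape(30, -1) - mean.ravel(), axis=1)
        assert result.representatives == [int(np.argmin(d))]

    def test_planted_two_conformers_recovered(self, helix20):
        rng = np.random.default_rng(12)
        a = helix20.coords
        b = a + np.array([0.0, 0.0, 8.0]) * np.sin(
            np.linspace(0, np.pi, len(a))
        ).reshape(-1, 1)
        frames = np.concatenate(
            [
                a[None] + 0.1 * rng.standard_normal((100, *a.shape)),
                b[None] + 0.1 * rng.standard_normal((100, *a.shape)),
            ]
        )
        ens = pp.CoordinateEnsemble(topology=helix20, frames=frames)
        result = pp.cluster_frames(ens, k=2, seed=0)
        first, second = result.labels[:100], result.labels[100:]
        assert len(set(first.tolist())) == 1
        assert len(set(second.tolist())) == 1
        assert first[0] != second[0]

    def test_seeded_reproducibility(self, helix_network, helix20):
        ens = pp.sample_anm_ensemble(helix_network, 40, seed=5, topology=helix20)
        r1 = pp.cluster_frames(ens, k=4, seed=3)
        r2 = pp.cluster_frames(ens, k=4, seed=3)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.representatives == r2.representatives

    def test_invalid_k(self, helix_network):
        ens = pp.sample_anm_ensemble(helix_network, 5, seed=5)
        with pytest.raises(ValueError):
            pp.cluster_frames(ens, k=6)
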