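import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ededock import io as eio
from ededock import synthetic
from ededock.decomposition import fit_pca
from ededock.exceptions import InfeasibleGeometryError, ZeroVarianceError
from ededock.scoring import ensemble_score


def sidechain_ligand_min_distances(s):
    lig = s.coords[s.is_ligand & s.heavy]
    out = {}
    for key in s.residue_keys:
        idx = s.residue_atom_indices(key)
        side = idx[~s.is_backbone[idx] & s.heavy[idx] & ~s.is_ligand[idx]]
        if side.size:
            out[key] = cdist(s.coords[side], lig).min()
    return out


class TestToyComplex:
    @pytest.mark.parametrize("seed", range(5))
    def test_contact_distances_exact(self, seed):
        rng = np.random.default_rng(seed)
        dists = rng.uniform(1.5, 5.0, 5)
        s = synthetic.make_toy_complex(5, 4, dists, seed=seed)
        got = sidechain_ligand_min_distances(s)
        for j, key in enumerate(k for k in s.residue_keys if k[2] != "LIG"):
            assert got[key] == pytest.approx(dists[j], abs=1e-9)

    def test_written_file_preserves_distances(self, tmp_path):
        dists = [2.5, 3.5]
        p = tmp_path / "toy.pdb"
        synthetic.make_toy_complex(2, 3, dists, seed=0, out_path=p)
        back = eio.read_structure(p, "LIG")
        got = sidechain_ligand_min_distances(back)
        for j, key in enumerate(k for k in back.residue_keys if k[2] != "LIG"):
            assert got[key] == pytest.approx(dists[j], abs=2e-3)

    def test_infeasible_requests_raise(self):
        with pytest.raises(InfeasibleGeometryError):
            synthetic.make_toy_complex(0, 3, [], seed=0)
        with pytest.raises(InfeasibleGeometryError):
            synthetic.make_toy_complex(2, 3, [-1.0, 2.0], seed=0)
        with pytest.raises(InfeasibleGeometryError):
            synthetic.make_toy_complex(2, 3, [1.0], seed=0)


class TestStateTrajectory:
    def test_single_frozen_state_gives_zero_variance(self):
        centers = np.random.default_rng(0).uniform(-5, 5, (3, 3))
        states = [synthetic.StateSpec(0, 1.0, centers, fluctuation_sigma=0.0)]
        traj, _ = synthetic.make_state_trajectory(states, 10, seed=0)
        assert np.abs(traj.frames - traj.frames[0]).max() == 0.0
        from ededock.pocket import extract_features, select_pocket

        ref = synthetic.make_reference_complex(states, seed=0)
        pocket = select_pocket(ref, cutoff=3.0)
        feats = extract_features(traj, pocket, ref)
        with pytest.raises(ZeroVarianceError):
            fit_pca(feats)

    def test_state_frequencies_within_binomial_ci(self):
        pops = (0.5, 0.3, 0.15, 0.05)
        rng_states = [
            synthetic.StateSpec(i, p, np.random.default_rng(i).uniform(-5, 5, (4, 3)))
            for i, p in enumerate(pops)
        ]
        n = 5000
        _, labels = synthetic.make_state_trajectory(rng_states, n, seed=17)
        freq = np.bincount(labels, minlength=4) / n
        for p, f in zip(pops, freq):
            half = 2.576 * np.sqrt(p * (1 - p) / n)  # 99% CI
            assert abs(f - p) <= half

    def test_determinism_and_seed_sensitivity(self, preset):
        t1, l1 = synthetic.make_state_trajectory(preset.states, 50, seed=5)
        t2, l2 = synthetic.make_state_trajectory(preset.states, 50, seed=5)
        t3, _ = synthetic.make_state_trajectory(preset.states, 50, seed=6)
        np.testing.assert_array_equal(t1.frames, t2.frames)
        np.testing.assert_array_equal(l1, l2)
        assert not np.array_equal(t1.frames, t3.frames)

    def test_residue_com_equals_sampled_point_structure(self, preset):
        """Pocket residue COM is the CA/CB midpoint by construction."""
        traj = preset.trajectory
        topo = traj.topology
        m = len(preset.states[0].pocket_com_centers)
        com = 0.5 * (traj.frames[0, 0:2 * m:2] + traj.frames[0, 1:2 * m:2])
        from ededock.pocket import residue_com

        for j, key in enumerate(topo.residue_keys[:m]):
            np.testing.assert_allclose(
                residue_com(traj.frames[0], topo, key), com[j], atol=1e-12)

    def test_reference_complex_pocket_is_all_pocket_residues(self, preset):
        from ededock.pocket import select_pocket

        p = select_pocket(preset.reference, cutoff=3.0)
        m = len(preset.states[0].pocket_com_centers)
        assert p.n_residues == m
        assert all(k[1] <= m for k in p.residue_keys)


class TestScoreTable:
    def _states(self, n_compounds=None, seed=0):
        rng = np.random.default_rng(seed)
        states = []
        for i, p in enumerate((0.5, 0.3, 0.2)):
            true = None if n_compounds is None else rng.uniform(-12, -4, n_compounds)
            states.append(synthetic.StateSpec(i, p, np.zeros((2, 3)),
                                              true_dg_bind=true))
        return states

    def test_noiseless_table_matches_truth(self):
        states = self._states(n_compounds=20, seed=1)
        table, truth, dg_conf = synthetic.make_score_table(
            states, 20, noise_sigma=0.0, missing_rate=0.0, seed=1)
        got = [ensemble_score(row, dg_conf)[0] for row in table.dg_bind]
        np.testing.assert_allclose(got, truth, atol=1e-10)

    def test_missing_rate_keeps_one_score_per_compound(self):
        table, _, _ = synthetic.make_score_table(
            self._states(), 300, noise_sigma=0.1, missing_rate=0.3, seed=2)
        assert np.isfinite(table.dg_bind).any(axis=1).all()
        frac = np.isnan(table.dg_bind).mean()
        assert 0.2 < frac < 0.4

    def test_error_decreases_with_noise(self):
        errs = []
        for noise in (0.5, 0.25, 0.1):
            states = self._states(n_compounds=1000, seed=3)
            table, truth, dg_conf = synthetic.make_score_table(
                states, 1000, noise_sigma=noise, seed=3)
            got = np.array([ensemble_score(r, dg_conf)[0] for r in table.dg_bind])
            errs.append(np.abs(got - truth).mean())
        assert errs[0] > errs[1] > errs[2]

    def test_dg_conf_from_populations(self):
        _, _, dg_conf = synthetic.make_score_table(self._states(), 5, seed=0)
        np.testing.assert_allclose(
            dg_conf, [0.0, -np.log(0.6), -np.log(0.4)], atol=1e-12)


class TestPreset:
    def test_state_centres_well_separated(self, preset):
        flat = np.array([s.pocket_com_centers.ravel() for s in preset.states])
        d = np.linalg.norm(flat[:, None] - flat[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 20 * preset.states[0].fluctuation_sigma

    def test_artifacts_consumable_by_readers(self, preset, tmp_path):
        ref_p = tmp_path / "ref.pdb"
        traj_p = tmp_path / "traj.pdb"
        eio.write_pdb(ref_p, preset.reference)
        eio.write_pdb(traj_p, preset.trajectory.topology,
                      frames=preset.trajectory.frames[:10])
        ref = eio.read_structure(ref_p, "LIG")
        traj = eio.read_trajectory(traj_p)
        assert ref.n_atoms == preset.reference.n_atoms
        assert traj.n_frames == 10
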