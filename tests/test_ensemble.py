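import numpy as np
import pytest

from flexlink import ensemble as ens
from flexlink.datatypes import SAXSProfile
from flexlink.saxs import sphere_intensity
from flexlink.synthetic import make_two_domain_model, simulate_saxs


class TestDebye:
    def test_two_bead_closed_form(self):
        q = np.linspace(0.01, 0.4, 50)
        d = 10.0
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        I = ens.debye_profile(coords, q)
        np.testing.assert_allclose(I, 2 + 2 * np.sin(q * d) / (q * d), rtol=1e-12)
        # forward limit: (n f)^2
        assert ens.debye_profile(coords, np.array([1e-6]))[0] == pytest.approx(4.0, abs=1e-9)

    def test_matches_brute_force_double_loop(self, pool):
        coords = pool.conformers[0].coords[:50]
        q = np.linspace(0.02, 0.3, 25)
        I = ens.debye_profile(coords, q)
        brute = np.zeros_like(q)
        for i in range(len(coords)):
            for j in range(len(coords)):
                r = np.linalg.norm(coords[i] - coords[j])
                brute += np.sinc(q * r / np.pi)
        np.testing.assert_allclose(I, brute, atol=1e-10 * brute[0])

    def test_rigid_motion_invariance(self, pool, rng):
        coords = pool.conformers[1].coords
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = coords @ R.T + np.array([5.0, -3.0, 12.0])
        q = np.linspace(0.02, 0.3, 30)
        np.testing.assert_allclose(ens.debye_profile(moved, q),
                                   ens.debye_profile(coords, q), rtol=1e-10)

    def test_uniform_sphere_matches_closed_form(self, rng):
        R = 20.0
        pts = rng.uniform(-R, R, size=(8000, 3))
        pts = pts[(pts**2).sum(axis=1) <= R * R][:2000]
        q = np.linspace(0.01, 6.0 / R, 40)
        I = ens.debye_profile(pts, q)
        I /= I[0]
        ref = sphere_intensity(q, R)
        ref /= ref[0]
        rms = np.sqrt(np.mean((I - ref) ** 2)) / np.sqrt(np.mean(ref**2))
        assert rms < 0.03

    def test_coincident_beads_rejected(self):
        with pytest.raises(ValueError):
            ens.debye_profile(np.zeros((2, 3)), np.array([0.1]))


class TestChiScore:
    def test_identity(self, pool):
        exp = SAXSProfile(pool.qgrid, pool.profiles[0], 0.01 * pool.profiles[0])
        chi, c = ens.chi_score(exp, pool.profiles[0])
        assert chi == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(1.0, rel=1e-12)

    def test_scale_invariance(self, pool):
        exp = SAXSProfile(pool.qgrid, pool.profiles[0], 0.01 * pool.profiles[0])
        chi, c = ens.chi_score(exp, 3.7 * pool.profiles[0])
        assert chi == pytest.approx(0.0, abs=1e-10)
        assert c == pytest.approx(1 / 3.7, rel=1e-10)

    def test_one_sigma_perturbation_gives_chi_near_one(self, pool):
        chis = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            I = pool.profiles[4]
            sigma = 0.01 * I
            exp = SAXSProfile(pool.qgrid, I + rng.normal(0, sigma), sigma)
            chis.append(ens.chi_score(exp, I)[0])
        assert np.mean(chis) == pytest.approx(1.0, abs=0.1)

    def test_out_of_range_grid_rejected(self, pool):
        exp = SAXSProfile(pool.qgrid + 0.5, pool.profiles[0], 0.01 * pool.profiles[0])
        with pytest.raises(ValueError):
            ens.chi_score(exp, pool.profiles[0], model_q=pool.qgrid)


class TestGenerateConformers:
    def test_zero_flexible_gives_identical_copies(self, topology):
        rigid = topology.with_coords(topology.coords)
        rigid.flexible = frozenset()
        p = ens.generate_conformers(rigid, 5, seed=1)
        assert len(p) == 5
        for c in p.conformers[1:]:
            np.testing.assert_array_equal(c.coords, p.conformers[0].coords)

    def test_rg_spread_compact_to_extended(self, pool):
        assert pool.rgs.max() / pool.rgs.min() > 1.5

    def test_deterministic_under_seed(self, topology):
        p1 = ens.generate_conformers(topology, 4, seed=9)
        p2 = ens.generate_conformers(topology, 4, seed=9)
        for a, b in zip(p1.conformers, p2.conformers):
            np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(p1.profiles, p2.profiles)

    def test_conformers_are_valid_bead_models(self, pool):
        # bond geometry and hard-core invariants hold after pivoting
        for c in pool.conformers[:5]:
            d = np.linalg.norm(np.diff(c.coords, axis=0), axis=1)
            assert d.min() >= 2.9 and d.max() <= 4.1


class TestMultistateFit:
    def test_single_member_self_consistency(self, pool):
        prof, _ = simulate_saxs(pool, {7: 1.0}, noise_a=1e-5, seed=0)
        best = ens.multistate_fit(pool, prof, 1, keep=3)[0]
        assert best.members == (7,)
        assert best.chi < 2.0

    def test_two_state_weight_recovery(self, pool):
        a, b = int(np.argmin(pool.rgs)), int(np.argmax(pool.rgs))
        for seed in range(20):
            prof, _ = simulate_saxs(pool, {a: 0.7, b: 0.3}, noise_a=0.01, seed=seed)
            m = ens.multistate_fit(pool, prof, 2, keep=1)[0]
            w = dict(zip(m.members, m.weights))
            assert set(m.members) == {a, b}
            assert w[a] == pytest.approx(0.7, abs=0.05)
            assert w[b] == pytest.approx(0.3, abs=0.05)

    def test_chi_monotone_in_n_states(self, pool):
        a, b = int(np.argmin(pool.rgs)), int(np.argmax(pool.rgs))
        prof, _ = simulate_saxs(pool, {a: 0.7, b: 0.3}, noise_a=0.01, seed=42)
        chis = [ens.multistate_fit(pool, prof, n, keep=1)[0].chi for n in range(1, 6)]
        assert np.all(np.diff(chis) <= 1e-9)

    def test_no_overfitting_reward_on_pure_component(self, pool):
        prof, _ = simulate_saxs(pool, {5: 1.0}, noise_a=0.01, seed=7)
        chi1 = ens.multistate_fit(pool, prof, 1, keep=1)[0].chi
        chi5 = ens.multistate_fit(pool, prof, 5, keep=1)[0].chi
        assert (chi1 - chi5) / chi1 < 0.05

    def test_mixture_profile_linearity(self, pool):
        prof, _ = simulate_saxs(pool, {2: 0.5, 9: 0.5}, noise_a=0.01, seed=1)
        m = ens.multistate_fit(pool, prof, 2, keep=1)[0]
        mix = m.mixture_profile(pool)
        manual = sum(w * pool.profiles[i] for w, i in zip(m.weights, m.members))
        np.testing.assert_allclose(mix, manual, rtol=1e-12)

    def test_weights_normalized_positive(self, pool):
        prof, _ = simulate_saxs(pool, {2: 0.6, 9: 0.4}, noise_a=0.01, seed=2)
        for m in ens.multistate_fit(pool, prof, 3, keep=10):
            assert m.weights.sum() == pytest.approx(1.0, rel=1e-9)
            assert np.all(m.weights > 0)


class TestRgDistribution:
    def test_single_model_delta(self, pool):
        prof, _ = simulate_saxs(pool, {7: 1.0}, noise_a=1e-5, seed=0)
        best = ens.multistate_fit(pool, prof, 1, keep=1)
        edges, hist = ens.rg_distribution(best, pool)
        assert hist.sum() == pytest.approx(1.0)
        assert (hist > 0).sum() == 1
        peak_bin = edges[:-1][np.argmax(hist)]
        assert peak_bin <= pool.rgs[7] <= peak_bin + 1.0

    def test_two_state_modes_in_seven_three_ratio(self, pool):
        a, b = int(np.argmin(pool.rgs)), int(np.argmax(pool.rgs))
        models = []
        for seed in range(10):
            prof, _ = simulate_saxs(pool, {a: 0.7, b: 0.3}, noise_a=0.01, seed=seed)
            models.append(ens.multistate_fit(pool, prof, 2, keep=1)[0])
        edges, hist = ens.rg_distribution(models, pool)
        top2 = np.sort(hist)[-2:]
        assert top2[0] / top2[1] == pytest.approx(3.0 / 7.0, abs=0.1)

    def test_pool_prior_is_broad(self, pool):
        # equal-weight pool occupancy spreads over many bins
        uniform = [ens.EnsembleModel(1, (i,), np.array([1.0]), 0.0, 1.0,
                                     np.array([pool.rgs[i]])) for i in range(len(pool))]
        edges, hist = ens.rg_distribution(uniform, pool)
        assert (hist > 0).sum() >= 5

    def test_empty_rejected(self, pool):
        with pytest.raises(ValueError):
            ens.rg_distribution([], pool)
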