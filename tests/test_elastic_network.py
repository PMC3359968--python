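import numpy as np
import pytest

from riboflex.elastic_network import (
    ANMConfig,
    AnisotropicNetworkModel,
    MobilityProfile,
    anm_rmsf,
    build_anm_hessian,
    decompose_modes,
    flag_tip_outliers,
)
from riboflex.errors import DegenerateSpectrumError, ParameterError, TipFilterError
from riboflex.synthetic_data import make_anm_fixture

from .conftest import random_rotation


def spectrum_of(coords, config=ANMConfig()):
    return decompose_modes(build_anm_hessian(coords, config), config, coords=coords)


class TestHessian:
    def test_two_body_eigenvalue_2gamma(self):
        for gamma in (1.0, 3.5):
            config = ANMConfig(gamma=gamma)
            fx = make_anm_fixture("two_body", gamma=gamma)
            spectrum = decompose_modes(build_anm_hessian(fx.coords, config), config)
            assert spectrum.n_zero_modes == 5
            nonzero = spectrum.eigenvalues[5:]
            assert nonzero.size == 1
            assert nonzero[0] == pytest.approx(2.0 * gamma, rel=1e-12)

    def test_block_row_sums_vanish(self, rng):
        coords = rng.uniform(0, 10, size=(8, 3))
        hessian = build_anm_hessian(coords, ANMConfig(cutoff=13.0))
        blocks = hessian.reshape(8, 3, 8, 3)
        row_sums = blocks.sum(axis=2)
        assert np.max(np.abs(row_sums)) < 1e-10

    def test_matches_finite_difference_of_harmonic_energy(self, rng):
        config = ANMConfig(cutoff=6.0, gamma=1.3)
        coords = rng.uniform(0, 5.0, size=(6, 3))
        hessian = build_anm_hessian(coords, config)
        d0 = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        pairs = [
            (i, j)
            for i in range(6)
            for j in range(i + 1, 6)
            if d0[i, j] <= config.cutoff
        ]

        def energy(x):
            x = x.reshape(6, 3)
            return sum(
                0.5 * config.gamma * (np.linalg.norm(x[i] - x[j]) - d0[i, j]) ** 2
                for i, j in pairs
            )

        x0 = coords.ravel()
        h = 1e-4
        fd = np.zeros((18, 18))
        for a in range(18):
            for b in range(a, 18):
                ea, eb = np.eye(18)[a] * h, np.eye(18)[b] * h
                fd[a, b] = fd[b, a] = (
                    energy(x0 + ea + eb)
                    - energy(x0 + ea - eb)
                    - energy(x0 - ea + eb)
                    + energy(x0 - ea - eb)
                ) / (4 * h * h)
        assert np.max(np.abs(fd - hessian)) < 1e-4

    def test_too_few_nodes(self):
        with pytest.raises(ParameterError):
            build_anm_hessian(np.zeros((1, 3)))

    def test_disconnected_warns(self):
        coords = np.array([[0, 0, 0], [3, 0, 0], [100, 0, 0], [103, 0, 0]], float)
        with pytest.warns(UserWarning, match="disconnected"):
            build_anm_hessian(coords, ANMConfig(cutoff=13.0))


class TestModes:
    def test_tetrahedron_six_zero_six_positive(self):
        fx = make_anm_fixture("tetrahedron", spacing=5.0)
        spectrum = spectrum_of(fx.coords)
        assert spectrum.n_zero_modes == 6
        assert np.all(spectrum.eigenvalues[6:] > 1e-8)
        assert spectrum.eigenvalues.size == 12

    def test_eigenvectors_orthonormal(self):
        fx = make_anm_fixture("random_cloud", n=10, seed=3)
        spectrum = spectrum_of(fx.coords)
        gram = spectrum.eigenvectors.T @ spectrum.eigenvectors
        assert np.max(np.abs(gram - np.eye(30))) < 1e-10

    def test_spectrum_rotation_invariant(self):
        fx = make_anm_fixture("random_cloud", n=12, seed=7)
        rot = random_rotation(2)
        a = spectrum_of(fx.coords)
        b = spectrum_of(fx.coords @ rot.T + np.array([5.0, -3.0, 1.0]))
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-8)

    def test_deterministic_decomposition(self):
        fx = make_anm_fixture("random_cloud", n=9, seed=5)
        a = spectrum_of(fx.coords)
        b = spectrum_of(fx.coords.copy())
        assert np.array_equal(a.eigenvalues, b.eigenvalues)
        assert np.array_equal(a.eigenvectors, b.eigenvectors)


class TestRmsf:
    def test_two_body_symmetric(self):
        fx = make_anm_fixture("two_body")
        config = ANMConfig()
        spectrum = decompose_modes(build_anm_hessian(fx.coords, config), config)
        profile = anm_rmsf(spectrum)
        assert profile.rmsf[0] == pytest.approx(profile.rmsf[1], rel=1e-12)

    def test_gamma_scale_law(self):
        fx = make_anm_fixture("random_cloud", n=10, seed=9)
        base = anm_rmsf(spectrum_of(fx.coords, ANMConfig(gamma=1.0)))
        scaled = anm_rmsf(spectrum_of(fx.coords, ANMConfig(gamma=10.0)))
        np.testing.assert_allclose(scaled.rmsf, base.rmsf / np.sqrt(10.0), rtol=1e-9)
        np.testing.assert_allclose(
            scaled.rmsf / scaled.rmsf[0], base.rmsf / base.rmsf[0], rtol=1e-9
        )

    def test_square_network_symmetric(self):
        fx = make_anm_fixture("square", spacing=4.0)
        config = ANMConfig(cutoff=13.0)
        spectrum = decompose_modes(build_anm_hessian(fx.coords, config), config)
        profile = anm_rmsf(spectrum)
        np.testing.assert_allclose(profile.rmsf, profile.rmsf[0], rtol=1e-9)

    def test_rigid_motion_invariance(self):
        fx = make_anm_fixture("random_cloud", n=15, seed=21)
        rot = random_rotation(4)
        a = anm_rmsf(spectrum_of(fx.coords))
        b = anm_rmsf(spectrum_of(fx.coords @ rot.T + 7.5))
        np.testing.assert_allclose(a.rmsf, b.rmsf, rtol=1e-8)

    def test_total_msf_equals_pseudoinverse_trace(self):
        fx = make_anm_fixture("random_cloud", n=11, seed=13)
        hessian = build_anm_hessian(fx.coords)
        profile = anm_rmsf(decompose_modes(hessian, coords=fx.coords))
        trace = np.trace(np.linalg.pinv(hessian, rcond=1e-8))
        assert np.sum(profile.rmsf**2) == pytest.approx(trace, rel=1e-6)

    def test_degenerate_spectrum_rejected(self):
        from riboflex.elastic_network import ModeSpectrum

        spectrum = ModeSpectrum(
            n_nodes=2,
            eigenvalues=np.zeros(6),
            eigenvectors=np.eye(6),
            n_zero_modes=6,
        )
        with pytest.raises(DegenerateSpectrumError):
            anm_rmsf(spectrum)


def uniform_profile(n=10, value=1.0):
    return MobilityProfile(
        residue_ids=list(range(n)),
        rmsf=np.full(n, value),
        excluded=np.zeros(n, dtype=bool),
    )


class TestTipFilter:
    def test_uniform_profile_untouched(self):
        out, report = flag_tip_outliers(uniform_profile(12))
        assert not out.excluded.any()
        assert report.flagged == []

    def test_planted_spike_excluded(self, rng):
        rmsf = 1.0 + 0.05 * rng.standard_normal(30)
        rmsf[17] = 50.0 * np.median(rmsf)
        profile = MobilityProfile(list(range(30)), rmsf, np.zeros(30, bool))
        out, report = flag_tip_outliers(profile)
        assert report.flagged == [17]
        assert out.excluded[17] and out.excluded.sum() == 1

    def test_manual_list_overrides(self):
        profile = uniform_profile(10)
        out, report = flag_tip_outliers(profile, manual_exclusions=[8, 9])
        assert report.flagged == [8, 9]
        assert list(np.nonzero(out.excluded)[0]) == [8, 9]

    def test_refuses_mass_exclusion(self, rng):
        rmsf = np.ones(10)
        rmsf[[8, 9]] = 100.0
        profile = MobilityProfile(list(range(10)), rmsf, np.zeros(10, bool))
        with pytest.raises(TipFilterError):
            flag_tip_outliers(profile)

    def test_too_short_profile(self):
        with pytest.raises(ParameterError):
            flag_tip_outliers(uniform_profile(5))


class TestModelResults:
    def test_fit_from_chain(self, toy_complex):
        structure, _, _ = toy_complex
        model = AnisotropicNetworkModel.from_chain(structure.chain("A"))
        results = model.fit()
        assert len(results.rmsf) == 6
        assert np.all(results.rmsf > 0)
        frame = results.summary()
        assert set(frame.columns) == {"residue_id", "rmsf", "excluded", "msf"}

    def test_fit_deterministic(self):
        fx = make_anm_fixture("random_cloud", n=20, seed=2)
        a = AnisotropicNetworkModel(fx.coords).fit()
        b = AnisotropicNetworkModel(fx.coords).fit()
        assert np.array_equal(a.rmsf, b.rmsf)
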