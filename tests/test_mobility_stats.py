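import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riboflex.elastic_network import MobilityProfile
from riboflex.errors import AlignmentError, ParameterError
from riboflex.mobility_stats import (
    EnrichmentTest,
    bfactor_from_rmsf,
    enrichment_factor,
    ensemble_rmsd,
    ensemble_rmsf,
    permutation_pvalue,
    profile_correlation,
    rmsf_from_bfactor,
)
from riboflex.synthetic_data import MobilitySampleSpec, make_mobility_sample

from .conftest import random_rotation


def profile_from(values, excluded=None, ids=None):
    values = np.asarray(values, float)
    return MobilityProfile(
        residue_ids=list(ids) if ids is not None else list(range(len(values))),
        rmsf=values,
        excluded=np.asarray(excluded, bool)
        if excluded is not None
        else np.zeros(len(values), bool),
    )


class TestEnrichmentFactor:
    def test_simple_ratio(self):
        assert enrichment_factor(profile_from([2, 2, 1, 1]), {0, 1}) == pytest.approx(2.0)

    def test_constant_profile_unity(self):
        assert enrichment_factor(profile_from([1.3] * 8), {2, 5}) == pytest.approx(1.0)

    def test_excluded_residues_ignored(self):
        profile = profile_from([2, 2, 1, 1, 99], excluded=[0, 0, 0, 0, 1])
        assert enrichment_factor(profile, {0, 1, 4}) == pytest.approx(2.0)

    @pytest.mark.parametrize("contacts", [set(), {0, 1, 2, 3}])
    def test_empty_side_rejected(self, contacts):
        with pytest.raises(ParameterError):
            enrichment_factor(profile_from([1, 2, 3, 4]), contacts)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True, deadline=None)
    def test_scale_invariance(self, c):
        values = np.array([0.5, 1.5, 2.5, 0.7, 1.1, 3.0])
        ef1 = enrichment_factor(profile_from(values), {1, 2})
        ef2 = enrichment_factor(profile_from(values * c), {1, 2})
        assert ef2 == pytest.approx(ef1, rel=1e-9)


class TestPermutationTest:
    def test_constant_profile_p_one(self):
        result = permutation_pvalue(profile_from([2.0] * 12), {0, 3}, n_perm=200, seed=0)
        assert result.p_value == 1.0

    def test_bitwise_reproducible(self):
        profile, contacts, _ = make_mobility_sample(MobilitySampleSpec(seed=4))
        a = permutation_pvalue(profile, contacts, n_perm=500, seed=42)
        b = permutation_pvalue(profile, contacts, n_perm=500, seed=42)
        assert a.p_value == b.p_value and a.null_mean == b.null_mean

    def test_p_within_exact_bounds(self):
        profile, contacts, _ = make_mobility_sample(MobilitySampleSpec(seed=8, effect=1.0))
        for n_perm in (1, 10, 200):
            p = permutation_pvalue(profile, contacts, n_perm=n_perm, seed=1).p_value
            assert 1.0 / (1 + n_perm) <= p <= 1.0

    def test_single_permutation_boundary(self):
        profile, contacts, _ = make_mobility_sample(MobilitySampleSpec(seed=2))
        p = permutation_pvalue(profile, contacts, n_perm=1, seed=3).p_value
        assert p in (0.5, 1.0)

    def test_planted_effect_detected(self):
        profile, contacts, _ = make_mobility_sample(
            MobilitySampleSpec(N=100, C=20, effect=2.0, noise_sd=0.1, seed=7)
        )
        result = permutation_pvalue(profile, contacts, n_perm=1999, seed=11)
        assert 1.8 <= result.observed <= 2.2
        assert result.p_value <= 0.001

    def test_scale_invariant_p(self):
        profile, contacts, _ = make_mobility_sample(MobilitySampleSpec(seed=6))
        scaled = profile_from(profile.rmsf * 37.0)
        a = permutation_pvalue(profile, contacts, n_perm=300, seed=9)
        b = permutation_pvalue(scaled, contacts, n_perm=300, seed=9)
        assert a.p_value == b.p_value

    def test_model_wrapper_summary(self):
        profile, contacts, _ = make_mobility_sample(MobilitySampleSpec(seed=5))
        result = EnrichmentTest(profile, contacts).fit(n_perm=100, seed=2)
        summary = result.summary()
        assert summary.loc["N", "value"] == 100
        assert summary.loc["C", "value"] == 20

    def test_contact_superset_rejected(self):
        with pytest.raises(ParameterError):
            permutation_pvalue(profile_from([1, 2, 3]), {0, 1, 2}, n_perm=10, seed=0)


class TestBfactor:
    def test_closed_form(self):
        assert bfactor_from_rmsf(0.0) == 0.0
        assert bfactor_from_rmsf(1.0) == pytest.approx(8 * np.pi**2 / 3, rel=1e-12)
        assert bfactor_from_rmsf(1.0) == pytest.approx(26.3189, abs=1e-3)

    def test_round_trip(self):
        values = np.array([0.0, 0.3, 1.0, 2.7])
        np.testing.assert_allclose(
            rmsf_from_bfactor(bfactor_from_rmsf(values)), values, atol=1e-12
        )

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            bfactor_from_rmsf(-0.1)


@pytest.fixture()
def base_frame(rng):
    frame = rng.normal(size=(100, 3)) * 20.0
    return frame - frame.mean(axis=0)


class TestEnsembleRmsd:
    def test_identity_frame_zero(self, base_frame):
        series = ensemble_rmsd(np.stack([base_frame, base_frame]))
        np.testing.assert_allclose(series, 0.0, atol=1e-12)

    def test_rotated_copy_zero(self, base_frame):
        rot = random_rotation(3)
        series = ensemble_rmsd(np.stack([base_frame, base_frame @ rot.T + 4.0]))
        assert series[1] < 1e-8

    def test_single_displaced_atom_formula(self, base_frame):
        moved = base_frame.copy()
        moved[0] += np.array([1.0, 0.0, 0.0])
        direct = np.sqrt(np.sum((moved - base_frame) ** 2) / len(base_frame))
        assert direct == pytest.approx(0.1)
        fitted = ensemble_rmsd(np.stack([base_frame, moved]))[1]
        assert 0.09 < fitted <= direct + 1e-12

    def test_mismatched_atoms_rejected(self, base_frame):
        with pytest.raises(AlignmentError):
            ensemble_rmsd(np.stack([base_frame, base_frame]), reference=base_frame[:10])


class TestEnsembleRmsf:
    def test_duplicated_frames_zero(self, base_frame):
        profile = ensemble_rmsf(np.repeat(base_frame[None], 5, axis=0))
        np.testing.assert_allclose(profile.rmsf, 0.0, atol=1e-10)

    def test_gaussian_closed_form(self, base_frame, rng):
        m = 500
        base = base_frame.copy()
        base[7] = [0.5, -0.3, 0.2]  # near the centroid: minimal fit absorption
        frames = np.repeat(base[None], m, axis=0)
        frames[:, 7, :] += rng.normal(0.0, 1.0, size=(m, 3))
        profile = ensemble_rmsf(frames)
        expected = np.sqrt(3.0) * np.sqrt((m - 1) / m)
        assert profile.rmsf[7] == pytest.approx(expected, rel=0.05)
        assert np.delete(profile.rmsf, 7).max() < 0.25

    def test_global_rotation_invariant(self, base_frame, rng):
        frames = np.repeat(base_frame[None], 20, axis=0)
        frames += rng.normal(0, 0.2, size=frames.shape)
        rot = random_rotation(5)
        a = ensemble_rmsf(frames)
        b = ensemble_rmsf(frames @ rot.T)
        np.testing.assert_allclose(a.rmsf, b.rmsf, atol=1e-8)

    def test_per_residue_averaging(self, rng):
        frames = rng.normal(size=(10, 6, 3)) * 5
        profile = ensemble_rmsf(frames, residue_index=[0, 0, 1, 1, 2, 2])
        assert len(profile.rmsf) == 3

    def test_single_frame_rejected(self, base_frame):
        with pytest.raises(ParameterError):
            ensemble_rmsf(base_frame[None])


class TestProfileCorrelation:
    def test_self_correlation_one(self):
        a = profile_from([1, 2, 3, 4, 5.0])
        assert profile_correlation(a, a) == pytest.approx(1.0)

    def test_anticorrelated_minus_one(self):
        a = profile_from([1, 2, 3, 4, 5.0])
        b = profile_from(10.0 - a.rmsf)
        assert profile_correlation(a, b) == pytest.approx(-1.0)

    def test_termini_trim_matches_direct_formula(self, rng):
        xs = rng.uniform(0.5, 3.0, size=20)
        ys = xs + rng.normal(0, 0.3, size=20)
        r = profile_correlation(profile_from(xs), profile_from(ys), exclude_termini=2)
        direct = np.corrcoef(xs[2:-2], ys[2:-2])[0, 1]
        assert r == pytest.approx(direct, rel=1e-12)

    def test_alignment_by_residue_id(self):
        a = profile_from([1, 2, 3, 4.0], ids=[1, 2, 3, 4])
        b = profile_from([9, 2, 3, 4.0], ids=[0, 2, 3, 4])
        r = profile_correlation(a, b)
        assert r == pytest.approx(1.0)  # only ids 2,3,4 shared, identical values

    def test_too_few_shared(self):
        a = profile_from([1, 2.0], ids=[0, 1])
        with pytest.raises(ParameterError):
            profile_correlation(a, a)
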