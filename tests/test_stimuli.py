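"""The generative model: circular geometry, acuity model, stimulus
profiles and position priors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from avinet import stimuli
from avinet.stimuli import (EnvironmentParams, calibrate_epsilon, circular_distance,
                            dendritic_diameter, make_stimulus, sample_positions,
                            signed_circular_difference, visual_acuity, visual_sigma,
                            visual_strength)


class TestCircularDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (1, 180, 1),    # position 1 is one degree from 180 by wrap
            (1, 2, 1),
            (90, 90, 0),
            (10, 100, 90),  # boundary of the wrap branch
            (0, 180, 0),
            (179, 3, 4),
        ],
    )
    def test_cases(self, a, b, expected):
        assert circular_distance(a, b) == pytest.approx(expected)

    @given(st.floats(0, 180), st.floats(0, 180))
    @settings(max_examples=200, deadline=None)
    def test_properties(self, a, b):
        d = circular_distance(a, b)
        assert 0 <= d <= 90
        assert d == pytest.approx(circular_distance(b, a))
        assert circular_distance(a, a) == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            circular_distance(-1, 10)
        with pytest.raises(ValueError):
            circular_distance(10, 181)

    @given(st.floats(0, 180), st.floats(0, 180))
    @settings(max_examples=100, deadline=None)
    def test_signed_difference_consistent(self, a, b):
        s = signed_circular_difference(a, b)
        assert -90 < s <= 90
        assert abs(s) == pytest.approx(circular_distance(a, b), abs=1e-9)


class TestAcuityModel:
    @pytest.mark.parametrize(
        "e, expected",
        [(0, 2.1), (30, 17.7), (90, 25.14)],
    )
    def test_dendritic_diameter(self, e, expected):
        assert dendritic_diameter(e) == pytest.approx(expected)

    def test_acuity_values(self):
        assert visual_acuity(0) == pytest.approx(60 / (3 * 2.1))
        assert visual_acuity(90) == pytest.approx(60 / (3 * 25.14))

    def test_acuity_diameter_identity(self):
        e = np.linspace(0, 90, 19)
        assert np.allclose(visual_acuity(e) * dendritic_diameter(e) * 3, 60)

    def test_sigma_endpoints(self, env):
        assert visual_sigma(0, env) == 4.0
        assert visual_sigma(90, env) == pytest.approx(12.0, abs=1e-6)
        assert np.all(visual_sigma(np.linspace(0, 90, 91), env) >= 4.0)

    def test_sigma_flat_when_epsilon_zero(self):
        env0 = EnvironmentParams(epsilon=0.0)
        assert np.allclose(visual_sigma(np.linspace(0, 90, 10), env0), 4.0)

    def test_epsilon_calibrations(self):
        assert calibrate_epsilon() == pytest.approx(125.0, rel=0.01)
        env_max = EnvironmentParams(epsilon=calibrate_epsilon(mode="max"))
        sig = visual_sigma(np.linspace(0, 90, 901), env_max)
        assert sig.max() == pytest.approx(12.0, abs=0.01)

    def test_strength_at_fovea_and_substitution(self, env):
        assert visual_strength(0, env) == pytest.approx(env.strength_v0)
        # sigma=8, sigma0=4, alpha=0.3 -> ratio 8/(4+1.2)
        env2 = EnvironmentParams(alpha=0.3)
        e8 = 27.0555  # eccentricity where sigma_v ~ 8 (solved numerically below)
        from scipy.optimize import brentq

        e8 = brentq(lambda e: visual_sigma(e, env2) - 8.0, 0, 60)
        assert visual_strength(e8, env2) == pytest.approx(8 / 5.2 * env2.strength_v0, rel=1e-6)


class TestStimulus:
    def test_noiseless_profile_area_and_peak(self, env):
        s = make_stimulus("V", 90.0, env)
        assert s.sigma_deg == 4.0
        assert s.profile.argmax() + 1 == 90
        assert s.profile.sum() == pytest.approx(env.strength_v0, rel=0.01)
        # symmetric about the center
        assert s.profile[89 - 3] == pytest.approx(s.profile[89 + 3])

    @pytest.mark.parametrize("center", [5.0, 60.0, 140.0])
    def test_area_close_to_strength_for_wide_profiles(self, env, center):
        for mod in "AV":
            s = make_stimulus(mod, center, env)
            assert s.sigma_deg >= 3
            assert s.profile.sum() == pytest.approx(s.strength, rel=0.01)

    def test_auditory_width_constant(self, env):
        for center in (10.0, 90.0, 170.0):
            assert make_stimulus("A", center, env).sigma_deg == env.sigma_a_deg

    def test_circular_shift_equivariance(self, env):
        base = make_stimulus("A", 40.0, env).profile
        shifted = make_stimulus("A", 53.0, env).profile
        assert np.allclose(np.roll(base, 13), shifted)

    def test_noise_contract(self, env, rng):
        """Empirical SD of the additive noise matches noise_frac x peak."""
        ref = make_stimulus("V", 90.0, env).profile
        peak = ref.max()
        draws = np.array([
            (make_stimulus("V", 90.0, env, 0.5, rng).profile - ref)[89]
            for _ in range(4000)
        ])
        assert draws.std() == pytest.approx(0.5 * peak, rel=0.05)
        assert abs(draws.mean()) < 0.05 * peak

    def test_invalid_inputs(self, env, rng):
        with pytest.raises(ValueError):
            make_stimulus("X", 90.0, env)
        with pytest.raises(ValueError):
            make_stimulus("V", 180.0, env)
        with pytest.raises(ValueError):
            make_stimulus("V", 90.0, env, noise_frac=0.5)  # rng missing


class TestPriors:
    def test_visual_prior_moments(self, env, rng):
        draws = sample_positions("uniV", env, rng, size=10_000)
        assert draws.mean() == pytest.approx(90, abs=1.0)
        assert draws.std() == pytest.approx(30, abs=1.0)

    def test_auditory_prior_uniform_gof(self, env, rng):
        draws = sample_positions("uniA", env, rng, size=100_000)
        counts, _ = np.histogram(draws, bins=18, range=(0.5, 180.5))
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=17)

    def test_visual_prior_gof(self, env, rng):
        """Truncated-Gaussian prior matches its density on 18 bins."""
        n = 100_000
        draws = sample_positions("uniV", env, rng, size=n)
        edges = np.linspace(0, 180, 19)
        counts, _ = np.histogram(draws, bins=edges)
        cdf = stats.norm(90, 30).cdf
        probs = np.diff(cdf(edges)) / (cdf(180) - cdf(0))
        chi2 = ((counts - n * probs) ** 2 / (n * probs)).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=17)

    def test_cross_pairs_nearly_coincident(self, rng):
        env0 = EnvironmentParams(beta=0.0)
        pairs = sample_positions("cross", env0, rng, size=10_000)
        d = np.abs(signed_circular_difference(pairs[:, 0], pairs[:, 1]))
        # half-normal mean for a 1-deg jitter
        assert d.mean() == pytest.approx(np.sqrt(2 / np.pi), rel=0.05)

    def test_cross_pairs_independent_when_beta_one(self, rng):
        env1 = EnvironmentParams(beta=1.0)
        pairs = sample_positions("cross", env1, rng, size=20_000)
        ang_v = np.deg2rad(2 * pairs[:, 0])
        ang_a = np.deg2rad(2 * pairs[:, 1])
        r = abs(np.corrcoef(np.sin(ang_v), np.sin(ang_a))[0, 1]) + \
            abs(np.corrcoef(np.cos(ang_v), np.cos(ang_a))[0, 1])
        assert r < 0.05

    def test_invalid_condition(self, env, rng):
        with pytest.raises(ValueError):
            sample_positions("bimodal", env, rng)


def test_profile_csv_export(env, tmp_path):
    import pandas as pd

    s = stimuli.make_stimulus("A", 60.0, env)
    path = tmp_path / "profile.csv"
    stimuli.export_profile_csv(s, path)
    table = pd.read_csv(path)
    assert list(table.columns) == ["position_deg", "activity"]
    assert np.allclose(table["activity"], s.profile)


def test_environment_param_validation():
    with pytest.raises(ValueError):
        EnvironmentParams(alpha=1.5)
    with pytest.raises(ValueError):
        EnvironmentParams(strength_a=5.0, strength_v0=10.0)
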