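"""Generative model of the audio-visual sensory environment.

The azimuthal space is a circular axis of 180 positions (1..180 deg) so
that positions 1 and 180 are neighbours and no border effects arise:
before learning, every position is statistically equivalent.

Stimuli of either modality are Gaussian activity profiles over this axis
(area = stimulus strength) with additive Gaussian white noise.  Visual
stimuli are spatially accurate near the fovea (90 deg) and broaden with
eccentricity following the dendritic-field diameter of parvocellular
retinal ganglion cells; auditory stimuli have a constant, much larger
width.  Stimulus positions are drawn from priors that encode the
statistics of experience: visual positions cluster at the fovea,
auditory positions are uniform, and cross-modal pairs are almost always
spatially coincident.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "N_POSITIONS",
    "PERIOD_DEG",
    "FOVEA_DEG",
    "POSITIONS_DEG",
    "EnvironmentParams",
    "Stimulus",
    "circular_distance",
    "signed_circular_difference",
    "dendritic_diameter",
    "visual_acuity",
    "visual_sigma",
    "visual_strength",
    "calibrate_epsilon",
    "make_stimulus",
    "sample_positions",
]

#: number of neurons / grid positions per layer
N_POSITIONS = 180
#: period of the circular azimuthal axis (deg)
PERIOD_DEG = 180.0
#: azimuth of the fovea (deg)
FOVEA_DEG = 90.0
#: grid of stimulus positions theta_j = 1..180 deg
POSITIONS_DEG = np.arange(1.0, N_POSITIONS + 1.0)

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _circ_dist(a, b):
    """Unchecked circular distance on the 180-deg axis (vectorised)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    return np.where(d > PERIOD_DEG / 2.0, PERIOD_DEG - d, d)


def circular_distance(a, b):
    """Circular distance between azimuths ``a`` and ``b``.

    Distances wrap around the 180-deg axis, so the result lies in
    [0, 90]; e.g. position 1 is one degree away from both 2 and 180.

    Parameters
    ----------
    a, b : float or array-like
        Azimuthal positions in degrees, each in [0, 180].

    Returns
    -------
    float or ndarray
        Circular distance in degrees.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any((a < 0) | (a > PERIOD_DEG)) or np.any((b < 0) | (b > PERIOD_DEG)):
        raise ValueError("positions must lie in [0, 180] deg")
    d = _circ_dist(a, b)
    return float(d) if d.ndim == 0 else d


def signed_circular_difference(a, b):
    """Signed circular difference ``a - b`` mapped into (-90, 90].

    Used for position errors (perceived minus true) so that wrap-around
    never inflates an error beyond half the period.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + PERIOD_DEG / 2.0) % PERIOD_DEG - PERIOD_DEG / 2.0
    d = np.where(d == -PERIOD_DEG / 2.0, PERIOD_DEG / 2.0, d)
    return float(d) if d.ndim == 0 else d


def dendritic_diameter(e):
    """Dendritic-field diameter of parvocellular cells (arcmin).

    Empirical cubic in eccentricity ``e`` (deg)::

        D(e) = 2.1 + 0.058 e + 0.022 e^2 - 0.00022 e^3

    The cubic is non-monotone: it peaks near e = 68 deg and decreases
    again toward 90 deg.  It is evaluated as printed over [0, 90].
    """
    e = np.asarray(e, dtype=float)
    if np.any((e < 0) | (e > 90)):
        raise ValueError("eccentricity must lie in [0, 90] deg")
    d = 2.1 + 0.058 * e + 0.022 * e**2 - 0.00022 * e**3
    return float(d) if d.ndim == 0 else d


def visual_acuity(e):
    """Visual acuity (1/deg) at eccentricity ``e``: A(e) = 60 / (3 D(e))."""
    d = np.asarray(dendritic_diameter(e), dtype=float)
    a = 60.0 / (3.0 * d)
    return float(a) if a.ndim == 0 else a


def calibrate_epsilon(target_sigma_deg: float = 12.0, mode: str = "endpoint") -> float:
    """Acuity-to-width scale factor reaching ``target_sigma_deg``.

    ``mode='endpoint'`` pins the visual input width at 90-deg
    eccentricity; ``mode='max'`` pins the maximum width over [0, 90]
    (attained near e = 68 deg, where the dendritic-diameter cubic
    peaks).  Both calibrations keep sigma_v(0) at its foveal value.
    """
    d0 = dendritic_diameter(0.0)
    if mode == "endpoint":
        span = dendritic_diameter(90.0) - d0
    elif mode == "max":
        span = float(np.max(dendritic_diameter(np.linspace(0.0, 90.0, 9001)))) - d0
    else:
        raise ValueError(f"unknown calibration mode: {mode!r}")
    return (target_sigma_deg - 4.0) * 360.0 / span


@dataclass
class EnvironmentParams:
    """Constants of the generative model of the sensory environment.

    Attributes
    ----------
    sigma0_v_deg : float
        SD of the visual input at the fovea (deg).
    sigma_a_deg : float
        SD of the auditory input, independent of azimuth (deg).
    epsilon : float
        Scale converting dendritic-diameter growth into visual-input
        width growth; calibrated so sigma_v(90) = 12 deg.
    alpha : float
        Attenuation (0 < alpha < 1) of the eccentricity-driven growth
        of the visual input strength.
    strength_v0 : float
        Area of the visual input at the fovea (activity x deg).
    strength_a : float
        Area of the auditory input (activity x deg); larger than the
        visual one because the wider input needs more drive against
        lateral competition.
    lambda_v_deg : float
        SD of the Gaussian prior of visual positions around the fovea.
    lambda_av_deg : float
        Space constant of the audio-visual coincidence prior.
    beta : float
        Weight of the uniform (independent-sources) component of the
        cross-modal conditional prior; close to zero.
    train_noise_frac : float
        SD of the training noise as a fraction of the noiseless peak.
    """

    sigma0_v_deg: float = 4.0
    sigma_a_deg: float = 20.0
    epsilon: float = 125.0
    alpha: float = 0.3
    strength_v0: float = 10.0
    strength_a: float = 22.0
    lambda_v_deg: float = 30.0
    lambda_av_deg: float = 1.0
    beta: float = 0.01
    train_noise_frac: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.strength_a <= self.strength_v0:
            raise ValueError("auditory strength must exceed foveal visual strength")
        for name in ("sigma0_v_deg", "sigma_a_deg", "strength_v0", "strength_a",
                     "lambda_v_deg", "lambda_av_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta < 0 or self.train_noise_frac < 0:
            raise ValueError("beta and train_noise_frac must be nonnegative")


def visual_sigma(e, env: EnvironmentParams):
    """SD of the visual input (deg) at eccentricity ``e`` (deg).

    Grows linearly with the dendritic-field diameter:
    sigma_v(e) = sigma0 + (epsilon/360) (D(e) - D(0)).
    """
    d = np.asarray(dendritic_diameter(e), dtype=float)
    s = env.sigma0_v_deg + env.epsilon / 360.0 * (d - 2.1)
    return float(s) if s.ndim == 0 else s


def visual_strength(e, env: EnvironmentParams):
    """Area of the visual input at eccentricity ``e`` (deg).

    The strength grows with the input width sigma_v(e), attenuated so
    the growth is sub-proportional::

        i(e) = sigma_v(e) / (sigma0 + alpha (sigma_v(e) - sigma0)) * i(0)
    """
    s = np.asarray(visual_sigma(e, env), dtype=float)
    out = s / (env.sigma0_v_deg + env.alpha * (s - env.sigma0_v_deg)) * env.strength_v0
    return float(out) if out.ndim == 0 else out


@dataclass
class Stimulus:
    """One noisy Gaussian activity profile over the 180 positions."""

    modality: str
    center_deg: float
    sigma_deg: float
    strength: float
    noise_sd: float
    profile: np.ndarray = field(repr=False)

    def noiseless(self) -> np.ndarray:
        """The noise-free Gaussian template of this stimulus."""
        return gaussian_profile(self.center_deg, self.sigma_deg, self.strength)


def gaussian_profile(center_deg: float, sigma_deg: float, strength: float) -> np.ndarray:
    """Noise-free Gaussian activity profile (area = strength) on the grid."""
    d = _circ_dist(center_deg, POSITIONS_DEG)
    return strength / (_SQRT_2PI * sigma_deg) * np.exp(-(d**2) / (2.0 * sigma_deg**2))


def stimulus_shape(modality: str, center_deg: float, env: EnvironmentParams):
    """Width and strength of a stimulus of ``modality`` at ``center_deg``.

    Visual parameters follow the eccentricity model evaluated at
    ``|center - 90|``; auditory ones are constants.
    """
    if modality == "V":
        e = abs(float(center_deg) - FOVEA_DEG)
        return visual_sigma(e, env), visual_strength(e, env)
    if modality == "A":
        return env.sigma_a_deg, env.strength_a
    raise ValueError(f"modality must be 'A' or 'V', got {modality!r}")


def make_stimulus(
    modality: str,
    center_deg: float,
    env: EnvironmentParams,
    noise_frac: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Stimulus:
    """Generate one (noisy) stimulus.

    Parameters
    ----------
    modality : {'A', 'V'}
    center_deg : float
        True source azimuth in [0, 180).
    env : EnvironmentParams
    noise_frac : float
        SD of the additive Gaussian white noise, expressed as a
        fraction of the peak of the noiseless profile.  The noise is
        drawn once per stimulus (it is static over the network
        dynamics) and is *not* clipped at zero.
    rng : numpy.random.Generator, optional
        Required when ``noise_frac > 0``.
    """
    if not 0.0 <= center_deg < PERIOD_DEG:
        raise ValueError("center_deg must lie in [0, 180)")
    if noise_frac < 0:
        raise ValueError("noise_frac must be nonnegative")
    sigma, strength = stimulus_shape(modality, center_deg, env)
    profile = gaussian_profile(center_deg, sigma, strength)
    peak = strength / (_SQRT_2PI * sigma)
    noise_sd = noise_frac * peak
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng is required for a noisy stimulus")
        profile = profile + rng.normal(0.0, noise_sd, N_POSITIONS)
    return Stimulus(modality, float(center_deg), float(sigma), float(strength),
                    float(noise_sd), profile)


def _sample_visual_prior(env: EnvironmentParams, rng: np.random.Generator, size: int) -> np.ndarray:
    # Gaussian prior at the fovea, truncated to [0, 180) by rejection
    # (~0.3% of draws redrawn for lambda_v = 30).
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(FOVEA_DEG, env.lambda_v_deg, size - n)
        keep = draw[(draw >= 0.0) & (draw < PERIOD_DEG)]
        out[n : n + keep.size] = keep
        n += keep.size
    return out


def _sample_coincident(centers: np.ndarray, env: EnvironmentParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Companion positions from the cross-modal conditional prior."""
    size = centers.size
    uniform = rng.random(size) < env.beta
    other = np.where(
        uniform,
        rng.random(size) * PERIOD_DEG,
        (centers + rng.normal(0.0, env.lambda_av_deg, size)) % PERIOD_DEG,
    )
    return other


def sample_positions(
    condition: str,
    env: EnvironmentParams,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw stimulus positions for one training/testing condition.

    ``'uniV'`` draws a visual azimuth from the foveal Gaussian prior;
    ``'uniA'`` draws an auditory azimuth uniformly over the 180 grid
    positions; ``'cross'`` draws a pair (theta_v, theta_a): with equal
    probability the pair follows the visual or the auditory marginal,
    and the companion position is coincident up to the lambda_av
    jitter (or, with probability beta, independent and uniform).

    Returns a float (or pair of floats); with ``size`` given, arrays of
    that length (``cross`` returns a (size, 2) array of [theta_v,
    theta_a] rows).
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    if condition == "uniV":
        out = _sample_visual_prior(env, rng, n)
        return float(out[0]) if scalar else out
    if condition == "uniA":
        out = rng.integers(1, N_POSITIONS + 1, n).astype(float)
        return float(out[0]) if scalar else out
    if condition == "cross":
        lead_visual = rng.random(n) < 0.5
        theta_v = np.empty(n)
        theta_a = np.empty(n)
        nv = int(lead_visual.sum())
        if nv:
            theta_v[lead_visual] = _sample_visual_prior(env, rng, nv)
            theta_a[lead_visual] = _sample_coincident(theta_v[lead_visual], env, rng)
        na = n - nv
        if na:
            theta_a[~lead_visual] = rng.integers(1, N_POSITIONS + 1, na).astype(float)
            theta_v[~lead_visual] = _sample_coincident(theta_a[~lead_visual], env, rng)
        pairs = np.column_stack([theta_v, theta_a])
        return (float(theta_v[0]), float(theta_a[0])) if scalar else pairs
    raise ValueError(f"unknown condition: {condition!r}")


def export_profile_csv(stimulus: Stimulus, path) -> None:
    """Write a stimulus profile as CSV (position_deg, activity)."""
    import pandas as pd

    pd.DataFrame({"position_deg": POSITIONS_DEG, "activity": stimulus.profile}).to_csv(
        path, index=False
    )


def env_to_dict(env: EnvironmentParams) -> dict:
    return {f.name: getattr(env, f.name) for f in fields(env)}
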