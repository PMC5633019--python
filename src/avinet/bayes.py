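"""Reference maximum-a-posteriori estimator.

The generative model is known exactly: an observed profile is a
Gaussian template (whose width and area follow the eccentricity model
for vision and are constant for audition) plus i.i.d. Gaussian white
noise of known SD.  Likelihoods are therefore Gaussian over the 180
residuals; priors are the same densities that generate the training
positions.  The MAP estimate is the exhaustive argmax of
log-likelihood(s) + log-prior over the 1-deg grid (180 candidates per
modality, 180x180 for a cross-modal pair), which removes any optimiser
ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import (FOVEA_DEG, N_POSITIONS, PERIOD_DEG, POSITIONS_DEG,
                      EnvironmentParams, _circ_dist, gaussian_profile,
                      stimulus_shape)

__all__ = [
    "PosteriorGrid",
    "template_matrix",
    "log_likelihood",
    "log_likelihood_profile",
    "log_prior",
    "map_estimate",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def template_matrix(modality: str, env: EnvironmentParams) -> np.ndarray:
    """Noiseless stimulus templates at every grid position.

    Row theta (0-based: candidate position ``theta+1`` deg) holds the
    expected profile of a stimulus of ``modality`` centred there.
    """
    templates = np.empty((N_POSITIONS, N_POSITIONS))
    for i, theta in enumerate(POSITIONS_DEG):
        sigma, strength = stimulus_shape(modality, theta % PERIOD_DEG, env)
        templates[i] = gaussian_profile(theta, sigma, strength)
    return templates


def log_likelihood_profile(
    observed: np.ndarray, modality: str, env: EnvironmentParams, noise_sd: float,
    templates: np.ndarray | None = None,
) -> np.ndarray:
    """Log-likelihood of an observed profile at every candidate position.

    Independent Gaussian noise on each of the 180 samples gives
    log L(theta) = -sum_j (i_j - template_theta_j)^2 / (2 nu^2) + const.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (N_POSITIONS,):
        raise ValueError(f"observed profile must have length {N_POSITIONS}")
    if templates is None:
        templates = template_matrix(modality, env)
    resid = observed[None, :] - templates
    const = -N_POSITIONS / 2.0 * np.log(2.0 * np.pi * noise_sd**2)
    return const - np.einsum("ij,ij->i", resid, resid) / (2.0 * noise_sd**2)


def log_likelihood(
    observed: np.ndarray, candidate_theta: float, modality: str,
    env: EnvironmentParams, noise_sd: float,
) -> float:
    """Log-likelihood at a single candidate grid position (deg)."""
    idx = int(round(candidate_theta)) - 1
    if not 0 <= idx < N_POSITIONS:
        raise ValueError("candidate_theta must lie on the 1..180 grid")
    return float(log_likelihood_profile(observed, modality, env, noise_sd)[idx])


def _visual_prior_grid(env: EnvironmentParams) -> np.ndarray:
    p = np.exp(-((POSITIONS_DEG - FOVEA_DEG) ** 2) / (2.0 * env.lambda_v_deg**2))
    return p / p.sum()


def _conditional_grid(env: EnvironmentParams) -> np.ndarray:
    """p(theta_other | theta) on the grid: beta-weighted uniform plus a
    circular Gaussian of SD lambda_av around theta (rows sum to 1)."""
    d = _circ_dist(POSITIONS_DEG[:, None], POSITIONS_DEG[None, :])
    g = np.exp(-(d**2) / (2.0 * env.lambda_av_deg**2))
    g /= g.sum(axis=1, keepdims=True)
    return env.beta / N_POSITIONS + (1.0 - env.beta) * g


def log_prior(
    theta_a: float | None, theta_v: float | None, condition: str,
    env: EnvironmentParams,
) -> float:
    """Log prior probability of grid position(s) under a condition.

    ``uniV``: Gaussian at the fovea on theta_v; ``uniA``: uniform on
    theta_a; ``cross``: even mixture of visual-led and auditory-led
    factorisations with the near-coincidence conditional.  Densities
    are normalised on the grid.
    """
    surface = log_prior_surface(condition, env)
    ia = None if theta_a is None else int(round(theta_a)) - 1
    iv = None if theta_v is None else int(round(theta_v)) - 1
    if condition == "uniA":
        return float(surface[ia])
    if condition == "uniV":
        return float(surface[iv])
    return float(surface[ia, iv])


def log_prior_surface(condition: str, env: EnvironmentParams) -> np.ndarray:
    """Log-prior on the grid: a length-180 vector for unisensory
    conditions, a (theta_a, theta_v)-indexed 180x180 matrix for
    ``cross`` (probabilities sum to 1)."""
    if condition == "uniA":
        return np.full(N_POSITIONS, -np.log(N_POSITIONS))
    if condition == "uniV":
        return np.log(_visual_prior_grid(env))
    if condition == "cross":
        p_v = _visual_prior_grid(env)
        p_a = np.full(N_POSITIONS, 1.0 / N_POSITIONS)
        cond = _conditional_grid(env)  # symmetric in its two arguments
        # joint[a, v] = 0.5 p(v) p(a|v) + 0.5 p(a) p(v|a)
        joint = 0.5 * p_v[None, :] * cond + 0.5 * p_a[:, None] * cond
        joint /= joint.sum()
        with np.errstate(divide="ignore"):  # log 0 -> -inf is fine here
            return np.log(joint)
    raise ValueError(f"unknown condition: {condition!r}")


@dataclass
class PosteriorGrid:
    """Log-posterior pieces for one observation pair (diagnostics)."""

    loglik_a: np.ndarray | None
    loglik_v: np.ndarray | None
    log_prior: np.ndarray
    log_posterior: np.ndarray


def _argmax_deterministic(surface: np.ndarray) -> tuple[int, ...]:
    """Argmax with deterministic tie-breaking: among exact ties, the
    candidate closest (circularly) to the grid centre, then the lowest
    index."""
    flat = surface.ravel()
    best = flat.max()
    ties = np.flatnonzero(flat == best)
    if ties.size == 1:
        return np.unravel_index(ties[0], surface.shape)
    coords = np.array(np.unravel_index(ties, surface.shape)).T
    dist = np.zeros(ties.size)
    for axis in range(coords.shape[1]):
        dist += _circ_dist(coords[:, axis] + 1.0, FOVEA_DEG) ** 2
    pick = ties[np.lexsort((ties, dist))[0]]
    return np.unravel_index(pick, surface.shape)


def map_estimate(
    observed_a: np.ndarray | None,
    observed_v: np.ndarray | None,
    env: EnvironmentParams,
    noise_sd_a: float | None = None,
    noise_sd_v: float | None = None,
    templates_a: np.ndarray | None = None,
    templates_v: np.ndarray | None = None,
    return_grid: bool = False,
):
    """Maximum-posterior position estimate(s).

    With both observations present the joint cross-modal posterior is
    maximised over the full 180x180 grid and a pair
    (theta_hat_a, theta_hat_v) is returned.  With one observation the
    corresponding unisensory marginal prior is used and a single float
    is returned.

    ``noise_sd_*`` are the true noise SDs of the observations (the
    estimator knows the generative model).
    """
    if observed_a is None and observed_v is None:
        raise ValueError("at least one observation is required")

    ll_a = ll_v = None
    if observed_a is not None:
        ll_a = log_likelihood_profile(observed_a, "A", env, noise_sd_a, templates_a)
    if observed_v is not None:
        ll_v = log_likelihood_profile(observed_v, "V", env, noise_sd_v, templates_v)

    if ll_a is not None and ll_v is not None:
        lp = log_prior_surface("cross", env)
        post = ll_a[:, None] + ll_v[None, :] + lp
        ia, iv = _argmax_deterministic(post)
        result = (float(POSITIONS_DEG[ia] % PERIOD_DEG), float(POSITIONS_DEG[iv] % PERIOD_DEG))
    elif ll_a is not None:
        lp = log_prior_surface("uniA", env)
        post = ll_a + lp
        (ia,) = _argmax_deterministic(post)
        result = float(POSITIONS_DEG[ia] % PERIOD_DEG)
    else:
        lp = log_prior_surface("uniV", env)
        post = ll_v + lp
        (iv,) = _argmax_deterministic(post)
        result = float(POSITIONS_DEG[iv] % PERIOD_DEG)

    if return_grid:
        return result, PosteriorGrid(ll_a, ll_v, lp, post)
    return result
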