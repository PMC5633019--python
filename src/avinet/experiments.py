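"""Result sweeps: unisensory bias/SD versus noise, coincident
cross-modal stimulation, ventriloquism versus disparity and azimuth,
and the network-versus-Bayes comparison.

Every sweep decodes repeated noisy trials per cell with the trained
network (activity-barycenter readout) and, optionally, the reference
MAP estimator on the very same stimuli, and reports circular-aware
mean signed errors (perceived minus true) and SDs per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayes, estimation
from .network import NetworkParams, NetworkWeights, lateral_kernel_matrix, steady_state_response
from .stimuli import EnvironmentParams, PERIOD_DEG, make_stimulus, signed_circular_difference

__all__ = [
    "SweepSpec",
    "run_unisensory_sweep",
    "run_crossmodal_coincident",
    "run_ventriloquism",
    "summarize_comparison",
    "CENTRAL_RANGE_AV",
    "CENTRAL_RANGE_V",
]

#: azimuth window (deg) over which auditory and cross-modal estimates
#: are summarised; the periphery is excluded for its large variance
CENTRAL_RANGE_AV = (40.0, 140.0)
#: the visual unisensory window can extend slightly further
CENTRAL_RANGE_V = (30.0, 150.0)


@dataclass
class SweepSpec:
    """Cells of a sweep.

    positions : stimulus azimuths (deg); for ventriloquism these are
        the visual azimuths.
    disparities : audio-visual shifts theta_v - theta_a (deg); positive
        means the auditory stimulus sits to the left of the visual one.
    noise_fracs : noise SD as a fraction of the noiseless peak.
    trials_per_cell : decoded trials per (position, disparity, noise).
    estimators : subset of {"network", "bayes"}.
    """

    positions: np.ndarray = field(default_factory=lambda: np.arange(40.0, 141.0, 10.0))
    disparities: np.ndarray = field(default_factory=lambda: np.arange(-40.0, 41.0, 5.0))
    noise_fracs: tuple = (0.5,)
    trials_per_cell: int = 100
    estimators: tuple = ("network", "bayes")

    def __post_init__(self):
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")


class _Decoder:
    """Shared machinery: decode one stimulus pair with both estimators."""

    def __init__(self, weights: NetworkWeights, net_params: NetworkParams,
                 env: EnvironmentParams, estimators: tuple):
        if not weights.is_trained():
            raise ValueError("sweeps require trained weights (no cross-modal synapses found)")
        self.weights = weights
        self.net_params = net_params
        self.env = env
        self.estimators = estimators
        self.lateral = lateral_kernel_matrix(net_params)
        self.prefs = estimation.preferred_positions(weights)
        if "bayes" in estimators:
            self.templates_a = bayes.template_matrix("A", env)
            self.templates_v = bayes.template_matrix("V", env)

    def decode(self, stim_a, stim_v):
        """Return {estimator: {modality: estimate-or-nan}}."""
        out = {}
        if "network" in self.estimators:
            state = steady_state_response(stim_a, stim_v, self.weights,
                                          self.net_params, self.lateral)
            res = estimation.population_estimate(state, self.prefs)
            out["network"] = {
                "A": res.theta_hat_a if stim_a is not None else np.nan,
                "V": res.theta_hat_v if stim_v is not None else np.nan,
            }
        if "bayes" in self.estimators:
            if stim_a is not None and stim_v is not None:
                est_a, est_v = bayes.map_estimate(
                    stim_a.profile, stim_v.profile, self.env,
                    noise_sd_a=stim_a.noise_sd, noise_sd_v=stim_v.noise_sd,
                    templates_a=self.templates_a, templates_v=self.templates_v)
            elif stim_a is not None:
                est_a = bayes.map_estimate(stim_a.profile, None, self.env,
                                           noise_sd_a=stim_a.noise_sd,
                                           templates_a=self.templates_a)
                est_v = np.nan
            else:
                est_v = bayes.map_estimate(None, stim_v.profile, self.env,
                                           noise_sd_v=stim_v.noise_sd,
                                           templates_v=self.templates_v)
                est_a = np.nan
            out["bayes"] = {"A": est_a, "V": est_v}
        return out


def _summarise(errors: dict, meta: dict) -> list[dict]:
    rows = []
    for (estimator, modality), errs in errors.items():
        errs = np.asarray(errs, dtype=float)
        valid = errs[np.isfinite(errs)]
        rows.append({
            **meta,
            "estimator": estimator,
            "modality": modality,
            "bias_deg": float(valid.mean()) if valid.size else np.nan,
            "sd_deg": float(valid.std(ddof=1)) if valid.size > 1 else np.nan,
            "n_valid": int(valid.size),
        })
    return rows


def _cell_errors(decoder: _Decoder, env, rng, theta_a, theta_v, noise_frac, n_trials):
    """Signed errors of every estimator/modality over one cell."""
    errors: dict[tuple, list] = {}
    for _ in range(n_trials):
        stim_a = (make_stimulus("A", theta_a % PERIOD_DEG, env, noise_frac, rng)
                  if theta_a is not None else None)
        stim_v = (make_stimulus("V", theta_v % PERIOD_DEG, env, noise_frac, rng)
                  if theta_v is not None else None)
        decoded = decoder.decode(stim_a, stim_v)
        for estimator, ests in decoded.items():
            for modality, est in ests.items():
                true = theta_a if modality == "A" else theta_v
                if true is None:
                    continue
                err = (signed_circular_difference(est, true)
                       if np.isfinite(est) else np.nan)
                errors.setdefault((estimator, modality), []).append(err)
    return errors


def run_unisensory_sweep(
    weights: NetworkWeights, spec: SweepSpec, env: EnvironmentParams,
    net_params: NetworkParams, rng: np.random.Generator,
    modalities: tuple = ("A", "V"),
) -> pd.DataFrame:
    """Bias and SD of unisensory estimates per (modality, position,
    noise) cell."""
    decoder = _Decoder(weights, net_params, env, spec.estimators)
    rows = []
    for noise_frac in spec.noise_fracs:
        for position in spec.positions:
            for modality in modalities:
                errors = _cell_errors(
                    decoder, env, rng,
                    theta_a=position if modality == "A" else None,
                    theta_v=position if modality == "V" else None,
                    noise_frac=noise_frac, n_trials=spec.trials_per_cell)
                rows += _summarise(errors, {
                    "condition": f"uni{modality}", "position_deg": float(position),
                    "disparity_deg": 0.0, "noise_frac": float(noise_frac),
                    "n_trials": spec.trials_per_cell,
                })
    return pd.DataFrame(rows)


def run_crossmodal_coincident(
    weights: NetworkWeights, spec: SweepSpec, env: EnvironmentParams,
    net_params: NetworkParams, rng: np.random.Generator,
) -> pd.DataFrame:
    """Bias and SD with spatially coincident audio-visual pairs."""
    decoder = _Decoder(weights, net_params, env, spec.estimators)
    rows = []
    for noise_frac in spec.noise_fracs:
        for position in spec.positions:
            errors = _cell_errors(decoder, env, rng, theta_a=position,
                                  theta_v=position, noise_frac=noise_frac,
                                  n_trials=spec.trials_per_cell)
            rows += _summarise(errors, {
                "condition": "coincident", "position_deg": float(position),
                "disparity_deg": 0.0, "noise_frac": float(noise_frac),
                "n_trials": spec.trials_per_cell,
            })
    return pd.DataFrame(rows)


def run_ventriloquism(
    weights: NetworkWeights, spec: SweepSpec, env: EnvironmentParams,
    net_params: NetworkParams, rng: np.random.Generator,
) -> pd.DataFrame:
    """Disparate audio-visual pairs: the visual stimulus sits at each
    position in ``spec.positions`` and the auditory one is shifted by
    each disparity (theta_a = theta_v - disparity, so a positive
    disparity places the auditory stimulus to the left of the visual
    one).  Per-cell biases can be pooled over positions downstream."""
    decoder = _Decoder(weights, net_params, env, spec.estimators)
    rows = []
    for noise_frac in spec.noise_fracs:
        for position in spec.positions:
            for disparity in spec.disparities:
                errors = _cell_errors(decoder, env, rng,
                                      theta_a=position - disparity,
                                      theta_v=position, noise_frac=noise_frac,
                                      n_trials=spec.trials_per_cell)
                rows += _summarise(errors, {
                    "condition": "ventriloquism", "position_deg": float(position),
                    "disparity_deg": float(disparity),
                    "noise_frac": float(noise_frac),
                    "n_trials": spec.trials_per_cell,
                })
    return pd.DataFrame(rows)


def pooled_ventriloquism(table: pd.DataFrame, estimator: str = "network") -> pd.DataFrame:
    """Mean bias per (modality, disparity), pooled over visual positions."""
    sub = table[table["estimator"] == estimator]
    return (sub.groupby(["modality", "disparity_deg"], as_index=False)
            .agg(bias_deg=("bias_deg", "mean"), sd_deg=("sd_deg", "mean")))


def summarize_comparison(network_table: pd.DataFrame, bayes_table: pd.DataFrame,
                         disparity_flag_deg: float = 20.0,
                         eccentricity_flag_deg: float = 30.0) -> pd.DataFrame:
    """Per-cell network-minus-Bayes differences in bias and SD.

    Cells where the two estimators are known to disagree on the visual
    estimate (large audio-visual disparity or high eccentricity) are
    flagged rather than treated as errors: there the Bayesian
    coincidence prior drags the visual estimate while the network does
    not.
    """
    keys = ["condition", "modality", "position_deg", "disparity_deg", "noise_frac"]
    net = network_table[network_table["estimator"] == "network"]
    bay = bayes_table[bayes_table["estimator"] == "bayes"]
    merged = net.merge(bay, on=keys, suffixes=("_network", "_bayes"), validate="one_to_one")
    if len(merged) != len(net) or len(merged) != len(bay):
        raise ValueError("network and Bayes tables do not share the same cells")
    merged["bias_diff_deg"] = merged["bias_deg_network"] - merged["bias_deg_bayes"]
    merged["sd_diff_deg"] = merged["sd_deg_network"] - merged["sd_deg_bayes"]
    merged["known_disagreement"] = (
        (merged["modality"] == "V")
        & ((merged["disparity_deg"].abs() >= disparity_flag_deg)
           | ((merged["position_deg"] - 90.0).abs() >= eccentricity_flag_deg))
    )
    return merged
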