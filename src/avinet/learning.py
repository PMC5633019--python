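"""Hebbian plasticity with a forgetting factor, and the training loop.

Both synapse families follow the same principle: a synapse is
potentiated when pre- and post-synaptic activities are both high, and a
fraction of the existing synapse decays whenever the post-synaptic
neuron is active.  The fixed point of such a rule is the average
pre-synaptic signal seen while the neuron fires, which is how the
receptive fields come to copy the mean sensory input (encoding the
likelihood) and the cross-modal synapses come to encode the
co-occurrence statistics of the two modalities (the cross-modal prior).

Plasticity is applied once per trial, at the steady state of the
network dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import estimation
from .network import (NetworkParams, NetworkWeights,
                      lateral_kernel_matrix, steady_state_response)
from .stimuli import EnvironmentParams, make_stimulus, sample_positions

__all__ = [
    "LearningParams",
    "TrainingSchedule",
    "TrainingResult",
    "hebbian_rf_update",
    "hebbian_crossmodal_update",
    "train_network",
    "reduced_schedule",
]


@dataclass
class LearningParams:
    """Learning rates and bounds.

    gamma_rf : float
        Receptive-field learning rate per trial.  Each active neuron's
        RF relaxes toward the current input profile with this rate, so
        the RF converges to the mean input (forgetting included).
    gamma_cm : float
        Cross-modal learning rate per trial.
    w_max_cm : float
        Saturation of a single cross-modal synapse; calibrated so that
        cross-modal drive alone stays subthreshold yet biases a
        concurrent noisy stimulus.
    post_threshold : float
        Minimum post-synaptic rate for any plasticity; keeps weak,
        cross-modally evoked echoes from eroding trained synapses.
    """

    gamma_rf: float = 0.01
    gamma_cm: float = 0.01
    w_max_cm: float = 0.35
    post_threshold: float = 0.1

    def __post_init__(self):
        if self.gamma_rf <= 0 or self.gamma_cm <= 0 or self.w_max_cm <= 0:
            raise ValueError("learning rates and the cross-modal cap must be positive")


@dataclass
class TrainingSchedule:
    """Trial mix of the developmental period.

    Defaults reproduce the reference rearing statistics: 100 epochs of
    360 unisensory visual + 360 unisensory auditory + 180 cross-modal
    trials (90,000 trials total, ratio 2:2:1), interleaved by a seeded
    shuffle within each epoch.
    """

    epochs: int = 100
    uni_v_per_epoch: int = 360
    uni_a_per_epoch: int = 360
    cross_per_epoch: int = 180
    shuffle: bool = True

    @property
    def trials_per_epoch(self) -> int:
        return self.uni_v_per_epoch + self.uni_a_per_epoch + self.cross_per_epoch

    @property
    def total_trials(self) -> int:
        return self.epochs * self.trials_per_epoch

    @property
    def cross_fraction(self) -> float:
        return self.cross_per_epoch / self.trials_per_epoch

    def with_cross_fraction(self, fraction: float) -> "TrainingSchedule":
        """Same epoch size, cross-modal trials raised to ``fraction`` of
        the total and the remainder split equally between the
        unisensory conditions."""
        total = self.trials_per_epoch
        n_cross = int(round(fraction * total))
        n_uni = (total - n_cross) // 2
        return replace(self, uni_v_per_epoch=n_uni, uni_a_per_epoch=n_uni,
                       cross_per_epoch=n_cross)


def reduced_schedule(
    schedule: TrainingSchedule, learn: LearningParams, factor: int
) -> tuple[TrainingSchedule, LearningParams]:
    """Desk-scale training: ``factor`` times fewer epochs with learning
    rates scaled up by the same factor, preserving the per-epoch trial
    mix and the total learning drive."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    epochs = max(1, round(schedule.epochs / factor))
    scale = schedule.epochs / epochs
    return (
        replace(schedule, epochs=epochs),
        replace(learn, gamma_rf=learn.gamma_rf * scale, gamma_cm=learn.gamma_cm * scale),
    )


def hebbian_rf_update(
    rf: np.ndarray, presynaptic_profile: np.ndarray, post_rates: np.ndarray,
    params: LearningParams,
) -> np.ndarray:
    """One Hebb-with-forgetting step on receptive-field synapses.

    delta r_kj = gamma_rf * y_k * (i_j - r_kj), gated by the
    post-synaptic threshold.  Works in place on a (180, 180) matrix or
    a single RF row; returns its first argument.
    """
    y = np.where(post_rates >= params.post_threshold, post_rates, 0.0)
    if rf.ndim == 1:
        rf += params.gamma_rf * y * (presynaptic_profile - rf)
    else:
        rf += params.gamma_rf * y[:, None] * (presynaptic_profile[None, :] - rf)
    np.maximum(rf, 0.0, out=rf)
    return rf


def hebbian_crossmodal_update(
    w: np.ndarray, presynaptic_rates: np.ndarray, post_rates: np.ndarray,
    params: LearningParams,
) -> np.ndarray:
    """One Hebb-with-forgetting step on cross-modal synapses.

    delta w_kj = gamma_cm * y_post_k * (y_pre_j * w_max - w_kj):
    potentiation toward the cap when both sides fire, pure decay when
    the post fires alone.  Both sides are gated by the plasticity
    threshold, so sub-threshold echoes neither potentiate nor count as
    presynaptic activity.  Returns its (in-place updated) first
    argument; weights remain in [0, w_max].
    """
    y = np.where(post_rates >= params.post_threshold, post_rates, 0.0)
    pre = np.where(presynaptic_rates >= params.post_threshold, presynaptic_rates, 0.0)
    if w.ndim == 1:
        w += params.gamma_cm * y * (pre * params.w_max_cm - w)
    else:
        w += params.gamma_cm * y[:, None] * (pre[None, :] * params.w_max_cm - w)
    np.clip(w, 0.0, params.w_max_cm, out=w)
    return w


@dataclass
class TrainingResult:
    weights: NetworkWeights
    log: pd.DataFrame
    n_nonconverged: int


def _rf_width_stats(rf: np.ndarray, threshold: float) -> float:
    """Mean thresholded-RF circular SD (deg) across neurons."""
    widths = []
    from .estimation import circular_barycenter
    from .stimuli import POSITIONS_DEG, signed_circular_difference

    for row in rf:
        w = np.maximum(row - threshold, 0.0)
        if w.sum() <= 0:
            continue
        mu = circular_barycenter(w)
        d = signed_circular_difference(POSITIONS_DEG, mu)
        widths.append(np.sqrt(np.sum(w * d**2) / w.sum()))
    return float(np.mean(widths)) if widths else float("nan")


def train_network(
    weights: NetworkWeights,
    schedule: TrainingSchedule,
    env: EnvironmentParams,
    net_params: NetworkParams,
    learn_params: LearningParams,
    rng: np.random.Generator,
    log_every: int = 1,
    progress: bool = False,
) -> TrainingResult:
    """Run the developmental training.

    Each trial draws a condition slot from the (shuffled) epoch mix,
    samples stimulus position(s) from the corresponding prior,
    generates noisy stimuli at the training noise level, integrates the
    network to steady state, and applies both plasticity rules once.

    Returns the trained weights together with a per-epoch log (mean RF
    widths, mean absolute preferred-position drift, cross-modal synapse
    mass, non-convergence count).
    """
    weights = weights.copy()
    lateral = lateral_kernel_matrix(net_params)
    slots = (["uniV"] * schedule.uni_v_per_epoch
             + ["uniA"] * schedule.uni_a_per_epoch
             + ["cross"] * schedule.cross_per_epoch)
    slots = np.array(slots)
    records = []
    n_nonconverged = 0

    epoch_iter = range(schedule.epochs)
    if progress:
        try:
            from tqdm import tqdm
        except ImportError:
            pass
        else:
            epoch_iter = tqdm(epoch_iter, desc="training")

    for epoch in epoch_iter:
        order = rng.permutation(len(slots)) if schedule.shuffle else np.arange(len(slots))
        for condition in slots[order]:
            stim_a = stim_v = None
            if condition == "uniV":
                theta_v = sample_positions("uniV", env, rng)
                stim_v = make_stimulus("V", theta_v, env, env.train_noise_frac, rng)
            elif condition == "uniA":
                theta_a = sample_positions("uniA", env, rng) % 180.0
                stim_a = make_stimulus("A", theta_a, env, env.train_noise_frac, rng)
            else:
                theta_v, theta_a = sample_positions("cross", env, rng)
                stim_v = make_stimulus("V", theta_v, env, env.train_noise_frac, rng)
                stim_a = make_stimulus("A", theta_a % 180.0, env, env.train_noise_frac, rng)

            state = steady_state_response(stim_a, stim_v, weights, net_params, lateral)
            if not state.converged:
                n_nonconverged += 1

            if stim_a is not None:
                hebbian_rf_update(weights.rf_a, stim_a.profile, state.y_a, learn_params)
            if stim_v is not None:
                hebbian_rf_update(weights.rf_v, stim_v.profile, state.y_v, learn_params)
            hebbian_crossmodal_update(weights.w_av, state.y_v, state.y_a, learn_params)
            hebbian_crossmodal_update(weights.w_va, state.y_a, state.y_v, learn_params)

        if (epoch + 1) % log_every == 0 or epoch == schedule.epochs - 1:
            prefs = estimation.preferred_positions(weights)
            from .stimuli import POSITIONS_DEG, signed_circular_difference

            drift_v = np.nanmean(np.abs(signed_circular_difference(prefs.rho_v, POSITIONS_DEG)))
            records.append({
                "epoch": epoch + 1,
                "rf_width_a_deg": _rf_width_stats(weights.rf_a, estimation.RF_THRESHOLD),
                "rf_width_v_deg": _rf_width_stats(weights.rf_v, estimation.RF_THRESHOLD),
                "mean_abs_drift_v_deg": float(drift_v),
                "w_av_mass": float(weights.w_av.sum()),
                "w_va_mass": float(weights.w_va.sum()),
                "n_nonconverged": n_nonconverged,
            })

    return TrainingResult(weights=weights, log=pd.DataFrame.from_records(records),
                          n_nonconverged=n_nonconverged)
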