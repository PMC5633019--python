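"""Two-layer recurrent firing-rate network.

Each of the two unisensory layers (auditory, visual) holds 180 neurons
labelled by azimuth.  A neuron's drive is the sum of (i) the inner
product of the external stimulus with its receptive-field synapses,
(ii) lateral input through a fixed Mexican-hat kernel within its own
layer, and (iii) cross-modal input from the other layer.  Rates follow
a first-order leaky integration toward a sigmoid of the total drive
(saturation normalised to 1) and are integrated by explicit Euler until
the steady state is reached; only steady states are consumed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .stimuli import N_POSITIONS, POSITIONS_DEG, Stimulus, _circ_dist

__all__ = [
    "NetworkParams",
    "NetworkWeights",
    "LayerState",
    "lateral_kernel",
    "lateral_kernel_matrix",
    "feedforward_input",
    "init_weights",
    "steady_state_response",
    "save_weights",
    "load_weights",
]

WEIGHT_FORMAT_VERSION = 1

#: SD (deg) of the immature, untrained receptive fields
RF_INITIAL_SIGMA_DEG = 30.0


@dataclass
class NetworkParams:
    """Dynamics and connectivity constants.

    tau_ms, dt_ms, t_max_ms : float
        Time constant, Euler step and integration horizon (ms).
    tol : float
        Steady-state criterion: max rate change per step.
    sigmoid_center, sigmoid_slope : float
        Input value of half-activation and steepness of the static
        nonlinearity; chosen so that zero input gives a rate < 0.01
        while a calibrated stimulus drives the bubble to >= 0.9.
    lat_* : float
        Mexican-hat kernel: difference of circular Gaussians, short-
        range excitation minus longer-range inhibition (weights in the
        same units as the feedforward drive).
    """

    n_neurons: int = N_POSITIONS
    tau_ms: float = 3.0
    dt_ms: float = 0.5
    t_max_ms: float = 200.0
    tol: float = 1e-4
    sigmoid_center: float = 5.5
    sigmoid_slope: float = 1.4
    max_rate: float = 1.0
    lat_ex_strength: float = 1.2
    lat_ex_sigma_deg: float = 2.5
    lat_in_strength: float = 0.4
    lat_in_sigma_deg: float = 60.0

    def __post_init__(self):
        if self.lat_ex_strength <= self.lat_in_strength:
            raise ValueError("Mexican hat must be excitatory at distance 0")
        if self.dt_ms <= 0 or self.tau_ms <= 0 or self.t_max_ms <= 0:
            raise ValueError("time constants must be positive")

    def sigmoid(self, u):
        return self.max_rate / (1.0 + np.exp(-self.sigmoid_slope * (u - self.sigmoid_center)))


def lateral_kernel(distance, params: NetworkParams):
    """Mexican-hat lateral weight at a circular distance (deg)."""
    d = np.asarray(distance, dtype=float)
    if np.any((d < 0) | (d > 90)):
        raise ValueError("circular distance must lie in [0, 90] deg")
    k = params.lat_ex_strength * np.exp(-(d**2) / (2.0 * params.lat_ex_sigma_deg**2)) - \
        params.lat_in_strength * np.exp(-(d**2) / (2.0 * params.lat_in_sigma_deg**2))
    return float(k) if k.ndim == 0 else k


def lateral_kernel_matrix(params: NetworkParams) -> np.ndarray:
    """Full 180x180 lateral weight matrix (self-connection included)."""
    d = _circ_dist(POSITIONS_DEG[:, None], POSITIONS_DEG[None, :])
    return lateral_kernel(d, params)


@dataclass
class NetworkWeights:
    """Trainable synapses of the network.

    ``rf_a[k, j]`` / ``rf_v[k, j]``: receptive-field synapse from input
    position j onto neuron k of the auditory / visual layer.
    ``w_av[k, j]``: cross-modal synapse from visual neuron j onto
    auditory neuron k; ``w_va`` the converse.  Lateral synapses are
    fixed and live in :class:`NetworkParams`.
    """

    rf_a: np.ndarray
    rf_v: np.ndarray
    w_av: np.ndarray
    w_va: np.ndarray

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.rf_a.copy(), self.rf_v.copy(),
                              self.w_av.copy(), self.w_va.copy())

    def is_trained(self) -> bool:
        """Heuristic: any nonzero cross-modal synapse marks training."""
        return bool(np.any(self.w_av > 0) or np.any(self.w_va > 0))


def init_weights(n_neurons: int = N_POSITIONS,
                 rf_sigma_deg: float = RF_INITIAL_SIGMA_DEG) -> NetworkWeights:
    """Immature pre-training weights.

    Every receptive field is a circular Gaussian of SD ``rf_sigma_deg``
    (peak 1) centred at the neuron's own label, identical for both
    layers; cross-modal synapses start at zero (no audio-visual
    relationship is assumed before experience).
    """
    d = _circ_dist(POSITIONS_DEG[:, None], POSITIONS_DEG[None, :])
    rf = np.exp(-(d**2) / (2.0 * rf_sigma_deg**2))
    zeros = np.zeros((n_neurons, n_neurons))
    return NetworkWeights(rf_a=rf.copy(), rf_v=rf.copy(),
                          w_av=zeros.copy(), w_va=zeros.copy())


def feedforward_input(stimulus_profile: np.ndarray, rf_row: np.ndarray) -> float:
    """External drive to one neuron: <stimulus, receptive field>."""
    stimulus_profile = np.asarray(stimulus_profile, dtype=float)
    rf_row = np.asarray(rf_row, dtype=float)
    if stimulus_profile.shape != rf_row.shape:
        raise ValueError("stimulus profile and RF row must have equal length")
    return float(stimulus_profile @ rf_row)


@dataclass
class LayerState:
    """Steady-state rates of both layers plus integration diagnostics."""

    y_a: np.ndarray
    y_v: np.ndarray
    converged: bool = True
    t_ms: float = 0.0
    n_steps: int = 0


def steady_state_response(
    stim_a: Stimulus | np.ndarray | None,
    stim_v: Stimulus | np.ndarray | None,
    weights: NetworkWeights,
    params: NetworkParams,
    lateral: np.ndarray | None = None,
) -> LayerState:
    """Integrate the rate dynamics to steady state for one stimulus pair.

    dy/dt = (-y + sigmoid(ff + lateral @ y_same + w @ y_other)) / tau,
    explicit Euler from rest, stopping when the largest rate change in
    one step falls below ``tol`` (or flagging non-convergence at
    ``t_max_ms``).

    Parameters
    ----------
    stim_a, stim_v : Stimulus, profile array, or None
        The external inputs; at least one must be present.
    lateral : ndarray, optional
        Precomputed lateral kernel matrix (otherwise rebuilt).
    """
    if stim_a is None and stim_v is None:
        raise ValueError("at least one stimulus must be present")
    if lateral is None:
        lateral = lateral_kernel_matrix(params)

    def _profile(s):
        return s.profile if isinstance(s, Stimulus) else np.asarray(s, dtype=float)

    n = params.n_neurons
    ff_a = weights.rf_a @ _profile(stim_a) if stim_a is not None else np.zeros(n)
    ff_v = weights.rf_v @ _profile(stim_v) if stim_v is not None else np.zeros(n)

    y_a = np.zeros(n)
    y_v = np.zeros(n)
    step = params.dt_ms / params.tau_ms
    n_max = int(round(params.t_max_ms / params.dt_ms))
    slope, center, ymax = params.sigmoid_slope, params.sigmoid_center, params.max_rate
    for i in range(1, n_max + 1):
        u_a = ff_a + lateral @ y_a + weights.w_av @ y_v
        u_v = ff_v + lateral @ y_v + weights.w_va @ y_a
        target_a = ymax / (1.0 + np.exp(-slope * (u_a - center)))
        target_v = ymax / (1.0 + np.exp(-slope * (u_v - center)))
        delta_a = step * (target_a - y_a)
        delta_v = step * (target_v - y_v)
        y_a += delta_a
        y_v += delta_v
        if max(np.abs(delta_a).max(), np.abs(delta_v).max()) < params.tol:
            return LayerState(y_a, y_v, converged=True, t_ms=i * params.dt_ms, n_steps=i)
    return LayerState(y_a, y_v, converged=False, t_ms=params.t_max_ms, n_steps=n_max)


def _params_to_arrays(params: NetworkParams) -> dict:
    return {f"param_{f.name}": np.asarray(getattr(params, f.name)) for f in fields(params)}


def save_weights(path, weights: NetworkWeights, params: NetworkParams | None = None) -> None:
    """Store the four synapse matrices (plus params and a format
    version) in a NumPy ``.npz`` container."""
    extra = _params_to_arrays(params) if params is not None else {}
    np.savez(
        path,
        format_version=np.asarray(WEIGHT_FORMAT_VERSION),
        rf_a=weights.rf_a,
        rf_v=weights.rf_v,
        w_av=weights.w_av,
        w_va=weights.w_va,
        **extra,
    )


def load_weights(path) -> tuple[NetworkWeights, NetworkParams | None]:
    """Load a weight store written by :func:`save_weights`."""
    with np.load(path) as data:
        version = int(data["format_version"])
        if version != WEIGHT_FORMAT_VERSION:
            raise ValueError(f"unsupported weight-store version {version}")
        weights = NetworkWeights(
            rf_a=data["rf_a"], rf_v=data["rf_v"],
            w_av=data["w_av"], w_va=data["w_va"],
        )
        pkeys = [k for k in data.files if k.startswith("param_")]
        params = None
        if pkeys:
            kwargs = {}
            for f in fields(NetworkParams):
                key = f"param_{f.name}"
                if key in data:
                    kwargs[f.name] = type(f.default)(data[key].item())
            params = NetworkParams(**kwargs)
    return weights, params
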