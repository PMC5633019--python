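"""Population decoders: thresholded-barycenter preferred positions and
activity-weighted position estimates.

Because the azimuthal axis is circular with period 180 deg, barycenters
are computed with the doubling-angle construction: positions are mapped
to angles of period 360, the weighted mean resultant vector is taken,
and the resulting angle is halved back into [0, 180).  Away from the
wrap point (all mass within a 90-deg arc) this reduces to the plain
weighted arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import N_POSITIONS, PERIOD_DEG, POSITIONS_DEG

__all__ = [
    "RF_THRESHOLD",
    "ACTIVITY_FLOOR",
    "PreferredPositions",
    "EstimateResult",
    "circular_barycenter",
    "preferred_position",
    "preferred_positions",
    "population_estimate",
]

#: threshold subtracted from RF synapses before the barycenter, to
#: suppress the contribution of residual training noise
RF_THRESHOLD = 0.2

#: minimum total layer activity for a population estimate to be valid
ACTIVITY_FLOOR = 0.05


def circular_barycenter(weights: np.ndarray, positions: np.ndarray | None = None) -> float:
    """Weighted circular mean of period-180 positions.

    Parameters
    ----------
    weights : array of nonnegative weights.
    positions : array of positions (deg); defaults to the grid 1..180.

    Returns
    -------
    float
        Barycenter in [0, 180), or ``nan`` when all weights are zero.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if positions is None:
        positions = POSITIONS_DEG
    positions = np.asarray(positions, dtype=float)
    total = w.sum()
    if total <= 0:
        return float("nan")
    # doubling-angle resultant gives a wrap-safe reference direction
    ang = np.deg2rad(2.0 * positions)
    c = float(np.sum(w * np.cos(ang)) / total)
    s = float(np.sum(w * np.sin(ang)) / total)
    ref = (np.rad2deg(np.arctan2(s, c)) / 2.0) % PERIOD_DEG
    # unwrap the positions around it and take the plain weighted mean,
    # which is exactly the arithmetic barycenter away from the border
    delta = (positions - ref + PERIOD_DEG / 2.0) % PERIOD_DEG - PERIOD_DEG / 2.0
    return float((ref + np.sum(w * delta) / total) % PERIOD_DEG)


def preferred_position(rf_row: np.ndarray, threshold: float = RF_THRESHOLD) -> float:
    """Preferred position of one neuron: the circular barycenter of the
    positive part of its receptive field above ``threshold``.

    Returns ``nan`` when every synapse is at or below the threshold
    (the neuron has no defined preferred position).
    """
    rf_row = np.asarray(rf_row, dtype=float)
    if rf_row.shape != (N_POSITIONS,):
        raise ValueError(f"rf_row must have length {N_POSITIONS}")
    return circular_barycenter(np.maximum(rf_row - threshold, 0.0))


@dataclass
class PreferredPositions:
    """Per-neuron preferred positions for both layers (deg; nan where
    the RF never exceeds the threshold)."""

    rho_a: np.ndarray
    rho_v: np.ndarray
    threshold: float = RF_THRESHOLD

    def for_modality(self, modality: str) -> np.ndarray:
        return self.rho_a if modality == "A" else self.rho_v


def preferred_positions(weights, threshold: float = RF_THRESHOLD) -> PreferredPositions:
    """Preferred positions of every neuron from trained weights."""
    rho_a = np.array([preferred_position(row, threshold) for row in weights.rf_a])
    rho_v = np.array([preferred_position(row, threshold) for row in weights.rf_v])
    return PreferredPositions(rho_a=rho_a, rho_v=rho_v, threshold=threshold)


@dataclass
class EstimateResult:
    """Decoded source positions from one steady state.

    ``theta_hat_a`` / ``theta_hat_v`` are nan when the corresponding
    layer is silent (total activity below the floor); ``valid`` flags
    whether the estimate of the stimulated layer(s) can be used.
    """

    theta_hat_a: float
    theta_hat_v: float
    total_activity_a: float
    total_activity_v: float
    valid_a: bool
    valid_v: bool

    def estimate(self, modality: str) -> float:
        return self.theta_hat_a if modality == "A" else self.theta_hat_v

    def is_valid(self, modality: str) -> bool:
        return self.valid_a if modality == "A" else self.valid_v


def _layer_estimate(rates: np.ndarray, rho: np.ndarray, floor: float):
    rates = np.asarray(rates, dtype=float)
    usable = np.isfinite(rho)
    total = float(rates[usable].sum())
    if total < floor:
        return float("nan"), total, False
    return circular_barycenter(rates[usable], rho[usable]), total, True


def population_estimate(
    state, prefs: PreferredPositions, floor: float = ACTIVITY_FLOOR
) -> EstimateResult:
    """Decode both layers of a steady state.

    The estimate of each modality is the circular barycenter of its
    neurons' activities located at their preferred positions.  Neurons
    without a defined preferred position are excluded; a layer whose
    remaining total activity is below ``floor`` yields an invalid
    (nan) estimate.
    """
    est_a, tot_a, ok_a = _layer_estimate(state.y_a, prefs.rho_a, floor)
    est_v, tot_v, ok_v = _layer_estimate(state.y_v, prefs.rho_v, floor)
    return EstimateResult(
        theta_hat_a=est_a,
        theta_hat_v=est_v,
        total_activity_a=tot_a,
        total_activity_v=tot_v,
        valid_a=ok_a,
        valid_v=ok_v,
    )
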