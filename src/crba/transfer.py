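"""Parameter transfer from the rate-based learner to the spiking network.

Weights move verbatim — both networks normalise each neuron's afferents
to the same column sum ``lambda`` — while firing thresholds, which the
rate-based learner drives to values far above what a spiking membrane
can reach, are rescaled linearly onto a spiking-compatible range
(default 35-60 mV, the range reached by a conventionally trained
network).  Linear min-max rescaling is used because it preserves the
rank order of neuron excitability exactly and is invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TransferSpec", "CSNNState", "rescale_thresholds", "transfer_parameters"]


@dataclass
class TransferSpec:
    """Target threshold range for the spiking network (mV)."""

    theta_target_min: float = 35.0
    theta_target_max: float = 60.0

    def __post_init__(self) -> None:
        if not self.theta_target_min < self.theta_target_max:
            raise ValueError("require theta_target_min < theta_target_max")


@dataclass
class CSNNState:
    """Initial state handed to the spiking simulator: weights + thresholds."""

    W: np.ndarray
    theta: np.ndarray


def rescale_thresholds(theta: np.ndarray, spec: TransferSpec) -> np.ndarray:
    """Linear min-max map of thresholds onto [target_min, target_max].

    All-equal thresholds (zero spread) map to the interval midpoint.
    """
    theta = np.asarray(theta, dtype=float)
    lo, hi = theta.min(), theta.max()
    if hi == lo:
        mid = 0.5 * (spec.theta_target_min + spec.theta_target_max)
        return np.full_like(theta, mid)
    span = spec.theta_target_max - spec.theta_target_min
    return spec.theta_target_min + (theta - lo) * (span / (hi - lo))


def transfer_parameters(W: np.ndarray, theta: np.ndarray,
                        spec: TransferSpec | None = None) -> CSNNState:
    """Build a spiking-network initial state from learned rate-based parameters.

    The rescaled values are used as the total effective firing threshold
    of each spiking neuron (offset included): it is the adaptive
    component that encodes each neuron's excitability history.
    """
    spec = spec or TransferSpec()
    return CSNNState(W=np.array(W, dtype=float, copy=True),
                     theta=rescale_thresholds(theta, spec))
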