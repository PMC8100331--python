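"""Low-level operations of the competitive rate-based algorithm (CRBA).

CRBA replaces the time-stepped competition of a competitive spiking neural
network (CSNN) by a single pass of five steps per sample presentation:

1. rank neurons by predicted spiking rate  ``<x, w_j> / theta_j``;
2. select the ``n`` top-ranked neurons as winners;
3. scale each winner's rate into a predicted spike count;
4. move winner weight columns toward the input and raise winner thresholds;
5. renormalise winner columns to a fixed total connection weight ``lambda``.

All functions here are pure/NumPy-level; the object-oriented fitting
interface lives in :mod:`crba.model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "CRBAConfig",
    "normalize_columns",
    "init_weights",
    "init_weights_spread",
    "firing_rates",
    "select_winners",
    "winner_coefficients",
    "predicted_spikes",
    "update_winner_weights",
    "update_thresholds",
    "batch_em_update",
    "sequential_em_update",
]


@dataclass
class CRBAConfig:
    """Hyper-parameters of the rate-based competitive learner.

    Parameters
    ----------
    m : int
        Number of competitive neurons.
    n : int
        Number of winner neurons updated per sample presentation.
    t : float
        Sample presentation time in ms (the window over which predicted
        spike counts are accumulated).
    lam : float
        Per-neuron total connection weight; every weight column sums to
        ``lam`` after each update.
    alpha_s : float
        Spike-count scale: predicted winner spikes = alpha_s * t * rate * c.
    alpha_w : float
        Weight-update scale.
    alpha_theta : float
        Threshold-update scale (mV per predicted spike).
    theta_0 : float
        Initial firing threshold (mV).
    theta_r : float
        Threshold resting value (mV) toward which thresholds decay.
    tau_theta : float
        Threshold decay constant, in units of sample presentations.
    seed : int
        Seed for weight initialisation (the learning pass itself is
        deterministic).
    theta_floor : float
        Lower clamp on the threshold used as divisor in the rate
        computation; keeps the rate defined when long-unwinning neurons
        decay toward the negative resting value.
    """

    m: int = 100
    n: int = 1
    t: float = 350.0
    lam: float = 1.0
    alpha_s: float = 10.0
    alpha_w: float = 5e-5
    alpha_theta: float = 0.05
    theta_0: float = 20.0
    theta_r: float = -10.0
    tau_theta: float = 1e5
    seed: int = 0
    theta_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 1 <= self.n <= self.m:
            raise ValueError("n must satisfy 1 <= n <= m")
        if self.t <= 0 or self.lam <= 0 or self.tau_theta <= 0:
            raise ValueError("t, lambda and tau_theta must be positive")
        if not self.theta_0 > self.theta_floor > 0:
            raise ValueError("require theta_0 > theta_floor > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CRBAConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def normalize_columns(W: np.ndarray, lam: float) -> np.ndarray:
    """Rescale every column of ``W`` to sum to ``lam`` (synaptic scaling).

    Shared by the rate-based learner and the spiking reference network;
    both constrain each neuron's total afferent weight to the same
    constant, which is what makes weights transferable between them.
    """
    W = np.asarray(W, dtype=float)
    sums = W.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("cannot normalize a column with non-positive sum")
    return W * (lam / sums)


def init_weights(
    samples: np.ndarray,
    m: int,
    lam: float,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.01,
) -> np.ndarray:
    """Sample-based weight initialisation.

    Each of the ``m`` columns is a training sample (drawn without
    replacement while unused samples remain, then with replacement), plus
    a small positive uniform jitter so no column is exactly zero, then
    column-normalised to sum ``lam``.  Starting neurons on actual data
    points instead of random noise cuts the presentations needed before
    prototypes emerge.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.size == 0 or X.shape[0] == 0:
        raise ValueError("no initialization samples")
    n_samples, p = X.shape
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = np.empty(m, dtype=int)
    n_direct = min(m, n_samples)
    idx[:n_direct] = rng.choice(n_samples, size=n_direct, replace=False)
    if m > n_samples:
        idx[n_direct:] = rng.choice(n_samples, size=m - n_samples, replace=True)
    W = X[idx].T.astype(float).copy()  # p x m
    W += jitter * rng.random((p, m))
    return normalize_columns(W, lam)


def init_weights_spread(
    samples: np.ndarray,
    m: int,
    lam: float,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.01,
) -> np.ndarray:
    """Farthest-point sample-based initialisation.

    Like :func:`init_weights`, every column starts as an actual training
    sample, but columns are chosen greedily to maximise the minimum
    cosine distance to the columns already chosen (the k-means++ style
    spread).  With fewer neurons than natural clusters a uniform draw
    almost surely leaves clusters uncovered and competing neurons
    doubled up; spreading the seeds removes that failure mode while
    staying fully unsupervised.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.size == 0 or X.shape[0] == 0:
        raise ValueError("no initialization samples")
    n_samples, p = X.shape
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0] = 1.0
    Xn = X / norms[:, None]
    chosen = [int(rng.integers(n_samples))]
    max_sim = Xn @ Xn[chosen[0]]
    while len(chosen) < min(m, n_samples):
        nxt = int(np.argmin(max_sim))  # farthest from everything chosen
        chosen.append(nxt)
        np.maximum(max_sim, Xn @ Xn[nxt], out=max_sim)
    idx = np.array(chosen[:m])
    if m > n_samples:
        idx = np.concatenate([idx, rng.choice(n_samples, size=m - n_samples, replace=True)])
    W = X[idx].T.astype(float).copy()
    W += jitter * rng.random((p, m))
    return normalize_columns(W, lam)


def firing_rates(x: np.ndarray, W: np.ndarray, theta: np.ndarray,
                 theta_floor: float = 1e-3) -> np.ndarray:
    """Predicted spiking rate of every neuron for input ``x``.

    rate_j = <x, w_j> / max(theta_j, theta_floor).  The dot product plays
    the role of the steady-state membrane drive; dividing by the adaptive
    threshold reproduces the competitive advantage of neurons that have
    fired less recently.
    """
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    if x.shape[0] != W.shape[0]:
        raise ValueError(f"dimension mismatch: x has {x.shape[0]} entries, W has {W.shape[0]} rows")
    return (x @ W) / np.maximum(np.asarray(theta, dtype=float), theta_floor)


def select_winners(rates: np.ndarray, n: int) -> np.ndarray:
    """Indices of the ``n`` largest rates, descending; ties -> lowest index."""
    rates = np.asarray(rates)
    if n > rates.shape[0]:
        raise ValueError("n exceeds number of neurons")
    if n < 1:
        raise ValueError("n must be >= 1")
    # stable sort on -rates keeps equal rates in index order
    return np.argsort(-rates, kind="stable")[:n]


def winner_coefficients(n: int) -> np.ndarray:
    """Rank-dependent spike-count coefficients c_i = exp(-5 i / n), i = 0..n-1.

    The leading winner gets coefficient 1.0; the exponential fall-off
    mimics the spike-count distribution across co-winning neurons observed
    in spiking simulations under soft inhibition.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.exp(-5.0 * np.arange(n) / n)


def predicted_spikes(rates: np.ndarray, winners: np.ndarray,
                     config: CRBAConfig) -> np.ndarray:
    """Predicted spike count for each winner: alpha_s * t * rate * c_rank.

    Kept real-valued: the count is only ever used as a multiplicative
    scale on the weight and threshold updates.
    """
    rates = np.asarray(rates, dtype=float)
    winners = np.asarray(winners, dtype=int)
    c = winner_coefficients(len(winners))
    return config.alpha_s * config.t * rates[winners] * c


def update_winner_weights(W: np.ndarray, x: np.ndarray, winners: np.ndarray,
                          spikes: np.ndarray, config: CRBAConfig) -> np.ndarray:
    """Move winner columns toward ``x`` and renormalise them (in place).

    W[:, k] <- normalise(W[:, k] + alpha_w * spikes_k * x).  The
    renormalisation both bounds total drive and redistributes the update
    across all of the column's synapses, which is the discrete-EM step:
    a convex pull of the prototype toward the presented sample.
    """
    x = np.asarray(x, dtype=float)
    for k, j in enumerate(np.asarray(winners, dtype=int)):
        col = W[:, j] + config.alpha_w * spikes[k] * x
        s = col.sum()
        if s <= 0:
            raise ValueError("degenerate neuron: winner column sums to zero")
        W[:, j] = col * (config.lam / s)
    return W


def update_thresholds(theta: np.ndarray, winners: np.ndarray,
                      spikes: np.ndarray, config: CRBAConfig) -> np.ndarray:
    """Homeostatic threshold update (in place).

    Winners are penalised in proportion to their predicted spikes
    (theta_j += alpha_theta * spikes_k), then every threshold takes one
    discrete decay step toward the resting value:
    theta += (theta_r - theta) / tau_theta.
    """
    winners = np.asarray(winners, dtype=int)
    theta[winners] += config.alpha_theta * np.asarray(spikes, dtype=float)
    theta += (config.theta_r - theta) / config.tau_theta
    return theta


def batch_em_update(assigned_samples: np.ndarray) -> np.ndarray:
    """Batch discrete-EM prototype update: the mean of the assigned samples.

    With unit variance and 0/1 posteriors the EM mean update collapses to
    the arithmetic mean of the samples currently assigned to the neuron —
    the K-means centroid step.
    """
    X = np.atleast_2d(np.asarray(assigned_samples, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty assignment set")
    return X.mean(axis=0)


def sequential_em_update(mu: np.ndarray, x: np.ndarray, k: int) -> np.ndarray:
    """One sequential (online) discrete-EM step with step size 1/k.

    mu' = mu + (x - mu)/k.  With k the running count of assigned samples
    this telescopes to the exact batch mean; in the learning rule proper
    the subtractive term is realised implicitly by column renormalisation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mu = np.asarray(mu, dtype=float)
    return mu + (np.asarray(x, dtype=float) - mu) / k
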