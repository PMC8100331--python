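"""Model/Results interface for competitive rate-based learning.

Usage follows the fit/results idiom of statistical modelling packages::

    from crba import CRBA, CRBAConfig
    from crba.datasets import make_synthetic, SyntheticSpec

    data = make_synthetic(SyntheticSpec(seed=1))
    model = CRBA(data.X, m=10, n=1, seed=1)
    res = model.fit(presentations=20_000)
    print(res.summary())
    res.label(data.X, data.y)
    acc = res.evaluate(data.X, data.y)

The results object carries the learned weight matrix and thresholds, the
windowed training trajectory (mean threshold, winner spike counts), and
the downstream verbs: labeling, max-voting prediction, accuracy,
parameter transfer to the spiking reference network, persistence.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import core, inference
from .core import CRBAConfig
from .csnn import CSNNParams, poisson_encode, simulate_sample
from .datasets import LabeledDataset
from .inference import NeuronLabeling
from .persist import save_model
from .transfer import CSNNState, TransferSpec, transfer_parameters

__all__ = ["CRBA", "CRBAResults"]


class CRBA:
    """Competitive rate-based model of a spiking winner-take-all layer.

    Parameters
    ----------
    data : array (n_samples, p) or LabeledDataset
        Non-negative inputs rescaled to [0, 1]; presented in order,
        cycling when more presentations than samples are requested.
    config : CRBAConfig, optional
        Full hyper-parameter set; keyword arguments override single
        fields (``CRBA(X, m=10, seed=1)``).
    """

    def __init__(self, data, config: CRBAConfig | None = None, **kwargs):
        if isinstance(data, LabeledDataset):
            data = data.X
        X = np.atleast_2d(np.asarray(data, dtype=float))
        if np.any(X < 0):
            raise ValueError("inputs must be non-negative")
        self.X = X
        if config is None:
            config = CRBAConfig(**kwargs)
        elif kwargs:
            config = CRBAConfig(**{**config.to_dict(), **kwargs})
        self.config = config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str | None = None,
                       **kwargs) -> "CRBA":
        """Build a model from a samples-by-features DataFrame.

        A label column, if named, is dropped (learning is unsupervised).
        """
        if label_col is not None:
            df = df.drop(columns=[label_col])
        return cls(df.to_numpy(dtype=float), **kwargs)

    def fit(self, presentations: int | None = None, W0: np.ndarray | None = None,
            log_window: int = 1000, init: str = "spread") -> "CRBAResults":
        """Run the sequential one-pass competitive learning loop.

        Each presentation applies the five steps (rates, winners,
        predicted spikes, weight update + renormalisation, threshold
        update + decay) to one sample; deterministic given the config
        seed and sample order.

        Parameters
        ----------
        presentations : int, optional
            Total samples presented (default: one pass over the data);
            the dataset is cycled in order beyond its length.
        W0 : array (p, m), optional
            Initial weights; default is sample-based initialisation.
        log_window : int
            Metrics (mean/min/max threshold, mean winner spikes) are
            averaged over windows of this many presentations.
        init : {"spread", "random"}
            Sample-based initialisation flavour: "spread" picks columns
            by farthest-point selection over the data (robust cluster
            coverage when m is close to the number of natural clusters),
            "random" draws them uniformly without replacement.
        """
        cfg = self.config
        n_samples = self.X.shape[0]
        if n_samples == 0 and W0 is None:
            raise ValueError("empty dataset and no initial weights")
        if presentations is None:
            presentations = n_samples
        if W0 is not None:
            W = core.normalize_columns(np.array(W0, dtype=float), cfg.lam)
        elif init == "spread":
            W = core.init_weights_spread(self.X, cfg.m, cfg.lam, cfg.seed)
        elif init == "random":
            W = core.init_weights(self.X, cfg.m, cfg.lam, cfg.seed)
        else:
            raise ValueError(f"unknown init {init!r}")
        theta = np.full(cfg.m, cfg.theta_0, dtype=float)

        rows = []
        win_spikes_acc = 0.0
        win_count = 0
        for i in range(presentations):
            x = self.X[i % n_samples]
            rates = core.firing_rates(x, W, theta, cfg.theta_floor)
            winners = core.select_winners(rates, cfg.n)
            spikes = core.predicted_spikes(rates, winners, cfg)
            core.update_winner_weights(W, x, winners, spikes, cfg)
            core.update_thresholds(theta, winners, spikes, cfg)
            win_spikes_acc += spikes[0]
            win_count += 1
            if (i + 1) % log_window == 0 or i + 1 == presentations:
                rows.append({
                    "presentation": i + 1,
                    "mean_theta": theta.mean(),
                    "min_theta": theta.min(),
                    "max_theta": theta.max(),
                    "mean_winner_spikes": win_spikes_acc / win_count,
                })
                win_spikes_acc = 0.0
                win_count = 0
        history = pd.DataFrame(rows)
        return CRBAResults(self, W, theta, history, presentations)


class CRBAResults:
    """Learned state of a fitted competitive rate-based model."""

    def __init__(self, model: CRBA, W: np.ndarray, theta: np.ndarray,
                 history: pd.DataFrame, presentations: int):
        self.model = model
        self.config = model.config
        self.W = W
        self.theta = theta
        self.history = history
        self.presentations = presentations
        self.labeling: NeuronLabeling | None = None

    # -- diagnostics ----------------------------------------------------

    def summary(self) -> str:
        """Plain-text overview of the fitted state and training trajectory."""
        cfg = self.config
        lines = [
            "Competitive Rate-Based Model Results",
            "=" * 52,
            f"{'Neurons (m)':<28}{cfg.m:>24}",
            f"{'Winners per sample (n)':<28}{cfg.n:>24}",
            f"{'Presentations':<28}{self.presentations:>24}",
            f"{'Input dimension (p)':<28}{self.W.shape[0]:>24}",
            f"{'Column sum (lambda)':<28}{cfg.lam:>24.6g}",
            "-" * 52,
            f"{'Mean threshold (mV)':<28}{self.theta.mean():>24.4f}",
            f"{'Threshold range (mV)':<28}"
            f"{f'{self.theta.min():.2f} .. {self.theta.max():.2f}':>24}",
        ]
        if len(self.history):
            lines.append(f"{'Final mean winner spikes':<28}"
                         f"{self.history['mean_winner_spikes'].iloc[-1]:>24.4f}")
        lines.append(f"{'Labeled':<28}{str(self.labeling is not None):>24}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def prototype_match(self, prototypes: np.ndarray):
        """Optimal bijective neuron-to-prototype assignment by cosine similarity.

        Returns (assignment array: neuron j -> prototype index, cosine
        similarities of the matched pairs).  Useful when the data come
        from a known cluster structure.
        """
        from scipy.optimize import linear_sum_assignment

        P = np.atleast_2d(np.asarray(prototypes, dtype=float))
        Wn = self.W / np.linalg.norm(self.W, axis=0, keepdims=True)
        Pn = P / np.linalg.norm(P, axis=1, keepdims=True)
        cos = Wn.T @ Pn.T  # (m, k)
        rows, cols = linear_sum_assignment(-cos)
        return cols, cos[rows, cols]

    def plot_history(self, ax=None):
        """Plot the windowed mean threshold and winner-spike trajectories."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.plot(h["presentation"], h["mean_theta"], label="mean threshold (mV)")
        ax2 = ax.twinx()
        ax2.plot(h["presentation"], h["mean_winner_spikes"], color="C1",
                 label="mean winner spikes")
        ax.set_xlabel("presentations")
        ax.set_ylabel("threshold (mV)")
        ax2.set_ylabel("winner spikes")
        return ax

    # -- classification -------------------------------------------------

    def label(self, X: np.ndarray, y: np.ndarray) -> NeuronLabeling:
        """Assign classes to neurons from labeled samples (no learning)."""
        self.labeling = inference.label_neurons(self.W, self.theta, X, y, self.config)
        return self.labeling

    def _require_labeling(self, labeling):
        labeling = labeling or self.labeling
        if labeling is None:
            raise ValueError("model unlabeled: call label() first")
        return labeling

    def predict(self, X: np.ndarray, labeling: NeuronLabeling | None = None) -> np.ndarray:
        return inference.predict(self.W, self.theta, self._require_labeling(labeling),
                                 X, self.config)

    def predict_votes(self, X: np.ndarray, labeling: NeuronLabeling | None = None):
        return inference.predict_votes(self.W, self.theta,
                                       self._require_labeling(labeling), X, self.config)

    def evaluate(self, X: np.ndarray, y: np.ndarray,
                 labeling: NeuronLabeling | None = None) -> float:
        return inference.evaluate(self.W, self.theta, self._require_labeling(labeling),
                                  X, y, self.config)

    # -- spiking network bridge -----------------------------------------

    def to_csnn(self, spec: TransferSpec | None = None) -> CSNNState:
        """Transfer learned weights (verbatim) and rescaled thresholds."""
        return transfer_parameters(self.W, self.theta, spec)

    def csnn_winner_agreement(self, X: np.ndarray, params: CSNNParams | None = None,
                              spec: TransferSpec | None = None, seed: int = 0,
                              n_presentations: int = 500) -> dict:
        """Fraction of presentations where the spiking network's first-
        spiking neuron equals this model's rate winner.

        Runs the transferred state through the reference simulator with
        learning off under strong inhibition.  Presentations on which the
        spiking network stays silent (no winner exists) are excluded from
        the denominator.
        """
        params = params or CSNNParams.strong_inhibition()
        state = self.to_csnn(spec)
        rng = np.random.default_rng(seed)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        agree = compared = skipped = 0
        for i in range(n_presentations):
            x = X[i % X.shape[0]]
            crba_winner = int(core.select_winners(
                core.firing_rates(x, self.W, self.theta, self.config.theta_floor), 1)[0])
            trains = poisson_encode(x, params, rng)
            result = simulate_sample(trains, state.W, state.theta, params, learning=False)
            first = result.spikes.first_spiker()
            if first is None:
                skipped += 1
                continue
            compared += 1
            agree += first[0] == crba_winner
        return {
            "agreement": agree / compared if compared else float("nan"),
            "n_compared": compared,
            "n_silent": skipped,
        }

    # -- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        save_model(path, self.W, self.theta, self.config, self.labeling)
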