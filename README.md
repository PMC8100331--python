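# crba — competitive rate-based learning for spiking winner-take-all networks

Competitive spiking neural networks (CSNNs) learn input prototypes without
labels: a layer of leaky integrate-and-fire (LIF) neurons with lateral
inhibition competes to respond first to each rate-coded input, the winner's
synapses are strengthened by spike-timing-dependent plasticity (STDP), and an
adaptive firing threshold keeps any one neuron from dominating. Simulating
those dynamics time step by time step is slow — hours of CPU time for a few
hundred neurons on an image dataset.

This package implements the **competitive rate-based algorithm (CRBA)**: a
one-pass-per-sample approximation of the CSNN that replaces the temporal
competition with

1. a **ranking** of neurons by predicted spiking rate
   `freq_j = ⟨X, W_j⟩ / ϑ_j` (dot product over adaptive threshold),
2. selection of the top-`n` **winners** (`n = 1` under strong inhibition),
3. a predicted **spike count** per winner, `spikes = α_s · t · freq · c_rank`
   with rank coefficients `c_i = e^(−5i/n)`,
4. a **discrete-EM weight update** pulling each winner column toward the
   input, `W_j ← W_j + α_w · spikes · X`, followed by column normalisation to
   a fixed total `λ` (the sequential K-means-style prototype step), and
5. a **homeostatic threshold update**: winners pay `ϑ_j += α_ϑ · spikes`,
   everyone relaxes toward a resting value, `ϑ += (ϑ_r − ϑ)/τ_ϑ`.

It also ships the **reference spiking simulator** being approximated
(Poisson rate encoding, linear LIF with delta synapses, lateral inhibition,
pair-based STDP, adaptive thresholds) together with the closed-form
sub-threshold solutions that justify the approximation,

```
u(t) ≈ τ_u β ⟨X, W⟩ (1 − e^(−t/τ_u)),
t_f  = τ_u [log(τ_u β ⟨X, W⟩) − log(τ_u β ⟨X, W⟩ − ϑ)],
```

plus neuron **labeling + max-voting inference**, and **parameter transfer**:
a trained rate-based model initialises the spiking network (weights verbatim,
thresholds rescaled linearly into a spiking-compatible 35–60 mV band).

Intended users: computational-neuroscience and neuromorphic-computing
practitioners who want CSNN-style unsupervised prototype learning at
vector-operation speed, with a faithful spiking simulator for validation.

## Worked example

```python
from crba import CRBA, SyntheticSpec, make_synthetic

data = make_synthetic(SyntheticSpec(seed=1))   # 10 clusters, p=196, 5,000 samples
model = CRBA(data.X, m=10, n=1, seed=1)
res = model.fit(presentations=20_000)
print(res.summary())
```

```
Competitive Rate-Based Model Results
====================================================
Neurons (m)                                       10
Winners per sample (n)                             1
Presentations                                  20000
Input dimension (p)                              196
Column sum (lambda)                                1
----------------------------------------------------
Mean threshold (mV)                         625.1131
Threshold range (mV)                612.02 .. 635.31
Final mean winner spikes                      3.8426
Labeled                                        False
====================================================
```

The thresholds have risen from 20 mV to ~625 mV while the predicted winner
spike count fell from tens to ~3.8 — the homeostatic signature of settled
competition: every neuron has claimed a cluster and is being priced
accordingly. Labeling the neurons and classifying by max-voting:

```python
res.label(data.X, data.y)
print("accuracy:", res.evaluate(data.X, data.y))   # accuracy: 1.0

state = res.to_csnn()                               # weights verbatim,
print(state.theta.round(2))                         # thresholds in 35-60 mV
rep = res.csnn_winner_agreement(data.X, seed=0, n_presentations=50)
print(rep)   # {'agreement': 1.0, 'n_compared': 50, 'n_silent': 0}
```

The last call runs the transferred state through the spiking simulator
(learning off, strong inhibition) and checks that the first-spiking LIF
neuron is the rate-based winner — here on all 50 presentations.

## Command line

```
crba make-data spec.yaml data.csv        # synthetic k-cluster dataset
crba train data.csv model.h5 --config cfg.yaml --presentations 20000
crba label model.h5 data.csv
crba evaluate model.h5 data.csv          # accuracy: 1.0000 (5000/5000)
crba predict model.h5 new.csv out.csv
crba transfer model.h5 csnn_state.h5     # rescaled 35-60 mV thresholds
crba simulate model.h5 data.csv          # rate-vs-spiking winner agreement
```

Each `train` run writes a `.manifest.json` (config, seed, dataset hash,
windowed metrics) sufficient to reproduce the model bitwise.

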