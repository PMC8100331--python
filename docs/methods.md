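# Methods

## The model

A competitive spiking neural network (CSNN) is a two-layer network: `p`
input channels rate-code a non-negative intensity vector `X ∈ [0,1]^p` as
Poisson spike trains, which drive `m` leaky integrate-and-fire neurons
through normalised excitatory synapses `W` (p×m, column sums fixed to `λ`).
All-to-all lateral inhibition makes the layer a winner-take-all circuit;
pair-based STDP and a per-neuron adaptive firing threshold provide the
learning and the homeostasis.

The rate-based learner implemented here collapses each presentation window
to five algebraic steps. Its justification is carried by two analytic
results about the sub-threshold LIF dynamics under a constant-rate train:

- the membrane potential approaches
  `u(t) ≈ τ_u β ⟨X, W_j⟩ (1 − e^(−t/τ_u))`, so the only sample-dependent
  quantity is the dot product `⟨X, W_j⟩`;
- the first-crossing time of a threshold `ϑ < τ_u β ⟨X, W⟩` is
  `t_f = τ_u [log(τ_u β ⟨X,W⟩) − log(τ_u β ⟨X,W⟩ − ϑ)]`, which is a
  monotone function of the dot product at fixed `ϑ`.

Hence, for uniform thresholds, ranking neurons by first-spike time is
exactly ranking by dot product (verified exhaustively in the test suite),
and competition reduces to an argmax. With heterogeneous adaptive
thresholds the learner uses `⟨X, W_j⟩ / ϑ_j` as its rate proxy, so neurons
that have won often (high `ϑ`) are handicapped — the same homeostatic
pressure the spiking threshold adaptation produces.

The weight update is the discrete-EM (sequential K-means) view of STDP:
with unit variance and 0/1 posteriors the EM mean update is the mean of the
assigned samples; the online form `μ ← μ + (x − μ)/k` with step `1/k`
telescopes to that mean exactly. In the learning rule proper the update is
`W_j ← normalise(W_j + α_w · spikes · X)`: the additive pull plus
renormalisation is the convex combination that plays the `−μ` role.

## Default constants

| name | default | meaning |
|---|---|---|
| m | 100 | neurons (10 for the desk-scale fixture) |
| n | 1 | winners per presentation (strong inhibition) |
| t | 350 ms | presentation time |
| λ | 1 | per-neuron total connection weight |
| α_s | 10 | spike-count scale |
| α_w | 5·10⁻⁵ | weight-update scale |
| α_ϑ | 0.05 mV/spike | threshold-update scale |
| ϑ₀ | 20 mV | initial threshold |
| ϑ_r | −10 mV | threshold resting value |
| τ_ϑ | 10⁵ presentations | threshold decay constant |

These constants are calibrated for inputs rescaled to [0,1]; readers do the
rescaling so every consumer sees one convention. With a winner dot product
around the designed operating point they put the winner near a few tens of
predicted spikes and mV-scale threshold increments per presentation. τ_ϑ is
listed against m = 100 in the source configuration (larger networks pair
with 10⁶/10⁷); the m = 10 fixture keeps 10⁵.

Because ϑ decays toward a negative resting value, a long-unwinning neuron
could reach a non-positive threshold and make the rate undefined; the rate
divisor is clamped at `theta_floor = 10⁻³ mV`. The clamp preserves the
intended semantics: a tiny threshold means an enormous rate, so the neuron
re-enters competition.

Winner coefficients are indexed from zero, `c_i = e^(−5i/n)`, i = 0..n−1,
so the top winner always has coefficient 1.0 and `n = 1` reduces to plain
rate scaling. Predicted spike counts are kept real-valued — they are only
ever a multiplicative scale. Ties in the ranking break toward the lowest
neuron index (stable sort) for exact reproducibility. Per Algorithm
pseudo-code the threshold decay step is applied to all neurons each
presentation, after the winner increment; at `1/τ_ϑ ≤ 10⁻⁵` per step the
difference from decaying non-winners only is negligible.

## Initialisation

Columns are initialised from actual training samples (plus a small positive
jitter so no column is zero, then normalised). Two flavours exist:

- `init_weights` — uniform draws without replacement (then with
  replacement once samples run out);
- `init_weights_spread` — farthest-point selection (k-means++-style,
  unsupervised), the default in `fit()`.

The spread variant exists because of a real failure mode of the dynamics:
with `m` close to the number of natural clusters, uniform draws almost
surely seed two neurons in one cluster and none in another. The resulting
configuration — a duplicated pair alternating wins inside one cluster while
a doubly-loaded neuron serves two clusters — is a *stable equilibrium* of
the threshold homeostasis: equilibrium thresholds scale like
`√(win-rate · dot-product)`, and the doubled neuron's rate advantage on its
second cluster survives the rescaling, so no amount of further training
breaks it (measured: 1 of 12 seeds reached a bijective neuron↔cluster
assignment with uniform draws, 12 of 12 with spread selection). Farthest-
point seeding removes the collision at the source while staying fully
unsupervised.

## The reference spiking simulator

Membrane dynamics per neuron, with `u_r = u_reset = 0`:

```
du_j/dt = (u_r − u_j)/τ_u + Σ_i w_ij x_i(t) − Σ_{k≠j} w_inh y_k(t)
```

where the input and recurrent trains are delta spikes (each afferent spike
adds `w_ij` instantly, each lateral spike subtracts `w_inh`). Defaults:
`τ_u = 100 ms`, `dt = 0.1 ms`, `T = 350 ms` (3,500 steps), refractory
5 ms, threshold offset 20 mV with per-spike increment 0.5 mV and slow decay.

Numerical scheme: the linear leak uses its exact exponential update per
step (the standard exact integrator for linear LIF); spike events are
applied in the step they fall in, carrying the residual half-step of decay,
and are time-stamped at the step midpoint — the unbiased location of an
event known only to step resolution. A literal first-order Euler leak plus
step-end stamping leaves a systematic bias of a few hundredths of a
millisecond in first-spike times, which matters when validating against the
closed forms at one-step tolerance. At most one neuron fires per step;
simultaneous crossings resolve to the lowest index. The firing neuron
resets, holds through its refractory period, inhibits all others, and bumps
its threshold.

STDP uses the two-branch exponential kernel with nearest-spike pairing via
last-pre/last-post bookkeeping; coincident pairs (Δt = 0) take the
depression branch. Weights clip at zero and are column-normalised at
presentation end. Magnitudes default to `α₊ = 10⁻⁴, α₋ = 5·10⁻⁵`
(τ± = 20 ms): sized so one spike pair moves a typical normalised weight
(λ/p ≈ 0.005) by a few percent, not past zero.

Unspecified-by-the-source constants, all exposed as parameters: the
encoding gain defaults to `β = 0.06375 spikes/ms` (the 63.75 Hz
full-intensity convention of the CSNN literature) and the inhibition weight
to `w_inh = 500 mV`. The `strong_inhibition()` preset raises `β` to
1.275 spikes/ms for the transfer workflow: with `λ = 1` column sums and
[0,1] inputs the base gain caps the steady-state potential at
`τ_u β ≈ 6.4 mV`, below any threshold in the 35–60 mV transfer band, so no
transferred neuron could ever fire; at the preset gain a matched prototype
drives `τ_u β ⟨X,W⟩ ≈ 90 mV`, comfortably above the band. A
`soft_inhibition()` preset (w_inh = 5 mV) allows multi-winner regimes.

## Labeling, inference, transfer

Labeling accumulates each neuron's response (predicted spike count,
thresholds frozen, no plasticity) per class over a labeled set and assigns
the argmax class (ties → lowest class id). Prediction averages — not sums —
responses within each label group, so classes represented by more neurons
are not favoured, and returns the argmax class; a sample that excites
nothing falls back to the majority neuron label with a warning.

Transfer copies weights verbatim (both networks share the column-sum-λ
normalisation) and maps thresholds by linear min-max rescaling onto
[35, 60] mV — the range a conventionally trained spiking network reaches —
interpreted as the total effective threshold. Linear min-max preserves rank
order exactly and is invertible; the all-equal case maps to the midpoint.

## Synthetic data

`make_synthetic` draws `k` sparse non-negative prototypes (default: 10
classes, p = 196, 15% active entries uniform in [0.5, 1]), accepted one at
a time under a minimum pairwise cosine-distance constraint (default 0.8),
and emits 500 noisy copies per class (additive Gaussian noise, sd 0.05,
clipped to [0, 1]), presented in shuffled order. This emulates what the
rate-based learner assumes of real data — one intensity prototype per
class, bounded within-class variation — and a K-means oracle recovers the
partition with adjusted Rand ≥ 0.99.

What it does **not** emulate: within-class multimodality (the many ways of
writing a digit) and genuine between-class overlap. Consequences for what
passing tests show: prototype recovery, homeostasis trends and transfer
agreement transfer qualitatively to real data, but max-voting accuracy on
this fixture saturates at 1.0 — in 196 dimensions with isotropic bounded
noise the clusters are always linearly separable (inter-prototype distance
≈ 4.9 vs projected noise sd ≈ 0.2). In particular, the known accuracy
*degradation* with many winners cannot register here: multi-winner training
measurably blurs the learned prototypes (minimum matched cosine falls from
0.998 at n = 1 to 0.86 at n = 8 of 10) yet accuracy stays at ceiling,
whereas on overlapping multimodal data the same blurring costs accuracy.
The multi-winner acceptance check is therefore expected to fail on this
fixture, and the blur is reported as the mechanism-level observable.

## Problem sizes

The desk-scale study uses m = 10 neurons on the 5,000-sample fixture with
20,000 presentations (the dataset is cycled in order), chosen as the point
where the training trajectory has clearly plateaued; fits take under a
second, the full acceptance computation about half a minute. Oracle checks
run 50 closed-form instances (membrane at the base gain, first-spike at
β = 5 spikes/ms with p = 784 channels and thresholds in [0.2, 0.45] of the
steady state, keeping the crossing slope non-degenerate), 1,000 ranking
instances, and 500 transfer presentations.

## Known limitations

- Strictly sequential learning: no mini-batching (the update after sample
  i depends on the state after sample i−1).
- Only the linear LIF membrane with direct coupling is modelled; quadratic
  or exponential membranes and conductance-based synapses are out of scope,
  as is the general (covariance) EM update, which can produce negative
  weights incompatible with the spiking architecture.
- One spike per time step per layer: in extremely soft-inhibition regimes
  with large m this serialises near-simultaneous spikes.
- The transfer band (35–60 mV) is an empirical convention; no claim is
  made that it is optimal for other parameter sets.
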