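# ecgcs — compressed-sensing reconstruction of ECG-like signals

`ecgcs` reconstructs quasi-periodic 1-D physiological signals (ECG being
the motivating case) from compressive random measurements. It is aimed at
people working on low-power wearable acquisition, where the device records
only M ≪ N random projections y = Φx of an N-sample trace and the original
signal must be recovered offline.

## Method

Recovery uses **denoising-based approximate message passing (D-AMP)**:

    q_t     = x_t + Φᵀ z_t
    x_{t+1} = D_{σ̂_t}(q_t)
    z_{t+1} = y − Φ x_{t+1} + z_t · div D(q_t) / M      (Onsager correction)
    σ̂_t    = ‖z_t‖₂ / √M

The Onsager term — the denoiser's Jacobian trace, estimated by a
Monte-Carlo probe div D ≈ bᵀ(D(q+τb) − D(q))/τ with b ~ N(0, I) and
τ = ‖q‖∞/1000 — keeps the effective noise in q_t approximately Gaussian,
so any Gaussian-noise denoiser can be plugged in.

The plug-in denoiser exploits **non-local self-similarity**: heartbeats
repeat, so blocks of the signal taken one beat apart are nearly identical.
Overlapping 32-sample blocks are grouped with their nearest neighbours
(squared Euclidean distance, searched within a ±256-position window) into
d×g matrices that are nearly low-rank, and each group is denoised by
**weighted nuclear norm minimization (WNNM)** — singular value shrinkage
with data-adaptive weights

    σ_j(X) = √max(σ_j(Q)² − g σ_n², 0),    w_j = c·g·σ_n² / (σ_j(X) + ε),
    A = U max(Σ − w, 0) Vᵀ,

which removes noise-level singular values while barely touching the large
(signal) ones. Overlapping block estimates are averaged back into a signal.

The package's distinguishing feature is **rank-weighted aggregation
(IWNNM)**: under noise, block matching sometimes groups dissimilar blocks,
which shows up as a *high post-shrinkage rank*. Instead of a plain average,
each group's estimates are weighted by exp(−rank/block_len), down-weighting
contaminated groups. `wnnm` (uniform averaging) and `iwnnm` (rank-weighted)
are both provided, along with CR/PRD/RMSE/SNR/P-SNR evaluation metrics and
a synthetic quasi-periodic ECG generator used throughout the tests.

## Worked example

```python
import ecgcs

sig = ecgcs.synth_ecg(ecgcs.EcgSynthParams(seed=0))        # N=1024 @ 360 Hz
phi = ecgcs.make_gaussian_operator(len(sig), 256, seed=1)  # CR = 4
obs = ecgcs.compress(sig, phi)
cfg = ecgcs.ReconConfig(n_iterations=30, denoiser_name="iwnnm", seed=0)
est, states, prd_traj = ecgcs.reconstruct(obs, phi, cfg, reference=sig)
print(f"PRD after 5 iters: {prd_traj[4]:.2f}%, after 30: {prd_traj[-1]:.2f}%")
```

prints

```
PRD after 5 iters: 9.01%, after 30: 0.26%
```

i.e. from 4× undersampled noiseless measurements the reconstruction error
falls to 0.26% of the signal energy within 30 iterations. With measurement
noise at 15 dB SNR the same pipeline floors at PRD ≈ 20% — the error floor
set by the noise, at which point the rank-weighted variant's advantage over
uniform averaging becomes visible (lower mean PRD over repeated trials).

The same pipeline is scriptable from the shell:

```sh
ecgcs synth --seed 0 --out sig.csv
ecgcs reconstruct --signal sig.csv --n-measurements 256 --seed 0 \
      --denoiser iwnnm --out-prefix run
ecgcs sweep --cr 2 --cr 4 --n-seeds 3 --out-prefix sweep
```

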