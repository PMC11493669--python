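# Methods

## Problem and model

A length-N trace x is observed through y = Φx (+ noise), with Φ an M×N
i.i.d. Gaussian matrix, entries N(0, 1/M) so column squared-norms are ≈ 1 —
the ensemble under which AMP's Gaussian-effective-noise heuristic is
justified. Reconstruction runs the D-AMP recursion (see README) for a fixed
K = 30 iterations from x₀ = 0, z₀ = y; an optional relative-change early
stop (1e−6) exists but is off by default, so trajectories are strictly
reproducible. The per-iteration effective noise level fed to the denoiser
is σ̂_t = ‖z_t‖₂/√M, never a user constant.

Measurement noise can be specified either as a standard deviation or as a
measurement SNR in dB (`snr_db_to_sigma`); both entry points exist because
noise levels in this literature are reported in both conventions, sometimes
inconsistently within a single study.

## Block matching

Blocks of `block_len` = 32 samples are extracted at stride `step` = 1 with
the final start clamped to N − block_len, so every sample is always covered
without zero padding. For each reference block, candidates whose start lies
within `window` = 256 positions are ranked by squared Euclidean distance
(ties broken by smaller start, for determinism) and the nearest
`group_size` = 16 — reference included — form the group. A fixed group
size, rather than a pure distance threshold, keeps the "number of similar
blocks" entering the shrinkage weights well defined; an optional threshold
can additionally prune far members. Group membership is invariant to adding
a constant to the signal, and with `window ≥ N` the windowed search equals
the unwindowed brute force (both properties are tested). The window exists
purely to bound the O((N−d+1)²) matching cost; 256 comfortably spans more
than one beat period at 360 Hz.

The production path vectorizes matching (one Gram matrix, windowed stable
argsort) and batches all group SVDs; it is verified against the
object-by-object reference path in the tests.

## Shrinkage

For a d×g group Q (blocks are columns), thin SVD Q = UΣVᵀ, clean singular
values are estimated as σ_j(X) = √max(σ_j(Q)² − g·σ_n², 0) — the square
root restores amplitude scale; the raw variance-clamp form is available via
`sqrt_correction=False` for fidelity experiments. Weights are

    w_j = c · g^p · σ_n² / (σ_j(X) + ε),   c = 2√2, p = 1, ε = 1e−16,

and A = U·max(Σ − w, 0)·Vᵀ. Two conventions coexist in the WNNM
literature for the group-size factor (g vs √g); we default to the linear
form p = 1 because at this package's 32×16 group geometry the √g scale
under-shrinks: the denoiser's divergence then exceeds M, the Onsager gain
passes 1, and the AMP iteration diverges. With p = 1 the divergence stays
near 0.5–0.9 of M and the loop converges (PRD < 1% noiseless at CR 4). The
σ_n² factor in the numerator follows the original weighted-nuclear-norm
convention; it makes shrinkage vanish as σ̂_t → 0, so the denoiser
approaches the identity as AMP converges. The bare form without σ_n² is
available via `noise_scaled_weights=False`.

The retained rank is counted above a numerical floor max(d,g)·ε_mach·σ_max
(the standard matrix-rank tolerance), so zero-shrinkage passes report the
true numerical rank.

## Aggregation: uniform vs rank-weighted

Every sample receives several block estimates (up to block_len × group
overlap). WNNM averages them uniformly. IWNNM weights each group's
contribution by exp(−rank/block_len) and normalizes per sample, so weights
always sum to one. The rationale: a group whose post-shrinkage rank is high
was likely contaminated by dissimilar blocks during matching (noise can
make unrelated blocks look close), and its estimates deserve less trust.
With all ranks equal the two modes coincide exactly. The weight is applied
per member-block contribution during aggregation — the only reading that
yields a well-defined per-sample normalization.

The inner denoiser loop supports `inner_iters` regularized passes
(q_t = x̂ + δ(q − x̂), δ = 0.1); the default is a single pass, which keeps
the AMP denoiser contract clean (one call = one denoise at one σ).

## Onsager correction

The divergence is estimated at the current q_t (the standard D-AMP form)
with `mc_probes` = 1 by default — the usual single-probe practice; the
probe seed is derived as seed + iteration, so a K = 35 run extends a
K = 30 run exactly. τ = ‖q‖∞/1000, with a 1e−6 fallback (logged) for the
all-zero corner. Raising `mc_probes` turns the estimator into a testable
trace oracle (unbiased for linear denoisers; variance ‖A‖_F² + tr(A²) per
probe).

## Synthetic data

`synth_ecg` sums five Gaussian bumps per beat (P, Q, R, S, T at offsets
−0.2/−0.03/0/0.03/0.3 s, widths 0.04/0.012/0.016/0.012/0.06 s, relative
amplitudes 0.15/−0.12/1/−0.25/0.3), R peak normalized to 1.0 before
jitter. Defaults: 360 Hz, 75 bpm (beat period exactly 288 samples, so
zero-jitter signals are periodic on the sample grid), 5% beat-period
jitter, 10% per-beat amplitude jitter, 0.05-amplitude 0.3 Hz baseline
wander, duration 1024/360 s so the default record is N = 1024. This
reproduces the property the method exploits — repeated beat morphology —
but not clinical ECG realism: no arrhythmia, muscle artifact, powerline
interference, or sensor drift beyond the sinusoidal wander. Passing tests
therefore demonstrate the mechanism under clean quasi-periodicity, not
diagnostic-grade performance on pathological records.

`synth_lowrank_group` builds d×g matrices of exactly known rank
(orthonormal factors, singular values 1, ½, ¼, …) plus i.i.d. noise, as
ground-truthed fixtures for the shrinkage operator.

A minimal WFDB reader (header + formats 16/212, local files only) lets
users run the pipeline on real PhysioNet-style records they already have;
nothing in the package performs network access.

## Standard evaluation instance and problem sizes

The package's standard demonstration instance is N = 1024 at CR = 5.12
(M = 200), K = 30, with measurement noise at 15 dB SNR — the conditions of
the reference experiments this design targets. The noise matters for one
qualitative behaviour: on noiseless clean synthetic signals PRD decays
geometrically (~8%/iteration at the tail) with no floor, so no iteration
count is a plateau in relative terms; with noise, PRD floors (≈ 20% at
15 dB) and the K = 30 → 35 change is under 1%. Real ECG records carry
intrinsic noise, which is why iteration-count plateaus are observed there.

Test and acceptance problem sizes (10-seed CR sweep over
M ∈ {1024, 768, 512, 384, 256}; 20-seed IWNNM-vs-WNNM comparison at
M = 256, 15 dB; 3-trial acceptance script) were chosen as the smallest
ensembles that make the directional claims statistically meaningful.

## Numerical choices and degenerate inputs

- Thin SVD everywhere; singular values descending.
- Ties in block matching break toward the smaller start index.
- A group may legally shrink to the reference alone (threshold pruning);
  aggregation then still covers every sample because every block is a
  reference once.
- An all-zero probe input, a zero reference norm (PRD), a zero reference
  peak (P-SNR), and M > N are explicit errors or logged fallbacks, not
  silent NaNs; exact reconstructions report SNR/P-SNR as +inf sentinels.
- All generators and the AMP loop are pure functions of their seeds; no
  global random state is used anywhere.

## Known limitations

- The IWNNM-over-WNNM advantage is small on clean synthetic data (the
  groups are rarely contaminated) and emerges clearly only under noise; on
  individual seeds either variant can win.
- The divergence probe with one sample makes late-iteration trajectories
  mildly stochastic (across seeds, not across reruns).
- The WFDB subset does not handle multi-segment records, skew, or byte
  offsets; use a full-featured reader for those.
- Runtime is dominated by the per-iteration Gram matrix and batched SVDs;
  N ≫ 10⁴ would want a smarter matcher than the dense windowed scan.
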