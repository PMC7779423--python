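# shardrecon

Scattered-slice SHARD reconstruction: slice-to-volume motion correction
for multi-shell diffusion MRI.

Subject motion during a dMRI scan scatters the acquired EPI slices in
space and — through rotation — scatters the effective diffusion-encoding
directions, so the volumes of a protocol no longer share a common
geometry or contrast. `shardrecon` recovers a consistent image by
jointly estimating

* a low-rank multi-shell signal representation (**SHARD**: per-shell
  real even spherical harmonics linked across shells by a data-driven
  SVD radial basis), and
* one rigid pose per multiband excitation, parameterized in the Lie
  algebra se(3),

so that the forward model `ŷ_s = B_s M(μ_s) Q_s(μ_s) x` explains every
acquired slice group: `Q_s` projects the coefficients to the shell and
motion-reoriented direction of excitation *s*, `M(μ_s)` maps subject to
scanner space by cubic interpolation, and `B_s` applies the combined
slice-profile/interpolation kernel along z and selects the excited
slices — which also gives through-plane resolution recovery from
overlapping slices. Estimation alternates a matrix-free conjugate-
gradient solve of

    min_x (1/n_v) Σ_s w_s ‖y_s − R_s x‖² + λ²‖Lx‖² + ζ²‖Zx‖²

with Levenberg–Marquardt rigid registration of each excitation against
a rank-reduced prediction of its own contrast, two-stage temporal
filtering of the pose trace, and per-shell log-normal mixture
reweighting w_s of outlier (dropout) slices. A synthetic-data module
generates motion-corrupted multi-shell phantoms with ground truth for
validation. See `docs/methods.md` for the full model description.

## Worked example

`examples/simulate_and_correct.py` builds a 16³ three-shell phantom,
corrupts it with a burst-augmented motion trace (excursion ≈ 1.6 mm /
1.9°), 10 % slice dropouts and noise, runs the full epoch schedule, and
prints:

```
simulated motion: excursion 1.57 mm / 1.92 deg, slice-to-slice 0.36 mm / 0.39 deg
24 of 232 excitations carry dropout bias
translation RMSE: 1.190 mm
rotation RMSE:    2.284 deg
signal RMSE:      9.82 % of the b=0 level
mean weight of dropout shots: 0.71, clean shots: 0.93
```

The trace RMSEs compare recovered and simulated poses after removing
each trace's global mean (the gauge freedom between independent
reconstructions); the signal RMSE is relative to the mean b=0 intensity
(1/SNR units); the weight line shows the outlier model separating
dropout shots from clean ones. `examples/basis_rank.py` walks through
the basis bookkeeping (rank 89 for the 4-shell neonatal protocol, 22
for the registration basis) and `examples/outlier_weights.py`
demonstrates the mixture-based slice reweighting.

A thin CLI wraps the same library:

```sh
shardrecon simulate --out sim/ --seed 1
shardrecon run sim/dwi.nii.gz --grad sim/grad.txt --mask sim/mask.nii.gz \
    --mb 2 --interleave 2 --out-motion motion.tsv --out-weights weights.tsv
shardrecon metrics motion.tsv weights.tsv --n-slices 24 --mb 2
```

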