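# iembench

Inverted encoding models (IEMs) for population-level neural data, with a
ground-truth neuron-population simulator.

## The problem

An IEM analyses multichannel neural measurements (e.g. fMRI voxel patterns)
by positing a small set of *channels* — information units tuned to regions
of a stimulus-feature space such as orientation. With **B** the signals ×
trials activation matrix and **C** the k × trials matrix of predicted
channel responses (each channel evaluated at each trial's stimulus), the
analysis is:

1. **Forward fit** (per signal, ordinary least squares):
   **W** = argmin ‖**B** − **W C**‖²
2. **Inversion** on held-out data:
   **Ĉ** = (**WᵀW**)⁻¹**Wᵀ B**_test
3. **Recentering & averaging**: each trial's reconstructed k-vector (the
   *channel response profile*, in arbitrary units) is circularly aligned on
   the true stimulus feature and averaged within condition.

A known objection is that any invertible linear transform **T** of the
basis fits the data exactly as well, so the shape of a channel response
profile is "one of an infinite family". This package demonstrates the
counterpoint: because the whole pipeline is linear, a change of basis acts
on the reconstructions as the *same* invertible map (**Ĉ**_T = **T Ĉ**,
recoverable via **T**⁻¹), so **differences between conditions reconstructed
through a fixed encoding model are preserved under any invertible change of
basis**. The library provides the basis machinery (raised-cosine, delta
"stick", and transformed variants such as a bimodal basis), the fit/invert
engine, model-free AUC gain quantification, and a simulator of voxels built
from circular-Gaussian-tuned neuron populations with condition-wise
multiplicative gain — so every claim can be checked against generative
ground truth.

It is intended for methods researchers and analysts who want a tested,
transparent reference implementation of the IEM pipeline and its
basis-transform algebra, not a neuroimaging I/O suite (no NIfTI/BIDS).

## Worked example

```python
import numpy as np
from iembench import (SimConfig, simulate_dataset, make_cosine_basis,
                      make_bimodal_transform, apply_transform, run_scheme,
                      recenter_profiles, average_by_condition, auc_gain_ratio)

# 100 voxels x 100 tuned neurons, 8 orientations x 2 conditions,
# condition-2 neural gain 1.8, no noise
dataset = simulate_dataset(SimConfig(noise_sd=0.0, gains=(1.0, 1.8), seed=1))

basis = make_cosine_basis(8)                      # 8 raised-cosine channels
rec = run_scheme(dataset, basis, scheme="fixed_model")
aligned = recenter_profiles(rec.values, rec.trial_orientation, basis)
avg = average_by_condition(aligned, rec.trial_condition)
print(auc_gain_ratio(avg[1], avg[0]).measured_gain)   # 1.7999999999999994

# same analysis in an invertibly transformed (bimodal) basis
T = make_bimodal_transform(8, alpha=0.5)
rec_b = run_scheme(dataset, apply_transform(basis, T), scheme="fixed_model")
print(np.max(np.abs(np.linalg.inv(T.entries) @ rec_b.values - rec.values)))
# 3.1450536619459513e-15
```

The measured AUC gain ratio (area under the condition-2 profile over
condition 1) recovers the generative gain of 1.8 to machine precision, and
multiplying the bimodal-basis reconstructions by the inverse transform
restores the unimodal ones exactly — the transform only changed the "view",
not the content.

The same demonstration is available as a CLI:

```bash
iembench reproduce-fig1 --seed 1 --n-repeats 100 --out out/
```

which prints

```
[PASS] roundtrip_max_abs_error: 3.14505e-15 (tolerance 1e-08)
[PASS] noiseless_gain_cosine: 1.8 (tolerance 1e-06)
[PASS] noiseless_gain_bimodal: 1.8 (tolerance 1e-06)
[PASS] condition2_auc_exceeds_condition1: 21.5458 (tolerance 0.0)
[PASS] noisy_gain_within_3se: 0.115098 (tolerance 1.0)
```

i.e. the round-trip through the bimodal basis is lossless, both bases
recover the modeled gain exactly without noise, condition 2's profile has
the larger area under every basis, and with heavy neural noise (SD 10) the
mean measured gain over 100 seeded repeats stays well within 3 standard
errors of 1.8 (here 0.12 SE away). `iembench simulate`, `basis`,
`reconstruct` and `quantify` expose the individual stages; see
`iembench --help`.

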