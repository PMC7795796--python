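# deringer

Two-step sinogram-domain ring-artifact reduction for high-resolution
(micro/nano) X-ray computed tomography.

Imperfect detector pixels leave constant per-column deviations in the
sinogram; after filtered back projection these become concentric rings
(half rings for 180° scans) centred on the rotation axis, which degrade
exactly the fine structure nano-CT exists to resolve.  `deringer`
classifies these defects by severity and corrects each class with a
dedicated scheme, entirely in the sinogram domain so the reconstruction
cannot smear correction errors:

1. **High-level ring artifacts** (dead pixels saturating the 16-bit
   dynamic range, "hot" pixels with large fixed-pattern offsets) are
   *detected* by an iterative scheme built on relative-total-variation
   (RTV) texture extraction — vertical mean filtering, row-wise
   2σ-binarised horizontal gradients, column-sum thresholding with gap
   closing, and verification against the texture column-mean profile —
   and *corrected* by solving the Laplace equation `∇²u = 0` with
   Dirichlet boundary values over the flagged columns (harmonic
   inpainting).  Four stopping conditions (texture convergence
   `‖T_i − T_{i−1}‖₂/‖T₁‖₂ ≤ R₁`, no candidates, none verified,
   nothing new) terminate the loop.
2. **Low-level ring artifacts** (small sensitivity miscalibrations) are
   corrected by iteratively equalizing the means of column-wise
   neighbouring homogeneous texture areas: per-column additive factors
   `C(y)` from a left-to-right sweep, Savitzky–Golay detrended
   (`C_d = C − t`, frame halving each iteration) so the texture's
   structural trend survives, then `S_C = S_s + T + C_d`.

The package ships the full synthetic validation study — ball,
Shepp–Logan and Siemens-star phantoms, Radon projection (800 angles,
1648-pixel detector), Gaussian noise σ = 0.01, and a seeded detector
defect simulator (25% of columns affected: 5% HRA with one fifth dead,
20% LRA) — plus the evaluation harness (cosine-filtered FBP, Z-scored
PSNR/SSIM, TPR/PPV/Dice detection scores, noise-robustness sweeps).

See `docs/methods.md` for the model, parameter meanings and known
limitations.

## Worked example

`examples/full_pipeline.py` simulates a Shepp-Logan acquisition at the
scaled desk geometry (412-pixel detector, 200 angles), runs both
correction stages and scores the tomograms:

```text
HRA detection: TPR 100.00%  PPV 100.00%  DSC 100.00%
corrected tomogram:   PSNR 37.20 dB  SSIM 0.920
uncorrected tomogram: PSNR 20.58 dB  SSIM 0.512
```

All simulated high-level defect columns were found with no false
alarms, and the corrected tomogram is ~17 dB closer to the
artifact-free reference than the uncorrected one.  The other examples
print the detection/labelling breakdown (`simulate_and_detect.py`) and
the detection-vs-noise table (`noise_robustness.py`).

From Python:

```python
from deringer import RunConfig, correct_sinogram, read_sinogram, write_sinogram

sino = read_sinogram("flat_field_corrected.tif")   # angles x detector
result = correct_sinogram(sino, RunConfig())       # HRA then LRA
write_sinogram("corrected.tif", result.corrected)
print(result.report())                             # columns, stop reason
```

A thin CLI wraps the same functions:

```sh
deringer simulate --phantom shepp_logan --det-width 412 --n-angles 200 --out sim.tif
deringer correct --input sim.tif --output corr.tif --stage both
deringer reconstruct --input corr.tif --output tomo.tif --filter cosine
deringer demo --small
```

Every threshold (λ, σ_s, ε, R₁, R₂, R₃, mean/Wiener filter lengths,
Savitzky–Golay order and frame) lives in `RunConfig` and round-trips
through YAML.

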