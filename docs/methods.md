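# Methods

`deringer` reduces ring artifacts of high-resolution (micro/nano) X-ray
CT data in the sinogram domain, where a defective detector column is a
vertical stripe rather than a ring.  The procedure distinguishes two
artifact classes by cause and appearance and corrects them in sequence:

1. **High-level ring artifacts (HRA)** — dead detector pixels
   (saturated at the top of the dynamic range, or stuck at its bottom)
   and "hot" pixels whose fixed-pattern dark-current offset is large.
   These produce prominent stripes.  They are *detected* by an
   iterative texture analysis and *corrected* by harmonic inpainting.
2. **Low-level ring artifacts (LRA)** — small constant sensitivity
   offsets of miscalibrated pixels, invisible in the sinogram but
   reconstructing into faint rings.  They are corrected by iteratively
   equalizing the mean intensities of column-wise neighbouring
   homogeneous texture areas.

The input is assumed flat-field corrected; both corrections model the
defects as *full-column, angle-independent* additive deviations (fixed
pattern noise).  Time-varying drifts and partial-height stripes are out
of scope.

## Structure–texture decomposition (RTV)

Both stages analyse the *texture* `T = I − S`, where the smooth part
`S` minimises the relative-total-variation objective

```
sum_p (S_p − I_p)²  +  λ · sum_p [ D_x(p)/(L_x(p)+ε) + D_y(p)/(L_y(p)+ε) ]
```

with `D` the Gaussian-windowed total variation and `L` the windowed
inherent variation at scale `σ_s`.  Oscillatory texture (stripes,
noise) has gradients that cancel inside the window (`D ≫ L`) and is
removed; structural edges have `D ≈ L` and survive.  The non-convex
objective is minimised by iteratively re-weighted least squares; each
outer pass solves one sparse 5-point linear system (direct sparse
factorisation).  Empirically the first solve reduces the objective
several-fold and later solves contract towards a fixed point, although
the objective is not strictly monotone between re-weightings — the test
suite asserts the former two properties, not spurious monotonicity.

Intensities are normalised to `[0, 1]` inside the smoother so `λ` acts
on relative contrast; this makes the operator positively homogeneous
and the same defaults usable for raw detector counts.

Parameters (`RTVParams`): `λ = 0.015`, `σ_s = 3 px`, `ε = 1e−3`,
4 solver iterations.  The pointwise-gradient stabiliser ("sharpness")
is fixed at 0.02 as in the published smoothing scheme.  Defaults were
chosen on the synthetic suite so that one-pixel stripes land in the
texture while phantom edges stay in the structure.

## HRA detection loop

Each iteration of `detect_hra`:

1. extracts the texture of the working sinogram;
2. applies a vertical (angle-axis) box mean of length `l = 9` to
   emphasise stripes and blur oblique structure;
3. takes horizontal forward differences, binarises each row at twice
   the row's standard deviation (absolute values, so negative-offset
   stripes are caught), marks the two columns incident to each flagged
   edge and sums the mask per column;
4. flags columns whose count exceeds `R2 = 0.6·M` (M = number of
   angles) as candidates, closing gaps narrower than `R3 = 3` columns;
5. verifies a candidate when its texture column mean deviates from the
   nearest candidate-free column by more than twice the standard
   deviation of the column-mean profile's derivative (ties in the
   reference choice break to the left);
6. inpaints the newly verified columns and iterates on the corrected
   sinogram.

The loop stops when the texture stops changing (normalised L2 change of
successive textures ≤ `R1 = 0.01`; skipped on the first iteration),
when no candidates or no verified columns are found, when an iteration
verifies nothing new, or at a safety cap of 20 iterations.  The final
correction inpaints the *original* sinogram once at all accumulated
columns, so unflagged pixels are returned bit-identical.

`R2 = 0.6·M` rests on a measured separation: true full-column stripes
saturate the binarised count near `M` while the worst structural
shadow-tangent columns stay below `≈ 0.47·M` on the synthetic suite.
The iterative re-detection matters because strong stripes inflate both
row thresholds and the verification band; each inpainting pass lowers
the thresholds and exposes weaker stripes.

**Inpainting.**  Flagged columns are filled with the harmonic function
(`∇²u = 0`) using Dirichlet values from the adjacent unflagged columns
and the first/last sinogram rows; a run touching a lateral detector
border gets a mirror condition there, and flagging *all* columns is an
error.  The discrete maximum principle bounds filled values by their
boundary values, and the solve matches a dense direct solution of the
5-point system to solver precision.

## LRA equalization loop

Each iteration of `remove_lra`:

1. extracts the texture (same decomposition and stopping rule);
2. denoises it column-wise with a length-5 adaptive Wiener filter (the
   classical local mean/variance MMSE filter; replicate padding).  The
   denoised copy is used only for analysis;
3. marks pixels homogeneous where `|T_f| ≤ mean_x |T_f|` per column
   (magnitudes — a signed reading would call strongly negative pixels
   homogeneous);
4. sweeps columns left to right: each column's correction factor is the
   mean difference over shared homogeneous rows against its
   already-corrected left neighbour (the smaller index is always the
   reference, the first column anchors the sweep at zero, and a column
   sharing no homogeneous rows inherits its neighbour's factor);
5. detrends the factor vector with a Savitzky–Golay filter (order 3,
   frame 31, frame halving each iteration, odd-floored, clamped at 5;
   polynomial edge fitting) and keeps only the residual `C_d`;
6. rebuilds the sinogram as `S_s + T + C_d` (the correction applies to
   the *raw* texture) and iterates until the texture convergence rule
   (`R1 = 0.01`) or 10 iterations.

The detrending frame is deliberately *narrow*.  The sweep accumulates
the structural component of neighbouring-mean differences as a smooth
drift across columns; the SG trend must track that drift so that `C_d`
contains only the per-column artifact spikes.  With a very wide frame
(e.g. 201 columns) the drift leaks into `C_d` and is *injected* into
the sinogram as rings — measured at roughly 2% of the dynamic range on
the synthetic suite — while frames of 15–31 remove it.  The residual
floor that remains is set by the mean-estimation error of homogeneous
areas, of order `σ_noise/√M` per column, plus the fraction of a
single-column spike the SG kernel absorbs into the trend (~10–20%).

## Synthetic study

`build_study_case` reproduces the validation conditions: a phantom
(homogeneous ball, modified Shepp–Logan, or an even-spoked Siemens
star) of side `⌊det_width/√2⌋`, Radon-projected over 800 angles in
[0°, 180°) onto a 1648-pixel detector; the sinogram is normalised to
[0, 1], i.i.d. Gaussian noise of σ = 0.01 is added on that scale, the
result is stretched to the 16-bit dynamic range, and ring artifacts are
injected: 25% of columns affected — 5% HRA (one fifth of them dead at
65535, the rest offset by ±10–60% of the sinogram maximum with random
sign) and 20% LRA (offsets within ±1% of the maximum).  Positions are
drawn without replacement, HRA and LRA columns are disjoint, untouched
columns are bit-identical, and a single seeded generator (stream order:
columns, types, offsets) makes layouts reproducible.  At 1648 columns
this yields exactly 82 HRA columns (16 dead).

What the simulator does *not* emulate: photon statistics and
beam-hardening, intensity-dependent or non-linear pixel responses,
time-varying drifts, and partial-height stripes.  Passing the synthetic
suite therefore demonstrates correctness of the procedure under the
fixed-pattern additive model, not performance on arbitrary real scans.

**Scaled study sizes.**  The packaged tests and the acceptance script
run the same study scaled to a 412-pixel detector with 200 angles
(phantom side 291), where detection behaviour matches the full
1648 × 800 study; a full-scale verification run reproduces the scaled
results (detection TPR 100%, PPV 97.6%, DSC 98.8% on Shepp–Logan) in
about 25 minutes on one CPU.  One quantity is resolution-dependent:
the LRA residual floor (`σ_noise/√M`) leaves the scaled study's SSIM a
few thousandths below the full-scale value (0.90 vs 0.913 on
Shepp–Logan), which the end-to-end test makes visible.

## Evaluation

Reconstruction is filtered back projection with a cosine frequency
filter (half-scan, uniform angles), min–max normalised to [0, 1].
Quality metrics are computed between Z-scored tomograms — corrected vs
the reconstruction of the artifact-free (noisy) sinogram — so global
intensity shifts cannot masquerade as structural error:

* **PSNR** with peak = value range of the Z-scored reference (a
  convention that must be stated, since it shifts absolute dB);
* **SSIM**, mean local similarity with an 11-pixel Gaussian window
  (σ = 1.5), data range taken from the reference.

Detection is scored on HRA columns only with exact set arithmetic:
TPR = TP/(TP+FN), PPV = TP/(TP+FP), DSC = 2TP/(2TP+FP+FN), reported in
percent; undefined rates are NaN sentinels.

## Known limitations

* A perfectly centred single-material disc produces stationary
  shadow-edge columns that are geometrically indistinguishable from
  stripes; a handful of edge columns are falsely flagged (and
  harmlessly inpainted) on the ball phantom, depressing its precision
  at small detector widths where the fixed false-positive count weighs
  more.  The Siemens star shows the analogous structural-false-positive
  effect.
* Detection precision on textureless phantoms is therefore
  resolution-dependent; true-positive rates are not.
* The LRA residual floor scales with `σ_noise/√M`; at few projection
  angles the equalization gains less.
* Columns at the extreme lateral detector borders rely on mirror
  boundary conditions for inpainting and on one-sided references for
  equalization.
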