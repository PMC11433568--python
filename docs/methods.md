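# Methods

## Model

`neutrotex` computes a texture descriptor for grayscale images in three
stages, then ranks and scores retrievals.

**Neutrosophic transform.** The truth image is the min–max normalization of
the `w×w` box-mean image `Z̄`; indeterminacy is the min–max normalization of
`δ = |Z − Z̄|`; falsity is `1 − T`. The box mean uses replicate padding so
`Z̄` is defined on the full grid; replicate padding avoids injecting
artificial zeros at the border. Intensities are promoted to float64 before
any arithmetic, regardless of source bit depth. Because both `T` and `I`
are min–max normalized, the transform — and hence the whole descriptor on
those channels — is exactly invariant to affine intensity rescaling
`Z → aZ + b` (`a > 0`) of the input.

**Pattern operators.** At scale `r`, each pixel's circular neighborhood
consists of `8r` samples at offsets `(−r sin θ_n, r cos θ_n)`,
`θ_n = 2πn/8r`, in (row, col) convention: sample 0 due east, index
increasing counter-clockwise. Off-grid samples are bilinearly interpolated;
coordinates within `1e-6` of a grid point snap to the exact pixel value.
Sampling is replicate-padded so derived per-pixel statistics are defined on
the full grid; pattern labels themselves are only emitted on the valid
region `[r, M−r) × [r, N−r)`, with the sentinel `−1` elsewhere, and
sentinel pixels never enter a histogram.

Arc group `k` covers sample indices `rk .. rk+r−1`. MsTrP reduces each
group by its median (even group sizes use the mean of the two middle order
statistics — the standard median); NrTxP by the mean of `|sample − p_c|`.
The NrTxP threshold `ν_r` and the RiTxP reference `μ_r` are both means over
the `8r` pixels of the square ring at Chebyshev distance `r`: the ring
aggregates are normalized by `8r` so that they are true local means and
the thresholds are not scale-dependent. The ring members are taken as raw
image-grid values (for `μ_r`) and full-grid mean-local-difference values
(for `ν_r`), which keeps the valid regions of all three label maps
identical at a given scale.

The riu2 relabeling assigns a thresholded 8-bit pattern its popcount (0–8)
when the circular transition count is at most 2, and the shared label 9
otherwise — 10 labels, 9 of which arise from uniform patterns. Since a 90°
image rotation cyclically shifts the `8r` circular samples by `2r`
positions (hence the 8 quantized arcs by 2), and both the popcount and the
transition count are shift-invariant, the label maps of a square image and
its quarter-turn rotation coincide on the (self-mapping) valid region; the
test suite asserts descriptor agreement to well below 2% relative L1.

**Descriptor assembly.** Per channel and scale, the joint histograms
(MsTrP × RiTxP) and (NrTxP × RiTxP) are flattened with the binary RiTxP
label fastest-varying (bin = `primary·2 + ri`) and concatenated: 40 bins.
The full vector concatenates scale-major, then T, I, F within a scale:
`120·S` values. The flattening order is not externally constrained; any
fixed order is internally consistent, and the chosen one is recorded in
the feature-store header names (`s{r}_{T|I|F}_{ms|nr}_{p}_{q}`). The
three-way joint histogram (MsTrP × NrTxP × RiTxP) would cost 200 bins per
scale per channel (1000 over five scales) and is deliberately not an
output.

**Retrieval and metrics.** The extended Canberra distance adds each
vector's mean to every denominator, bounding each summand in `[0, 1)` and
making the distance invariant to a common positive rescaling of both
vectors. Ranking sorts ascending by distance with ties broken by
lexicographic image id, so runs are reproducible across platforms. A query
that is itself a database member self-matches at distance zero and ranks
first; this is the convention used by default, with `exclude_self`
available. Consistently, the per-class relevant count `g` includes the
query when it is a database member. The mean-average-precision metric is
the standard one: per query, `(1/g) Σ_{relevant ranks k ≤ η}
(relevant-so-far at k)/k`, averaged over queries and scaled to percent.
The coefficient of variation uses the population (÷N) standard deviation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w` | 3 | neutrosophic local-mean window (pixels, odd). 3 is the smallest odd window and preserves fine texture; exposed in config. |
| `scales` | auto | circular radii `r`. `1..9` when the image's min side ≥ 64, else `1..5` (small images cannot support large rings without losing most of the valid region). |
| `normalize` | true | emit probability histograms (each 20-bin block sums to 1). Raw counts available; normalization makes images of different sizes comparable and suits the Canberra denominators. |
| `eta` | 100 | retrieval depth. |
| `sigma_min, sigma_max` | 5, 50 | AWGN band on the 0–255 scale for the noisy-query protocol; per-image σ drawn uniformly from the band. |

## Numerical choices

- The threshold function `s` (with `s(0) = 1`) is implemented as
  `x ≥ −10⁻⁹`. Box filters and bilinear interpolation introduce rounding
  at the last-ulp level, and a strict `≥ 0` would let exact ties (constant
  regions, symmetric neighborhoods) flip to 0 on noise of order 10⁻¹⁶;
  the 10⁻⁹ slack is far below any meaningful intensity difference on
  either the [0,1] neutrosophic scale or the 0–255 raw scale.
- Min–max denominators smaller than `10⁻¹² · max(1, |max|)` are treated as
  degenerate: the affected channel becomes the constant 0 (so `F = 1`) and
  a warning is logged. This keeps downstream patterns defined on constant
  images and prevents last-ulp filter noise from being amplified to full
  range.
- Grid-snap tolerance for circular sampling is `10⁻⁶` (relative to pixel
  units), so axis-aligned samples use exact pixel values.
- The feature store writes floats with shortest round-trip repr and reads
  them back with round-trip parsing, making write → read → write
  byte-identical.

## Synthetic data

The generator emulates a labeled multi-class texture database: classes
cycle through oriented sinusoidal gratings (class-specific frequency and
orientation), checkerboards (class-specific period) and smoothed-noise blob
fields (class-specific correlation length), with per-image random phase,
offset and orientation jitter. Defaults used throughout the tests: 4
classes × 25 images of 64×64 pixels, intensities on the 0–255 scale,
retrieval depth η = 25, noise band σ ∈ [5, 50]. These sizes keep a full
clean-plus-noisy benchmark to well under two minutes on one CPU while
leaving the classes non-trivially separable.

What the generator does *not* emulate: anatomical structure, CT/MRI
acquisition physics, correlated or signal-dependent noise, partial-volume
effects, or the subtle inter-class overlap of real clinical databases.
Passing tests therefore demonstrate that the implementation is correct and
that the descriptor's noise- and rotation-robustness mechanisms work as
designed — not that any particular retrieval rate carries over to clinical
images. On these synthetic classes the descriptor saturates near 100%
precision, so the informative readouts are the *relative* ones: the drop
under noise and the cross-condition coefficient of variation against a
single-scale LBP baseline.

## Design notes

- Noise is applied on the 0–255 scale before any neutrosophic
  normalization and then clipped to [0, 255], matching how display-range
  images degrade.
- Estimator surface: feature extraction is a scikit-learn transformer
  (`MsNrRiTxPExtractor`) and retrieval a fitted index
  (`CanberraRetrievalIndex`), so both compose with sklearn pipelines and
  model selection; the module-level functions are thin wrappers over the
  same code paths.
- The debug path for label maps (scaling labels to 8-bit and writing PNG)
  is available through the CLI image writers; label maps themselves are
  plain integer arrays and can be inspected directly.

## Known limitations

- Quantization width is fixed at 8 (arc groups of `r` samples); other
  widths are out of scope.
- Rotation invariance is exact only for quarter-turn rotations of square
  images; arbitrary-angle rotations change the border pixels entering the
  valid region and are only approximately invariant.
- No approximate nearest-neighbor index: queries scan the full database,
  which is fine up to tens of thousands of images but not beyond.
- The CLI's resumable extraction matches rows by image id only; it does
  not detect that an image's content changed on disk.
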