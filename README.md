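# neutrotex

Multi-scale, noise-resistant, rotation-invariant texture descriptors for
content-based retrieval of grayscale (medical) images — CT/MRI slices,
X-rays, or any single-channel texture database.

Content-based medical image retrieval ranks a database of images by visual
similarity to a query image, so a clinician can pull up previously
diagnosed cases that look like the one at hand. Plain local binary
patterns (LBP) do this by thresholding a pixel's circular neighborhood
against the pixel itself, but they degrade badly under image noise and mix
poorly across scales. `neutrotex` implements a descriptor that addresses
both weaknesses.

## The descriptor

An input image `Z` is first mapped to three **neutrosophic** membership
images: truth `T` (min–max normalized `w×w` local mean `Z̄`),
indeterminacy `I` (normalized `|Z − Z̄|`), and falsity `F = 1 − T`. On each
of `T`, `I`, `F`, three per-pixel pattern operators are computed at each
scale `r`, from `8r` bilinearly interpolated samples on the radius-`r`
circle around every pixel `p_c`:

- **MsTrP** — the `8r` samples are median-quantized arc-wise down to 8
  values `mqp_k`; the bits `s(mqp_k − p_c)` (with `s(x) = 1` iff `x ≥ 0`)
  form an 8-bit code mapped through the rotation-invariant uniform (riu2)
  relabeling: patterns with at most two circular bit transitions get their
  popcount (0–8), all others label 9. The arc median rejects impulsive
  outliers, so the code is stable under noise.
- **NrTxP** — absolute local differences `|sample − p_c|` are mean-quantized
  arc-wise to 8 magnitudes and thresholded against `ν_r`, the mean (over
  the square ring at Chebyshev distance `r`) of the per-pixel mean absolute
  local difference; riu2-mapped to 10 labels.
- **RiTxP** — one bit: `s(p_c − μ_r)`, where `μ_r` is the mean intensity of
  the square ring at Chebyshev distance `r`.

Per channel and scale, the joint histograms `MsTrP×RiTxP` (10×2) and
`NrTxP×RiTxP` (10×2) are concatenated to a 40-bin block; blocks are
concatenated scale-major, then `T`, `I`, `F` within each scale, giving a
`120·S`-dimensional descriptor for `S` scales (default `r = 1..9` for
images with min side ≥ 64, else `r = 1..5`).

Retrieval ranks database descriptors by the **extended Canberra distance**

    D(a, b) = Σ_τ |a_τ − b_τ| / (a_τ + μ_a + b_τ + μ_b),

where `μ_a`, `μ_b` are the vector means — a scale-free histogram
dissimilarity whose summands lie in `[0, 1)`. Evaluation uses every
database image as a query and reports average precision at depth `η`
(avgP), average recall (avgR), their harmonic mean (Fscore), and mean
average precision (MavgP), all in percent, plus the coefficient of
variation of each rate between clean and noise-degraded query conditions.

## Worked example

```python
import numpy as np
from neutrotex import (
    MsNrRiTxPExtractor, CanberraRetrievalIndex,
    generate_texture_dataset, NoiseSpec,
)
from neutrotex.benchmark import run_benchmark

ds = generate_texture_dataset(n_classes=4, n_per_class=25, size=64, seed=1)
res = run_benchmark(ds, noise_spec=NoiseSpec(seed=2), eta=25)
print(res.clean)
print(res.noisy)
print(res.cv)
```

prints

```
MetricsReport(avgP=100.0, avgR=100.0, Fscore=100.0, MavgP=100.0, eta=25, omega=100)
MetricsReport(avgP=99.88, avgR=99.88, Fscore=99.87999999999998, MavgP=99.8784, eta=25, omega=100)
{'avgP': 0.0006003602161297006, 'avgR': 0.0006003602161297006,
 'Fscore': 0.0006003602161297717, 'MavgP': 0.0006083698888924507}
```

With all 100 clean database images used as queries at depth η = 25, every
top-25 list contains only same-class images (avgP = avgR = 100%). When the
queries are corrupted with additive white Gaussian noise of per-image
σ drawn from [5, 50] on the 0–255 scale, precision drops only to 99.88%;
the coefficient of variation of each rate across the two conditions is
about 6 × 10⁻⁴. A plain single-scale uniform-LBP histogram baseline on the
same data collapses from 99.5% to 24.9% (CV ≈ 0.6) — the comparison is in
`tests/test_acceptance.py`.

The same pipeline is scriptable from the shell:

```sh
neutrotex simulate --classes 4 --per-class 25 --size 64 --seed 7 --out db/
neutrotex extract  --manifest db/labels.csv --out features.csv
neutrotex evaluate --db features.csv --manifest db/labels.csv --eta 25
neutrotex benchmark --dir db/ --sigma 5 50 --eta 25 --seed 11
```

`simulate` writes PNGs plus a `labels.csv` manifest; `extract` writes a CSV
feature store with one row per image and a sidecar JSON recording `w`, the
scales and the normalization flag; `query` prints a ranked TSV for a single
query image.

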