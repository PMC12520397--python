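# pigmentsep

Separation of the two dominant skin chromophores — melanin and hemoglobin —
from a single RGB skin image, for medical-aesthetics and dermatology image
analysis. The package implements the full pipeline as a library plus a small
CLI, together with a synthetic-skin forward simulator that provides ground
truth for every stage.

## The method

In the optical-density domain, each color channel of a cross-polarized skin
image follows a log-linear mixing model

```
log C_i(x,y) = −v_m(i)·c_m(x,y) − v_h(i)·c_h(x,y) + log p(x,y) + log Ē_i ,
```

where `c_m`, `c_h` are the melanin and hemoglobin concentration fields,
`v_m(i)`, `v_h(i)` are per-channel pigment coefficients (extinction
coefficient × mean photon path length), `p(x,y)` is the multiplicative shading
from surface shape, and `Ē_i` is the baseline illumination. The channel
differences

```
H = (ln B − ln R, ln G − ln R) = V·c + Ē
```

cancel the shading term, leaving a 2-D linear mixture of the two (independent)
concentration fields — a blind source separation problem solved by FastICA.
The pipeline stages are:

1. **Channel differences** — per-pixel `(ln B − ln R, ln G − ln R)`.
2. **Sub-block selection** — score `q×q` tiles by
   `d_{B,G−R} = |mean(ln B − ln R)| + |mean(ln G − ln R)|` and keep the top
   fraction (default `q=5`, top 25%), discarding shadow-dominated, near-gray
   tiles whose log-space noise would contaminate the separation.
3. **Local clustering** — after centering/whitening, condense the samples with
   a bounded k-means (centers seeded as means of contiguous sample windows,
   assignment restricted to the ±r neighboring centers, <1% label-change
   stopping; defaults `k=1200`, `r=2`), then draw `m=3` feature points per
   cluster. This shrinks and regularizes the FastICA input.
4. **FastICA** — deflationary negentropy fixed-point iteration with
   `g = tanh`, Gram–Schmidt orthogonalization, tolerance `1e-6`, budget 200
   iterations; convergence is tracked per component and never raised as an
   error (the benchmark counts failures).
5. **Synthesis** — the estimated coefficient matrix `V` (unit-norm,
   nonnegative columns) is column-ordered by the empirical ratio intervals
   `v21/v11 ∈ (1, 6.33]` (melanin) and `v22/v12 ∈ [0.48, 1)` (hemoglobin),
   inverted per pixel over the full region (`c = (V*)⁻¹H`), and re-rendered
   into a melanin-only and a hemoglobin-only image that share the input's R
   channel.

Because no public dataset with pixel-level pigment ground truth exists, the
package includes a forward simulator (`pigmentsep.scene`) implementing the
mixing model above with blob-textured concentration fields, a smooth shading
field, and an optional camera-capture model (quantization + sensor noise).

## Worked example

Render a synthetic 128×128 skin patch with moderate shading and separate it
with the full method:

```
$ pigmentsep simulate --height 128 --width 128 --n-spots 40 --spot-scale 6 \
      --amp-scale 3 --shading-amplitude 0.3 --seed 1 --out demo_scene
wrote synthetic scene to demo_scene: c_h, c_m, image, image16, meta, shading

$ pigmentsep separate demo_scene/skin.png --seed 1 --out demo_sep
converged in [6, 1] iterations; outputs in demo_sep
```

`demo_sep/` now contains `melanin.png` / `hemoglobin.png` (plus 16-bit TIFF
versions), the concentration maps `c_m.tif` / `c_h.tif`, and
`separation.json`, which for this run records

```
"converged": true,
"iterations_per_component": [6, 1],
"ordering_swapped": false,
"ratios": [1.2555, 0.6502]
```

The two unmixing vectors converged in 6 and 1 fixed-point iterations; the
estimated melanin/hemoglobin column ratios (1.26, 0.65) fall inside the
ordering intervals, so no column swap was needed. Compared against the
scene's ground-truth coefficient matrix, the estimated columns have cosine
similarities 0.94 (melanin) and 0.999 (hemoglobin).

A small convergence benchmark over the three method variants (plain DL-ICA,
sub-block selection only, and the full method):

```
$ pigmentsep benchmark --scenes 2 --height 160 --width 160 \
      --sizes 3000,6000 --repeats 10 --seed 1 --out bench.csv
wrote 12 rows to bench.csv
  mean rate plain_dlica: 0.9000
  mean rate subblock_only: 0.7500
  mean rate subblock_plus_cluster: 1.0000
```

Each rate is the fraction of repeated seeded runs in which both unmixing
vectors converged within the iteration budget. `pigmentsep sweep` varies one
of `q`, `k` or the selection fraction while holding the others at their
defaults.

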