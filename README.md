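# octlayers

Automated segmentation of the eleven retinal layer boundaries in
macular OCT B-scans, with an improved-Canny edge pipeline, a
ground-truthed synthetic phantom generator, and boundary-positioning
evaluation.

Quantifying retinal structure — nerve fiber layer thickness for
glaucoma, the photoreceptor inner/outer segment junction for retinitis
pigmentosa, the RPE for age-related macular degeneration — starts with
reliable layer segmentation. Plain Canny edge detection struggles on
OCT: vessel shadows produce spurious vertical edges, boundaries break
where image quality dips, and speckle causes misdetection. This
package implements a layered-anatomy variant of the Canny recipe:

1. **Enhancement** — 3×3 Gaussian denoising; polarity-specific axial
   gradients with the 4×1 templates `[-1,-1,1,1]ᵀ` (dark→bright) and
   `[1,1,-1,-1]ᵀ` (bright→dark), so only horizontal interfaces
   respond; point-to-point multiplication with a large-scale smoothed
   image to damp interference outside the retina; per-A-scan
   non-maximum suppression.
2. **Boundary search** — peak points in two 30 px lateral bands seed
   paths that grow across the whole B-scan, at each step choosing the
   3- or 5-neighbourhood pixel whose enhanced value is closest to the
   seed's, keeping the previous direction on ties and extending
   straight where the signal is lost (vessel shadows).
3. **Boundary selection** — the N paths of a channel are superposed
   into a probability map, `P(i,j) = 100 · #paths(i,j) / N`, and the
   boundaries are extracted with Canny's dual-threshold (hysteresis)
   rule plus anatomical identification rules that name the eleven
   boundaries ILM, o-NFL, o-GCL, o-IPL, o-INL, o-OPL, o-ONL, o-IS,
   o-OSJ, o-OS, o-RPE in depth order.

Accuracy against two curves is reported as the mean unsigned
positioning error over the N A-scans of a B-scan,
`MUE(L₁, L₂) = (1/N) Σⱼ |L₁(j) − L₂(j)|`, in micrometres.

No patient data ships with the package: the `phantom` module renders
seeded synthetic maculae (alternating bright/dark bands, foveal dip,
vessel shadows, posterior vitreous face line, multiplicative speckle,
optional AMD-like dome) together with their exact boundary truth, so
every stage is testable end to end. See `docs/methods.md` for the full
model, parameter defaults and the measured operating envelope.

## Worked example

Generate a noisy healthy phantom (speckle 0.2, one vessel shadow, a
posterior vitreous face line), segment it, and score the result
against the bundled truth:

```bash
python - <<'PY'
from octlayers import healthy_config
from octlayers.io import save_configs
cfg = healthy_config(speckle_level=0.2, vessel_shadows=((170, 8, 0.35),), pvf_offset=25.0)
save_configs("phantom.yaml", phantom=cfg)
PY
octlayers phantom --config phantom.yaml --seed 7 --out phantom/
octlayers segment --input phantom/bscan.tiff --out seg/ --overlay
octlayers evaluate --pred seg/segmentation.csv --truth phantom/truth.csv --axial-um 3.9
```

which prints:

```
boundary  mue_um  sd_um  n_columns  n_excluded
     ILM   2.887  0.849        512           0
   o-NFL   1.635  0.998        512           0
   o-GCL   2.418  1.140        512           0
   o-IPL   1.787  0.992        512           0
   o-INL   2.641  1.056        512           0
   o-OPL   1.587  0.919        512           0
   o-ONL   2.658  0.958        512           0
    o-IS   2.758  0.976        512           0
   o-OSJ   1.870  1.056        512           0
    o-OS   3.014  1.158        512           0
   o-RPE   2.199  0.963        512           0
    mean   2.314    NaN          0           0
```

Each row is one boundary's mean unsigned positioning error against the
phantom truth, in micrometres over the 512 A-scans: every boundary is
recovered to within ~3 μm, i.e. under one pixel at the 3.9 μm axial
pitch (about half a pixel of that is the unavoidable rasterisation
offset of rendering fractional boundary positions onto a pixel grid).
`seg/overlay.png` shows the eleven curves superimposed on the B-scan.

The same library API is three calls:

```python
from octlayers import healthy_config, generate_bscan, segment_bscan, evaluate_against_truth

bscan, truth = generate_bscan(healthy_config(speckle_level=0.2, rng_seed=7))
result = segment_bscan(bscan)
print(evaluate_against_truth(result.segmentation, truth).to_frame())
```

Volumes (multi-page TIFF or a directory of slices) are segmented with
`octlayers segment-volume`, optionally only every k-th slice
(`--stride 4`) with linear interpolation of the boundary surfaces in
between; thickness maps of the superficial and deep vascular
complexes and the inner and outer retina are written as CSV and PNG.
Use `--neighborhood 5` for diseased eyes with steep boundary slopes.

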