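# irtkit

Semi-automated extraction of skin temperatures from repeated thermal
images of the upper thorax/neck region. A follow-up image is first
shifted onto the reference using the neck as an anatomical landmark
(row-gradient foreground segmentation, minimum-foreground-row neck
detection), then non-rigidly registered with a cubic B-spline free-form
deformation that maximizes Mattes mutual information. A single region of
interest drawn on the reference image transfers unchanged to every
registered follow-up, and agreement between segmentations is quantified
with Dice overlap and repeated-measures Bland–Altman limits of
agreement.

Because no acquired images ship with the package, a phantom module
generates body-shaped synthetic temperature maps (warm silhouette with a
neck constriction on a room-temperature background) with ground-truth
neck coordinates, translations, and smooth deformation fields, so every
pipeline stage is testable end to end.

## Library layout

| module | role |
| --- | --- |
| `irtkit.thermal_io` | temperature-map I/O (text matrix / float TIFF), camera geometry, pixel-to-cm conversions |
| `irtkit.phantom` | synthetic phantoms with ground truth; translation and smooth-warp operators; session generator |
| `irtkit.prealign` | row-gradient foreground segmentation, neck detection, integer-pixel pre-alignment |
| `irtkit.registration` | B-spline deformation model, Mattes MI, multi-resolution stochastic-gradient registration, convergence check |
| `irtkit.roi_tools` | ROI polygons, rasterization, vertex-file I/O, reference-ROI transfer |
| `irtkit.thermometry` | mean/max ROI temperature, area in cm², gradient-homogeneity summary |
| `irtkit.agreement` | Dice with qualitative bins, repeated-measures Bland–Altman, method comparison |
| `irtkit.pipeline` | per-subject session runner and batch mode |

## CLI

One entry point, `irt`, with subcommands:

```sh
# synthetic 4-image session (reference + 3 follow-ups) with ground truth
irt phantom generate --seed 42 --out session/

# neck-landmark pre-alignment of a follow-up onto the reference
irt prealign --reference session/reference.txt \
             --follow session/followup_1.txt --out pre/

# non-rigid registration (defaults: 10 mm grid, 4 resolutions,
# 450 iterations, max step 0.5)
irt register --fixed session/reference.txt --moving pre/shifted.txt \
             --seed 1 --out reg/

# full batch pipeline from a JSON manifest
irt run --manifest study.json --out results/ --seed 1
```

The manifest is a JSON file with optional `geometry` and `settings`
objects and a `sessions` list (`subject`, `reference`, `followups`,
`rois` with paths relative to the manifest).

## Notes

- Image values are plain degrees Celsius; radiometric decoding of camera
  vendor formats is out of scope — convert to temperature matrices first.
- Pre-alignment shifts are integer-pixel by design so raw temperatures
  are never interpolated before registration.
- Registration test/acceptance runs use reduced frames (160×120) and
  2 resolutions × 100 iterations to stay desk-scale; defaults match the
  full protocol.
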