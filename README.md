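# pigdepth

Fully automatic pig weight and body-size estimation from overhead depth
images, as a testable software pipeline:

- **`synthetic_scene`** — a parametric depth-scene simulator: pig bodies as
  lofted solids of semi-elliptical cross-sections on a weighing platform,
  rendered as 16-bit depth maps (pixel value = camera distance in mm,
  camera 1650 mm above the platform) with analytically known labels
  `[BW kg, SW cm, SH cm, HW cm, HH cm, BL cm]` (body weight, shoulder
  width/height, hip width/height, body length).
- **`preprocessing`** — depth inversion (`height = 1650 − depth`), linear
  0–255 gray scaling, bilinear square resize (224 / 299 / free size).
- **`model_factory`** — multiple-output regression CNNs: a named backbone
  (DenseNet201, ResNet152 V2, Xception, MobileNet V2, or a small `tinycnn`)
  with the classifier removed, global average pooling retained, and six
  parallel single-node linear dense heads.
- **`training`** — shuffled 7:3 split, summed per-target MSE loss,
  mini-batch Adam (lr 0.001, batch 16), best-on-validation checkpoint
  retention.
- **`evaluation`** — per-target RMSE / MAE / MRE / R², aggregate MSE, mean
  estimation time.
- **`acquisition`** — the capture trigger: fire when 4 consecutive scale
  readings are inside the population weight range with spread < 0.2 kg.
- **`cli_io` / `cli`** — 16-bit depth PNGs, CSV manifests, YAML configs,
  checkpoints, and the `pigdepth` command.

## A note on the engine

No deep-learning framework is assumed: the package ships a small NumPy
graph engine. The four reference backbones are built layer-by-layer from
their published definitions and support forward inference and exact
parameter counting (totals and trainables match the reference
implementations exactly). End-to-end gradient training is provided for the
`tinycnn` backbone (hand-written backprop), which is what the scaled-down
experiments use.

## CLI

```bash
pigdepth simulate  --n 600 --seed 7 --image-size 64 --out data/sim
pigdepth preprocess --manifest data/sim/manifest.csv --target-size 64 --out data/gray
pigdepth train     --manifest data/sim/manifest.csv --backbone tinycnn \
                   --input-size 64 --epochs 30 --seed 7 --out runs/tiny
pigdepth evaluate  --checkpoint runs/tiny/best.npz \
                   --manifest data/sim/manifest.csv --out runs/tiny/eval
pigdepth trigger-demo --readings readings.csv --out events.csv
```

Every command logs seed, config hash, and versions to a `run.json` in its
output directory; `simulate` output is byte-reproducible from
(config, seed).

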