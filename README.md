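# vesselseg

Segmenting the retinal vasculature in fundus photographs is a routine first
step in screening for diabetic retinopathy, glaucoma and hypertensive
retinopathy, yet thin low-contrast capillaries and vessel boundaries are
easily lost by a single encoder–decoder network. `vesselseg` implements a
**three-path fusion segmentation network** for researchers who want a fully
tested, CPU-runnable reference implementation of this architecture family,
together with the complete training/evaluation pipeline around it — dataset
readers for DRIVE/CHASE-style trees, patch-based training, pixel metrics,
and a seeded synthetic fundus-scene generator so everything runs without
downloading clinical data.

## The model

Three parallel encoder–decoder paths process the grayscale image
X ∈ ℝ^{1×H×W}, each with four feature levels (level *i* at resolution
H/2^{i−1} × W/2^{i−1}) built from the shared CBR₂ block (two rounds of 3×3
convolution → batch norm → ReLU):

* **spatial path** — a U-Net: max-pool downsampling, transposed-convolution
  upsampling, skip concatenation;
* **boundary path** — a SegNet: max pooling that records each 2×2 window's
  argmax index, and a decoder that unpools values back to exactly those
  positions, preserving edge localisation;
* **frequency path** — wavelet down/up-sampling: the orthonormal 2-D Haar
  analysis g_i ↦ Concat[DWT(g_i)] quarters resolution losslessly into the
  LL/HL/LH/HH subbands (channels ×4), and the exact synthesis transform
  restores it in the decoder.

The paths couple only at the heads. Per decoder level *i*, a
**deep-supervision head** forms u_i = softmax[Conv1×1(Concat(D_i))] with
D_i = [d_i^1, d_i^2, d_i^3], giving the model output

    f(X) = [u_1, u_2, u_3, u_4, X^R],   u_i ∈ ℝ^{2×H/2^{i−1}×W/2^{i−1}},

where X^R ∈ ℝ^{1×H×W} is an **auto-encoder head** that reconstructs the
input from the joint bottleneck E_4 = [e_4^1, e_4^2, e_4^3] through three
2×2 stride-2 deconvolutions. Training minimises

    Loss = β·Loss_AE + Σ_{i=1..4} α_i · Lⁱ(u_i, v_i),

the mean-squared reconstruction error plus equilibrium-weighted per-level
cross-entropies against subsampled labels v_i, with
[β, α₁, α₂, α₃, α₄] = [0.1, 1, 0.2, 0.2, 0.2]. Prediction uses the vessel
channel of u_1. Ablation presets (`unet`, `segnet+haarnet`,
`tp-unet+ae+dsl`, …) switch paths and heads on and off.

The network is implemented on a small NumPy reverse-mode autodiff engine
(`vesselseg.nn`: im2col convolutions, batch norm, pooling with indices,
Haar operators, Adam) whose backward passes are finite-difference checked
in the test suite; no deep-learning framework is required.

## Worked example

Train on four synthetic 128×128 scenes at reduced scale (tiny widths, 64
patches, 25 epochs — a couple of minutes on one CPU; the full printed
protocol is 4000 patches of 64×64, batch 64, Adam lr 0.0005, 50 epochs):

```bash
vesselseg synth scenes --n 4 --seed 7
vesselseg train scenes --preset tp-unet+ae+dsl --widths 8,16,32,64 \
    --epochs 25 --n-patches 64 --batch-size 8 --no-augment --seed 7 \
    --checkpoint model.npz --log train.jsonl
vesselseg predict model.npz scenes/images/synth00007.png --out-dir pred
vesselseg evaluate model.npz scenes --split all --report report.csv
```

which prints

```
wrote 4 scenes of 128x128 to scenes
final epoch mean loss 0.2051; checkpoint at model.npz
wrote 2 rasters to pred
n_images=4 dice=0.8250 se=0.8162 sp=0.9897 acc=0.9793; report at report.csv
```

The composite loss fell from ≈1.0 at initialisation to 0.21; on the four
training scenes the model recovers 82% of vessel pixels by Dice overlap at
threshold 0.5, with sensitivity 0.816 (fraction of true vessel pixels
found) and specificity 0.990 (background correctly left unmarked) — typical
for a short run at these widths; `report.csv` adds the per-image rows and
confusion counts. `pred/` holds the probability map and the thresholded
mask as PNGs.

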