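# sdsseg

Hierarchical brain-tumor-region segmentation with a hybrid 2D/3D
multi-scale attention network trained by **selective deep supervision
(SDS)** — packaged with a synthetic phantom generator, the full
preprocessing chain, and exact volumetric evaluation metrics, so the
whole method runs and is tested on one CPU without any external data.

## Who this is for

Researchers and students who want a readable, fully tested, desk-scale
implementation of the SDS training idea for nested segmentation
targets: BraTS-style scans label voxels 0 (healthy), 1
(necrotic/non-enhancing core), 2 (edema), 4 (enhancing tumor), and are
evaluated on the nested regions

    WT = {1, 2, 4}  ⊇  TC = {1, 4}  ⊇  ET = {4}.

## The method

A 3D encoder (bottleneck residual blocks) reads a five-slice context
patch while a 2D encoder (conv blocks) reads the center slice; bridge
blocks fold the slice axis into channels so the two feature streams
concatenate at every level.  The decoder upsamples through DeConv
blocks whose skips are filtered by additive attention gates,

    α = σ(ψᵀ ReLU(W_x x + W_g g + b_g) + b_ψ),   x̂ = α · x,

one scalar α per pixel, with the gating signal g from one level
coarser.  Four heads emit full-resolution softmax maps.  Training
minimizes

    L = L_main + Σ_d η_d γ^epoch L_d + λ(‖W‖² + Σ_d‖ŵ_d‖²),

where the auxiliary heads' targets follow the region nesting: the
earliest decoder head segments only the whole tumor, the next adds the
enhancing region, and the last two outputs carry all three regions
(each head's overlapping regions become mutually exclusive classes by
set difference, so softmax + NLL is well posed).  Setting η ≡ 0
recovers conventional training exactly; the all-region scheme with
γ = 1 recovers standard deep supervision exactly.

Evaluation reports Dice 2|P∩R|/(|P|+|R|), sensitivity |P∩R|/|R|, the
prediction-conditioned specificity |P∩R|/|P|, and Hausdorff / HD95
distances between mask surfaces in physical units.

The numerical core is a compact reverse-mode autodiff engine on numpy
(finite-difference-verified); no deep-learning framework is required.

## Worked example

```python
import numpy as np
from sdsseg.phantom import PhantomSpec, generate_phantom
from sdsseg.metrics import evaluate_volume

vol = generate_phantom(PhantomSpec(shape=(16, 64, 64), seed=3))
pred = np.roll(vol.labels, 1, axis=2)   # mimic a prediction: 1-voxel shift
report = evaluate_volume(pred, vol.labels, spacing=vol.spacing)
print(report.to_frame().round(3))
```

prints

```
     dice  sensitivity  specificity   hd  hd95
WT  0.942        0.942        0.942  1.0   1.0
TC  0.909        0.909        0.909  1.0   1.0
ET  0.851        0.851        0.851  1.0   1.0
```

A one-voxel shift leaves every region surface within 1 mm of the
reference (HD = HD95 = 1.0) and costs more Dice on the smaller regions
(ET 0.851) than the large one (WT 0.942) — the size sensitivity that
makes the nested regions progressively harder.

Training end to end on phantoms, from the shell:

```bash
sdsseg generate --n 30 --seed 0 --out work/phantoms
sdsseg train --data work/phantoms --scheme sds --profile desk --seed 0 --out work/run
sdsseg predict --checkpoint work/run/checkpoint.npz --data work/phantoms --out work/pred
sdsseg evaluate --pred work/pred/phantom000_pred_seg.nii.gz \
                --ref work/phantoms/phantom000_seg.nii.gz --out work/report.csv
sdsseg compare-schemes --data work/phantoms --seeds 0,1,2 --out work/curves
```

In the desk profile (base width 16, 64×64 inputs, ≤300 SGD steps) the
SDS-trained model reaches held-out whole-tumor Dice ≈ 0.99 on zero-noise
phantoms in a few minutes on one CPU.

## Layout

- `src/sdsseg/phantom.py` — synthetic BraTS-like labeled volumes
- `src/sdsseg/preprocess.py` — trim / crop / equalize / normalize / sampling
- `src/sdsseg/autograd.py`, `layers.py` — numpy autodiff + NN layers
- `src/sdsseg/network.py` — the hybrid 2D/3D attention architecture
- `src/sdsseg/supervision.py` — selective targets and the SDS objective
- `src/sdsseg/train.py` — SGD harness, early stopping, scheme comparison
- `src/sdsseg/metrics.py` — Dice/sensitivity/specificity/HD/HD95
- `src/sdsseg/pipeline.py`, `cli.py` — NIfTI I/O, slice-wise inference, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
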