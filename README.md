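# cacseg

Anatomically guided segmentation and quantification of **coronary artery
calcification (CAC)** in cardiac CT: a cascaded pipeline of heart-ROI
extraction, Frangi vessel enhancement with coronary segmentation, an
ensemble of four 2D U-Net variants fused by **rank-based selective
ensembling** under a vessel prior, and Agatston calcium scoring. A seeded
synthetic-phantom generator makes every stage runnable and testable with
no clinical data.

Intended users: medical-image-analysis researchers and engineers who want
a transparent, fully tested reference implementation of vessel-aware CAC
segmentation — the cascade bookkeeping, the selective-fusion rule, and
the scoring conventions — at desk scale.

## Method

**Cascade.** CT is converted to Hounsfield units, windowed, resampled to
an isotropic 1 mm grid and normalized. A heart-stage model yields a 3D
region of interest; a vessel-stage model, fed vesselness-enhanced inputs
(the multiscale Hessian line measure V(R_A, R_B, S) of Frangi), segments
the coronary tree; dilating the tree by 2 mm gives a *vessel prior*.

**Ensemble.** Four 2D encoder–decoders — U-Net, Residual U-Net,
Attention U-Net, UNet++ — share a five-scale skeleton with channels
doubling 64→1024 and transpose-conv upsampling (31.03 M parameters for
the baseline U-Net at that configuration). Each is trained on
calcification-positive slices. Instead of soft voting (voxelwise mean),
every candidate region — a connected component of the union of binarized
member maps — ranks the members by a convex combination of three
reliability scores: morphological consistency (circularity 4πA/P²),
topological continuity (fraction of foreground in components ≥ s_min
voxels) and vessel conformity (|mask ∩ prior|/|mask|). Only the top-k
members are averaged; foreground outside the prior is forbidden outright.

**Scoring.** Per-slice lesions (≥130 HU, ≥1 mm²) contribute
area × density-weight (peak-HU bins 130/200/300/400) to the Agatston
score; Dice / sensitivity / specificity come from exact voxel counts.

The networks run on a small NumPy autodiff engine included in the
package; see `docs/methods.md` for every pinned default and convention.

## Worked example

Train the four tiny ensemble members on a 20-phantom benchmark and
tabulate the fusion ablation (about 2–3 minutes on one CPU core):

```bash
cacseg demo --out demo_out --seed 0
```

prints the voxel-pooled test-split table:

```
         config   dice  sensitivity  specificity  tp  fp     tn  fn
           unet 0.6361       0.8107       0.9993 347 316 441624  81
        resunet 0.6912       0.8995       0.9993 385 301 441639  43
 attention_unet 0.5888       0.8481       0.9990 363 442 441498  65
         unetpp 0.6516       0.7079       0.9995 303 199 441741 125
      soft_vote 0.6895       0.8481       0.9994 363 262 441678  65
      selective 0.6073       0.8925       0.9990 382 448 441492  46
selective+prior 0.8673       0.8855       0.9998 379  67 441873  49
```

Reading it: each single variant reaches Dice 0.59–0.69 on held-out
phantoms; plain soft voting averages away some noise (0.69); the
rank-based selection alone keeps more lesion voxels (sensitivity 0.89)
but also more stray ones; adding the vessel prior removes essentially all
extracardiac false positives (fp 448 → 67, specificity 0.9998) and lifts
Dice to 0.87 — the behaviour the anatomical constraint is for. The
phantoms plant bright decoys *outside* the coronary tree precisely to
make that mechanism measurable.

Other entry points (`cacseg COMMAND --help` for options):

```bash
cacseg phantom --n 4 --seed 7 --out phantoms/     # volumes + masks + XML
cacseg preprocess phantoms/case000_ct.nii.gz pre.nii.gz
cacseg segment-heart  ... --oracle-mask ... --mask-out ... --box-out ...
cacseg segment-vessels ... --prior-out prior.nii.gz
cacseg fuse m1.nii.gz m2.nii.gz --prior prior.nii.gz \
      --prob-out fused.nii.gz --mask-out mask.nii.gz
cacseg score ct.nii.gz mask.nii.gz --json-out agatston.json
cacseg ablate --n-cases 40 --epochs 30 --out run/ --leave-one-out
```

`cacseg score` prints, e.g., `Agatston total 118.2 ((100,400])` — the
calcium burden and its risk stratum.

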