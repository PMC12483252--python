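# prognomil

Weakly supervised prognostic prediction from whole-slide images (WSI), in
three stages:

1. **ROI derivation** — turn tissue-class segmentation masks (urothelium,
   lamina propria, muscle, blood, damage, background) into domain-knowledge
   regions of interest: the urothelium/lamina-propria border band (disk
   dilation at a physical 800 um depth) and the muscle-proximal invasive
   front, plus deterministic tile grids at standard magnifications.
2. **Contrastive tile features** — train a tile encoder with NT-Xent,
   supervised-contrastive or multi-task objectives and embed tiles into
   feature vectors.
3. **Attention-based multiple instance learning (MIL)** — classify a
   patient's bag of tile embeddings with gated attention,

   a_i = softmax_i( wᵀ( tanh(V h_i) ⊙ σ(U h_i) ) ),   ŷ = Ψ( Σ_i a_i h_i ),

   optionally nested (tile→region and region→slide attention, NMIA),
   optionally fused with integer-coded clinical variables, trained with the
   focal Tversky loss TI_c = TP_c/(TP_c + α·FN_c + (1−α)·FP_c),
   FTL = Σ_c (1 − TI_c)^(1/γ).

The intended users are computational-pathology researchers who need a
transparent, CPU-runnable reference implementation of this pipeline and of
the controlled Gaussian-bag benchmark for validating bag classifiers under
known witness rates, bag sizes and class-distribution overlap.  No clinical
cohort data ships with the package; every experiment here runs on synthetic
inputs generated by `prognomil.synthetic_data`.

All trainable parts run on a small, gradient-checked numpy autodiff core
(`prognomil.nn`) — no GPU or deep-learning framework required.

## Worked example

Train the scaled attention-MIL learner on the partial-overlap Gaussian bag
benchmark (class 0 instances ~ N(3, 2.5); positive bags contain a <50%
fraction of N(0, 2) witnesses; 150 bags of 3000–7000 instances, split
90/30/30):

```bash
python examples/03_gaussian_bag_benchmark.py
```

prints (about half a minute on one CPU core):

```
90/30/30 bags, sizes 3050-6995
stopped after 39 epochs; best validation AUC 0.960 at epoch 7
test AUC: 1.000
```

A test AUC near 1.0 means the gated-attention pooling detects the
witness-induced shift in each positive bag's instance distribution — easy
here because every bag carries thousands of instances.  `examples/` holds
one short script per capability: ROI derivation and tiling, contrastive
pretraining, the bag benchmark, nested MIL with region-level attention, and
attention-heatmap export.  A thin CLI mirrors the stages:

```bash
prognomil simulate --preset bags-partial --seed 1 --out bags.h5
prognomil train-mil --bags bags.h5 --model abmil --seed 1 --out run/
prognomil roi --mask M.png --meta M.yaml --roi border,front --distance-um 800 --out rois/
```

## Layout

```
src/prognomil/
  roi_geometry.py    masks -> ROIs -> tile grids (+ PNG/TIFF/YAML/CSV I/O)
  contrastive.py     NT-Xent / supcon / multitask losses, augment, pretrain, embed
  mil_models.py      Bag/NestedBag, gated attention, AbMIL, NMIA, baselines, FTL
  training_eval.py   training loop, AUC, MC dropout, grid search, heatmaps
  synthetic_data.py  Gaussian bag benchmark, synthetic masks and tiles, HDF5 I/O
  experiments.py     packaged presets and the end-to-end demo pipeline
  nn.py              numpy reverse-mode autodiff, layers, optimizers
  cli.py             `prognomil` command-line interface
docs/methods.md      models, parameters, numerical choices, limitations
examples/            one narrative script per capability
```
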