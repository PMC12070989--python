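# lesiongraph

Graph-based classification of lesion segmentation masks. The pipeline turns
labeled region masks (real or synthetic) into per-region feature vectors,
builds inverse-distance weighted graphs from them, and classifies whole graphs
with a from-scratch two-layer graph convolutional network (GCN) under
stratified K-fold cross-validation with exhaustive grid search and early
stopping. A full segmentation/classification metric suite (Dice, IoU,
precision/recall, per-class and macro F1, confusion matrix, one-vs-rest
ROC-AUC, class imbalance ratio) is included.

## Modules

| Module | Purpose |
|---|---|
| `lesiongraph.synth` | Class-conditioned synthetic image+mask generation, LabelMe-style polygon rasterization, paired geometric/photometric augmentation, PNG dataset layout |
| `lesiongraph.features` | Per-region geometric descriptors, region-restricted GLCM texture statistics, mean intensity; CSV feature tables |
| `lesiongraph.graphs` | Fully connected and noise-augmented threshold-pruned graphs with `w = 1/(dist + eps)` edge weights; GML I/O |
| `lesiongraph.gcn` | Numpy GCN: normalized adjacency with self-loops, ReLU conv layers, mean pooling, softmax head, analytic backprop, Adam/SGD, early stopping |
| `lesiongraph.crossval` | Stratified K-fold splits, exhaustive hyperparameter grid search, two-phase training (initial + fine-tune) |
| `lesiongraph.metrics` | Segmentation and classification metrics, imbalance ratio, ROC-AUC |
| `lesiongraph.mapping` | Graph → (mask, image) correspondence table and per-case visual reports |
| `lesiongraph.cli` | `lesiongraph` command-line pipeline |

## CLI

Every stage reads the previous stage's artifacts from the run directory:

```bash
lesiongraph simulate  --out runs/demo --seed 1        # synthetic image+mask pairs
lesiongraph features  --out runs/demo                 # per-class feature CSVs
lesiongraph graphs    --out runs/demo                 # original + augmented GML graphs
lesiongraph crossval  --out runs/demo                 # K-fold CV with grid search
lesiongraph train     --out runs/demo                 # single train/val model + checkpoint
lesiongraph evaluate  --out runs/demo                 # metrics JSON + confusion matrix
lesiongraph map       --out runs/demo                 # graph->mask->image table
lesiongraph report    --out runs/demo --limit 5       # per-case composite figures
```

All keys can also be set in a YAML file passed via `--config`; flags override
file values, and one `--seed` fans out deterministically to every stage.

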