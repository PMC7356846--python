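# molsnap

Molecular image-based QSAR for quantitative high-throughput screening
(qHTS) data. Nuclear-receptor screens of chemical libraries produce, per
compound, a SMILES string and a 0–100 activity score; `molsnap` turns that
into an image-classification problem: each compound's 3D conformer is
photographed as a grid of ball-and-stick snapshots from many rotation
angles, a classifier scores every snapshot, and the per-image
probabilities are median-aggregated back to one score per molecule. The
package is aimed at computational toxicologists and cheminformaticians who
want the full pipeline — curation, qHTS normalization, rendering,
leakage-safe splitting, a fixed training protocol, and molecule-level
evaluation — reproducible on a laptop.

## The method

- **Curation** — desalt to the largest organic fragment, neutralize simple
  protonation states, canonicalize; drop carbon-free species, unparseable
  SMILES and duplicate structures with conflicting labels. Compounds with
  activity score ≥ 40 are active, 0–39 inactive.
- **qHTS analysis** — plate signals normalize as
  `% Activity = (V_compound − V_dmso)/(V_pos − V_dmso) × 100`;
  concentration–response series fit the four-parameter Hill model
  `y = bottom + (top − bottom)/(1 + (IC50/x)^slope)`.
- **Snapshots** — per axis, pose angles are multiples of an angle
  increment below 360°; the default (176°, 176°, 176°) gives 27 poses.
  Poses rasterize deterministically to 256 × 256 RGB PNGs: orthographic
  projection, CPK colors, atoms at 23% of vdW radius, distance-based bond
  perception (0.4 Å floor, 0.8 Å covalent tolerance).
- **Datasets** — compounds shuffle into 11 label-stratified groups; two
  replicated splits at Tra:Val:Test = 4:4:1 (in groups), the second with a
  fresh test group. Splits are strictly molecule-level; a leakage check
  runs on every emitted manifest.
- **Training** — minibatch SGD (momentum 0.9), learning rate 0.006, batch
  size 108, fixed epochs with per-epoch validation; the deployed model is
  the epoch with the lowest validation cross-entropy. The classifier is
  pluggable; the default is a small frozen color-bank CNN with a trainable
  softmax head (see `docs/methods.md`).
- **Evaluation** — median aggregation per molecule, Youden-index
  (J = sensitivity + specificity − 1) cutoff selection, then ROC AUC,
  balanced accuracy, accuracy, F-measure and MCC (standard square-root
  form), averaged over replicates with standard errors.

## Worked example

Forty synthetic compounds (20 bromine-bearing actives, 20 inactive
hydrocarbons), 27 snapshots each at 64 × 64 px, both replicates trained
for 10 epochs:

```python
from molsnap import chem_prep, datasets, evaluate, fixtures, model
from molsnap.snapshot import SnapshotConfig

records = fixtures.make_toy_library(fixtures.ToyLibrarySpec(n_per_class=20, seed=1))
kept = [r for r in records if r.kept]
conformers = {r.compound_id: chem_prep.embed_3d(r, seed=1) for r in kept}
plan = datasets.build_replicates(datasets.partition_groups(records, n_groups=11, seed=1))
manifest = datasets.emit_dataset(records, conformers, plan, "example_ds",
                                 SnapshotConfig(pixel_size=(64, 64)))

reports = []
for rep in plan.replicates:
    view = model.replicate_view(manifest, rep.replicate_id)
    handle, epochs = model.train(view, model.TrainConfig(epochs=10, seed=1),
                                 root="example_ds")
    table = model.predict_images(handle, view[view["partition"] == "Test"],
                                 "example_ds")
    reports.append(evaluate.evaluate_replicate(table, replicate=rep.replicate_id))
print(evaluate.average_replicates(reports).to_string(index=False))
```

Output:

```
library: 40 records, 20 active
rendered 1755 snapshot rows over 2 replicates
replicate 01: best epoch 10, Loss(Val) 0.2102, Acc(Val) 100.00%
  Test: AUC 1.000  BAC 1.000  Acc 100.0%  F 1.000  MCC 1.000  cutoff 0.850
replicate 02: best epoch 10, Loss(Val) 0.1581, Acc(Val) 100.00%
  Test: AUC 1.000  BAC 1.000  Acc 100.0%  F 1.000  MCC 1.000  cutoff 0.871
     metric  mean  se  n
        auc   1.0 0.0  2
        bac   1.0 0.0  2
acc_percent 100.0 0.0  2
  f_measure   1.0 0.0  2
        mcc   1.0 0.0  2
```

Each snapshot of a test molecule gets a probability of activity; the
median over its 27 views is the molecule's score. On this deliberately
separable library the Youden-chosen cutoff classifies every test molecule
correctly in both replicates, so all five metrics sit at their maxima —
the library exists to verify the pipeline end to end, not to pose a hard
learning problem.

The same steps are available from the shell:

```
molsnap fixtures toy-library --n-per-class 20 --out library.csv
molsnap curate --library library.csv --out curated.csv
molsnap embed --library curated.csv --out conformers.sdf
molsnap build-dataset --library curated.csv --sdf conformers.sdf --out-dir ds
molsnap train --manifest ds/manifest.csv --epochs 30 --lr 0.006 --batch-size 108
```

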