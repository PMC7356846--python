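# Methods

`molsnap` implements an image-based QSAR pipeline for quantitative
high-throughput screening (qHTS) data: compounds arrive as SMILES with
PubChem-style activity scores, are standardized and embedded in 3D,
photographed as multi-angle ball-and-stick snapshots, split into replicated
molecule-level datasets, classified per image, and evaluated per molecule.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Compound curation

Curation mirrors standard library washing: the largest organic fragment is
kept (fragments without carbon are "nonorganic" and excluded), simple
protonation states (carboxylates, ammoniums) are neutralized with RDKit's
uncharger, and the structure is canonicalized. Quaternary centers and true
zwitterions are left alone; no pKa model or tautomer enumeration is
applied. Unparseable SMILES are excluded with reason `inaccurate_smiles`;
exclusion is always a labeled state, never an exception, so a curation run
over a large library cannot die halfway.

Duplicate canonical structures (salts or stereoisomer entries collapsing to
one parent) are resolved all-or-nothing: if every entry agrees on the
active/inactive call, one record survives; if they disagree, every member
of the group is excluded as `indefinite_activity`. The all-or-nothing rule
is deliberately conservative — with conflicting assay outcomes there is no
principled way to pick a winner, and a wrong label is worse than a dropped
compound.

3D embedding uses seeded ETKDG distance geometry plus MMFF94 cleanup (UFF
fallback for atoms without MMFF parameters), one conformer per molecule
with explicit hydrogens. A fixed seed reproduces coordinates bit for bit.
One conformer is a simplification: the rendered images depict a single
low-energy conformation, not a conformational ensemble.

## qHTS normalization and the Hill model

Raw plate signals are normalized against in-plate controls:

    % Activity = (V_compound − V_dmso) / (V_pos − V_dmso) × 100

so the DMSO-only median anchors 0% and the positive-control median 100%.
The value is unbounded in both directions by design. Antagonist-mode plates
use the same formula with their own controls; the mode is carried as
metadata and no sign convention is imposed beyond the controls themselves.
Equal control medians make the normalization undefined and raise a
dedicated error. An optional plate-drift correction subtracts a DMSO
baseline interpolated linearly over plate index between compound-free
plates run before and after the stack.

Concentration–response series (≥ 5 points) are fit to the four-parameter
logistic (Hill) model

    y(x) = bottom + (top − bottom) / (1 + (IC50 / x)^slope)

by trust-region least squares. IC50 is parameterized as log10(IC50), which
keeps it positive and conditions the Jacobian across concentration decades;
starting values are bottom = min(y), top = max(y), IC50 at the geometric
mid-concentration, slope 1. The slope is bounded at |slope| ≤ 20; a fit
pinned there has degenerated to a step and is flagged unconverged, as are
flat series (span below 1e-6 of scale), for which IC50 is unidentifiable.
The maximum response over the fitted range is reported alongside the
parameters. Integer activity scores in [0, 100] binarize at 40
(active ≥ 40); the three-class scheme (0 inactive, 1–39 inconclusive,
40–100 active) is available as metadata only.

## Snapshot rendering

The rotation grid takes one angle increment per axis; per axis the pose
angles are k·inc for k = 0, 1, … while k·inc < 360 (count = ceil(360/inc)),
and the grid is the Cartesian product over x, y, z. The default increment
(176°, 176°, 176°) therefore yields 3³ = 27 poses per molecule. Rotations
compose in the fixed order Rz·Ry·Rx (x applied first); the order is a
convention that must be pinned for reproducibility, nothing more.

Rendering is an orthographic, depth-sorted (painter's algorithm) NumPy
rasterization with anti-aliasing off, so identical inputs give
byte-identical PNGs. Defaults: 256 × 256 px RGB, white background, atoms as
filled circles at 23% of the van der Waals radius in CPK colors, bonds as
capsules split half-and-half in the end atoms' colors. The projection scale
is set once per molecule from its rotation-invariant bounding sphere
(molecule fills `zoom_percent` of the frame minus a 5% margin), so apparent
size does not change between poses — per-pose rescaling would destroy
shape cues. Atom-size scaling is applied before zoom normalization.

The stick radius default of 14.5 mÅ is taken literally (0.0145 Å), which at
256 px rasterizes about one pixel wide; `JMOL_STICK_PRESET` provides the
conventional 145 mÅ thickness for on-screen work, since the literal value
is plausibly a decimal-point slip in its source. Rasterized stick width is
floored at one pixel so bonds never vanish.

Bond perception is purely geometric: atoms i, j bond iff
`min_bond_distance ≤ d(i,j) ≤ r_cov(i) + r_cov(j) + bond_tolerance` with
defaults 0.4 Å and 0.8 Å and classic covalent radii from the packaged,
versioned element table (also the source of vdW radii and CPK colors).
Unknown elements raise an error naming the symbol.

## Dataset construction

Kept compounds are shuffled under a seed and dealt round-robin into 11
groups, stratified by label so each group's active count is within one
compound of the ideal — on heavily imbalanced data an unstratified draw can
produce test partitions with no actives at all, which would make every
molecule-level metric undefined. Two replicated dataset groups are built at
Tra:Val:Test = 4:4:1 in groups; replicate 02 takes a previously unused
group as its fresh Test and re-draws 4 + 4 training/validation groups from
the remaining ten. The re-draw rule for replicate 02's Tra/Val is a design
choice (the split procedure's text fixes only the fresh-test constraint).
Eleven groups for a nine-part ratio means each replicate leaves two groups
idle; the group weights are exposed as configuration.

Splitting is strictly at the molecule level. Every snapshot of a compound
inherits the compound's partition, the emitted directory tree is
class-labeled per partition per replicate, and `check_no_leakage` asserts
on every emitted manifest that no compound straddles partitions within a
replicate.

## Classifier and training protocol

The training protocol is minibatch SGD with momentum 0.9, learning rate
0.006, batch size 108, a fixed number of epochs (default 30) with one full
validation pass per epoch, and a single random seed governing
initialization and shuffling. Per-epoch parameter checkpoints are kept and
the deployed model is the checkpoint minimizing validation cross-entropy
(ties to the earliest epoch). Cross-entropy is the loss throughout.

The default `tiny_cnn` backbone is a small convolutional network in NumPy,
built for palette-rendered molecular depictions:

1. a frozen 1 × 1 convolution whose channel k computes
   `relu(1 − ‖pixel − c_k‖² / τ²)` for a reference color c_k — the CPK
   palette entries for H, C, N, O, F, P, S, Cl, Br, I — with τ = 0.35;
   the quadratic color expansion makes this selective color matching a
   linear per-pixel operation;
2. global average pooling (soft color fractions) and global max pooling
   (color presence) per channel;
3. a standardization layer whose statistics are calibrated once on the
   training partition at initialization and then frozen (colored structure
   covers a small fraction of each frame, so raw pooled features live at a
   tiny scale; without this the head's gradients are far off the scale the
   protocol's learning rate expects);
4. a trainable linear softmax head, initialized at zero.

Freezing the feature bank and training only the head mirrors the
fixed-pretrained-backbone fine-tuning paradigm, keeps the optimization
convex and seeded-deterministic, and — importantly at desk scale — avoids
the small-sample failure mode where a trainable first layer latches onto
chance color correlations across a few dozen training molecules. The
backbone registry (`register_backbone`) is the extension point for heavier
architectures; nothing in the harness assumes the default network beyond
the `forward/backward/calibrate/get_params` surface.

## Evaluation

Per-image probabilities are aggregated to one molecule score by the median
(mean of the central pair for even counts) — medians first, thresholding
after. The cutoff maximizes the Youden index J = sensitivity +
specificity − 1 over all observed scores plus the trivial all-negative
threshold, so J ≥ 0 always; molecules are called active at score ≥ cutoff
(ties active). The panel reports ROC AUC (equal to the Mann–Whitney
pairwise probability, ties half-weighted), balanced accuracy, accuracy in
percent, F-measure, and MCC with the square root over its denominator
product — the radical-free variant sometimes printed is not
scale-consistent. Zero denominators in F or MCC yield a sentinel 0 rather
than NaN. Metric means and standard errors are reported across replicates.

By default the cutoff is chosen on the evaluated scores themselves; on
small test sets this is optimistic, and `confusion_metrics` accepts an
externally derived (e.g. validation-set) cutoff for an honest estimate.

## Synthetic data: what it shows and what it does not

The toy library pairs pure-hydrocarbon scaffolds (linear, branched,
cyclohexyl) with bromine-substituted versions: actives carry one Br atom,
whose dark-red CPK hue is a localized, rotation-robust image signal;
scores are drawn uniformly in 40–100 (actives) and 0–39 (inactives), with
an optional label-noise fraction whose scores are resampled from the other
range. Hydrocarbon scaffolds are deliberate: with heteroatoms in the pool,
chance N/O composition differences across a ~15-molecule training
partition act as spurious color features. An independent oracle — counting
rendered pixels of the exact motif hue — separates the classes perfectly
at zero noise without touching the classifier, so the image path itself is
validated, not just the end-to-end number.

Dose–response fixtures place log-spaced concentrations ±3 decades around a
known IC50 and add Gaussian noise; prediction-table fixtures draw
per-image probabilities from class-conditional Beta distributions whose
generating-process AUC is computed independently by numerical integration.

Default desk-scale problem sizes, used by the test suite: 40 molecules ×
27 poses at 64 × 64 px, 10 training epochs, two replicates; Hill-recovery
simulations use 8-point curves × 100 repeats. At these sizes the toy task
is solved essentially perfectly (validation accuracy 100%, molecule-level
test AUC 1.0 on both replicates under the default seed).

Passing these tests shows the pipeline's plumbing, determinism, splitting,
protocol and metrics are correct, and that the image path carries
class-relevant signal end to end. It does not show that real,
structurally diverse screening libraries are predictable this way: the toy
classes differ by a single injected motif, class balance is even, and the
default backbone's color-composition features cannot represent the subtle
shape and connectivity cues a deep network would need on real data.

## Known limitations

- One conformer per molecule; no ensembles, tautomers or stereo expansion.
- The renderer is a flat-shaded rasterizer (no lighting, perspective or
  anti-aliasing); faithfulness targets reproducibility, not beauty.
- The default classifier is color-compositional; it is a desk-scale
  stand-in wired to the same protocol, not a deep architecture.
- Antagonist-mode normalization applies the same formula with mode-specific
  controls; no additional sign convention is imposed.
- Youden-on-test cutoff selection is optimistic; a validation-derived
  cutoff mode is provided.
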