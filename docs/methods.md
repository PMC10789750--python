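# Methods

`lsfregio` predicts, atom by atom, where a drug-like molecule will react
under radical late-stage functionalization (LSF) conditions — Minisci-type
C–H alkylation/fluoroalkylation and P450-style oxidation. This note
describes the models and procedures the package implements, the choices
made where the design was genuinely open, and what the bundled synthetic
benchmark does and does not demonstrate.

## Reactive-site labels from SM/product pairs

LSF leaves the substrate core intact: the starting material (SM) is a
subgraph of each product. `reaction_center` therefore derives training
labels without atom-mapped reaction SMILES:

1. Enumerate **every** element- and bond-compatible embedding of the SM
   heavy-atom graph into the product graph (networkx VF2, node-induced:
   SM bonds must exist in the product; extra product bonds may only touch
   unmapped, newly installed atoms). Bond matching tolerates
   aromatic-vs-single/double discrepancies when both bonds lie in an
   aromatic environment, since functionalization can perturb the Kekulé
   assignment of an untouched core.
2. Under each embedding, flag every SM carbon whose oxidation number or
   heavy-atom degree differs from its image.
3. Take the union over embeddings and products.

Because the set of embeddings is closed under composition with SM
automorphisms, the resulting label set is closed under the molecule's
symmetry group: if one of two homotopic positions reacted, both are
labeled, which is also how the positions behave in a ¹³C spectrum.

**Oxidation numbers.** Each bond contributes its order, signed toward the
more electronegative partner (Pauling scale; H counts −1 per hydrogen;
differences ≤ 0.05, e.g. C–S, count 0). Aromatic bonds count order 1.5.
The usual integer convention assigns aromatic bonds alternating orders
1 and 2 from some Kekulé structure, but which structure a toolkit picks is
arbitrary, and SM and product can kekulize differently — producing phantom
"oxidation changes" at untouched ring positions (e.g. quinoline N=C2 vs
N=C8a). With order 1.5 the value is Kekulé-independent; aromatic carbons
may carry half-integer values, and the changes caused by an actual H → C/O
substitution remain intact. A record whose product does not contain the SM
(fragmentation, ring-opening) raises `DegradedProductError` and is routed
to manual curation, mirroring how such records are handled in practice.

## The network

A message-passing neural network over heavy-atom graphs, NumPy throughout
(`lsfregio.autodiff` provides the reverse-mode differentiation and Adam).

* **Features** (per atom): scaled atomic number, element one-hot
  (14 named elements + other), H-bond donor/acceptor flags (Lipinski
  SMARTS), hybridization one-hot (sp/sp²/sp³/other), aromaticity flag,
  hydrogen count. Formal charge is an optional, default-off column.
* **Trunk**: input projection + T rounds of per-bond-type linear messages
  (single/double/triple/aromatic/universal), sum-aggregated, with a
  GRU-style gated state update. Message weights are shared across rounds,
  so the receptive field after T rounds is exactly T bonds.
* **Universal node**: one extra node bidirectionally connected to every
  atom through a dedicated bond type; it gives each atom molecule-level
  context within two rounds. On by default.
* **Shift head** (pretraining): linear readout per carbon of the trunk
  embedding, predicting the ¹³C shift normalized by the training
  corpus mean/std (stored in the checkpoint).
* **Reactivity head** (fine-tuning): each atom embedding is concatenated
  with the one-hot reaction-condition vector and passed through a
  three-layer feed-forward network with a terminal sigmoid.

Defaults are hidden width 200 and T = 4; the bundled benchmark and tests
use width 64 and T = 3, which this synthetic chemistry does not outgrow.
Both heads inherit the trunk's symmetry behavior: atoms in one
automorphism orbit receive identical outputs to machine precision.

Conditions (reagent, oxidant, solvent, additive, acid) are free-text
tokens, case-folded, one-hot encoded per slot; the reaction-class tag is
metadata only — the network must infer the mechanism from the condition
tokens themselves.

## Losses

Training minimizes the negated weighted binary cross-entropy
`-Σ w_i (y_i log x_i + (1-y_i) log(1-x_i))` with probabilities clamped to
[ε, 1−ε], ε = 10⁻⁶. Three imbalance weighting schemes are implemented;
their shared idea is that the weight of a correct class prediction is
inversely related to how often that class is predicted. The schemes
combine the terms {x, y, log pred_p, log true_p}, where `x` is the hard
thresholded prediction, `pred_p` is the fraction of batch atoms predicted
positive and `true_p` the fraction labeled positive (both clamped). Log
magnitudes enter as −log(·) ≥ 0 so that rarer predicted classes carry
larger weights; a signed reading would reward errors. Scheme 2 adds a
second bracket of cross terms to scheme 1's, and scheme 3 doubles
scheme 1's bracket inside scheme 2. Weights are constants with respect to
the gradient (they contain the prediction itself, which would otherwise
double-count gradient paths). Default scheme: 1.

Two numerical choices in the training loop, applied identically to every
configuration: the per-batch loss is the weighted **mean** (Σ w·BCE / Σ w),
which keeps the gradient scale comparable across schemes whose absolute
weight scales differ by orders of magnitude; and gradients are clipped to
global norm 5 (the schemes can spike when a batch's `pred_p` saturates).
The classifier's output bias is initialized to the logit of the training
base rate of reactive atoms, the standard remedy for all-negative collapse
on heavily imbalanced atom labels.

## Transfer learning protocol

Pretraining minimizes MSE on per-carbon shifts (the regression loss is an
open choice; MSE is the default for shift prediction). Fine-tuning in
`transfer` mode loads the trunk and reinitializes the reactivity head;
`scratch` mode initializes everything fresh (the ablation baseline).

A fresh head backpropagates noise into a pretrained trunk during its first
epochs, which we observed to reliably erase the trunk's advantage. The
protocol therefore supports gradual unfreezing: `freeze_epochs` warmup
epochs train the head on frozen trunk features before the whole network
trains together. The benchmark protocol uses 8 warmup epochs followed by
40 full-network epochs, against 40 full-network epochs for the scratch
arm — equal full-network budgets, with the cheap head-only warmup treated
as alignment rather than training. A cosine learning-rate decay
(3·10⁻³ → 3·10⁻⁴) removes late-training run-to-run variance.

## The synthetic benchmark

The real LSF reaction corpus this framework was designed for is
restricted-access, and its headline scores are not reproducible at desk
scale. The `synthetic` module provides a fully specified stand-in whose
ground truth is known, so that every stage of the pipeline is falsifiable.

**Molecules.** Seeded assembly from a fragment grammar: 17 azine/azole
cores, 13 carbocyclic/saturated cores, 18 substituents, grown to 10–40
heavy atoms (the size range of typical LSF substrates), with a 65% chance
of an N-heteroaromatic primary core. The grammar deliberately excludes
aryl-methyl, terminal-hydroxyl, fluorinated and four-membered-ring
substituents so that no installed motif (CF₃, CF₂H, OH) can be
impersonated by a symmetry swap — this makes the generator's stored truth
provably equal to the labeling pipeline's union-over-embeddings output,
which the tests verify record by record.

**Planted chemistry.** Three reagents with structure rules:
CF₃ (sodium triflinate-like) attacks aromatic C–H alpha to a ring N
unless an electron-donating substituent sits within two bonds; CF₂H
attacks aromatic C–H exactly two bonds from a ring N; P450 oxidation
hydroxylates benzylic sp³ C–H. Each reagent turns over only with its
matched activation system (persulfate, TBHP, NADPH respectively); a
mismatched pairing gives a negative record. Every oxidant token also
appears in productive records of another reagent, so recognizing the
unproductive combinations requires the reagent-by-oxidant interaction —
learnable only from negative data, which is what makes the
negative-data ablation mechanistic rather than accidental. Positive
records functionalize every eligible symmetry orbit (one mono-substituted
product per orbit), making the reactive set a deterministic function of
structure and conditions; draws offering more than 4 reactive orbits are
skipped, as unselective reactions drop out of curated datasets. 25% of
records are negative.

**Synthetic shifts.** Per-carbon values from a class base (sp³ 28,
aromatic 128, sp² 135, carbonyl 193 ppm) plus distance-resolved
substituent increments shaped after empirical ¹³C additivity systematics:
attached heteroatoms shift downfield, ring nitrogens and π-donors two
bonds away shift aromatic carbons upfield (the pyridine-C3 /
ortho-to-donor effect). A small (2 ppm) deterministic hash of the
canonical 2-bond environment keeps the model from being exactly additive,
and 1 ppm Gaussian noise is added per carbon. Symmetry-equivalent carbons
share the noiseless value exactly. The model is not spectroscopically
accurate; what matters for pretraining is that chemically distinct
environments occupy distinct, *coherent* shift bands — we found that an
incoherent (purely hashed) shift model actively degrades transfer, because
the trunk's learned coordinate stops tracking chemical similarity.

**What passing does and does not show.** On this benchmark
(400 reactions, 120 molecules, scaffold-split 80/20; ~20k pretraining
shifts from 1000 molecules) the transfer-learned model reaches mean test
F-score ≈ 0.96 over five seeds, above both the scratch arm (≈ 0.90) and
the without-negatives arm (≈ 0.82). This demonstrates that the pipeline is
wired correctly end to end and that the two qualitative findings —
pretraining helps, negative data helps — hold under the planted
mechanisms designed to exercise them. It does not certify performance on
real LSF chemistry: the synthetic rules are 2-bond-local and noise-free,
real selectivity is neither, and the real corpus's headline numbers
(F ≈ 0.6 at ~96% atom accuracy) reflect that much harder problem.

## Baselines

* **Fukui indices.** Condensed reactivity descriptors from per-atom
  charges at the N−1, N, N+1 electron states (supplied as input; computing
  the charges is upstream quantum chemistry): F(+) = q(N) − q(N+1),
  F(−) = q(N−1) − q(N), F(0) = (F(+)+F(−))/2. Electrophilic radicals are
  ranked by F(+), nucleophilic radicals by F(0); for a radical of unknown
  character both indices are scored against the observed sites and the
  better fit is reported, flagged as such. Site sets are top-k over C–H
  carbons with ties expanded. Global electrophilicity/nucleophilicity
  multipliers rescale a molecule's ranks uniformly and therefore never
  change within-molecule site selection; they are accepted and ignored.
* **Random forest.** One row per atom: atom-centered Morgan fingerprint
  (radius 2, 2048 bits) concatenated with the condition one-hot;
  scikit-learn `RandomForestClassifier`, 200 trees, seeded.

## Metrics

Pooled atom-level confusion counts give F = 2TP/(2TP+FP+FN) and accuracy
(TP+TN)/total; recall is reported separately because a recall-style
reading of "accuracy" is inconsistent with accuracies near 95% at F ≈ 0.6.
AUROC uses scikit-learn (ties count ½). Top-1 accuracy scores a reaction
as correct when its highest-probability eligible atom (a carbon bearing at
least one hydrogen) is among the true reactive sites; ties break toward
the lowest canonical atom index, and negative records are excluded.

## Known limitations

* The matching step is exponential in the worst case; it is comfortable
  for ≤ 50-atom drug-like molecules but not for highly symmetric
  macromolecules.
* Training is single-threaded NumPy: suitable for the benchmark scale
  (minutes), not for corpora of 10⁵ molecules.
* Stereochemistry is ignored throughout (heavy-atom constitution only),
  and degraded/fragmented products are flagged rather than solved.
* The three weighting schemes are implemented exactly as specified
  term-for-term; scheme 1's false-negative weight −log(1−true_p) is small
  when positives are rare, which slows recovery from conservative
  predictions — the prior-logit bias initialization exists to compensate.
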