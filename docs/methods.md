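# Methods

`ddikit` predicts whether two drugs interact, from molecular structure
alone.  Each drug is encoded twice — as a molecular graph and as a SMILES
string — the two representations are fused, and a classifier scores the
pair.  A contrastive objective over chemically-valid augmented views of the
same molecule regularizes the representation.  This note records the model,
its assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Molecular graphs

A molecule is a heavy-atom graph G = (V, E, Xv, Xe): atoms carry one-hot
element (C, N, O, S, P, F, Cl, Br, I, other), degree (0–5), formal charge
(−2..+2), an aromatic flag and implicit-H count (0–4), for d_atom = 27;
bonds carry order (single/double/triple/aromatic) and an in-ring flag.
Hydrogens are implicit, so augmentation bookkeeping only has to track heavy
atoms, and atom indices follow SMILES reading order.  Parsing and
aromaticity perception are delegated to RDKit behind a pluggable backend;
validity is additionally checked against the package's own valence table
(C 4, N 3, O 2, S {2,4,6}, P {3,5}, halogens 1, B 3), which is the table the
augmentation operators must respect.

## Spatial encoding

The chemical distance d_chem(v_i, v_j) is the minimum summed bond weight
over paths between two atoms.  Unit weights (the default) make this the
topological shortest path; an alternative scheme weighs a bond 1/order so
multiple bonds pull atoms closer.  Distances are clipped into D_max + 2
integer buckets (default D_max = 8): one bucket per distance 0..D_max, one
shared bucket for longer paths, and one reserved bucket for unreachable
pairs — augmentation can disconnect a molecule, and a learned "unreachable"
offset degrades more gracefully than −∞ masking.  A learned
(D_max + 2) × H table maps each bucket to one scalar per attention head;
the realized n × n bias S is added to the attention logits:

    Attention(Q, K, V, S) = softmax((Q Kᵀ + S) / √d_k) V.

The bias sits inside the √d_k scaling by default (a flag moves it outside).
Per-head scalars — rather than a d_model-dimensional embedding per pair —
are the only shape compatible with an additive logit bias, and distances
are the only positional signal: molecular graphs have no canonical node
order for sinusoidal encodings.

## Encoder and hierarchical readout

Atom features are projected to d_model and passed through n_layers pre-norm
transformer blocks (multi-head attention with the spatial bias, then a
GELU feed-forward of width ffn_mult × d_model; residual connections and
dropout 0.3 around both).  Pre-norm was chosen for optimization stability;
nothing else in the design depends on it.

The readout is hierarchical.  A single differentiable-pooling level
soft-assigns the n atoms to K clusters (assignment scores come from node
states concatenated with one adjacency-smoothed copy, row-softmaxed), giving
cluster states H2 = S2ᵀZ and a coarsened adjacency A2 = S2ᵀAS2; optional
link-prediction and entropy auxiliary losses are computed but weighted 0 by
default.  K defaults to max(2, ⌈n/4⌉) capped at 16, per molecule; in padded
batches each molecule's inactive cluster columns are masked out of the
softmax so pooling is independent of batch composition (this is asserted by
a test).  A gated attention pool over clusters (softmax gate, learned value
map) yields the molecule vector h_mol — so information is aggregated at
atomic, functional-group, and molecular scales.

All batched operations mask padded atoms out of every softmax and zero
their states; per-molecule and batched execution agree to float tolerance.

## Augmentation

Four operators, each constrained to emit a chemically valid graph:

* **Atom masking** (ratio 0.15).  Chemical importance of an atom is
  0.4·ring + 0.3·heteroatom + 0.2·functional-group-member +
  0.1·min(degree,4)/4 — a deterministic, monotone stand-in for "essential";
  atoms scoring below τ_imp = 0.5 are candidates, and ⌊0.15·n⌋ of them have
  their feature rows replaced by a learned mask token.  Topology is kept so
  batch shapes stay stable; a delete-atom mode exists behind a flag.
* **Bond perturbation** (ratio 0.10).  Selected non-aromatic bonds are
  re-typed uniformly among the orders that keep both endpoints within the
  valence table (implicit hydrogens shrink to absorb added order); bonds
  with no alternative are left unchanged.
* **Subgraph sampling** (ratio 0.75).  Breadth-first growth from a detected
  functional-group atom (carboxyl, amine, hydroxyl, carbonyl, sulfonyl,
  halogen-on-carbon, aromatic ring — matched by SMARTS) to ⌈0.75·n⌉ atoms;
  the induced subgraph is connected by construction.
* **Scaffold hopping** (probability 0.05).  The Murcko scaffold (ring
  systems + linkers, found by pruning non-ring terminal atoms) is replaced
  by a scaffold harvested from the training drugs with the same number of
  attachment points; side chains reattach by single bonds and the result
  must re-validate, otherwise the hop is abandoned.  "Same attachment-point
  count" is the compatibility criterion; a ring-count filter would be a
  natural refinement but is not implemented.

Views re-serialize their SMILES (masked atoms as `*`) so the sequence
branch sees the augmented structure.  The ensemble draws one operator per
view by configurable weights (uniform by default).

## Contrastive objective

Drug vectors pass through a 2-layer projection head (d_model → d_model →
128) and are L2-normalized; the representation used downstream is the
pre-projection vector, following standard contrastive practice.  For a
batch of B drugs with views z_i⁺:

    L = −(1/B) Σ_i log [ exp(sim(z_i, z_i⁺)/τ) / D_i ],   τ = 0.1.

The denominator D_i includes the positive term plus all in-batch negatives
(`with_positive`, the default — bounded below by 0 and consistent with the
hard-mining form); a `literal` mode with negatives only is kept as an
alternative.  Hard-negative mining replaces the negative set by the k
most-similar other drugs (cosine in projection space, ties broken by
index); with k = B−1 it coincides exactly with the full loss, which is
asserted by a test.  Mining by similarity is the label-free
operationalization of "structurally similar but functionally different" —
at pretraining time no labels exist to do better.

## Cross-modal fusion

The sequence branch is a small trainable transformer (d_bert = 128, 2
layers, 4 heads by default) over a character-level SMILES vocabulary with
Cl/Br as single tokens; any external encoder exposing token states can be
plugged in instead, and no pretrained weights are bundled — the fusion
mechanism, not the encoder, is the point.  Atom states cross-attend over
token states (learned projections to a shared dimension; rows of the
attention matrix are convex weights) and the result is added residually
before pooling.  After pooling, a scalar gate per drug

    λ = σ(MLP([h_mol ; h_seq])),   h_final = λ·h_mol + (1−λ)·h_seq

balances the modalities (h_seq linearly projected to d_model so the convex
combination type-checks).  A per-dimension gate is a flagged alternative.
With fusion disabled, h_final := h_mol and the pipeline still trains.

## Pair classification and objective

A drug pair (i, j) is encoded as [h_i ; h_j ; h_i⊙h_j ; |h_i−h_j|] and
scored by a two-hidden-layer ReLU MLP (1024, 256 at full scale) with
dropout 0.3 and sigmoid output.  Training optimizes the raw, order-dependent
prediction; because interaction is an unordered relation, inference averages
both argument orders, making predictions exactly symmetric (switchable).

The total objective is L_DDI + α·L_contrastive + β·L_reg with α = 0.5,
β = 1e-5; L_DDI is binary cross-entropy (mean reduction by default for
batch-size-invariant learning rates; a literal summed form is a flag) and
L_reg is the explicit sum of squared parameters — the optimizer's own
weight decay is set to 0 to avoid regularizing twice.

## Training protocol

Three phases: (1) contrastive pretraining, (2) joint optimization of the
full objective, (3) fine-tuning at 0.1× learning rate with the spatial-bias
table frozen — "fine-tune" is under-determined, and freezing the most
dataset-specific geometry prior while relaxing everything else is this
package's reading; both the factor and the frozen set are configurable.
AdamW (lr 1e-4 at full scale), cosine annealing to zero within each phase
(no warm restarts), gradient-norm clipping at 1.0, early stopping on
validation loss with patience 15, best-validation checkpoint restored.

Splits: transductive (random 60/20/20 over pairs); inductive (drugs
partitioned 0.7/0.1/0.2 — the canonical 80/20 train/test with a validation
share carved from the training side; test pairs touch ≥1 held-out drug,
train pairs use training drugs only, validation pairs touch a validation
drug but no test drug); scaffold-inductive (identical, but whole Murcko
scaffold groups are assigned to one partition, so no scaffold spans train
and test).  Pair tables containing only positives are completed by seeded
uniform sampling of non-positive pairs at 1:1.

Metrics: ACC/precision/recall/F1 at threshold 0.5 (configurable), AUC
(probability a random positive outranks a random negative, ties ½) and AP
(step-interpolated precision-recall area), computed via scikit-learn and
cross-checked in the test suite against brute-force concordance and
step-sum oracles.

## Synthetic benchmark

The generator assembles molecules from a fragment grammar — an alkyl
backbone (3–8 carbons) decorated with benzene/pyridine rings and the
functional groups listed above, every fragment attaching through a single
bond to a carbon, which is valence-safe by construction — rejection-sampled
to 6–24 heavy atoms.  Pair labels follow a deterministic symmetric rule
(R1): interaction iff one drug has an amine and the other a carboxyl group,
or both are aromatic and at least one carries a halogen.  Labels can be
flipped with probability ε; a pattern-matching oracle that applies the rule
directly therefore scores 1−ε, the ceiling against which trained models are
judged.  Defaults (300 drugs, 3,000 pairs, 1:1 classes) are sized so the
full three-phase protocol finishes in minutes on one CPU.

Because labels are functions of detectable substructures, a model can only
solve the benchmark by attending to functional groups — exercising exactly
the premise of the architecture.  What passing does **not** show: synthetic
molecules are far smaller and more regular than pharmaceutical chemical
space, the rule is noiseless and pairwise-decomposable, and no statement
about performance on real DDI databases follows.

## Numerical choices

The neural stack runs on the package's own reverse-mode autodiff engine
over numpy arrays (`ddikit.autodiff`): models at this scale need no GPU,
every operation stays inspectable, and the acceptance-level
finite-difference gradient checks exercise the exact code path that
training uses.  Fused single-node kernels (GELU in its sigmoid
approximation, softmax, layer normalization) keep tape overhead low.
Training tensors default to float32; analyses and gradient checks run in
float64 (results promote automatically when mixed).  Probabilities are
clamped to [1e-7, 1−1e-7] inside the cross-entropy; softmaxes subtract the
row maximum; masked positions get −1e30 logits, giving them exactly zero
weight after normalization.  Weighted shortest-path matrices are
symmetrized by min(D, Dᵀ) to remove float asymmetry from Dijkstra.  Scaled
studies use d_model 64 / 2 layers / 2 heads / batch 32, ffn_mult 2, d_bert
32, projection 32, head (128, 64), lr 1e-3, phases 5/20/5 — these are the
package's desk-scale study conditions, declared once in
`RunConfig.desk_scale()`.

## Known limitations

* Chemistry subset: no stereochemistry, isotopes, multi-fragment SMILES or
  tautomer handling; elements outside the schema map to an "other" slot.
* Binary interaction presence only; interaction-type classification is out
  of scope.
* The importance function and interaction rule are declared, deterministic
  formulas — useful for testing, not statements about pharmacology.
* One pooling level; deeper cluster hierarchies are not implemented.
* The scaffold-hop pool is harvested from the training drugs; with few
  ring-bearing drugs the operator degenerates to identity (logged).
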