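# Methods

## Problem setting

Given a protein known only by sequence and a library of compounds known only
by SMILES, rank the library by predicted probability of binding. The protein
enters the model exclusively through a fixed-length vector of predicted
molecular-function class scores (each in [0, 1]); predicting those scores
from sequence is an upstream concern and an input contract here — the
package consumes the vectors, it does not produce them. The working
hypothesis is that proteins with similar function profiles bind similar
chemistry, which is also what makes zero-shot screening of a target with no
known binders possible.

## Model

**Molecule encoder.** A directed bond-level message-passing network. Atom
features: element one-hot (C, N, O, S, F, Cl, Br, I, P, other), degree
one-hot (0–5), formal charge, aromaticity, attached-H one-hot (0–4). Bond
features: order one-hot (single/double/triple/aromatic), conjugation, ring
membership. Stereochemistry is kept in the canonical SMILES but deliberately
absent from features (2D model). Every bond is stored twice, once per
direction. Hidden states are initialised per directed bond from the source
atom's features concatenated with the bond's features through a learned
linear map + ReLU; each of `depth` steps sums the states of incoming bonds
excluding the reverse bond, applies a learned linear map, and re-adds the
initial state before the activation (skip connection). Bond features are not
updated across steps and atom features re-enter only at the final atom
aggregation — the standard convention for this encoder family. Readout is a
sum by default (mean available). All aggregations are sums, so embeddings
are exactly invariant to atom input order (up to float associativity; tested
at 1e-5, observed ≲1e-12).

`depth = 0` is special-cased to a pure bag-of-atom-projections readout: no
bond information enters the atom stage at all. This makes the degenerate
configuration a clean baseline and matches the single-atom case (which has
no bonds at any depth).

**Prompt hook.** An optional externally supplied vector of hidden size can
be added to every initial bond projection (pre-activation) before message
passing. This preserves the architectural slot used by knowledge-enhanced
pretrained encoders while keeping pretraining itself out of scope. Default
off; never learned here.

**Protein side and fusion.** The function vector f is mapped by a learned
affine projection `f @ W + b` into the encoder's hidden space and fused with
the molecule embedding by elementwise addition (default) or concatenation.
Addition is the default because pilot-scale comparisons of the two modes
favour it slightly; concatenation is retained as a config option for
ablations. The fused vector passes through a feed-forward head (default: one
ReLU hidden layer of 64 with dropout 0.1, then a linear output) to a sigmoid
probability. Dropout is always off at inference; inference is bitwise
deterministic.

**Training.** Binary cross-entropy (from logits, numerically stable
softplus form) with seeded minibatch Adam (default lr 1e-3, batch 128).
Decoys enter as label-0 examples exactly like measured inactives; class
balance is handled through decoy augmentation rather than loss weighting, so
`class_handling="none"` is the default and a `pos_weight` option exists but
is off. Each model carves a scaffold-balanced validation split (default 10%
of molecules) controlled by `split_seed`; an ensemble of three members uses
split seeds s, s+1, s+2 and averages probabilities arithmetically.
Single-class datasets are rejected; a non-finite loss aborts with
diagnostics. Checkpoints are single `.npz` archives holding every weight
array, all configs, the init seed and the training log.

**Autodiff.** No autodiff framework is available in the target environment,
so gradients come from a minimal in-repo reverse-mode tape over NumPy
float64 (`_autograd.py`: matmul, broadcast add/mul, concat, gather,
scatter-add, relu, sigmoid, softplus, reductions). Gradients are verified
against central finite differences both op-by-op and through the full
encoder.

## Curation rules

* Affinity units convert to μM by exact powers of ten (M, mM, μM, nM, pM).
* A (protein, compound) pair is **active** if every reported metric
  (Ki/IC50/EC50/Kd) is below the 50 μM cutoff, **inactive** if every metric
  is above it. A value exactly at the cutoff, or metrics on both sides,
  makes the pair **ambiguous**: excluded from training and logged. The
  boundary case is undefined by the source labeling convention ("below" for
  actives, "higher than" for inactives), so exclusion is the conservative
  choice; the rule is order-independent.
* Decoys are sampled per protein, uniformly without replacement from the
  pool of compounds with measured activity against *some* protein, excluding
  every compound measured against *this* protein (any label, including
  ambiguous). Default ratio 1 decoy per active. An exhausted pool yields all
  remaining eligible compounds plus a logged shortfall.
* Screening-assay inactives can be merged through the same labeled-pair type
  with a per-protein cap (default 2000).
* Censored records ("> 10 μM") are out of scope; the schema takes point
  values only.

**Scaffold-balanced split.** Molecules are grouped by Bemis–Murcko scaffold
(acyclic molecules share the empty scaffold). Groups larger than half the
test-set target count are pinned to train; the cutoff is floored at one
molecule so singleton scaffolds remain placeable when targets are tiny
(without the floor, a 10-molecule split with a test target of 1 would pin
everything to train). Remaining groups are shuffled with the seed and placed
greedily into the partition with the largest remaining deficit (ties resolve
train → val → test; zero-fraction partitions never receive). Fewer scaffold
groups than partitions ⇒ everything goes to train with a warning. Partition
sizes therefore deviate from targets by at most the largest placed group.

## Evaluation

* **EF_α** uses top-k with k = ⌈αN⌉ (guarantees a non-empty window on small
  libraries) over a ranking sorted by probability descending with mol_id
  ascending as the deterministic tiebreak. EF at α = 1 is exactly 1; EF is
  rank-based and thus invariant to monotone rescaling of scores.
* **Confusion at τ** uses the closed rule "predicted positive ⇔ p ≥ τ";
  precision is reported as null when nothing is predicted positive.
* **Global identity** is Needleman–Wunsch (BLOSUM62, gap open 10, gap extend
  0.5, a gap of length L costing 10 + 0.5(L−1)) via Biopython's
  PairwiseAligner; identity = identical aligned columns / full alignment
  length including gap columns; `X` never counts as identical. Values from
  other aligners (e.g. Clustal Omega) will differ slightly and are treated
  as reference context only.
* **Leakage filter**: a test pair (p, m) is removed iff some single train
  pair (p′, m′) has identity(p, p′) × Tanimoto(m, m′) > threshold — the
  per-train-pair product, not the product of separate maxima, because the
  removal unit is a protein–compound *pair*. An exact mode removes test
  pairs whose compound canonical SMILES appears among train compounds.
  Comparison is against all training pairs regardless of label.
* Tanimoto conventions for degenerate fingerprints: all-zero vs all-zero
  := 1.0, all-zero vs non-zero := 0.0 (tiny acyclic molecules at radius 0
  can produce sparse prints; the convention makes the filter conservative
  for identical degenerate pairs).

## Synthetic world

The generator emulates a curated bioactivity collection with a planted,
recoverable signal. Defaults: 4 archetypes, 50 proteins, 400 molecules,
function length 16, Gaussian function noise σ = 0.1, label flip rate 5%.
Fixed conventions chosen once:

* **Fragment grammar.** 20 hand-curated SMILES fragments whose first and
  last atoms are carbons with a free valence, so plain string concatenation
  of any 2–4 fragments is valid SMILES — molecules parse by construction
  without a chemistry dependency at generation time.
* **Archetypes.** Disjoint support blocks of the function vector (values
  uniform in [0.55, 0.95], zero elsewhere), so a linear projection can
  separate them — matching the model's protein-side capacity. Each
  archetype prefers 6 of the 20 fragments; a molecule truly binds a protein
  iff at least half its fragment slots are preferred. Synthetic sequences
  are an 80-residue archetype core with 8% point substitutions, making
  within-archetype identity (~0.85) clearly exceed between-archetype
  identity (~0.15).
* **Affinities.** Binders draw log-uniform from [0.1, 10] μM, non-binders
  from [100, 1000] μM — both labels occur well above 10% frequency and the
  50 μM boundary is avoided by construction, so ambiguity only arises if a
  user moves the cutoff. Records get a random metric and a random unit
  (μM/nM/mM at 60/30/10%), exercising unit normalisation. 80 molecules per
  protein are measured (unbiased by default; the decoy-ablation world
  instead samples records 10:1 in favour of binders, the scarce-negatives
  regime that motivates decoy augmentation). Label flips are realised by
  resampling the affinity from the opposite range, so noise flows through
  the real labeling rule.

What a green test does establish: the full pipeline — curation, decoys,
scaffold-disjoint generalisation, zero-shot transfer through the function
embedding — works end-to-end and beats the random baseline for the stated
reasons. What it does not establish: performance on real chemistry (the
fragment grammar has no synthesizability or property realism), on real
function predictors (whose 489 scores are correlated, not block-disjoint),
or at benchmark scale; published benchmark enrichment values require
external libraries and GPU-scale training and are out of scope.

## Experiment recipes (desk scale)

The recipes in `pipeline.py` use hidden 32 / depth 2, FFN hidden 64, Adam
lr 3e-3, batch 256, 15 epochs — small enough that a 3-member ensemble trains
in ~15 s on one CPU, large enough that held-out EF1% lands around 3–4.
Held-out evaluation screens, per protein, the molecules of a 20% scaffold
test partition (ground-truth planted labels), skipping proteins whose test
library is single-class (EF undefined), and averages EF1% over proteins.
With ~70-molecule test libraries, k = ⌈0.01·N⌉ = 1, so per-protein EF1% is
coarse; averaging over ~50 proteins restores resolution. The zero-shot
recipe holds 2 proteins of the most populous archetype fully out of training
and screens the entire 400-molecule library for them.

## Known limitations

* The NumPy tape is single-threaded and desk-scale; hidden sizes and data
  volumes near the published system (millions of pairs, ~2.6M parameters)
  are out of reach and out of scope.
* The similarity filter is O(test × train) with cached pairwise identities;
  fine for audits at fixture scale, not for millions of pairs.
* Censored affinities, assay-quality weighting and ontology-aware function
  handling are not modelled.
* `sample_decoys` iterates proteins in sorted order; determinism is with
  respect to the same input set, not insertion order.
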