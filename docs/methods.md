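# Methods

## Scope and data model

`p31shift` predicts the ³¹P NMR chemical shift δ (ppm) of molecules
containing exactly one phosphorus atom.  The single-P restriction keeps the
assignment unambiguous: one molecule, one shift.  Internally every molecule
is an undirected graph with explicit hydrogens; descriptors that need
integer bond orders (environment labels, HOSE spheres, substituent keys)
read from a kekulized copy, while aromatic flags are retained for
fingerprints and GNN atom features.  Canonicalization is RDKit's canonical
SMILES; substituent vocabularies and uniqueness counts depend on that
choice, and it is recorded here as the package's fixed convention.

The first-sphere **environment label** is one token per bond incident to P
— neighbor element symbol plus integer bond order — sorted alphabetically
by element and then by order: `C1C1C1` is a phosphine, `O1O1O1O2` a
phosphate, `C1O1O1O2` a phosphonate.  Tokens carry no charge marks; formal
charges do enter substituent keys (below), where a `P–O⁻` and a `P–OH`
fragment must not collide.

## HOSE-code model

Prediction by hierarchical lookup: for a query, the depth-5 spherical
environment code of the P atom is searched in the training index; on a
miss the model falls back to depth 4, 3, 2, 1, and if even depth 1 is
unknown it *abstains* — evaluation counts this as non-coverage, never as a
numeric prediction.  On a hit, the prediction is the unweighted arithmetic
mean of all training shifts stored under that code (duplicates count with
multiplicity).

The sphere serialization is this package's own canonical scheme: the atom
token is element symbol plus charge mark, children at the next
breadth-first shell are serialized recursively and sorted
lexicographically, bond symbols ({`''`,`=`,`#`} after kekulization) prefix
each child, and same-shell ring closures are marked `&`.  It is
deterministic and invariant under atom renumbering — the two properties
the lookup table needs.  It does not attempt byte-compatibility with other
HOSE implementations, and stereochemistry is deliberately not encoded.

The conventional split for this model reserves 60% for training and 20%
for testing, leaving 20% unused so that the test partition is comparable
with the three-way split used by the trainable models.

## Bag-of-Substituents increment models

The increment model assumes additivity: δ = b + Σᵢ aᵢ·nᵢ with nᵢ the count
of substituent i.  Substituents are obtained by cutting every bond
incident to P in the explicit-H kekulized graph; each detached fragment
becomes a canonical SMILES key with dummy-atom attachment markers that
preserve the broken bond's order (`*=O` for the phosphoryl oxygen, `*OC`
for methoxy, `*[O-]` for the oxide anion).  A ring through phosphorus
yields one bivalent key (`*CCCC*`), so Σ count×arity always equals the
number of bonds at P.

Variants: **BoS3** truncates the molecule to atoms at most 3 bonds from P
before extraction, capping opened valences with hydrogens (the least
perturbing cap that keeps valences legal; whether the original pipeline
capped with H, left radicals or kept whole fragments is not documented
anywhere we could check, so capping is our fixed choice).  The
**rare-substituent filter** drops substituents below a minimum total
occurrence count (default 10, measured once on the unfiltered dataset) and
then every molecule that used one; it is a single pass, so surviving
columns can fall below the threshold afterwards.  **Class-restricted**
fits keep a single environment label, e.g. `C1C1C1`.

Because the count matrix is sparse in rare substituents, training uses a
**coverage split**: a greedy pass over substituents in descending rarity
forces one random carrier of every substituent into the training set, and
the remaining molecules are assigned randomly to reach the requested
fractions.  This is the only way to make the fit well-posed, but it leaks
vocabulary information into training and therefore *overestimates*
increment-model performance relative to a fully random split; reports
should carry that caveat.

Fitting is either ordinary least squares (`mlr`), which raises a
collinearity error naming the implicated keys on rank-deficient designs,
or an elastic-net penalized regression (`ridge`) whose mixing parameter
(log-spaced over 1e-10..1) and penalty strength (linear over 0..1) are
selected by 4-fold cross-validation repeated 3 times on validation RMSE.
The default grid is 20×21 points; desk-scale runs use coarser grids, which
only affects how finely the printed ranges are sampled.  Prediction on a
bag containing unseen keys reports those keys and sums over the known
ones — a flagged prediction, not a refusal.

## Fingerprint models

Whole-molecule 1024-bit ECFP6 fingerprints (Morgan radius 3, folded) feed
five regressors: linear (`mlr`), elastic net (`lrr`, same grid as above),
k-nearest neighbors (`knn`, k from 3 to 60), random forest (`rf`, mtry
from 3 to 1000, variance or extra-trees split rule, minimum node size 5)
and gradient boosting (`xgb`, 250–1500 rounds, depth 3, learning rate
0.2–0.4, gamma 2, column subsample 0.8, row subsample 0.5).
Hyperparameters are selected by repeated k-fold CV on validation RMSE
within those fixed ranges; grid densities are configurable (default 10
points per continuous range).  KNN uses Jaccard distance, the standard
choice for binary fingerprints.  All stochastic learners take explicit
seeds.

## Graph neural network

Node features on the hydrogen-collapsed graph, 8 per atom in fixed order:
atomic number, heavy-atom degree, formal charge, chirality code, attached
hydrogen count, hybridization code, atomic mass, aromatic flag.  No edge
features: bond orders never enter the model — the adjacency is unweighted
connectivity only, which the test suite verifies by swapping bond orders
at fixed connectivity.

Architecture: input standardization (fit on training nodes) → `n_pre`
dense layers → `n_mpl` message-passing layers → `n_post` dense layers →
global sum pooling → linear read-out.  Every layer is linear → batch
normalization → PReLU (learnable slope).  A message-passing layer
concatenates a node's own state with the sum of its neighbors' states
(the skip-by-concatenation) before the linear transform; sum aggregation
and sum pooling make the output exactly permutation invariant.  Batch
statistics are taken over the node axis during training and replaced by
running statistics at inference, so predictions are deterministic and
independent of batch composition.  Without the internal batch norm the
deep sum-aggregation stack does not train — activations grow with node
degree at every layer — which is why normalization is part of the
architecture rather than an option.

Defaults are the selected optimum of the architecture search (1
preprocessing layer, 6 MPLs, 2 post-processing layers, 256 hidden
channels); the search space itself is n_pre ∈ {1,2} × n_mpl ∈ {4,6,8} ×
n_post ∈ {1,2} × learning rate ∈ {0.001, 0.01}, 24 configurations ranked
by validation MSE.  Training minimizes MSE with Adam on disjoint-union
batches of 32 graphs; targets are standardized internally and rescaled at
prediction.  The implementation is NumPy/SciPy with hand-written
backpropagation; the test suite checks the analytic gradients of every
parameter tensor against central finite differences.

Desk-scale defaults used by the test suite and the reproduction script:
hidden width 64, 200 training epochs, learning rate 0.01, datasets of
1000–2000 molecules.  These are the package's standard small-problem
settings; the 256-wide, 500-epoch configuration remains the constructor
default for full-scale work.

## Evaluation protocol

Models are compared on seeded 60/20/20 train/validation/test splits with
MAE, RMSE and R².  R² defaults to 1 − SS_res/SS_tot; the squared-Pearson
variant is available because some toolchains report that instead.  HOSE
abstentions are excluded from error metrics and reported as coverage —
values are never imputed.  Per-class breakdowns group by environment
label, pooling everything beyond the n most frequent labels as "Other";
the overall MAE equals the count-weighted mean of per-class MAEs, which
the suite asserts as an identity.

## Synthetic generator

The generator emulates the statistical structure the increment model
assumes, with controlled violations.  A library of 27 common P
substituents (hydride, alkyls, phenyl, vinyl, cyano, fluoroalkyls,
hydroxy/alkoxy/phenoxy, oxide anion, amino, thio, halides, oxo/thioxo,
and two ring diyls) carries hand-chosen signed increments: alkyl donors
negative (methyl −7.5 ppm/group), perfluoroalkyls and electronegative
partners positive (pentafluoroethyl +10.1 ppm/group), intercept b = 20
ppm — magnitudes in the range increment analyses of ³¹P shifts report.
Molecules are assembled by sampling a phosphorus valence class — P(III)
(65%), of which 30% gain a P=O/P=S (`oxo_probability`), phosphonium
cations (25%) and neutral P(V) (10%) — and filling the σ-slots with
Zipf-weighted draws (exponent 1.0), so common substituents dominate and a
long rare tail exists.  The varying valence is chemically realistic *and*
necessary: with a constant substituent count the intercept column would
be exactly collinear with the counts and the increments unidentifiable.

The true shift is δ = b + Σaᵢnᵢ + γ·Σ_{i<j} aᵢaⱼ/10 + N(0, σ²), the
pairwise product term being the simplest non-linearity that degrades
linear fits while leaving lookup-, tree- and graph-based models able to
learn the mapping; the /10 scale keeps interactions comparable to the
increments themselves.  Default conditions: σ = 2 ppm, γ = 0 (additive)
or γ = 0.3 (interaction studies), n = 1000–2000.  Structure sampling and
noise use separate seeded streams, so the same seed yields identical
structures at any noise level — which is how the variance-scaling test
can compare σ = 0 and σ > 0 runs molecule by molecule.

What the generator does **not** emulate: real electronic effects beyond
first-order additivity, solvent and temperature dependence, conformer
effects, measurement digitization errors, and the extreme vocabulary size
of a real database (27 library substituents versus thousands in practice).
Passing tests therefore demonstrate that the algorithms are implemented
correctly and respond to additivity violations as expected — not that the
models reach any particular accuracy on experimental data.

## Numerical choices and degenerate inputs

* Quantiles and the central 95% shift interval use linear-interpolation
  percentiles (NumPy default).
* Unique molecules are distinct canonical SMILES; unique references are
  whitespace-trimmed, case-folded distinct strings.
* Zero-variance targets with nonzero residuals flag R² as NaN rather than
  raising.
* Elastic-net penalty 0 is replaced by 1e-6 (coordinate descent requires a
  positive penalty); the mixing grid's lower end 1e-10 is effectively pure
  ridge.
* OLS rank deficiency is detected by SVD; the error names the columns with
  non-trivial null-space loadings.
* Truncation capping, duplicate bond prevention and valence legality are
  delegated to RDKit sanitization; a truncated subgraph is re-sanitized
  with implicit hydrogens which are then made explicit.
* GNN divergence (non-finite loss) aborts with a diagnostic rather than
  returning a silently broken model.

## Known limitations

* HOSE codes are not byte-compatible with CDK's; indexes built by other
  software cannot be imported.
* The rare-substituent filter is single-pass by design (see above).
* The GNN supports no edge features or attention by construction; that is
  the modeled architecture, not an omission.
* Multi-phosphorus molecules, coupling constants and solvent-conditional
  prediction are out of scope.
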