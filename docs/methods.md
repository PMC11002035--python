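# Methods

## Molecular graphs

SMILES strings are parsed with RDKit into heavy-atom graphs: hydrogens are
counted per atom but never become nodes (the standard molecular-graph
convention), stereo descriptors and isotopes are accepted but do not affect
topology, and multi-component SMILES are kept whole as disconnected graphs
(block-diagonal adjacency) rather than stripped to the largest fragment.
The adjacency matrix is binary and symmetric regardless of bond order; bond
order instead enters the atom-environment signatures below. With self-loops
Ã = A + I and degree matrix D̃ (diagonal entries 1 + degree ≥ 1, so the
inverse square root always exists), the propagation matrix is
Â = D̃^(-1/2) Ã D̃^(-1/2), symmetric with spectrum in [-1, 1].

## Atom environments and initial features

The model's one structural hyperparameter besides depth is the environment
radius r. An atom's radius-0 signature is the tuple (element, formal charge,
aromaticity); its radius-r signature prepends that tuple to the sorted
multiset of (bond order, neighbor radius-(r-1) signature) pairs. Sorting
makes signatures independent of atom input order, so isomorphic molecules
receive identical signature multisets. A vocabulary maps signatures to dense
integer ids; id 0 is reserved for environments never seen while the
vocabulary was growing. In the hold-out protocol the vocabulary is built on
the training fold only and then frozen, so test-fold atoms with novel
environments fall back to the unknown id — this prevents information leaking
from test to train through the embedding table. H^(0) is the embedding row
of each node's id; this "embedding indexed by r-radius subgraph" reading is
the standard way a radius hyperparameter acts in molecular GNNs, and is a
design choice of this package (alternatives such as one-hot element features
would ignore the radius entirely).

## Classifier and training

Defaults: radius 1, L_g = 6 graph layers, L_f = 10 fully connected layers,
hidden width d = 50, batch size 4, learning rate 1e-4 multiplied by 0.99
every 10 epochs, 1000 epochs, 70% of the data for training. Width d and the
activation are not pinned down by the published schedule; d = 50 keeps a
single CPU run around a minute, and the rectifier is the field default.

Decisions where the published description is open, and why:

- **Output head and loss.** The loss is the mean squared error, but for a
  two-class problem MSE needs a target convention. We use a linear two-unit
  output, a normalized-exponential (softmax) transform to probabilities, and
  MSE against one-hot targets averaged over all 2m components of an m-sample
  batch. This keeps scores in [0, 1] so the positive-class probability can
  feed the ROC sweep directly.
- **Readout.** Arithmetic mean over node vectors: size-invariant, and the
  prediction for a graph containing k identical disconnected copies of a
  molecule equals the single-copy prediction (tested).
- **Iteration = epoch.** One iteration is one full sweep over the training
  set in batches of 4, with the last short batch kept. The epoch order is
  reshuffled each epoch from a seeded generator separate from the
  initialization stream.
- **Optimizer.** Plain SGD. The only schedule specified is the multiplicative
  decay, which is meaningful exactly for SGD; adaptive optimizers would
  absorb it.
- **Initialization.** Seeded uniform with rectifier-preserving (He) scaling,
  ±sqrt(6/fan_in) per weight matrix, unit-variance uniform embedding rows,
  zero biases. With sixteen rectified layers between embedding and output,
  variance-averaged (Glorot) scaling attenuates the forward signal and the
  gradients so strongly that the small fixed learning rate cannot recover
  within the epoch budget; He scaling is the standard pairing with rectifiers
  and keeps both signal and gradient magnitudes O(1) through the stack.
- **FC stack shape.** Ten d→d rectified layers followed by the d→2 output
  map; whether the output map counts as one of the ten is unknowable from
  the published description, so it is configurable.

Backpropagation is hand-written NumPy. Within a mini-batch the member graphs
are stacked block-diagonally so each propagation layer is a single matrix
product; the mean readout becomes one segment-mean matrix, and its transpose
routes gradients back to nodes. Gradient correctness is enforced by a
central-difference check (relative tolerance 1e-4) in the test suite.

## Evaluation

All metrics are computed from the 2×2 confusion matrix without external
libraries. Precision, recall and F are reported as percentages rounded to
two decimals, AUC as a fraction to four — matching the usual print format of
hold-out tables. Zero-denominator cases (e.g. no predicted positives) return
0 with a logged warning rather than NaN, so multi-run aggregation never
drops a run. The ROC sweep uses "predict positive iff score ≥ threshold"
over descending distinct scores with ties collapsed to one threshold; with
this convention the trapezoidal AUC is exactly the pairwise statistic
P(s⁺ > s⁻) + ½P(s⁺ = s⁻), and the test suite asserts that identity to 1e-12
against a brute-force pairwise oracle (and against scikit-learn as an
independent implementation).

## Hold-out protocol

Each run shuffles the records with its own seed and takes the first
⌊0.7·n⌋ for training (243/105 at n = 348) — floor rounding, not stratified,
so per-run class balance varies as it does in practice. Runs retrain from
scratch with seed = base + run index. The summary table averages per-run
precision/recall/F1/AUC and rounds like the per-run reports; runs whose test
fold is single-class record AUC as missing and are excluded from the AUC
mean only.

## Synthetic data

The generator assembles molecules by concatenating fragments from a fixed
grammar (alkyl chains, branch points, ethers, amines, alcohols, halides,
carbocycles and benzene rings), 2–5 fragments per molecule, capped at 30
heavy atoms. Positives additionally receive one carbonyl-bearing fragment
(ketone, aldehyde or ester); negatives are built from carbonyl-free
fragments, and every candidate is audited with an independent SMARTS
substructure match ([#6]=[#8]) so accidental motif creation or loss is
rejected. Defaults are 174/174 — a balanced 348-molecule set — with label
noise 0; a noise fraction can flip labels independently to study graceful
degradation. Every emitted SMILES is canonicalized and re-parsed.

What this emulates and what it does not: the generator reproduces the
*composition* (balanced binary labels over small organics) and the
*learnability regime* of a curated bioactivity set, but its label is a
single-substructure rule — far easier than real structure–activity
relationships, with no activity cliffs, no scaffold bias, no measurement
noise unless requested. Passing the learnability check therefore shows the
pipeline can extract a genuine structural signal end to end; it says nothing
about accuracy on real fruit-quality chemistry.

## Numerical and degenerate-case choices

- All arithmetic in float64; probabilities sum to 1 within 1e-9.
- Softmax is computed with max-subtraction for stability.
- Argmax ties (score exactly 0.5) resolve to the negative class.
- Single-atom molecules are valid graphs (Â = [[1]]).
- Unparseable SMILES raise a named error at the parsing layer; the
  experiment layer drops them with a logged count before splitting, and the
  batch scorer reports per-record failures.
- Dataset files reject non-binary labels and malformed rows with line
  numbers.

## Problem sizes

The packaged demonstrations and the acceptance script use the default
348-molecule dataset; ten hold-out runs at the default 1000-epoch schedule
take about ten minutes on one CPU (one run ≈ 63 s). Unit tests use reduced
widths/depths (d = 8–16, 2–3 layers, ≤ 200 epochs) chosen to finish in
seconds while still demonstrating separation on planted-motif data.

## Known limitations

- Bond order does not enter the adjacency (only the signatures), so the
  propagation cannot distinguish, e.g., butadiene from butane topologically;
  this mirrors the binary-adjacency formulation the package implements.
- The unknown-environment id gives novel test atoms a shared embedding; a
  test molecule made entirely of unseen environments carries no usable
  signal.
- Mean readout dilutes small-motif signal in very large molecules.
- No regularization, early stopping or validation-based model selection:
  the protocol trains for a fixed epoch count and evaluates once, by design.
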