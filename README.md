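# molgcn

Graph-convolutional binary classification of small molecules from SMILES
strings, with every evaluation primitive built from first principles.

The scientific setting: given a collection of small organic compounds, each
labeled by whether it has a positive effect on a property of interest (the
motivating application is fruit-quality chemistry — pigments and flavor
compounds versus inert or detrimental molecules), learn to predict the label
from molecular structure alone. The package is for computational chemists and
method developers who want a transparent, dependency-light reference pipeline:
every matrix, metric and gradient is inspectable NumPy, with RDKit used only
to read SMILES.

## The model

A molecule parses to a heavy-atom graph with adjacency matrix **A**
(A<sub>ij</sub> = 1 iff atoms *i*, *j* are bonded, any bond order). With
self-loops Ã = A + I and its degree matrix D̃, each of L<sub>g</sub> graph
layers propagates node features by

    H^(l+1) = σ( D̃^(-1/2) Ã D̃^(-1/2) H^(l) W^(l) )

with rectifier σ. Node identity comes from a radius-r atom-environment
vocabulary: each atom's initial feature H^(0) is a learned embedding row
indexed by its (element, charge, aromaticity) plus the sorted multiset of its
bonded neighborhood out to r bonds. The node matrix is pooled by an
arithmetic mean into one graph vector, passed through L<sub>f</sub> fully
connected rectified layers and a linear two-unit map, and normalized to class
probabilities. Training minimises the mean squared error against one-hot
targets with plain SGD; the default schedule is radius 1, 6 graph layers, 10
fully connected layers, batch size 4, learning rate 10⁻⁴ decaying by 0.99
every 10 epochs, 1000 epochs.

Evaluation is written from scratch: the 2×2 confusion matrix; precision,
recall and FPR/TPR; the weighted harmonic mean
F<sub>α</sub> = (α²+1)·P·R / (α²·P + R); the ROC curve as a threshold sweep
over descending distinct scores; and AUC as its trapezoidal area (provably
equal to the pairwise probability that a positive outscores a negative).
The experiment layer runs repeated random 70/30 hold-out splits — vocabulary
built on each training fold only — and aggregates a per-run table with a
mean row.

Because curated bioactivity labels are not redistributable, the
`synthetic_data` module generates balanced datasets (174 positive / 174
negative by default) from a fragment grammar with a planted carbonyl motif,
so the full pipeline is exercisable end to end with a label that is a pure
function of structure.

## Worked example

```python
from molgcn import GeneratorConfig, TrainConfig, generate_dataset, run_experiment

records = generate_dataset(GeneratorConfig(n_pos=50, n_neg=50, seed=7))
config = TrainConfig(hidden_dim=16, graph_layers=3, fc_layers=2,
                     iterations=200, learning_rate=1e-2, seed=0)
result = run_experiment(records, config, run_seed=0)
```

This trains on 70 molecules and evaluates on the held-out 30, printing (see
`examples/train_and_evaluate.py`):

```
train / test molecules: 70 / 30
training loss:          0.3017 -> 0.0141
precision: 88.24%
recall:    93.75%
F1:        90.91%
AUC:       0.9732
```

The loss falling from 0.30 to 0.014 shows the fit converging; precision says
88% of the molecules predicted active are truly active, recall says 94% of
the truly active molecules were found, and AUC 0.97 means a randomly chosen
positive outscores a randomly chosen negative 97% of the time. The
`examples/` directory has one short script per capability (parsing and graph
inspection, metric arithmetic, dataset generation, repeated hold-out tables).

A thin CLI mirrors the library:

```
molgcn molparse "C[C@H](CCC=C(C)C)CC=O"
molgcn make-synthetic --out data.csv --seed 1
molgcn run-experiments --data data.csv --runs 10 --seed 7 --outdir results/
```

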