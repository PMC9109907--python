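# phagoscreen

Dose-conditioned prediction of a compound's effect on glial phagocytosis
from its molecular structure.

Excessive synaptic pruning by glial cells is implicated in the grey-matter
loss seen in schizophrenia, and high-throughput phenotypic screens hunt for
compounds that tone that phagocytic activity down. `phagoscreen` is a
library (plus a thin CLI) for the computational side of such a screen:
turning raw plate readouts into a labeled dataset, quantifying the chemical
diversity of the screened library, training structure-based models that
predict the phenotypic outcome of a (compound, dose) pair, evaluating them
with the care an imbalanced screen demands, and finally running a trained
model over a new library to shortlist repurposing candidates.

## The model

A screened instance is a pair of a compound *c* (a SMILES string, parsed
into a molecular graph *g* = (*V*, *E*, **X**, **E**) with 37-dimensional
atom features and 6-dimensional bond features) and a dose *d* ∈ {1.39,
2.78, 5.56, 11.11, 22.22} μM. Prediction factorizes into a compound
embedding module and an output module:

    h_c = f_comp(c)        o = f_out(h_c, d)

where the dose is concatenated to the embedding (rescaled to [0, 1] over
the training dose ladder) and *o* scores the three outcome classes
*increase phagocytosis*, *no change*, *decrease phagocytosis*. Seven named
configurations pair an embedding family with a head:

| name   | f_comp                                   | f_out         |
|--------|------------------------------------------|---------------|
| MoRF   | static ECFP (Morgan, r=3, 1024 bits)     | random forest |
| MoNN   | static ECFP                              | MLP           |
| LinNN  | per-atom MLP + readout (topology-blind)  | MLP           |
| SAGENN | GraphSAGE message passing                | MLP           |
| GaNN   | graph attention message passing          | MLP           |
| ENN    | bond-conditioned convolution             | MLP           |
| NeFPNN | neural fingerprint (bond-feature sums)   | MLP           |

Labels come from the plate-median-normalized signal β: *increase* if
β ≥ 130%, *decrease* if β ≤ 70%, *no change* between. Because *no change*
dominates (~81% of instances), MLP heads are trained with cross-entropy
under per-epoch majority undersampling, and models are compared by
macro-AUROC = (1/c) Σᵢ AUROCᵢ over an 80/20 development/test split with
3-fold stratified cross-validation (simple: by label; complex: by label ×
molecule size × dose). The neural layers run on a small numpy autodiff
core shipped with the package — no GPU stack required.

The real screen behind this problem is unpublished, so the package ships a
synthetic-screen generator (`phagoscreen.synthdata`) that reproduces its
statistical shape — five-dose ladder, 81/9/10 class marginal — and plants
structure–activity–dose rules on ring substitution patterns (ortho / meta /
para), which are invisible to any bag-of-atoms model by construction. That
gives every stage of the pipeline a ground truth to be tested against.

## Worked example

```python
import numpy as np
import phagoscreen as ps
from phagoscreen.evaluate import SplitPlan, grid_search, make_split
from phagoscreen.models import ModelSpec

library = ps.generate_library(150, seed=42)                 # synthetic library
dataset = ps.build_dataset(ps.plant_screen(library, seed=42))
print(len(dataset), dataset.class_counts())
# 750 {'increase': 78, 'no_change': 590, 'decrease': 82}

plan = make_split(dataset, SplitPlan(holdout_fraction=0.2, k=3, seed=42))
gat = ModelSpec.named("GaNN", layers=2, hidden=32, head_hidden=[32],
                      readout="sum", epochs=60, seed=42)
report = grid_search(gat, {"lr": [1e-3, 3e-3]}, dataset, plan)
print(report.chosen_params, round(report.valid_auroc_mean, 4), round(report.test_auroc, 4))
# {'lr': 0.003} 0.7139 0.6759
```

The attention model reaches a validation macro-AUROC of 0.71 and a held-out
test score of 0.68 on this small 150-compound screen, well above chance on
a 3-class problem where 79% of labels are *no change*; the topology-blind
`LinNN` baseline lands near 0.5 on the same split because the planted
effects live in ring substitution patterns its bag-of-atoms embedding
cannot see. At the full study size (500 compounds, `examples/`), the gap
widens to ≈0.95 vs ≈0.53.

The `examples/` directory holds one short script per capability: diversity
analytics, screen labeling, training/evaluation, and virtual screening with
dose-consolidated outcomes and an ATC level-1 tally. The `phagoscreen` CLI
exposes the same stages (`synthdata`, `label`, `diversity`, `train`,
`evaluate`, `screen`).

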