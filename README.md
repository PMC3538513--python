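# chemvs

Ligand-based virtual screening for kinase-inhibitor discovery.

Virtual screening triages a large compound library so that only a small,
enriched fraction goes to assay. `chemvs` implements a descriptor-based
workflow aimed at screens where very low false-hit rates matter: each
molecule is featurized into a fixed vector of 98 1D/2D descriptors (simple
counts, Sanderson electronegativity / polarizability / ALogP, topological
connectivity and shape indices, Kier–Hall electrotopological-state sums); a
putative non-inhibitor training set is generated — without any experimentally
confirmed inactives — by clustering the library into chemical-space families
and taking representatives of every family containing no known active; and
four screening engines are trained and compared on equal footing:

* a hard-margin SVM with RBF kernel K(xᵢ,xⱼ) = exp(−‖xⱼ−xᵢ‖²/2σ²),
  decision f(x) = sign(Σᵢ αᵢ⁰yᵢK(x,xᵢ) + b), defaults c = 100,000, σ = 1.2;
* Tanimoto similarity search on min–max-scaled descriptor vectors,
  sim(i,j) = xᵢ·xⱼ/(‖xᵢ‖² + ‖xⱼ‖² − xᵢ·xⱼ), hit cut-off 0.9;
* k-nearest-neighbour voting (Euclidean distance, default k = 1);
* a probabilistic neural network: Bayes rule over Gaussian Parzen class
  densities fᵢ(x) = (1/nᵢ) Σ exp(−Σⱼ((xⱼ−xᵢⱼ)/σⱼ)²), default σ = 0.02,
  computed in the log domain.

Performance is reported as sensitivity SE = TP/(TP+FN)·100, specificity
SP = TN/(TN+FP)·100, overall accuracy Q, and the Matthews correlation
C = (TP·TN − FN·FP)/√((TP+FN)(TP+FP)(TN+FN)(TN+FP)) under stratified 5-fold
cross-validation, and at the screening level as yield TP/(TP+FN), virtual-hit
rate, the false-hit-rate upper bound FP/(TP+FP), and a compound-family
novelty analysis (which hits fall outside the families covered by training
actives). See `docs/methods.md` for every formula and convention.

Audience: cheminformaticians and method developers who want a transparent,
fully seeded reference implementation of this screening workflow, including
a synthetic descriptor-space generator that makes every stage testable
without proprietary compound collections.

## Worked example

Featurize a molecule and inspect descriptors by registry name:

```python
from chemvs import parse_smiles, compute_descriptor_vector

vec = compute_descriptor_vector(parse_smiles("CCO", "ethanol"))
for name in ("nC", "nO", "MW", "Wiener", "Chi1v", "SsOH", "ALogP"):
    print(f"{name:8s} {vec[name]:.4f}")
```

```
nC       2.0000
nO       1.0000
MW       46.0690
Wiener   4.0000
Chi1v    1.0233
SsOH     7.5694
ALogP    -0.0014
```

`MW` is the average molecular weight including attached hydrogens; `Wiener`
the half-sum of topological distances (4 for the 3-atom path); `Chi1v` the
first-order valence connectivity index; `SsOH` the E-state sum of the
hydroxyl oxygen, 6 + 4.5/4 + 4/9 ≈ 7.57 — the intrinsic state of the oxygen
plus the perturbations from the two carbons.

End-to-end on a synthetic library from the command line (50 actives in 2
compound families, 2,000 putative inactives in 8 families, near-separable):

```bash
chemvs simulate --n-active 50 --n-inactive 2000 --seed 1 --out lib.tsv
chemvs crossval --in lib.tsv --engine svm --seed 1 --out cv.txt
```

```
| fold | TP | FN | SE | TN | FP | SP | Q | C |
|---|---|---|---|---|---|---|---|---|
| 1 | 10 | 0 | 100.00% | 400 | 0 | 100.00% | 100.00% | 1.000 |
| 2 | 10 | 0 | 100.00% | 400 | 0 | 100.00% | 100.00% | 1.000 |
| 3 | 10 | 0 | 100.00% | 400 | 0 | 100.00% | 100.00% | 1.000 |
| 4 | 10 | 0 | 100.00% | 400 | 0 | 100.00% | 100.00% | 1.000 |
| 5 | 10 | 0 | 100.00% | 400 | 0 | 100.00% | 100.00% | 1.000 |
| Average | | | 100.00% | | | 100.00% | 100.00% | 1.000 |
| SD | | | 0.0000 | | | 0.0000 | 0.0000 | 0.0000 |
| SE | | | 0.0000 | | | 0.0000 | 0.0000 | 0.0000 |
```

Each fold holds out 10 actives and 400 inactives; on this well-separated
library the hard-margin SVM classifies every held-out compound correctly, so
all five folds sit at SE = SP = Q = 100% and C = 1. On harder (less
separated) libraries the per-fold rows and the SD row become informative.
Other subcommands: `featurize`, `cluster`, `make-negatives`, `train`,
`screen` (which reports yield, hit rate, the false-hit bound and family
novelty), and `report`.

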