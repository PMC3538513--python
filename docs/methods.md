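# Methods

`chemvs` implements a ligand-based virtual-screening workflow for
kinase-inhibitor discovery: molecules are featurized into a fixed vector of
98 one- and two-dimensional descriptors, a putative-negative training set is
constructed by clustering a compound library into chemical-space families,
and four classification engines (hard-margin RBF-SVM, Tanimoto similarity
search, k-nearest-neighbour, probabilistic neural network) are trained and
compared with cross-validated sensitivity/specificity/accuracy/Matthews-C
statistics and screening-level yield and false-hit-rate bounds.

## Molecular graphs and descriptors

All descriptors are pure functions of a hydrogen-suppressed molecular graph
(element, formal charge, attached-H count and aromaticity per atom; order
and aromaticity per bond). RDKit performs parsing and aromaticity
perception; multi-fragment inputs keep the largest fragment, since salts and
counterions carry no information for this featurization.

The 98 descriptors split into four classes (18 simple + 3 chemical + 35
connectivity/shape + 42 electrotopological state) in a fixed registry order.
Where a descriptor family admits several published parameterizations, the
convention used here is:

* **Simple properties.** "Number of bonds" includes bonds to suppressed
  hydrogens; "number of non-H bonds" does not. Ring counts use the minimum
  cycle basis (the smallest-set-of-smallest-rings analogue). Rotatable bond:
  single, non-ring, both atoms non-terminal, excluding amide C–N. H-bond
  donor: N/O with at least one attached H; acceptor: N/O not positively
  charged. Molecular weight sums average atomic masses including attached
  hydrogens.
* **Chemical properties.** Total Sanderson electronegativity is the sum of
  carbon-relative Sanderson values over all atoms including hydrogens;
  polarizability sums CRC static atomic polarizabilities; ALogP delegates to
  RDKit's Crippen atom-contribution model. An element missing from a
  parameter table contributes zero and logs a warning — descriptors stay
  finite.
* **Connectivity and shape.** Handbook definitions (Schultz and Gutman MTI,
  Wiener, Harary, Balaban J, Kier–Hall valence connectivity and kappa shape
  indices, solvation connectivity, Petitjean shape coefficient,
  centralization `2W − n·min-row-sum`). Three indices whose
  parameterization varies across sources are fixed as: gravitational index =
  Σ_{i<j} m_i m_j / d_ij² on topological distances (the 2-D analogue of the
  3-D mass–distance index); Pogliani index = Σ Z_v/N (valence electrons over
  period); logP-from-connectivity = 0.950·¹χᵛ − 1.480, a classic
  single-variable linear calibration. Any index whose formula divides by a
  vanishing path or distance count (single-atom graphs) is emitted as 0,
  never NaN, so downstream linear algebra stays total.
* **E-state.** Intrinsic state I = ((2/N)²δᵛ + 1)/δ with δᵛ = Zᵛ − h;
  perturbation ΔI_ij = (I_i − I_j)/(d_ij + 1)² over all heavy-atom pairs
  (bonded atoms therefore use 2² = 4, which makes the ethanol hydroxyl
  E-state 7.569). Formal charges are ignored in δᵛ. The 24 per-type sums use
  canonical bond-pattern atom types; the registry labels `SsssC` and `SaOH`
  denote the quaternary-carbon and aromatic-oxygen patterns respectively,
  and charge-separated nitro nitrogens are typed `ddsN`. Hydrogen E-states
  are computed on the H-augmented graph with I(H) = 5 (the same intrinsic
  formula at N = 1, δ = δᵛ = 1); each hydrogen is typed by its parent heavy
  atom, with `HCsats`/`HCsatu` distinguishing saturated carbons without/with
  an unsaturated neighbour and `Havin` collecting the remaining
  environments. Because all hydrogens share one intrinsic value, H–H
  perturbations cancel exactly.

## Chemical space, families and putative negatives

Descriptors are min–max scaled to [0,1] against a named reference library;
constant columns map to 0 and out-of-reference values are clipped.
Similarity between scaled vectors uses the continuous Tanimoto coefficient
sim(i,j) = x_i·x_j/(|x_i|² + |x_j|² − x_i·x_j), with a default hit cut-off
of 0.9 (the stricter end of the customary 0.8–0.9 range). The coefficient is
left undefined (an error) when both vectors are all-zero.

Compound families are k-means clusters in the scaled space with seeded
k-means++ initialization, so a given (matrix, k, seed) always yields the
same partition. Putative negatives are drawn from every family containing no
known active: the `per_family` members nearest the family centroid (default
2, ties broken by id) are taken as representatives. The rationale is that
undiscovered actives occupy a small fraction of the active-free families, so
the induced label noise is well below what a hard-margin SVM tolerates; this
is a data-dependent argument, documented rather than asserted.

## Engines

* **SVM**: RBF kernel exp(−‖x−x′‖²/2σ²), defaults σ = 1.2 and margin
  parameter c = 100,000 — an essentially hard margin. scikit-learn's SMO
  solver computes the dual; the trained state is extracted (support vectors,
  αᵢ⁰yᵢ, bias) and the decision value is always re-evaluated from those
  coefficients. Dual feasibility (0 ≤ αᵢ ≤ c, Σαᵢyᵢ ≈ 0) is checked on
  construction.
* **kNN**: Euclidean distance, majority vote, default k = 1; distance ties
  break by training index.
* **PNN**: per-class Gaussian Parzen densities with shared smoothing width
  σ (default 0.02; per-descriptor widths supported), equal priors and
  costs. Per-class 1/nᵢ normalization is the default — with strong class
  imbalance the unnormalized summation layer degenerates to the majority
  class — and the raw variant is available. All accumulation is in the log
  domain: at σ = 0.02 in 98 dimensions individual kernel terms underflow
  double precision, and log-sum-exp keeps the class comparison exact (the
  σ→0 limit then provably agrees with 1-NN).
* **Tanimoto screen**: a library row is a hit when its best similarity to
  any training active exceeds the cut-off.

Every engine resolves an exact decision tie to the non-inhibitor class: a
tie is no evidence of activity, and screening errs conservative. The engine
wrapper fits the scaling model on the training split only and applies it to
queries, so all four methods see identical inputs. Hyperparameters can be
selected by maximizing mean cross-validated Matthews C over a user grid.

## Evaluation

SE = TP/(TP+FN)·100, SP = TN/(TN+FP)·100, Q = (TP+TN)/total·100 and the
Matthews coefficient with the √((TP+FN)(TP+FP)(TN+FN)(TN+FP)) denominator;
C is reported as undefined (not 0) when a marginal vanishes.
Cross-validation uses a stratified random 5-way split (stratification is a
deliberate choice: at ~40:1 imbalance an unstratified fold can lose the
minority class; the unstratified mode remains available). Summary rows
report the mean, the ddof=1 standard deviation of the five fold values on
the proportion scale, and SD/√5. Report rendering rounds percentages to two
decimals and C to three; internal values keep full precision.

Screening metrics treat every hit outside the known-active set as a false
positive, so the reported false-hit rate FP/(TP+FP) is an upper bound — in
an unlabelled library some hits may be undiscovered actives. The
family-novelty analysis counts hits whose family contains no training
active, and reports the fraction of members predicted positive within each
training-active family, the check that a classifier is recognising activity
rather than family membership.

## Synthetic study conditions

The generator emulates the structure the method assumes about chemical
space: compound families are spherical Gaussians in descriptor space, with
actives confined to a few families. Defaults: 50 actives in 2 families,
2,000 inactives in 8 families, 98 dimensions, per-coordinate spread 0.05 and
minimum centroid separation 3.0 on the unit cube — about ten times the
within-family point scale, i.e. a near-separable library sized to run the
full pipeline in seconds on one core. The decoy screen (10,000 rows) adds
unseen families: 70% far from everything in training, 30% in shells at
0.4/0.7/1.0 × separation around the active centroids but closer to their
seeding active family than to any training negative family — the analogue of
a similar-compound subset, the harder screening condition. Under these
conditions nearest-neighbour-type engines flag every near-active decoy
family while the RBF-SVM's decision decays to its (negative) bias far from
the training data, which is exactly the mechanism by which the SVM attains
a lower false-hit bound at matched yield.

What the synthetic data does not emulate: real descriptor distributions are
heavy-tailed, correlated and partly discrete; family structure in real
libraries is neither spherical nor equally sized; and activity cliffs place
actives and inactives in the same family. Passing the synthetic acceptance
checks therefore demonstrates correctness of the machinery and the expected
qualitative ordering of the engines, not screening performance on real
libraries.

## Numerical and degenerate-input conventions

Descriptor degeneracies map to 0 (never NaN); the Tanimoto coefficient on
two zero vectors raises; k-means drops empty clusters with a warning and
renumbers; a cross-validation split that loses a class raises with advice to
stratify or reseed; PNN densities are log-domain throughout; all randomness
(generator, k-means, fold shuffling) flows from explicit integer seeds and
repeated runs are bit-identical.

## Known limitations

Descriptor values follow the documented conventions above and will not
numerically match other descriptor packages where published
parameterizations differ (aromaticity model, E-state H formulation,
gravitational/Pogliani/logP-from-connectivity parameters). Total path counts
enumerate all simple paths and can be slow on dense polycyclic graphs far
outside the drug-like regime. The family-count default in real screens (the
thousands of families appropriate to multi-million-compound libraries) is a
scale this package's tests deliberately down-size to k ≤ 20.
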