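# Methods

This note records the modelling choices, parameter meanings and numerical
conventions behind `ptmlkit`, in the spirit of a model-description
appendix. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Molecular graphs and weight schemes

SMILES are parsed with RDKit; the working representation is the
hydrogen-suppressed graph (heavy atoms as vertices, bonds as edges).
Multi-fragment SMILES are rejected — salt stripping and charge
neutralization are upstream curation concerns, not parser behaviour.
Bond multiplicity is stored but never inflates `NB`, the bond count: an
aromatic bond is one edge both in `NB` and in the line graph.

Atom-level quantities: the vertex degree `delta` is the heavy-neighbour
count; the valence delta is the Kier–Hall convention, `Zv - h` for
second-row elements and `(Zv - h)/(Z - Zv - 1)` for higher rows (`Zv`
valence electrons, `h` attached hydrogens). Note the higher-row correction
can push `delta_v` below `delta` (chlorine: 7/9); only second-row
heteroatoms satisfy `delta_v >= delta`.

Five physicochemical weight schemes are built in. `Hyd` and `Mol` use the
Wildman–Crippen per-atom logP and molar-refractivity contributions, `Psa`
the Ertl TPSA contributions, `Gas` Gasteiger–Marsili partial charges, and
`Ato` atomic masses — all through RDKit, so the contribution tables are
the published ones those methods define. Bond weight is fixed as the
arithmetic mean of the two endpoint atomic contributions and sits on the
diagonal of the bond-adjacency matrix. Bit-compatibility with legacy
descriptor programs is a non-goal; the contract is the structure-level
identities the tests verify (trace identities, oracle equality,
permutation invariance).

## Topological indices

`SM(w)k` is the trace of the k-th power of the weighted bond-adjacency
matrix; `SM(w)0 = NB`. Orders up to 15 are supported, 1–6 exported by
default. Closed walks of length k traverse specific bond patterns, which
is why low-order moments are conventionally described in terms of path /
cluster / ring fragments of k bonds; the implementation computes the
matrix trace directly and does not split a moment into per-class parts.

Connected edge-subgraphs of 1–6 edges are enumerated once per molecule
with Wernicke's ESU algorithm on the line graph (each subset generated
exactly once from its minimum-index edge) and shared by all chi families.
Classification uses subgraph-internal degrees: trees with maximum degree
<= 2 are paths (P); trees with a branch vertex and no degree-2 vertex are
clusters (C); trees with both are path-clusters (PC); subsets containing
a cycle are chain/ring (Ch). An order-m chain subgraph is counted only
when it *is* an m-edge cycle (all internal degrees 2); cyclic subsets
with pendant edges are classified Ch but not counted at any order, so a
six-membered ring contributes one order-6 chain subgraph and none at
order 5. Chi terms use parent-graph degrees (atom form), valence deltas
(valence form) or edge degrees `epsilon = delta(u) + delta(v) - 2` (bond
form). The degenerate single-bond molecule has `epsilon = 0`; its bond-chi
term contributes 0 with a logged warning — such molecules sit below any
realistic curation floor. Normalized indices divide by `NB` exactly, so
`NTI * NB = TI` holds to machine precision.

## Curation, labeling, splitting

Rows lacking SMILES, value or units, non-IC50 endpoints and non-positive
values are dropped with per-reason logging; micromolar rows are converted
(x1000) to nM before unit filtering (configurable off). Duplicates share
a (molecule, tp, ai) key after the assay columns are merged into the
assay-information string; the survivor has the minimum IC50, ties keeping
the first-seen row. Activity uses the inclusive cutoff IC50 <= 150 nM.
The split sorts each protein's cases by increasing IC50 (ties broken by
molecule id for determinism) and tags the repeating pattern training,
training, training, test — approximately 3:1, with the most potent
chemistry guaranteed in training.

## Condition-perturbation transform

The reference is fit on the training split only: per-element means
`avg[TBI]cj` over training actives (elements are the protein labels and
the assay-information labels, handled separately), and one standard
deviation per descriptor over all training cases — the sample form
(n-1), an immaterial but documented choice. Zero-variance descriptors are
dropped with a log message. The a-priori probability is pluggable; the
default is the dataset frequency of the element (cases annotated with it
divided by all cases), the convention of the PTML literature this
transform comes from. Training cases are transformed with the same frozen
reference (no leave-one-out). Two properties pin the implementation down:
the mean D over a given element's training actives is exactly zero, and
rescaling any raw descriptor by a positive constant leaves every D value
unchanged. Group means are computed on contiguous array copies so the
reference is bitwise independent of the caller's memory layout.

## Feature selection

Mutual information between a discretized descriptor and the class label,
in bits, with equal-frequency binning (ceil(sqrt(n)) bins capped at 10;
columns with few distinct values keep them as bins so a label-copy scores
the full prior entropy). This discrete estimator is a documented stand-in
serving the ordering role of entropy-based relevance ranking; no bias
correction is applied. The redundancy filter is a greedy pass in rank
order keeping a descriptor only when every Pearson correlation with the
already-kept set lies strictly inside (-0.7, +0.7), stopping at 15 kept
(both configurable). Ties in score are broken alphabetically so the
ranking is a total order and row-permutation invariant.

## Classifier search

The primary learner is scikit-learn's single-hidden-layer `MLPClassifier`.
Candidates are (H, activation) pairs with H in 15–70 by default and
activations {logistic, tanh} — the hyperbolic-tangent and logistic units
of the classical MLP toolkits; an exponential hidden unit is not offered
by the backend and is omitted from the candidate set. Every candidate
must satisfy `rho = T/[(I+1)H + (H+1)O] > 3` with `O = 2` (one output per
class); infeasible topologies are never trained, and the search errors
out when no H qualifies, advising a smaller hidden range. Candidates are
scored by the mean of training and test nMCC (Sn/Sp floors can be layered
on top); the budget parameters default to the published protocol (3000
candidates, 250 retained, 500 epochs), while the pipeline defaults scale
the search to 6 candidates and 300 epochs — sizes chosen so a full run on
~2000 cases completes in seconds on one core without changing the method.
Everything is seeded: candidate sampling and per-fit initialisation
derive from one `numpy` generator, so a fixed seed reproduces the bundle
exactly. The prediction threshold is 50% on the active-class probability.
LDA, SVM (RBF) and random-forest adapters reuse the same evaluation path
for side-by-side comparison; they are deliberately thin.

Metrics come from the confusion counts: Sn = CC_active/N_active,
Sp = CC_inactive/N_inactive (percent), accuracy over all cases, Matthews
correlation from the four counts with a degenerate denominator mapped to
MCC = 0, and the normalization `nMCC = (MCC + 1)/2` placing a random
predictor at 0.5. Local metrics repeat the computation within each
protein or assay group; a group with no actives reports the sensitivity
as not-applicable rather than a silent zero.

## Applicability domain

Closed intervals [min, max] per selected D descriptor, fit on the
training split. A query earns one local score per descriptor inside its
interval (boundary inclusive — "inside" is read as closed, so training
cases are in-domain by construction); TSAD is the sum and the in-domain
flag requires the full count (15 with the default selection).

## Interpretation (FBTD substrate)

Sensitivity values use mean substitution: SV(j) = error with input j
replaced by its training mean / full-model error, evaluated on the
training split by default (configurable); a zero full error is floored at
1/(2n) with a log message. SVs are meaningful at the rank level —
redundant inputs dilute each other's SV, which the tests assert rather
than hide. Class-based means average each selected descriptor over
correctly-classified training actives and inactives separately; the
propensity is Increase when the active mean exceeds the inactive mean,
Decrease when it is below, and an exact tie is reported as "None", never
silently either label. The guideline report renders descriptor, rank, SV
and propensity in rank order. Turning these tables into actual fragment
edits remains a human design step.

## Synthetic data generator

The generator emulates the shape of a curated ChEMBL extract for two
transporters: six conditions (four NET assay formats, two SERT), molecule
ids with canonical SMILES, IC50 in nM, and a planted log-linear activity
model. Molecules come from a scaffold + two-substituent grammar (ten
scaffolds: benzene, pyridine, pyrimidine, pyrazine, oxazole, furan,
thiophene, cyclohexane, cyclopentane, piperidine; ten substituents from
halogens to dimethylamino and amide), about 700 distinct structures.
log10 IC50 sums a scaffold effect and substituent effects per protein
(0.1–1.2 log-unit magnitudes, signs chosen so polar/bulky groups hurt and
halogen/amino groups help, with NET/SERT differing quantitatively), an
assay-format offset (±0.25–0.5), and Gaussian noise of 0.3 log units.
A global shift calibrates the active fraction at IC50 <= 150 nM to the
target, 0.5 by default — the balanced regime the cutoff is meant to
produce — which also concentrates cases near the cutoff. Each molecule is
tested under each condition with probability 0.75. Setting the effect
scale to 0 removes every planted dependence, structural and assay alike,
giving the null dataset used to check that the pipeline then performs at
chance. Because activity is planted on substructures rather than on
descriptors, recovering it genuinely exercises the descriptor →
perturbation → selection → classifier chain.

What the generator does **not** emulate: realistic medicinal-chemistry
diversity (the grammar spans ~700 small structures), inter-assay
systematic error beyond an additive offset, censored measurements
("> 10000 nM" rows), stereochemistry, or correlations between molecule
identity and condition coverage. Passing the recovery tests therefore
shows the machinery is sound, not that the model generalizes to real
screening data. A duplicate/gap injector adds rows with inflated IC50
copies and rows with blanked units or SMILES at configurable rates to
exercise the curation bookkeeping exactly.

## Sizes and determinism

Test and acceptance runs use 450 molecules (~2000 cases over the six
conditions), a 6-candidate / 300-epoch MLP search, and a 200-molecule
(<= 10 heavy atoms) random fixture for the descriptor oracle suite; these
are the package's default study sizes and complete in well under a minute
each on one core. All randomness flows through `numpy.random.default_rng`
seeded explicitly; fixed seeds give byte-identical datasets and identical
model bundles.

## Known limitations

- Descriptor values are not bit-compatible with legacy closed-source
  descriptor software; only structure-level identities are guaranteed.
- The MI estimator and the a-priori probability are documented
  conventions, pluggable but not tuned against any external reference.
- Chain (ring) chi indices count pure cycles only; ring-with-pendant
  subgraphs contribute to no order (a deliberate taxonomy choice).
- The MLP search samples topologies; it does not reproduce any specific
  commercial optimizer's retention scheme.
- Sensitivity values depend on the fitted network; across refits only
  their ranks are comparable, not their magnitudes.
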