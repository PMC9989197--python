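# Methods

## Scope and assumptions

The package operates on *pre-processed* antibody–antigen complexes:
single-model PDB files, Chothia-numbered antibody chains, explicit
heavy/light/antigen chain roles, and (for training) a K_D label per
complex.  Structure preparation — renumbering, side-chain repacking,
relaxation — is upstream and out of scope; side-chain geometry is taken
exactly as given in the input pose.  Waters, heteroatoms and
non-standard residues are excluded at parse time (non-standard residues
with a warning); a retained residue without a CA atom is an error.
Alternate locations resolve to the highest-occupancy conformer (first on
tie).  Multiple antigen chains are pooled into a single epitope
surface.  Only protein components are considered; glycan and lipid
interface chemistry is not modelled.

## Contact criterion

Two residues are potentially interacting when the distance between
their alpha carbons is strictly less than the sum of their side-chain
lengths plus an interaction distance (default 4.5 Å), the side-chain
length being the CA-to-furthest-side-chain-heavy-atom distance.
Glycine's side-chain length is 0; alanine's is its CB distance.  The
strict `<` at the boundary is a deliberate convention, as is measuring
reach on the input pose.  Contact-map computation prunes candidate
pairs with a KD-tree on CA coordinates at the largest admissible radius
and then applies the exact criterion, so it is provably identical to
the exhaustive O(n²) scan (and is tested against it).

CDR boundaries default to North definitions expressed in Chothia
positions (H1 23–35, H2 50–58, H3 93–102, L1 24–34, L2 49–56,
L3 89–97), held as an overridable constant table: boundary conventions
differ between sources, so an explicit per-chain annotation file takes
precedence when supplied.

## Feature sets

*Counting sets.*  `aa_counts` counts ordered (antibody-aa, antigen-aa)
contacts — 400 features; `aa_counts_CDR` collapses amino acids to five
chemical classes (charged R/H/K/D/E, aromatic F/Y/W, polar S/T/N/Q,
hydrophobic A/V/I/L/M, special C/G/P; histidine is charged only) and
attributes each contact to the engaging CDR — 150 features, framework
contacts excluded.  `num_multivalent` counts, per CDR, the epitope
residues it engages whose distinct-CDR count is ≥ 3 (the residue plus
at least two *additional* CDRs), and closes with the number of CDRs
having at least five such multivalent interactions (threshold
configurable).

*Ab_info.*  Six CDR lengths (residues assigned to each CDR) plus a
one-hot encoding of per-CDR canonical classes.  The class vocabulary is
learned from the dataset annotations at table-build time, with a per-CDR
`None` category for missing or failed assignments; no fixed width is
asserted because the vocabulary is a property of the dataset, not of
the method.

*Network (SIN).*  Each residue is a node; edges arise from eight
geometrically detected interaction categories (hydrogen bond,
salt bridge, disulfide, π–π, cation–π, hydrophobic, van der Waals,
backbone–backbone).  The canonical weighting of these categories is not
published alongside the aggregation schema this package implements, so
the detection rules here are an explicit, fully configurable stand-in:
each category has a distance cutoff (3.5 / 4.0 / 2.5 / 7.0 / 6.0 / 5.0 /
4.5 / 6.0 Å respectively) evaluated on CA and side-chain heavy-atom
coordinates, eligibility is gated on residue identity (e.g. salt bridge
requires an acidic–basic pair), and all default weights are 1.0.  A
residue's networking score sums the weights of its edges that cross the
antibody–antigen divide; every SIN feature is therefore exactly linear
in the weight configuration (tested).  Detection from pseudo-atom
geometry rather than full atom typing is a simplification: it cannot
distinguish donor from acceptor atoms within a side chain, so the
hydrogen-bond category is permissive.

*Statistical (AIF).*  A 20×20 propensity matrix is trained on reference
contact maps as

    score(x, y) = log2( f(x, y) / (p(x) · p(y)) )

with f the pseudocount-regularized joint frequency of ordered
(antibody-x, antigen-y) contacts and p(·) its marginals.  The published
formulation of this score is not printed with the aggregation schema,
so the log-odds definition is this package's documented choice; the
matrix is TSV round-trippable so published weights can be dropped in.
Per-residue scores are the *mean* matrix entry over a residue's contact
partners (the aggregation layer then produces both avg and total
variants).  A uniform reference yields an exactly zero matrix; an
independent-sides reference converges to zero as the reference grows —
note that with 400 cells the extreme cell of a Poisson count field
needs ≈ 500 expected counts per cell before max |score| drops below
0.2, i.e. ≳ 2×10⁵ reference contacts.

*External adapters.*  Per-residue surface-interface scores and
per-complex interface-energetics records are consumed from files (TSV /
JSON), never computed: both derive from trained models or a
macromolecular modelling suite outside this package.  The energetics
schema is fixed at 18 named fields and validated strictly.  Complexes
missing an adapter file get *masked* (not zero-filled) entries for that
set only, so runs restricted to the internally computed sets are
first-class.

The SIN, AIF and dMaSIF sets share one aggregation layer (avg + total
per CDR ×12, per CDR-epitope ×12, whole-epitope and whole-paratope
averages ×2 = 26 features), and that layer is exercised by one common
test contract.  Averages over empty sets are defined as 0 so feature
vectors are always total.

## Curation

Order: nanobody removal → heavy-chain homology filter → middle-drop-out
(MDO).  Heavy-chain identity is computed by global alignment (match 1,
mismatch 0, gap −1; identity = matches / alignment length including gap
columns), with score ties broken toward more matches so the identity of
co-optimal alignments is well-defined; the pair is canonically ordered
first, making the function symmetric.  Homology clustering is greedy in
id order against cluster representatives (threshold 0.95); each cluster
retains the member whose −log₁₀ K_D lies furthest from the dataset
median (lower id on ties).  MDO removes complexes within 1.0 log of the
median of its input set, computed before removal.  Labels: `high` iff
K_D < 1 nM, strict at the boundary.  All thresholds sit in
`CurationConfig`; disabling a filter strictly enlarges the dataset.

## Cross-validation protocol

Stratified 10-fold cross-validation (90/10) repeated 50 times with a
fresh seeded partition per repeat; medians of AUROC and F1 over the 500
fold evaluations.  The default classifier is gradient-boosted trees
with a logistic objective at library-default hyperparameters (as are
the random-forest, SVC and MLP alternatives — deliberately untuned).
F1 takes the high-affinity class as positive at a 0.5 probability
threshold.  Feature selection (ANOVA F, top k, undefined F ranked last,
ties broken by name for determinism) runs *inside* each training fold
by default; `full_data_selection` selects once on the full table,
which leaks test-fold information into selection — both modes exist so
the gap is measurable.  Importances are normalized mean gain averaged
over all fitted tree models.  Folds whose training or test partition is
single-class are skipped and counted.

**Label-randomization control.**  A single fixed permutation of ~142
labels retains a chance feature–label association of order
n^(−1/2) ≈ 0.08 which a flexible classifier partially learns: one-shot
permutation medians scatter roughly 0.43–0.57.  The control therefore
draws a fresh permutation for every repeat and takes the median over
the pooled 500 folds, which concentrates at 0.50 ± ~0.015.  The
package's chance-level tests pool across fresh permutations or fresh
null-dataset realizations for the same reason.

## Synthetic data

The generator emulates exactly the statistical structure the analysis
consumes: two antibody chains and one antigen chain of residues with CA
plus a single pseudo side-chain atom at fixed length (1.0 Å by
default), CDR assignments for six loops, and an interface realized from
an explicit *contact plan* — shared epitope sites listing the CDRs that
engage them, per-CDR private sites, and framework-contact sites.  Sites
sit on a 40 Å grid (far beyond any contact threshold); each planned
(CDR, site) incidence places one CDR residue 4.0 Å from the site's CA,
inside the threshold even for two glycines; everything else sits on
shelves > 100 Å away.  Contact counts, per-CDR counts and multivalency
values are therefore achieved *exactly* and emitted as ground truth,
and infeasible plans (more contact residues than a CDR's Chothia window
holds) fail before generation.  Affinity labels come from a logistic
model on standardized named features (default: coefficient 2 on two
multivalency features, logistic noise scale 1), and K_D values are
drawn consistent with each label as −log₁₀ K_D = 9 ± |N(0, 1.25)| —
about five logs of spread around the 1 nM class boundary, a qualitative
(not quantitative) mimic of curated affinity datasets.  A
feature-level generator (`synthetic_classification_table`, default 142
complexes × 16 standard-normal features, 2 informative) serves the
classifier-level calibration checks.

What the synthetic data does *not* emulate: realistic loop
conformations, packed protein cores, correlated amino-acid composition,
real canonical-class distributions, or any physical relation between
geometry and affinity beyond the planted model.  Passing tests
demonstrate the correctness and calibration of the machinery, not
biological performance on real structures — headline metrics on real
curated datasets additionally require the external relaxation,
surface-score and energetics inputs that are out of scope here.

## Numerical choices and problem sizes

Floating-point accumulation over identity-hashed residue sets is sorted
by (chain, number, insertion-code) so repeated runs are bit-identical.
All stochastic components (generator, planting, folds, classifiers,
permutations) derive from explicit integer seeds.  Test and acceptance
problem sizes — 142 complexes for classifier calibration, 100 random
fixtures for oracle-equivalence sweeps, 5–40 complexes for end-to-end
smoke runs, 500 pooled fold evaluations for chance-level checks — were
chosen as the smallest sizes at which each property is
statistically decided.  The signal-recovery check plants coefficient 3:
under the planting model the Bayes-optimal AUROC at coefficient 2 is
≈ 0.91 (simulated), leaving no headroom for a finite-sample classifier
above a 0.90 bar, while coefficient 3 gives a Bayes optimum ≈ 0.95.

## Known limitations

- SIN detection rules and the AIF formula are documented stand-ins for
  unpublished formulations; both are configurable/overridable so
  published parameterizations can be substituted.
- The hydrogen-bond and van der Waals categories are permissive without
  full atom typing.
- Identity filtering uses the full heavy-chain sequence as supplied;
  restricting to the variable domain is the caller's responsibility.
- Canonical-class assignment and per-residue surface scores are
  consumed as annotations; no assignment tool is run.
- Probabilities are not calibrated; no hyperparameter search is
  performed by design.
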