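# Methods

This note documents the models, conventions and design choices behind
`dtiforge`, in the spirit of a statistical package's methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Pair representation

A drug–target pair is represented by concatenating the drug's chemical
descriptor block and the target's protein descriptor block into one vector.
This joint-space encoding means one classifier sees both partners at once and
can, in principle, transfer information across protein families via ligand
similarity and across scaffolds via target similarity. Its known cost is that
chemical and biological similarity cannot be tuned separately (as a
tensor-product kernel would allow); we accept that trade-off for simplicity
and learner-agnosticism.

## Protein descriptors (default profile, 1080 dimensions)

| family | dims | parameters |
|---|---|---|
| amino acid composition (AAC) | 20 | — |
| dipeptide composition (DPC) | 400 | — |
| normalized Moreau–Broto autocorrelation | 240 | 8 scales × 30 lags |
| composition/transition/distribution (CTD) | 147 | 7 attributes × 3 groups |
| sequence-order coupling (SOC) | 60 | 2 matrices × 30 lags |
| quasi-sequence-order (QSO) | 100 | 2 × (20 + 30), weight 0.1 |
| amphiphilic pseudo-AAC (APAAC) | 80 | λ = 30, weight 0.05 |
| averaged amino-acid properties | 33 | standardized scales |

Conventions that had to be fixed for testability:

* **Property scales.** All lag/correlation families standardize their scale
  to zero mean and unit variance over the 20 residues (population standard
  deviation) before use. The 8 autocorrelation scales are standard published
  tables (Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity,
  Bhaskaran–Ponnuswamy flexibility, Charton–Charton polarizability and free
  energy, Chothia accessible surface area, Bigelow volume, Dayhoff
  mutability). APAAC uses the Eisenberg hydrophobicity / Hopp–Woods
  hydrophilicity pair conventional for pseudo-amino-acid composition.
* **Zero-variance profiles** (e.g. homopolymers) make the Moran and Geary
  forms 0/0; the result is defined as 0, guarded by an epsilon of 1e−12 on
  the profile variance to absorb float residue.
* **CTD groups** are the standard three-group partitions of the alphabet by
  hydrophobicity, van der Waals volume, polarity, polarizability, charge,
  secondary-structure propensity and solvent accessibility. Transition counts
  are unordered adjacent group pairs over L−1 positions. Distribution reports
  the 1-based positions of the first and the ⌈q·n⌉-th occurrence
  (q = 25/50/75/100 %) of each group as a percentage of L; an absent group
  contributes zeros.
* **Distance matrices for SOC/QSO.** A Grantham-style chemical distance
  built from Grantham's composition/polarity/volume components with his
  weights, and a physicochemical distance (Euclidean over standardized
  hydrophobicity, hydrophilicity and residue volume). Both are max-normalized
  to [0, 1]; QSO's own denominators make the overall matrix scale immaterial.
  The exact matrices used by the historical web servers are not recoverable;
  these are documented reconstructions, versioned via the profile.
* **The 33 averaged properties** are the 8 autocorrelation scales, the two
  APAAC scales, residue molecular weight, isoelectric point, and the 21
  binary CTD group-membership indicators — each standardized, then averaged
  over the sequence.
* **Sequence admission.** Nonstandard residues (B, J, O, U, X, Z, `*`) are a
  hard error naming the residue and position; with `--sanitize` they are
  stripped with a logged warning. The default profile requires length ≥ 31
  (maxlag + 1); shorter sequences are rejected, mirroring the omission of
  uncomputable entries during catalog curation.

Any profile must declare its expected total, which is checked against the
computed family sum, so a profile cannot silently drift from its advertised
dimensionality.

## Chemical descriptors

The battery is the RDKit 2D descriptor list (~210 descriptors:
constitutional counts, topological indices, VSA/BCUT-style surfaces,
physicochemical estimates). The framework is descriptor-set agnostic — any
externally computed matrix in the canonical TSV format can be supplied —
so descriptor counts from proprietary tools are not reproduction targets.
Curation drops, in order: descriptors incomputable (or non-finite) for at
least one molecule; constant descriptors; near-constant descriptors (modal
fraction ≥ 0.95, a default the source protocol leaves unstated). Curation is
idempotent and order-preserving. Salts and mixtures keep their largest
covalent fragment, logged.

## Dataset assembly, scaling and splits

Negatives are drawn uniformly without replacement from the non-interaction
space, by default as many as there are positives (class balance). For small
requests a rejection sampler over a positives hash avoids materializing the
cross product; dense requests enumerate the complement. Both paths are
uniform over the same support and seeded.

Feature scaling maps each feature's training range [min, max] linearly to
[−1, 1]; constant features map to 0; transformed test data may leave [−1, 1]
(no clipping). The default fits ranges on the training set only, to avoid
test-information leakage; `mode="joint"` reproduces the literal
all-data-at-once protocol for comparison.

Scenario I is a plain random split. Scenarios II and III start from a random
initial split and move samples from the initial test set into training —
II moves known-drug *or* new-target samples (leaving new-drug/known-target
tests), III the mirror image. The movement is iterated to a fixed point:
moved samples can introduce new entities into the training side, and a
single pass against the initial entity sets can leave test samples that
violate the scenario predicate against the final training set. Scenario IV
deletes from the initial test every sample whose drug or target is known;
the training set is left unchanged (one pass is exact). Scenario IV can be
empty on small or dense catalogs; the error advises a larger test fraction.

## Learners

* **Random forest:** 500 unpruned trees on bootstrap samples, mtry = ⌊√M⌋
  candidate features per node, delegated to scikit-learn with a fixed seed
  and single-threaded execution for determinism. The binding score is the
  fraction of trees voting interaction — granularity 1/ntree, threshold 0.5 =
  majority vote. (A score defined as the raw vote *ratio* +1/−1 votes is
  exposed as `vote_ratio` but is unbounded; the fraction-of-total form is
  what keeps published per-pair scores on a [0, 1] grid with 0.002 steps at
  500 trees.) Ties at the threshold classify positive — arbitrary but fixed
  and tested. No feature selection is applied before the forest.
* **RBF-SVM:** soft margin, (C, γ) chosen by 5-fold stratified
  cross-validated accuracy over C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} (exponent
  step 2 — the conventional grid; the choice of ranges is a package
  default). Ties break to the smallest C, then the smallest γ, making the
  search invariant to grid ordering. For screening, SVM decision values are
  squashed through a logistic so all score tables live on a common [0, 1]
  scale; ranking metrics use the raw decision value.

`DTIModel.fit()` returns a `DTIResults` object holding the fitted estimator,
the scaling ranges and the training entity-id sets, so "known vs new" status
of any screened entity is always resolved against the model that scored it.

## Evaluation

SE, SP and CO are reported as percentages; a metric whose denominator class
is absent is NA (never 0), and fold averages skip NA with a logged count.
ROC curves group tied scores (one vertex per unique score); the trapezoid
AUC therefore equals the Mann–Whitney statistic with midranks, which the
test suite verifies against an independent rank-sum oracle. AUC is reported
on the 0–100 scale (100 perfect, 50 random). Cross-validation is stratified
by label so both classes appear in every fold; when k exceeds the smallest
class count (leave-one-out), plain K-fold is used instead. PCA standardizes
features by default because descriptor units are incommensurable. The
applicability domain is the per-feature training min–max box; out-of-domain
queries report their offending features by name.

## Screening and network topology

Screening scores the full drug × target cross product in fixed-size blocks
(output independent of block size) and sorts by (score desc, drug id,
target id) — the documented deterministic tie rule, also used at the top-N
cutoff. Scores are rounded to 3 decimals only at presentation. Topology
statistics follow the network-analyzer convention: degree centralization
(n/(n−2))·(k_max/(n−1) − density) and heterogeneity √var(k)/mean(k)
(population variance; the convention was fixed here because published values
alone cannot disambiguate it). Both are computed on the bipartite graph as a
whole. Ligand clustering standardizes descriptors, uses Euclidean/Ward
linkage, cuts at k = 4 by default (or at a height), and canonicalizes
cluster labels by the smallest member id after sorting rows by id, making
assignments stable under row permutation; dendrograms export as Newick.

## Synthetic data: what it emulates and what it does not

The generator plants a latent rule
s(d, t) = w_d·x_d + w_t·x_t + c·(x_d A x_t) with sparse weights (8 active
descriptors per side — in real descriptor sets only a minority of dimensions
carry binding signal) and a rank-2 bilinear coupling (strength 0.5) so that
drug–target compatibility is not additively separable and cold-start
prediction is possible but harder. Pairs above the (1 − density) quantile of
s are true interactions.

**Label noise** emulates catalog errors: each true interaction is dropped
with probability p and spurious ones are added at the rate p·n_true/n_false,
keeping the catalog near the requested density with ~(1−p) purity. A
symmetric per-pair flip would instead make spurious positives rival true
ones in number (the non-interaction space is an order of magnitude larger),
which no curated catalog resembles and which would cap achievable ranking
quality well below what a 5 %-noise catalog supports.

The default desk-scale fixture is 60 drugs × 60 targets, density 0.08,
noise 0.05, seed 17 (vector mode: Gaussian descriptor blocks of 50 and 60
dimensions; structure mode generates valid SMILES from a fragment grammar
and random sequences of length 50–500 and runs the real featurizers). The
**cold-start ordering experiment** uses sparser worlds — 300 drugs × 150
targets at density 0.007, i.e. about two known pairs per drug and four per
target, the sparsity regime of real interaction catalogs — with a 0.5 test
fraction, because cold-start splits are only constructible when entities can
fall wholly into the held-out side, and entity-sparse catalogs keep the
scenario training sets comparable in size so the comparison measures
cold-start difficulty rather than training-set volume. Test scores are
pooled across the 10 world seeds before the ROC is computed, since a single
scenario-IV test set is small and can be single-class. The **permutation
null** permutes scenario-I training labels and scores the full dataset
against the true labels, averaged over 3 permutation replicates — a single
small held-out test set would put several AUC points of pure sampling spread
on an expectation of 50.

What passing these tests shows: the pipeline wiring, the featurization
math, the split semantics and the learners' ability to recover a planted
feature-based signal at realistic noise. What it does not show: performance
on real catalogs — synthetic descriptor blocks are Gaussian rather than
heavy-tailed and collinear, the planted rule is feature-based (a perfect
learner would suffer no cold-start penalty at all; the observed penalty is
an estimation effect), and the degree distribution is not matched to any
real database.

## Problem sizes and numerical choices

Tests run on desk-scale problems: 60×60 worlds for recovery checks, 300×150
for the ordering experiment, 500-tree forests, ~110-dimensional pair
vectors. Tolerances: descriptor oracles at 1e−9; scaling round trip 1e−9;
profile standardization 1e−9. All randomness flows from explicit seeds;
pipeline stages derive their seeds as sha256(root:stage) mod 2³¹, so stages
are decoupled but reproducible, and a pipeline rerun with the same config
reproduces its metrics report byte-identically.

## Known limitations

* Protein property scales and distance matrices are reconstructions of the
  standard families, not bit-compatible with any historical web server.
* The chemical battery is whatever the installed RDKit provides; matrices
  computed elsewhere can be substituted via TSV but are not validated
  chemically.
* SVM screening scores are logistic-squashed decision values, not calibrated
  probabilities.
* Scenario II/III movement inflates the training set relative to scenario I
  on dense catalogs; cold-start comparisons are only meaningful on
  entity-sparse catalogs (see above).
* The bipartite network treats interactions as undirected and unweighted
  beyond the score attribute; no multi-edge or affinity-value support.
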